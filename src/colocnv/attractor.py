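"""Genomically co-localized attractor metagene discovery.

Each gene seeds an iteration restricted to its genomic window (the nearest
``window_size`` genes by midpoint order, half on each side, truncated at
chromosome boundaries).  The iteration alternates between (a) scoring every
window gene's pan-cancer association with the current metagene and (b)
rebuilding each cohort's metagene as the expression average weighted by
``max(weight, 0) ** exponent``.  A converged fixed point is a co-expression
signature; its strength is the fifth-highest gene weight, so surviving
signatures contain at least five strongly co-expressed genes.

Discovery runs in two passes: every gene seeds once, surviving signatures'
chromosomal ranges are merged into clusters, and each cluster is re-seeded
from all its member genes to pick a single representative.  Final filters
remove signatures dominated by unexpressed genes and the gender-driven
signatures on chromosomes X and Y.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    bspline_memberships,
    mi_profile_t,
    self_information,
    self_information_profile,
    weighted_median_axis,
)
from .config import AssociationConfig, AttractorConfig
from .io_preprocess import SEX_CHROMOSOMES, CohortSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# caches


@dataclass
class _CohortCache:
    name: str
    expr: np.ndarray  # (G, n) normalized expression
    memberships_t: np.ndarray  # (G, n_bins, n), C-contiguous for fast joints
    marginals: np.ndarray  # (G, n_bins) mean memberships
    self_mi: np.ndarray  # (G,)
    centered: np.ndarray  # (G, n) row-centered expression, for Pearson signs


@dataclass
class GenomeCaches:
    """Per-cohort B-spline memberships and self-MI for every gene, built once."""

    genes: pd.Index
    chromosomes: np.ndarray
    cohorts: list[_CohortCache]
    weights: np.ndarray

    def chromosome_span(self, chrom: str) -> tuple[int, int]:
        """[lo, hi) global index span of a chromosome (annotation is sorted)."""
        idx = np.flatnonzero(self.chromosomes == chrom)
        return int(idx[0]), int(idx[-1]) + 1


def build_caches(
    cohort_set: CohortSet, assoc_cfg: AssociationConfig = AssociationConfig()
) -> GenomeCaches:
    genes = cohort_set.annotation.index
    n_genes = len(genes)
    caches = []
    for cohort in cohort_set.cohorts:
        expr = cohort.expression.to_numpy(dtype=float)
        n = expr.shape[1]
        memb = np.zeros((n_genes, n, assoc_cfg.n_bins), dtype=float)
        for g in range(n_genes):
            b = bspline_memberships(expr[g], assoc_cfg)
            if b is not None:
                memb[g] = b
        self_mi = self_information_profile(memb)
        centered = expr - expr.mean(axis=1, keepdims=True)
        caches.append(
            _CohortCache(
                name=cohort.name,
                expr=expr,
                memberships_t=np.ascontiguousarray(memb.transpose(0, 2, 1)),
                marginals=memb.mean(axis=1),
                self_mi=self_mi,
                centered=centered,
            )
        )
    return GenomeCaches(
        genes=genes,
        chromosomes=cohort_set.annotation["chromosome"].to_numpy(),
        cohorts=caches,
        weights=cohort_set.weights,
    )


# ---------------------------------------------------------------------------
# signature


@dataclass
class AttractorSignature:
    """A converged co-expression signature over a window of adjacent genes."""

    name: str
    seed: str
    chromosome: str
    window_genes: list[str]
    weights: np.ndarray  # aligned to window_genes, signed associations in [-1, 1]
    strength: float
    converged: bool
    degenerate: bool = False
    range_span: Optional[tuple[int, int]] = None  # global [first, last] gene positions
    range_genes: Optional[tuple[str, str]] = None
    metagene: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def ordered_genes(self) -> list[str]:
        """Window genes by descending weight (ties keep genomic order)."""
        order = np.argsort(-self.weights, kind="stable")
        return [self.window_genes[i] for i in order]

    def top_genes(self, k: int = 5) -> list[str]:
        return self.ordered_genes()[:k]

    def member_genes(self, threshold: float = 0.5) -> list[str]:
        return [g for g, w in zip(self.window_genes, self.weights) if w > threshold]


def window_bounds(position: int, n_genes: int, window_size: int) -> tuple[int, int]:
    """Inclusive window [lo, hi] around an ordered position on one chromosome."""
    half = window_size // 2
    return max(0, position - half), min(n_genes - 1, position + half)


def iterate_attractor(
    seed_pos: int,
    window: np.ndarray,
    caches: GenomeCaches,
    cfg: AttractorConfig = AttractorConfig(),
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> AttractorSignature:
    """Run the attractor iteration from one seed over a fixed gene window.

    ``seed_pos`` and ``window`` are global annotation positions; the window
    must contain the seed.  The reported per-gene weight is the signed
    pan-cancer association between the gene and the converged metagene.
    The algorithm is deterministic: identical inputs give identical weights.
    """
    window = np.asarray(window, dtype=int)
    in_window = np.flatnonzero(window == seed_pos)
    if in_window.size == 0:
        raise ValueError("seed gene must lie inside its window")
    g = window.size
    # contiguous windows (the normal case) slice as zero-copy views
    if np.array_equal(window, np.arange(window[0], window[-1] + 1)):
        sel: slice | np.ndarray = slice(int(window[0]), int(window[-1]) + 1)
    else:
        sel = window
    per_cohort = []
    for cache in caches.cohorts:
        per_cohort.append(
            (
                cache.expr[sel],
                cache.memberships_t[sel],
                cache.marginals[sel],
                cache.self_mi[sel],
                cache.centered[sel],
            )
        )
    w = np.zeros(g)
    w[in_window[0]] = 1.0
    converged = False
    degenerate = False
    assoc = np.zeros((len(per_cohort), g))
    for _ in range(cfg.max_iterations):
        mix = np.maximum(w, 0.0) ** cfg.exponent
        total = mix.sum()
        if total <= 0:
            degenerate = True
            break
        mix /= total
        for c, (expr, memb_t, marg, self_mi, centered) in enumerate(per_cohort):
            m = mix @ expr
            bm = bspline_memberships(m, assoc_cfg)
            if bm is None:
                assoc[c] = 0.0
                continue
            self_m = self_information(bm)
            denom = np.maximum(self_mi, self_m)
            mis = mi_profile_t(memb_t, marg, bm)
            a = np.where(
                denom > 0,
                np.minimum(mis / np.where(denom > 0, denom, 1.0), 1.0),
                0.0,
            )
            sign = centered @ (m - m.mean())
            a = np.where(sign < 0, -a, a)
            assoc[c] = a
        w_new = weighted_median_axis(assoc, caches.weights)
        if np.max(np.abs(w_new - w)) < cfg.convergence_eps:
            w = w_new
            converged = True
            break
        w = w_new
    if degenerate or (not converged and not np.any(w > 0)):
        degenerate = True
        strength = 0.0
    order = np.argsort(-w, kind="stable")
    name_idx = int(order[0])
    if not degenerate:
        strength = float(w[order[min(4, g - 1)]])
    members = np.flatnonzero(w > cfg.range_weight_threshold)
    if members.size == 0 and not degenerate:
        members = order[: min(5, g)]
        members = np.sort(members)
    range_span = (
        (int(window[members.min()]), int(window[members.max()]))
        if members.size
        else None
    )
    mix = np.maximum(w, 0.0) ** cfg.exponent
    metagene = {}
    if mix.sum() > 0:
        mix = mix / mix.sum()
        for cache, (expr, *_rest) in zip(caches.cohorts, per_cohort):
            metagene[cache.name] = mix @ expr
    genes = caches.genes
    return AttractorSignature(
        name=str(genes[window[name_idx]]),
        seed=str(genes[seed_pos]),
        chromosome=str(caches.chromosomes[seed_pos]),
        window_genes=[str(genes[i]) for i in window],
        weights=w,
        strength=strength,
        converged=converged,
        degenerate=degenerate,
        range_span=range_span,
        range_genes=(
            (str(genes[range_span[0]]), str(genes[range_span[1]]))
            if range_span
            else None
        ),
        metagene=metagene,
    )


def _same_attractor(a: AttractorSignature, b: AttractorSignature, tol: float = 1e-4) -> bool:
    """Identity for deduplication: same name gene, weights within tol on shared genes."""
    if a.name != b.name:
        return False
    wa = dict(zip(a.window_genes, a.weights))
    wb = dict(zip(b.window_genes, b.weights))
    shared = set(wa) & set(wb)
    if not shared:
        return False
    return max(abs(wa[g] - wb[g]) for g in shared) < tol


def first_pass(
    caches: GenomeCaches,
    cfg: AttractorConfig = AttractorConfig(),
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> list[AttractorSignature]:
    """Seed every gene; keep deduplicated signatures with strength >= threshold.

    Windows never cross chromosome boundaries: at chromosome ends the window
    simply truncates.
    """
    survivors: list[AttractorSignature] = []
    n_nonconverged = 0
    for chrom in pd.unique(pd.Series(caches.chromosomes)):
        lo, hi = caches.chromosome_span(chrom)
        n_chrom = hi - lo
        for k in range(n_chrom):
            w_lo, w_hi = window_bounds(k, n_chrom, cfg.window_size)
            window = np.arange(lo + w_lo, lo + w_hi + 1)
            sig = iterate_attractor(lo + k, window, caches, cfg, assoc_cfg)
            if not sig.converged and not sig.degenerate:
                n_nonconverged += 1
            if sig.degenerate or sig.strength < cfg.strength_threshold:
                continue
            if any(_same_attractor(sig, s) for s in survivors):
                continue
            survivors.append(sig)
    if n_nonconverged:
        log.warning("%d seeds did not converge within max_iterations", n_nonconverged)
    log.info("first pass: %d distinct signatures above strength threshold", len(survivors))
    return survivors


@dataclass
class RangeCluster:
    chromosome: str
    span: tuple[int, int]  # global gene positions, inclusive
    members: list[AttractorSignature]


def merge_ranges(signatures: Sequence[AttractorSignature]) -> list[RangeCluster]:
    """Transitive closure of chromosomal-range overlap, per chromosome.

    Each cluster's span is the union of its members' ranges (min first gene,
    max last gene).
    """
    with_range = [s for s in signatures if s.range_span is not None]
    clusters: list[RangeCluster] = []
    by_chrom: dict[str, list[AttractorSignature]] = {}
    for s in with_range:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom, sigs in by_chrom.items():
        sigs = sorted(sigs, key=lambda s: s.range_span)
        current: Optional[RangeCluster] = None
        for s in sigs:
            lo, hi = s.range_span
            if current is not None and lo <= current.span[1]:
                current.span = (current.span[0], max(current.span[1], hi))
                current.members.append(s)
            else:
                current = RangeCluster(chromosome=chrom, span=(lo, hi), members=[s])
                clusters.append(current)
    return clusters


def second_pass(
    clusters: Sequence[RangeCluster],
    caches: GenomeCaches,
    cfg: AttractorConfig = AttractorConfig(),
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> list[AttractorSignature]:
    """Re-seed each cluster from all its member genes; keep one representative.

    The iteration considers only genes inside the cluster's span.  The
    representative is the highest-strength converged attractor, ties broken
    by the leftmost seed; clusters where every run is degenerate are dropped
    with a warning.
    """
    out = []
    for cluster in clusters:
        lo, hi = cluster.span
        window = np.arange(lo, hi + 1)
        best: Optional[AttractorSignature] = None
        for seed in window:
            sig = iterate_attractor(int(seed), window, caches, cfg, assoc_cfg)
            if sig.degenerate or not sig.converged:
                continue
            if best is None or sig.strength > best.strength:
                best = sig
        if best is None:
            warnings.warn(
                f"cluster {cluster.chromosome}:{cluster.span} yielded no "
                "converged attractor; dropped"
            )
            continue
        out.append(best)
    log.info("second pass: %d representative signatures", len(out))
    return out


def final_filters(
    signatures: Sequence[AttractorSignature],
    cohort_set: CohortSet,
    top_k: int = 5,
) -> list[AttractorSignature]:
    """Drop signatures with unexpressed top genes and sex-chromosome signatures.

    A signature is removed iff any of its top ``top_k`` genes has raw
    expression 0 in more than half of all tumor samples pooled across
    cohorts, or its range lies on chromosome X or Y.
    """
    raw = pd.concat([c.raw_expression for c in cohort_set.cohorts], axis=1)
    zero_frac = (raw == 0).sum(axis=1) / raw.shape[1]
    kept = []
    for sig in signatures:
        if sig.chromosome in SEX_CHROMOSOMES:
            log.info("signature %s removed: sex chromosome", sig.name)
            continue
        if any(zero_frac.get(g, 0.0) > 0.5 for g in sig.top_genes(top_k)):
            log.info("signature %s removed: top gene mostly unexpressed", sig.name)
            continue
        kept.append(sig)
    return kept


def discover_signatures(
    cohort_set: CohortSet,
    cfg: AttractorConfig = AttractorConfig(),
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> list[AttractorSignature]:
    """Full discovery: first pass, range merging, second pass, final filters."""
    caches = build_caches(cohort_set, assoc_cfg)
    sigs = first_pass(caches, cfg, assoc_cfg)
    clusters = merge_ranges(sigs)
    log.info("merged into %d range clusters", len(clusters))
    reps = second_pass(clusters, caches, cfg, assoc_cfg)
    return final_filters(reps, cohort_set)
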