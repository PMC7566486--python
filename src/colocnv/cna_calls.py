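"""Driver designation: expression/CNA association and frequency classification.

A signature's expression level and CNA level in each sample are the means
over its top five genes.  Two conditions make a driver:

* the pan-cancer expression/CNA association is significant under a
  permutation null (CNA levels sample-permuted within each cohort; each
  cohort's null sorted ascending and aggregated rank-by-rank with the
  weighted median; Bonferroni over the tested signatures), and
* the signature's region is frequently altered: per-cohort amplification
  (deletion) frequency strictly above ``t_freq`` in strictly more than
  ``min_types`` cohorts, with the amplitude thresholds t_amp/t_del derived
  from the per-sample-centered CNA of normal samples (mean of the top /
  bottom decile, aggregated by weighted median across cohorts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .association import (
    bspline_memberships,
    mi_profile,
    pan_cancer_association,
    self_information,
    weighted_median,
    weighted_median_axis,
)
from .attractor import AttractorSignature
from .config import AssociationConfig, CallConfig
from .io_preprocess import CohortSet

log = logging.getLogger(__name__)

_PERMUTATION_CHUNK = 2000


@dataclass
class SignatureLevels:
    """Per-cohort signature-level expression and CNA vectors."""

    expr: dict[str, np.ndarray]
    cna: dict[str, np.ndarray]


@dataclass
class SignatureCall:
    signature: AttractorSignature
    levels: SignatureLevels = field(repr=False)
    assoc: float = np.nan
    p_raw: float = np.nan
    p_bonferroni: float = np.nan
    amp_freq: dict[str, float] = field(default_factory=dict)
    del_freq: dict[str, float] = field(default_factory=dict)
    n_types_amp: int = 0
    n_types_del: int = 0
    is_pan_amp: bool = False
    is_pan_del: bool = False
    is_driver: bool = False

    @property
    def direction(self) -> str:
        if self.is_pan_amp:
            return "amp"
        if self.is_pan_del:
            return "del"
        return "none"


def signature_levels(
    sig: AttractorSignature, cohort_set: CohortSet, top_k: int = 5
) -> SignatureLevels:
    """Unweighted mean over the top-k genes' rows, per cohort and matrix."""
    genes = sig.top_genes(top_k)
    expr, cna = {}, {}
    for cohort in cohort_set.cohorts:
        for g in genes:
            if g not in cohort.cna.index:
                raise KeyError(
                    f"top gene {g} of signature {sig.name} missing from CNA matrix "
                    f"of cohort {cohort.name}"
                )
        expr[cohort.name] = cohort.expression.loc[genes].to_numpy().mean(axis=0)
        cna[cohort.name] = cohort.cna.loc[genes].to_numpy().mean(axis=0)
    return SignatureLevels(expr=expr, cna=cna)


def _null_associations(
    expr: np.ndarray,
    cna: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    assoc_cfg: AssociationConfig,
) -> np.ndarray:
    """Normalized associations between expr and sample-permuted cna."""
    n = expr.size
    be = bspline_memberships(expr, assoc_cfg)
    bc = bspline_memberships(cna, assoc_cfg)
    if be is None or bc is None:
        return np.zeros(n_permutations)
    denom = max(self_information(be), self_information(bc))
    if denom <= 0:
        return np.zeros(n_permutations)
    ze = expr - expr.mean()
    zc = cna - cna.mean()
    out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        r = min(_PERMUTATION_CHUNK, n_permutations - done)
        perms = np.argsort(rng.random((r, n)), axis=1)
        bperm = bc[perms]  # (r, n, n_bins)
        mis = mi_profile(bperm, be)
        vals = np.minimum(mis / denom, 1.0)
        signs = zc[perms] @ ze
        out[done : done + r] = np.where(signs < 0, -vals, vals)
        done += r
    return out


def permutation_test(
    levels: SignatureLevels,
    weights: Sequence[float],
    cfg: CallConfig,
    assoc_cfg: AssociationConfig = AssociationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Observed pan-cancer association and its permutation P value.

    Per cohort, ``n_permutations`` associations between the expression level
    and a permuted CNA level form the cohort null; nulls are sorted and
    combined rank-by-rank with the weighted median.  The P value uses the
    add-one estimator (count + 1) / (n + 1) so it can never be exactly 0.
    """
    if cfg.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    names = list(levels.expr)
    pairs = [(levels.expr[c], levels.cna[c]) for c in names]
    observed = pan_cancer_association(pairs, weights, assoc_cfg)
    nulls = np.empty((len(names), cfg.n_permutations))
    for i, c in enumerate(names):
        nulls[i] = np.sort(
            _null_associations(
                levels.expr[c], levels.cna[c], cfg.n_permutations, rng, assoc_cfg
            )
        )
    pan_null = weighted_median_axis(nulls, np.asarray(weights, dtype=float))
    count = int(np.sum(pan_null > observed))
    p_raw = (count + 1) / (cfg.n_permutations + 1)
    return observed, p_raw


def derive_thresholds(
    cohort_set: CohortSet, cfg: CallConfig
) -> tuple[float, float]:
    """Amplification/deletion thresholds from normal-sample CNA.

    Each normal sample's gene-level CNA vector is centered by its own mean;
    per cohort, the centered values of all normal samples are pooled and
    t_amp|c (t_del|c) is the mean of the values at or above (below) the
    90th (10th) percentile.  Cohorts are aggregated by weighted median;
    cohorts without normals are excluded with a warning.
    """
    t_amp_c, t_del_c, kept_w = [], [], []
    for cohort, w in zip(cohort_set.cohorts, cohort_set.weights):
        if cohort.normal_cna is None or cohort.normal_cna.shape[1] == 0:
            warnings.warn(f"cohort {cohort.name} has no normal samples; excluded")
            continue
        values = cohort.normal_cna.to_numpy(dtype=float)
        centered = values - values.mean(axis=0, keepdims=True)
        pool = centered.ravel()
        hi = np.percentile(pool, 100 - cfg.percentile)
        lo = np.percentile(pool, cfg.percentile)
        t_amp_c.append(float(pool[pool >= hi].mean()))
        t_del_c.append(float(pool[pool <= lo].mean()))
        kept_w.append(w)
    if not kept_w:
        raise ValueError(
            "no cohort has normal samples; supply t_amp/t_del in the config"
        )
    t_amp = weighted_median(t_amp_c, kept_w)
    t_del = weighted_median(t_del_c, kept_w)
    if abs(t_amp) < 1e-12 and abs(t_del) < 1e-12:
        warnings.warn("degenerate thresholds t_amp = t_del = 0 (constant normal CNA)")
        return 0.0, 0.0
    return t_amp, t_del


def classify_frequencies(
    call: SignatureCall,
    thresholds: tuple[float, float],
    cfg: CallConfig,
) -> SignatureCall:
    """Per-cohort alteration frequencies and the pan-cancer frequency rule.

    All comparisons are strict: a sample is amplified iff its CNA level is
    strictly above t_amp; a cohort counts iff its frequency is strictly
    above t_freq; pan-cancer requires strictly more than ``min_types``
    qualifying cohorts.
    """
    t_amp, t_del = thresholds
    for name, cna in call.levels.cna.items():
        n = cna.size
        call.amp_freq[name] = float(np.sum(cna > t_amp)) / n
        call.del_freq[name] = float(np.sum(cna < t_del)) / n
    call.n_types_amp = sum(1 for f in call.amp_freq.values() if f > cfg.t_freq)
    call.n_types_del = sum(1 for f in call.del_freq.values() if f > cfg.t_freq)
    call.is_pan_amp = call.n_types_amp > cfg.min_types
    call.is_pan_del = call.n_types_del > cfg.min_types
    return call


def co_alteration(
    call_a: SignatureCall,
    call_b: SignatureCall,
    weights: Sequence[float],
    thresholds: tuple[float, float],
    cfg: CallConfig,
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> tuple[Optional[float], float]:
    """Co-alteration frequency of two adjacent same-direction signatures.

    Among tumor samples where at least one signature is altered beyond the
    relevant threshold, a sample is co-altered iff the two CNA levels differ
    by strictly less than ``co_cna_diff``.  Also returns the pan-cancer
    association of the two expression levels.  Returns (None, assoc) when no
    sample is altered.
    """
    t_amp, t_del = thresholds
    direction = call_a.direction
    if direction == "none" or call_b.direction != direction:
        raise ValueError("signatures must be called in the same direction")
    altered_total = 0
    co_total = 0
    for name in call_a.levels.cna:
        la = call_a.levels.cna[name]
        lb = call_b.levels.cna[name]
        if direction == "amp":
            altered = (la > t_amp) | (lb > t_amp)
        else:
            altered = (la < t_del) | (lb < t_del)
        co = altered & (np.abs(la - lb) < cfg.co_cna_diff)
        altered_total += int(altered.sum())
        co_total += int(co.sum())
    expr_assoc = pan_cancer_association(
        [
            (call_a.levels.expr[c], call_b.levels.expr[c])
            for c in call_a.levels.expr
        ],
        weights,
        assoc_cfg,
    )
    if altered_total == 0:
        return None, expr_assoc
    return co_total / altered_total, expr_assoc


def designate_drivers(
    calls: Sequence[SignatureCall], cfg: CallConfig
) -> list[SignatureCall]:
    """Bonferroni-correct the permutation P values and apply the dual rule.

    A driver must have p_bonferroni < alpha AND be located on a pan-cancer
    amplicon or deleted region.  The multiplier is the number of signatures
    entering the test.
    """
    m = len(calls)
    for call in calls:
        call.p_bonferroni = min(1.0, call.p_raw * m)
        call.is_driver = call.p_bonferroni < cfg.alpha and (
            call.is_pan_amp or call.is_pan_del
        )
    return list(calls)


def call_signatures(
    signatures: Sequence[AttractorSignature],
    cohort_set: CohortSet,
    cfg: CallConfig,
    assoc_cfg: AssociationConfig = AssociationConfig(),
) -> tuple[list[SignatureCall], tuple[float, float]]:
    """End-to-end calling: levels, permutation test, thresholds, frequencies.

    Thresholds come from normal samples when available, otherwise from the
    config overrides.  Returns the calls (with driver status) and the
    (t_amp, t_del) pair actually used.
    """
    if cfg.t_amp is not None and cfg.t_del is not None:
        thresholds = (cfg.t_amp, cfg.t_del)
        log.info("using configured thresholds t_amp=%.3f t_del=%.3f", *thresholds)
    else:
        thresholds = derive_thresholds(cohort_set, cfg)
        log.info("derived thresholds t_amp=%.3f t_del=%.3f", *thresholds)
    weights = cohort_set.weights
    rng = np.random.default_rng(cfg.rng_seed)
    calls = []
    for sig in signatures:
        levels = signature_levels(sig, cohort_set, cfg.top_k)
        assoc, p_raw = permutation_test(levels, weights, cfg, assoc_cfg, rng)
        call = SignatureCall(signature=sig, levels=levels, assoc=assoc, p_raw=p_raw)
        classify_frequencies(call, thresholds, cfg)
        calls.append(call)
    designate_drivers(calls, cfg)
    n_assoc = sum(1 for c in calls if c.p_bonferroni < cfg.alpha)
    n_freq = sum(1 for c in calls if c.is_pan_amp or c.is_pan_del)
    n_driver = sum(1 for c in calls if c.is_driver)
    log.info(
        "calls: %d signatures, %d association-passing, %d frequency-passing, %d drivers",
        len(calls),
        n_assoc,
        n_freq,
        n_driver,
    )
    return calls, thresholds
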