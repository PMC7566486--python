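"""Signed, normalized B-spline mutual-information association.

The association between two sample-indexed vectors is estimated as

    assoc(a, b) = sign(pearson(a, b)) * I(a; b) / max(I(a; a), I(b; b))

where ``I`` is a B-spline mutual-information estimate: each observation is
soft-assigned to ``n_bins`` bins through B-spline basis functions of the
configured order (order 1 recovers classical hard binning), the joint and
marginal probabilities are the mean basis weights, and the MI is the usual
plug-in sum in nats.  Dividing by the larger self-information maps the
estimate into [0, 1]; the Pearson sign extends it to [-1, 1].  A constant
vector carries no information, so any association involving one is 0.

Per-cohort associations are aggregated into a pan-cancer value with a lower
weighted median, the weights being each cohort's share of tumor samples.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline

from .config import AssociationConfig

DEFAULT_CONFIG = AssociationConfig()

#: cohorts with fewer samples than this are excluded from pan-cancer medians
MIN_COHORT_SAMPLES = 8

_EPS = 1e-300


def bspline_memberships(
    x: np.ndarray,
    cfg: AssociationConfig = DEFAULT_CONFIG,
    value_range: Optional[tuple[float, float]] = None,
) -> Optional[np.ndarray]:
    """Soft bin memberships of ``x``: an (n, n_bins) row-stochastic matrix.

    Knots are uniform over ``value_range`` (default: the observed
    [min, max] of ``x``).  Returns None for a constant vector, whose bin
    placement is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("vector contains non-finite values")
    lo, hi = value_range if value_range is not None else (x.min(), x.max())
    if hi <= lo:
        return None
    order = cfg.spline_order
    n_int = cfg.n_bins - order + 1  # number of knot intervals
    z = np.clip((x - lo) / (hi - lo), 0.0, 1.0) * n_int
    knots = np.concatenate(
        [np.zeros(order), np.arange(1, n_int), np.full(order, n_int)]
    )
    return BSpline.design_matrix(z, knots, order - 1).toarray()


def _mi_from_memberships(bx: np.ndarray, by: np.ndarray) -> float:
    n = bx.shape[0]
    joint = bx.T @ by / n
    denom = np.outer(bx.mean(axis=0), by.mean(axis=0))
    mask = joint > 0
    terms = joint[mask] * np.log(joint[mask] / denom[mask])
    # summing in sorted order makes the result exactly invariant under bin
    # permutation/reflection, so I(a;-a) equals I(a;a) bit for bit
    return float(np.sort(terms).sum())


def spline_mi(
    a: np.ndarray, b: np.ndarray, cfg: AssociationConfig = DEFAULT_CONFIG
) -> float:
    """Mutual information I(a; b) in nats via soft B-spline binning.

    Symmetric in its arguments by construction.  Degenerate (constant)
    vectors yield 0, including I(a; a) for constant ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < MIN_COHORT_SAMPLES:
        raise ValueError(f"need at least {MIN_COHORT_SAMPLES} samples, got {a.size}")
    ba = bspline_memberships(a, cfg)
    bb = bspline_memberships(b, cfg)
    if ba is None or bb is None:
        return 0.0
    # averaging both argument orders makes symmetry exact in floating point
    return 0.5 * (_mi_from_memberships(ba, bb) + _mi_from_memberships(bb, ba))


def self_information(b: Optional[np.ndarray]) -> float:
    """I(a; a) from precomputed memberships (0 for a constant vector)."""
    if b is None:
        return 0.0
    return _mi_from_memberships(b, b)


def normalized_association(
    a: np.ndarray, b: np.ndarray, cfg: AssociationConfig = DEFAULT_CONFIG
) -> float:
    """Signed normalized MI in [-1, 1]; 1 iff b reproduces a exactly."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < MIN_COHORT_SAMPLES:
        raise ValueError(f"need at least {MIN_COHORT_SAMPLES} samples, got {a.size}")
    ba = bspline_memberships(a, cfg)
    bb = bspline_memberships(b, cfg)
    if ba is None or bb is None:
        return 0.0
    denom = max(self_information(ba), self_information(bb))
    if denom <= 0:
        return 0.0
    value = min(_mi_from_memberships(ba, bb) / denom, 1.0)
    if value > 1.0 - 1e-12:
        value = 1.0  # snap rounding residue so b = +/-a gives exactly +/-1
    # multiply by -1 only for strictly negative Pearson correlation
    sa, sb = a - a.mean(), b - b.mean()
    if float(sa @ sb) < 0:
        value = -value
    return value


def mi_profile(bg: np.ndarray, bt: np.ndarray) -> np.ndarray:
    """MI between each of G vectors and one target, from memberships.

    ``bg`` has shape (G, n, n_bins); ``bt`` has shape (n, n_bins).  This is
    the vectorized inner loop of the attractor iteration and the permutation
    test; it is numerically identical to calling :func:`spline_mi` per gene.
    """
    bg = np.asarray(bg)
    return mi_profile_t(
        np.ascontiguousarray(bg.transpose(0, 2, 1)), bg.mean(axis=1), bt
    )


def mi_profile_t(
    bt_genes: np.ndarray, marginals: np.ndarray, bt: np.ndarray
) -> np.ndarray:
    """MI profile from pre-transposed memberships (the BLAS-friendly layout).

    ``bt_genes`` has shape (G, n_bins, n) and must be C-contiguous so the
    joint over all genes collapses into one matrix product; ``marginals``
    (G, n_bins) are the genes' mean memberships, which do not change between
    calls and are therefore supplied precomputed.
    """
    g, m, n = bt_genes.shape
    joint = (bt_genes.reshape(g * m, n) @ bt).reshape(g, m, -1) / n
    denom = marginals[:, :, None] * bt.mean(axis=0)[None, None, :]
    ratio = np.log(np.maximum(joint, _EPS) / np.maximum(denom, _EPS))
    terms = joint * np.where(joint > 0, ratio, 0.0)
    return terms.sum(axis=(1, 2))


def self_information_profile(bg: np.ndarray) -> np.ndarray:
    """I(g; g) for each of G membership matrices, shape (G, n, n_bins)."""
    n = bg.shape[1]
    joint = np.einsum("gnm,gnk->gmk", bg, bg) / n
    p = bg.mean(axis=1)
    denom = p[:, :, None] * p[:, None, :]
    ratio = np.log(np.maximum(joint, _EPS) / np.maximum(denom, _EPS))
    return np.einsum("gmk,gmk->g", joint, np.where(joint > 0, ratio, 0.0))


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median: the smallest v with cum-weight{values <= v} >= 1/2.

    Deterministic and interpolation-free, so it is exactly reproducible and
    testable against an exhaustive oracle.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of an empty sequence")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, 0.5 - 1e-12))
    return float(v[order][min(idx, v.size - 1)])


def weighted_median_axis(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Column-wise lower weighted median of a (C, K) matrix with (C,) weights."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    order = np.argsort(values, axis=0, kind="stable")
    sv = np.take_along_axis(values, order, axis=0)
    cw = np.cumsum(w[order], axis=0)
    idx = np.argmax(cw >= 0.5 - 1e-12, axis=0)
    return sv[idx, np.arange(values.shape[1])]


def pan_cancer_association(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    weights: Sequence[float],
    cfg: AssociationConfig = DEFAULT_CONFIG,
) -> float:
    """Weighted median of per-cohort normalized associations.

    Cohorts with fewer than ``MIN_COHORT_SAMPLES`` samples are excluded with
    a warning and the remaining weights renormalized.
    """
    if len(pairs) != len(list(weights)):
        raise ValueError("one weight per cohort is required")
    vals, kept_w = [], []
    for (a, b), w in zip(pairs, weights):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < MIN_COHORT_SAMPLES:
            warnings.warn(
                f"cohort with {a.size} samples excluded from pan-cancer association"
            )
            continue
        vals.append(normalized_association(a, b, cfg))
        kept_w.append(w)
    if not vals:
        raise ValueError("no cohort has enough samples for association")
    return weighted_median(vals, kept_w)
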