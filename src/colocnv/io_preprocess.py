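"""Readers and preprocessing: expression, copy-number segments, annotation.

Input conventions
-----------------
* Expression: TSV, first column ``gene_id``, one column per sample, raw
  nonnegative abundances (FPKM-like).
* Segments: SEG-like TSV with columns Sample, Chromosome, Start, End,
  Segment_Mean; coordinates 1-based inclusive; Segment_Mean is a log2 ratio
  (0 = diploid).
* Annotation: TSV with gene_id, chromosome, start, end (1-based inclusive).
* Manifest: YAML/JSON mapping cohort name -> {tumor: [...], normal: [...]}.

All interval arithmetic internally uses half-open [start, end + 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y"}


def normalize_chromosome(name: str) -> str:
    """Strip a leading 'chr' prefix so '1' and 'chr1' compare equal."""
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


def _chromosome_sort_key(name: str):
    s = normalize_chromosome(name)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


# ---------------------------------------------------------------------------
# annotation


def sort_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide total ordering by (chromosome, midpoint, gene_id).

    Adds the derived ``midpoint`` column (floor of the interval centre).
    Chromosomes sort naturally (1..22, then X, Y, others lexicographic).
    """
    ann = annotation.copy()
    ann["chromosome"] = ann["chromosome"].map(normalize_chromosome)
    if (ann["start"] > ann["end"]).any():
        bad = ann.index[ann["start"] > ann["end"]][0]
        raise ValueError(f"annotation start > end for gene {bad}")
    ann["midpoint"] = (ann["start"] + ann["end"]) // 2
    key = ann["chromosome"].map(_chromosome_sort_key)
    ann = ann.assign(_key=key, _gid=ann.index).sort_values(
        ["_key", "midpoint", "_gid"], kind="stable"
    )
    return ann.drop(columns=["_key", "_gid"])


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    ann = ann.set_index("gene_id")
    return sort_annotation(ann)


def read_expression(path: str) -> pd.DataFrame:
    """Genes x samples raw expression matrix (first column = gene_id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    return mat.astype(float)


def read_segments(path: str) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    seg = seg.rename(
        columns={
            "Sample": "sample_id",
            "Chromosome": "chromosome",
            "Start": "start",
            "End": "end",
            "Segment_Mean": "seg_mean",
        }
    )
    seg["chromosome"] = seg["chromosome"].map(normalize_chromosome)
    return seg


def read_manifest(path: str) -> dict[str, dict[str, list[str]]]:
    with open(path) as fh:
        if path.endswith(".json"):
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    out = {}
    for cohort, groups in data.items():
        out[str(cohort)] = {
            "tumor": [str(s) for s in groups.get("tumor", [])],
            "normal": [str(s) for s in groups.get("normal", [])],
        }
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_expression(raw: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """log2(1 + X) transform followed by quantile normalization.

    After normalization every sample column carries the identical sorted
    value multiset: the per-rank mean across samples.  Ties within a column
    receive the average of the tied ranks' reference values (the limma
    dialect), which makes the rank-substitution step idempotent.
    """
    values = raw.to_numpy(dtype=float) if isinstance(raw, pd.DataFrame) else np.asarray(raw, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a genes x samples matrix")
    if values.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    logged = np.log2(1.0 + values)
    out = quantile_normalize(logged)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Columns mapped onto the mean sorted profile, averaging tied ranks."""
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    reference = np.sort(mat, axis=0).mean(axis=1)
    from scipy.stats import rankdata

    out = np.empty_like(mat)
    grid = np.arange(n, dtype=float)
    for j in range(mat.shape[1]):
        ranks = rankdata(mat[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return out


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """One cancer type: matrices are genes x samples, genes in annotation order."""

    name: str
    raw_expression: pd.DataFrame
    expression: pd.DataFrame
    cna: pd.DataFrame
    normal_cna: Optional[pd.DataFrame] = None

    @property
    def n_tumors(self) -> int:
        return self.expression.shape[1]


@dataclass
class CohortSet:
    cohorts: list[Cohort]
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        genes = self.annotation.index
        for c in self.cohorts:
            if not c.expression.index.equals(genes) or not c.cna.index.equals(genes):
                raise ValueError(f"cohort {c.name}: gene index differs from annotation")
        w = self.weights
        if abs(w.sum() - 1.0) > 1e-9:
            raise AssertionError("cohort weights must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        n = np.array([c.n_tumors for c in self.cohorts], dtype=float)
        return n / n.sum()

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cohorts]


def filter_zero_genes(
    raw_by_cohort: dict[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Drop genes whose raw value is 0 in every sample of ANY cohort.

    Returns the filtered matrices (same keys, common gene order preserved)
    and the removed gene ids.
    """
    if not raw_by_cohort:
        return {}, []
    genes = next(iter(raw_by_cohort.values())).index
    dead = pd.Series(False, index=genes)
    for mat in raw_by_cohort.values():
        dead |= (mat.loc[genes] == 0).all(axis=1)
    removed = list(genes[dead])
    kept = genes[~dead]
    return {k: v.loc[kept] for k, v in raw_by_cohort.items()}, removed


# ---------------------------------------------------------------------------
# segments -> gene-level CNA


def _sample_chrom_cna(
    starts: np.ndarray,
    ends: np.ndarray,
    means: np.ndarray,
    g_start: np.ndarray,
    g_end: np.ndarray,
) -> np.ndarray:
    """Gene-level values for one (sample, chromosome); intervals 1-based inclusive."""
    out = np.empty(g_start.size, dtype=float)
    # first segment overlapping each gene: segments with end >= gene start
    lo = np.searchsorted(ends, g_start, side="left")
    # one past the last segment overlapping: segments with start <= gene end
    hi = np.searchsorted(starts, g_end, side="right")
    nseg = starts.size
    for i in range(g_start.size):
        a, b = lo[i], hi[i]
        if b - a == 1:
            out[i] = means[a]
        elif b - a > 1:
            # gene spans a breakpoint: length-weighted mean of overlaps
            ov = np.minimum(ends[a:b], g_end[i]) - np.maximum(starts[a:b], g_start[i]) + 1
            out[i] = float(np.average(means[a:b], weights=ov))
        else:
            # gene falls in a gap: mean of the two flanking segments,
            # or the single nearest one beyond the first/last segment
            left = a - 1
            if left < 0:
                out[i] = means[0]
            elif a >= nseg:
                out[i] = means[-1]
            else:
                out[i] = 0.5 * (means[left] + means[a])
    return out


def segments_to_gene_cna(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Map per-sample segment tables onto gene-level log2-ratio values.

    A gene inside one segment takes its seg_mean; a gene spanning several
    takes their length-weighted mean; a gene in a gap takes the mean of the
    two flanking segments (the single nearest one at chromosome ends).  A
    sample with no segments on a gene's chromosome yields 0 (diploid) with
    a warning.
    """
    samples = (
        list(sample_ids)
        if sample_ids is not None
        else sorted(segments["sample_id"].unique())
    )
    genes = annotation.index
    out = np.zeros((len(genes), len(samples)), dtype=float)
    chrom_rows = {
        chrom: np.flatnonzero((annotation["chromosome"] == chrom).to_numpy())
        for chrom in annotation["chromosome"].unique()
    }
    g_start_all = annotation["start"].to_numpy()
    g_end_all = annotation["end"].to_numpy()
    by_sample = dict(tuple(segments.groupby("sample_id", sort=False)))
    for j, sid in enumerate(samples):
        seg_s = by_sample.get(sid)
        groups = (
            dict(tuple(seg_s.groupby("chromosome", sort=False)))
            if seg_s is not None
            else {}
        )
        for chrom, rows in chrom_rows.items():
            seg_c = groups.get(chrom)
            if seg_c is None or seg_c.empty:
                warnings.warn(
                    f"sample {sid}: no segments on chromosome {chrom}; "
                    "recording diploid (0)"
                )
                continue
            seg_c = seg_c.sort_values("start", kind="stable")
            out[rows, j] = _sample_chrom_cna(
                seg_c["start"].to_numpy(dtype=float),
                seg_c["end"].to_numpy(dtype=float),
                seg_c["seg_mean"].to_numpy(dtype=float),
                g_start_all[rows],
                g_end_all[rows],
            )
    return pd.DataFrame(out, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# full assembly


def build_cohort_set(
    annotation: pd.DataFrame,
    raw_expression: dict[str, pd.DataFrame],
    segments: pd.DataFrame,
    manifest: dict[str, dict[str, list[str]]],
) -> tuple[CohortSet, list[str]]:
    """Preprocess raw inputs into an analysis-ready :class:`CohortSet`.

    Steps: restrict expression to manifest tumor samples, drop genes that
    are all-zero in any cohort, quantile-normalize log2(1+X) per cohort, and
    map segments to gene-level CNA for tumor and normal samples.
    Returns the cohort set plus the list of removed gene ids.
    """
    tumor_raw = {}
    for name, groups in manifest.items():
        if name not in raw_expression:
            raise ValueError(f"cohort {name} missing from expression inputs")
        mat = raw_expression[name]
        missing = [s for s in groups["tumor"] if s not in mat.columns]
        if missing:
            raise ValueError(f"cohort {name}: tumor samples missing from expression: {missing[:5]}")
        sub = mat[groups["tumor"]]
        sub = sub.reindex(annotation.index)
        if sub.isna().any().any():
            raise ValueError(f"cohort {name}: expression missing annotated genes")
        tumor_raw[name] = sub
    tumor_raw, removed = filter_zero_genes(tumor_raw)
    ann = annotation.loc[next(iter(tumor_raw.values())).index]
    cohorts = []
    for name, groups in manifest.items():
        raw = tumor_raw[name]
        norm = normalize_expression(raw)
        cna = segments_to_gene_cna(segments, ann, groups["tumor"])
        normal_cna = (
            segments_to_gene_cna(segments, ann, groups["normal"])
            if groups["normal"]
            else None
        )
        cohorts.append(
            Cohort(
                name=name,
                raw_expression=raw,
                expression=norm,
                cna=cna,
                normal_cna=normal_cna,
            )
        )
        log.info(
            "cohort %s: %d tumors, %d normals, %d genes",
            name,
            raw.shape[1],
            len(groups["normal"]),
            raw.shape[0],
        )
    return CohortSet(cohorts=cohorts, annotation=ann), removed


def load_cohort_set(
    annotation_path: str,
    expression_paths: dict[str, str],
    segments_path: str,
    manifest_path: str,
) -> tuple[CohortSet, list[str]]:
    """File-path convenience wrapper around :func:`build_cohort_set`."""
    annotation = read_annotation(annotation_path)
    raw = {name: read_expression(p) for name, p in expression_paths.items()}
    segments = read_segments(segments_path)
    manifest = read_manifest(manifest_path)
    return build_cohort_set(annotation, raw, segments, manifest)
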