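"""End-to-end orchestration: simulate -> preprocess -> discover -> call -> score.

Every stage reads and writes plain TSV/BED/JSON files under the run
directory, so intermediate results are inspectable and stages can be re-run
individually.  A JSON run manifest records the configuration snapshot, the
output paths with checksums, and the versions involved; re-running with the
same configuration and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .attractor import AttractorSignature, discover_signatures
from .cna_calls import SignatureCall, call_signatures, co_alteration
from .config import PipelineConfig, load_pipeline_config
from .io_preprocess import CohortSet, load_cohort_set
from .synthetic_data import (
    SyntheticTruth,
    generate_to_dir,
    profile_config,
    score_recovery,
)

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: str | Path) -> dict[str, str]:
    """Write a synthetic dataset under ``outdir``/data."""
    data_dir = Path(outdir) / "data"
    return generate_to_dir(cfg.synthetic, data_dir)


def stage_preprocess(data_dir: str | Path) -> tuple[CohortSet, list[str]]:
    """Load and preprocess a dataset directory written by the simulator."""
    data_dir = Path(data_dir)
    for required in ("annotation.tsv", "segments.tsv", "manifest.yaml"):
        if not (data_dir / required).exists():
            raise FileNotFoundError(f"missing input file: {data_dir / required}")
    expr_paths = {
        p.stem.removeprefix("expression_"): str(p)
        for p in sorted(data_dir.glob("expression_*.tsv"))
    }
    if not expr_paths:
        raise FileNotFoundError(f"no expression_*.tsv files under {data_dir}")
    return load_cohort_set(
        str(data_dir / "annotation.tsv"),
        expr_paths,
        str(data_dir / "segments.tsv"),
        str(data_dir / "manifest.yaml"),
    )


def write_signatures(
    signatures: Sequence[AttractorSignature],
    annotation: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, str]:
    """Signature outputs: per-gene weights TSV, ranges BED, summary TSV, JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_rows, summary_rows, bed_rows, blob = [], [], [], []
    for sig in signatures:
        top5 = set(sig.top_genes(5))
        for g, w in zip(sig.window_genes, sig.weights):
            a = annotation.loc[g]
            gene_rows.append(
                {
                    "signature": sig.name,
                    "gene_id": g,
                    "chromosome": a["chromosome"],
                    "start": int(a["start"]),
                    "end": int(a["end"]),
                    "weight": w,
                    "is_top5": g in top5,
                }
            )
        first, last = sig.range_genes if sig.range_genes else (sig.name, sig.name)
        summary_rows.append(
            {
                "name": sig.name,
                "chromosome": sig.chromosome,
                "strength": sig.strength,
                "n_members": len(sig.member_genes(0.5)),
                "range_first": first,
                "range_last": last,
                "converged": sig.converged,
            }
        )
        # BED is 0-based half-open
        bed_rows.append(
            (
                sig.chromosome,
                int(annotation.loc[first, "start"]) - 1,
                int(annotation.loc[last, "end"]),
                sig.name,
            )
        )
        blob.append(
            {
                "name": sig.name,
                "seed": sig.seed,
                "chromosome": sig.chromosome,
                "window_genes": sig.window_genes,
                "weights": [float(w) for w in sig.weights],
                "strength": sig.strength,
                "converged": sig.converged,
                "degenerate": sig.degenerate,
                "range_span": list(sig.range_span) if sig.range_span else None,
                "range_genes": list(sig.range_genes) if sig.range_genes else None,
            }
        )
    paths = {}
    p = Path(outdir) / "signature_genes.tsv"
    pd.DataFrame(gene_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["signature_genes"] = str(p)
    p = Path(outdir) / "signatures_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["signatures_summary"] = str(p)
    p = Path(outdir) / "signature_ranges.bed"
    with open(p, "w") as fh:
        for chrom, s, e, name in bed_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    paths["signature_ranges"] = str(p)
    p = Path(outdir) / "signatures.json"
    p.write_text(json.dumps(blob, indent=1))
    paths["signatures_json"] = str(p)
    return paths


def load_signatures(path: str | Path) -> list[AttractorSignature]:
    """Reload signatures serialized by :func:`write_signatures` (no metagenes)."""
    out = []
    for rec in json.loads(Path(path).read_text()):
        out.append(
            AttractorSignature(
                name=rec["name"],
                seed=rec["seed"],
                chromosome=rec["chromosome"],
                window_genes=rec["window_genes"],
                weights=np.asarray(rec["weights"], dtype=float),
                strength=rec["strength"],
                converged=rec["converged"],
                degenerate=rec["degenerate"],
                range_span=tuple(rec["range_span"]) if rec["range_span"] else None,
                range_genes=tuple(rec["range_genes"]) if rec["range_genes"] else None,
            )
        )
    return out


def stage_discover(
    cohort_set: CohortSet, cfg: PipelineConfig, outdir: str | Path
) -> list[AttractorSignature]:
    signatures = discover_signatures(cohort_set, cfg.attractor, cfg.association)
    write_signatures(signatures, cohort_set.annotation, outdir)
    return signatures


def write_calls(
    calls: Sequence[SignatureCall],
    cohort_names: Sequence[str],
    thresholds: tuple[float, float],
    outdir: str | Path,
) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in calls:
        sig = c.signature
        first, last = sig.range_genes if sig.range_genes else (sig.name, sig.name)
        row = {
            "name": sig.name,
            "chromosome": sig.chromosome,
            "range_first": first,
            "range_last": last,
            "strength": sig.strength,
            "assoc": c.assoc,
            "p_raw": c.p_raw,
            "p_bonferroni": c.p_bonferroni,
            "n_types_amp": c.n_types_amp,
            "n_types_del": c.n_types_del,
            "is_pan_amp": c.is_pan_amp,
            "is_pan_del": c.is_pan_del,
            "is_driver": c.is_driver,
            "direction": c.direction,
        }
        for name in cohort_names:
            row[f"amp_freq_{name}"] = c.amp_freq.get(name, np.nan)
            row[f"del_freq_{name}"] = c.del_freq.get(name, np.nan)
        rows.append(row)
    p = outdir / "calls.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    summary = {
        "t_amp": thresholds[0],
        "t_del": thresholds[1],
        "n_signatures": len(calls),
        "n_association_passing": sum(
            1 for c in calls if c.p_bonferroni < 0.05
        ),
        "n_frequency_passing": sum(1 for c in calls if c.is_pan_amp or c.is_pan_del),
        "n_drivers": sum(1 for c in calls if c.is_driver),
        "n_amp_drivers": sum(1 for c in calls if c.is_driver and c.is_pan_amp),
        "n_del_drivers": sum(1 for c in calls if c.is_driver and c.is_pan_del),
    }
    ps = outdir / "call_summary.json"
    ps.write_text(json.dumps(summary, indent=1))
    return {"calls": str(p), "call_summary": str(ps)}


def _adjacent_driver_pairs(
    calls: Sequence[SignatureCall], annotation: pd.DataFrame
) -> list[tuple[SignatureCall, SignatureCall]]:
    order = {g: i for i, g in enumerate(annotation.index)}
    drivers = sorted(
        (c for c in calls if c.is_driver),
        key=lambda c: (c.signature.chromosome, order[c.signature.name]),
    )
    pairs = []
    for a, b in zip(drivers, drivers[1:]):
        if (
            a.signature.chromosome == b.signature.chromosome
            and a.direction == b.direction
            and a.direction != "none"
        ):
            pairs.append((a, b))
    return pairs


def stage_call(
    cohort_set: CohortSet,
    signatures: Sequence[AttractorSignature],
    cfg: PipelineConfig,
    outdir: str | Path,
) -> tuple[list[SignatureCall], tuple[float, float]]:
    calls, thresholds = call_signatures(
        signatures, cohort_set, cfg.calls, cfg.association
    )
    paths = write_calls(calls, cohort_set.names, thresholds, outdir)
    pair_rows = []
    for a, b in _adjacent_driver_pairs(calls, cohort_set.annotation):
        co_freq, expr_assoc = co_alteration(
            a, b, cohort_set.weights, thresholds, cfg.calls, cfg.association
        )
        pair_rows.append(
            {
                "sig_a": a.signature.name,
                "sig_b": b.signature.name,
                "direction": a.direction,
                "co_freq": np.nan if co_freq is None else co_freq,
                "expr_assoc": expr_assoc,
            }
        )
    p = Path(outdir) / "co_alteration.tsv"
    pd.DataFrame(
        pair_rows, columns=["sig_a", "sig_b", "direction", "co_freq", "expr_assoc"]
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    return calls, thresholds


def stage_score(
    truth: SyntheticTruth,
    calls: Sequence[SignatureCall],
    annotation: pd.DataFrame,
    outdir: str | Path,
):
    score = score_recovery(truth, calls, annotation)
    p = Path(outdir) / "recovery.json"
    p.write_text(
        json.dumps(
            {
                "precision": score.precision,
                "recall": score.recall,
                "jaccard": score.jaccard,
                "n_calls": score.n_calls,
                "n_events": score.n_events,
                "matched_events": score.matched_events,
                "false_calls": score.false_calls,
            },
            indent=1,
        )
    )
    return score


# ---------------------------------------------------------------------------
# full run


def run_pipeline(
    config: PipelineConfig | str,
    outdir: str | Path,
    resume: bool = False,
) -> dict:
    """Run every stage and write a manifest with per-file checksums.

    With ``resume=True``, an existing data directory is reused instead of
    re-simulated (useful when only downstream settings changed).
    """
    cfg = load_pipeline_config(config) if isinstance(config, str) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = outdir / "data"
    if resume and (data_dir / "manifest.yaml").exists():
        log.info("resume: reusing existing dataset under %s", data_dir)
    else:
        stage_simulate(cfg, outdir)
    cohort_set, removed = stage_preprocess(data_dir)
    log.info("preprocess: %d genes retained, %d removed", len(cohort_set.annotation), len(removed))
    signatures = stage_discover(cohort_set, cfg, outdir)
    calls, thresholds = stage_call(cohort_set, signatures, cfg, outdir)
    truth = SyntheticTruth.from_json((data_dir / "truth.json").read_text())
    score = stage_score(truth, calls, cohort_set.annotation, outdir)
    log.info(
        "funnel: %d signatures -> %d drivers; precision=%s recall=%.2f",
        len(signatures),
        sum(1 for c in calls if c.is_driver),
        f"{score.precision:.2f}" if score.precision is not None else "NA",
        score.recall,
    )
    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file()
        and p.suffix in {".tsv", ".bed", ".json", ".yaml"}
        and p.name != "run_manifest.json"
    }
    manifest = {
        "version": __version__,
        "rng_seed": cfg.rng_seed,
        "config": cfg.to_dict(),
        "outputs": outputs,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def run_profile(name: str, seed: int, outdir: str | Path, **overrides) -> dict:
    """Run the full pipeline on a named synthetic profile."""
    cfg = PipelineConfig(synthetic=profile_config(name, rng_seed=seed), rng_seed=seed)
    cfg.calls.rng_seed = seed
    for key, value in overrides.items():
        section, field_name = key.split(".", 1)
        setattr(getattr(cfg, section), field_name, value)
    return run_pipeline(cfg, outdir)
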