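"""Multi-cohort synthetic genomes with known amplicon/deletion ground truth.

The generator emulates the statistical structure the pipeline assumes in
real tumor data, at desk scale:

* several cohorts of unequal size with matched normal samples;
* per-sample copy-number profiles built from piecewise-constant baseline
  segments, sparse germline-like CNVs (present in tumors and normals), and
  recurrent planted events that fire independently per sample;
* expression coupled to copy number through a log-scale dosage slope, with
  planted blocks additionally sharing a latent co-expression factor
  (co-regulation) and optional copy-number-neutral confounder blocks;
* expression emitted on the raw nonnegative scale (2**x - 1) so the
  pipeline's log2(1 + X) step is exercised.

Outputs are exactly the TSV/YAML formats the preprocessing module consumes,
and generation is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import ConfounderBlock, PlantedEvent, SyntheticConfig

__all__ = [
    "EventTruth",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "write_dataset",
    "generate_to_dir",
    "score_recovery",
    "profile_config",
]


@dataclass
class EventTruth:
    chromosome: str
    start_gene: int
    end_gene: int
    direction: str
    gene_ids: list[str]
    realized_freq: dict[str, float] = field(default_factory=dict)
    indicators: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    events: list[EventTruth]
    confounders: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {"events": [asdict(e) for e in self.events], "confounders": self.confounders},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        return cls(
            events=[EventTruth(**e) for e in data["events"]],
            confounders=data["confounders"],
        )


@dataclass
class SyntheticDataset:
    annotation: pd.DataFrame
    expression: dict[str, pd.DataFrame]  # cohort -> raw genes x (tumor+normal)
    segments: pd.DataFrame
    manifest: dict[str, dict[str, list[str]]]
    truth: SyntheticTruth


def _gene_table(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for chrom in cfg.chromosomes:
        for i in range(cfg.genes_per_chromosome):
            start = i * cfg.gene_spacing + 1
            rows.append(
                {
                    "gene_id": f"g{chrom}_{i:04d}",
                    "chromosome": chrom,
                    "start": start,
                    "end": start + cfg.gene_length - 1,
                }
            )
    ann = pd.DataFrame(rows).set_index("gene_id")
    ann["midpoint"] = (ann["start"] + ann["end"]) // 2
    return ann


def _profile_to_segments(
    values: np.ndarray, ann_chrom: pd.DataFrame, chrom_len: int
) -> list[tuple[int, int, float]]:
    """Maximal runs of equal gene values, as segments tiling the chromosome."""
    starts = ann_chrom["start"].to_numpy()
    segs = []
    run_start = 0
    for i in range(1, values.size + 1):
        if i == values.size or values[i] != values[run_start]:
            seg_start = 1 if run_start == 0 else int(starts[run_start])
            seg_end = chrom_len if i == values.size else int(starts[i]) - 1
            segs.append((seg_start, seg_end, float(values[run_start])))
            run_start = i
    return segs


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full multi-cohort dataset with ground truth.

    Deterministic for a fixed ``cfg.rng_seed``; every stochastic choice
    flows from one generator.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    ann = _gene_table(cfg)
    gp = cfg.genes_per_chromosome
    chrom_len = gp * cfg.gene_spacing
    cohort_names = [f"C{i + 1:02d}" for i in range(len(cfg.cohort_sizes))]

    events = [
        EventTruth(
            chromosome=ev.chromosome,
            start_gene=ev.start_gene,
            end_gene=ev.end_gene,
            direction=ev.direction,
            gene_ids=[
                f"g{ev.chromosome}_{i:04d}" for i in range(ev.start_gene, ev.end_gene + 1)
            ],
        )
        for ev in cfg.planted_events
    ]
    conf_truth = []
    for blk in cfg.confounder_blocks:
        conf_truth.append(
            {
                "gene_ids": [f"g{blk.chromosome}_{i:04d}" for i in blk.gene_indices],
                "co_localized": bool(blk.co_localized),
                "chromosome": blk.chromosome,
            }
        )

    baseline_expr = rng.uniform(3.0, 8.0, size=len(ann))
    # genes excluded from planted structure may be zeroed to exercise the filter
    structured = set()
    for e in events:
        structured.update(e.gene_ids)
    for c in conf_truth:
        structured.update(c["gene_ids"])
    free_genes = [g for g in ann.index if g not in structured]
    zero_genes = (
        list(rng.choice(free_genes, size=cfg.n_zero_genes, replace=False))
        if cfg.n_zero_genes
        else []
    )

    seg_rows = []
    expression: dict[str, pd.DataFrame] = {}
    manifest: dict[str, dict[str, list[str]]] = {}
    gene_pos = {g: i for i, g in enumerate(ann.index)}

    for cohort, n_tum in zip(cohort_names, cfg.cohort_sizes):
        tumor_ids = [f"{cohort}_T{i:03d}" for i in range(n_tum)]
        normal_ids = [f"{cohort}_N{i:03d}" for i in range(cfg.n_normal_per_cohort)]
        manifest[cohort] = {"tumor": tumor_ids, "normal": normal_ids}
        all_ids = tumor_ids + normal_ids
        n_all = len(all_ids)

        cna = np.zeros((len(ann), n_all))
        for s, sid in enumerate(all_ids):
            is_tumor = s < n_tum
            for ci, chrom in enumerate(cfg.chromosomes):
                lo = ci * gp
                profile = np.zeros(gp)
                # baseline piecewise-constant noise segments
                n_seg = cfg.baseline_segments_per_chromosome
                if n_seg > 1:
                    breaks = np.sort(
                        rng.choice(np.arange(1, gp), size=n_seg - 1, replace=False)
                    )
                else:
                    breaks = np.array([], dtype=int)
                bounds = np.concatenate([[0], breaks, [gp]])
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    profile[b0:b1] = rng.normal(0.0, cfg.cna_noise_sd)
                # sparse germline-like CNVs, in tumors and normals alike
                for _ in range(cfg.germline_cnvs_per_sample):
                    on_chrom = rng.integers(0, cfg.n_chromosomes)
                    start = int(rng.integers(0, gp - cfg.germline_cnv_genes + 1))
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    if on_chrom == ci:
                        profile[start : start + cfg.germline_cnv_genes] = (
                            sign * cfg.germline_cnv_effect
                        )
                cna[lo : lo + gp, s] = profile
        # planted recurrent events (tumor samples only)
        for ev, tr in zip(cfg.planted_events, events):
            affected = ev.cohorts is None or cohort in ev.cohorts
            fires = (
                rng.random(n_tum) < ev.frequency
                if affected
                else np.zeros(n_tum, dtype=bool)
            )
            sign = 1.0 if ev.direction == "amp" else -1.0
            lo = cfg.chromosomes.index(ev.chromosome) * gp
            rows = slice(lo + ev.start_gene, lo + ev.end_gene + 1)
            for s in np.flatnonzero(fires):
                amplitude = sign * (ev.effect + rng.normal(0.0, cfg.cna_noise_sd))
                cna[rows, s] = amplitude
            tr.indicators[cohort] = fires.astype(int).tolist()
            tr.realized_freq[cohort] = float(fires.mean())

        # emit segments from each sample's gene-level profile
        for s, sid in enumerate(all_ids):
            for ci, chrom in enumerate(cfg.chromosomes):
                lo = ci * gp
                ann_chrom = ann.iloc[lo : lo + gp]
                for seg_start, seg_end, mean in _profile_to_segments(
                    cna[lo : lo + gp, s], ann_chrom, chrom_len
                ):
                    seg_rows.append((sid, chrom, seg_start, seg_end, mean))

        # expression: baseline + dosage + latent factors + noise
        x = baseline_expr[:, None] + cfg.dosage_slope * cna
        x += rng.normal(0.0, cfg.expr_noise_sd, size=x.shape)
        for ev, tr in zip(cfg.planted_events, events):
            h = rng.normal(0.0, 1.0, size=n_all)
            rows = [gene_pos[g] for g in tr.gene_ids]
            x[rows, :] += ev.coexpression * h[None, :]
        for blk, tr in zip(cfg.confounder_blocks, conf_truth):
            h = rng.normal(0.0, 1.0, size=n_all)
            rows = [gene_pos[g] for g in tr["gene_ids"]]
            x[rows, :] += blk.strength * h[None, :]
        raw = np.clip(np.exp2(x) - 1.0, 0.0, None)
        if cohort == cohort_names[0]:
            for g in zero_genes:
                raw[gene_pos[g], :] = 0.0
        expression[cohort] = pd.DataFrame(raw, index=ann.index, columns=all_ids)

    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"]
    )
    return SyntheticDataset(
        annotation=ann,
        expression=expression,
        segments=segments,
        manifest=manifest,
        truth=SyntheticTruth(events=events, confounders=conf_truth),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset in the formats the preprocessing readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    ann_path = outdir / "annotation.tsv"
    ds.annotation.drop(columns="midpoint").to_csv(ann_path, sep="\t")
    paths["annotation"] = str(ann_path)
    seg_path = outdir / "segments.tsv"
    seg = ds.segments.rename(
        columns={
            "sample_id": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "seg_mean": "Segment_Mean",
        }
    )
    seg.to_csv(seg_path, sep="\t", index=False, float_format="%.6g")
    paths["segments"] = str(seg_path)
    expr_paths = {}
    for cohort, mat in ds.expression.items():
        p = outdir / f"expression_{cohort}.tsv"
        mat.to_csv(p, sep="\t", float_format="%.6g")
        expr_paths[cohort] = str(p)
    paths["expression"] = expr_paths
    man_path = outdir / "manifest.yaml"
    with open(man_path, "w") as fh:
        yaml.safe_dump(ds.manifest, fh, sort_keys=True)
    paths["manifest"] = str(man_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(ds.truth.to_json())
    paths["truth"] = str(truth_path)
    return paths


def generate_to_dir(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, str]:
    return write_dataset(generate(cfg), outdir)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryScore:
    precision: Optional[float]  # None when there are no calls
    recall: float
    jaccard: dict[str, float]  # per-event member-gene Jaccard (best match)
    n_calls: int
    n_events: int
    matched_events: list[str]
    false_calls: list[str]


def _event_label(e: EventTruth) -> str:
    return f"{e.direction}:{e.chromosome}:{e.start_gene}-{e.end_gene}"


def score_recovery(
    truth: SyntheticTruth,
    calls: Sequence,
    annotation: pd.DataFrame,
) -> RecoveryScore:
    """Precision/recall of driver calls against planted events.

    An event is recovered iff some driver call's chromosomal range overlaps
    its gene range in the matching direction; the Jaccard index compares the
    call's member genes (weight > 0.5) with the planted members.
    """
    drivers = [c for c in calls if getattr(c, "is_driver", False)]
    order = {g: i for i, g in enumerate(annotation.index)}
    call_ranges = []
    for c in drivers:
        sig = c.signature
        first, last = sig.range_genes if sig.range_genes else (sig.name, sig.name)
        covered = {
            g
            for g in annotation.index[order[first] : order[last] + 1]
        }
        call_ranges.append((c, covered, set(sig.member_genes(0.5))))
    matched_events = []
    jaccard = {}
    matched_calls = set()
    for e in truth.events:
        label = _event_label(e)
        egenes = set(e.gene_ids)
        best = None
        for i, (c, covered, members) in enumerate(call_ranges):
            if c.direction != e.direction or not (covered & egenes):
                continue
            j = len(members & egenes) / len(members | egenes) if members | egenes else 0.0
            if best is None or j > best[1]:
                best = (i, j)
        if best is not None:
            matched_events.append(label)
            jaccard[label] = best[1]
            matched_calls.add(best[0])
            for i, (c, covered, members) in enumerate(call_ranges):
                if c.direction == e.direction and covered & egenes:
                    matched_calls.add(i)
    n_events = len(truth.events)
    recall = len(matched_events) / n_events if n_events else 1.0
    precision = (
        len(matched_calls) / len(drivers) if drivers else None
    )
    false_calls = [
        call_ranges[i][0].signature.name
        for i in range(len(call_ranges))
        if i not in matched_calls
    ]
    return RecoveryScore(
        precision=precision,
        recall=recall,
        jaccard=jaccard,
        n_calls=len(drivers),
        n_events=n_events,
        matched_events=matched_events,
        false_calls=false_calls,
    )


# ---------------------------------------------------------------------------
# named profiles


def profile_config(name: str, rng_seed: int = 0) -> SyntheticConfig:
    """Named study conditions: 'clean', 'realistic', or 'null'.

    ``realistic`` is the default-noise multi-cohort genome with three
    recurrent amplicons, one recurrent deletion and one copy-number-neutral
    co-localized confounder block; ``clean`` is a smaller low-noise genome
    with high event frequencies for fast end-to-end checks; ``null`` has no
    planted structure at all.
    """
    if name == "realistic":
        return SyntheticConfig(
            planted_events=[
                PlantedEvent("1", 30, 43, "amp"),
                PlantedEvent("1", 150, 162, "amp"),
                PlantedEvent("2", 60, 72, "amp"),
                PlantedEvent("3", 140, 154, "del"),
            ],
            confounder_blocks=[
                ConfounderBlock("3", list(range(30, 42)), co_localized=True, strength=0.9)
            ],
            rng_seed=rng_seed,
        )
    if name == "clean":
        return SyntheticConfig(
            n_chromosomes=2,
            genes_per_chromosome=100,
            cohort_sizes=(50,) * 8,
            n_normal_per_cohort=10,
            planted_events=[
                PlantedEvent("1", 30, 40, "amp", effect=1.5, frequency=0.3, coexpression=1.2),
                PlantedEvent("2", 50, 62, "del", effect=1.5, frequency=0.3, coexpression=1.2),
            ],
            expr_noise_sd=0.2,
            cna_noise_sd=0.05,
            germline_cnvs_per_sample=1,
            n_zero_genes=2,
            rng_seed=rng_seed,
        )
    if name == "null":
        return SyntheticConfig(
            n_chromosomes=2,
            genes_per_chromosome=100,
            cohort_sizes=(50,) * 8,
            n_normal_per_cohort=10,
            planted_events=[],
            confounder_blocks=[],
            n_zero_genes=2,
            rng_seed=rng_seed,
        )
    raise ValueError(f"unknown profile {name!r}; expected clean/realistic/null")
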