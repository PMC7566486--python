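"""Configuration objects for every pipeline stage.

All tunables live in small frozen-ish dataclasses so a single YAML file can
describe a full run.  Validation happens eagerly in ``__post_init__`` so a
bad configuration fails before any compute starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class AssociationConfig:
    """Settings for the B-spline mutual-information association measure.

    ``n_bins`` soft bins per dimension and ``spline_order`` control the
    resolution of the density estimate; the defaults are the standard
    configuration of the spline estimator used throughout the co-expression
    literature (six bins, order 3, knots uniform over each vector's observed
    range).
    """

    n_bins: int = 6
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.spline_order < 1:
            raise ConfigError(f"spline_order must be >= 1, got {self.spline_order}")
        if self.spline_order > self.n_bins:
            raise ConfigError(
                f"spline_order ({self.spline_order}) must not exceed n_bins ({self.n_bins})"
            )


@dataclass
class AttractorConfig:
    """Settings for the genomically co-localized attractor iteration.

    ``window_size`` is the number of flanking genes considered around each
    seed (half on each side); ``exponent`` sharpens the metagene mixing
    weights; iteration stops when the weight vector moves less than
    ``convergence_eps`` in the sup norm.
    """

    window_size: int = 150
    exponent: float = 2.0
    convergence_eps: float = 1e-7
    strength_threshold: float = 0.5
    range_weight_threshold: float = 0.5
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.window_size < 10 or self.window_size % 2:
            raise ConfigError(
                f"window_size must be even and >= 10, got {self.window_size}"
            )
        if self.exponent <= 0:
            raise ConfigError("exponent must be positive")
        if self.convergence_eps <= 0:
            raise ConfigError("convergence_eps must be positive")
        for name in ("strength_threshold", "range_weight_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")


@dataclass
class CallConfig:
    """Settings for expression/CNA association testing and frequency calls."""

    n_permutations: int = 10_000
    alpha: float = 0.05
    percentile: float = 10.0
    t_freq: float = 0.03
    min_types: int = 6  # pan-cancer requires alteration in MORE than this many cohorts
    co_cna_diff: float = 0.1
    top_k: int = 5
    rng_seed: int = 0
    # optional overrides when no normal samples are available
    t_amp: Optional[float] = None
    t_del: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if not 0 < self.t_freq < 1:
            raise ConfigError("t_freq must lie in (0, 1)")
        if not 0 < self.percentile < 50:
            raise ConfigError("percentile must lie in (0, 50)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")


@dataclass
class PlantedEvent:
    """A recurrent copy-number event planted on a contiguous gene range.

    ``start_gene``/``end_gene`` are 0-based inclusive gene indices within the
    chromosome.  ``effect`` is the mean |log2 ratio| added when the event
    fires; ``frequency`` is the per-cohort Bernoulli rate.  ``coexpression``
    is the loading of a shared latent expression factor over the member
    genes, emulating the co-regulation that makes amplicon signatures
    co-expressed across all samples rather than only in altered ones.
    """

    chromosome: str
    start_gene: int
    end_gene: int
    direction: str  # "amp" or "del"
    effect: float = 1.5
    frequency: float = 0.10
    cohorts: Optional[Sequence[str]] = None  # None = all cohorts
    coexpression: float = 0.95

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ConfigError(f"direction must be 'amp' or 'del', got {self.direction!r}")
        if self.start_gene > self.end_gene:
            raise ConfigError("event start_gene must be <= end_gene")
        if not 0 <= self.frequency <= 1:
            raise ConfigError("event frequency must lie in [0, 1]")
        if self.effect < 0:
            raise ConfigError("event effect is a magnitude and must be >= 0")


@dataclass
class ConfounderBlock:
    """A co-expressed gene set with no copy-number footprint.

    Co-localized blocks probe the dual-condition driver rule (they pass the
    strength filter but must fail the CNA conditions); scattered blocks probe
    the window constraint.
    """

    chromosome: str
    gene_indices: Sequence[int]
    co_localized: bool = True
    strength: float = 0.9


@dataclass
class SyntheticConfig:
    """Study conditions for the multi-cohort synthetic genome generator."""

    n_chromosomes: int = 3
    genes_per_chromosome: int = 200
    gene_spacing: int = 100_000  # base pairs between successive gene starts
    gene_length: int = 60_000
    cohort_sizes: Sequence[int] = (150, 140, 130, 120, 110, 100, 100, 100)
    n_normal_per_cohort: int = 15
    planted_events: Sequence[PlantedEvent] = ()
    confounder_blocks: Sequence[ConfounderBlock] = ()
    dosage_slope: float = 1.0  # log2 expression units per log2-ratio CNA unit
    expr_noise_sd: float = 0.4
    cna_noise_sd: float = 0.1
    baseline_segments_per_chromosome: int = 5
    germline_cnvs_per_sample: int = 2
    germline_cnv_genes: int = 5
    germline_cnv_effect: float = 0.8
    n_zero_genes: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cohort_sizes, default=0) < 1:
            raise ConfigError("every cohort must have at least one tumor sample")
        chroms = [str(c + 1) for c in range(self.n_chromosomes)]
        by_chrom: dict[str, list[PlantedEvent]] = {}
        for ev in self.planted_events:
            if ev.chromosome not in chroms:
                raise ConfigError(f"event chromosome {ev.chromosome!r} not in genome")
            if ev.end_gene >= self.genes_per_chromosome:
                raise ConfigError("event range exceeds chromosome bounds")
            by_chrom.setdefault(ev.chromosome, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start_gene)
            for a, b in zip(evs, evs[1:]):
                if b.start_gene <= a.end_gene:
                    raise ConfigError(
                        f"planted events overlap on chromosome {chrom}: "
                        f"[{a.start_gene},{a.end_gene}] and [{b.start_gene},{b.end_gene}]"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]


@dataclass
class PipelineConfig:
    """Top-level configuration: one object per stage plus the run seed."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    attractor: AttractorConfig = field(default_factory=AttractorConfig)
    calls: CallConfig = field(default_factory=CallConfig)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _build(section: dict, cls):
    try:
        return cls(**section)
    except TypeError as exc:  # unknown key
        raise ConfigError(f"{cls.__name__}: {exc}") from exc


def load_pipeline_config(path: str) -> PipelineConfig:
    """Parse a YAML pipeline configuration file.

    Unknown keys and invalid values raise :class:`ConfigError` with the
    offending field named, before any compute runs.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("pipeline config must be a mapping")
    syn = dict(data.get("synthetic", {}))
    if "planted_events" in syn:
        syn["planted_events"] = [_build(e, PlantedEvent) for e in syn["planted_events"]]
    if "confounder_blocks" in syn:
        syn["confounder_blocks"] = [
            _build(b, ConfounderBlock) for b in syn["confounder_blocks"]
        ]
    cfg = PipelineConfig(
        synthetic=_build(syn, SyntheticConfig),
        association=_build(dict(data.get("association", {})), AssociationConfig),
        attractor=_build(dict(data.get("attractor", {})), AttractorConfig),
        calls=_build(dict(data.get("calls", {})), CallConfig),
        rng_seed=int(data.get("rng_seed", 0)),
    )
    cfg.calls.rng_seed = cfg.calls.rng_seed or cfg.rng_seed
    return cfg
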