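"""Shared fixtures: small synthetic cohorts with planted structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from colocnv import ConfounderBlock, SyntheticConfig
from colocnv.attractor import GenomeCaches, build_caches
from colocnv.io_preprocess import Cohort, CohortSet, build_cohort_set
from colocnv.synthetic_data import generate


def make_cohort_set(
    expr_by_cohort: dict[str, np.ndarray],
    cna_by_cohort: dict[str, np.ndarray] | None = None,
    chromosome: str = "1",
    raw_by_cohort: dict[str, np.ndarray] | None = None,
    normal_cna: dict[str, np.ndarray] | None = None,
) -> CohortSet:
    """Assemble a CohortSet directly from matrices, bypassing file formats.

    Expression is taken as already normalized; raw expression defaults to
    2**expr - 1.  Genes are placed 100 kb apart on one chromosome.
    """
    n_genes = next(iter(expr_by_cohort.values())).shape[0]
    genes = [f"g_{i:04d}" for i in range(n_genes)]
    ann = pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": [i * 100_000 + 1 for i in range(n_genes)],
            "end": [i * 100_000 + 60_000 for i in range(n_genes)],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    ann["midpoint"] = (ann["start"] + ann["end"]) // 2
    cohorts = []
    for name, expr in expr_by_cohort.items():
        n = expr.shape[1]
        cols = [f"{name}_T{i:03d}" for i in range(n)]
        cna = (
            cna_by_cohort[name]
            if cna_by_cohort is not None
            else np.zeros_like(expr)
        )
        raw = (
            raw_by_cohort[name]
            if raw_by_cohort is not None
            else np.clip(np.exp2(expr) - 1.0, 0.0, None)
        )
        nc = None
        if normal_cna is not None and name in normal_cna:
            mat = normal_cna[name]
            nc = pd.DataFrame(
                mat,
                index=genes,
                columns=[f"{name}_N{i:03d}" for i in range(mat.shape[1])],
            )
        cohorts.append(
            Cohort(
                name=name,
                raw_expression=pd.DataFrame(raw, index=genes, columns=cols),
                expression=pd.DataFrame(expr, index=genes, columns=cols),
                cna=pd.DataFrame(cna, index=genes, columns=cols),
                normal_cna=nc,
            )
        )
    return CohortSet(cohorts=cohorts, annotation=ann)


BLOCK_RANGE = (70, 80)  # half-open gene-index range of the planted block


@pytest.fixture(scope="session")
def block_cohort_set() -> CohortSet:
    """151-gene chromosome with a 10-gene co-expressed block (r ~ 0.9)."""
    cfg = SyntheticConfig(
        n_chromosomes=1,
        genes_per_chromosome=151,
        cohort_sizes=(100, 100, 100),
        n_normal_per_cohort=5,
        confounder_blocks=[
            ConfounderBlock("1", list(range(*BLOCK_RANGE)), strength=1.2)
        ],
        planted_events=[],
        n_zero_genes=0,
        rng_seed=5,
    )
    ds = generate(cfg)
    cs, _ = build_cohort_set(ds.annotation, ds.expression, ds.segments, ds.manifest)
    return cs


@pytest.fixture(scope="session")
def block_caches(block_cohort_set) -> GenomeCaches:
    return build_caches(block_cohort_set)


@pytest.fixture(scope="session")
def noise_cohort_set() -> CohortSet:
    """300 independent noise genes, three cohorts; no planted structure."""
    cfg = SyntheticConfig(
        n_chromosomes=1,
        genes_per_chromosome=300,
        cohort_sizes=(100, 100, 100),
        n_normal_per_cohort=5,
        planted_events=[],
        n_zero_genes=0,
        rng_seed=9,
    )
    ds = generate(cfg)
    cs, _ = build_cohort_set(ds.annotation, ds.expression, ds.segments, ds.manifest)
    return cs


@pytest.fixture(scope="session")
def noise_caches(noise_cohort_set) -> GenomeCaches:
    return build_caches(noise_cohort_set)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """One full pipeline run on the low-noise 'clean' profile (seed 1)."""
    from colocnv import run_profile

    outdir = tmp_path_factory.mktemp("clean_run")
    manifest = run_profile("clean", 1, outdir)
    return outdir, manifest
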