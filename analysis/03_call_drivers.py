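#!/usr/bin/env python
"""Designate driver amplifications and deletions among the signatures.

Derives t_amp/t_del from the normal samples, tests each signature's
expression/CNA coupling with the cohort-stratified permutation test, applies
the pan-cancer frequency rule, and reports the funnel:
signatures -> association-passing -> frequency-passing -> drivers.
"""

import argparse
import json
import logging
from pathlib import Path

import pandas as pd

from colocnv import PipelineConfig
from colocnv.pipeline import load_signatures, stage_call, stage_preprocess


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=str, default="results/run")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    outdir = Path(args.out)
    sig_path = outdir / "signatures.json"
    if not sig_path.exists():
        raise SystemExit(f"{sig_path} missing: run 02_discover_signatures.py first")
    cohort_set, _ = stage_preprocess(outdir / "data")
    cfg = PipelineConfig(rng_seed=args.seed)
    cfg.calls.rng_seed = args.seed
    stage_call(cohort_set, load_signatures(sig_path), cfg, outdir)
    summary = json.loads((outdir / "call_summary.json").read_text())
    print(
        f"t_amp={summary['t_amp']:.3f}, t_del={summary['t_del']:.3f}; "
        f"{summary['n_signatures']} signatures -> "
        f"{summary['n_association_passing']} association-passing -> "
        f"{summary['n_frequency_passing']} frequency-passing -> "
        f"{summary['n_drivers']} drivers "
        f"({summary['n_amp_drivers']} amplified, {summary['n_del_drivers']} deleted)"
    )
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t")
    cols = [
        "name", "chromosome", "range_first", "range_last", "strength",
        "assoc", "p_bonferroni", "n_types_amp", "n_types_del", "direction",
        "is_driver",
    ]
    print(calls[cols].to_string(index=False))
    pairs = pd.read_csv(outdir / "co_alteration.tsv", sep="\t")
    if len(pairs):
        print("adjacent same-direction driver pairs:")
        print(pairs.to_string(index=False))


if __name__ == "__main__":
    main()
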