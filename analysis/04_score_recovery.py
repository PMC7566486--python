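#!/usr/bin/env python
"""Score the driver calls against the planted ground truth.

Reports precision and recall over the planted events and the member-gene
Jaccard index per recovered event; writes results/run/recovery.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from colocnv.cna_calls import SignatureCall, SignatureLevels
from colocnv.pipeline import load_signatures, stage_preprocess, stage_score
from colocnv.synthetic_data import SyntheticTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=str, default="results/run")
    args = parser.parse_args()
    outdir = Path(args.out)
    calls_path = outdir / "calls.tsv"
    if not calls_path.exists():
        raise SystemExit(f"{calls_path} missing: run 03_call_drivers.py first")
    cohort_set, _ = stage_preprocess(outdir / "data")
    sigs = {s.name: s for s in load_signatures(outdir / "signatures.json")}
    calls = []
    for _, row in pd.read_csv(calls_path, sep="\t").iterrows():
        call = SignatureCall(
            signature=sigs[row["name"]], levels=SignatureLevels({}, {})
        )
        call.is_driver = bool(row["is_driver"])
        call.is_pan_amp = bool(row["is_pan_amp"])
        call.is_pan_del = bool(row["is_pan_del"])
        calls.append(call)
    truth = SyntheticTruth.from_json((outdir / "data" / "truth.json").read_text())
    score = stage_score(truth, calls, cohort_set.annotation, outdir)
    precision = "NA" if score.precision is None else f"{score.precision:.2f}"
    print(f"precision={precision} recall={score.recall:.2f} over {score.n_events} planted events")
    for label, j in score.jaccard.items():
        print(f"  {label}: member-gene Jaccard {j:.2f}")
    if score.false_calls:
        print(f"  false driver calls: {score.false_calls}")
    print(json.dumps(json.loads((outdir / "recovery.json").read_text()), indent=1))


if __name__ == "__main__":
    main()
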