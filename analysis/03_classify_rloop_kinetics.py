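#!/usr/bin/env python
"""Seven-category hybrid-peak kinetic classification with RNase H filtering.

Reads the dataset written by 01_simulate_study.py, builds the replicate
consensus universe, removes RNase H-insensitive false positives, tests each
treatment timepoint against untreated, assigns the seven kinetic categories,
and scores recovery against the planted truth under results/rloops.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from endrip.evaluate import rloop_recovery, rnaseh_metrics
from endrip.io import write_intervals
from endrip.pipeline import run_rloop_analysis
from endrip.simulate import TruthTable


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    parser.add_argument("--out", type=Path, default=Path("results/rloops"))
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO)

    res = run_rloop_analysis(args.dataset)
    args.out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(args.out / "rloop_categories.tsv", sep="\t", index=False)
    res.scale_factors.to_csv(args.out / "scale_factors.tsv", sep="\t", index=False)
    for cat in sorted(set(res.categories)):
        ivs = [iv.with_name(cat) for iv, c in zip(res.kept, res.categories) if c == cat]
        write_intervals(ivs, args.out / f"rloops_{cat}.bed")

    truth = TruthTable.read(args.dataset / "truth.tsv")
    cat_scores = rloop_recovery(truth.of_kind("rloop"), res.kept, res.categories)
    rh_scores = rnaseh_metrics(truth.frame, res.universe, res.rnaseh_pass)
    pd.DataFrame([{**cat_scores, **rh_scores}]).to_csv(
        args.out / "recovery_summary.tsv", sep="\t", index=False
    )

    print("category counts:", pd.Series(res.categories).value_counts().to_dict())
    print(
        f"category accuracy {cat_scores['category_accuracy']:.1%} over "
        f"{cat_scores['n_planted']} planted hybrid peaks; RNase H filter removed "
        f"{rh_scores['decoy_removal']:.0%} of decoys, retained "
        f"{rh_scores['true_retention']:.0%} of true peaks"
    )


if __name__ == "__main__":
    main()
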