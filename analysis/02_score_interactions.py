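#!/usr/bin/env python
"""Score the simulated screens: PCA scores, interaction calls, dependency classes.

Reads the normalized plates written by 01_simulate_screen.py, computes
replicate-median PCA scores, calls interactions above the top-7.3% pooled
score quantile, classifies every called pair by its fate in the mutant
screen, and reports recovery of the planted truth.
"""

import argparse
import json
from pathlib import Path

from sh3kit import plates
from sh3kit.io import read_plates

TOP_QUANTILE = 0.073


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/screen"))
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    wt_scores = plates.collect_ppi_scores(
        read_plates(args.indir / "wt_normalized.tsv"))
    mut_scores = plates.collect_ppi_scores(
        read_plates(args.indir / "mut_normalized.tsv"))
    wt_calls = plates.detect_interactions(wt_scores, TOP_QUANTILE)
    mut_calls = plates.detect_interactions(mut_scores, TOP_QUANTILE)
    calls = plates.classify_ppis(wt_scores, mut_scores, wt_calls, mut_calls,
                                 ratio_quantile=TOP_QUANTILE)

    plates.ppi_scores_frame(wt_scores).to_csv(
        args.outdir / "wt_ppi_scores.tsv", sep="\t", index=False)
    plates.ppi_scores_frame(mut_scores).to_csv(
        args.outdir / "mut_ppi_scores.tsv", sep="\t", index=False)
    plates.calls_frame(calls).to_csv(
        args.outdir / "dependency_classes.tsv", sep="\t", index=False)

    truth = json.loads((args.indir / "ground_truth.json").read_text())
    called_preys = {p for _, p in wt_calls}
    recall = (len(called_preys & set(truth["wt_interactions"]))
              / len(truth["wt_interactions"]))
    by_class: dict[str, int] = {}
    for c in calls:
        by_class[c.ppi_class] = by_class.get(c.ppi_class, 0) + 1
    summary = {
        "n_wt_scores": len(wt_scores),
        "n_wt_called": len(wt_calls),
        "wt_planted_recall": recall,
        "dependency_class_counts": by_class,
    }
    (args.outdir / "scoring_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
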