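#!/usr/bin/env python
"""Simulate the WT and domain-deletion DHFR-PCA colony screens.

Writes raw and plate-normalized colony grids for a wild-type bait screen and
a matched mutant screen in which half of the planted interactions are lost
and a few new ones appear, plus the planted ground truth for downstream
recovery checks.
"""

import argparse
import json
from pathlib import Path

from sh3kit import synth
from sh3kit.io import write_plates
from sh3kit.plates import normalize_plate

N_PREYS = 200
N_WT_INTERACTIONS = 14   # 7% of preys: under the 7.3% call quantile
N_LOST = 7               # interactions absent from the mutant screen
N_GAINED = 4             # interactions present only in the mutant screen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    preys = [f"prey_{j:03d}" for j in range(N_PREYS)]
    wt_effects = {("bait", p): 4.0 for p in preys[:N_WT_INTERACTIONS]}
    mut_effects = {("bait", p): 4.0
                   for p in preys[N_LOST:N_WT_INTERACTIONS]}
    mut_effects.update({("bait", p): 4.0 for p in preys[-N_GAINED:]})

    cfg_wt = synth.SimConfig(seed=args.seed, effect_log2=4.0, noise_sd=1.0)
    cfg_mut = synth.SimConfig(seed=args.seed + 1, effect_log2=4.0, noise_sd=1.0)
    wt_grids, _ = synth.gen_plate_screen(cfg_wt, ["bait"], preys,
                                         effects=wt_effects)
    mut_grids, _ = synth.gen_plate_screen(cfg_mut, ["bait"], preys,
                                          effects=mut_effects)

    write_plates(wt_grids, args.outdir / "wt_raw.tsv")
    write_plates(mut_grids, args.outdir / "mut_raw.tsv")
    write_plates([normalize_plate(g) for g in wt_grids],
                 args.outdir / "wt_normalized.tsv")
    write_plates([normalize_plate(g) for g in mut_grids],
                 args.outdir / "mut_normalized.tsv")
    truth = {
        "wt_interactions": sorted(p for _, p in wt_effects),
        "lost_in_mutant": preys[:N_LOST],
        "gained_in_mutant": preys[-N_GAINED:],
        "effect_log2": 4.0,
        "seed": args.seed,
    }
    (args.outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2) + "\n")
    print(f"wrote {len(wt_grids)} WT and {len(mut_grids)} mutant plates "
          f"to {args.outdir}")


if __name__ == "__main__":
    main()
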