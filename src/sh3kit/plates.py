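"""DHFR-PCA colony-array scoring and stress-condition growth scoring.

A protein-fragment complementation screen reads interaction strength out as
colony size on methotrexate plates. The scoring chain implemented here:

1. log2 colony sizes are normalized per plate by subtracting the plate
   background (median of quality-passing, non-border positions);
2. replicates that failed diploid selection are dropped, pairs retaining at
   least two replicates get a PCA score = median normalized log2 size;
3. interactions are called above a pooled score quantile (top 7.3% in the
   deletion screen convention, top 2.75% in the shuffling screen);
4. domain-deletion effects are classified from presence/absence in the WT
   and mutant screens and from the PCA-score ratio (mutant - WT, a log2
   difference), thresholded at the same quantile convention on the pooled
   ratio distribution.

Growth assays in stress conditions use the same plate container: per-plate
median-centering, per-strain plate medians, removal of strains whose two
plate medians disagree by more than 2 log2 units, and the growth score as
the mean of the two plate medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_COLUMNS = ["row", "col", "prey", "is_border", "log2_size", "qc_pass"]


@dataclass
class PlateGrid:
    """One plate at one timepoint: long-form positions with annotations.

    `df` columns: row, col, prey (strain label), is_border (bool),
    log2_size (float), qc_pass (bool). Border positions carry the control
    pair and are used only for QC, never scored.
    """

    plate_id: str
    bait: str
    df: pd.DataFrame
    condition: str = ""
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"plate {self.plate_id}: missing columns {missing}")

    def scored_mask(self) -> pd.Series:
        return ~self.df["is_border"] & self.df["qc_pass"]


@dataclass(frozen=True)
class PPIScore:
    bait: str
    prey: str
    replicate_values: tuple[float, ...]
    pca_score: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pca_score", float(np.median(self.replicate_values)))

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_values)


@dataclass(frozen=True)
class DependencyCall:
    bait: str
    prey: str
    wt_detected: bool
    mut_detected: bool
    score_ratio: float | None
    ppi_class: str  # dependent_lost | dependent_weaker | independent | inhibited_stronger | inhibited_gained


@dataclass(frozen=True)
class GrowthScore:
    strain: str
    condition: str
    per_plate_medians: tuple[float, float]
    discordant: bool

    @property
    def growth_score(self) -> float:
        return float(np.mean(self.per_plate_medians))


def normalize_plate(grid: PlateGrid, background_override: float | None = None) -> PlateGrid:
    """Subtract the plate background from all log2 colony sizes.

    The background is the median of qc-passing, non-border values; plates
    with no detectable background (e.g., a mutant bait that lost all
    interactions) can be given a matched plate's measured background via
    `background_override`.
    """
    if background_override is not None:
        background = float(background_override)
    else:
        vals = grid.df.loc[grid.scored_mask(), "log2_size"].dropna()
        if vals.empty:
            raise ValueError(
                f"plate {grid.plate_id}: no qc-passing non-border colonies and no override"
            )
        background = float(vals.median())
    df = grid.df.copy()
    df["log2_size"] = df["log2_size"] - background
    return replace(grid, df=df)


def collect_ppi_scores(
    grids: Sequence[PlateGrid],
    diploid_grids: Sequence[PlateGrid] | None = None,
    min_replicates: int = 2,
) -> list[PPIScore]:
    """Pool replicate values per (bait, prey) and take the median.

    Replicates whose position failed diploid selection (qc_pass False in the
    matching diploid grid) are removed first; pairs left with fewer than
    `min_replicates` values are dropped. Border control positions never
    contribute.
    """
    if diploid_grids is not None:
        if len(diploid_grids) != len(grids):
            raise ValueError("screen and diploid plate lists differ in length")
        for g, d in zip(grids, diploid_grids):
            a = g.df[["row", "col"]].reset_index(drop=True)
            b = d.df[["row", "col"]].reset_index(drop=True)
            if len(a) != len(b) or not (a.values == b.values).all():
                raise ValueError(
                    f"position mismatch between screen plate {g.plate_id} "
                    f"and diploid plate {d.plate_id}"
                )
    values: dict[tuple[str, str], list[float]] = {}
    for i, grid in enumerate(grids):
        keep = grid.scored_mask()
        if diploid_grids is not None:
            keep = keep & diploid_grids[i].df["qc_pass"].to_numpy()
        sub = grid.df.loc[keep]
        for prey, val in zip(sub["prey"], sub["log2_size"]):
            if pd.isna(val):
                continue
            values.setdefault((grid.bait, prey), []).append(float(val))
    out = []
    for (bait, prey), reps in sorted(values.items()):
        if len(reps) < min_replicates:
            continue
        out.append(PPIScore(bait=bait, prey=prey, replicate_values=tuple(reps)))
    return out


def detect_interactions(
    scores: Sequence[PPIScore], top_quantile: float
) -> set[tuple[str, str]]:
    """Pairs whose PCA score reaches the top `top_quantile` of the pooled
    score distribution (linear-interpolation quantile; threshold ties are
    included in the called set)."""
    if not 0 < top_quantile < 1:
        raise ValueError("top_quantile must be in (0, 1)")
    if not scores:
        raise ValueError("no scores to threshold")
    pooled = np.array([s.pca_score for s in scores])
    threshold = float(np.quantile(pooled, 1.0 - top_quantile))
    return {(s.bait, s.prey) for s in scores if s.pca_score >= threshold}


def score_ratio(mut: PPIScore, wt: PPIScore) -> float:
    """PCA score ratio: mutant minus WT score (a log2 size ratio)."""
    return mut.pca_score - wt.pca_score


def classify_ppis(
    wt_scores: Sequence[PPIScore],
    mut_scores: Sequence[PPIScore],
    wt_calls: set[tuple[str, str]],
    mut_calls: set[tuple[str, str]],
    ratio_quantile: float = 0.073,
) -> list[DependencyCall]:
    """Classify each pair by its fate upon domain mutation.

    Decision table: detected in WT only -> dependent_lost; detected in both
    with ratio below the lower `ratio_quantile` of the pooled ratio
    distribution -> dependent_weaker; between the quantiles -> independent;
    at or above the upper quantile -> inhibited_stronger (ties included
    upward); detected in the mutant only -> inhibited_gained.
    """
    wt_by = {(s.bait, s.prey): s for s in wt_scores}
    mut_by = {(s.bait, s.prey): s for s in mut_scores}

    ratios: dict[tuple[str, str], float] = {}
    for pair in wt_calls & mut_calls:
        if pair in wt_by and pair in mut_by:
            ratios[pair] = score_ratio(mut_by[pair], wt_by[pair])
    if ratios:
        pooled = np.array(list(ratios.values()))
        lower = float(np.quantile(pooled, ratio_quantile))
        upper = float(np.quantile(pooled, 1.0 - ratio_quantile))
    else:
        lower = upper = float("nan")

    calls: list[DependencyCall] = []
    for pair in sorted(wt_calls | mut_calls):
        in_wt, in_mut = pair in wt_calls, pair in mut_calls
        ratio = ratios.get(pair)
        if in_wt and not in_mut:
            cls = "dependent_lost"
        elif in_mut and not in_wt:
            cls = "inhibited_gained"
        elif ratio is None:
            logger.info("pair %s detected in both screens but unscored; skipped", pair)
            continue
        elif ratio >= upper:
            cls = "inhibited_stronger"
        elif ratio <= lower:
            cls = "dependent_weaker"
        else:
            cls = "independent"
        calls.append(
            DependencyCall(
                bait=pair[0], prey=pair[1],
                wt_detected=in_wt, mut_detected=in_mut,
                score_ratio=ratio, ppi_class=cls,
            )
        )
    return calls


def growth_scores(
    plates: Sequence[PlateGrid],
    timepoint_h: float | None = 74.0,
    discordance_cutoff: float = 2.0,
) -> list[GrowthScore]:
    """Growth score per strain from exactly two plate replicates per condition.

    Only plates at `timepoint_h` (default the 74 h reading; None keeps all)
    enter the analysis. Plates are first median-centered (qc-passing,
    non-border positions) to remove plate effects; each strain's per-plate
    median is computed; strains whose two medians differ by more than
    `discordance_cutoff` are removed; the growth score is the mean of the
    two medians.
    """
    if timepoint_h is not None:
        plates = [p for p in plates
                  if p.timepoint_h is None or p.timepoint_h == timepoint_h]
    by_condition: dict[str, list[PlateGrid]] = {}
    for p in plates:
        by_condition.setdefault(p.condition, []).append(p)
    out: list[GrowthScore] = []
    for condition, reps in sorted(by_condition.items()):
        if len(reps) != 2:
            raise ValueError(
                f"condition {condition!r}: expected 2 plate replicates, got {len(reps)}"
            )
        centered = [normalize_plate(p) for p in reps]
        medians: list[dict[str, float]] = []
        for plate in centered:
            sub = plate.df.loc[plate.scored_mask()]
            medians.append(sub.groupby("prey")["log2_size"].median().to_dict())
        strains = sorted(set(medians[0]) & set(medians[1]))
        for strain in strains:
            m1, m2 = medians[0][strain], medians[1][strain]
            discordant = abs(m1 - m2) > discordance_cutoff
            if discordant:
                logger.info("strain %s discordant in %s (|%.2f - %.2f| > %.1f)",
                            strain, condition, m1, m2, discordance_cutoff)
                continue
            out.append(GrowthScore(strain=strain, condition=condition,
                                   per_plate_medians=(m1, m2), discordant=False))
    return out


def ppi_scores_frame(scores: Iterable[PPIScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bait": s.bait, "prey": s.prey, "pca_score": s.pca_score,
             "n_replicates": s.n_replicates}
            for s in scores
        ]
    )


def calls_frame(calls: Iterable[DependencyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bait": c.bait, "prey": c.prey, "wt_detected": c.wt_detected,
             "mut_detected": c.mut_detected, "score_ratio": c.score_ratio,
             "class": c.ppi_class}
            for c in calls
        ]
    )


def profile_matrix(scores: Iterable[PPIScore], fill_value: float = 0.0) -> pd.DataFrame:
    """Pivot PPI scores to a bait x prey matrix; missing entries take
    `fill_value` (plate background after normalization)."""
    df = ppi_scores_frame(scores)
    mat = df.pivot(index="bait", columns="prey", values="pca_score")
    return mat.fillna(fill_value)
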