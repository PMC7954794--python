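"""Plate normalization, PPI scoring, interaction calls, dependency classes
and growth scoring."""

import numpy as np
import pandas as pd
import pytest

from sh3kit.plates import (
    PlateGrid,
    PPIScore,
    classify_ppis,
    collect_ppi_scores,
    detect_interactions,
    growth_scores,
    normalize_plate,
    score_ratio,
)
from sh3kit.synth import SimConfig, gen_growth_plates, gen_plate_screen


def make_plate(values, plate_id="p1", bait="b", border=0, condition="",
               timepoint_h=None):
    """Small plate from a 2D array; outer `border` positions flagged."""
    arr = np.asarray(values, dtype=float)
    rows = []
    n_rows, n_cols = arr.shape
    for r in range(n_rows):
        for c in range(n_cols):
            is_border = (r < border or c < border
                         or r >= n_rows - border or c >= n_cols - border)
            rows.append({"row": r, "col": c,
                         "prey": "BORDER" if is_border else f"prey_{r}_{c}",
                         "is_border": is_border, "log2_size": arr[r, c],
                         "qc_pass": True})
    return PlateGrid(plate_id=plate_id, bait=bait, df=pd.DataFrame(rows),
                     condition=condition, timepoint_h=timepoint_h)


class TestNormalizePlate:
    def test_constant_plate_becomes_zero(self):
        g = normalize_plate(make_plate(np.full((4, 4), 7.0)))
        assert np.allclose(g.df["log2_size"], 0.0)

    def test_override_subtracted_for_empty_background_plates(self):
        plate = make_plate(np.full((3, 3), np.nan))
        g = normalize_plate(plate, background_override=5.0)
        assert g.df["log2_size"].isna().all()  # nan - 5 stays nan
        valued = make_plate(np.full((3, 3), 8.0))
        g2 = normalize_plate(valued, background_override=5.0)
        assert np.allclose(g2.df["log2_size"], 3.0)

    def test_empty_plate_without_override_errors(self):
        with pytest.raises(ValueError):
            normalize_plate(make_plate(np.full((3, 3), np.nan)))

    def test_median_of_nonborder_is_zero_after_normalization(self, rng):
        g = normalize_plate(make_plate(rng.normal(10, 2, size=(8, 8)), border=2))
        sub = g.df.loc[~g.df["is_border"], "log2_size"]
        assert sub.median() == pytest.approx(0.0, abs=1e-12)

    def test_idempotence(self, rng):
        g1 = normalize_plate(make_plate(rng.normal(10, 2, size=(6, 6))))
        g2 = normalize_plate(g1)
        assert np.allclose(g1.df["log2_size"], g2.df["log2_size"])


class TestCollectScores:
    def test_median_of_surviving_replicates(self):
        g = make_plate([[1.0, 2.0, 9.0]])
        g.df["prey"] = "preyA"
        dip = make_plate([[1.0, 1.0, 0.0]])
        dip.df["prey"] = "preyA"
        dip.df["qc_pass"] = [True, True, False]  # third failed diploid selection
        scores = collect_ppi_scores([g], [dip])
        assert len(scores) == 1
        assert scores[0].pca_score == pytest.approx(1.5)
        assert scores[0].n_replicates == 2

    def test_single_surviving_replicate_dropped(self):
        g = make_plate([[1.0, 2.0]])
        g.df["prey"] = "preyA"
        dip = make_plate([[1.0, 0.0]])
        dip.df["prey"] = "preyA"
        dip.df["qc_pass"] = [True, False]
        assert collect_ppi_scores([g], [dip]) == []

    def test_position_mismatch_errors(self):
        g = make_plate([[1.0, 2.0]])
        dip = make_plate([[1.0], [2.0]])
        with pytest.raises(ValueError):
            collect_ppi_scores([g], [dip])

    def test_border_pairs_never_scored(self):
        g = make_plate(np.full((4, 4), 2.0), border=1)
        scores = collect_ppi_scores([g], min_replicates=1)
        assert all("BORDER" not in s.prey for s in scores)

    def test_planted_pairs_exceed_background_by_effect(self):
        cfg = SimConfig(seed=7, n_rows=16, n_cols=24, effect_log2=4.0,
                        noise_sd=0.2, frac_positive=0.1)
        preys = [f"p{j:02d}" for j in range(40)]
        grids, truth = gen_plate_screen(cfg, ["b"], preys)
        scores = collect_ppi_scores([normalize_plate(g) for g in grids])
        by_pair = {(s.bait, s.prey): s.pca_score for s in scores}
        planted = [by_pair[p] for p in truth.planted_pairs]
        others = [v for k, v in by_pair.items() if k not in truth.planted_pairs]
        assert np.mean(planted) - np.mean(others) == pytest.approx(4.0, abs=0.5)


class TestDetectAndClassify:
    def test_call_rate_matches_quantile_without_ties(self):
        scores = [PPIScore("b", f"p{i}", (float(i),)) for i in range(1000)]
        # min_replicates not enforced here: direct construction
        called = detect_interactions(scores, 0.10)
        assert len(called) == 100

    def test_score_ratio_is_log2_difference(self):
        wt = PPIScore("b", "p", (2.0, 2.0))
        mut = PPIScore("b", "p", (3.0, 3.0))
        assert score_ratio(mut, wt) == pytest.approx(1.0)
        assert score_ratio(wt, wt) == 0.0

    def test_decision_table(self):
        wt_scores = [PPIScore("b", f"p{i}", (float(i), float(i))) for i in range(8)]
        # mutant: p0 lost, p7 unchanged, others mildly shifted
        mut_scores = [PPIScore("b", f"p{i}", (float(i), float(i)))
                      for i in range(1, 8)]
        wt_calls = {("b", f"p{i}") for i in range(8)}
        mut_calls = {("b", f"p{i}") for i in range(1, 8)} | {("b", "new")}
        mut_scores.append(PPIScore("b", "new", (5.0, 5.0)))
        calls = {c.prey: c.ppi_class for c in classify_ppis(
            wt_scores, mut_scores, wt_calls, mut_calls, ratio_quantile=0.2)}
        assert calls["p0"] == "dependent_lost"
        assert calls["new"] == "inhibited_gained"
        assert set(calls.values()) <= {
            "dependent_lost", "dependent_weaker", "independent",
            "inhibited_stronger", "inhibited_gained",
        }

    def test_every_scored_pair_gets_exactly_one_class(self):
        cfg = SimConfig(seed=11, n_rows=16, n_cols=24, effect_log2=4.0,
                        noise_sd=0.5, frac_positive=0.1)
        preys = [f"p{j:02d}" for j in range(40)]
        wt_grids, truth = gen_plate_screen(cfg, ["b"], preys)
        mut_effects = {k: 0.0 for k in truth.planted_pairs}
        mut_grids, _ = gen_plate_screen(
            SimConfig(**{**cfg.__dict__, "seed": 12}), ["b"], preys,
            effects=mut_effects)
        wt_s = collect_ppi_scores([normalize_plate(g) for g in wt_grids])
        mut_s = collect_ppi_scores([normalize_plate(g) for g in mut_grids])
        wt_c = detect_interactions(wt_s, 0.1)
        mut_c = detect_interactions(mut_s, 0.1)
        calls = classify_ppis(wt_s, mut_s, wt_c, mut_c)
        pairs = [(c.bait, c.prey) for c in calls]
        assert len(pairs) == len(set(pairs)) == len(wt_c | mut_c)


class TestGrowthScores:
    def test_identical_plates_give_common_median(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        p1 = make_plate(vals, plate_id="a", condition="c1")
        p2 = make_plate(vals, plate_id="b", condition="c1")
        out = growth_scores([p1, p2], timepoint_h=None)
        centered = vals - np.median(vals)
        for g in out:
            r, c = int(g.strain.split("_")[1]), int(g.strain.split("_")[2])
            assert g.growth_score == pytest.approx(centered[r, c])

    def test_discordant_strain_removed(self):
        cfg = SimConfig(seed=3, n_rows=16, n_cols=24, noise_sd=0.1)
        strains = [f"s{i:02d}" for i in range(10)]
        plates = gen_growth_plates(cfg, strains, discordant={"s03"})
        out = growth_scores(plates)
        assert "s03" not in {g.strain for g in out}
        assert {g.strain for g in out} == set(strains) - {"s03"}

    def test_centering_removes_plate_offset(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        p1 = make_plate(vals, plate_id="a", condition="c1")
        p2 = make_plate(vals + 5.0, plate_id="b", condition="c1")  # plate effect
        out = growth_scores([p1, p2], timepoint_h=None)
        assert all(not g.discordant for g in out)
        assert all(abs(g.per_plate_medians[0] - g.per_plate_medians[1]) < 1e-9
                   for g in out)

    def test_wrong_replicate_count_errors(self):
        p1 = make_plate(np.ones((3, 3)), condition="c1")
        with pytest.raises(ValueError):
            growth_scores([p1], timepoint_h=None)

    def test_twelve_replicates_per_strain(self):
        cfg = SimConfig(seed=4, n_rows=16, n_cols=24)
        plates = gen_growth_plates(cfg, ["sA", "sB"])
        count = sum((p.df["prey"] == "sA").sum() for p in plates)
        assert count == 12
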