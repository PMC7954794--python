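"""Generator contracts: determinism, conservation, degenerate settings and
round-trip through the text formats."""

import numpy as np
import pandas as pd
import pytest

from sh3kit.dms import CODONS
from sh3kit.io import read_fasta, read_plates, write_fasta, write_plates
from sh3kit.synth import (
    SimConfig,
    gen_coupled_profiles,
    gen_dms_counts,
    gen_growth_plates,
    gen_motif_dataset,
    gen_plate_screen,
    gen_tracks,
    translate_check_fixtures,
)
from sh3kit.tracks import read_tracks, write_tracks

from conftest import one_hot_pwm


class TestDeterminism:
    def test_plate_screen_identical_on_same_seed(self):
        cfg = SimConfig(seed=42, n_rows=12, n_cols=16)
        preys = [f"p{i}" for i in range(20)]
        g1, t1 = gen_plate_screen(cfg, ["b"], preys)
        g2, t2 = gen_plate_screen(cfg, ["b"], preys)
        assert t1.planted_pairs == t2.planted_pairs
        for a, b in zip(g1, g2):
            pd.testing.assert_frame_equal(a.df, b.df)

    def test_growth_plates_identical_on_same_seed(self):
        cfg = SimConfig(seed=9, n_rows=12, n_cols=16)
        p1 = gen_growth_plates(cfg, ["s1", "s2"])
        p2 = gen_growth_plates(cfg, ["s1", "s2"])
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a.df, b.df)

    def test_motif_tracks_dms_identical_on_same_seed(self):
        pwm = one_hot_pwm("PAWP")
        d1, i1, m1 = gen_motif_dataset([pwm], 5, 5, seed=3)
        d2, i2, m2 = gen_motif_dataset([pwm], 5, 5, seed=3)
        assert d1 == d2 and i1 == i2 and m1.motif_positions == m2.motif_positions
        tr1, _ = gen_tracks(5, seed=4)
        tr2, _ = gen_tracks(5, seed=4)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.xy, b.xy)
        ta, _ = gen_dms_counts(["GCT"] * 3, depth=500, seed=5)
        tb, _ = gen_dms_counts(["GCT"] * 3, depth=500, seed=5)
        assert ta[0].counts == tb[0].counts


class TestPlateScreen:
    def test_zero_noise_zero_effect_gives_constant_plates(self):
        cfg = SimConfig(seed=1, n_rows=10, n_cols=12, noise_sd=0.0,
                        effect_log2=0.0, plate_sd=0.0, frac_positive=0.0)
        grids, _ = gen_plate_screen(cfg, ["b"], [f"p{i}" for i in range(10)])
        for g in grids:
            assert np.allclose(g.df["log2_size"], cfg.background_log2)

    def test_four_replicates_per_prey(self):
        cfg = SimConfig(seed=2, n_rows=12, n_cols=16)
        grids, _ = gen_plate_screen(cfg, ["b"], [f"p{i}" for i in range(10)])
        counts = sum((g.df["prey"] == "p0").sum() for g in grids)
        assert counts == 4

    def test_capacity_error(self):
        cfg = SimConfig(seed=3, n_rows=6, n_cols=6, border_width=2)
        with pytest.raises(ValueError):
            gen_plate_screen(cfg, ["b"], [f"p{i}" for i in range(50)])

    def test_duplicates_never_adjacent(self):
        cfg = SimConfig(seed=4, n_rows=12, n_cols=16)
        grids, _ = gen_plate_screen(cfg, ["b"], [f"p{i}" for i in range(30)])
        for g in grids:
            sub = g.df.loc[~g.df["is_border"]]
            for prey, grp in sub.groupby("prey"):
                pos = list(zip(grp["row"], grp["col"]))
                for i in range(len(pos)):
                    for j in range(i + 1, len(pos)):
                        manhattan = abs(pos[i][0] - pos[j][0]) + abs(pos[i][1] - pos[j][1])
                        assert manhattan > 1

    def test_border_frame_shape(self):
        cfg = SimConfig(seed=5, n_rows=10, n_cols=12, border_width=2)
        grids, _ = gen_plate_screen(cfg, ["b"], ["p0"])
        g = grids[0].df
        border = g.loc[g["is_border"], ["row", "col"]]
        assert ((border["row"] < 2) | (border["row"] >= 8)
                | (border["col"] < 2) | (border["col"] >= 10)).all()


class TestMotifDataset:
    def test_full_planting_with_one_hot_pwm_contains_consensus(self):
        pwm = one_hot_pwm("PAWPYK")
        dep, ind, truth = gen_motif_dataset([pwm], 20, 5, length=50,
                                            planted_frac=1.0, seed=6)
        for sid, seq in dep.items():
            start = truth.motif_positions[sid]
            assert seq[start:start + 6] == "PAWPYK"

    def test_zero_planting_records_no_positions(self):
        pwm = one_hot_pwm("PAWPYK")
        dep, _, truth = gen_motif_dataset([pwm], 10, 0, planted_frac=0.0, seed=7)
        assert all(v is None for v in truth.motif_positions.values())

    def test_invalid_planted_frac(self):
        with pytest.raises(ValueError):
            gen_motif_dataset([one_hot_pwm("PA")], 1, 1, planted_frac=1.5)


class TestDmsCounts:
    def test_counts_sum_to_depth_per_position_per_condition(self):
        tables, _ = gen_dms_counts(["GCT", "TGG"], depth=1000, n_reps=2, seed=8)
        for t in tables:
            for pos in t.positions():
                total = sum(v for (p, _), v in t.counts.items() if p == pos)
                assert total == t.depth[pos]

    def test_zero_effects_preserve_frequencies_in_expectation(self):
        tables, _ = gen_dms_counts(["GCT"] * 5, depth=50000, n_reps=1, seed=9)
        ref = next(t for t in tables if t.condition == "reference")
        sel = next(t for t in tables if t.condition == "selection")
        rf = np.array([ref.counts[(1, c)] for c in CODONS]) / ref.depth[1]
        sf = np.array([sel.counts[(1, c)] for c in CODONS]) / sel.depth[1]
        assert np.abs(rf - sf).max() < 0.01

    def test_lethal_surrogate_gives_zero_selection_count(self):
        effects = {(1, "TGT"): -60.0}  # weight ~ 0
        tables, _ = gen_dms_counts(["GCT"], depth=10000, effects=effects,
                                   n_reps=1, seed=10)
        sel = next(t for t in tables if t.condition == "selection")
        assert sel.counts[(1, "TGT")] == 0

    def test_58_positions_give_58_libraries(self):
        tables, _ = gen_dms_counts(["GCT"] * 58, depth=100, n_reps=1, seed=11)
        assert len(tables[0].positions()) == 58

    def test_unknown_codon_in_effects(self):
        with pytest.raises(KeyError):
            gen_dms_counts(["GCT"], effects={(1, "XYZ"): -1.0})


class TestCoupledProfiles:
    def test_zero_coupling_independent_of_sequences(self):
        p1, a1 = gen_coupled_profiles(6, 10, 0.0, seed=12)
        p2, a2 = gen_coupled_profiles(6, 10, 0.0, seed=12)
        pd.testing.assert_frame_equal(p1, p2)
        assert list(p1.index) == list(a1.keys())

    def test_requires_three_domains(self):
        with pytest.raises(ValueError):
            gen_coupled_profiles(2, 10, 0.5)


class TestTracksGen:
    def test_default_duration_180_frames(self):
        tracks, truth = gen_tracks(3, disassembly_rate=0.0, seed=13)
        assert truth.track_params["n_frames_total"] == 180
        assert all(t.n_frames == 180 for t in tracks)

    def test_stationary_when_drift_and_noise_zero(self):
        tracks, _ = gen_tracks(3, drift=0.0, noise_sd=0.0,
                               disassembly_rate=0.0, seed=14)
        for t in tracks:
            assert np.allclose(t.xy, t.xy[0])

    def test_no_disassembly_all_incomplete_in_truth(self):
        _, truth = gen_tracks(10, disassembly_rate=0.0, seed=15)
        assert not any(truth.track_complete.values())


class TestStufferFixtures:
    def test_two_pairs_translate_correctly(self):
        from sh3kit.seqstruct import translate_dna

        pairs = translate_check_fixtures()
        assert len(pairs) == 2
        for dna, peptide in pairs:
            assert translate_dna(dna) == peptide


class TestRoundTrip:
    def test_plates_round_trip(self, tmp_path):
        cfg = SimConfig(seed=16, n_rows=10, n_cols=12)
        grids, _ = gen_plate_screen(cfg, ["b1", "b2"], [f"p{i}" for i in range(8)])
        path = tmp_path / "plates.tsv"
        write_plates(grids, path)
        back = read_plates(path)
        assert {g.plate_id for g in back} == {g.plate_id for g in grids}
        orig = {g.plate_id: g for g in grids}
        for g in back:
            pd.testing.assert_frame_equal(
                g.df.reset_index(drop=True),
                orig[g.plate_id].df.reset_index(drop=True),
                check_dtype=False,
            )

    def test_fasta_round_trip(self, tmp_path):
        pwm = one_hot_pwm("PAWP")
        dep, ind, _ = gen_motif_dataset([pwm], 4, 4, seed=17)
        path = tmp_path / "seqs.fasta"
        write_fasta({**dep, **ind}, path)
        assert read_fasta(path) == {**dep, **ind}

    def test_tracks_round_trip(self, tmp_path):
        tracks, _ = gen_tracks(5, seed=18, disassembly_rate=0.05)
        write_tracks(tracks, tmp_path / "t.tsv", tmp_path / "c.tsv")
        back = read_tracks(tmp_path / "t.tsv", tmp_path / "c.tsv")
        assert len(back) == len(tracks)
        orig = {t.track_id: t for t in tracks}
        for t in back:
            assert np.allclose(t.xy, orig[t.track_id].xy)
            assert np.allclose(t.centroid, orig[t.track_id].centroid)

    def test_pwm_round_trip(self, tmp_path, rng):
        from sh3kit.motif import read_pwms, write_pwms

        from conftest import random_pwm

        pwms = [random_pwm(rng, 4, "a"), random_pwm(rng, 6, "b")]
        write_pwms(pwms, tmp_path / "pwms.tsv")
        back = read_pwms(str(tmp_path / "pwms.tsv"))
        assert [p.name for p in back] == ["a", "b"]
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.f, rt.f, atol=1e-6)
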