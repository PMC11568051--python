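"""Growth trajectories, the three dependent variables, pattern labels."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import phonogrow as pg
from phonogrow.growth_metrics import (
    GrowthError,
    GrowthPattern,
    avg_weighted_degree_new,
    build_model_table,
    classify_growth_pattern,
    compute_all_trajectories,
    compute_trajectory,
    proportional_degree_gain,
    saturation,
    sv_transform,
)
from phonogrow.synthetic_data import trajectory_from_gains


@pytest.fixture(scope="module")
def worked_trajectories(worked_networks):
    return {
        w: compute_trajectory(tuple(w), worked_networks) for w in ("bad", "eni", "bi", "brad")
    }


class TestTrajectories:
    def test_hand_counted_gains(self, worked_trajectories):
        assert worked_trajectories["bad"].gains == (8, 3, 2, 1, 1, 1)
        assert worked_trajectories["eni"].gains == (2, 0, 2, 0, 1, 0)
        assert worked_trajectories["bi"].gains == (7, 0, 5, 0, 0, 0)

    def test_spurt_count_is_seven_minus_aoa(self, worked_trajectories):
        assert worked_trajectories["brad"].aoa == 5
        assert worked_trajectories["brad"].n_spurts == 2
        assert worked_trajectories["bad"].n_spurts == 6

    def test_gains_sum_to_final_degree(self, small_networks):
        for traj in compute_all_trajectories(small_networks):
            assert sum(traj.gains) == traj.final_degree
            cum = [s.cumulative_degree for s in traj.spurts]
            assert all(a <= b for a, b in zip(cum, cum[1:]))
            assert traj.n_spurts == 7 - traj.aoa

    def test_absent_form_raises(self, worked_networks):
        with pytest.raises(GrowthError):
            compute_trajectory(tuple("zzz"), worked_networks)


class TestProportionalDegreeGain:
    def test_worked_percentages(self, worked_trajectories):
        bad = worked_trajectories["bad"]
        g1 = proportional_degree_gain(bad, 1)
        g2 = proportional_degree_gain(bad, 2)
        assert g1 == pytest.approx(50.0)
        assert round(g1 + g2) == 69
        assert round(g2) == 19

    def test_gains_sum_to_hundred(self, small_networks):
        for traj in compute_all_trajectories(small_networks):
            if traj.final_degree > 0:
                total = sum(proportional_degree_gain(traj, j) for j in range(1, traj.n_spurts + 1))
                assert total == pytest.approx(100.0)

    def test_all_growth_first_spurt(self):
        traj = trajectory_from_gains(tuple("pa"), 1, [5, 0, 0, 0, 0, 0])
        assert proportional_degree_gain(traj, 1) == 100.0
        assert proportional_degree_gain(traj, 4) == 0.0

    def test_never_growing_word_excluded(self):
        traj = trajectory_from_gains(tuple("pa"), 1, [0] * 6)
        with pytest.raises(GrowthError):
            proportional_degree_gain(traj, 1)


class TestSaturation:
    def test_worked_ladder(self, worked_trajectories):
        eni = worked_trajectories["eni"]
        sats = [saturation(eni, 15, j) for j in range(1, 7)]
        assert [math.floor(s) for s in sats] == [13, 13, 26, 26, 33, 33]

    def test_data_cat_ratios(self):
        # a dense word reaching 4 of 5 vs a sparse one reaching 17 of 50
        t_data = trajectory_from_gains(tuple("pa"), 4, [4, 0, 0])
        t_cat = trajectory_from_gains(tuple("ka"), 1, [10, 3, 2, 1, 1, 0])
        assert saturation(t_data, 5, 3) == pytest.approx(80.0)
        assert saturation(t_cat, 50, 6) == pytest.approx(34.0)

    def test_full_saturation(self):
        traj = trajectory_from_gains(tuple("pa"), 1, [3, 2, 0, 0, 0, 0])
        assert saturation(traj, 5, 6) == pytest.approx(100.0)

    def test_monotone_and_bounded_on_synthetic(self, small_synthetic, small_networks):
        lex = small_synthetic.lexicon
        for traj in compute_all_trajectories(small_networks):
            l1 = lex.entry(traj.phon).l1_density
            if l1 == 0:
                continue
            sats = [saturation(traj, l1, j) for j in range(1, traj.n_spurts + 1)]
            assert all(a <= b for a, b in zip(sats, sats[1:]))
            assert sats[-1] <= 100.0 + 1e-9  # L2 lexicon is a subset of the L1 pool

    def test_zero_l1_density_signalled(self):
        traj = trajectory_from_gains(tuple("pa"), 1, [1, 0, 0, 0, 0, 0])
        with pytest.raises(GrowthError):
            saturation(traj, 0, 1)


class TestAvgWeightedDegree:
    def test_worked_values_cumulative_mode(self, worked_trajectories):
        bi = worked_trajectories["bi"]
        assert avg_weighted_degree_new(bi, 1) == pytest.approx(352 / 7)
        assert avg_weighted_degree_new(bi, 2) == pytest.approx(352 / 7)  # carried forward
        assert avg_weighted_degree_new(bi, 3) == pytest.approx(704 / 12)
        assert round(avg_weighted_degree_new(bi, 1), 1) == 50.3
        assert round(avg_weighted_degree_new(bi, 3), 1) == 58.7

    def test_per_new_neighbor_mode(self, worked_trajectories):
        bi = worked_trajectories["bi"]
        assert avg_weighted_degree_new(bi, 3, mode="new") == pytest.approx(352 / 5)
        assert avg_weighted_degree_new(bi, 2, mode="new") == pytest.approx(352 / 7)

    def test_uniform_weights_constant(self):
        spurts = []
        cum_d = cum_w = 0
        for g in (3, 2, 0, 1, 0, 0):
            cum_d += g
            cum_w += 60 * g
            spurts.append(pg.growth_metrics.Spurt(g, cum_d, 60 * g, cum_w))
        traj = pg.GrowthTrajectory(tuple("pa"), 1, tuple(spurts))
        for j in range(1, 7):
            assert avg_weighted_degree_new(traj, j) == pytest.approx(60.0)

    def test_empty_neighborhood_zero(self):
        traj = trajectory_from_gains(tuple("pa"), 3, [0, 0, 2, 0])
        assert avg_weighted_degree_new(traj, 1) == 0.0
        assert avg_weighted_degree_new(traj, 2) == 0.0

    def test_unknown_mode(self, worked_trajectories):
        with pytest.raises(ValueError):
            avg_weighted_degree_new(worked_trajectories["bi"], 1, mode="median")


class TestGrowthPatterns:
    @pytest.mark.parametrize(
        "gains,label",
        [
            ([8, 0, 0, 0, 0, 0], GrowthPattern.INITIAL),
            ([3, 1, 2, 1, 1, 1], GrowthPattern.CONTINUOUS),
            ([2, 0, 1, 2, 1, 1], GrowthPattern.DELAYED),
            ([2, 0, 0, 1, 1, 1], GrowthPattern.DELAYED),
            ([2, 0, 0, 0, 1, 1], GrowthPattern.OTHER),  # three dormant spurts
            ([1, 2, 0, 1, 1, 1], GrowthPattern.OTHER),
        ],
    )
    def test_examples(self, gains, label):
        traj = trajectory_from_gains(tuple("pa"), 1, gains)
        assert classify_growth_pattern(traj) == label

    def test_too_few_spurts_error(self):
        traj = trajectory_from_gains(tuple("pa"), 5, [1, 0])
        with pytest.raises(GrowthError):
            classify_growth_pattern(traj)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.integers(0, 4), min_size=3, max_size=6))
    def test_partition_exactly_one_label(self, gains):
        traj = trajectory_from_gains(tuple("pa"), 7 - len(gains), gains)
        label = classify_growth_pattern(traj)
        assert label in set(GrowthPattern)


class TestSvTransform:
    @pytest.mark.parametrize("y,n,expected", [(0.0, 100, 0.005), (1.0, 100, 0.995), (0.5, 17, 0.5)])
    def test_values(self, y, n, expected):
        assert sv_transform(y, n) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sv_transform(-0.1, 10)
        with pytest.raises(ValueError):
            sv_transform(1.1, 10)
        with pytest.raises(ValueError):
            sv_transform(0.5, 0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.integers(1, 100000)
    )
    def test_strictly_monotone_into_open_interval(self, y1, y2, n):
        t1, t2 = sv_transform(y1, n), sv_transform(y2, n)
        assert 0.0 < t1 < 1.0
        if y2 - y1 > 1e-9 and n > 1:
            assert t1 < t2


class TestModelTable:
    def test_row_counts(self):
        trajs = [
            trajectory_from_gains(tuple("pa"), 1, [3, 1, 0, 0, 0, 0]),
            trajectory_from_gains(tuple("ti"), 5, [2, 1]),
            trajectory_from_gains(tuple("ku"), 2, [0, 0, 0, 0, 0]),  # never grows
        ]
        table = build_model_table(trajs, {}, {}, {})
        assert len(table) == 8  # 6 + 2 rows; the non-growing word contributes none
        assert set(table["word"]) == {"pa", "ti"}
        assert table.attrs["sv_n"] == 8

    def test_fixture_rows_match_hand_computation(self, worked_lexicon, worked_networks):
        trajs = compute_all_trajectories(worked_networks)
        l1 = {t.phon: worked_lexicon.entry(t.phon).l1_density for t in trajs}
        fl = {t.phon: worked_lexicon.entry(t.phon).freq_log for t in trajs}
        ln = {t.phon: worked_lexicon.entry(t.phon).length for t in trajs}
        table = build_model_table(trajs, l1, fl, ln)
        n = table.attrs["sv_n"]
        row = table[(table["word"] == "bad") & (table["spurt"] == 1)].iloc[0]
        assert row["degree_gain_raw"] == pytest.approx(0.5)
        assert row["prop_degree_gain"] == pytest.approx(sv_transform(0.5, n))
        assert row["saturation_gain_raw"] == pytest.approx(8 / 20)
        bi3 = table[(table["word"] == "bi") & (table["spurt"] == 3)].iloc[0]
        assert bi3["avg_wd_int"] == 59  # round(704/12)
        import numpy as np

        assert np.allclose(table.groupby("word")["degree_gain_raw"].sum(), 1.0)

    def test_sv_bounds(self, small_synthetic, small_networks):
        lex = small_synthetic.lexicon
        trajs = compute_all_trajectories(small_networks)
        l1 = {t.phon: lex.entry(t.phon).l1_density for t in trajs}
        fl = {t.phon: lex.entry(t.phon).freq_log for t in trajs}
        ln = {t.phon: lex.entry(t.phon).length for t in trajs}
        table = build_model_table(trajs, l1, fl, ln)
        assert ((table["prop_degree_gain"] > 0) & (table["prop_degree_gain"] < 1)).all()
        sat = table["prop_saturation_gain"].dropna()
        assert ((sat > 0) & (sat < 1)).all()
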