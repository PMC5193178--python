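"""The synergy-score pipeline: normalization, AUC, testing, scaling, map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmip
from fmip.synergy import (adjust_pvalues, auc, expected_additive,
                          normality_check, scale_and_mask, synergy_analysis,
                          synergy_map, synergy_normalize, synergy_test)


class TestSynergyNormalize:
    def test_null_response_is_zero(self, rng):
        t = np.arange(10.0)
        untreated = rng.uniform(0.9, 1.3, size=10)
        # cell identical to the untreated mean, after its own baseline
        from fmip.trajectories import normalize_baseline
        cell = normalize_baseline(t, untreated, 4.5) * untreated
        out = synergy_normalize(t, cell, untreated, 4.5)
        # trace proportional to untreated: ratio/baseline == untreated-shape
        np.testing.assert_allclose(
            synergy_normalize(t, untreated,
                              normalize_baseline(t, untreated, 4.5), 4.5),
            0.0, atol=1e-12)

    def test_arithmetic(self):
        out = synergy_normalize([0.0, 1.0, 5.0], [2.0, 2.0, 4.0],
                                np.ones(3), 3.0)
        np.testing.assert_allclose(out, [0.0, 0.0, 1.0])

    def test_noiseless_cell_recovers_activity(self, strong_model,
                                              egf_condition, time_grid):
        noise = fmip.CellNoise(amplitude_sigma=0.0, ratio_noise_sd=0.0)
        a = fmip.simulate_trajectory(strong_model, egf_condition, noise,
                                     time_grid, 0)
        ratio = strong_model.baseline_ratio * (1.0 + a)
        out = synergy_normalize(time_grid, ratio, np.ones_like(time_grid),
                                egf_condition.stimulation_time)
        np.testing.assert_allclose(out, a, atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            synergy_normalize([0.0, 1.0, 2.0], [1.0, 1.0, 1.0],
                              np.ones(2), 1.5)


class TestAUC:
    def test_trapezoid_example(self):
        assert auc([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 1.0, 0.0], 0.0) == 2.0

    def test_zero_trace(self):
        assert auc(np.arange(5.0), np.zeros(5), 0.0) == 0.0

    def test_negative_excursions_subtract(self):
        assert auc([0.0, 1.0, 2.0], [0.0, -1.0, 0.0], 0.0) == -1.0

    def test_matches_fine_grid_riemann_sum(self, rng):
        t = np.linspace(0.0, 100.0, 51)
        v = rng.normal(0.0, 0.3, size=51)
        coarse = auc(t, v, 20.0)
        fine_t = np.linspace(t[t >= 20.0][0], 100.0, 100001)
        fine_v = np.interp(fine_t, t, v)
        riemann = float(np.sum(fine_v[:-1] * np.diff(fine_t)))
        assert coarse == pytest.approx(riemann, abs=1e-3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc([0.0, 10.0], [0.0, 1.0], 5.0)


class TestNormality:
    def test_w_bounded_by_one(self, rng):
        w, _ = normality_check(rng.normal(size=30))
        assert 0.0 < w <= 1.0

    def test_normal_sample_near_one(self, rng):
        w, _ = normality_check(rng.normal(size=10))
        assert w > 0.9

    def test_bimodal_sample_rejected(self, rng):
        x = np.concatenate([rng.normal(-10, 0.5, 25),
                            rng.normal(10, 0.5, 25)])
        _, p = normality_check(x)
        assert p < 0.01

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])


class TestExpectedAdditive:
    def test_error_propagation_example(self):
        assert expected_additive(2.0, 0.3, 1.0, 0.4) == (3.0, 0.5)

    def test_zero_errors(self):
        assert expected_additive(2.5, 0.0, -1.0, 0.0) == (1.5, 0.0)

    def test_commutative(self):
        assert expected_additive(1.0, 0.2, 2.0, 0.5) == \
            expected_additive(2.0, 0.5, 1.0, 0.2)


class TestSynergyTest:
    def test_null_case(self):
        obs = np.array([1.0, 2.0, 3.0, 2.0])
        ss, t, p = synergy_test(obs, obs.mean(), 0.1)
        assert ss == 0.0 and t == 0.0 and p == 1.0

    def test_large_shift_is_significant(self, rng):
        obs = rng.normal(0.0, 1.0, size=50)
        sem = obs.std(ddof=1) / np.sqrt(50)
        shift = 5.0 * np.hypot(sem, 0.05)
        _, t, p = synergy_test(obs, obs.mean() - shift, 0.05)
        assert p < 0.001

    def test_sign_consistency(self, rng):
        obs = rng.normal(1.0, 0.5, size=20)
        ss, t, _ = synergy_test(obs, 0.2, 0.1)
        assert np.sign(ss) == np.sign(t)

    def test_matches_t_distribution_tail(self, rng):
        """p equals the two-sided tail of the t distribution at the
        Welch-Satterthwaite df computed by hand."""
        from scipy import stats
        obs = rng.normal(0.5, 1.0, size=30)
        arm_stats = [(25, 0.12), (40, 0.07)]
        ss, t, p = synergy_test(obs, 0.1, np.hypot(0.12, 0.07), arm_stats)
        sem_o = obs.std(ddof=1) / np.sqrt(30)
        var = sem_o ** 2 + 0.12 ** 2 + 0.07 ** 2
        df = var ** 2 / (sem_o ** 4 / 29 + 0.12 ** 4 / 24
                         + 0.07 ** 4 / 39)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df))

    def test_zero_se_nonzero_difference(self):
        with pytest.warns(UserWarning, match="zero combined SE"):
            ss, t, p = synergy_test(np.array([1.0, 1.0, 1.0]), 0.0, 0.0)
        assert p == 0.0 and ss == 1.0


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03]), [0.03])

    def test_bh_stepup_by_hand(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_at_most_one(self, ps):
        adj = adjust_pvalues(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 1.2])

    def test_alternative_methods(self):
        ps = [0.01, 0.04]
        np.testing.assert_allclose(adjust_pvalues(ps, "bonferroni"),
                                   [0.02, 0.08])
        np.testing.assert_allclose(adjust_pvalues(ps, "holm"),
                                   [0.02, 0.04])


class TestScaleAndMask:
    def _results(self, ss, p_adj, biosensor="BS1"):
        return pd.DataFrame({"biosensor_id": biosensor, "ss_raw": ss,
                             "p_adj": p_adj})

    def test_scaling_arithmetic(self):
        out = scale_and_mask(self._results([0.2, -0.4], [0.01, 0.01]))
        np.testing.assert_allclose(out["ss_scaled"], [0.5, -1.0])

    def test_range_and_extremum(self, rng):
        ss = rng.normal(size=10)
        out = scale_and_mask(self._results(ss, np.full(10, 0.01)))
        assert out["ss_scaled"].abs().max() == pytest.approx(1.0)
        assert out["ss_scaled"].between(-1, 1).all()

    def test_mask_threshold(self):
        out = scale_and_mask(self._results([0.2, 0.3], [0.06, 0.04]))
        assert list(out["masked"]) == [True, False]

    def test_all_zero_scores_stay_zero(self):
        out = scale_and_mask(self._results([0.0, 0.0], [0.5, 0.5]))
        np.testing.assert_array_equal(out["ss_scaled"], 0.0)

    def test_scale_invariance(self, rng):
        ss = rng.normal(size=8)
        a = scale_and_mask(self._results(ss, np.full(8, 0.01)))
        b = scale_and_mask(self._results(ss * 123.0, np.full(8, 0.01)))
        np.testing.assert_allclose(a["ss_scaled"], b["ss_scaled"])


class TestSynergyMap:
    def test_identical_rows_adjacent_with_zero_height(self):
        scores = pd.DataFrame([[1.0, -1.0, 0.5]] * 2 + [[-1.0, 1.0, 0.0]],
                              index=["a", "b", "c"],
                              columns=["p1", "p2", "p3"])
        smap = synergy_map(scores)
        order = list(smap.matrix.index)
        assert abs(order.index("a") - order.index("b")) == 1
        assert smap.row_linkage[0, 2] == 0.0

    def test_planted_blocks_recovered(self, rng):
        block = np.vstack([np.tile([1.0, 1.0, -1.0], (5, 1)),
                           np.tile([-1.0, -1.0, 1.0], (5, 1))])
        block = block + rng.normal(0, 0.05, block.shape)
        scores = pd.DataFrame(block,
                              index=[f"bs{i}" for i in range(10)],
                              columns=["p1", "p2", "p3"])
        smap = synergy_map(scores)
        from scipy.cluster import hierarchy
        labels = hierarchy.fcluster(smap.row_linkage, 2,
                                    criterion="maxclust")
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score([0] * 5 + [1] * 5, labels) == 1.0

    def test_reordering_is_a_permutation(self, rng):
        scores = pd.DataFrame(rng.normal(size=(6, 4)))
        smap = synergy_map(scores)
        assert sorted(smap.matrix.to_numpy().ravel()) == \
            sorted(scores.to_numpy().ravel())

    def test_single_row_identity(self):
        scores = pd.DataFrame([[0.1, 0.2]], index=["a"],
                              columns=["p1", "p2"])
        smap = synergy_map(scores)
        assert list(smap.row_order) == [0]


# --------------------------------------------------------------------------
# end-to-end statistical behaviour on simulated experiments
# --------------------------------------------------------------------------


def run_one_interaction(model, gamma, n_cells, seed, stim=30.0):
    """Simulate one interaction experiment and score the AB pair."""
    df = fmip.simulate_interaction_experiment(
        model, gamma=gamma, n_cells_per_arm=n_cells, n_vehicle=100,
        cell_noise=fmip.CellNoise(amplitude_sigma=0.25,
                                  ratio_noise_sd=0.02),
        stimulation_time=stim, seed=seed)
    norm = fmip.normalize_trajectories(df, stim,
                                       vehicle_condition="vehicle")
    norm = norm[norm.condition_id != "vehicle"]
    rows = []
    for (cond, cell), sub in norm.groupby(["condition_id", "cell_id"]):
        sub = sub.sort_values("time_min")
        rows.append({"biosensor_id": model.biosensor_id,
                     "condition_id": cond, "auc":
                     fmip.auc(sub["time_min"].to_numpy(),
                              sub["normalized"].to_numpy() - 1.0, stim)})
    table = pd.DataFrame(rows)
    return synergy_analysis(table, {"AB": ("A", "B", "AB")}).iloc[0]


def test_additive_simulations_are_rarely_significant(strong_model):
    results = [run_one_interaction(strong_model, 0.0, 60, seed)
               for seed in range(20)]
    p_adj = adjust_pvalues([r["p"] for r in results])
    assert (p_adj < 0.05).mean() <= 0.15  # small-sample type-I sanity check


def test_injected_interaction_sign_recovered(strong_model):
    for gamma, sign in ((0.5, 1.0), (-0.5, -1.0)):
        results = [run_one_interaction(strong_model, gamma, 100, 100 + s)
                   for s in range(8)]
        assert all(np.sign(r["ss_raw"]) == sign for r in results)
        assert np.mean([r["p"] < 0.05 for r in results]) >= 0.8


def test_score_error_shrinks_with_sample_size(strong_model):
    """log-RMSE of ss_raw vs log-n has slope near -1/2 (consistency)."""
    ns = [25, 50, 100, 200]
    rmse = []
    for n in ns:
        errors = [run_one_interaction(strong_model, 0.0, n, 1000 + 17 * n
                                      + r)["ss_raw"]
                  for r in range(40)]
        rmse.append(np.sqrt(np.mean(np.square(errors))))
    slope = np.polyfit(np.log(ns), np.log(rmse), 1)[0]
    assert -0.6 <= slope <= -0.4
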