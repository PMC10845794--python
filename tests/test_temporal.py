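import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from swmap.grid import CENTER_LOCATION, RANK_COLUMNS
from swmap.model import fit_swm
from swmap.preprocess import preprocess
from swmap.simulate import (
    center_boost_profile,
    exp3_design,
    exp4_design,
    fixed_weight_observer,
    linear_rank_profile,
    simulate_dataset,
)
from swmap.temporal import (
    add_serial_ranks,
    aggregate_and_zscore,
    cross_condition_prediction,
    polynomial_model_comparison,
    rank_serial_positions,
    serial_swm_matrix,
)
from swmap.grid import DEV_COLUMNS


class TestRanks:
    def test_strictly_increasing_onsets(self):
        onsets = np.arange(25.0)
        assert np.array_equal(rank_serial_positions(onsets), np.arange(1, 26))

    def test_reversed_onsets(self):
        onsets = np.arange(25.0)[::-1]
        assert np.array_equal(rank_serial_positions(onsets), np.arange(25, 0, -1))

    def test_tie_convention_competition_ranking(self):
        onsets = np.arange(25.0)
        onsets[1] = 0.0  # two elements at the earliest time
        ranks = rank_serial_positions(onsets)
        assert ranks[0] == ranks[1] == 1
        assert ranks[2] == 3

    def test_missing_onsets_raise(self):
        with pytest.raises(ValueError, match="simultaneous"):
            rank_serial_positions(np.full(25, np.nan))


class TestAggregateAndZscore:
    @staticmethod
    def _pre(n_subjects=3, n_trials=40, seed=0):
        rng = np.random.default_rng(seed)
        design = exp4_design(n_trials_per_subject=n_trials)
        observers = [fixed_weight_observer(name=f"S{i}") for i in range(n_subjects)]
        pre, _ = preprocess(simulate_dataset(design, observers, rng))
        return pre

    def test_two_value_subject_zscores(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b", "b"],
            "error_deg": [-10.0, 10.0, 0.0, 1.0, 2.0],
        })
        pooled, dropped = aggregate_and_zscore(df)
        a = pooled.loc[pooled.subject_id == "a", "error_z"].to_numpy()
        assert np.allclose(sorted(a), [-np.sqrt(0.5), np.sqrt(0.5)])
        assert dropped == []

    def test_per_subject_moments(self):
        pooled, _ = aggregate_and_zscore(self._pre())
        for _, grp in pooled.groupby("subject_id"):
            assert grp["error_z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["error_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_of_pooled_fit(self):
        """Multiplying one subject's error scale changes nothing after
        z-scoring."""
        pre = self._pre()
        scaled = pre.copy()
        mask = scaled["subject_id"] == scaled["subject_id"].iloc[0]
        scaled.loc[mask, "error_deg"] *= 7.0
        p1, _ = aggregate_and_zscore(pre)
        p2, _ = aggregate_and_zscore(scaled)
        w1 = fit_swm(p1[DEV_COLUMNS].to_numpy(), p1["error_z"].to_numpy()).params
        w2 = fit_swm(p2[DEV_COLUMNS].to_numpy(), p2["error_z"].to_numpy()).params
        assert np.allclose(w1, w2)

    def test_duplicated_subject_leaves_weights_unchanged(self):
        pre = self._pre()
        pooled, _ = aggregate_and_zscore(pre)
        dup = pre.copy()
        dup["subject_id"] = dup["subject_id"] + "_copy"
        pooled2, _ = aggregate_and_zscore(pd.concat([pre, dup], ignore_index=True))
        w1 = fit_swm(pooled[DEV_COLUMNS].to_numpy(), pooled["error_z"].to_numpy()).params
        w2 = fit_swm(pooled2[DEV_COLUMNS].to_numpy(), pooled2["error_z"].to_numpy()).params
        assert np.allclose(w1, w2, atol=1e-10)

    def test_single_trial_subject_dropped(self):
        df = pd.DataFrame({
            "subject_id": ["solo", "b", "b", "b"],
            "error_deg": [5.0, 0.0, 1.0, 2.0],
        })
        pooled, dropped = aggregate_and_zscore(df)
        assert dropped == ["solo"]
        assert "solo" not in set(pooled["subject_id"])


@pytest.fixture(scope="module")
def pooled_linear_center():
    """Pooled Exp-4 style data from observers whose central weight is
    exactly linear in the central element's serial rank."""
    rng = np.random.default_rng(1101)
    design = exp4_design(n_trials_per_subject=220)
    observers = [fixed_weight_observer(rank_weight_fn=linear_rank_profile(CENTER_LOCATION),
                                       name=f"S{i}") for i in range(8)]
    pre, _ = preprocess(simulate_dataset(design, observers, rng))
    pooled, _ = aggregate_and_zscore(add_serial_ranks(pre))
    return pooled


class TestSerialMatrix:
    def test_shape_windows_and_counts(self, pooled_linear_center):
        mat = serial_swm_matrix(pooled_linear_center, locations=[CENTER_LOCATION])
        assert mat.matrix.shape == (25, 23)
        assert np.array_equal(mat.window_positions, np.arange(1, 24))
        row_counts = mat.n_trials_per_cell[CENTER_LOCATION - 1]
        assert row_counts.sum() > 0

    def test_center_row_tracks_rank(self, pooled_linear_center):
        mat = serial_swm_matrix(pooled_linear_center, locations=[CENTER_LOCATION])
        row = mat.matrix[CENTER_LOCATION - 1]
        ok = np.isfinite(row)
        rho = spearmanr(np.arange(23)[ok], row[ok]).statistic
        assert rho > 0.6

    def test_rank_insensitive_observer_row_is_flat(self):
        rng = np.random.default_rng(1102)
        design = exp4_design(n_trials_per_subject=220)
        observers = [fixed_weight_observer(weight_profile=center_boost_profile(3.0),
                                           name=f"S{i}") for i in range(8)]
        pre, _ = preprocess(simulate_dataset(design, observers, rng))
        pooled, _ = aggregate_and_zscore(add_serial_ranks(pre))
        mat = serial_swm_matrix(pooled, locations=[CENTER_LOCATION])
        row = mat.matrix[CENTER_LOCATION - 1]
        ok = np.isfinite(row)
        rho = spearmanr(np.arange(23)[ok], row[ok]).statistic
        assert abs(rho) < 0.5

    def test_trial_order_invariance(self, pooled_linear_center):
        shuffled = pooled_linear_center.sample(frac=1.0, random_state=3)
        m1 = serial_swm_matrix(pooled_linear_center, locations=[8])
        m2 = serial_swm_matrix(shuffled, locations=[8])
        assert np.allclose(m1.matrix[7], m2.matrix[7], equal_nan=True)

    def test_requires_ranks(self):
        df = pd.DataFrame({"error_z": [0.0]})
        with pytest.raises(ValueError, match="rank"):
            serial_swm_matrix(df)


class TestPolynomialComparison:
    def test_noiseless_linear_timecourse(self):
        x = np.arange(20.0)
        tc = np.tile(0.5 * x, (6, 1)) + np.random.default_rng(0).normal(0, 1e-6, (6, 20))
        res = polynomial_model_comparison(tc, n_splits=200,
                                          rng=np.random.default_rng(1))
        assert res.mean_correlation[1] == pytest.approx(1.0, abs=1e-3)
        assert all(res.mean_correlation[m] <= res.mean_correlation[1] + 1e-9
                   for m in (2, 3, 4))

    def test_noiseless_quadratic_timecourse(self):
        x = np.arange(20.0) - 9.5
        tc = np.tile(x ** 2, (6, 1)) + np.random.default_rng(2).normal(0, 1e-6, (6, 20))
        res = polynomial_model_comparison(tc, n_splits=200,
                                          rng=np.random.default_rng(3))
        assert res.best_order == 2

    def test_linear_plus_noise_prefers_order_one(self):
        """Monte-Carlo: over repeated noisy linear timecourses, order 1 wins
        the split-half comparison in at least 90% of repetitions."""
        rng = np.random.default_rng(4)
        wins = 0
        reps = 20
        x = np.arange(23.0)
        for _ in range(reps):
            tc = 0.05 * x + rng.normal(0, 0.1, (16, 23))
            res = polynomial_model_comparison(tc, n_splits=200, rng=rng)
            wins += res.best_order == 1
        assert wins >= 0.9 * reps

    def test_input_validation(self):
        with pytest.raises(ValueError):
            polynomial_model_comparison(np.zeros((3, 20)), n_splits=10,
                                        rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            polynomial_model_comparison(np.zeros((6, 4)), n_splits=10,
                                        rng=np.random.default_rng(0))


class TestCrossConditionPrediction:
    def test_noiseless_fixed_weights_near_perfect(self):
        rng = np.random.default_rng(5)
        design = exp3_design(n_trials_per_subject=240)
        observers = [fixed_weight_observer(weight_profile=center_boost_profile(5.0),
                                           motor_noise_sd=0.0, name=f"S{i}")
                     for i in range(3)]
        pre, _ = preprocess(simulate_dataset(design, observers, rng))
        res = cross_condition_prediction(pre, "duration_ms", 100.0,
                                         rng=np.random.default_rng(6), n_shuffles=50)
        assert res.mean_correlation() > 0.99

    def test_stable_weights_beat_chance_band(self):
        rng = np.random.default_rng(7)
        design = exp3_design(n_trials_per_subject=900)
        observers = [fixed_weight_observer(weight_profile=center_boost_profile(5.0),
                                           motor_noise_sd=2.0, name=f"S{i}")
                     for i in range(5)]
        pre, _ = preprocess(simulate_dataset(design, observers, rng))
        res = cross_condition_prediction(pre, "duration_ms", 100.0,
                                         rng=np.random.default_rng(8), n_shuffles=100)
        assert res.mean_correlation() > res.null_q99
        assert res.null_q01 < res.null_median < res.null_q99

    def test_unstable_weights_fall_in_chance_band(self):
        """If the weight profile is re-drawn between conditions there is
        nothing to transfer: prediction correlations sit inside the band."""
        rng = np.random.default_rng(9)
        frames = []
        for dur in (100.0, 500.0):
            profile = rng.dirichlet(np.ones(25) * 0.4)
            design = exp3_design(duration_levels_ms=(dur,), n_trials_per_subject=300)
            observers = [fixed_weight_observer(weight_profile=profile,
                                               motor_noise_sd=2.0, name=f"S{i}")
                         for i in range(4)]
            frames.append(simulate_dataset(design, observers, rng))
        pre, _ = preprocess(pd.concat(frames, ignore_index=True))
        res = cross_condition_prediction(pre, "duration_ms", 100.0,
                                         test_levels=[500.0],
                                         rng=np.random.default_rng(10),
                                         n_shuffles=100)
        assert res.null_q01 < res.mean_correlation() < res.null_q99

    def test_missing_training_condition(self):
        df = pd.DataFrame({"subject_id": ["a"], "duration_ms": [500.0],
                           "error_deg": [1.0], **{c: [0.0] for c in DEV_COLUMNS}})
        with pytest.raises(ValueError):
            cross_condition_prediction(df, "duration_ms", 100.0,
                                       rng=np.random.default_rng(0))
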