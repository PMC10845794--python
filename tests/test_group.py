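import numpy as np
import pandas as pd
import pytest

from swmap.grid import CENTER_LOCATION, N_LOCATIONS
from swmap.group import (
    bias_score,
    cohens_d,
    condition_effect_map,
    permutation_location_test,
    rm_anova,
)


class TestPermutationLocationTest:
    def test_identical_scores_nothing_significant(self):
        maps = [np.full(N_LOCATIONS, 2.0)] * 6
        res = permutation_location_test(maps, n_permutations=500,
                                        rng=np.random.default_rng(0))
        assert not res.significant.any()
        assert np.allclose(res.p_values, 1.0)

    def test_consistent_spike_detected(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(0, 1, (15, N_LOCATIONS))
        maps[:, 4] = 10.0
        res = permutation_location_test(maps, n_permutations=2000,
                                        rng=np.random.default_rng(2))
        assert res.significant[4]
        assert res.significant.sum() == 1
        assert res.p_values[4] == pytest.approx(1.0 / 2001.0)

    def test_pvalue_floor_and_fields(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(0, 1, (5, N_LOCATIONS))
        res = permutation_location_test(maps, n_permutations=300,
                                        rng=np.random.default_rng(4))
        assert np.all(res.p_values >= 1.0 / 301.0)
        assert np.all(res.p_values <= 1.0)
        assert res.alpha_corrected == pytest.approx(0.05 / 25)
        assert (res.significant == (res.p_values < res.alpha_corrected)).all()

    def test_few_permutations_warns(self):
        maps = np.random.default_rng(5).normal(0, 1, (4, N_LOCATIONS))
        with pytest.warns(UserWarning, match="permutations"):
            permutation_location_test(maps, n_permutations=50,
                                      rng=np.random.default_rng(6))

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            permutation_location_test([np.zeros(N_LOCATIONS)], n_permutations=200,
                                      rng=np.random.default_rng(0))

    def test_null_pvalues_super_uniform(self):
        """Under an exchangeable null, P(p <= a) <= a (checked at several
        thresholds over repeated null datasets)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(60):
            maps = rng.normal(0, 1, (6, N_LOCATIONS))
            res = permutation_location_test(maps, n_permutations=200, rng=rng)
            pvals.extend(res.p_values)
        pvals = np.asarray(pvals)
        for a in (0.05, 0.1, 0.25, 0.5):
            # binomial slack: 3 sigma on 1500 correlated draws
            assert (pvals <= a).mean() < a + 3 * np.sqrt(a * (1 - a) / 300)


class TestBiasScore:
    def test_uniform_map_zero(self):
        assert bias_score(np.ones(N_LOCATIONS)) == 0.0

    def test_simple_arithmetic(self):
        scores = np.ones(N_LOCATIONS)
        scores[CENTER_LOCATION - 1] = 3.0
        assert bias_score(scores) == pytest.approx(2.0)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, N_LOCATIONS)
        b0 = bias_score(scores, target=7, controls=[1, 2, 25])
        b1 = bias_score(scores + 11.3, target=7, controls=[1, 2, 25])
        assert b0 == pytest.approx(b1)

    def test_index_validation(self):
        scores = np.zeros(N_LOCATIONS)
        with pytest.raises(ValueError):
            bias_score(scores, target=13, controls=[13, 1])
        with pytest.raises(ValueError):
            bias_score(scores, target=13, controls=[])
        with pytest.raises(ValueError):
            bias_score(scores, target=26)


class TestConditionEffectMap:
    @staticmethod
    def _maps(slope_per_level, noise, rng, subjects=8, levels=(5.0, 10.0, 15.0)):
        maps = {}
        for s in range(subjects):
            for lv in levels:
                m = rng.normal(0, noise, N_LOCATIONS)
                m[CENTER_LOCATION - 1] += slope_per_level * lv
                maps[(f"S{s}", lv)] = m
        return maps

    def test_level_independent_scores_not_significant(self):
        rng = np.random.default_rng(9)
        maps = self._maps(0.0, 1.0, rng)
        res = condition_effect_map(maps, (5.0, 10.0, 15.0), n_permutations=1000,
                                   rng=np.random.default_rng(10))
        assert not res.significant.any()
        assert np.abs(res.slopes).max() < 0.2

    def test_center_slope_detected(self):
        rng = np.random.default_rng(11)
        maps = self._maps(0.3, 0.5, rng, subjects=12)
        res = condition_effect_map(maps, (5.0, 10.0, 15.0), n_permutations=2000,
                                   rng=np.random.default_rng(12))
        assert res.significant[CENTER_LOCATION - 1]
        assert res.slopes[CENTER_LOCATION - 1] == pytest.approx(0.3, abs=0.1)

    def test_invariance_to_subject_and_level_order(self):
        rng = np.random.default_rng(13)
        maps = self._maps(0.1, 0.3, rng)
        reordered = dict(reversed(list(maps.items())))
        r1 = condition_effect_map(maps, (15.0, 5.0, 10.0), n_permutations=200,
                                  rng=np.random.default_rng(1))
        r2 = condition_effect_map(reordered, (5.0, 10.0, 15.0), n_permutations=200,
                                  rng=np.random.default_rng(1))
        assert np.allclose(r1.slopes, r2.slopes)

    def test_missing_cell_names_subject(self):
        rng = np.random.default_rng(14)
        maps = self._maps(0.0, 1.0, rng, subjects=3)
        del maps[("S1", 10.0)]
        with pytest.raises(ValueError, match="S1"):
            condition_effect_map(maps, (5.0, 10.0, 15.0), n_permutations=100,
                                 rng=np.random.default_rng(0))


class TestRmAnova:
    def test_constant_values_give_zero_F(self):
        df = pd.DataFrame([{"subject_id": s, "cond": c, "val": 1.0}
                           for s in range(4) for c in "abc"])
        res = rm_anova(df, dv="val", within="cond")
        assert res["cond"].F == 0.0
        assert res["cond"].p == 1.0

    def test_hand_worked_two_level_table(self):
        """3 subjects x 2 conditions, worked by hand: the paired t on the
        differences (1, 4, 1) is 2, so F = t^2 = 4 with df (1, 2)."""
        cells = [(1.0, 2.0), (0.0, 4.0), (2.0, 3.0)]
        df = pd.DataFrame([{"subject_id": s, "cond": c, "val": v}
                           for s, pair in enumerate(cells)
                           for c, v in zip("ab", pair)])
        res = rm_anova(df, dv="val", within="cond")["cond"]
        assert res.F == pytest.approx(4.0)
        assert (res.df1, res.df2) == (1, 2)
        assert res.partial_eta_sq == pytest.approx(res.F * res.df1 /
                                                   (res.F * res.df1 + res.df2))

    def test_two_way_effects_present(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame([
            {"subject_id": s, "sigma": sg, "loc": lc,
             "val": rng.normal() + 0.8 * sg}
            for s in range(6) for sg in (1, 2, 3) for lc in "xyz"
        ])
        res = rm_anova(df, dv="val", within=["sigma", "loc"])
        assert set(res) == {"sigma", "loc", "sigma * loc"}
        assert res["sigma"].p < 0.01
        for eff in res.values():
            assert eff.partial_eta_sq == pytest.approx(
                eff.F * eff.df1 / (eff.F * eff.df1 + eff.df2))

    def test_unbalanced_raises(self):
        df = pd.DataFrame([{"subject_id": s, "cond": c, "val": 1.0}
                           for s in range(3) for c in "ab"][:-1])
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(df, dv="val", within="cond")


class TestCohensD:
    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0, 1.0, 1.0])

    def test_two_point_value(self):
        assert cohens_d([0.0, 2.0]).d_prime == pytest.approx(1 / np.sqrt(2))

    def test_paired_reference(self):
        res = cohens_d([3.0, 5.0, 4.0], reference=[1.0, 2.0, 3.0])  # diffs 2, 3, 1
        assert res.d_prime == pytest.approx(2.0)
        with pytest.raises(ValueError):  # constant paired difference: zero SD
            cohens_d([3.0, 4.0, 5.0], reference=[1.0, 2.0, 3.0])
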