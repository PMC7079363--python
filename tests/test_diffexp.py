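"""Linear-model fits, variance moderation and differential calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protcoex import (
    GeneratorConfig,
    call_de,
    classify_restored,
    compute_contrast,
    filter_low_abundance,
    fit_condition_means,
    generate,
    log2_transform,
    moderate_variances,
)
from protcoex.diffexp import ModelFit, trigamma_inverse
from scipy import special

from conftest import build_matrix


def two_condition_fit(values_a, values_b):
    """Fit a 2-condition layout from explicit replicate values."""
    values = np.array([list(values_a) + list(values_b)])
    n = len(values_a)
    matrix = build_matrix(2.0 ** values, conditions=("O19", "O1"), replicates=n)
    return fit_condition_means(log2_transform(matrix))


class TestFitConditionMeans:
    def test_hand_computed_two_by_two(self):
        # conditions (0,2 | 1,3): means (1,2), pooled s2 = (2+2)/2 = 2, df = 2
        fit = two_condition_fit((0.0, 2.0), (1.0, 3.0))
        assert fit.means.iloc[0].tolist() == [1.0, 2.0]
        assert fit.s2.iloc[0] == pytest.approx(2.0)
        assert fit.df_resid == 2

    def test_identical_replicates_zero_variance(self):
        fit = two_condition_fit((1.0, 1.0, 1.0), (4.0, 4.0, 4.0))
        assert fit.s2.iloc[0] == 0.0

    def test_single_replicate_rejected(self):
        values = np.array([[1.0, 2.0]])
        matrix = build_matrix(2.0 ** values, conditions=("O19", "O1"), replicates=1)
        with pytest.raises(ValueError, match="replicate"):
            fit_condition_means(log2_transform(matrix))

    def test_variance_estimate_unbiased_on_null(self):
        rng = np.random.default_rng(21)
        sigma = 0.4
        matrix = build_matrix(2.0 ** rng.normal(10, sigma, size=(5000, 9)))
        fit = fit_condition_means(log2_transform(matrix))
        assert fit.s2.mean() == pytest.approx(sigma**2, rel=0.05)


class TestModerateVariances:
    def test_equal_variances_give_infinite_prior(self):
        fit = ModelFit(
            means=pd.DataFrame({"O19": np.zeros(100), "O1": np.zeros(100)}),
            s2=pd.Series(np.full(100, 0.5)),
            df_resid=4,
            n_per_condition={"O19": 3, "O1": 3},
        )
        mfit = moderate_variances(fit)
        assert math.isinf(mfit.d0)
        np.testing.assert_allclose(mfit.s2_post, mfit.s0_sq)

    def test_skip_flag_is_identity(self):
        rng = np.random.default_rng(1)
        fit = ModelFit(
            means=pd.DataFrame({"O19": np.zeros(50), "O1": np.zeros(50)}),
            s2=pd.Series(rng.gamma(2.0, 0.1, size=50)),
            df_resid=4,
            n_per_condition={"O19": 3, "O1": 3},
        )
        mfit = moderate_variances(fit, skip=True)
        assert mfit.d0 == 0.0
        np.testing.assert_array_equal(mfit.s2_post, fit.s2)

    def test_all_zero_variances_rejected(self):
        fit = ModelFit(
            means=pd.DataFrame({"O19": np.zeros(60), "O1": np.zeros(60)}),
            s2=pd.Series(np.zeros(60)),
            df_resid=4,
            n_per_condition={"O19": 3, "O1": 3},
        )
        with pytest.raises(ValueError, match="zero"):
            moderate_variances(fit)

    def test_prior_df_recovery(self):
        # true variances from a scaled inverse-chi-square prior with d0=4,
        # s0^2=1; observed s2 ~ sigma_g^2 chi2_d / d with d=6
        rng = np.random.default_rng(42)
        d0_true, s0_sq, d = 4.0, 1.0, 6
        n = 5000
        sigma_sq = d0_true * s0_sq / rng.chisquare(d0_true, size=n)
        s2 = sigma_sq * rng.chisquare(d, size=n) / d
        fit = ModelFit(
            means=pd.DataFrame({"O19": np.zeros(n), "O1": np.zeros(n)}),
            s2=pd.Series(s2),
            df_resid=d,
            n_per_condition={"O19": 4, "O1": 4},
        )
        mfit = moderate_variances(fit)
        assert mfit.d0 == pytest.approx(d0_true, rel=0.30)
        assert mfit.s0_sq == pytest.approx(s0_sq, rel=0.30)

    def test_shrinkage_between_bounds_and_monotone(self):
        rng = np.random.default_rng(3)
        s2 = rng.gamma(1.5, 0.2, size=500)
        fit = ModelFit(
            means=pd.DataFrame({"O19": np.zeros(500), "O1": np.zeros(500)}),
            s2=pd.Series(s2),
            df_resid=6,
            n_per_condition={"O19": 4, "O1": 4},
        )
        mfit = moderate_variances(fit)
        lo = np.minimum(s2, mfit.s0_sq)
        hi = np.maximum(s2, mfit.s0_sq)
        assert ((mfit.s2_post >= lo - 1e-12) & (mfit.s2_post <= hi + 1e-12)).all()
        order = np.argsort(s2)
        assert (np.diff(mfit.s2_post.to_numpy()[order]) >= -1e-15).all()

    def test_trigamma_inverse_round_trip(self):
        for x in (0.01, 0.5, 1.0, 4.0, 100.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-8)


class TestComputeContrast:
    def test_zero_fold_change_gives_p_one(self):
        fit = two_condition_fit((0.0, 2.0), (0.0, 2.0))
        res = compute_contrast(moderate_variances(fit, skip=True), "O19_vs_O1")
        assert res.table["log2fc"].iloc[0] == 0.0
        assert res.table["t"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_unmoderated_equals_classical_pooled_t(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, size=(200, 6))
        matrix = build_matrix(2.0 ** values, conditions=("O19", "O1"), replicates=3)
        fit = fit_condition_means(log2_transform(matrix))
        res = compute_contrast(moderate_variances(fit, skip=True), "O19_vs_O1")
        t_ref, p_ref = stats.ttest_ind(values[:, :3], values[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(7)
        matrix = build_matrix(2.0 ** rng.normal(5, 1, size=(50, 9)))
        mfit = moderate_variances(fit_condition_means(log2_transform(matrix)))
        ab = compute_contrast(mfit, "O19_vs_O1").table
        ba = compute_contrast(mfit, "O1_vs_O19").table
        np.testing.assert_allclose(ba["log2fc"], -ab["log2fc"])
        np.testing.assert_allclose(ba["t"], -ab["t"])
        np.testing.assert_allclose(ba["p"], ab["p"])

    def test_null_pvalues_uniform(self, null_pvalues_5000):
        stat = stats.kstest(null_pvalues_5000, "uniform").statistic
        assert stat < 0.03

    def test_unknown_contrast_rejected(self):
        fit = two_condition_fit((0.0, 2.0), (1.0, 3.0))
        with pytest.raises(ValueError, match="unknown condition"):
            compute_contrast(moderate_variances(fit, skip=True), "O19_vs_O5")


class TestCallDe:
    def test_fold_change_arm_excludes(self):
        table = pd.DataFrame(
            {"log2fc": [0.4, 0.6], "t": [5.0, 5.0], "p": [0.005, 0.005],
             "p_adj": [0.01, 0.01]},
            index=["A", "B"],
        )
        from protcoex.diffexp import ContrastResult

        assert call_de(ContrastResult("O19_vs_O1", table)) == {"B"}

    def test_de_set_shrinks_with_stricter_thresholds(self, small_synthetic):
        _, matrix, _ = small_synthetic
        filtered, _ = filter_low_abundance(matrix)
        mfit = moderate_variances(fit_condition_means(log2_transform(filtered)))
        res = compute_contrast(mfit, "O19_vs_O1")
        loose = call_de(res, p_max=0.05, lfc_min=0.25)
        default = call_de(res)
        strict = call_de(res, p_max=0.001, lfc_min=1.0)
        assert strict <= default <= loose

    def test_planted_effects_recovered(self, small_synthetic):
        _, matrix, truth = small_synthetic
        filtered, _ = filter_low_abundance(matrix)
        mfit = moderate_variances(fit_condition_means(log2_transform(filtered)))
        de = call_de(compute_contrast(mfit, "O19_vs_O1"))
        planted = truth.de_proteins
        recall = len(de & planted) / len(planted)
        unplanted = set(truth.labels.index[truth.labels == "null"]) - set(truth.module_of)
        fp_rate = len(de & unplanted) / len(unplanted)
        assert recall >= 0.8
        assert fp_rate <= 0.02


class TestClassifyRestored:
    @staticmethod
    def _contrasts(matrix):
        filtered, _ = filter_low_abundance(matrix)
        mfit = moderate_variances(fit_condition_means(log2_transform(filtered)))
        return {
            name: compute_contrast(mfit, name)
            for name in ("O19_vs_O1", "O19_vs_O1CyA", "O1_vs_O1CyA")
        }

    def test_de_everywhere_is_not_restored(self, small_synthetic):
        _, matrix, truth = small_synthetic
        restored = classify_restored(self._contrasts(matrix))
        # persistent DE proteins (shifted in both hypoxia arms) never qualify
        assert not restored & truth.de_proteins

    def test_no_effect_is_not_restored(self, small_synthetic):
        _, matrix, truth = small_synthetic
        restored = classify_restored(self._contrasts(matrix))
        unplanted = set(truth.labels.index[truth.labels == "null"]) - set(truth.module_of)
        assert len(restored & unplanted) <= 1

    def test_planted_restored_detected(self):
        # 200 independent replications of a restored protein (delta=1, sigma=0.2)
        # plus calibration nulls, analysed jointly
        rng = np.random.default_rng(15)
        n_restored, n_null = 200, 300
        values = rng.normal(10, 0.2, size=(n_restored + n_null, 9))
        values[:n_restored, 3:6] += 1.0  # shift at O1 only
        matrix = build_matrix(2.0 ** values)
        restored = classify_restored(self._contrasts(matrix))
        hits = sum(1 for i in range(n_restored) if f"P{i + 1}" in restored)
        assert hits / n_restored >= 0.9
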