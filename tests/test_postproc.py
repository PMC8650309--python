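"""Covariance functions, heritability, accuracies, correlations, curves."""
import numpy as np
import pandas as pd
import pytest

from heatnorm import postproc
from heatnorm.envgrad import build_gradient


def _basis():
    return build_gradient([0.0, 10.0])


class TestCovarianceFunction:
    def test_zero_map(self):
        phi = _basis().design(np.linspace(0, 10, 5))
        assert np.all(postproc.covariance_function(np.zeros((2, 2)), phi) == 0)

    def test_intercept_only_gives_constant_one(self):
        g0 = np.array([[2.0, 0.0], [0.0, 0.0]])
        phi = _basis().design(np.linspace(0, 10, 7))
        gamma = postproc.covariance_function(g0, phi)
        np.testing.assert_allclose(np.diag(gamma), 1.0)   # phi0^2 * 2 = 0.5 * 2

    def test_matches_elementwise_triple_sum(self, rng):
        B = rng.standard_normal((2, 2))
        g0 = B @ B.T + 0.1 * np.eye(2)
        phi = _basis().design(np.linspace(0, 10, 20))
        gamma = postproc.covariance_function(g0, phi)
        brute = np.zeros((20, 20))
        for k in range(20):
            for kp in range(20):
                for i in range(2):
                    for j in range(2):
                        brute[k, kp] += phi[k, i] * g0[i, j] * phi[kp, j]
        np.testing.assert_allclose(gamma, brute, atol=1e-12)


class TestHeritability:
    def test_hand_computed_third(self):
        gammas = {"a": np.eye(4)}
        out = postproc.heritability_trajectory(gammas, sigma2_e=2.0)
        np.testing.assert_allclose(out["h2"], 1.0 / 3.0)

    def test_flat_when_no_slope_variance(self):
        g0 = np.array([[1.0, 0.0], [0.0, 0.0]])
        phi = _basis().design(np.linspace(0, 10, 9))
        gammas = {"a": postproc.covariance_function(g0, phi)}
        out = postproc.heritability_trajectory(gammas, 1.0)
        assert out["h2"].std() == pytest.approx(0.0, abs=1e-15)

    def test_unity_without_residual(self):
        gammas = {"a": 2.5 * np.eye(3)}
        out = postproc.heritability_trajectory(gammas, 0.0)
        np.testing.assert_allclose(out["h2"], 1.0)

    def test_bounded_for_psd_components(self, rng):
        phi = _basis().design(np.linspace(0, 10, 15))
        for _ in range(25):
            gammas = {}
            for name in ("a", "pe", "ce"):
                B = rng.standard_normal((2, 2))
                gammas[name] = postproc.covariance_function(B @ B.T, phi)
            out = postproc.heritability_trajectory(gammas, float(rng.uniform(0.01, 3)))
            assert ((out["h2"] >= 0) & (out["h2"] <= 1)).all()


class TestAccuracy:
    def _gebv(self, sds):
        return pd.DataFrame({
            "animal": range(1, len(sds) + 1),
            "a0": 0.0, "a0_sd": sds, "a1": 0.0, "a1_sd": sds,
        })

    def test_fully_resolved_posterior(self):
        gebv = self._gebv([0.0])
        F = pd.Series([0.0], index=[1])
        acc = postproc.gebv_accuracy(gebv, F, {"a0": 1.0, "a1": 1.0})
        assert acc["acc_a0"].iloc[0] == 1.0

    def test_prior_level_uncertainty_gives_zero(self):
        F = pd.Series([0.21], index=[1])
        gebv = self._gebv([np.sqrt(1.21)])
        acc = postproc.gebv_accuracy(gebv, F, {"a0": 1.0, "a1": 1.0})
        assert acc["acc_a0"].iloc[0] == pytest.approx(0.0)

    def test_point_eight(self):
        gebv = self._gebv([0.6])
        F = pd.Series([0.0], index=[1])
        acc = postproc.gebv_accuracy(gebv, F, {"a0": 1.0, "a1": 1.0})
        assert acc["acc_a0"].iloc[0] == pytest.approx(0.8)

    def test_monotone_in_posterior_sd(self):
        gebv = self._gebv(np.linspace(0.0, 1.0, 11))
        F = pd.Series(0.0, index=gebv["animal"])
        acc = postproc.gebv_accuracy(gebv, F, {"a0": 1.0, "a1": 1.0})
        assert (np.diff(acc["acc_a0"]) < 0).all()

    def test_clipping_is_counted(self):
        gebv = self._gebv([2.0])
        F = pd.Series([0.0], index=[1])
        acc = postproc.gebv_accuracy(gebv, F, {"a0": 1.0, "a1": 1.0})
        assert acc["acc_a0"].iloc[0] == 0.0 and acc.attrs["n_clipped"] == 2


class TestEnvCorrelation:
    def test_unit_diagonal_and_symmetry(self, rng):
        g0 = np.array([[1.0, 0.2], [0.2, 0.6]])
        values = rng.uniform(0, 10, 500)
        out = postproc.env_genetic_correlation(g0, _basis(), values)
        r = out.to_numpy()
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)
        assert np.abs(r).max() <= 1.0 + 1e-12

    def test_no_gxe_gives_unit_correlation(self, rng):
        g0 = np.array([[1.5, 0.0], [0.0, 0.0]])
        out = postproc.env_genetic_correlation(g0, _basis(), rng.uniform(0, 10, 200))
        np.testing.assert_allclose(out.to_numpy(), 1.0)
        assert out.attrs["gxe_class"] == "weak"

    def test_opposite_extremes_uncorrelated(self):
        # equal intercept/slope variance, no covariance, phi = -+1
        g0 = np.eye(2)
        basis = build_gradient([0.0, 1.0])
        phi = basis.design([0.0, 1.0])
        cov = (g0[0, 0] * phi[:, 0] ** 2)[0] + g0[1, 1] * phi[0, 1] * phi[1, 1]
        # with normalized basis phi0^2 = 0.5, phi1 = -+sqrt(1.5): r = (0.5 - 1.5)/2
        gamma = postproc.covariance_function(g0, phi)
        r = gamma[0, 1] / np.sqrt(gamma[0, 0] * gamma[1, 1])
        assert r == pytest.approx(-0.5)
        assert cov == pytest.approx(gamma[0, 1])

    def test_closed_form_equals_gamma_ratio(self, rng):
        for _ in range(20):
            B = rng.standard_normal((2, 2))
            g0 = B @ B.T + 0.05 * np.eye(2)
            values = rng.uniform(-5, 30, 300)
            basis = build_gradient(values)
            out = postproc.env_genetic_correlation(g0, basis, values, n_grid=11)
            grid = out.attrs["values"]
            gamma = postproc.covariance_function(g0, basis.design(grid))
            ratio = gamma / np.sqrt(np.outer(np.diag(gamma), np.diag(gamma)))
            np.testing.assert_allclose(out.to_numpy(), ratio, atol=1e-12)

    def test_percentile_trim(self, rng):
        values = np.concatenate([rng.uniform(0, 10, 100), [100.0]])
        out = postproc.env_genetic_correlation(np.eye(2), _basis(), values)
        assert out.attrs["values"].max() <= np.percentile(values, 90)

    def test_classification_bands_partition(self):
        assert postproc.classify_gxe(0.49) == "large"
        assert postproc.classify_gxe(0.50) == "moderate"
        assert postproc.classify_gxe(0.80) == "moderate"
        assert postproc.classify_gxe(0.81) == "weak"


class TestReactionNormCurves:
    def _gebv(self):
        return pd.DataFrame({
            "animal": range(1, 16),
            "a0": np.linspace(-1, 1, 15), "a0_sd": 0.1,
            "a1": np.linspace(1, -1, 15), "a1_sd": 0.1,
            "n_offspring": [40] * 12 + [5, 5, 5],
        })

    def test_eligibility_filter(self):
        curves = postproc.reaction_norm_curves(self._gebv(), _basis(), np.array([0.0, 10.0]),
                                               min_offspring=30, n_extreme=3)
        sires = set(curves.loc[curves["group"] != "population", "animal"])
        assert sires.isdisjoint({13, 14, 15})
        assert len(sires) == 6

    def test_zero_slope_curve_is_flat(self):
        gebv = self._gebv()
        gebv["a1"] = 0.0
        curves = postproc.reaction_norm_curves(gebv, _basis(), np.array([0.0, 10.0]),
                                               min_offspring=30, n_extreme=2)
        one = curves[curves["animal"] == 1]
        np.testing.assert_allclose(one["gebv"], gebv.loc[0, "a0"] * np.sqrt(0.5))

    def test_opposite_slopes_cross_at_midrange(self):
        gebv = pd.DataFrame({
            "animal": [1, 2], "a0": [1.0, 1.0], "a0_sd": 0.1,
            "a1": [0.5, -0.5], "a1_sd": 0.1, "n_offspring": [50, 50],
        })
        curves = postproc.reaction_norm_curves(gebv, _basis(), np.array([0.0, 10.0]),
                                               min_offspring=30, n_extreme=1, n_grid=21)
        mid = curves[np.isclose(curves["value"], 5.0)]
        sire_curves = mid[mid["group"] != "population"]["gebv"]
        assert sire_curves.nunique() == 1

    def test_few_sires_returns_all_with_warning(self, caplog):
        gebv = self._gebv().iloc[:3]
        with caplog.at_level("WARNING"):
            curves = postproc.reaction_norm_curves(gebv, _basis(), np.array([0.0, 10.0]),
                                                   min_offspring=30, n_extreme=5)
        assert set(curves["group"]) == {"eligible", "population"}


class TestTraitCorrelation:
    def _tables(self, x, y, acc=0.9):
        n = len(x)
        animals = range(1, n + 1)
        gx = pd.DataFrame({"animal": animals, "a0": x, "a1": x})
        gy = pd.DataFrame({"animal": animals, "a0": y, "a1": y})
        ax = pd.DataFrame({"animal": animals, "acc_a0": acc, "acc_a1": acc})
        return gx, gy, ax, ax.copy()

    def test_equal_weights_reduce_to_pearson(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        gx, gy, ax, ay = self._tables(x, y)
        est = postproc.weighted_trait_correlation(gx, gy, ax, ay)
        assert est.r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(30)
        gx, gy, ax, ay = self._tables(x, x)
        est = postproc.weighted_trait_correlation(gx, gy, ax, ay)
        assert est.r == pytest.approx(1.0) and est.se == pytest.approx(0.0)

    def test_se_formula(self):
        # r = 0 with n = 102 gives SE = sqrt(1/100) = 0.1
        n = 102
        rng = np.random.default_rng(5)
        x = rng.standard_normal(n)
        x -= x.mean()
        y = rng.standard_normal(n)
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)   # exactly uncorrelated with x
        gx, gy, ax, ay = self._tables(x, y)
        est = postproc.weighted_trait_correlation(gx, gy, ax, ay)
        assert est.r == pytest.approx(0.0, abs=1e-12)
        assert est.se == pytest.approx(0.1)

    def test_accuracy_threshold_filters_animals(self, rng):
        x = rng.standard_normal(20)
        gx, gy, ax, ay = self._tables(x, x)
        ax.loc[:9, "acc_a1"] = 0.1   # first 10 animals fail the cut on trait x
        est = postproc.weighted_trait_correlation(gx, gy, ax, ay)
        assert est.n == 10

    def test_too_few_animals_is_error(self, rng):
        x = rng.standard_normal(5)
        gx, gy, ax, ay = self._tables(x, x, acc=0.1)
        with pytest.raises(ValueError, match="accuracy cut"):
            postproc.weighted_trait_correlation(gx, gy, ax, ay)


class TestRankCorrelation:
    @pytest.mark.parametrize("y,expected", [
        ([1, 2, 3], 1.0),
        ([3, 2, 1], -1.0),
        ([1, 3, 2], 0.5),
    ])
    def test_hand_values(self, y, expected):
        assert postproc.rank_correlation([1, 2, 3], y) == pytest.approx(expected)

    def test_constant_vector_returns_nan(self):
        assert np.isnan(postproc.rank_correlation([1, 2, 3], [5, 5, 5]))


class TestPlots:
    def test_plot_helpers_return_axes(self, rng):
        import matplotlib
        matplotlib.use("Agg")
        from heatnorm import plots

        h2 = pd.DataFrame({"value": np.linspace(0, 10, 9),
                           "h2": rng.uniform(0.05, 0.3, 9)})
        ax = plots.plot_heritability(h2, env_name="MaxT")
        assert ax.get_ylabel() == "h$^2$"

        curves = pd.DataFrame({
            "animal": [1] * 5 + [0] * 5,
            "group": ["tolerant"] * 5 + ["population"] * 5,
            "value": list(np.linspace(0, 10, 5)) * 2,
            "gebv": rng.standard_normal(10),
        })
        ax = plots.plot_reaction_norms(curves)
        assert len(ax.lines) == 2

        corr = postproc.env_genetic_correlation(
            np.array([[1.0, 0.2], [0.2, 0.5]]),
            build_gradient([0.0, 10.0]), rng.uniform(0, 10, 100), n_grid=7)
        ax = plots.plot_env_correlation(corr)
        assert ax.images
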