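"""Taper equations: evaluation, LM fitting, volume integration, tables."""

import numpy as np
import pytest
from scipy import integrate
from sklearn.base import clone

from lidarvol.metrics import regression_metrics
from lidarvol.taper import (
    K_VOLUME,
    TaperFit,
    TaperModelRegressor,
    build_volume_table,
    eval_taper,
    fit_taper,
    select_model,
    stand_volume,
    stand_volume_per_ha,
    tree_volume,
)

#: modified-Schumacher coefficients of the conifer (dawn redwood) fit
CONIFER_A = (0.598, 1.900, 1.417, 1.279)


def _fit(model_id, coeffs, n=8):
    coeffs = np.asarray(coeffs, float)
    k = len(coeffs)
    return TaperFit(
        model_id=model_id, coeffs=coeffs, se=np.zeros(k),
        ci_lower=coeffs, ci_upper=coeffs,
        stats=regression_metrics([1.0, 2.0], [1.0, 2.0]), n_samples=n,
    )


class TestEvalTaper:
    def test_m4_breast_height_anchor(self):
        """The relative-height form passes exactly through d = D at 1.3 m."""
        for a0 in (0.5, 1.417, 2.0):
            assert eval_taper("M4", (a0,), 30.0, 25.0, 1.3) == pytest.approx(30.0)

    def test_m2_direct_arithmetic(self):
        expected = np.sqrt(0.598 * 30**1.9 * 23.7**1.417 / 25**1.279)
        assert eval_taper("M2", CONIFER_A, 30.0, 25.0, 1.3) == pytest.approx(expected)

    def test_m2_vanishes_at_tip(self):
        assert eval_taper("M2", CONIFER_A, 30.0, 25.0, 25.0 - 1e-9) < 1e-3

    def test_h_outside_domain_raises(self):
        with pytest.raises(ValueError):
            eval_taper("M2", CONIFER_A, 30.0, 25.0, 25.0)
        with pytest.raises(ValueError):
            eval_taper("M2", CONIFER_A, 30.0, 25.0, -0.1)

    def test_negative_d2_raises(self):
        with pytest.raises(ValueError):
            eval_taper("M5", (-1.0, 0.0), 30.0, 25.0, 5.0)


def _m2_samples(n, rng, noise=0.0):
    D = rng.uniform(20, 40, n)
    H = rng.uniform(20, 30, n)
    h = rng.uniform(0, 0.95, n) * H
    d = eval_taper("M2", CONIFER_A, D, H, h) + rng.normal(0, noise, n)
    return np.column_stack([D, H, h, d])


class TestFitTaper:
    def test_noiseless_m2_recovery(self):
        samples = _m2_samples(500, np.random.default_rng(1))
        fit = fit_taper(samples, "M2")
        assert np.max(np.abs(fit.coeffs - np.asarray(CONIFER_A))) < 1e-4

    def test_noiseless_m4_single_parameter(self):
        rng = np.random.default_rng(2)
        D, H = rng.uniform(20, 40, 200), rng.uniform(20, 30, 200)
        h = rng.uniform(0, 0.9, 200) * H
        d = eval_taper("M4", (2.0,), D, H, h)
        fit = fit_taper(np.column_stack([D, H, h, d]), "M4")
        assert fit.coeffs[0] == pytest.approx(2.0, abs=1e-8)

    def test_standard_errors_scale_with_noise(self):
        rng = np.random.default_rng(3)
        lo = fit_taper(_m2_samples(500, rng, noise=0.2), "M2")
        hi = fit_taper(_m2_samples(500, rng, noise=2.0), "M2")
        assert np.all(hi.se > lo.se)

    def test_ci_brackets_estimate(self):
        fit = fit_taper(_m2_samples(300, np.random.default_rng(4), noise=1.0), "M2")
        assert np.all(fit.ci_lower <= fit.coeffs)
        assert np.all(fit.coeffs <= fit.ci_upper)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_taper(_m2_samples(4, np.random.default_rng(0)), "M2")

    def test_sklearn_estimator_contract(self):
        reg = TaperModelRegressor(model="M2")
        assert clone(reg).get_params()["model"] == "M2"
        samples = _m2_samples(100, np.random.default_rng(5))
        reg.fit(samples[:, :3], samples[:, 3])
        pred = reg.predict(samples[:, :3])
        assert pred.shape == (100,)
        assert np.allclose(pred, samples[:, 3], atol=1e-6)


def _fit_with_stats(mid, rmse, r2=0.9, n_coef=1):
    from lidarvol.metrics import FitStats

    c = np.ones(n_coef)
    return TaperFit(
        model_id=mid, coeffs=c, se=np.zeros(n_coef), ci_lower=c, ci_upper=c,
        stats=FitStats(r2=r2, mae=rmse, rmse=rmse, rrmse=5.0), n_samples=10,
    )


class TestSelectModel:
    def test_minimal_rmse_wins(self):
        # the five-model comparison for the conifer species: RMSEs in cm
        fits = [_fit_with_stats(f"M{i + 1}", r)
                for i, r in enumerate([1.5, 1.6, 2.8, 1.6, 1.7])]
        assert select_model(fits).model_id == "M1"
        assert select_model(fits).stats.rmse == 1.5

    def test_single_fit_returns_itself(self):
        f = _fit("M2", CONIFER_A)
        assert select_model([f]) is f

    def test_tie_broken_by_r2(self):
        assert select_model(
            [_fit_with_stats("A", 1.0, r2=0.90), _fit_with_stats("B", 1.0, r2=0.91)]
        ).model_id == "B"

    def test_tie_broken_by_parsimony(self):
        fits = [_fit_with_stats("A", 1.0, n_coef=4), _fit_with_stats("B", 1.0, n_coef=1)]
        assert select_model(fits).model_id == "B"


class TestTreeVolume:
    def test_cylinder(self):
        """Constant taper d = D: V = pi D^2 H / 40000."""
        fit = _fit("M5", (1.0, 0.0))
        v = tree_volume(fit, 20.0, 10.0, method="quadrature")
        assert v == pytest.approx(np.pi * 400 * 10 / 40000, rel=1e-9)

    def test_m2_analytic_matches_quadrature_on_grid(self):
        fit = _fit("M2", CONIFER_A)
        for D in (20.0, 30.0, 40.0):
            for H in (20.0, 25.0, 30.0):
                va = tree_volume(fit, D, H, method="analytic")
                vq = tree_volume(fit, D, H, method="quadrature")
                assert abs(va - vq) / vq < 1e-6

    def test_m4_symbolic_integral(self):
        """For the anchored form with a0 = 2 the stem integral has a closed
        form: K * D^2 * H^3 / (3 (H-1.3)^2)."""
        fit = _fit("M4", (2.0,))
        D, H = 28.0, 24.0
        expected = K_VOLUME * D**2 * H**3 / (3 * (H - 1.3) ** 2)
        assert tree_volume(fit, D, H, method="quadrature") == pytest.approx(
            expected, rel=1e-8
        )

    def test_volume_homogeneity_in_dbh(self):
        """M2 volume scales as D^a1 at fixed height."""
        fit = _fit("M2", CONIFER_A)
        v1, v2 = tree_volume(fit, 20.0, 25.0), tree_volume(fit, 30.0, 25.0)
        assert v2 / v1 == pytest.approx((30.0 / 20.0) ** 1.9, rel=1e-9)

    def test_invalid_domain_raises(self):
        fit = _fit("M2", CONIFER_A)
        with pytest.raises(ValueError):
            tree_volume(fit, -1.0, 25.0)
        with pytest.raises(ValueError):
            tree_volume(fit, 30.0, 1.0)

    def test_negative_integrand_raises(self):
        fit = _fit("M5", (-0.5, 0.1))
        with pytest.raises(ValueError):
            tree_volume(fit, 30.0, 25.0, method="quadrature")


class TestVolumeTable:
    def test_single_cell_equals_tree_volume(self):
        fit = _fit("M2", CONIFER_A)
        table = build_volume_table(fit, [30.0], [25.0])
        assert table.volumes_m3[0, 0] == pytest.approx(
            round(tree_volume(fit, 30.0, 25.0), 4)
        )

    def test_monotone_in_both_axes(self):
        fit = _fit("M2", CONIFER_A)
        table = build_volume_table(
            fit, np.arange(20, 41, 2.0), np.arange(20, 31, 1.0)
        )
        assert np.all(np.diff(table.volumes_m3, axis=0) > 0)
        assert np.all(np.diff(table.volumes_m3, axis=1) > 0)

    def test_cells_match_quadrature(self):
        fit = _fit("M2", CONIFER_A)
        table = build_volume_table(fit, [20.0, 30.0, 40.0], [20.0, 25.0, 30.0])
        for i, D in enumerate(table.dbh_classes_cm):
            for j, H in enumerate(table.height_classes_m):
                a = np.asarray(fit.coeffs)
                vq, _ = integrate.quad(
                    lambda h: a[0] * D ** a[1] * (H - h) ** a[2] / H ** a[3],
                    0.0, H, epsabs=0.0, epsrel=1e-10,
                )
                # table values carry 4-decimal rounding on top of quadrature
                assert abs(table.volumes_m3[i, j] - K_VOLUME * vq) <= 5e-5 + 1e-6

    def test_height_below_breast_height_rejected(self):
        with pytest.raises(ValueError):
            build_volume_table(_fit("M2", CONIFER_A), [30.0], [1.0])


class TestStandVolume:
    def test_all_standard_trees_reduce_to_sum_of_volumes(self):
        fit = _fit("M2", CONIFER_A)
        trees = [(30.0, 25.0)] * 5
        s = stand_volume(trees, fit, plot_area_m2=900.0)
        assert s.plot_volume_m3 == pytest.approx(5 * tree_volume(fit, 30.0, 25.0))
        assert len(s.standard_tree_ids) == 5

    def test_ratio_expansion(self):
        """M = (sum V_std / sum g_std) * G with G over all trees."""
        fit = _fit("M5", (1.0, 0.0))  # cylinder: V = K D^2 H exactly
        # Dg = sqrt(963) = 31.0, so the 33-cm tree falls outside +/-5%
        trees = [(30.0, 25.0), (30.0, 25.0), (33.0, 25.0)]
        s = stand_volume(trees, fit, plot_area_m2=900.0, tolerance=0.05)
        g30 = np.pi * (30 / 200) ** 2
        g33 = np.pi * (33 / 200) ** 2
        v30 = K_VOLUME * 30**2 * 25
        expected_m = (2 * v30) / (2 * g30) * (2 * g30 + g33)
        assert sorted(s.standard_tree_ids) == [0, 1]
        assert s.plot_volume_m3 == pytest.approx(expected_m)
        assert s.stand_volume_m3_ha == pytest.approx(expected_m / 0.09)

    def test_quadratic_mean_diameter(self):
        fit = _fit("M5", (1.0, 0.0))
        s = stand_volume([(30.0, 25.0), (40.0, 25.0)], fit, 900.0, tolerance=0.2)
        assert s.dg_cm == pytest.approx(np.sqrt((900 + 1600) / 2))

    def test_no_standard_tree_raises(self):
        fit = _fit("M5", (1.0, 0.0))
        with pytest.raises(ValueError, match="tolerance"):
            stand_volume([(20.0, 30.0), (40.0, 20.0)], fit, 900.0, tolerance=0.01)

    @pytest.mark.parametrize(
        "plot_m3,expected",
        [(19.15, 212.78), (33.42, 371.33)],
    )
    def test_per_hectare_scaling_on_900m2_plots(self, plot_m3, expected):
        assert stand_volume_per_ha(plot_m3, 900.0) == pytest.approx(expected, abs=0.005)
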