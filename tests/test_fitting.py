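"""Objectives, metrics, the multistart fit, enthalpies and crossover."""

import math

import numpy as np
import pytest

from scsol import (
    MODEL_IDS,
    FitResult,
    SyntheticConfig,
    ValidationError,
    aard,
    density_interpolator,
    derive_enthalpies,
    evaluate_model,
    find_crossover,
    fit_model,
    generate_dataset,
    goodness_of_fit,
    load_sitagliptin,
)

SLOPE_LIKE = {
    "chrastil": ("kappa", "B1"),
    "reformulated_chrastil": ("kappa", "B2"),
    "mst": ("B3",),
    "bartle": ("B4", "C4"),
    "kj": ("B5", "C5"),
    "association": ("kappa", "C6"),
}


class TestAard:
    def test_identical_vectors_give_zero(self):
        y = np.array([1e-5, 2e-5, 3e-5])
        assert aard(y, y) == 0.0

    def test_hand_value(self):
        # (10% + 10%) / 2
        assert aard([1e-5, 2e-5], [1.1e-5, 1.8e-5]) == pytest.approx(10.0, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            aard([1e-5, 2e-5], [1e-5])
        with pytest.raises(ValueError):
            aard([0.0, 2e-5], [1e-5, 2e-5])


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        y = np.linspace(1.0, 2.0, 10)
        assert goodness_of_fit(y, y, 3) == (1.0, 1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r2, _ = goodness_of_fit(y, np.full_like(y, y.mean()), 1)
        assert r2 == pytest.approx(0.0, abs=1e-14)

    def test_adjusted_r2_hand_value(self):
        # engineered so SS_res/SS_tot = 1 - 0.98817 with n=28, p=5:
        # r2_adj = 1 - (1-0.98817)*27/22 = 0.985481
        n, p, r2_target = 28, 5, 0.98817
        y = np.arange(n, dtype=float)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        e = math.sqrt((1 - r2_target) * ss_tot / n)
        r2, r2_adj = goodness_of_fit(y, y + e, p)
        assert r2 == pytest.approx(r2_target, rel=1e-12)
        assert r2_adj == pytest.approx(0.9854812, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 3)


class TestFitModel:
    def test_chrastil_matches_reported_fit(self, sitagliptin):
        res = fit_model("chrastil", sitagliptin)
        assert res.aard_percent == pytest.approx(4.97, abs=0.5)
        assert res.params["kappa"] == pytest.approx(3.24, abs=0.1)

    def test_kj_matches_reported_fit(self, sitagliptin):
        res = fit_model("kj", sitagliptin)
        assert res.aard_percent == pytest.approx(3.16, abs=0.5)

    def test_metrics_self_consistent(self, sitagliptin):
        res = fit_model("kj", sitagliptin)
        y = sitagliptin.mole_fractions
        pred = np.array(res.predictions)
        assert res.aard_percent == pytest.approx(aard(y, pred), rel=1e-12)
        r2, r2_adj = goodness_of_fit(y, pred, 3)
        assert res.r2 == pytest.approx(r2, rel=1e-12)
        assert res.r2_adj == pytest.approx(r2_adj, rel=1e-12)
        assert np.allclose(res.residuals, pred - y)
        assert res.r2_adj <= res.r2 <= 1.0

    def test_single_isotherm_rejected(self, published):
        grid = tuple((308.0, p, 700.0 + 10 * p) for p in range(12, 31, 3))
        ds, _ = generate_dataset(
            SyntheticConfig("kj", published["kj"], grid=grid, noise_level=0.0)
        )
        with pytest.raises(ValidationError, match="2 distinct temperatures"):
            fit_model("kj", ds)

    def test_unknown_objective_rejected(self, sitagliptin):
        with pytest.raises(ValueError, match="objective"):
            fit_model("kj", sitagliptin, objective="rmse")

    @pytest.mark.parametrize("objective", ["sse_log", "sse"])
    def test_alternative_objectives_fit_sensibly(self, sitagliptin, objective):
        res = fit_model("kj", sitagliptin, objective=objective)
        assert res.aard_percent < 5.0

    def test_reference_pressure_choice_only_shifts_intercept(self, sitagliptin):
        """Switching the association-model P* from bar to atm must not change
        the achievable fit; at the optimum only D6 absorbs the change."""
        f_bar = fit_model("association", sitagliptin, p_star_bar=1.0)
        f_atm = fit_model("association", sitagliptin, p_star_bar=1.01325)
        assert f_atm.aard_percent == pytest.approx(f_bar.aard_percent, abs=1e-3)
        shifted = dict(f_bar.params)
        shifted["D6"] += (f_bar.params["kappa"] - 1.0) * math.log(1.01325)
        e = evaluate_model("association", shifted, sitagliptin, p_star_bar=1.01325)
        assert np.allclose(e.predictions, f_bar.predictions, rtol=1e-12)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_noisy_parameter_recovery(self, model_id, published):
        """5% relative lognormal noise on the experimental grid: slope-like
        parameters recover with median relative error <= 10%, and the fitted
        AARD is of the same order as the injected noise."""
        errs = {name: [] for name in SLOPE_LIKE[model_id]}
        aards = []
        for seed in range(20):
            ds, truth = generate_dataset(
                SyntheticConfig(model_id, published[model_id], noise_level=0.05, seed=seed)
            )
            res = fit_model(model_id, ds)
            aards.append(res.aard_percent)
            for name in errs:
                true = truth["true_params"][name]
                errs[name].append(abs(res.params[name] - true) / abs(true))
        for name, vals in errs.items():
            assert np.median(vals) <= 0.10, f"{model_id}.{name}: {np.median(vals):.3f}"
        assert all(2.0 <= a <= 10.0 for a in aards)


class TestEnthalpies:
    def test_hand_values_from_temperature_coefficients(self):
        total = abs(-2624.0) * 8.314 / 1000
        assert total == pytest.approx(21.8159, abs=1e-3)
        sub = -(-4861.2) * 8.314 / 1000
        assert sub == pytest.approx(40.4160, abs=1e-3)

    def test_identity_and_sources(self, sitagliptin):
        ch = fit_model("chrastil", sitagliptin)
        ba = fit_model("bartle", sitagliptin)
        ens = derive_enthalpies(ch, ba)
        assert ens.solvation_kJ_mol == ens.total_kJ_mol - ens.sublimation_kJ_mol
        assert ens.total_source == "chrastil"
        assert ens.sublimation_source == "bartle"

    def test_zero_coefficient_gives_zero_enthalpy(self, sitagliptin):
        ch = evaluate_model("chrastil", {"kappa": 3.0, "A1": -10.0, "B1": 0.0}, sitagliptin)
        ba = fit_model("bartle", sitagliptin)
        assert derive_enthalpies(ch, ba).total_kJ_mol == 0.0

    def test_wrong_model_rejected(self, sitagliptin):
        kj = fit_model("kj", sitagliptin)
        ba = fit_model("bartle", sitagliptin)
        with pytest.raises(ValueError):
            derive_enthalpies(kj, ba)
        with pytest.raises(ValueError):
            derive_enthalpies(fit_model("chrastil", sitagliptin), kj)


class TestCrossover:
    def test_identical_isotherms_give_none(self, sitagliptin, published):
        surf = density_interpolator(sitagliptin)
        assert find_crossover("kj", published["kj"], 308.0, 308.0, (12, 30), surf) is None

    def test_density_only_temperature_dependence_never_crosses(self, sitagliptin):
        # chrastil with B1 = 0: temperature enters only through density, and the
        # colder isotherm is denser everywhere, so solubilities never cross
        surf = density_interpolator(sitagliptin)
        params = {"kappa": 3.0, "A1": -14.0, "B1": 0.0}
        assert find_crossover("chrastil", params, 308.0, 338.0, (12, 30), surf) is None
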