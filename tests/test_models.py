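"""Unit tests for biphasic model evaluation, inversion and fitting."""

import numpy as np
import pytest

from loewe2d import (
    BiphasicModel,
    DoseResponseDataset,
    FitFailureError,
    InvalidInputError,
    NoiseModel,
    dilution_series,
    dose_at_p,
    edp,
    effect_at_p,
    evaluate,
    fit_biphasic,
    select_model,
    simulate_single,
)
from tests.conftest import random_model


class TestEvaluate:
    @pytest.mark.parametrize(
        "kind,params,dose,expected",
        [
            ("gaussian", dict(b=1, c=0, d=10, e=5, f=1), 5.0, 10.0),  # peak value is d
            ("gaussian", dict(b=1, c=0, d=10, e=5, f=1), 4.0, 10 * np.exp(-0.5)),
            ("gaussian", dict(b=1, c=0, d=10, e=5, f=2), 7.0, 10 * np.exp(-0.5)),  # right width b*f
            ("loggaussian", dict(b=0.4, c=1.5, d=80, e=2.5, f=0.7), 0.0, 1.5),  # left-tail limit
            ("loggaussian", dict(b=0.4, c=1.5, d=80, e=2.5, f=0.7), 2.5, 80.0),
        ],
    )
    def test_closed_form_values(self, kind, params, dose, expected):
        model = BiphasicModel(kind, **params)
        assert evaluate(model, dose) == pytest.approx(expected, rel=1e-12)

    def test_vectorized(self, simple_gaussian):
        doses = np.array([3.0, 5.0, 7.0])
        out = evaluate(simple_gaussian, doses)
        assert out.shape == (3,)
        assert out[1] == pytest.approx(10.0)

    def test_tail_limits(self, zn_model, simple_gaussian):
        assert evaluate(zn_model, 1e9) == pytest.approx(zn_model.c, abs=1e-9)
        assert evaluate(simple_gaussian, 1e6) == pytest.approx(simple_gaussian.c, abs=1e-12)

    def test_invalid_dose(self, simple_gaussian):
        with pytest.raises(InvalidInputError):
            evaluate(simple_gaussian, np.nan)
        with pytest.raises(InvalidInputError):
            evaluate(simple_gaussian, -1.0)

    def test_symmetry_iff_f_one(self):
        sym = BiphasicModel("gaussian", b=1, c=0, d=10, e=5, f=1)
        asym = BiphasicModel("gaussian", b=1, c=0, d=10, e=5, f=2)
        assert evaluate(sym, 4.0) == pytest.approx(evaluate(sym, 6.0))
        assert evaluate(asym, 4.0) != pytest.approx(evaluate(asym, 6.0))


class TestEffectAtP:
    def test_midpoint_and_peak(self):
        m = BiphasicModel("gaussian", b=1, c=0, d=10, e=5, f=1)
        assert effect_at_p(m, -50) == pytest.approx(5.0)
        assert effect_at_p(m, 0) == pytest.approx(10.0)

    def test_published_zn_half_effect(self, zn_model):
        # E_(-50) = (c + d) / 2 for the Zn parameter set -> 40.79 BIF
        assert effect_at_p(zn_model, -50) == pytest.approx(40.79, abs=5e-3)

    def test_even_in_p(self, zn_model):
        for p in (10, 37.5, 50, 99):
            assert effect_at_p(zn_model, p) == effect_at_p(zn_model, -p)

    def test_out_of_range(self, zn_model):
        with pytest.raises(InvalidInputError):
            effect_at_p(zn_model, 101)


class TestDoseAtP:
    def test_peak_location(self, zn_model):
        assert dose_at_p(zn_model, 0) == zn_model.e

    def test_gaussian_closed_form(self, simple_gaussian):
        # e - b * sqrt(2 ln 2)
        assert dose_at_p(simple_gaussian, -50) == pytest.approx(5 - np.sqrt(2 * np.log(2)), rel=1e-9)

    def test_published_zn_dose(self, zn_model):
        assert dose_at_p(zn_model, -50) == pytest.approx(1.50, abs=5e-3)

    def test_boundary_p_rejected(self, zn_model):
        for p in (-100, 100, 150):
            with pytest.raises(InvalidInputError):
                dose_at_p(zn_model, p)

    def test_gaussian_negative_dose_clipped_with_warning(self):
        m = BiphasicModel("gaussian", b=1.0, c=0, d=10, e=2.0, f=1.0)
        with pytest.warns(RuntimeWarning, match="clipped"):
            assert dose_at_p(m, -99) == 0.0

    def test_strictly_increasing_in_p(self, zn_model):
        grid = np.linspace(-99, 99, 81)
        doses = dose_at_p(zn_model, grid)
        assert np.all(np.diff(doses) > 0)


class TestEdp:
    def test_bundles_components(self, zn_model):
        v = edp(zn_model, -50)
        assert (v.p, v.dose, v.effect) == (-50, dose_at_p(zn_model, -50), effect_at_p(zn_model, -50))

    def test_peak_vector(self, zn_model):
        v = edp(zn_model, 0)
        assert (v.dose, v.effect) == (zn_model.e, zn_model.d)

    def test_effect_symmetric(self, zn_model):
        assert edp(zn_model, -30).effect == edp(zn_model, 30).effect


class TestRoundTrip:
    def test_inversion_consistency(self, zn_model, simple_gaussian):
        for model in (zn_model, simple_gaussian):
            for p in np.linspace(-99, 99, 41):
                dose = dose_at_p(model, p)
                assert evaluate(model, dose) == pytest.approx(effect_at_p(model, p), rel=1e-10)

    def test_monotone_branches(self, zn_model):
        # stay within ~5 widths of the peak: beyond that the response
        # underflows to the baseline and strict monotonicity is vacuous
        left = zn_model.e * np.exp(np.linspace(-5 * zn_model.b, 0, 200))
        right = zn_model.e * np.exp(np.linspace(0, 5 * zn_model.b * zn_model.f, 200))
        assert np.all(np.diff(evaluate(zn_model, left)) > 0)
        assert np.all(np.diff(evaluate(zn_model, right)) < 0)


class TestFitting:
    def test_noise_free_recovery(self):
        true = BiphasicModel("gaussian", b=1.2, c=1, d=50, e=4, f=0.8)
        ds = simulate_single(true, dilution_series(12, 2, 9), NoiseModel(cv_or_sd=0.0), n_rep=1)
        res = fit_biphasic(ds, "gaussian")
        assert res.converged
        for name in "bcdef":
            assert getattr(res.model, name) == pytest.approx(getattr(true, name), rel=1e-6)

    def test_too_few_dose_levels(self):
        ds = DoseResponseDataset("x", [1, 2, 4, 8], [1, 5, 5, 1], [1, 1, 1, 1])
        with pytest.raises(InvalidInputError, match="5 distinct"):
            fit_biphasic(ds, "loggaussian")

    def test_degenerate_flat_data_flagged_not_crashing(self):
        doses = dilution_series(16, 2, 6)
        ds = DoseResponseDataset("flat", doses, np.full_like(doses, 3.0), np.ones(6, int))
        with pytest.warns(RuntimeWarning):
            res = fit_biphasic(ds, "loggaussian")
        assert not res.converged

    def test_boxcox_lambda_one_matches_untransformed(self):
        true = BiphasicModel("loggaussian", b=0.4, c=1, d=80, e=2.5, f=0.7)
        ds = simulate_single(true, dilution_series(10, 2, 8), NoiseModel(cv_or_sd=0.05, seed=3), n_rep=3)
        plain = fit_biphasic(ds, "loggaussian")
        bc = fit_biphasic(ds, "loggaussian", boxcox=True, lambda_grid=[1.0])
        assert bc.boxcox_lambda == 1.0
        for name in "bcdef":
            assert getattr(bc.model, name) == pytest.approx(getattr(plain.model, name), rel=1e-4)

    def test_boxcox_picks_log_for_lognormal_noise(self):
        true = BiphasicModel("loggaussian", b=0.4, c=1, d=80, e=2.5, f=0.7)
        ds = simulate_single(true, dilution_series(10, 2, 8), NoiseModel(cv_or_sd=0.2, seed=5), n_rep=4)
        res = fit_biphasic(ds, "loggaussian", boxcox=True)
        assert res.boxcox_lambda is not None and res.boxcox_lambda <= 0.5

    def test_parameter_bias_shrinks_with_noise(self):
        true = BiphasicModel("loggaussian", b=0.4, c=1, d=80, e=2.5, f=0.7)
        doses = dilution_series(10, 2, 8)
        errs = {}
        for cv in (0.0, 0.02, 0.1):
            runs = []
            for seed in range(20):
                ds = simulate_single(true, doses, NoiseModel(cv_or_sd=cv, seed=100 + seed), n_rep=3)
                res = fit_biphasic(ds, "loggaussian", multistart=False)
                runs.append(abs(res.model.e - true.e) / true.e)
            errs[cv] = float(np.median(runs))
        assert errs[0.0] < 1e-6
        assert errs[0.0] <= errs[0.02] <= errs[0.1] + 1e-12


class TestSelectModel:
    def test_prefers_generating_kind_noise_free(self):
        true = BiphasicModel("gaussian", b=1.2, c=1, d=50, e=4, f=0.8)
        ds = simulate_single(true, dilution_series(12, 2, 9), NoiseModel(cv_or_sd=0.0), n_rep=1)
        res = select_model(ds)
        assert res.model.kind == "gaussian"
        assert res.rss_untransformed == pytest.approx(0.0, abs=1e-12)

    def test_selects_loggaussian_under_noise(self):
        true = BiphasicModel("loggaussian", b=0.45, c=1, d=60, e=3.0, f=0.6)
        ds = simulate_single(true, dilution_series(12, 2, 9), NoiseModel(cv_or_sd=0.05, seed=11), n_rep=3)
        assert select_model(ds).model.kind == "loggaussian"

    def test_partial_failure_returns_other_with_warning(self, monkeypatch):
        import loewe2d.models as mod

        true = BiphasicModel("loggaussian", b=0.45, c=1, d=60, e=3.0, f=0.6)
        ds = simulate_single(true, dilution_series(12, 2, 9), NoiseModel(cv_or_sd=0.02, seed=2), n_rep=2)
        orig = mod.fit_biphasic

        def flaky(data, kind, **kw):
            res = orig(data, kind, **kw)
            if kind == "gaussian":
                return mod.FitResult(
                    model=res.model, rss=res.rss, n_obs=res.n_obs, converged=False,
                    message="forced failure", rss_untransformed=res.rss_untransformed,
                )
            return res

        monkeypatch.setattr(mod, "fit_biphasic", flaky)
        with pytest.warns(RuntimeWarning, match="failed"):
            res = mod.select_model(ds)
        assert res.model.kind == "loggaussian"

    def test_all_fail_raises_aggregate(self):
        doses = dilution_series(16, 2, 6)
        flat = DoseResponseDataset("flat", doses, np.full_like(doses, 2.0), np.ones(6, int))
        with pytest.warns(RuntimeWarning):
            with pytest.raises(FitFailureError) as exc:
                select_model(flat)
        assert "gaussian" in str(exc.value) and "loggaussian" in str(exc.value)

    def test_empty_candidates(self, zn_model):
        ds = simulate_single(zn_model, dilution_series(10, 2, 6), n_rep=1)
        with pytest.raises(InvalidInputError):
            select_model(ds, candidates=[])


class TestDatasetValidation:
    def test_rejects_negative_dose(self):
        with pytest.raises(InvalidInputError):
            DoseResponseDataset("x", [-1, 2, 3, 4, 5], [1, 2, 3, 2, 1], [1] * 5)

    def test_rejects_non_finite_response(self):
        with pytest.raises(InvalidInputError):
            DoseResponseDataset("x", [1, 2, 3, 4, 5], [1, np.inf, 3, 2, 1], [1] * 5)

    def test_model_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            BiphasicModel("loggaussian", b=0.4, c=5.0, d=4.0, e=1.0, f=1.0)  # d <= c
        with pytest.raises(InvalidInputError):
            BiphasicModel("loggaussian", b=-0.1, c=0, d=1, e=1, f=1)
        with pytest.raises(InvalidInputError):
            BiphasicModel("sigmoid", b=1, c=0, d=1, e=1, f=1)


def test_random_models_round_trip_spot_check():
    rng = np.random.default_rng(0)
    for _ in range(10):
        m = random_model(rng)
        for p in (-90.0, -10.0, 25.0, 75.0):
            assert evaluate(m, dose_at_p(m, p)) == pytest.approx(effect_at_p(m, p), rel=1e-10)
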