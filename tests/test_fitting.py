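"""Estimation: classification rule, guesses, ODE fits, fallbacks, CIs."""

import numpy as np
import pytest

from slicekin.fitting import (
    FitOptions,
    FitResult,
    SlicingSeries,
    SlicingTimeCourse,
    classify_slow_association,
    confidence_intervals,
    fit_monophasic,
    fit_multiple_turnover,
    fit_single_turnover,
    fold_change,
    initial_guess,
)
from slicekin.models import (
    KineticParams,
    MultiTurnoverParams,
    ReactionDesign,
    monophasic_fraction_sliced,
)
from slicekin.synthetic import (
    NoiseModel,
    generate_multiturnover_dataset,
    generate_slicing_dataset,
)


def _course(series):
    return SlicingTimeCourse(guide_id="g", target_id="t", series=series)


def _series(e_all, times, fractions, s0=0.02):
    return SlicingSeries(e_all=e_all, s0=s0, times=np.asarray(times),
                         fractions=np.asarray(fractions))


class TestClassifySlowAssociation:
    def test_spread_above_threshold(self):
        t = [10.0, 100.0, 1000.0]
        data = _course([
            _series(0.3, t, [0.10, 0.30, 0.60]),
            _series(3.0, t, [0.10, 0.50, 0.65]),
        ])
        assert classify_slow_association(data) is True

    def test_identical_series_are_fast(self):
        t = [10.0, 100.0, 1000.0]
        f = [0.2, 0.5, 0.8]
        data = _course([_series(0.3, t, f), _series(3.0, t, f)])
        assert classify_slow_association(data) is False

    def test_single_concentration_warns_false(self):
        data = _course([_series(1.0, [1.0, 2.0, 3.0], [0.1, 0.2, 0.3])])
        with pytest.warns(UserWarning, match="not assessable"):
            assert classify_slow_association(data) is False

    @pytest.mark.parametrize("k_on,expected", [(0.001, True), (1.0, False)])
    def test_generated_data_classified_by_true_k_on(self, k_on, expected):
        truth = KineticParams(k_on=k_on, k_slice=0.01, k_phase2=1e-5, f_a=0.9)
        designs = [
            ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(10, 1e5, 10))
            for e in (0.3, 3.0)
        ]
        data = generate_slicing_dataset(truth, designs, NoiseModel(sigma=0.0))
        assert classify_slow_association(data) is expected


class TestInitialGuess:
    def test_slow_association_start_and_fa_rule(self):
        truth = KineticParams(k_on=0.001, k_slice=0.01, k_phase2=1e-5, f_a=0.9)
        designs = [
            ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(10, 1e5, 10))
            for e in (0.3, 3.0)
        ]
        data = generate_slicing_dataset(truth, designs, NoiseModel(sigma=0.0))
        assert classify_slow_association(data)
        guess = initial_guess(data)
        # refined guesses stay inside the guess-stage bounds
        assert 1e-6 <= guess.k_on <= 1.0
        assert 0.3 <= guess.f_a <= 0.999

    def test_regression_failure_falls_back_to_fixed_inits(self, monkeypatch):
        # when the closed-form regression fails, the fixed initializations
        # are kept with f_a adjusted to 0.85
        import slicekin.fitting as fitting_mod

        def boom(*args, **kwargs):
            raise RuntimeError("regression failed")

        monkeypatch.setattr(fitting_mod, "least_squares", boom)
        t = [10.0, 100.0, 1000.0]
        f = [0.2, 0.5, 0.8]
        data = _course([_series(0.3, t, f), _series(3.0, t, f)])
        guess = initial_guess(data)
        assert guess.f_a == 0.85
        assert guess.k_on == 0.167  # fast-association initialization
        assert guess.k_slice == 0.0167
        assert guess.k_phase2 == 3.33e-6


class TestFitSingleTurnover:
    def test_noiseless_round_trip(self, small_noiseless_dataset,
                                  reference_params):
        fit = fit_single_turnover(small_noiseless_dataset)
        p, truth = fit.params, reference_params
        assert p.k_on == pytest.approx(truth.k_on, rel=0.01)
        assert p.k_slice == pytest.approx(truth.k_slice, rel=0.01)
        assert p.k_phase2 == pytest.approx(truth.k_phase2, rel=0.01)
        assert p.f_a == pytest.approx(truth.f_a, rel=0.01)
        assert fit.converged
        assert not any(fit.constrained.values())

    def test_diffusion_limited_binding_flagged(self):
        # k_on = 1 at e_all >= 3 nM: binding contributes nothing
        # observable, so the fit pins k_on and still recovers k_slice
        truth = KineticParams(k_on=1.0, k_slice=0.01, k_phase2=1e-5, f_a=0.9)
        designs = [
            ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(10, 1.7e5, 9))
            for e in (3.0, 10.0)
        ]
        data = generate_slicing_dataset(
            truth, designs, NoiseModel(sigma=0.02, seed=3)
        )
        fit = fit_single_turnover(data)
        assert fit.constrained["k_on_at_diffusion_limit"]
        assert fit.params.k_on == 1.0
        assert fit.params.k_slice == pytest.approx(truth.k_slice, rel=0.03)
        assert fit.ci95["k_on"] is None

    def test_unresolved_second_phase_pinned_to_zero(self):
        # time points end long before the slow phase moves: k_phase2
        # cannot be resolved and is constrained to zero
        truth = KineticParams(k_on=0.005, k_slice=0.01, k_phase2=1.67e-6,
                              f_a=0.9)
        designs = [
            ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(10, 3000.0, 9))
            for e in (0.5, 5.0)
        ]
        data = generate_slicing_dataset(
            truth, designs, NoiseModel(sigma=0.02, seed=4)
        )
        fit = fit_single_turnover(data)
        assert fit.constrained["k_phase2_zero"]
        assert fit.params.k_phase2 == 0.0
        assert fit.params.k_slice == pytest.approx(truth.k_slice, rel=0.05)

    def test_noisy_recovery_is_reasonable(self, reference_params):
        errs = []
        for seed in (101, 102, 103):
            data = generate_slicing_dataset(
                reference_params, noise=NoiseModel(sigma=0.02, seed=seed)
            )
            fit = fit_single_turnover(data)
            errs.append(
                abs(fit.params.k_slice - reference_params.k_slice)
                / reference_params.k_slice
            )
        assert np.median(errs) < 0.15

    def test_deterministic(self, small_noiseless_dataset):
        f1 = fit_single_turnover(small_noiseless_dataset)
        f2 = fit_single_turnover(small_noiseless_dataset)
        assert f1.params == f2.params

    def test_tau_slice_is_reciprocal_with_reversed_ci(
        self, small_noiseless_dataset
    ):
        fit = fit_single_turnover(small_noiseless_dataset)
        assert fit.tau_slice * fit.params.k_slice == pytest.approx(1.0)
        lo, hi = fit.ci95["k_slice"]
        tlo, thi = fit.tau_slice_ci95
        assert tlo == pytest.approx(1.0 / hi) and thi == pytest.approx(1.0 / lo)


class TestFitMonophasic:
    def test_noiseless_recovery_to_four_digits(self):
        truth_k = 4e-5
        times = np.geomspace(600.0, 3e5, 10)
        f = monophasic_fraction_sliced(0.9, truth_k, times)
        data = _course([_series(1.0, times, f)])
        fit = fit_monophasic(data, f_a_fixed=0.9)
        assert fit.params.k_slice == pytest.approx(truth_k, rel=1e-4)

    def test_slowest_fit_reports_tau_in_hours(self):
        # k_slice = 5.787e-5 s^-1 corresponds to tau_slice = 4.8 h
        from slicekin.pipeline import format_tau

        tau = 1.0 / 5.787e-5
        assert tau == pytest.approx(4.8 * 3600.0, rel=1e-3)
        assert format_tau(tau) == "4.8 h"

    def test_rejects_bad_f_a(self):
        data = _course([_series(1.0, [1.0, 2.0, 3.0], [0.0, 0.1, 0.2])])
        with pytest.raises(ValueError, match="f_a_fixed"):
            fit_monophasic(data, f_a_fixed=1.5)


class TestFitMultipleTurnover:
    @pytest.fixture
    def st_fit(self, reference_params):
        return FitResult(
            params=reference_params, ci95={}, constrained={
                "k_on_at_diffusion_limit": False, "k_phase2_zero": False,
                "f_a_fixed": False},
            cost=0.0, converged=True, se_log10={}, n_obs=0,
        )

    def test_low_fraction_dataset_fixes_f_max(self, reference_params, st_fit):
        mt = MultiTurnoverParams(k_offP=0.0005, f_max=1.0)
        with pytest.warns(UserWarning):
            design = ReactionDesign(e_all=0.25, s0=4.0,
                                    times=np.geomspace(60, 1800, 8))
        data = generate_multiturnover_dataset(
            reference_params, mt, design, NoiseModel(sigma=0.0)
        )
        assert data.max_fraction() < 0.2
        res = fit_multiple_turnover(data, st_fit)
        assert res.f_max_fixed and res.mt_params.f_max == 1.0

    def test_noiseless_k_offP_round_trip(self, reference_params, st_fit):
        mt = MultiTurnoverParams(k_offP=0.002, f_max=0.95)
        with pytest.warns(UserWarning):
            design = ReactionDesign(e_all=0.25, s0=4.0,
                                    times=np.geomspace(100, 3e4, 10))
        data = generate_multiturnover_dataset(
            reference_params, mt, design, NoiseModel(sigma=0.0)
        )
        assert data.max_fraction() > 0.2
        res = fit_multiple_turnover(data, st_fit)
        assert res.mt_params.k_offP == pytest.approx(mt.k_offP, rel=0.02)
        assert res.mt_params.f_max == pytest.approx(mt.f_max, abs=0.02)

    def test_enzyme_concentration_deviation_recovered(self, reference_params,
                                                      st_fit):
        # data generated at 1.5x the intended enzyme concentration: the
        # fitted deviation stays within the two-fold bound and near truth
        mt = MultiTurnoverParams(k_offP=0.002, f_max=0.95)
        with pytest.warns(UserWarning):
            design = ReactionDesign(e_all=0.375, s0=4.0,
                                    times=np.geomspace(100, 3e4, 10))
        data = generate_multiturnover_dataset(
            reference_params, mt, design, NoiseModel(sigma=0.0)
        )
        # relabel the series with the intended concentration
        data.series[0].e_all = 0.25
        res = fit_multiple_turnover(data, st_fit)
        assert 0.125 <= res.e_all_fitted <= 0.5
        assert res.e_all_fitted == pytest.approx(0.375, rel=0.10)

    def test_missing_single_turnover_fit_rejected(self):
        data = _course([_series(0.25, [1.0, 2.0, 3.0], [0.0, 0.1, 0.2], s0=4.0)])
        with pytest.raises(ValueError, match="single-turnover"):
            fit_multiple_turnover(data, None)


class TestUncertainty:
    def test_noiseless_intervals_collapse(self, small_noiseless_dataset):
        fit = fit_single_turnover(small_noiseless_dataset)
        lo, hi = fit.ci95["k_slice"]
        assert (hi - lo) / fit.params.k_slice < 1e-3

    def test_bootstrap_agrees_with_asymptotic(self, reference_params):
        designs = [
            ReactionDesign(e_all=5.0, s0=0.02, times=np.geomspace(20, 1.7e5, 10))
        ]
        data = generate_slicing_dataset(
            reference_params, designs, NoiseModel(sigma=0.02, seed=5)
        )
        fit = fit_single_turnover(data)
        boot = confidence_intervals(fit, data, method="bootstrap",
                                    n_boot=200, seed=17)
        asym = fit.ci95
        for name in ("k_slice",):
            b, a = boot[name], asym[name]
            assert b is not None and a is not None
            width_b = np.log(b[1] / b[0])
            width_a = np.log(a[1] / a[0])
            assert width_b == pytest.approx(width_a, rel=0.30)

    def test_fold_change_identity_and_reciprocity(self, reference_params):
        fit = FitResult(
            params=reference_params, ci95={}, constrained={},
            cost=0.0, converged=True,
            se_log10={"k_slice": 0.05}, n_obs=10,
        )
        fc = fold_change(fit, fit)
        assert fc.ratio == 1.0
        a = FitResult(
            params=KineticParams(0.01, 0.02, 1e-5, 0.9), ci95={},
            constrained={}, cost=0.0, converged=True,
            se_log10={"k_slice": 0.1}, n_obs=10,
        )
        b = FitResult(
            params=KineticParams(0.01, 0.005, 1e-5, 0.9), ci95={},
            constrained={}, cost=0.0, converged=True,
            se_log10={"k_slice": 0.04}, n_obs=10,
        )
        ab, ba = fold_change(a, b), fold_change(b, a)
        assert ab.ratio * ba.ratio == pytest.approx(1.0, rel=1e-12)

    def test_fold_change_closed_form_propagation(self, reference_params):
        # two fits with natural-log SE 0.1 each: the CI half-width factor
        # is exp(1.96 * sqrt(0.02))
        se_log10 = 0.1 / np.log(10.0)
        fit = FitResult(
            params=reference_params, ci95={}, constrained={}, cost=0.0,
            converged=True, se_log10={"k_slice": se_log10}, n_obs=10,
        )
        fc = fold_change(fit, fit)
        factor = fc.ci95[1] / fc.ratio
        assert factor == pytest.approx(np.exp(1.96 * np.sqrt(0.02)), rel=1e-6)
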