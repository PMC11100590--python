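"""Forward-model correctness: closed forms, ODE oracles, conservation."""

import numpy as np
import pytest

from slicekin.models import (
    KineticParams,
    MultiTurnoverParams,
    ReactionDesign,
    VARIANT_DESCRIPTIONS,
    monophasic_fraction_sliced,
    pssa_fraction_sliced,
    simulate_multiple_turnover,
    simulate_single_turnover,
    simulate_variant,
)

from conftest import rk4_fraction_sliced


class TestClosedForms:
    def test_pssa_starts_at_zero_and_saturates(self):
        p = KineticParams(k_on=0.01, k_slice=0.005, k_phase2=1e-4, f_a=0.8)
        f = pssa_fraction_sliced(p, 1.0, [0.0, 1e7])
        assert f[0] == 0.0
        assert f[-1] == pytest.approx(1.0, abs=1e-6)

    def test_pssa_effective_rate_hand_evaluated(self):
        # k_on*E = k_slice = 0.01 -> effective rate 0.005; at t = 200 s
        # the fraction is 1 - e^-1
        p = KineticParams(k_on=0.01, k_slice=0.01, k_phase2=0.0, f_a=1.0)
        f = pssa_fraction_sliced(p, 1.0, [200.0])
        assert f[0] == pytest.approx(1.0 - np.exp(-1.0), rel=1e-12)

    def test_pssa_undefined_rate_raises(self):
        p = KineticParams(k_on=0.0, k_slice=0.0, k_phase2=1e-5, f_a=0.9)
        with pytest.raises(ValueError, match="undefined rate"):
            pssa_fraction_sliced(p, 1.0, [10.0])

    def test_monophasic_anchors(self):
        t_half = np.log(2) / 3e-4
        f = monophasic_fraction_sliced(0.85, 3e-4, [0.0, t_half, 1e9])
        assert f[0] == 0.0
        assert f[1] == pytest.approx(0.425, rel=1e-12)
        assert f[2] == pytest.approx(0.85, rel=1e-12)

    @pytest.mark.parametrize("f_a,k", [(0.0, 1e-4), (1.2, 1e-4), (0.9, 0.0)])
    def test_monophasic_rejects_bad_inputs(self, f_a, k):
        with pytest.raises(ValueError):
            monophasic_fraction_sliced(f_a, k, [1.0])


class TestSingleTurnover:
    def test_no_product_at_time_zero(self, reference_params):
        d = ReactionDesign(e_all=1.0, s0=0.02, times=np.array([0.0, 10.0]))
        f = simulate_single_turnover(reference_params, d)
        assert f[0] == 0.0

    def test_instantaneous_binding_limit_equals_monophasic(self):
        # with k_on*E = 100 s^-1 >> k_slice, binding is effectively
        # instantaneous and the curve collapses to the monophasic form
        p = KineticParams(k_on=1.0, k_slice=0.01, k_phase2=0.0, f_a=1.0)
        d = ReactionDesign(e_all=100.0, s0=0.02, times=np.array([100.0]))
        f = simulate_single_turnover(p, d)
        assert f[0] == pytest.approx(1.0 - np.exp(-1.0), rel=0.01)

    def test_matches_fine_step_rk4_oracle(self):
        p = KineticParams(k_on=0.001, k_slice=0.01, k_phase2=1e-5, f_a=0.9)
        d = ReactionDesign(
            e_all=1.0, s0=0.02,
            times=np.array([0.0, 300.0, 900.0, 2400.0, 4800.0, 7200.0]),
        )
        ode = simulate_single_turnover(p, d)
        oracle = rk4_fraction_sliced(p, d)
        assert np.max(np.abs(ode - oracle)) < 1e-4

    def test_fraction_non_decreasing_over_random_parameters(self):
        rng = np.random.default_rng(7)
        times = np.geomspace(1.0, 2e5, 30)
        for _ in range(25):
            p = KineticParams(
                k_on=10.0 ** rng.uniform(-4, 0),
                k_slice=10.0 ** rng.uniform(-5, -1),
                k_phase2=10.0 ** rng.uniform(-6, -4),
                f_a=rng.uniform(0.3, 0.999),
            )
            d = ReactionDesign(
                e_all=10.0 ** rng.uniform(np.log10(0.09), np.log10(33)),
                s0=0.02,
                times=times,
            )
            f = simulate_single_turnover(p, d)
            assert np.all(np.diff(f) >= -1e-7)
            assert np.all((f >= 0) & (f <= 1 + 1e-12))

    def test_mass_conservation_to_roundoff(self, reference_params):
        d = ReactionDesign(e_all=0.09, s0=0.02, times=np.geomspace(1, 2e5, 40))
        _, states = simulate_single_turnover(
            reference_params, d, return_states=True
        )
        assert np.max(np.abs(states.target_total() - d.s0)) < 1e-12 * d.s0

    def test_fast_binding_limit_is_sum_of_two_exponentials(self):
        # k_on*E >> k_slice, k_phase2: the solution reduces to
        # f_a(1-e^-k_slice t) + (1-f_a)(1-e^-k_phase2 t)
        p = KineticParams(k_on=1.0, k_slice=1e-3, k_phase2=1e-5, f_a=0.85)
        d = ReactionDesign(e_all=33.0, s0=0.02, times=np.geomspace(10, 3e5, 20))
        f = simulate_single_turnover(p, d)
        closed = p.f_a * (-np.expm1(-p.k_slice * d.times)) + (
            1 - p.f_a
        ) * (-np.expm1(-p.k_phase2 * d.times))
        assert np.max(np.abs(f - closed)) < 2e-3


class TestValidation:
    def test_diffusion_limit_enforced(self):
        with pytest.raises(ValueError, match="diffusion limit"):
            KineticParams(k_on=1.5, k_slice=0.01, k_phase2=0.0, f_a=0.9)

    def test_sub_single_turnover_design_warns(self):
        with pytest.warns(UserWarning, match="single-turnover"):
            ReactionDesign(e_all=0.1, s0=4.0, times=np.array([1.0, 2.0, 3.0]))

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ReactionDesign(e_all=1.0, s0=0.02, times=np.array([1.0, 1.0]))


class TestMultipleTurnover:
    def test_no_product_at_time_zero(self, reference_params):
        mt = MultiTurnoverParams(k_offP=0.01, f_max=0.95)
        with pytest.warns(UserWarning):
            d = ReactionDesign(e_all=0.25, s0=4.0, times=np.array([0.0, 60.0]))
        f = simulate_multiple_turnover(reference_params, mt, d)
        assert f[0] == 0.0

    def test_single_turnover_limit(self, reference_params):
        # enzyme at 100x target with f_max = 1: fraction sliced matches
        # the single-turnover model at all times
        mt = MultiTurnoverParams(k_offP=0.01, f_max=1.0)
        d = ReactionDesign(e_all=2.0, s0=0.02, times=np.geomspace(10, 1e5, 15))
        f_mt = simulate_multiple_turnover(reference_params, mt, d)
        f_st = simulate_single_turnover(reference_params, d)
        assert np.max(np.abs(f_mt - f_st)) < 0.01

    def test_post_burst_slope_equals_release_flux(self):
        # k_slice >> k_offP with substrate in excess: after the burst the
        # steady-state product flux is k_offP * f_a * e_all
        st = KineticParams(k_on=0.01, k_slice=0.1, k_phase2=1e-5, f_a=0.9)
        mt = MultiTurnoverParams(k_offP=0.001, f_max=1.0)
        with pytest.warns(UserWarning):
            d = ReactionDesign(
                e_all=0.25, s0=4.0, times=np.array([300.0, 800.0])
            )
        f = simulate_multiple_turnover(st, mt, d)
        sliced_nM = f * d.s0
        slope = (sliced_nM[1] - sliced_nM[0]) / (d.times[1] - d.times[0])
        expected = mt.k_offP * st.f_a * d.e_all
        assert slope == pytest.approx(expected, rel=0.10)

    def test_mass_conservation(self, reference_params):
        mt = MultiTurnoverParams(k_offP=0.005, f_max=0.95)
        with pytest.warns(UserWarning):
            d = ReactionDesign(e_all=0.25, s0=4.0,
                               times=np.geomspace(10, 2e4, 20))
        _, states = simulate_multiple_turnover(
            reference_params, mt, d, return_states=True
        )
        assert np.max(np.abs(states.target_total() - d.s0)) < 1e-12 * d.s0


class TestVariants:
    def test_all_variants_start_at_zero(self, reference_params,
                                        reference_design):
        for v in VARIANT_DESCRIPTIONS:
            d = ReactionDesign(
                e_all=reference_design.e_all,
                s0=reference_design.s0,
                times=np.array([0.0, 100.0]),
            )
            assert simulate_variant(v, reference_params, d)[0] == 0.0

    def test_variant_4_is_the_accepted_model(self, reference_params,
                                             reference_design):
        f4 = simulate_variant(4, reference_params, reference_design)
        f = simulate_single_turnover(reference_params, reference_design)
        assert np.array_equal(f4, f)

    def test_unknown_variant_rejected(self, reference_params,
                                      reference_design):
        with pytest.raises(ValueError, match="unknown variant"):
            simulate_variant(6, reference_params, reference_design)

    def test_variants_fit_accepted_data_indistinguishably(self):
        # all five alternative mechanisms, fitted to noisy data generated
        # by the accepted model, reach residual norms within 10% of one
        # another (the models cannot be told apart from fits alone)
        from scipy.optimize import least_squares

        from slicekin.synthetic import NoiseModel, generate_slicing_dataset

        truth = KineticParams(k_on=0.005, k_slice=0.01, k_phase2=1e-5, f_a=0.9)
        designs = [
            ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(20, 1.7e5, 8))
            for e in (0.5, 5.0)
        ]
        data = generate_slicing_dataset(
            truth, designs, NoiseModel(sigma=0.02, seed=11)
        )

        def fit_variant(v):
            def residual(x):
                p = KineticParams(
                    k_on=10.0 ** x[0], k_slice=10.0 ** x[1],
                    k_phase2=10.0 ** x[2], f_a=x[3],
                )
                out = []
                for s in data.series:
                    d = ReactionDesign(e_all=s.e_all, s0=s.s0, times=s.times)
                    out.append(simulate_variant(v, p, d) - s.fractions)
                return np.concatenate(out)

            x0 = np.array([np.log10(0.005), -2.0, -5.0, 0.9])
            res = least_squares(
                residual, x0,
                bounds=([-6, -6, np.log10(1.67e-6), 0.3],
                        [0, 2, np.log10(3.33e-3), 1.0]),
                method="trf", max_nfev=150,
            )
            return float(np.sqrt(2.0 * res.cost))

        norms = np.array([fit_variant(v) for v in sorted(VARIANT_DESCRIPTIONS)])
        assert norms.max() / norms.min() < 1.10
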