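import numpy as np
import pytest

from slicekin.models import KineticParams, ReactionDesign
from slicekin.synthetic import NoiseModel, generate_slicing_dataset


@pytest.fixture
def reference_params() -> KineticParams:
    """Moderately slow association so that the dilution series is
    informative; values in the realistic assay range."""
    return KineticParams(k_on=0.005, k_slice=0.01, k_phase2=1e-5, f_a=0.9)


@pytest.fixture
def reference_design() -> ReactionDesign:
    return ReactionDesign(
        e_all=1.0, s0=0.02, times=np.geomspace(10.0, 1.7e5, 12)
    )


@pytest.fixture
def small_noiseless_dataset(reference_params):
    """Two-concentration noiseless dataset, small enough for fast fits."""
    designs = [
        ReactionDesign(e_all=e, s0=0.02, times=np.geomspace(20.0, 1.7e5, 9))
        for e in (0.5, 5.0)
    ]
    return generate_slicing_dataset(
        reference_params, designs, NoiseModel(sigma=0.0, seed=0)
    )


def rk4_fraction_sliced(params, design, step=0.25):
    """Independent fixed-step RK4 integration of the accepted
    single-turnover system (full six species, plain Python floats).

    Serves as a brute-force oracle for the adaptive stiff solver; the
    step is chosen so the local truncation error sits far below the
    comparison tolerances used in tests.
    """
    kon, ks, kp2, fa = params.k_on, params.k_slice, params.k_phase2, params.f_a
    e_t = fa * design.e_all
    ep_t = (1.0 - fa) * design.e_all
    s0 = design.s0

    def deriv(state):
        p, es, eps, e, e_def, s = state
        bi = kon * e * s
        bd = kon * e_def * s
        return (
            ks * es + kp2 * eps,
            bi - ks * es,
            bd - kp2 * eps,
            -bi + ks * es,
            -bd + kp2 * eps,
            -bi - bd,
        )

    state = (0.0, 0.0, 0.0, e_t, ep_t, s0)
    t = 0.0
    out = []
    targets = list(np.asarray(design.times, dtype=float))
    for t_target in targets:
        while t < t_target - 1e-12:
            h = min(step, t_target - t)
            k1 = deriv(state)
            s2 = tuple(y + 0.5 * h * k for y, k in zip(state, k1))
            k2 = deriv(s2)
            s3 = tuple(y + 0.5 * h * k for y, k in zip(state, k2))
            k3 = deriv(s3)
            s4 = tuple(y + h * k for y, k in zip(state, k3))
            k4 = deriv(s4)
            state = tuple(
                y + h / 6.0 * (a + 2 * b + 2 * c + d)
                for y, a, b, c, d in zip(state, k1, k2, k3, k4)
            )
            t += h
        p, es, eps, *_ = state
        out.append(p / s0)
    return np.array(out)
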