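"""Forward kinetic models of RISC-catalyzed target slicing.

Single-turnover slicing by an Argonaute-guide complex (RISC) is biphasic:
a majority fraction ``f_a`` of the purified enzyme is functionally intact
and slices bound target at ``k_slice``, while the remaining fraction is
defective and turns over its bound target only at the much slower
``k_phase2``.  Binding of free enzyme to free target is bimolecular with
rate constant ``k_on`` (nM^-1 s^-1, capped at the diffusion limit of
1 nM^-1 s^-1).

This module provides the accepted single-turnover ODE model, its
closed-form approximations (the pseudo-steady-state biphasic expression
used to seed fits, and the monophasic form used for very slow reactions),
the multiple-turnover ODE model with explicit product release and
re-binding, and the five rejected alternative biphasic mechanisms.

All concentrations are in nM and times in seconds.  ODE systems are
integrated in reduced form: the linear conservation laws (total target,
total intact enzyme, total defective enzyme) are eliminated analytically,
so conserved totals hold to floating-point roundoff and the systems are
smaller and faster to solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DIFFUSION_LIMIT",
    "KineticParams",
    "ReactionDesign",
    "MultiTurnoverParams",
    "StateVector",
    "KineticsError",
    "SolverError",
    "simulate_single_turnover",
    "pssa_fraction_sliced",
    "monophasic_fraction_sliced",
    "simulate_multiple_turnover",
    "simulate_variant",
    "VARIANT_DESCRIPTIONS",
]

#: Diffusion limit on the bimolecular association rate constant, nM^-1 s^-1.
DIFFUSION_LIMIT = 1.0


class KineticsError(RuntimeError):
    """Base class for kinetic-model errors."""


class SolverError(KineticsError):
    """ODE integration failed or produced inconsistent concentrations."""


@dataclass(frozen=True)
class KineticParams:
    """Single-turnover kinetic parameters.

    Parameters
    ----------
    k_on : float
        Association rate constant, nM^-1 s^-1 (0 <= k_on <= 1, the
        diffusion limit).
    k_slice : float
        Slicing rate constant of the intact enzyme, s^-1.
    k_phase2 : float
        Slow second-phase rate constant of the defective enzyme, s^-1.
    f_a : float
        Fraction of enzyme that is functionally intact, in [0, 1].
    """

    k_on: float
    k_slice: float
    k_phase2: float
    f_a: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_on <= DIFFUSION_LIMIT):
            raise ValueError(
                f"k_on must be in [0, {DIFFUSION_LIMIT}] nM^-1 s^-1 "
                f"(diffusion limit); got {self.k_on}"
            )
        if self.k_slice < 0 or self.k_phase2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0.0 <= self.f_a <= 1.0):
            raise ValueError(f"f_a must be in [0, 1]; got {self.f_a}")
        if self.k_phase2 > self.k_slice > 0:
            warnings.warn(
                "k_phase2 exceeds k_slice; the 'slow phase' is the fast one",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReactionDesign:
    """Concentrations and sampling times of one slicing reaction.

    ``e_all`` is the total enzyme concentration (intact plus defective),
    ``s0`` the initial target concentration, both nM; ``times`` are the
    observation times in seconds (non-negative, strictly increasing).
    """

    e_all: float
    s0: float
    times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.e_all <= 0:
            raise ValueError("e_all must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        t = self.times
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.e_all < self.s0:
            warnings.warn(
                "e_all < s0: not a single-turnover regime "
                "(enzyme should be in excess over target)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MultiTurnoverParams:
    """Multiple-turnover parameters: product release and plateau height.

    ``k_offP`` is the product-release rate constant (s^-1, > 0) and
    ``f_max`` the maximum plateau of the fraction sliced, in (0, 1].
    """

    k_offP: float
    f_max: float = 1.0

    def __post_init__(self) -> None:
        if self.k_offP <= 0:
            raise ValueError("k_offP must be positive")
        if not (0.0 < self.f_max <= 1.0):
            raise ValueError(f"f_max must be in (0, 1]; got {self.f_max}")


@dataclass(frozen=True)
class StateVector:
    """Species concentrations (nM) along a simulated reaction.

    Single-turnover states carry P, ES, E'S, E, E', S; multiple-turnover
    states additionally carry EP and E'P.  Values are raw solver output
    (plus algebraically reconstructed conserved species), not clipped.
    """

    times: np.ndarray
    p: np.ndarray
    es: np.ndarray
    e_def_s: np.ndarray
    e: np.ndarray
    e_def: np.ndarray
    s: np.ndarray
    ep: np.ndarray | None = None
    e_def_p: np.ndarray | None = None

    def target_total(self) -> np.ndarray:
        """Sum of all target-containing species; conserved and equal to s0."""
        total = self.p + self.es + self.e_def_s + self.s
        if self.ep is not None:
            total = total + self.ep
        if self.e_def_p is not None:
            total = total + self.e_def_p
        return total


def _check_solution(sol, s0: float, atol: float) -> np.ndarray:
    if sol.status != 0 or not sol.success:
        raise SolverError(
            "ODE integration failed (stiff regime: widely separated rate "
            f"constants may require smaller tolerances): {sol.message}"
        )
    y = sol.y
    neg_tol = 1e3 * atol + 1e-9 * s0
    if np.any(y < -neg_tol):
        raise SolverError(
            "internal-consistency error: negative concentrations beyond "
            f"solver tolerance (min {y.min():.3e} nM)"
        )
    return y


def _fraction(p: np.ndarray, s0: float) -> np.ndarray:
    # Negative round-off at the tolerance scale is clipped before forming
    # the fraction; the raw states are left untouched.
    return np.clip(p, 0.0, s0) / s0


def simulate_single_turnover(
    params: KineticParams,
    design: ReactionDesign,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    return_states: bool = False,
):
    """Fraction of target sliced under the accepted single-turnover model.

    Integrates the biphasic ODE system in which intact enzyme E binds
    target S at ``k_on`` and slices at ``k_slice`` (releasing E), while
    defective enzyme E' binds at the same ``k_on`` but its complex E'S
    turns over only at ``k_phase2``.  Returns

        F_sliced(t) = [P] / ([P] + [S] + [ES] + [E'S])

    evaluated at ``design.times``.  With ``return_states=True`` also
    returns the full :class:`StateVector`.
    """
    kon, ks, kp2, fa = params.k_on, params.k_slice, params.k_phase2, params.f_a
    e_t = fa * design.e_all          # intact enzyme total
    ep_t = (1.0 - fa) * design.e_all  # defective enzyme total
    s0 = design.s0
    times = design.times

    # Reduced state y = [S, ES, E'S]; E = e_t - ES, E' = ep_t - E'S,
    # P = s0 - S - ES - E'S by conservation.
    def rhs(_t, y):
        s, es, eps = y
        e = e_t - es
        e_def = ep_t - eps
        bind_i = kon * e * s
        bind_d = kon * e_def * s
        return (-bind_i - bind_d, bind_i - ks * es, bind_d - kp2 * eps)

    def jac(_t, y):
        s, es, eps = y
        e = e_t - es
        e_def = ep_t - eps
        return np.array(
            [
                [-kon * (e + e_def), kon * s, kon * s],
                [kon * e, -kon * s - ks, 0.0],
                [kon * e_def, 0.0, -kon * s - kp2],
            ]
        )

    y = _integrate(rhs, jac, (s0, 0.0, 0.0), times, rtol, atol, s0)
    s, es, eps = y
    p = s0 - s - es - eps
    frac = _fraction(p, s0)
    if not return_states:
        return frac
    states = StateVector(
        times=times, p=p, es=es, e_def_s=eps,
        e=e_t - es, e_def=ep_t - eps, s=s,
    )
    return frac, states


def _integrate(rhs, jac, y0, times, rtol, atol, s0):
    """Solve with the stiff-capable BDF method and evaluate at `times`."""
    t_end = float(times[-1])
    if t_end == 0.0:
        return np.array(y0, dtype=float)[:, None].repeat(len(times), axis=1)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.asarray(y0, dtype=float),
        method="BDF",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    return _check_solution(sol, s0, atol)


def pssa_fraction_sliced(
    params: KineticParams, e_total: float, times
) -> np.ndarray:
    """Closed-form biphasic fraction sliced under the pseudo-steady-state
    approximation of the enzyme-substrate complex:

        F(t) = f_a * (1 - exp(-t / (1/(k_on*E) + 1/k_slice)))
             + (1 - f_a) * (1 - exp(-k_phase2 * t))

    where E is the total enzyme concentration (nM).  Used to seed the ODE
    fit; least accurate when k_on*E is comparable to k_slice.
    """
    if e_total <= 0:
        raise ValueError("e_total must be positive")
    t = np.asarray(times, dtype=float)
    kb = params.k_on * e_total
    ks = params.k_slice
    if kb == 0.0 and ks == 0.0:
        raise ValueError(
            "undefined rate: k_on*e_total and k_slice are both zero"
        )
    k_eff = 0.0 if (kb == 0.0 or ks == 0.0) else 1.0 / (1.0 / kb + 1.0 / ks)
    return params.f_a * (-np.expm1(-k_eff * t)) + (1.0 - params.f_a) * (
        -np.expm1(-params.k_phase2 * t)
    )


def monophasic_fraction_sliced(f_a: float, k_slice: float, times) -> np.ndarray:
    """Single-exponential fraction sliced, F(t) = f_a * (1 - exp(-k_slice*t)).

    Used for very slow (mismatched-target) reactions whose plateau cannot
    be resolved and whose association kinetics contribute nothing.
    """
    if not (0.0 < f_a <= 1.0):
        raise ValueError(f"f_a must be in (0, 1]; got {f_a}")
    if k_slice <= 0:
        raise ValueError("k_slice must be positive")
    t = np.asarray(times, dtype=float)
    return f_a * (-np.expm1(-k_slice * t))


def simulate_multiple_turnover(
    st_params: KineticParams,
    mt_params: MultiTurnoverParams,
    design: ReactionDesign,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    return_states: bool = False,
):
    """Fraction of target sliced under the multiple-turnover model.

    Extends the accepted single-turnover mechanism with explicit
    enzyme-product complexes: slicing converts ES -> EP (E'S -> E'P at
    k_phase2), product is released at ``k_offP``, and free product can
    re-bind free enzyme at ``k_on``.  Returns

        F_sliced(t) = ([P] + [EP] + [E'P]) / s0 * f_max
    """
    kon, ks = st_params.k_on, st_params.k_slice
    kp2, fa = st_params.k_phase2, st_params.f_a
    koff = mt_params.k_offP
    e_t = fa * design.e_all
    ep_t = (1.0 - fa) * design.e_all
    s0 = design.s0
    times = design.times

    # Reduced state y = [S, ES, EP, E'S, E'P]; conservation gives
    # E = e_t - ES - EP, E' = ep_t - E'S - E'P,
    # P = s0 - S - ES - EP - E'S - E'P.
    def rhs(_t, y):
        s, es, ep, eps, epp = y
        e = e_t - es - ep
        e_def = ep_t - eps - epp
        p = s0 - s - es - ep - eps - epp
        return (
            -kon * (e + e_def) * s,
            kon * e * s - ks * es,
            ks * es - koff * ep + kon * e * p,
            kon * e_def * s - kp2 * eps,
            kp2 * eps - koff * epp + kon * e_def * p,
        )

    def jac(_t, y):
        s, es, ep, eps, epp = y
        e = e_t - es - ep
        e_def = ep_t - eps - epp
        p = s0 - s - es - ep - eps - epp
        return np.array(
            [
                [-kon * (e + e_def), kon * s, kon * s, kon * s, kon * s],
                [kon * e, -kon * s - ks, -kon * s, 0.0, 0.0],
                [
                    -kon * e,
                    ks - kon * e + kon * p,
                    -koff - kon * e - kon * p,
                    -kon * e,
                    -kon * e,
                ],
                [kon * e_def, 0.0, 0.0, -kon * s - kp2, -kon * s],
                [
                    -kon * e_def,
                    -kon * e_def,
                    -kon * e_def,
                    kp2 - kon * e_def + kon * p,
                    -koff - kon * e_def - kon * p,
                ],
            ]
        )

    y = _integrate(rhs, jac, (s0, 0.0, 0.0, 0.0, 0.0), times, rtol, atol, s0)
    s, es, ep, eps, epp = y
    p = s0 - s - es - ep - eps - epp
    sliced = np.clip(p, 0.0, s0) + np.clip(ep, 0.0, s0) + np.clip(epp, 0.0, s0)
    frac = np.clip(sliced / s0, 0.0, 1.0) * mt_params.f_max
    if not return_states:
        return frac
    states = StateVector(
        times=times, p=p, es=es, e_def_s=eps,
        e=e_t - es - ep, e_def=ep_t - eps - epp, s=s,
        ep=ep, e_def_p=epp,
    )
    return frac, states


#: One-line mechanisms of the five alternative biphasic models that were
#: considered and rejected in favor of the accepted defective-enzyme model.
VARIANT_DESCRIPTIONS = {
    1: "inactive RISC binds target but cannot slice; dissociates at k_phase2",
    2: "complex adopts a slicing-incompetent conformation on binding; "
       "dissociates at k_phase2",
    3: "complex adopts a slicing-incompetent conformation on binding; "
       "converts to the competent conformation at k_phase2",
    4: "complex adopts a slicing-defective conformation on binding; "
       "slices at k_phase2 (the accepted model's structure)",
    5: "complex undergoes guide unloading, leaving naked guide blocking "
       "the target; the guide:target duplex dissociates at k_phase2",
}


def simulate_variant(
    variant_id: int,
    params: KineticParams,
    design: ReactionDesign,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> np.ndarray:
    """Fraction sliced under one of the five rejected biphasic mechanisms.

    The alternative mechanisms are only described verbally in the source
    material; each is reconstructed here as the minimal ODE system that
    introduces exactly one k_phase2-governed transition (reconstructions
    documented inline).  Dissociated target is allowed to re-bind free
    enzyme in variants 1, 2 and 5.
    """
    if variant_id not in VARIANT_DESCRIPTIONS:
        raise ValueError(
            f"unknown variant_id {variant_id!r}; expected one of 1-5"
        )
    if variant_id == 4:
        # Definitionally the accepted model: the "defective" complex simply
        # slices at k_phase2.  Delegate so the identity is exact.
        return simulate_single_turnover(params, design, rtol=rtol, atol=atol)

    kon, ks, kp2, fa = params.k_on, params.k_slice, params.k_phase2, params.f_a
    s0 = design.s0
    times = design.times

    if variant_id == 1:
        # Reconstruction: a fraction (1 - f_a) of RISC is inactive.  It
        # binds target at k_on like active RISC but never slices; its
        # complex dissociates at k_phase2, and released target re-binds
        # either pool.  State y = [S, ES, E'S]; P = s0 - S - ES - E'S.
        e_t = fa * design.e_all
        ep_t = (1.0 - fa) * design.e_all

        def rhs(_t, y):
            s, es, eps = y
            e = e_t - es
            e_def = ep_t - eps
            return (
                -kon * (e + e_def) * s + kp2 * eps,
                kon * e * s - ks * es,
                kon * e_def * s - kp2 * eps,
            )

        def jac(_t, y):
            s, es, eps = y
            e = e_t - es
            e_def = ep_t - eps
            return np.array(
                [
                    [-kon * (e + e_def), kon * s, kon * s + kp2],
                    [kon * e, -kon * s - ks, 0.0],
                    [kon * e_def, 0.0, -kon * s - kp2],
                ]
            )

        y0 = (s0, 0.0, 0.0)

    elif variant_id in (2, 3):
        # Reconstruction: all enzyme is one pool E (total e_all), but each
        # binding event yields a slicing-competent complex ES with
        # probability f_a and an incompetent complex XS otherwise.
        # Variant 2: XS dissociates at k_phase2 (target re-binds).
        # Variant 3: XS converts to ES at k_phase2 (then slices at k_slice).
        # State y = [S, ES, XS]; E = e_all - ES - XS; P = s0 - S - ES - XS.
        e_all = design.e_all
        dissociates = variant_id == 2

        def rhs(_t, y):
            s, es, xs = y
            e = e_all - es - xs
            bind = kon * e * s
            if dissociates:
                return (-bind + kp2 * xs, fa * bind - ks * es,
                        (1.0 - fa) * bind - kp2 * xs)
            return (-bind, fa * bind + kp2 * xs - ks * es,
                    (1.0 - fa) * bind - kp2 * xs)

        def jac(_t, y):
            s, es, xs = y
            e = e_all - es - xs
            if dissociates:
                return np.array(
                    [
                        [-kon * e, kon * s, kon * s + kp2],
                        [fa * kon * e, -fa * kon * s - ks, -fa * kon * s],
                        [
                            (1 - fa) * kon * e,
                            -(1 - fa) * kon * s,
                            -(1 - fa) * kon * s - kp2,
                        ],
                    ]
                )
            return np.array(
                [
                    [-kon * e, kon * s, kon * s],
                    [fa * kon * e, -fa * kon * s - ks, -fa * kon * s + kp2],
                    [
                        (1 - fa) * kon * e,
                        -(1 - fa) * kon * s,
                        -(1 - fa) * kon * s - kp2,
                    ],
                ]
            )

        y0 = (s0, 0.0, 0.0)

    else:  # variant 5
        # Reconstruction: each binding event unloads the guide with
        # probability (1 - f_a), leaving an inactive naked-guide:target
        # duplex GS that blocks the target; GS dissociates at k_phase2,
        # releasing target that can re-bind remaining enzyme.  The protein
        # that lost its guide is inactive, so enzyme is consumed by
        # unloading and must be carried as a state.
        # State y = [S, ES, GS, E]; P = s0 - S - ES - GS.
        def rhs(_t, y):
            s, es, gs, e = y
            bind = kon * e * s
            return (
                -bind + kp2 * gs,
                fa * bind - ks * es,
                (1.0 - fa) * bind - kp2 * gs,
                -bind + ks * es + fa * bind,
            )

        def jac(_t, y):
            s, es, gs, e = y
            return np.array(
                [
                    [-kon * e, 0.0, kp2, -kon * s],
                    [fa * kon * e, -ks, 0.0, fa * kon * s],
                    [(1 - fa) * kon * e, 0.0, -kp2, (1 - fa) * kon * s],
                    [-(1 - fa) * kon * e, ks, 0.0, -(1 - fa) * kon * s],
                ]
            )

        y0 = (s0, 0.0, 0.0, design.e_all)

    y = _integrate(rhs, jac, y0, times, rtol, atol, s0)
    p = s0 - y[0] - y[1] - y[2]
    return _fraction(p, s0)
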