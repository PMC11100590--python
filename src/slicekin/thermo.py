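"""Thermodynamic model of 3'-mismatch tolerance and the knockdown ceiling.

Targets complementary only through guide position 16 ("16-bp" targets)
are sliced more slowly than perfectly complementary targets, and the
penalty depends on how strongly the guide can pair at its central
positions 9-12.  The relationship is modeled as a two-state (Fermi-like)
sigmoid: the free energy gained from central pairing, dG(9-12), must
overcome an energetic threshold dG_thres for the complex to populate the
slicing-competent conformation,

    k_slice(16-bp) / k_slice(perfect) = 1 / (exp((dG + dG_thres)/RT) + 1)

with R the molar gas constant and T = 310.15 K (37 C).  dG values are
standard predicted pairing energies in kcal/mol (negative = stable) taken
as inputs; helpers are provided to remove duplex-initiation and symmetry
penalties that nearest-neighbor programs impose on short duplexes.

The module also provides the steady-state knockdown ceiling: treating
slicing as an added first-order decay (rate 1/tau_slice) on top of basal
mRNA decay (rate ln2 / half-life), the maximum achievable knockdown is
(1/tau_slice) / (ln2/half_life + 1/tau_slice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT_KCAL",
    "TEMPERATURE_K",
    "INITIATION_PENALTY",
    "SYMMETRY_PENALTY",
    "ThermoPoint",
    "ThermoFit",
    "UnidentifiableError",
    "relative_kslice",
    "fit_dG_thres",
    "correct_duplex_energy",
    "max_knockdown",
]

#: Molar gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3
#: Assay temperature, K (37 C).
TEMPERATURE_K = 310.15
#: Duplex initiation penalty imposed by nearest-neighbor models, kcal/mol.
INITIATION_PENALTY = 4.09
#: Self-complementarity (symmetry) penalty, kcal/mol.
SYMMETRY_PENALTY = 0.43

_RT = GAS_CONSTANT_KCAL * TEMPERATURE_K


class UnidentifiableError(ValueError):
    """The threshold energy cannot be identified from the data."""


@dataclass(frozen=True)
class ThermoPoint:
    """One guide's (central pairing energy, relative k_slice) pair."""

    dG_9_12: float
    ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.dG_9_12):
            raise ValueError("dG_9_12 must be finite")
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError(f"ratio must be in (0, 1]; got {self.ratio}")


@dataclass
class ThermoFit:
    """Fitted threshold energy with 95% CI and t-test significance."""

    dG_thres: float
    ci95: tuple | None
    se: float | None
    p_value: float | None
    n: int
    unidentifiable: bool = False
    R: float = GAS_CONSTANT_KCAL
    T: float = TEMPERATURE_K


def relative_kslice(dG_9_12, dG_thres: float):
    """Sigmoid ratio k_slice(16-bp)/k_slice(perfect); strictly decreasing
    in dG_9_12 and mapping the real line onto (0, 1)."""
    dg = np.asarray(dG_9_12, dtype=float)
    out = 1.0 / (np.exp((dg + dG_thres) / _RT) + 1.0)
    return float(out) if np.isscalar(dG_9_12) else out


def fit_dG_thres(points) -> ThermoFit:
    """Fit the threshold energy by nonlinear least squares on log(ratio).

    ``points`` is a sequence of :class:`ThermoPoint` (or (dG, ratio)
    pairs).  dG_thres is initialized at 10 kcal/mol and unbounded.  Data
    spanning no range of dG, or sitting entirely at ratio ~= 1 (no
    detectable barrier), are unidentifiable.
    """
    pts = [p if isinstance(p, ThermoPoint) else ThermoPoint(*p) for p in points]
    if len(pts) < 3:
        raise UnidentifiableError("need at least 3 points")
    dg = np.array([p.dG_9_12 for p in pts])
    ratio = np.array([p.ratio for p in pts])
    if np.ptp(dg) == 0.0:
        raise UnidentifiableError(
            "all points share one dG value; threshold unidentifiable"
        )

    def residual(x):
        return np.log(relative_kslice(dg, x[0])) - np.log(ratio)

    res = least_squares(residual, np.array([10.0]), method="lm")
    dth = float(res.x[0])
    dof = max(ratio.size - 1, 1)
    s2 = 2.0 * res.cost / dof
    jtj = float((res.jac.T @ res.jac).item())
    if jtj <= 0 or not np.isfinite(jtj):
        se = None
    else:
        se = float(np.sqrt(s2 / jtj))
    # no barrier detectable: the sigmoid is pinned at 1 over the whole
    # observed range and the threshold runs off to -infinity
    unident = (
        np.all(ratio >= 0.999)
        or not np.isfinite(dth)
        or se is None
        or se > 1e3
        or dth < -1e3
    )
    if unident:
        return ThermoFit(dG_thres=dth, ci95=None, se=se, p_value=None,
                         n=ratio.size, unidentifiable=True)
    ci = (dth - 1.96 * se, dth + 1.96 * se)
    p = 0.0 if se == 0.0 else float(2.0 * stats.t.sf(abs(dth / se), dof))
    return ThermoFit(dG_thres=dth, ci95=ci, se=se, p_value=p, n=ratio.size)


def correct_duplex_energy(
    raw_dG: float,
    apply_initiation: bool = False,
    apply_symmetry: bool = False,
) -> float:
    """Remove initiation and/or symmetry penalties from a predicted duplex
    energy when the upstream nearest-neighbor calculation imposed them,
    restoring the pure pairing (stacking) energy.

    Removing a penalty makes the energy more negative: e.g. a raw -2.0
    kcal/mol with the initiation penalty imposed becomes -6.09.
    """
    if not np.isfinite(raw_dG):
        raise ValueError("raw_dG must be finite")
    corrected = raw_dG
    if apply_initiation:
        corrected -= INITIATION_PENALTY
    if apply_symmetry:
        corrected -= SYMMETRY_PENALTY
    return corrected


def max_knockdown(tau_slice: float, half_life: float) -> float:
    """Steady-state ceiling on slicing-mediated knockdown.

    With basal decay rate k_deg = ln2 / half_life and slicing adding a
    first-order decay at rate 1/tau_slice, the steady-state mRNA level
    drops from alpha/k_deg to alpha/(k_deg + 1/tau_slice), so the maximal
    knockdown fraction is

        (1/tau_slice) / (ln2/half_life + 1/tau_slice).

    ``tau_slice`` and ``half_life`` may be in any single consistent time
    unit.  A guide with tau_slice of 12 min gives 0.94 against a 2-h
    half-life and 0.78 against a 30-min half-life.
    """
    if tau_slice <= 0 or half_life <= 0:
        raise ValueError("tau_slice and half_life must be positive")
    k_s = 1.0 / tau_slice
    k_deg = np.log(2.0) / half_life
    return k_s / (k_deg + k_s)
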