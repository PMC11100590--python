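"""RISC quantification and binding kinetics from filter-binding data.

Stock concentrations of purified RISC are estimated from titration
filter binding against a fixed concentration of a seed-matched target
oligonucleotide.  Sub-saturating dilution series are fit by simple linear
regression of fraction bound against dilution factor; series that
approach target saturation are fit to the tight-binding quadratic, which
accounts for ligand depletion at 1:1 stoichiometry.  Association rate
constants come from time-resolved filter binding fit to a single
exponential, with the diffusion limit reported as a lower bound when the
reaction is complete by the first time point.

Internally all concentrations are reconciled to pM (the titration stock
scale); the target concentration is supplied in nM and converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .models import DIFFUSION_LIMIT

__all__ = [
    "TitrationDataset",
    "TitrationResult",
    "AssociationDataset",
    "AssociationResult",
    "InsufficientDataError",
    "quadratic_fraction_bound",
    "fit_titration_linear",
    "fit_titration_quadratic",
    "fit_association",
    "SATURATION_CUTOFF",
]

#: Fraction-bound cutoff below which a titration point is considered
#: sub-saturating and eligible for the linear fit.
SATURATION_CUTOFF = 0.60


class InsufficientDataError(ValueError):
    """Too few eligible data points to fit."""


@dataclass
class TitrationDataset:
    """Dilution-series binding data: (dilution factor, fraction bound)
    pairs at a fixed total target concentration (nM)."""

    target_total: float
    dilution_factors: np.ndarray
    fractions_bound: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        self.fractions_bound = np.asarray(self.fractions_bound, dtype=float)
        if self.target_total <= 0:
            raise ValueError("target_total must be positive")
        df = self.dilution_factors
        if np.any(df <= 0):
            raise ValueError("dilution factors must be positive")
        if len(np.unique(df)) != df.size:
            raise ValueError("dilution factors must be distinct")
        fb = self.fractions_bound
        if np.any((fb < 0) | (fb > 1)):
            raise ValueError("fractions bound must lie in [0, 1]")


@dataclass
class TitrationResult:
    """Fitted stock concentration (pM) with intercept, optional K_D (pM),
    the model actually used, and the significance of the stock estimate."""

    stock: float
    yint: float
    kd: float | None
    model_used: str
    p_value_stock: float
    stock_se: float | None = None
    flagged: bool = False


@dataclass
class AssociationDataset:
    """Time-resolved filter-binding data at a fixed RISC concentration
    (nM, assumed in vast excess over target and K_D)."""

    risc_total: float
    times: np.ndarray
    fractions_bound: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions_bound = np.asarray(self.fractions_bound, dtype=float)
        if self.risc_total <= 0:
            raise ValueError("risc_total must be positive")
        if self.times.shape != self.fractions_bound.shape:
            raise ValueError("times and fractions must have the same length")


@dataclass
class AssociationResult:
    """Fitted plateau A and association rate k_on (nM^-1 s^-1); when the
    first time point is already at plateau, k_on is a lower bound at the
    diffusion limit."""

    a: float
    k_on: float
    ci95: dict
    lower_bound: bool = False

    @property
    def k_on_per_min(self) -> float:
        """k_on expressed in nM^-1 min^-1 (x60)."""
        return self.k_on * 60.0

    def summary(self) -> str:
        if self.lower_bound:
            return (
                f"k_on >= {self.k_on:g} nM^-1 s^-1 "
                f"(>= {self.k_on_per_min:g} nM^-1 min^-1, diffusion limit)"
            )
        return f"k_on = {self.k_on:.3g} nM^-1 s^-1 (A = {self.a:.3g})"


def quadratic_fraction_bound(stock_pM, dilution_factor, target_pM, kd_pM, yint):
    """Tight-binding (ligand-depletion) fraction of target bound.

    theta = (S + T + K_D - sqrt((S + T + K_D)^2 - 4 S T)) / (2 T) with
    S = stock*DF and T the total target, then F = theta*(1 - yint) + yint,
    the unique reading bounded in [yint, 1].
    """
    s = np.asarray(stock_pM, dtype=float) * np.asarray(
        dilution_factor, dtype=float
    )
    t = float(target_pM)
    b = s + t + kd_pM
    disc = np.clip(b * b - 4.0 * s * t, 0.0, np.inf)
    theta = (b - np.sqrt(disc)) / (2.0 * t)
    return theta * (1.0 - yint) + yint


def fit_titration_linear(data: TitrationDataset) -> TitrationResult:
    """Ordinary least squares of F_bound = stock*DF/target_total + yint on
    sub-saturating points (fraction bound <= 0.60).  Returns the stock in
    pM with the slope's standard significance."""
    keep = data.fractions_bound <= SATURATION_CUTOFF
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} points at <= {SATURATION_CUTOFF:.0%} "
            "bound; need at least 3 for the linear titration fit"
        )
    df = data.dilution_factors[keep]
    fb = data.fractions_bound[keep]
    reg = stats.linregress(df, fb)
    target_pM = data.target_total * 1e3
    stock = reg.slope * target_pM
    flagged = not np.isfinite(reg.pvalue) or reg.pvalue > 0.05 or stock <= 0
    if flagged:
        warnings.warn(
            "linear titration slope not significant (or non-positive); "
            "stock estimate flagged",
            stacklevel=2,
        )
    return TitrationResult(
        stock=float(stock),
        yint=float(reg.intercept),
        kd=None,
        model_used="linear",
        p_value_stock=float(reg.pvalue),
        stock_se=float(reg.stderr * target_pM) if np.isfinite(reg.stderr) else None,
        flagged=flagged,
    )


# quadratic-fit initializations and bounds (pM; K_D in log10 space)
_QUAD_X0 = (30_000.0, 0.1, 2.0)
_QUAD_LO = (1e-6, 0.0, -2.0)
_QUAD_HI = (1e6, 1.0 - 1e-9, 4.0)


def fit_titration_quadratic(data: TitrationDataset) -> TitrationResult:
    """Nonlinear least squares of the tight-binding quadratic.

    Fits stock (pM), y-intercept, and K_D (pM, log space).  If the stock
    estimate is not significant (asymptotic t-test, p > 0.05), falls back
    to the linear fit on sub-saturation points and records
    ``model_used='linear'``.
    """
    target_pM = data.target_total * 1e3
    df = data.dilution_factors
    fb = data.fractions_bound

    def residual(x):
        stock, yint, log_kd = x
        return (
            quadratic_fraction_bound(stock, df, target_pM, 10.0 ** log_kd, yint)
            - fb
        )

    try:
        res = least_squares(
            residual,
            np.array(_QUAD_X0),
            bounds=(np.array(_QUAD_LO), np.array(_QUAD_HI)),
            method="trf",
            x_scale="jac",
        )
        stock, yint, log_kd = res.x
        dof = max(fb.size - 3, 1)
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
            se_stock = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            se_stock = np.inf
        if se_stock > 0 and np.isfinite(se_stock):
            tval = stock / se_stock
            p = float(2.0 * stats.t.sf(abs(tval), dof))
        else:
            p = 1.0
    except Exception as exc:
        warnings.warn(f"quadratic titration fit failed ({exc}); "
                      "falling back to linear", stacklevel=2)
        p = 1.0
        res = None

    if res is None or p > 0.05:
        linear = fit_titration_linear(data)
        linear.p_value_stock = linear.p_value_stock
        return linear
    return TitrationResult(
        stock=float(stock),
        yint=float(yint),
        kd=float(10.0 ** log_kd),
        model_used="quadratic",
        p_value_stock=p,
        stock_se=se_stock,
    )


def fit_association(data: AssociationDataset, max_iter: int = 100
                    ) -> AssociationResult:
    """Fit F_bound = A * (1 - exp(-k_on * [RISC_T] * t)).

    Approximates the association rate as k_on*[RISC_T] with negligible
    dissociation (RISC in vast excess over target and K_D).  If the first
    (non-zero-time) observation is already at the plateau, the rate is
    unresolvable and k_on is reported as a lower bound at the diffusion
    limit (1 nM^-1 s^-1, i.e. 60 nM^-1 min^-1).
    """
    if data.times.size < 4:
        raise InsufficientDataError("need at least 4 time points")
    t = data.times
    fb = data.fractions_bound
    r = data.risc_total

    def residual(x):
        a, kon = x
        return a * (-np.expm1(-kon * r * t)) - fb

    res = least_squares(
        residual,
        np.array([0.8, 0.0333]),
        bounds=(np.array([1e-6, 1e-9]), np.array([1.0, DIFFUSION_LIMIT])),
        method="trf",
        max_nfev=max_iter * 3,
    )
    if not res.success and not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"association fit did not converge: {res.message}")
    a, kon = float(res.x[0]), float(res.x[1])
    dof = max(fb.size - 2, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        ci = {
            "A": (a - 1.96 * se[0], a + 1.96 * se[0]),
            "k_on": (kon - 1.96 * se[1], kon + 1.96 * se[1]),
        }
    except np.linalg.LinAlgError:
        ci = {"A": None, "k_on": None}

    nonzero = t > 0
    if np.any(nonzero):
        first = fb[nonzero][int(np.argmin(t[nonzero]))]
        if first >= 0.95 * a:
            return AssociationResult(
                a=a,
                k_on=DIFFUSION_LIMIT,
                ci95={"A": ci["A"], "k_on": None},
                lower_bound=True,
            )
    return AssociationResult(a=a, k_on=kon, ci95=ci)
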