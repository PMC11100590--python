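"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the assays the pipeline was designed for: biphasic
single-turnover slicing time courses at a dilution series of enzyme
concentrations, multiple-turnover courses, titration filter-binding
curves, time-resolved association curves, and hydroxyl-radical
footprinting lane profiles.  Each generator is a bit-exact function of
(truth, design, seed), attaches its ground-truth parameters to the
returned dataset, and applies additive Gaussian measurement noise on the
fraction scale (default sigma = 0.02, matching phosphorimager
quantification noise, approximately homoscedastic at this scale),
clamped to [0, 1].

Default designs mirror realistic assay layouts: enzyme at 0.37-3.3 nM
(within the 0.09-33 nM range such assays use), target at 0.02 nM, and
log-spaced time points out to ~48 h so the slow second phase is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import AssociationDataset, TitrationDataset, quadratic_fraction_bound
from .fitting import SlicingSeries, SlicingTimeCourse
from .footprint import ReactivityProfile
from .models import (
    KineticParams,
    MultiTurnoverParams,
    ReactionDesign,
    simulate_multiple_turnover,
    simulate_single_turnover,
)
from .thermo import ThermoPoint, relative_kslice

__all__ = [
    "NoiseModel",
    "ThermoDataset",
    "FootprintLaneSet",
    "default_designs",
    "default_slicing_params",
    "generate_slicing_dataset",
    "generate_multiturnover_dataset",
    "generate_auxiliary_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the generators.

    ``kind`` is "additive-gaussian" (fraction-scale SD ``sigma``, clamped
    to [0, 1] when ``truncation``) or "multiplicative-lognormal"
    (``sigma`` is the SD of log values; used for rate-ratio data).
    Identical seeds give identical datasets.
    """

    kind: str = "additive-gaussian"
    sigma: float = 0.02
    truncation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(clean, dtype=float).copy()
        if self.kind == "additive-gaussian":
            noisy = clean + rng.normal(0.0, self.sigma, size=np.shape(clean))
            if self.truncation:
                noisy = np.clip(noisy, 0.0, 1.0)
            return noisy
        return clean * np.exp(rng.normal(0.0, self.sigma, size=np.shape(clean)))


def default_slicing_params() -> KineticParams:
    """Representative single-turnover truth: moderately slow association
    (k_on well below the diffusion limit so the dilution series is
    informative), k_slice of 0.01 s^-1, a 90% intact enzyme fraction and
    a slow phase near the middle of its resolvable range."""
    return KineticParams(k_on=0.005, k_slice=0.01, k_phase2=1e-5, f_a=0.9)


def default_designs(
    s0: float = 0.02,
    e_all=(0.33, 3.3, 33.0),
    t_min: float = 10.0,
    t_max: float = 1.7e5,
    n_times: int = 12,
) -> list[ReactionDesign]:
    """A ten-fold enzyme dilution series spanning the 0.09-33 nM assay
    range, sharing one log-spaced time grid (10 s to ~48 h), enzyme
    always in excess over 0.02 nM target."""
    times = np.geomspace(t_min, t_max, n_times)
    return [ReactionDesign(e_all=float(e), s0=s0, times=times) for e in e_all]


def generate_slicing_dataset(
    true_params: KineticParams | None = None,
    designs: list[ReactionDesign] | None = None,
    noise: NoiseModel | None = None,
    guide_id: str = "synthetic-guide",
    target_id: str = "perfect",
) -> SlicingTimeCourse:
    """Simulate the accepted single-turnover model per design, add noise,
    and return a :class:`SlicingTimeCourse` with the truth attached."""
    params = true_params or default_slicing_params()
    designs = designs if designs is not None else default_designs()
    noise = noise or NoiseModel()
    rng = noise.rng()
    series = []
    for d in designs:
        clean = simulate_single_turnover(params, d)
        series.append(
            SlicingSeries(
                e_all=d.e_all,
                s0=d.s0,
                times=d.times,
                fractions=np.clip(noise.apply(clean, rng), 0.0, 1.0),
            )
        )
    return SlicingTimeCourse(
        guide_id=guide_id,
        target_id=target_id,
        series=series,
        truth={
            "k_on": params.k_on,
            "k_slice": params.k_slice,
            "k_phase2": params.k_phase2,
            "f_a": params.f_a,
            "sigma": noise.sigma,
            "seed": noise.seed,
        },
    )


def generate_multiturnover_dataset(
    st_params: KineticParams | None = None,
    mt_params: MultiTurnoverParams | None = None,
    design: ReactionDesign | None = None,
    noise: NoiseModel | None = None,
    guide_id: str = "synthetic-guide",
    target_id: str = "perfect-mt",
) -> SlicingTimeCourse:
    """Simulate a multiple-turnover course (substrate in excess: default
    4 nM target, 0.25 nM enzyme) with noise and attached truth."""
    import warnings as _warnings

    st = st_params or default_slicing_params()
    mt = mt_params or MultiTurnoverParams(k_offP=0.002, f_max=0.95)
    if design is None:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            design = ReactionDesign(
                e_all=0.25, s0=4.0, times=np.geomspace(30.0, 2e4, 12)
            )
    noise = noise or NoiseModel()
    rng = noise.rng()
    clean = simulate_multiple_turnover(st, mt, design)
    series = SlicingSeries(
        e_all=design.e_all,
        s0=design.s0,
        times=design.times,
        fractions=np.clip(noise.apply(clean, rng), 0.0, 1.0),
    )
    return SlicingTimeCourse(
        guide_id=guide_id,
        target_id=target_id,
        series=[series],
        truth={
            "k_offP": mt.k_offP,
            "f_max": mt.f_max,
            "e_all": design.e_all,
            "sigma": noise.sigma,
            "seed": noise.seed,
        },
    )


@dataclass
class ThermoDataset:
    """Synthetic (dG, relative k_slice) points with the generating truth."""

    points: list[ThermoPoint]
    truth: dict


@dataclass
class FootprintLaneSet:
    """Raw synthetic footprinting lanes plus the reactivity templates that
    generated them."""

    profiles: list[ReactivityProfile]
    truth: dict

    def by_condition(self, condition: str) -> list[ReactivityProfile]:
        return [p for p in self.profiles if p.condition == condition]


def _footprint_template(condition: str, n: int) -> np.ndarray:
    """Deterministic per-position reactivity templates.

    The slicing-competent (perfect-target) state exposes the guide
    backbone around the central positions 9-11 and beyond position 18;
    the no-target state keeps the seed pre-organized (protected) and the
    3' region docked.  Templates are parameterized shapes, not traced
    data.
    """
    pos = np.arange(1, n + 1)
    base = np.full(n, 0.25)
    if condition in ("perfect", "seed+supp", "16-bp"):
        react = base.copy()
        react[(pos >= 9) & (pos <= 11)] = 0.90
        if condition == "perfect":
            react[pos >= 19] = 0.80
        elif condition == "seed+supp":
            react[pos >= 19] = 0.45
        return react
    if condition in ("no-target", "seed-only"):
        react = base.copy()
        react[(pos >= 2) & (pos <= 8)] = 0.12
        react[pos >= 12] = 0.15
        return react
    raise ValueError(f"no template for condition {condition!r}")


def _generate_footprint(truth: dict | None, noise: NoiseModel) -> FootprintLaneSet:
    t = {
        "guide_id": "synthetic-guide",
        "n_positions": 22,
        "conditions": ("no-target", "perfect"),
        "replicates": 2,
        "quenched_level": 100.0,
        "dynamic_range": 300.0,
        "masked_positions": (1, 2, 3, 21, 22),
    }
    if truth:
        t.update(truth)
    n = int(t["n_positions"])
    pos = np.arange(1, n + 1)
    # position-dependent anchors: lane background and per-position
    # cleavability both vary smoothly along the gel
    q = t["quenched_level"] * (1.0 + 0.1 * np.sin(pos / 3.0))
    span = t["dynamic_range"] * (1.0 + 0.2 * np.cos(pos / 4.0))
    naked = q + span
    mask = np.zeros(n, dtype=bool)
    mask[[p - 1 for p in t["masked_positions"]]] = True
    rng = noise.rng()

    def lane(condition, reactivity, rep):
        eps = rng.normal(0.0, noise.sigma, size=n) if noise.sigma else 0.0
        values = q + (reactivity + eps) * span
        return ReactivityProfile(
            guide_id=t["guide_id"],
            condition=condition,
            replicate_id=f"rep{rep}",
            values=values,
            mask=mask.copy(),
        )

    profiles = []
    reps = int(t["replicates"])
    for rep in range(1, reps + 1):
        profiles.append(lane("quenched", np.zeros(n), rep))
        profiles.append(lane("naked", np.ones(n), rep))
        for cond in t["conditions"]:
            profiles.append(lane(cond, _footprint_template(cond, n), rep))
    t["quenched_profile"] = q
    t["naked_profile"] = naked
    t["templates"] = {c: _footprint_template(c, n) for c in t["conditions"]}
    return FootprintLaneSet(profiles=profiles, truth=t)


def generate_auxiliary_dataset(
    kind: str,
    truth: dict | None = None,
    noise: NoiseModel | None = None,
):
    """Generate a titration, association, thermo, or footprint dataset.

    Kind-specific truth defaults:

    - ``titration``: stock 25,000 pM, K_D 50 pM, yint 0.05, target 1 nM,
      two-fold dilution series from 0.25 (spans saturation).
    - ``association``: A 0.85, k_on 0.02 nM^-1 s^-1, RISC 1 nM,
      log-spaced times.
    - ``thermo``: dG_thres 8 kcal/mol on a dG grid from -12 to -1
      (multiplicative noise on the ratio scale).
    - ``footprint``: 22-nt guide, quenched/naked anchor lanes plus
      no-target and perfect-target conditions in duplicate.
    """
    noise = noise or NoiseModel()
    if kind == "titration":
        t = {
            "stock_pM": 25_000.0,
            "kd_pM": 50.0,
            "yint": 0.05,
            "target_total_nM": 1.0,
            "dilution_factors": 0.25 * 2.0 ** -np.arange(12.0),
        }
        if truth:
            t.update(truth)
        df = np.asarray(t["dilution_factors"], dtype=float)
        clean = quadratic_fraction_bound(
            t["stock_pM"], df, t["target_total_nM"] * 1e3, t["kd_pM"], t["yint"]
        )
        rng = noise.rng()
        return TitrationDataset(
            target_total=t["target_total_nM"],
            dilution_factors=df,
            fractions_bound=np.clip(noise.apply(clean, rng), 0.0, 1.0),
            truth=t,
        )
    if kind == "association":
        t = {
            "A": 0.85,
            "k_on": 0.02,
            "risc_total_nM": 1.0,
            "times": np.geomspace(5.0, 2000.0, 10),
        }
        if truth:
            t.update(truth)
        times = np.asarray(t["times"], dtype=float)
        clean = t["A"] * (-np.expm1(-t["k_on"] * t["risc_total_nM"] * times))
        rng = noise.rng()
        return AssociationDataset(
            risc_total=t["risc_total_nM"],
            times=times,
            fractions_bound=np.clip(noise.apply(clean, rng), 0.0, 1.0),
            truth=t,
        )
    if kind == "thermo":
        t = {"dG_thres": 8.0, "dG_grid": np.linspace(-12.0, -1.0, 12)}
        if truth:
            t.update(truth)
        dg = np.asarray(t["dG_grid"], dtype=float)
        clean = relative_kslice(dg, t["dG_thres"])
        if noise.kind == "additive-gaussian" and noise.sigma > 0:
            # rate ratios carry multiplicative error; reinterpret sigma on
            # the log scale for this dataset kind
            noise = NoiseModel(
                kind="multiplicative-lognormal",
                sigma=noise.sigma,
                truncation=False,
                seed=noise.seed,
            )
        rng = noise.rng()
        ratios = np.clip(noise.apply(clean, rng), 1e-9, 1.0)
        return ThermoDataset(
            points=[ThermoPoint(float(g), float(r)) for g, r in zip(dg, ratios)],
            truth=t,
        )
    if kind == "footprint":
        return _generate_footprint(truth, noise)
    raise ValueError(f"unknown dataset kind {kind!r}")
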