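"""Hydroxyl-radical footprinting reactivity normalization and QC.

Per-position backbone-cleavage intensities of a radiolabeled guide RNA
report its solvent accessibility within RISC.  Raw lane intensities are
normalized position-by-position between two anchors measured on the same
gel: quenched-reagent lanes (no cleavage; mean set to 0) and naked-guide
lanes (maximal accessibility; mean set to 1).  Utilities correct
non-specific degradation bands by neighbor averaging and flag denatured
replicates (uniform, strongly elevated reactivity).

Positions are 1-based along the guide, 5'->3'; position p denotes
cleavage after nucleotide p.  Unquantifiable positions (e.g. cleavage
products merging with the full-length band or running into the salt
front) are carried in a boolean mask and excluded from every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ReactivityProfile",
    "condition_mean",
    "normalize_reactivity",
    "correct_degradation_bands",
    "flag_denatured",
]

#: Recognized experimental conditions for a footprinting lane.
CONDITIONS = (
    "no-target",
    "seed-only",
    "seed+supp",
    "16-bp",
    "perfect",
    "quenched",
    "naked",
)


@dataclass
class ReactivityProfile:
    """Per-position intensities (or normalized reactivities) of one lane.

    ``values[i]`` is the value at guide position i+1; ``mask[i]`` is True
    where the position is unquantifiable.
    """

    guide_id: str
    condition: str
    replicate_id: str
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if self.mask is None:
            self.mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values in length")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.values.size + 1)

    def unmasked(self) -> np.ndarray:
        return ~self.mask


def condition_mean(profiles) -> tuple[np.ndarray, np.ndarray]:
    """Simple per-position mean across replicate lanes.

    Returns (mean values, mask); a position is masked only where it is
    masked in every replicate, and masked replicate values never enter
    the mean.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    n = profiles[0].values.size
    if any(p.values.size != n for p in profiles):
        raise ValueError("profiles must share the position index")
    vals = np.stack([p.values for p in profiles])
    masks = np.stack([p.mask for p in profiles])
    counts = (~masks).sum(axis=0)
    total = np.where(masks, 0.0, vals).sum(axis=0)
    out_mask = counts == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(out_mask, np.nan, total / np.maximum(counts, 1))
    return mean, out_mask


def normalize_reactivity(
    raw: ReactivityProfile,
    quenched_mean: np.ndarray,
    naked_mean: np.ndarray,
) -> ReactivityProfile:
    """Linearly rescale each position between the quenched (0) and naked
    (1) anchors: normalized(p) = (raw(p) - q(p)) / (n(p) - q(p)).

    Positions with zero dynamic range (naked == quenched) are auto-masked
    with a warning.  Normalization is invariant to any positive affine
    transform applied jointly to raw and both anchors.
    """
    q = np.asarray(quenched_mean, dtype=float)
    n = np.asarray(naked_mean, dtype=float)
    if q.shape != raw.values.shape or n.shape != raw.values.shape:
        raise ValueError("anchors must share the profile's position index")
    span = n - q
    degenerate = np.abs(span) <= 1e-12 * np.maximum.reduce(
        [np.abs(n), np.abs(q), np.ones_like(q)]
    )
    mask = raw.mask | degenerate
    if np.any(degenerate & ~raw.mask):
        bad = np.flatnonzero(degenerate & ~raw.mask) + 1
        warnings.warn(
            f"zero dynamic range at position(s) {bad.tolist()}; auto-masked",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(degenerate, np.nan, (raw.values - q) / span)
    return replace(raw, values=normalized, mask=mask)


def correct_degradation_bands(
    profile: ReactivityProfile, positions
) -> ReactivityProfile:
    """Replace values at degradation-band positions with the mean of the
    two flanking positions.

    Non-specific degradation bands (identified on the gel) contaminate
    single positions; each listed position takes the arithmetic mean of
    its immediate neighbors.  Terminal positions, positions whose
    neighbor is masked, and runs of adjacent flagged positions cannot be
    corrected and are masked instead, with a warning.  Corrections are
    logged via warnings at debug-free level (the returned profile is a
    new object; the input is unchanged).
    """
    flagged = sorted({int(p) for p in positions})
    out_values = profile.values.copy()
    out_mask = profile.mask.copy()
    n = out_values.size
    flagged_set = set(flagged)
    for p in flagged:
        i = p - 1
        if i < 0 or i >= n:
            raise ValueError(f"position {p} outside 1..{n}")
        left, right = i - 1, i + 1
        correctable = (
            left >= 0
            and right < n
            and not out_mask[left]
            and not out_mask[right]
            and (p - 1) not in flagged_set
            and (p + 1) not in flagged_set
        )
        if correctable:
            out_values[i] = 0.5 * (profile.values[left] + profile.values[right])
        else:
            out_mask[i] = True
            warnings.warn(
                f"position {p} cannot be corrected (terminal, masked "
                "neighbor, or adjacent flagged position); masked instead",
                stacklevel=2,
            )
    return replace(profile, values=out_values, mask=out_mask)


def flag_denatured(profile: ReactivityProfile, replicate_set) -> bool:
    """True when the lane looks like a denatured complex: uniformly and
    substantially elevated reactivity, operationalized as more than half
    of the unmasked positions lying > 2 standard deviations above the
    per-position mean across replicates.
    """
    refs = [r for r in replicate_set if r is not profile]
    if len(refs) < 2:
        warnings.warn(
            "fewer than 2 reference replicates: denaturation not "
            "assessable; returning False",
            stacklevel=2,
        )
        return False
    n = profile.values.size
    if any(r.values.size != n for r in refs):
        raise ValueError("replicates must share the position index")
    vals = np.stack([r.values for r in refs])
    masks = np.stack([r.mask for r in refs])
    counts = (~masks).sum(axis=0)
    ok = (counts >= 2) & ~profile.mask
    if not np.any(ok):
        return False
    masked_vals = np.ma.masked_array(vals, mask=masks)
    mean = masked_vals.mean(axis=0).filled(np.nan)
    sd = masked_vals.std(axis=0, ddof=1).filled(np.nan)
    elevated = ok & (profile.values > mean + 2.0 * sd)
    return int(elevated.sum()) * 2 > int(ok.sum())
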