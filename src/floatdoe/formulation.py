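"""Tablet mass balance and swelling / matrix-erosion statistics.

The tablet contains a fixed drug mass and a fixed floating-agent (cetyl
alcohol) mass, while the gel-forming polymer (HPMC K15M) and the lubricant
(magnesium stearate) are dosed as percentages of the *total* tablet mass.
The total therefore follows from the fixed masses alone:

    total = (drug + cetyl) / (1 - hpmc/100 - mgst/100)

Swelling and matrix erosion are weight-based percentages from the
gravimetric dissolution experiment: swelling is the relative weight gain of
the hydrated tablet, erosion the relative weight loss after drying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "TabletComposition",
    "SwellingSeries",
    "tablet_mass",
    "swelling_percent",
    "erosion_percent",
]


def tablet_mass(
    drug_mg: float, cetyl_mg: float, hpmc_pct: float, mgst_pct: float
) -> float:
    """Total tablet mass (mg) from the fixed masses and percentage excipients.

    ``hpmc_pct`` and ``mgst_pct`` are percentages of the total tablet mass;
    their sum must stay below 100 for the balance to close.
    """
    if drug_mg <= 0 or cetyl_mg < 0:
        raise ValidationError("component masses must be positive")
    if hpmc_pct < 0 or mgst_pct < 0:
        raise ValidationError("percentages must be non-negative")
    denom = 1.0 - hpmc_pct / 100.0 - mgst_pct / 100.0
    if denom <= 1e-12:
        raise ValidationError(
            "percentage excipients sum to >= 100% of the tablet; no finite mass"
        )
    return (drug_mg + cetyl_mg) / denom


@dataclass(frozen=True)
class TabletComposition:
    """One formulation's components with the derived total mass.

    ``total_mg`` is always recomputed from the mass balance; the invariant
    ``total * (1 - hpmc/100 - mgst/100) == drug + cetyl`` holds by
    construction.
    """

    drug_mg: float
    cetyl_mg: float
    hpmc_pct: float
    mgst_pct: float

    def __post_init__(self) -> None:
        if self.hpmc_pct + self.mgst_pct >= 100:
            raise ValidationError("percentage components must sum below 100%")
        tablet_mass(self.drug_mg, self.cetyl_mg, self.hpmc_pct, self.mgst_pct)

    @property
    def total_mg(self) -> float:
        return tablet_mass(self.drug_mg, self.cetyl_mg, self.hpmc_pct, self.mgst_pct)

    @property
    def hpmc_mg(self) -> float:
        return self.total_mg * self.hpmc_pct / 100.0

    @property
    def mgst_mg(self) -> float:
        return self.total_mg * self.mgst_pct / 100.0


def swelling_percent(initial_mg, swollen_mg):
    """Relative weight gain (%) of the hydrated tablet.

    ``(swollen - initial) / initial * 100``; a swollen weight below the
    initial weight yields a negative value (physically odd, returned as is —
    callers may flag it).
    """
    initial = np.asarray(initial_mg, dtype=float)
    swollen = np.asarray(swollen_mg, dtype=float)
    if np.any(initial <= 0) or np.any(swollen <= 0):
        raise ValidationError("weights must be positive")
    out = (swollen - initial) / initial * 100.0
    return float(out) if out.ndim == 0 else out


def erosion_percent(initial_mg, dried_mg):
    """Relative weight loss (%) of the dried tablet matrix.

    ``(initial - dried) / initial * 100``; a dried weight above the initial
    weight yields a negative value, returned as is.
    """
    initial = np.asarray(initial_mg, dtype=float)
    dried = np.asarray(dried_mg, dtype=float)
    if np.any(initial <= 0) or np.any(dried <= 0):
        raise ValidationError("weights must be positive")
    out = (initial - dried) / initial * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SwellingSeries:
    """Gravimetric swelling experiment: swollen and dried weights over time.

    ``dried_mg`` holds the post-drying weight at each collection time (the
    experiment sacrifices one tablet per time point).  Dried weights above
    the initial weight are physically implausible but only flagged, never
    rejected, since blotting and assay noise can produce them.
    """

    initial_mg: float
    times_h: np.ndarray
    swollen_mg: np.ndarray
    dried_mg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        sw = np.asarray(self.swollen_mg, dtype=float)
        dr = np.atleast_1d(np.asarray(self.dried_mg, dtype=float))
        if dr.size == 1:
            dr = np.full_like(t, dr[0])
        if not (t.size == sw.size == dr.size):
            raise ValidationError("times, swollen and dried weights must align")
        if self.initial_mg <= 0 or np.any(sw <= 0) or np.any(dr <= 0):
            raise ValidationError("weights must be positive")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "swollen_mg", sw)
        object.__setattr__(self, "dried_mg", dr)

    @property
    def implausible(self) -> np.ndarray:
        """Mask of time points where the dried weight exceeds the initial."""
        return self.dried_mg > self.initial_mg

    def swelling(self) -> np.ndarray:
        return swelling_percent(self.initial_mg, self.swollen_mg)

    def erosion(self) -> np.ndarray:
        return erosion_percent(self.initial_mg, self.dried_mg)
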