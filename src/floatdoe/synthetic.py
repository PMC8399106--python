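"""Synthetic dissolution, DoE-response and swelling data generators.

Every downstream statistic in this package (similarity factor, bootstrap
intervals, kinetics fits, response-surface models) is exercised on data from
these generators, which emulate the structure of a 12-unit USP Apparatus II
dissolution run:

* a power-law (Korsmeyer-Peppas) mean release curve ``Q(t) = min(cap, k t^n)``
  on the percent scale,
* independent additive Gaussian between-tablet noise at each time point,
* monotonization of each unit's series by running maximum (cumulative release
  cannot decrease) and clipping to ``[0, cap]``.

The default sampling grid is the ten-point schedule 15-1440 min used for
sustained-release testing, and the default reference product releases about
30/60/80 % at 60/240/480 min, the three comparison points used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import DissolutionProfile

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_SEED",
    "REFERENCE_TARGETS",
    "ReleaseCurveSpec",
    "NoiseSpec",
    "curve_through_points",
    "reference_curve",
    "generate_profile_set",
    "generate_doe_dataset",
    "generate_swelling_series",
]

#: Sampling grid (min) of the emulated dissolution run.
DEFAULT_GRID = (15.0, 30.0, 45.0, 60.0, 120.0, 240.0, 480.0, 720.0, 1080.0, 1440.0)

#: Global default seed for reproducible generation.
DEFAULT_SEED = 20210808

#: (time min, release %) anchor points of the reference product.
REFERENCE_TARGETS = ((60.0, 30.0), (480.0, 80.0))


@dataclass(frozen=True)
class ReleaseCurveSpec:
    """Power-law mean release curve ``Q(t) = min(cap, k * t**n_exp)``.

    ``k`` is on the percent-per-min^n scale, ``n_exp`` is the dimensionless
    release exponent and ``cap`` the asymptotic cumulative release (%).
    """

    k: float
    n_exp: float
    cap: float = 100.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError("rate constant k must be positive")
        if not 0 < self.n_exp < 1.5:
            raise ValidationError("release exponent must lie in (0, 1.5)")
        if not 0 < self.cap <= 120:
            raise ValidationError("cap must lie in (0, 120]")

    def mean_release(self, times: Sequence[float]) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return np.minimum(self.cap, self.k * t**self.n_exp)


@dataclass(frozen=True)
class NoiseSpec:
    """Between-tablet additive noise: SD in percentage points plus a seed."""

    unit_sd: float = 2.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.unit_sd < 0:
            raise ValidationError("unit_sd must be non-negative")


def curve_through_points(
    p1: tuple[float, float], p2: tuple[float, float], cap: float = 100.0
) -> ReleaseCurveSpec:
    """Power-law curve through two (time, release) anchors.

    Solves the two-equation log-log system ``q = k t^n`` exactly:
    ``n = log(q2/q1)/log(t2/t1)`` and ``k = q1 / t1^n``.
    """
    (t1, q1), (t2, q2) = p1, p2
    if min(t1, q1, t2, q2) <= 0 or t1 == t2:
        raise ValidationError("anchors must be positive with distinct times")
    n = math.log(q2 / q1) / math.log(t2 / t1)
    k = q1 / t1**n
    return ReleaseCurveSpec(k=k, n_exp=n, cap=cap)


def reference_curve(cap: float = 100.0) -> ReleaseCurveSpec:
    """Default reference product: ~30/60/80 % released at 60/240/480 min."""
    return curve_through_points(*REFERENCE_TARGETS, cap=cap)


def generate_profile_set(
    curve: ReleaseCurveSpec,
    times: Sequence[float] = DEFAULT_GRID,
    n_units: int = 12,
    noise: NoiseSpec = NoiseSpec(),
    product_id: str = "SYN",
) -> DissolutionProfile:
    """Simulate one dissolution run of ``n_units`` tablets.

    Each unit's series is the mean curve plus one independent Gaussian draw
    per time point, made non-decreasing by running maximum and clipped to
    ``[0, cap]``.  Identical seeds give identical output.
    """
    if n_units < 1:
        raise ValidationError("n_units must be at least 1")
    t = np.asarray(times, dtype=float)
    mean = curve.mean_release(t)
    rng = np.random.default_rng(noise.seed)
    raw = mean[None, :] + rng.normal(0.0, noise.unit_sd, size=(n_units, t.size))
    units = np.clip(np.maximum.accumulate(raw, axis=1), 0.0, curve.cap)
    return DissolutionProfile(product_id=product_id, times=t, units=units)


_TERMS = ("intercept", "A", "B", "AB", "A2", "B2")


def evaluate_actual_equation(
    coeffs: Mapping[str, float], A, B
) -> np.ndarray:
    """Evaluate a response equation in physical units at (A, B).

    Recognized terms: intercept, A, B, AB, A2, B2; absent terms are zero.
    """
    unknown = set(coeffs) - set(_TERMS)
    if unknown:
        raise ValidationError(f"unknown equation term(s): {sorted(unknown)}")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    c = {t: float(coeffs.get(t, 0.0)) for t in _TERMS}
    return (
        c["intercept"]
        + c["A"] * A
        + c["B"] * B
        + c["AB"] * A * B
        + c["A2"] * A**2
        + c["B2"] * B**2
    )


def generate_doe_dataset(
    actual_coeffs: Mapping[str, Mapping[str, float]],
    design,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Fill a design table with responses from actual equations plus noise.

    ``actual_coeffs`` maps response ids (e.g. ``"R1"``) to term->coefficient
    mappings in physical units.  ``noise_sd = 0`` reproduces the equations
    exactly; otherwise independent Gaussian noise is added per run.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    points = design.points if hasattr(design, "points") else design
    if not {"A_mg", "B_pct"}.issubset(points.columns):
        raise ValidationError("design points need A_mg and B_pct columns")
    if not actual_coeffs:
        raise ValidationError("no response equations supplied")
    rng = np.random.default_rng(seed)
    out = points.copy()
    for resp, coeffs in actual_coeffs.items():
        clean = evaluate_actual_equation(coeffs, out["A_mg"], out["B_pct"])
        out[resp] = clean + rng.normal(0.0, noise_sd, size=len(out))
    return out


def generate_swelling_series(
    initial_mg: float,
    swell_plateau_pct: float,
    swell_rate_per_h: float,
    erosion_pct_per_h: float,
    times_h: Sequence[float],
    seed: int = DEFAULT_SEED,
    noise_sd_mg: float = 0.0,
):
    """Simulate a swelling / matrix-erosion weighing experiment.

    Swollen weight follows the saturating form
    ``W(t) = initial * (1 + plateau/100 * (1 - exp(-rate t)))`` — rapid early
    water uptake flattening to a plateau — while the dried weight declines
    linearly, ``D(t) = initial * (1 - e t / 100)``, mimicking steady matrix
    erosion.  Zero rates give constant weights.
    """
    from .formulation import SwellingSeries

    if initial_mg <= 0:
        raise ValidationError("initial_mg must be positive")
    if min(swell_plateau_pct, swell_rate_per_h, erosion_pct_per_h) < 0:
        raise ValidationError("rates must be non-negative")
    t = np.asarray(times_h, dtype=float)
    rng = np.random.default_rng(seed)
    swollen = initial_mg * (
        1.0 + swell_plateau_pct / 100.0 * (1.0 - np.exp(-swell_rate_per_h * t))
    )
    dried = initial_mg * (1.0 - erosion_pct_per_h * t / 100.0)
    if noise_sd_mg > 0:
        swollen = swollen + rng.normal(0.0, noise_sd_mg, size=t.size)
        dried = dried + rng.normal(0.0, noise_sd_mg, size=t.size)
    swollen = np.maximum(swollen, 1e-9)
    dried = np.maximum(dried, 1e-9)
    return SwellingSeries(
        initial_mg=initial_mg, times_h=t, swollen_mg=swollen, dried_mg=dried
    )
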