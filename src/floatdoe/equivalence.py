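"""Similarity factor f2, its unbiased variant, and bootstrap intervals.

The similarity factor of Moore and Flanner compares two mean dissolution
profiles at P common time points:

    f2 = 50 * log10( [1 + (1/P) * sum_i (mu_t,i - mu_r,i)^2]^(-1/2) * 100 )

(base-10 log; 100 means identical profiles, values above 50 are conventionally
read as similar).  Because f2 is a concave function of noisy sample means it
is biased upward; the asymptotically unbiased variant E(f2) adds a per-point
between-unit variance penalty (s_t^2 + s_r^2)/n inside the bracket.

Sampling uncertainty is quantified by a nonparametric bootstrap that
resamples whole tablet units (their entire time vectors) with replacement
within each product, preserving within-tablet correlation.  Both the
percentile interval (PI) and Efron's bias-corrected and accelerated (BCa)
interval are reported; the equivalence decision requires the sample f2 and
both lower bounds to exceed the cutoff (default 50) strictly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .profiles import DissolutionProfile, ProfileSummary, summarize

__all__ = [
    "F2Result",
    "EquivalenceDecision",
    "f2_mean",
    "f2_expected",
    "bootstrap_f2",
    "bca_levels",
    "assess_equivalence",
    "DEFAULT_TIME_POINTS",
]

#: Default comparison time points (min): early / middle / late release.
DEFAULT_TIME_POINTS = (60.0, 240.0, 480.0)

DEFAULT_CUTOFF = 50.0
DEFAULT_ALPHA = 0.10
DEFAULT_B = 500


def f2_mean(test_means: Sequence[float], ref_means: Sequence[float]) -> float:
    """Similarity factor of two mean profiles.

    Equals ``100 - 25*log10(1 + msd)`` where ``msd`` is the mean squared
    per-time-point difference; exactly 100 iff the profiles coincide.
    """
    t = np.asarray(test_means, dtype=float)
    r = np.asarray(ref_means, dtype=float)
    if t.ndim != 1 or r.ndim != 1 or t.size == 0:
        raise ValidationError("mean vectors must be non-empty and 1-D")
    if t.size != r.size:
        raise ValidationError(
            f"length mismatch: test has {t.size} points, reference {r.size}"
        )
    msd = float(np.mean((t - r) ** 2))
    return 100.0 - 25.0 * np.log10(1.0 + msd)


def f2_expected(
    test: ProfileSummary,
    ref: ProfileSummary,
    scale_variance_by_p: bool = True,
) -> float:
    """Asymptotically unbiased similarity factor E(f2).

    Adds the variance penalty ``(s_t^2 + s_r^2)/n`` at each time point to the
    squared mean difference before the log transform, correcting the upward
    bias of the plug-in f2.  With ``scale_variance_by_p`` (default) the 1/P
    factor averages the variance penalty together with the squared
    differences — the grouping consistent with
    ``E[(x_t - x_r)^2] = (mu_t - mu_r)^2 + (s_t^2 + s_r^2)/n`` applied per
    point; set it False to add the raw variance sum unaveraged instead.
    Equals :func:`f2_mean` of the same means when every variance is zero, and
    is strictly smaller whenever any variance is positive.
    """
    if test.P != ref.P:
        raise ValidationError("summaries must share the number of time points")
    if not np.allclose(test.times, ref.times):
        raise ValidationError("summaries must share the comparison time points")
    n = min(test.n, ref.n)
    sq = (test.means - ref.means) ** 2
    var_pen = (test.variances + ref.variances) / n
    if scale_variance_by_p:
        inner = float(np.mean(sq + var_pen))
    else:
        inner = float(np.mean(sq) + np.sum(var_pen))
    return 100.0 - 25.0 * np.log10(1.0 + inner)


@dataclass(frozen=True)
class EquivalenceDecision:
    """Outcome of the cutoff rule, with the criteria that failed."""

    equivalent: bool
    cutoff: float
    failed: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.equivalent:
            return f"equivalent (all bounds > {self.cutoff})"
        return f"not equivalent ({', '.join(self.failed)} <= {self.cutoff})"


@dataclass(frozen=True)
class F2Result:
    """Sample f2, E(f2), bootstrap distribution and interval bounds."""

    f2_sample: float
    f2_expected: float
    boot_values: np.ndarray
    boot_mean: float
    pi_lower: float
    pi_upper: float
    bca_lower: float
    bca_upper: float
    B: int
    alpha: float = DEFAULT_ALPHA
    cutoff: float = DEFAULT_CUTOFF
    equivalent: bool = False
    z0: float = 0.0
    accel: float = 0.0
    degenerate: bool = False
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be at least 1")
        if not self.pi_lower <= self.pi_upper + 1e-12:
            raise ValidationError("percentile bounds out of order")
        if not self.bca_lower <= self.bca_upper + 1e-12:
            raise ValidationError("BCa bounds out of order")

    def to_dict(self) -> dict:
        """JSON-safe summary (native Python scalars, no replicate vector)."""
        return {
            "f2_sample": float(self.f2_sample),
            "f2_expected": float(self.f2_expected),
            "boot_mean": float(self.boot_mean),
            "pi_lower": float(self.pi_lower),
            "pi_upper": float(self.pi_upper),
            "bca_lower": float(self.bca_lower),
            "bca_upper": float(self.bca_upper),
            "B": int(self.B),
            "alpha": float(self.alpha),
            "cutoff": float(self.cutoff),
            "equivalent": bool(self.equivalent),
            "z0": float(self.z0),
            "accel": float(self.accel),
            "degenerate": bool(self.degenerate),
            "warnings": list(self.warnings),
        }


def bca_levels(z0: float, accel: float, alpha: float) -> tuple[float, float]:
    """Quantile levels of the BCa interval for bias z0 and acceleration a.

    With ``z0 = a = 0`` this returns ``(alpha/2, 1 - alpha/2)`` exactly, so
    the BCa interval collapses to the percentile interval.
    """
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    lvl_lo = float(norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo))))
    lvl_hi = float(norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi))))
    return lvl_lo, lvl_hi


def _type1_quantile(sorted_vals: np.ndarray, level: float) -> float:
    """Empirical-CDF (type-1) quantile: value at 1-based index ceil(B*level)."""
    B = sorted_vals.size
    idx = int(np.ceil(B * level))
    idx = min(max(idx, 1), B)
    return float(sorted_vals[idx - 1])


def _f2_of_resample(test_units, ref_units, idx_t, idx_r) -> float:
    return f2_mean(test_units[idx_t].mean(axis=0), ref_units[idx_r].mean(axis=0))


def bootstrap_f2(
    test: DissolutionProfile,
    ref: DissolutionProfile,
    time_points: Sequence[float] = DEFAULT_TIME_POINTS,
    B: int = DEFAULT_B,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    cutoff: float = DEFAULT_CUTOFF,
    scale_variance_by_p: bool = True,
) -> F2Result:
    """Unit-resampling bootstrap of the similarity factor.

    Each of the ``B`` replicates draws, with a single ``numpy`` Generator
    seeded by ``seed``, first ``n_t`` test-unit indices then ``n_r``
    reference-unit indices (``rng.integers``, with replacement, sample sizes
    preserved) and computes f2 of the resampled mean profiles.  The
    percentile interval uses type-1 empirical quantiles at levels alpha/2 and
    1 - alpha/2; the BCa interval shifts those levels using the
    bias-correction constant z0 (normal quantile of the fraction of
    replicates below the sample f2, ties counting half) and the acceleration
    ``a`` from a delete-one jackknife over the combined unit list.  When
    every replicate is below or above the sample value z0 is undefined: the
    result is flagged ``degenerate`` and the BCa bounds fall back to the
    percentile bounds.
    """
    if test.n_units < 2 or ref.n_units < 2:
        raise ValidationError("bootstrap needs at least 2 units per product")
    if B < 1:
        raise ValidationError("B must be at least 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    warnings: list[str] = []
    if B < 100:
        warnings.append(f"B={B} replicates is small; intervals will be unstable")

    it = test.time_indices(time_points)
    ir = ref.time_indices(time_points)
    t_units = test.units[:, it]
    r_units = ref.units[:, ir]
    n_t, n_r = t_units.shape[0], r_units.shape[0]

    sample_f2 = f2_mean(t_units.mean(axis=0), r_units.mean(axis=0))
    ef2 = f2_expected(
        summarize(test, time_points),
        summarize(ref, time_points),
        scale_variance_by_p=scale_variance_by_p,
    )

    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        idx_t = rng.integers(0, n_t, size=n_t)
        idx_r = rng.integers(0, n_r, size=n_r)
        boot[b] = _f2_of_resample(t_units, r_units, idx_t, idx_r)
    srt = np.sort(boot)
    pi_lower = _type1_quantile(srt, alpha / 2)
    pi_upper = _type1_quantile(srt, 1 - alpha / 2)

    # Bias correction: fraction of replicates strictly below the sample f2,
    # replicates exactly equal counting half.
    below = np.count_nonzero(boot < sample_f2) + 0.5 * np.count_nonzero(
        boot == sample_f2
    )
    frac = float(below / B)
    degenerate = frac <= 0.0 or frac >= 1.0 or srt[0] == srt[-1]
    if degenerate:
        z0 = 0.0
        accel = 0.0
        bca_lower, bca_upper = pi_lower, pi_upper
        warnings.append("BCa degenerate: bias-correction undefined, using PI")
    else:
        z0 = float(norm.ppf(frac))
        # Delete-one jackknife over the combined unit list: drop one test
        # unit (reference intact) or one reference unit (test intact).
        theta = np.empty(n_t + n_r)
        all_t = np.arange(n_t)
        all_r = np.arange(n_r)
        for i in range(n_t):
            theta[i] = _f2_of_resample(t_units, r_units, np.delete(all_t, i), all_r)
        for j in range(n_r):
            theta[n_t + j] = _f2_of_resample(
                t_units, r_units, all_t, np.delete(all_r, j)
            )
        dev = theta.mean() - theta
        denom = 6.0 * np.sum(dev**2) ** 1.5
        accel = float(np.sum(dev**3) / denom) if denom > 0 else 0.0
        lvl_lo, lvl_hi = bca_levels(z0, accel, alpha)
        bca_lower = _type1_quantile(srt, lvl_lo)
        bca_upper = _type1_quantile(srt, lvl_hi)
        if bca_upper < bca_lower:
            bca_lower, bca_upper = bca_upper, bca_lower

    result = F2Result(
        f2_sample=sample_f2,
        f2_expected=ef2,
        boot_values=boot,
        boot_mean=float(boot.mean()),
        pi_lower=pi_lower,
        pi_upper=pi_upper,
        bca_lower=bca_lower,
        bca_upper=bca_upper,
        B=B,
        alpha=alpha,
        cutoff=cutoff,
        z0=z0,
        accel=accel,
        degenerate=degenerate,
        warnings=tuple(warnings),
    )
    decision = assess_equivalence(result, cutoff)
    return dataclasses.replace(result, equivalent=decision.equivalent)


def assess_equivalence(
    result: F2Result, cutoff: float = DEFAULT_CUTOFF
) -> EquivalenceDecision:
    """Apply the cutoff rule to an :class:`F2Result`.

    Equivalent iff the sample f2 AND the percentile lower bound AND the BCa
    lower bound all exceed ``cutoff`` strictly; the decision records which
    criteria failed.
    """
    failed = []
    if not result.f2_sample > cutoff:
        failed.append("f2_sample")
    if not result.pi_lower > cutoff:
        failed.append("pi_lower")
    if not result.bca_lower > cutoff:
        failed.append("bca_lower")
    return EquivalenceDecision(
        equivalent=not failed, cutoff=cutoff, failed=tuple(failed)
    )
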