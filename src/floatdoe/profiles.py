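"""Unit-level dissolution profiles and their per-time-point summaries.

A dissolution run measures cumulative drug release (%) from several tablet
units of one product at a common grid of sampling times.  The
:class:`DissolutionProfile` container holds the full unit-by-time matrix;
:func:`summarize` reduces it to the per-time-point means and unbiased sample
variances that the similarity-factor statistics consume.

Canonical file format is long CSV with columns ``product, unit, time_min,
release_pct``; a wide layout (one row per unit, one column per time) is
auto-detected on read.  Release is always a percentage on the 0-100 scale
(values up to 120 are tolerated for assay overshoot) and time is always in
minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, NotFoundError, ValidationError

__all__ = [
    "DissolutionProfile",
    "ProfileSummary",
    "read_profiles",
    "write_profiles",
    "summarize",
]

#: Maximum tolerated cumulative release (%); allows assay overshoot above 100.
RELEASE_CEILING = 120.0

LONG_COLUMNS = ("product", "unit", "time_min", "release_pct")


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative-release matrix for one product.

    Parameters
    ----------
    product_id:
        Label of the product (formulation code or reference name).
    times:
        Strictly increasing, positive sampling times in minutes.
    units:
        Matrix of cumulative release percentages with one row per tablet
        unit and one column per time point.
    unit_labels:
        Optional identifiers for the rows; defaults to ``1..n``.
    """

    product_id: str
    times: np.ndarray
    units: np.ndarray
    unit_labels: tuple = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        units = np.atleast_2d(np.asarray(self.units, dtype=float))
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("times must be a non-empty 1-D sequence")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            raise ValidationError("sampling times must be finite and positive")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if units.shape[0] < 1:
            raise ValidationError("profile needs at least one unit")
        if units.shape[1] != times.size:
            raise ValidationError(
                f"unit matrix has {units.shape[1]} columns but {times.size} times"
            )
        if np.any(~np.isfinite(units)):
            raise ValidationError("release matrix contains missing values")
        if units.min() < 0 or units.max() > RELEASE_CEILING:
            raise ValidationError(
                f"release values must lie in [0, {RELEASE_CEILING}]"
            )
        labels = tuple(self.unit_labels) or tuple(range(1, units.shape[0] + 1))
        if len(labels) != units.shape[0]:
            raise ValidationError("unit_labels length does not match unit count")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "unit_labels", labels)

    @property
    def n_units(self) -> int:
        return self.units.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    def time_indices(self, time_points: Sequence[float]) -> np.ndarray:
        """Column indices of ``time_points``; error if any is absent."""
        idx = []
        for t in time_points:
            hits = np.nonzero(np.isclose(self.times, t))[0]
            if hits.size == 0:
                raise ValidationError(
                    f"time {t} min is not a sampling time of {self.product_id}"
                )
            idx.append(int(hits[0]))
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (product, unit, time_min, release_pct)."""
        rows = []
        for label, row in zip(self.unit_labels, self.units):
            for t, q in zip(self.times, row):
                rows.append((self.product_id, label, t, q))
        return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


@dataclass(frozen=True)
class ProfileSummary:
    """Per-time-point means and variances of one product's profile.

    ``means`` and ``variances`` feed the similarity-factor statistics;
    ``variances`` are unbiased (divisor ``n - 1``).  ``single_unit`` is set
    when ``n == 1`` and variances were reported as zero by convention.
    """

    times: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    n: int
    single_unit: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        means = np.asarray(self.means, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        if not (times.size == means.size == variances.size):
            raise ValidationError("times, means and variances must align")
        if self.n < 1:
            raise ValidationError("n must be at least 1")
        if np.any(variances < 0):
            raise ValidationError("variances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "variances", variances)

    @property
    def P(self) -> int:
        """Number of time points entering the comparison."""
        return self.times.size


def summarize(
    profile: DissolutionProfile, time_points: Sequence[float] | None = None
) -> ProfileSummary:
    """Reduce a profile to per-time means and unbiased sample variances.

    ``time_points`` selects a subset of the sampling grid (default: all).
    With a single unit the variance is undefined; it is reported as zero and
    flagged via ``single_unit``.
    """
    if time_points is None:
        idx = np.arange(profile.n_times)
        times = profile.times
    else:
        idx = profile.time_indices(time_points)
        times = profile.times[idx]
    sub = profile.units[:, idx]
    means = sub.mean(axis=0)
    if profile.n_units == 1:
        return ProfileSummary(times, means, np.zeros_like(means), 1, single_unit=True)
    variances = sub.var(axis=0, ddof=1)
    return ProfileSummary(times, means, variances, profile.n_units)


def _profile_from_long(df: pd.DataFrame, product_id: str) -> DissolutionProfile:
    sel = df[df["product"].astype(str) == str(product_id)]
    if sel.empty:
        raise NotFoundError(f"product {product_id!r} not present in file")
    pivot = sel.pivot_table(
        index="unit", columns="time_min", values="release_pct", aggfunc="first"
    )
    if pivot.isna().any().any():
        raise ValidationError(
            f"ragged unit/time grid for product {product_id!r}: "
            "every unit must have a value at every time"
        )
    pivot = pivot.sort_index().sort_index(axis=1)
    return DissolutionProfile(
        product_id=str(product_id),
        times=pivot.columns.to_numpy(dtype=float),
        units=pivot.to_numpy(dtype=float),
        unit_labels=tuple(pivot.index),
    )


def _profile_from_wide(df: pd.DataFrame, product_id: str) -> DissolutionProfile:
    if "product" in df.columns:
        df = df[df["product"].astype(str) == str(product_id)]
        if df.empty:
            raise NotFoundError(f"product {product_id!r} not present in file")
    time_cols = []
    for c in df.columns:
        if c in ("product", "unit"):
            continue
        try:
            float(str(c).removeprefix("t_").removeprefix("time_"))
        except ValueError:
            raise FormatError(f"column {c!r} is neither metadata nor a time column")
        time_cols.append(c)
    if not time_cols:
        raise FormatError("wide-format file has no time columns")
    times = [float(str(c).removeprefix("t_").removeprefix("time_")) for c in time_cols]
    order = np.argsort(times)
    labels = tuple(df["unit"]) if "unit" in df.columns else ()
    return DissolutionProfile(
        product_id=str(product_id),
        times=np.asarray(times)[order],
        units=df[time_cols].to_numpy(dtype=float)[:, order],
        unit_labels=labels,
    )


def read_profiles(path, product_id: str) -> DissolutionProfile:
    """Read one product's profile from CSV (long canonical, wide detected).

    Long format requires the columns ``product, unit, time_min, release_pct``.
    Anything else is treated as wide (one row per unit) provided every
    non-metadata column name parses as a sampling time.
    """
    try:
        # round_trip parsing + %.17g writing make write/read bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if set(LONG_COLUMNS).issubset(df.columns):
        return _profile_from_long(df, product_id)
    if {"unit"}.issubset(df.columns) or all(
        c == "product" or _parses_as_time(c) for c in df.columns
    ):
        return _profile_from_wide(df, product_id)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    raise FormatError(f"{path}: missing required column(s) {missing}")


def _parses_as_time(name: object) -> bool:
    try:
        float(str(name).removeprefix("t_").removeprefix("time_"))
        return True
    except ValueError:
        return False


def write_profiles(path, *profiles: DissolutionProfile) -> None:
    """Write one or more profiles to a long-format CSV."""
    if not profiles:
        raise ValidationError("nothing to write")
    # %.17g guarantees the float64 matrix round-trips bit-exactly
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
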