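"""Factorial / response-surface designs, response models and optimization.

Two factors drive the dissolution profile of the floating tablet: the mass
of cetyl alcohol (factor A, mg — the low-density floating agent) and the
proportion of HPMC K15M (factor B, % of total tablet mass — the gel-forming
sustained-release polymer).  The responses R1/R2/R3 are the mean cumulative
release (%) at 60, 240 and 480 min.

This module builds the two standard designs (two-level full factorial for
screening; face-centered central composite for response-surface modelling),
fits linear or quadratic OLS models on coded (-1..+1) factor levels with the
usual ANOVA statistics, converts coded coefficients to the actual
(physical-unit) equation by exact algebraic substitution of the coding
transform, and uses the fitted equations to predict dissolution, predict the
similarity factor f2 against a reference profile, and solve for the minimal
HPMC level whose predicted f2 clears the similarity cutoff.  External
validation uses the root mean squared error of prediction,
RMSEP = sqrt((1/n) * sum (y_i - yhat_i)^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .equivalence import f2_mean
from .errors import ValidationError

__all__ = [
    "DoEDesign",
    "ResponseModel",
    "ValidationSet",
    "Prediction",
    "build_ffd_design",
    "build_ccf_design",
    "fit_response_model",
    "predict_dissolution",
    "predict_f2",
    "solve_hpmc_threshold",
    "rmsep",
]

LINEAR_TERMS = ("intercept", "A", "B")
QUADRATIC_TERMS = ("intercept", "A", "B", "AB", "A2", "B2")

DESIGN_COLUMNS = ("run", "A_mg", "B_pct", "a_coded", "b_coded", "replicate", "is_center")


@dataclass(frozen=True)
class DoEDesign:
    """A two-factor design: run table plus the factor ranges that code it.

    ``points`` columns: run (randomized order), A_mg, B_pct, a_coded,
    b_coded, replicate, is_center.  Coded levels satisfy
    ``a = (A - A_mid) / (A_halfwidth)`` so corners sit at +/-1 and centers
    at 0.
    """

    points: pd.DataFrame
    factor_ranges: tuple  # (A_low, A_high, B_low, B_high)

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValidationError(f"design table missing column(s) {missing}")
        a_lo, a_hi, b_lo, b_hi = self.factor_ranges
        if a_lo >= a_hi or b_lo >= b_hi:
            raise ValidationError("degenerate factor range (low >= high)")
        a, b = self.coded(self.points["A_mg"], self.points["B_pct"])
        if not (
            np.allclose(a, self.points["a_coded"])
            and np.allclose(b, self.points["b_coded"])
        ):
            raise ValidationError("coded levels inconsistent with factor ranges")

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded(self, A, B) -> tuple[np.ndarray, np.ndarray]:
        a_lo, a_hi, b_lo, b_hi = self.factor_ranges
        a = (np.asarray(A, dtype=float) - (a_lo + a_hi) / 2) / ((a_hi - a_lo) / 2)
        b = (np.asarray(B, dtype=float) - (b_lo + b_hi) / 2) / ((b_hi - b_lo) / 2)
        return a, b

    def actual(self, a, b) -> tuple[np.ndarray, np.ndarray]:
        a_lo, a_hi, b_lo, b_hi = self.factor_ranges
        A = (a_lo + a_hi) / 2 + np.asarray(a, dtype=float) * (a_hi - a_lo) / 2
        B = (b_lo + b_hi) / 2 + np.asarray(b, dtype=float) * (b_hi - b_lo) / 2
        return A, B


def _assemble(coded_pts, ranges, seed) -> DoEDesign:
    """coded_pts: list of (a, b, replicate, is_center)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(coded_pts)) + 1
    a_lo, a_hi, b_lo, b_hi = ranges
    rows = []
    for run, (a, b, rep, center) in zip(order, coded_pts):
        A = (a_lo + a_hi) / 2 + a * (a_hi - a_lo) / 2
        B = (b_lo + b_hi) / 2 + b * (b_hi - b_lo) / 2
        rows.append((int(run), A, B, float(a), float(b), rep, center))
    df = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    return DoEDesign(points=df, factor_ranges=tuple(ranges))


def build_ffd_design(
    ranges: Sequence[float],
    replicates: int = 2,
    center_points: int = 2,
    seed: int | None = None,
) -> DoEDesign:
    """Two-level full factorial screening design.

    ``4 * replicates`` corner runs at coded (+/-1, +/-1) plus
    ``center_points`` center runs at (0, 0); run order randomized under
    ``seed`` (stored for provenance, irrelevant to fitting).
    """
    if replicates < 0 or center_points < 0:
        raise ValidationError("counts must be non-negative")
    pts = [
        (a, b, rep, False)
        for rep in range(1, replicates + 1)
        for a in (-1.0, 1.0)
        for b in (-1.0, 1.0)
    ]
    pts += [(0.0, 0.0, rep, True) for rep in range(1, center_points + 1)]
    if not pts:
        raise ValidationError("design has no runs")
    return _assemble(pts, ranges, seed)


def build_ccf_design(
    ranges: Sequence[float],
    center_points: int = 2,
    seed: int | None = None,
) -> DoEDesign:
    """Face-centered central composite design.

    Four corners, four axial points on the cube faces (coded (+/-1, 0) and
    (0, +/-1)) and ``center_points`` centers: with two centers, the classic
    10-run layout.
    """
    if center_points < 0:
        raise ValidationError("center_points must be non-negative")
    pts = [(a, b, 1, False) for a in (-1.0, 1.0) for b in (-1.0, 1.0)]
    pts += [(s, 0.0, 1, False) for s in (-1.0, 1.0)]
    pts += [(0.0, s, 1, False) for s in (-1.0, 1.0)]
    pts += [(0.0, 0.0, rep, True) for rep in range(1, center_points + 1)]
    return _assemble(pts, ranges, seed)


@dataclass(frozen=True)
class ResponseModel:
    """Fitted response equation in coded and actual (physical) units.

    ``coded_coeffs`` and ``actual_coeffs`` map term names (intercept, A, B,
    and AB/A2/B2 for quadratic fits) to coefficients; the actual form is an
    exact algebraic re-expansion of the coded fit, so the two agree at every
    point.  ``r_squared``/``adj_r_squared`` are percentages; ``p_values``
    holds per-term t-test p-values plus the whole-model F-test under
    ``"model"`` (NaN, with ``degenerate=True``, when the response is
    constant).
    """

    response_id: str
    model_type: str
    coded_coeffs: dict
    actual_coeffs: dict
    p_values: dict
    r_squared: float
    adj_r_squared: float
    factor_ranges: tuple
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.model_type not in ("linear", "quadratic"):
            raise ValidationError("model_type must be 'linear' or 'quadratic'")
        if self.adj_r_squared > self.r_squared + 1e-9:
            raise ValidationError("adjusted R^2 cannot exceed R^2")

    def predict(self, A, B) -> np.ndarray:
        """Evaluate the actual equation at physical (A, B)."""
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        c = self.actual_coeffs
        out = c["intercept"] + c.get("A", 0.0) * A + c.get("B", 0.0) * B
        out = out + c.get("AB", 0.0) * A * B
        out = out + c.get("A2", 0.0) * A**2 + c.get("B2", 0.0) * B**2
        return out

    def predict_coded(self, a, b) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        c = self.coded_coeffs
        out = c["intercept"] + c.get("A", 0.0) * a + c.get("B", 0.0) * b
        out = out + c.get("AB", 0.0) * a * b
        out = out + c.get("A2", 0.0) * a**2 + c.get("B2", 0.0) * b**2
        return out

    def in_range(self, A: float, B: float) -> bool:
        a_lo, a_hi, b_lo, b_hi = self.factor_ranges
        return a_lo <= A <= a_hi and b_lo <= B <= b_hi

    def to_dict(self) -> dict:
        return {
            "response_id": self.response_id,
            "model_type": self.model_type,
            "coded_coeffs": dict(self.coded_coeffs),
            "actual_coeffs": dict(self.actual_coeffs),
            "p_values": dict(self.p_values),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "factor_ranges": list(self.factor_ranges),
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponseModel":
        return cls(
            response_id=d["response_id"],
            model_type=d["model_type"],
            coded_coeffs=dict(d["coded_coeffs"]),
            actual_coeffs=dict(d["actual_coeffs"]),
            p_values=dict(d.get("p_values", {})),
            r_squared=float(d["r_squared"]),
            adj_r_squared=float(d["adj_r_squared"]),
            factor_ranges=tuple(d["factor_ranges"]),
            degenerate=bool(d.get("degenerate", False)),
        )


def _design_matrix(a: np.ndarray, b: np.ndarray, model_type: str) -> tuple:
    if model_type == "linear":
        terms = LINEAR_TERMS
        cols = [np.ones_like(a), a, b]
    elif model_type == "quadratic":
        terms = QUADRATIC_TERMS
        cols = [np.ones_like(a), a, b, a * b, a**2, b**2]
    else:
        raise ValidationError("model_type must be 'linear' or 'quadratic'")
    return terms, np.column_stack(cols)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    """Name the first term whose column adds no new information."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    rank = 0
    for j in range(1, X.shape[1] + 1):
        new_rank = np.linalg.matrix_rank(X[:, :j])
        if new_rank == rank:
            raise ValidationError(
                f"design cannot estimate term {terms[j - 1]!r} "
                f"(column linearly dependent on earlier terms)"
            )
        rank = new_rank


def _coded_to_actual(coeffs: Mapping[str, float], ranges) -> dict:
    """Exact re-expansion of a coded polynomial in physical units.

    With a = (A - A0)/dA, b = (B - B0)/dB, substitute and collect terms.
    """
    a_lo, a_hi, b_lo, b_hi = ranges
    A0, dA = (a_lo + a_hi) / 2, (a_hi - a_lo) / 2
    B0, dB = (b_lo + b_hi) / 2, (b_hi - b_lo) / 2
    c = {t: float(coeffs.get(t, 0.0)) for t in QUADRATIC_TERMS}
    actual = {
        "intercept": (
            c["intercept"]
            - c["A"] * A0 / dA
            - c["B"] * B0 / dB
            + c["AB"] * A0 * B0 / (dA * dB)
            + c["A2"] * A0**2 / dA**2
            + c["B2"] * B0**2 / dB**2
        ),
        "A": c["A"] / dA - c["AB"] * B0 / (dA * dB) - 2 * c["A2"] * A0 / dA**2,
        "B": c["B"] / dB - c["AB"] * A0 / (dA * dB) - 2 * c["B2"] * B0 / dB**2,
        "AB": c["AB"] / (dA * dB),
        "A2": c["A2"] / dA**2,
        "B2": c["B2"] / dB**2,
    }
    if all(coeffs.get(t, 0.0) == 0.0 for t in ("AB", "A2", "B2")):
        actual = {t: actual[t] for t in LINEAR_TERMS}
    return actual


def fit_response_model(
    design: DoEDesign,
    response: Sequence[float],
    model_type: str = "linear",
    response_id: str = "R1",
) -> ResponseModel:
    """OLS fit of one response on coded factor levels.

    Reports the whole-model F-test p-value under ``p_values["model"]`` and
    per-term t-test p-values, R^2 / adjusted R^2 as percentages, and both the
    coded and (exactly re-expanded) actual coefficient sets.  A constant
    response yields zero slopes and a ``degenerate`` flag.
    """
    y = np.asarray(response, dtype=float)
    if y.size != design.n_runs:
        raise ValidationError(
            f"{y.size} responses supplied for {design.n_runs} design runs"
        )
    a = design.points["a_coded"].to_numpy(dtype=float)
    b = design.points["b_coded"].to_numpy(dtype=float)
    terms, X = _design_matrix(a, b, model_type)
    if y.size < X.shape[1] + 1:
        raise ValidationError(
            f"{model_type} model needs at least {X.shape[1] + 1} runs, got {y.size}"
        )
    _check_rank(X, terms)

    fit = sm.OLS(y, X).fit()
    coded = {t: float(v) for t, v in zip(terms, fit.params)}
    degenerate = bool(np.allclose(y, y[0]))
    p_values = {t: float(p) for t, p in zip(terms, fit.pvalues)}
    p_values["model"] = float(fit.f_pvalue) if not degenerate else float("nan")
    r2 = 100.0 if degenerate else float(fit.rsquared) * 100.0
    adj = 100.0 if degenerate else float(fit.rsquared_adj) * 100.0
    return ResponseModel(
        response_id=response_id,
        model_type=model_type,
        coded_coeffs=coded,
        actual_coeffs=_coded_to_actual(coded, design.factor_ranges),
        p_values=p_values,
        r_squared=r2,
        adj_r_squared=min(adj, r2),
        factor_ranges=design.factor_ranges,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class Prediction:
    """Predicted release at the three comparison times, with QA flags."""

    r1: float
    r2: float
    r3: float
    clipped: bool = False
    extrapolated: bool = False

    @property
    def values(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.r3])


def predict_dissolution(
    models: Sequence[ResponseModel], A: float, B: float
) -> Prediction:
    """Evaluate the three response equations at a candidate composition.

    Values are clipped to [0, 100] (flagged when clipping occurred); a
    composition outside the fitted factor ranges is still evaluated but
    flagged ``extrapolated``.
    """
    if len(models) != 3:
        raise ValidationError("need models for all three responses R1, R2, R3")
    raw = np.array([float(m.predict(A, B)) for m in models])
    clipped = np.clip(raw, 0.0, 100.0)
    return Prediction(
        *clipped,
        clipped=bool(np.any(raw != clipped)),
        extrapolated=not all(m.in_range(A, B) for m in models),
    )


def predict_f2(
    models: Sequence[ResponseModel],
    A: float,
    B: float,
    ref_means: Sequence[float],
) -> float:
    """Similarity factor of the model-predicted profile against a reference.

    ``ref_means`` are the reference mean releases at the same three time
    points the response models were fitted for.
    """
    ref = np.asarray(ref_means, dtype=float)
    if ref.size != 3:
        raise ValidationError("ref_means must give the reference at 3 time points")
    return f2_mean(predict_dissolution(models, A, B).values, ref)


def solve_hpmc_threshold(
    models: Sequence[ResponseModel],
    A: float,
    ref_means: Sequence[float],
    cutoff: float = 50.0,
    b_range: tuple | None = None,
    tol: float = 1e-4,
) -> float:
    """HPMC level B (%) at which the predicted f2 crosses the cutoff.

    Bisection on ``predicted_f2(B) - cutoff`` at fixed cetyl alcohol mass A,
    over ``b_range`` (default: the fitted B range), to ``tol`` percentage
    points.  Raises when the predicted f2 does not change side within the
    bracket, reporting the end values.
    """
    if b_range is None:
        b_range = (models[0].factor_ranges[2], models[0].factor_ranges[3])
    lo, hi = float(b_range[0]), float(b_range[1])
    if lo >= hi:
        raise ValidationError("empty B bracket")

    def g(bb: float) -> float:
        return predict_f2(models, A, bb, ref_means) - cutoff

    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValidationError(
            f"predicted f2 does not cross cutoff {cutoff} on B in "
            f"[{lo}, {hi}]: f2({lo}) = {g_lo + cutoff:.4f}, "
            f"f2({hi}) = {g_hi + cutoff:.4f}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        if g_mid == 0.0:
            return mid
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ValidationSet:
    """Observed vs predicted release for external model validation."""

    observations: np.ndarray
    predictions: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        pred = np.asarray(self.predictions, dtype=float)
        if obs.size != pred.size:
            raise ValidationError("observations and predictions must align")
        if obs.size < 1:
            raise ValidationError("validation set is empty")
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "predictions", pred)

    @property
    def n(self) -> int:
        return self.observations.size


def rmsep(validation: ValidationSet) -> float:
    """Root mean squared error of prediction: sqrt(mean((y - yhat)^2))."""
    return float(
        np.sqrt(np.mean((validation.observations - validation.predictions) ** 2))
    )
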