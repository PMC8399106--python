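"""Release-kinetics model fitting and mechanism classification.

Four classical models for the mean cumulative release curve Q(t) (%):

* zero order:        Q = k * t                    (constant release rate)
* first order:       ln(100 - Q) = ln(100) - k*t  (rate proportional to drug remaining)
* Higuchi:           Q = k * sqrt(t)              (matrix diffusion)
* Korsmeyer-Peppas:  Q/100 = k * t^n              (power law, fitted on log10-log10
                      scale, restricted to the early-release window Q <= 60 %)

Each model is linear on its own transformed scale and is fitted by least
squares there; R^2 is reported on that fitting scale.  The Korsmeyer-Peppas
exponent n classifies the transport mechanism for this tablet geometry:
n < 0.45 Fickian diffusion, 0.45 <= n <= 0.89 anomalous transport,
n > 0.89 case-II (relaxation-controlled) transport.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "KineticModelFit",
    "fit_release_models",
    "classify_mechanism",
    "select_best_model",
    "MODEL_NAMES",
    "KP_WINDOW_MAX_Q",
]

MODEL_NAMES = ("zero_order", "first_order", "higuchi", "korsmeyer_peppas")

#: Upper release bound (%) of the power-law fitting window.
KP_WINDOW_MAX_Q = 60.0

_N_PARAMS = {"zero_order": 1, "first_order": 1, "higuchi": 1, "korsmeyer_peppas": 2}


@dataclass(frozen=True)
class KineticModelFit:
    """One model's fitted coefficients and goodness of fit.

    ``r_squared`` is computed on the model's own fitting (transformed) scale
    against the centered total sum of squares, so it can be negative for a
    badly misspecified model but never exceeds 1.
    """

    model: str
    params: dict
    r_squared: float
    n_points: int
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValidationError(f"unknown model {self.model!r}")
        if self.success:
            if self.r_squared > 1 + 1e-12:
                raise ValidationError("R^2 cannot exceed 1")
            if self.n_points < 2:
                raise ValidationError("a fit needs at least 2 points")
            if self.model == "korsmeyer_peppas" and len(self.params) != 2:
                raise ValidationError("power-law fit must have exactly k and n")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _failed(model: str, message: str) -> KineticModelFit:
    return KineticModelFit(
        model=model, params={}, r_squared=np.nan, n_points=0,
        success=False, message=message,
    )


def fit_release_models(
    times: Sequence[float], mean_release: Sequence[float]
) -> list[KineticModelFit]:
    """Fit all four release models to a mean cumulative release curve.

    ``times`` in minutes, ``mean_release`` in percent.  Points violating a
    model's transform (Q >= 100 for first order, Q = 0 or Q > 60 for the
    power law) are excluded from that model only; a model left with fewer
    than 2 usable points is returned with ``success=False``.  Fits are
    invariant to input ordering.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(mean_release, dtype=float)
    if t.size != q.size:
        raise ValidationError("times and release must have equal length")
    order = np.argsort(t)
    t, q = t[order], q[order]
    if np.any(t <= 0):
        raise ValidationError("times must be positive")
    if np.count_nonzero(q > 0) < 3:
        raise ValidationError("need at least 3 positive-release points")

    fits: list[KineticModelFit] = []

    # Zero order: Q = k t, through the origin.
    k0 = float(np.sum(q * t) / np.sum(t * t))
    fits.append(
        KineticModelFit("zero_order", {"k": k0}, _r2(q, k0 * t), t.size)
    )

    # First order: ln(100 - Q) = ln(100) - k t, intercept pinned at ln(100).
    ok = q < 100.0
    msg = "" if ok.all() else f"{np.count_nonzero(~ok)} point(s) with Q >= 100 excluded"
    if np.count_nonzero(ok) < 2:
        fits.append(_failed("first_order", "fewer than 2 points with Q < 100"))
    else:
        y = np.log(100.0 - q[ok])
        tt = t[ok]
        k1 = float(np.sum(tt * (np.log(100.0) - y)) / np.sum(tt * tt))
        fits.append(
            KineticModelFit(
                "first_order", {"k": k1}, _r2(y, np.log(100.0) - k1 * tt),
                int(ok.sum()), message=msg,
            )
        )

    # Higuchi: Q = k sqrt(t), through the origin.
    rt = np.sqrt(t)
    kh = float(np.sum(q * rt) / np.sum(rt * rt))
    fits.append(
        KineticModelFit("higuchi", {"k": kh}, _r2(q, kh * rt), t.size)
    )

    # Korsmeyer-Peppas: log10(Q/100) = log10(k) + n log10(t), early window only.
    win = (q > 0) & (q <= KP_WINDOW_MAX_Q)
    if np.count_nonzero(win) < 2:
        fits.append(
            _failed("korsmeyer_peppas", "fewer than 2 points with 0 < Q <= 60%")
        )
    else:
        x = np.log10(t[win])
        y = np.log10(q[win] / 100.0)
        slope, intercept = np.polyfit(x, y, 1)
        fits.append(
            KineticModelFit(
                "korsmeyer_peppas",
                {"k": float(10.0**intercept), "n": float(slope)},
                _r2(y, intercept + slope * x),
                int(win.sum()),
            )
        )
    return fits


def classify_mechanism(n_exp: float) -> str:
    """Transport mechanism implied by the power-law exponent.

    Boundaries: n < 0.45 -> "Fickian diffusion"; 0.45 <= n <= 0.89 ->
    "anomalous transport"; n > 0.89 -> "case-II transport".  The 0.45
    boundary is assigned to the upper class.
    """
    if not n_exp > 0:
        raise ValidationError("release exponent must be positive")
    if n_exp < 0.45:
        return "Fickian diffusion"
    if n_exp <= 0.89:
        return "anomalous transport"
    return "case-II transport"


def select_best_model(fits: Sequence[KineticModelFit]) -> KineticModelFit:
    """Highest-R^2 successful fit; exact ties go to the simpler model."""
    usable = [f for f in fits if f.success]
    if not usable:
        raise ValidationError("no successful fits to select from")
    return max(usable, key=lambda f: (f.r_squared, -f.n_params))
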