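"""Continuous age-dependent lower reference limits by spline quantile regression.

The lower reference limit (LRL) of eGFR at a given age is the 2.5th
percentile of eGFR among reference individuals of that age.  It is
estimated here as a smooth function of age: a quantile-regression fit of
eGFR on a cubic B-spline basis in age with a single interior knot at
40 years — the age from which kidney function physiologically starts to
decline — and boundary knots at the ends of the training age range
(30 and 85 by default).  Ages are floored to whole years before fitting,
i.e. the regression operates on annual age groups.  No further covariates
(in particular not sex) enter the model.

The fit minimises the pinball (check) loss

    L(β) = Σ_i ρ_τ(y_i − x_iᵀβ),   ρ_τ(u) = u · (τ − 1[u < 0]),

which is solved exactly as a linear program (two non-negative residual
splits) with the HiGHS solver.  At the optimum the fraction of training
points strictly below the fitted curve lies within ``k/n`` of τ, where k is
the basis dimension (sub-gradient optimality of quantile regression).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.optimize import linprog

__all__ = [
    "ReferenceLimitModel",
    "floor_age",
    "spline_basis",
    "pinball_loss",
    "fit_pinball",
    "fit_quantile_curve",
    "predict_lrl",
]

SPLINE_DEGREE = 3


def floor_age(age):
    """Round age down to whole years (annual age groups)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = np.floor(age)
    return int(out) if out.ndim == 0 else out.astype(int)


def _knot_vector(interior_knots, boundary_knots) -> np.ndarray:
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    if not lo < hi:
        raise ValueError("boundary knots must satisfy lo < hi")
    interior = np.sort(np.asarray(interior_knots, dtype=float))
    if interior.size and (interior[0] <= lo or interior[-1] >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary")
    return np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), interior, [hi] * (SPLINE_DEGREE + 1)]
    )


def spline_basis(
    ages,
    interior_knots=(40.0,),
    boundary_knots=(30.0, 85.0),
    clamp: bool = False,
) -> np.ndarray:
    """Cubic B-spline design matrix in age.

    Returns the full partition-of-unity basis: ``3 + 1 + len(interior_knots)``
    non-negative columns that sum to one at every age within the boundary
    knots and reduce to a single unit entry at either boundary.  The basis
    spans constants, so no separate intercept column is needed.

    Ages outside the boundary are an error unless ``clamp=True``, in which
    case they are pinned to the nearest boundary (constant extrapolation of
    any fit, used at prediction time).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    t = _knot_vector(interior_knots, boundary_knots)
    lo, hi = t[0], t[-1]
    if clamp:
        ages = np.clip(ages, lo, hi)
    elif np.any((ages < lo) | (ages > hi)):
        raise ValueError(
            f"age outside the spline boundary [{lo}, {hi}]; "
            "use clamp=True to pin to the boundary"
        )
    return BSpline.design_matrix(ages, t, SPLINE_DEGREE, extrapolate=False).toarray()


def pinball_loss(y, yhat, tau: float) -> float:
    """Total check loss Σ ρ_τ(y − ŷ)."""
    u = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_pinball(X: np.ndarray, y: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """Exact pinball-loss regression of ``y`` on design ``X`` via LP.

    min over (β, u⁺ ≥ 0, u⁻ ≥ 0) of τ·1ᵀu⁺ + (1−τ)·1ᵀu⁻
    subject to Xβ + u⁺ − u⁻ = y.

    Returns (β, loss).  The optimum may sit on a flat LP face (quantile
    regression on discrete data can have multiple optimal coefficient
    vectors); the deterministic HiGHS solver path fixes the reported one,
    and the loss is unique.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    eye = sparse.identity(n, format="csc")
    a_eq = sparse.hstack([sparse.csc_matrix(X), eye, -eye], format="csc")
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed to converge: {res.message}")
    beta = res.x[:p]
    return beta, pinball_loss(y, X @ beta, tau)


@dataclass
class ReferenceLimitModel:
    """Fitted age-dependent quantile curve for one eGFR formula."""

    formula: str
    tau: float
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    coefficients: np.ndarray
    training_n: int
    training_loss: float
    model_id: str = "model"
    extras: dict = field(default_factory=dict)

    def predict(self, ages) -> np.ndarray:
        """LRL(age) at full precision; ages outside the boundary clamped."""
        basis = spline_basis(ages, self.interior_knots, self.boundary_knots,
                             clamp=True)
        return basis @ self.coefficients

    def to_json(self) -> str:
        payload = {
            "formula": self.formula,
            "tau": self.tau,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "coefficients": [float(c) for c in self.coefficients],
            "training_n": self.training_n,
            "training_loss": self.training_loss,
            "model_id": self.model_id,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceLimitModel":
        d = json.loads(text)
        return cls(
            formula=d["formula"],
            tau=d["tau"],
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            training_n=d["training_n"],
            training_loss=d["training_loss"],
            model_id=d.get("model_id", "model"),
        )


def fit_quantile_curve(
    ages,
    egfr,
    tau: float = 0.025,
    interior_knots=(40.0,),
    boundary_knots=None,
    formula: str = "fas",
    model_id: str = "model",
) -> ReferenceLimitModel:
    """Fit the age-dependent τ-quantile curve of eGFR.

    Ages are floored to whole years; the curve is a cubic B-spline with the
    stated interior knot(s).  ``boundary_knots`` default to the min/max of
    the floored training ages.
    """
    ages = floor_age(np.asarray(ages, dtype=float))
    egfr = np.asarray(egfr, dtype=float)
    if ages.shape != egfr.shape:
        raise ValueError("ages and egfr must have the same length")
    if not 0.0 < tau <= 0.5:
        raise ValueError("tau must be in (0, 0.5] for a lower limit")
    if np.unique(ages).size < 2:
        raise ValueError("degenerate design: all training ages identical")
    if boundary_knots is None:
        boundary_knots = (float(ages.min()), float(ages.max()))
    basis = spline_basis(ages, interior_knots, boundary_knots)
    beta, loss = fit_pinball(basis, egfr, tau)
    return ReferenceLimitModel(
        formula=formula,
        tau=tau,
        interior_knots=tuple(float(k) for k in interior_knots),
        boundary_knots=(float(boundary_knots[0]), float(boundary_knots[1])),
        coefficients=beta,
        training_n=len(egfr),
        training_loss=loss,
        model_id=model_id,
    )


def predict_lrl(model: ReferenceLimitModel, ages=None) -> pd.DataFrame:
    """Tabulate LRL(age) at integer ages (default 30–85).

    Returns columns ``age`` (int years), ``lrl`` (full precision,
    ml/min/1.73 m²) and ``lrl_rounded`` (nearest-integer display value).
    """
    if ages is None:
        ages = np.arange(30, 86)
    ages = np.atleast_1d(np.asarray(ages, dtype=int))
    lrl = model.predict(ages.astype(float))
    return pd.DataFrame(
        {
            "age": ages,
            "lrl": lrl,
            "lrl_rounded": np.rint(lrl).astype(int),
            "formula": model.formula,
            "model_id": model.model_id,
        }
    )
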