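"""Four-parameter log-logistic dose-response fitting and correlation.

The response (colony area %, colony intensity %, or an external readout
such as dye absorbance) is modelled as a function of compound
concentration ``x > 0`` by the LL.4 curve

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with lower limit ``c``, upper limit ``d``, steepness ``b`` and inflection
``e``.  For an inhibition curve (``b > 0``, ``d > c``) the response falls
from ``d`` at low dose to ``c`` at high dose, and ``e`` is the IC50: at
``x = e`` the response is exactly ``(c + d) / 2``.

Fitting is ordinary nonlinear least squares on the raw replicate points
(not the per-dose means), on log-dose internally for numerical stability;
standard errors come from the estimated parameter covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError

__all__ = [
    "DoseResponseModel",
    "FitResult",
    "CorrelationResult",
    "ll4",
    "fit_ll4",
    "ic50",
    "pearson",
]


@dataclass(frozen=True)
class DoseResponseModel:
    """LL.4 parameters: steepness ``b``, lower limit ``c``, upper limit
    ``d`` (response units) and inflection ``e`` (concentration units, the
    IC50)."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if not self.e > 0:
            raise ValidationError("the IC50 parameter e must be positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class FitResult:
    model: DoseResponseModel
    standard_errors: dict[str, float]
    residual_sd: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    p_value: float


def ll4(x, model: DoseResponseModel | tuple):
    """Evaluate the four-parameter log-logistic curve at dose(s) ``x > 0``."""
    b, c, d, e = model.as_tuple() if isinstance(model, DoseResponseModel) else model
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("doses must be strictly positive")
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - math.log(e))))


def _ll4_logx(logx, b, c, d, loge):
    return c + (d - c) / (1.0 + np.exp(b * (logx - loge)))


def fit_ll4(
    doses,
    responses,
    anchor_upper: float | None = None,
) -> FitResult:
    """Fit the LL.4 model to raw replicate (dose, response) points.

    Requires at least 5 points over at least 4 distinct positive doses.
    Zero-dose (control) points are rejected — ``ln x`` is undefined there;
    if control wells should pin the upper plateau, pass their mean response
    as ``anchor_upper`` to fix ``d``.

    Initialisation: ``d0`` = max response, ``c0`` = min response, ``e0`` =
    dose nearest the half-range crossing, ``b0 = 1``; ``e`` is bounded to
    ``[min dose / 10, max dose * 10]``.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValidationError("doses and responses must be equal-length 1-D vectors")
    if np.any(doses <= 0):
        raise ValidationError(
            "doses must be strictly positive (exclude controls or use anchor_upper)"
        )
    distinct = np.unique(doses)
    if len(doses) < 5 or distinct.size < 4:
        raise ValidationError(
            "need >= 5 points over >= 4 distinct doses to fit 4 parameters"
        )
    if np.ptp(responses) == 0:
        raise FitError("responses show no dose effect (zero spread)")

    logx = np.log(doses)
    d0 = anchor_upper if anchor_upper is not None else float(responses.max())
    c0 = float(responses.min())
    half = (d0 + c0) / 2.0
    per_dose = [responses[doses == x].mean() for x in distinct]
    e0 = float(distinct[int(np.argmin(np.abs(np.array(per_dose) - half)))])
    loge_lo = math.log(distinct.min() / 10.0)
    loge_hi = math.log(distinct.max() * 10.0)
    loge0 = min(max(math.log(e0), loge_lo), loge_hi)

    if anchor_upper is None:
        fun = _ll4_logx
        p0 = [1.0, c0, d0, loge0]
        bounds = ([-50, -np.inf, -np.inf, loge_lo], [50, np.inf, np.inf, loge_hi])
        names = ["b", "c", "d", "e"]
    else:
        def fun(lx, b, c, loge):  # d fixed at the control anchor
            return _ll4_logx(lx, b, c, d0, loge)

        p0 = [1.0, c0, loge0]
        bounds = ([-50, -np.inf, loge_lo], [50, np.inf, loge_hi])
        names = ["b", "c", "e"]

    try:
        popt, pcov = optimize.curve_fit(
            fun, logx, responses, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"LL.4 fit did not converge: {exc}") from exc

    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    params = dict(zip(names, popt))
    errs = dict(zip(names, perr))
    # back-transform e = exp(log e); delta-method SE
    loge, se_loge = params.pop("e"), errs.pop("e")
    e = math.exp(loge)
    errs["e"] = e * se_loge if np.isfinite(se_loge) else float("nan")
    if anchor_upper is not None:
        params["d"] = d0
        errs["d"] = 0.0
    model = DoseResponseModel(b=params["b"], c=params["c"], d=params["d"], e=e)
    resid = responses - ll4(doses, model)
    dof = max(len(doses) - len(popt), 1)
    return FitResult(
        model=model,
        standard_errors=errs,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=len(doses),
    )


def ic50(fit: FitResult) -> tuple[float, float]:
    """The IC50 (parameter ``e``) and its standard error from a converged fit."""
    if not fit.converged:
        raise FitError("cannot report an IC50 from an unconverged fit")
    return fit.model.e, fit.standard_errors["e"]


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need two equal-length vectors of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation is undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(r=float(r), slope=float(reg.slope),
                             intercept=float(reg.intercept), p_value=float(p))
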