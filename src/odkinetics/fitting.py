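"""Least-squares estimation of kinetic-model parameters and fit statistics.

Models are fitted to (tau, Y) series by bounded trust-region nonlinear
least squares.  Goodness of fit is summarised by four statistics:

R^2    1 - SS_res/SS_tot (coefficient of determination)
chi2   reduced chi-squared, SS_res / (N - n)
RMSE   sqrt(SS_res / N)
CRV    coefficient of residual variation, 100 * sqrt(chi2) / mean(Y_exp),
       in percent.  A fit with CRV < 20% is considered usable for
       prediction; larger values flag the model as descriptive only.

``N`` is the number of fitted points of the (usually replicate-averaged)
series, including the tau = 0 anchor for responses with a known initial
value (0 for WL/SG/WL_T, 1 for CR); ``n`` is the number of free
parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    FAMILIES,
    BurgersParams,
    KelvinVoigtParams,
    ModelParams,
    PelegParams,
)

__all__ = [
    "FitError",
    "InsufficientDataError",
    "FitResult",
    "goodness_of_fit",
    "r2_ratio_form",
    "initial_guess",
    "fit_model",
    "fit_report",
    "CRV_PREDICTION_LIMIT",
    "DEFAULT_RESPONSE_FAMILIES",
    "REPORT_COLUMNS",
]

log = logging.getLogger(__name__)

#: CRV (in percent) below which a fitted model is deemed usable for prediction.
CRV_PREDICTION_LIMIT = 20.0

_EPS = 1e-9  # lower bound for strictly positive parameters


class FitError(RuntimeError):
    """The optimizer failed to converge after the allowed restarts."""


class InsufficientDataError(ValueError):
    """Fewer points than free parameters (plus one) were supplied."""


def goodness_of_fit(predicted, experimental, n_params: int) -> dict:
    """The four fit statistics for a predicted-vs-experimental pair.

    Returns a dict with keys ``r2, chi2, rmse, crv`` (crv in percent).
    Raises if N <= n_params or the experimental mean is zero (CRV is a
    relative measure and has no meaning then).
    """
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("predicted and experimental series differ in length")
    n_pts = pred.size
    if n_pts <= n_params:
        raise InsufficientDataError(
            f"need more points ({n_pts}) than free parameters ({n_params})")
    resid = pred - exp
    ss_res = float(resid @ resid)
    chi2 = ss_res / (n_pts - n_params)
    rmse = math.sqrt(ss_res / n_pts)
    ybar = float(exp.mean())
    if ybar == 0:
        raise ValueError("CRV undefined: experimental series has zero mean")
    crv = 100.0 * math.sqrt(chi2) / ybar
    ss_tot = float(np.sum((exp - ybar) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0 else float("nan")
    return {"r2": r2, "chi2": chi2, "rmse": rmse, "crv": crv}


def r2_ratio_form(predicted, experimental) -> float:
    """Diagnostic R^2 variant: sum(pred - mean_pred)^2 / sum(exp - mean_pred)^2.

    Kept for comparison with reports that print this ratio; the standard
    1 - SS_res/SS_tot form is what :func:`goodness_of_fit` returns.
    """
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    pbar = pred.mean()
    denom = float(np.sum((exp - pbar) ** 2))
    if denom == 0:
        raise ValueError("ratio-form R^2 undefined: zero denominator")
    return float(np.sum((pred - pbar) ** 2) / denom)


@dataclass
class FitResult:
    """A converged model fit with its statistics.

    ``residuals`` are predicted - experimental, in series order
    (ascending tau).  ``usable_for_prediction`` applies the CRV < 20%
    rule.
    """

    family: str
    params: ModelParams
    n_points: int
    n_free: int
    tau: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    r2: float
    chi2: float
    rmse: float
    crv: float
    cost: float

    @property
    def usable_for_prediction(self) -> bool:
        return self.crv < CRV_PREDICTION_LIMIT


def _sorted_series(tau, y):
    tau = np.asarray(tau, dtype=float)
    y = np.asarray(y, dtype=float)
    if tau.shape != y.shape or tau.ndim != 1:
        raise ValueError("tau and y must be 1-d arrays of equal length")
    order = np.argsort(tau, kind="stable")
    return tau[order], y[order]


def initial_guess(tau, y, family: str, *, y0: float = 0.0, direction: int = 1) -> dict:
    """Closed-form parameter seeds for the optimizer.

    Peleg: the model linearizes exactly as tau/|Y - Y0| = k1 + k2*tau, so
    an ordinary regression of tau/|Y - Y0| on tau yields the seed (and
    recovers noise-free data to machine precision).

    Kelvin-Voigt: the plateau is seeded as 1.05 * max|Y| and the time
    constant from the earliest informative point,
    B = -tau_1 / ln(1 - Y_1/A_seed).  Later points sit close to the
    (deliberately inflated) plateau, where the log transform is dominated
    by the inflation rather than the true decay, so the first point gives
    the most faithful seed.

    Burgers: the Kelvin-Voigt seed plus C from the slope of the last two
    points in excess of the seeded saturation curve, floored at 0.
    """
    tau, y = _sorted_series(tau, y)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate series: response is constant")
    if family == "peleg":
        z = direction * (y - y0)
        mask = (tau > 0) & (z > 1e-12)
        if mask.sum() < 2:
            raise ValueError("too few informative points for a Peleg seed")
        slope, intercept = np.polyfit(tau[mask], tau[mask] / z[mask], 1)
        return {"k1": max(float(intercept), _EPS), "k2": max(float(slope), _EPS)}
    if family in ("kelvin_voigt", "burgers"):
        imax = int(np.argmax(np.abs(y)))
        a0 = 1.05 * float(y[imax])
        if a0 == 0:
            raise ValueError("degenerate series: all-zero response")
        u = 1.0 - y / a0
        mask = (tau > 0) & (u > 1e-12)
        if not mask.any():
            b0 = float(tau[-1]) if tau[-1] > 0 else 1.0
        else:
            t1 = float(tau[mask][0])
            u1 = float(u[mask][0])
            b0 = max(-t1 / math.log(u1), 1e-6)
        if family == "kelvin_voigt":
            return {"a": a0, "b": b0}
        dt = tau[-1] - tau[-2]
        if dt <= 0:
            raise ValueError("need two distinct trailing times for a Burgers seed")
        sat_slope = a0 * (math.exp(-tau[-2] / b0) - math.exp(-tau[-1] / b0)) / dt
        c0 = max(0.0, float((y[-1] - y[-2]) / dt) - sat_slope)
        return {"a": a0, "b": b0, "c": c0}
    raise ValueError(f"unknown model family {family!r}; valid keys: {FAMILIES}")


def _model_setup(family, tau, y, y0, direction, fit_y0, nonneg_c, x0):
    """Build (predict, x0, lb, ub, make_params, n_free) for the optimizer."""
    if family == "peleg":
        if direction is None:
            direction = 1 if y[-1] >= y[0] else -1
        if fit_y0:
            y0_seed = float(y[0]) if y0 is None else float(y0)
            seed = initial_guess(tau, y, "peleg", y0=y0_seed, direction=direction)
            x_init = np.array([y0_seed, seed["k1"], seed["k2"]])
            lb = np.array([-np.inf, _EPS, _EPS])
            ub = np.full(3, np.inf)

            def predict(x):
                return x[0] + direction * tau / (x[1] + x[2] * tau)

            def make(x):
                return PelegParams(k1=float(x[1]), k2=float(x[2]), y0=float(x[0]), direction=direction)

            return predict, x_init, lb, ub, make, 3
        if y0 is None:
            if tau[0] == 0:
                y0 = float(y[0])
            else:
                raise ValueError(
                    "Peleg fit with fixed Y0 needs y0= or a tau=0 point in the series")
        y0 = float(y0)
        seed = initial_guess(tau, y, "peleg", y0=y0, direction=direction)
        x_init = np.array([seed["k1"], seed["k2"]])
        lb = np.array([_EPS, _EPS])
        ub = np.full(2, np.inf)

        def predict(x):
            return y0 + direction * tau / (x[0] + x[1] * tau)

        def make(x):
            return PelegParams(k1=float(x[0]), k2=float(x[1]), y0=y0, direction=direction)

        return predict, x_init, lb, ub, make, 2

    if family == "kelvin_voigt":
        seed = initial_guess(tau, y, "kelvin_voigt")
        x_init = np.array([seed["a"], seed["b"]])
        lb = np.array([-np.inf, _EPS])
        ub = np.full(2, np.inf)

        def predict(x):
            return x[0] * (1.0 - np.exp(-tau / x[1]))

        def make(x):
            return KelvinVoigtParams(a=float(x[0]), b=float(x[1]))

        return predict, x_init, lb, ub, make, 2

    if family == "burgers":
        seed = initial_guess(tau, y, "burgers")
        x_init = np.array([seed["a"], seed["b"], seed["c"]])
        lb = np.array([-np.inf, _EPS, 0.0 if nonneg_c else -np.inf])
        ub = np.full(3, np.inf)

        def predict(x):
            return x[0] * (1.0 - np.exp(-tau / x[1])) + x[2] * tau

        def make(x):
            return BurgersParams(a=float(x[0]), b=float(x[1]), c=float(x[2]))

        return predict, x_init, lb, ub, make, 3

    raise ValueError(f"unknown model family {family!r}; valid keys: {FAMILIES}")


def fit_model(
    tau,
    y,
    family: str,
    *,
    y0: Optional[float] = None,
    direction: Optional[int] = None,
    fit_y0: bool = False,
    nonneg_c: bool = True,
    x0: Optional[Sequence[float]] = None,
    max_restarts: int = 3,
    restart_seed: int = 0,
) -> FitResult:
    """Fit one model family to a (tau, y) series.

    Parameters
    ----------
    family
        "peleg", "kelvin_voigt" or "burgers".
    y0, direction
        Peleg only.  By default Y0 is *fixed* (not fitted): to the given
        ``y0``, or to the observed value at tau = 0.  ``direction`` is
        inferred from the series trend when not given.  ``fit_y0=True``
        frees Y0 as a third parameter.
    nonneg_c
        Constrain the Burgers constant-rate term C >= 0 (the default;
        pass False for diagnostic unconstrained fits).
    x0
        Optional explicit parameter seed overriding :func:`initial_guess`.
    max_restarts, restart_seed
        Up to ``max_restarts`` additional optimizer starts from seeds
        jittered by a fixed-seed RNG when the first start does not reach
        a near-zero cost; the best cost wins.  The procedure is
        deterministic for identical inputs and options, and invariant to
        the row order of the series (it is sorted internally).

    Raises
    ------
    InsufficientDataError
        if there are fewer distinct time points than free parameters + 1.
    FitError
        if no start converges.
    """
    tau, y = _sorted_series(tau, y)
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; valid keys: {FAMILIES}")
    n_free_expected = {"peleg": 3 if fit_y0 else 2, "kelvin_voigt": 2, "burgers": 3}[family]
    n_distinct = np.unique(tau).size
    if n_distinct < n_free_expected + 1:
        raise InsufficientDataError(
            f"{family} needs >= {n_free_expected + 1} distinct time points, "
            f"got {n_distinct}")
    predict, x_init, lb, ub, make, n_free = _model_setup(
        family, tau, y, y0, direction, fit_y0, nonneg_c, x0)
    if x0 is not None:
        x_init = np.asarray(x0, dtype=float)
        if x_init.shape != lb.shape:
            raise ValueError(f"x0 must have {lb.size} entries for family {family!r}")

    def run(x_start):
        x_start = np.minimum(np.maximum(x_start, lb + 1e-12), ub)
        return least_squares(
            lambda x: predict(x) - y, x_start, bounds=(lb, ub), method="trf",
            x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=5000)

    best = run(x_init)
    # restart from jittered seeds unless the first start already found an
    # essentially perfect fit (cost here is 0.5 * SSR)
    if best.cost > 1e-10 and max_restarts > 0:
        rng = np.random.default_rng(restart_seed)
        for _ in range(max_restarts):
            jitter = np.exp(rng.normal(0.0, 0.3, size=x_init.size))
            xj = np.where(x_init != 0, x_init * jitter,
                          np.abs(rng.normal(0.0, 1e-3, size=x_init.size)))
            res = run(xj)
            if res.cost < best.cost:
                best = res
    if not best.success:
        raise FitError(
            f"{family} fit did not converge (status {best.status}, "
            f"cost {best.cost:.3e}, nfev {best.nfev}): {best.message}")

    params = make(best.x)
    pred = predict(best.x)
    gof = goodness_of_fit(pred, y, n_free)
    return FitResult(
        family=family, params=params, n_points=int(tau.size), n_free=n_free,
        tau=tau, observed=y, predicted=pred, residuals=pred - y,
        r2=gof["r2"], chi2=gof["chi2"], rmse=gof["rmse"], crv=gof["crv"],
        cost=float(best.cost),
    )


#: Families fitted to each response when none are requested explicitly.
#: WC and CR follow the Peleg form with a fixed initial value; the
#: saturation models (which start at 0 by construction) additionally
#: describe WL, SG and WL_T.
DEFAULT_RESPONSE_FAMILIES = {
    "WC": ("peleg",),
    "WL": ("peleg", "kelvin_voigt", "burgers"),
    "SG": ("peleg", "kelvin_voigt", "burgers"),
    "WLT": ("peleg", "kelvin_voigt", "burgers"),
    "CR": ("peleg",),
}

REPORT_COLUMNS = [
    "solute", "response", "family", "k1", "k2", "A", "B", "C",
    "N", "n", "R2", "chi2", "RMSE", "CRV_pct", "usable", "fit_ok",
]


def _report_row(solute, response, family, fr: Optional[FitResult], error=None) -> dict:
    row = {c: np.nan for c in REPORT_COLUMNS}
    row.update(solute=solute, response=response, family=family, fit_ok=error is None)
    if fr is None:
        row["usable"] = False
        log.warning("fit failed for %s/%s/%s: %s", solute, response, family, error)
        return row
    p = fr.params
    if isinstance(p, PelegParams):
        row.update(k1=p.k1, k2=p.k2)
    elif isinstance(p, KelvinVoigtParams):
        row.update(A=p.a, B=p.b)
    elif isinstance(p, BurgersParams):
        row.update(A=p.a, B=p.b, C=p.c)
    row.update(N=fr.n_points, n=fr.n_free, R2=fr.r2, chi2=fr.chi2,
               RMSE=fr.rmse, CRV_pct=fr.crv, usable=fr.usable_for_prediction)
    return row


def fit_report(
    kinetics: pd.DataFrame,
    responses: Optional[Sequence[str]] = None,
    families: Optional[Sequence[str]] = None,
    *,
    nonneg_c: bool = True,
) -> pd.DataFrame:
    """Fit the requested families to every solute/response series.

    Parameters
    ----------
    kinetics
        A replicate-averaged kinetics table (columns ``solute, tau_min``
        plus response columns WC/SG/WL/WLT/CR as available).
    responses
        Responses to fit; defaults to all present in the table.
    families
        Families to fit for every response; defaults per response to
        :data:`DEFAULT_RESPONSE_FAMILIES`.

    Returns one row per (solute, response, family) with the fitted
    parameters, N, n and the four statistics; fits that raise are kept
    as rows with ``fit_ok=False`` rather than propagating.  The CR
    series is anchored at CR=1 for tau=0 (where the measured ratio is
    0/0) before fitting.
    """
    if responses is None:
        responses = [c for c in ("WC", "SG", "WL", "WLT", "CR") if c in kinetics.columns]
    rows = []
    for solute, sub in kinetics.groupby("solute", sort=True):
        sub = sub.sort_values("tau_min")
        tau_all = sub["tau_min"].to_numpy(float)
        for response in responses:
            y_all = sub[response].to_numpy(float)
            if response == "CR":
                y_all = np.where((tau_all == 0) & ~np.isfinite(y_all), 1.0, y_all)
            keep = np.isfinite(y_all)
            tau, yv = tau_all[keep], y_all[keep]
            fams = families if families is not None else DEFAULT_RESPONSE_FAMILIES[response]
            for family in fams:
                kwargs = {}
                if family == "peleg":
                    if response == "WC":
                        kwargs = {"direction": -1}  # y0 from the tau=0 point
                    elif response == "CR":
                        kwargs = {"y0": 1.0, "direction": -1}
                    else:
                        kwargs = {"y0": 0.0, "direction": 1}
                try:
                    fr = fit_model(tau, yv, family, nonneg_c=nonneg_c, **kwargs)
                    rows.append(_report_row(solute, response, family, fr))
                except Exception as exc:  # noqa: BLE001 - flagged row, not a crash
                    rows.append(_report_row(solute, response, family, None, error=exc))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
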