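"""Least-squares estimation of the scaling parameters.

The allometric pair (a, b) is fitted by additive least squares on the
original gram scale — minimizing sum (w_i - a*l_i**b)^2 — with starting
values from an ordinary log-log regression. The isometric ratio c has
the closed form of a regression through the origin. Shoot-aggregated
variants replace the per-leaf prediction by the additive shoot sum.

Standard errors come from the Gauss-Newton covariance approximation
sigma^2 * (J'J)^-1 at the optimum, with sigma^2 = rss/(n - p). A
``log_scale`` switch fits ln w on ln l instead (multiplicative error
model) for sensitivity analysis; fitted values and residuals are always
reported on the gram scale so fit summaries stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DataError, DegenerateDataError
from .models import AllometricParams, IsometricParams, LeafRecord, ShootRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "loglog_initializer",
    "fit_allometric_leaf",
    "fit_isometric_leaf",
    "fit_allometric_shoot",
    "fit_isometric_shoot",
]

# Convergence tolerances fixed for cross-platform reproducibility.
_FTOL = 1e-12
_XTOL = 1e-12
_GTOL = 1e-10
_MAX_NFEV = 500


@dataclass(frozen=True)
class FitResult:
    """Fit summary for either scaling model.

    ``x`` holds the per-observation predictor (leaf length for leaf
    fits, total shoot length for shoot fits); ``observed`` the measured
    weights. ``se_fit`` is the residual standard error
    sqrt(rss/(n - p)) in grams.
    """

    params: Union[AllometricParams, IsometricParams]
    se: Dict[str, float]
    rss: float
    n: int
    fitted: np.ndarray
    residuals: np.ndarray
    se_fit: float
    x: np.ndarray
    observed: np.ndarray
    n_excluded: int = 0
    model: str = ""

    @property
    def n_params(self) -> int:
        return 2 if isinstance(self.params, AllometricParams) else 1

    def to_dict(self) -> dict:
        p = self.params
        if isinstance(p, AllometricParams):
            params = {"a": p.a, "b": p.b}
        else:
            params = {"c": p.c}
        return {
            "model": self.model,
            "params": params,
            "se": dict(self.se),
            "rss": self.rss,
            "n": self.n,
            "se_fit": self.se_fit,
            "n_excluded": self.n_excluded,
        }


def _leaf_arrays(records: Sequence[LeafRecord], min_n: int):
    """Extract (lengths, weights) from records that carry a weight."""
    usable = [r for r in records if r.weight_g is not None]
    n_excluded = len(records) - len(usable)
    if n_excluded:
        logger.info("excluded %d record(s) without weight from fitting", n_excluded)
    if len(usable) < min_n:
        raise DataError(
            f"need at least {min_n} records with weights, got {len(usable)}"
        )
    l = np.array([r.length_mm for r in usable], dtype=float)
    w = np.array([r.weight_g for r in usable], dtype=float)
    return l, w, n_excluded


def loglog_initializer(records: Sequence[LeafRecord]):
    """OLS of ln w on ln l; returns (exp(intercept), slope).

    Records with nonpositive weight cannot enter the log regression and
    are dropped with a logged warning. Used as the starting point of the
    nonlinear fit; on noiseless power-law data it is already exact.
    """
    l, w, _ = _leaf_arrays(records, 3)
    keep = w > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning(
            "log-log initializer dropped %d record(s) with nonpositive weight",
            n_dropped,
        )
    l, w = l[keep], w[keep]
    if len(l) < 3:
        raise DataError(
            f"need at least 3 records with positive weights for the "
            f"log-log initializer, got {len(l)}"
        )
    X = np.column_stack([np.ones_like(l), np.log(l)])
    coef, *_ = np.linalg.lstsq(X, np.log(w), rcond=None)
    return float(np.exp(coef[0])), float(coef[1])


def _gauss_newton_se(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    sigma2 = rss / (n - p)
    jtj = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(jtj)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def _fit_power_law(
    x: np.ndarray,
    w: np.ndarray,
    predict,
    jac_fn,
    init: tuple,
    n_excluded: int,
    model: str,
) -> FitResult:
    """Shared NLS core: minimize sum (w - predict(a, b))^2 over a, b > 0."""
    if np.ptp(x) == 0:
        raise DegenerateDataError("all lengths equal: (a, b) not identifiable")

    def resid(theta):
        return predict(theta[0], theta[1]) - w

    def jac(theta):
        return jac_fn(theta[0], theta[1])

    a0, b0 = init
    a0 = max(a0, 1e-300)
    b0 = max(b0, 1e-8)
    res = optimize.least_squares(
        resid,
        x0=[a0, b0],
        jac=jac,
        bounds=([1e-300, 1e-8], [np.inf, np.inf]),
        method="trf",
        ftol=_FTOL,
        xtol=_XTOL,
        gtol=_GTOL,
        max_nfev=_MAX_NFEV,
    )
    if res.status <= 0:
        raise ConvergenceError(
            f"allometric fit did not converge: {res.message}",
            last_params=tuple(res.x),
            diagnostics={"nfev": res.nfev, "cost": res.cost, "status": res.status},
        )
    a_hat, b_hat = res.x
    n = len(w)
    fitted = predict(a_hat, b_hat)
    residuals = w - fitted
    rss = float(np.sum(residuals**2))
    se = _gauss_newton_se(jac_fn(a_hat, b_hat), rss, n, 2)
    return FitResult(
        params=AllometricParams(a=float(a_hat), b=float(b_hat)),
        se={"a": float(se[0]), "b": float(se[1])},
        rss=rss,
        n=n,
        fitted=fitted,
        residuals=residuals,
        se_fit=float(np.sqrt(rss / (n - 2))),
        x=x,
        observed=w,
        n_excluded=n_excluded,
        model=model,
    )


def _fit_loglog(l, w, x, n_excluded, model) -> FitResult:
    """Multiplicative-error variant: OLS on ln w ~ ln l, reported on the gram scale."""
    keep = w > 0
    if np.sum(keep) < 3:
        raise DataError("log-scale fitting needs >= 3 positive weights")
    ll, lw = np.log(l[keep]), np.log(w[keep])
    X = np.column_stack([np.ones_like(ll), ll])
    coef, _, _, _ = np.linalg.lstsq(X, lw, rcond=None)
    log_resid = lw - X @ coef
    sigma2 = float(np.sum(log_resid**2)) / (len(ll) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    a_hat, b_hat = float(np.exp(coef[0])), float(coef[1])
    n = len(w)
    fitted = a_hat * l**b_hat
    residuals = w - fitted
    rss = float(np.sum(residuals**2))
    return FitResult(
        params=AllometricParams(a=a_hat, b=b_hat),
        # delta method for se(a) = a * se(ln a); se(b) is the OLS slope se
        se={"a": a_hat * float(np.sqrt(cov[0, 0])), "b": float(np.sqrt(cov[1, 1]))},
        rss=rss,
        n=n,
        fitted=fitted,
        residuals=residuals,
        se_fit=float(np.sqrt(rss / (n - 2))),
        x=x,
        observed=w,
        n_excluded=n_excluded,
        model=model + "_loglog",
    )


def fit_allometric_leaf(
    records: Sequence[LeafRecord], *, log_scale: bool = False
) -> FitResult:
    """Fit w = a*l**b to individual leaves by nonlinear least squares."""
    l, w, n_excluded = _leaf_arrays(records, 3)
    if log_scale:
        return _fit_loglog(l, w, l, n_excluded, "allometric_leaf")
    init = loglog_initializer([r for r in records if r.weight_g is not None])
    return _fit_power_law(
        l,
        w,
        predict=lambda a, b: a * l**b,
        jac_fn=lambda a, b: np.column_stack([l**b, a * l**b * np.log(l)]),
        init=init,
        n_excluded=n_excluded,
        model="allometric_leaf",
    )


def fit_isometric_leaf(records: Sequence[LeafRecord]) -> FitResult:
    """Closed-form regression through the origin: c = sum(w*l)/sum(l^2)."""
    l, w, n_excluded = _leaf_arrays(records, 2)
    return _fit_isometric(l, w, l, n_excluded, "isometric_leaf")


def _fit_isometric(x, w, pred_x, n_excluded, model) -> FitResult:
    denom = float(np.sum(pred_x**2))
    if denom == 0:
        raise DegenerateDataError("all lengths zero: c not identifiable")
    c_hat = float(np.sum(w * pred_x)) / denom
    if not c_hat > 0:
        raise DataError(f"fitted weight-to-length ratio is nonpositive ({c_hat:g})")
    n = len(w)
    fitted = c_hat * pred_x
    residuals = w - fitted
    rss = float(np.sum(residuals**2))
    sigma2 = rss / (n - 1)
    return FitResult(
        params=IsometricParams(c=c_hat),
        se={"c": float(np.sqrt(sigma2 / denom))},
        rss=rss,
        n=n,
        fitted=fitted,
        residuals=residuals,
        se_fit=float(np.sqrt(sigma2)),
        x=x,
        observed=w,
        n_excluded=n_excluded,
        model=model,
    )


def _shoot_arrays(shoots: Sequence[ShootRecord], min_n: int):
    if len(shoots) < min_n:
        raise DataError(f"need at least {min_n} shoots, got {len(shoots)}")
    lengths = [np.asarray(s.leaf_lengths_mm, dtype=float) for s in shoots]
    w = np.array([s.shoot_weight_g for s in shoots], dtype=float)
    totals = np.array([float(np.sum(lk)) for lk in lengths])
    return lengths, totals, w


def fit_allometric_shoot(
    shoots: Sequence[ShootRecord], *, log_scale: bool = False
) -> FitResult:
    """Fit w_s = sum_k a*l_k**b to shoot aggregates.

    Initialization treats each shoot's total length as a pseudo-leaf,
    which is exact when every shoot holds a single leaf and a serviceable
    starting point otherwise.
    """
    lengths, totals, w = _shoot_arrays(shoots, 3)
    if log_scale:
        return _fit_loglog(totals, w, totals, 0, "allometric_shoot")
    pseudo = [
        LeafRecord(site=s.site, shoot_id=s.shoot_id, leaf_rank=1,
                   length_mm=t, weight_g=float(wi))
        for s, t, wi in zip(shoots, totals, w)
    ]
    init = loglog_initializer(pseudo)
    # ragged per-shoot lengths: precompute flat array + shoot index for speed
    flat = np.concatenate(lengths)
    idx = np.repeat(np.arange(len(shoots)), [len(lk) for lk in lengths])
    n_shoots = len(shoots)

    def predict(a, b):
        return np.bincount(idx, weights=a * flat**b, minlength=n_shoots)

    def jac_fn(a, b):
        da = np.bincount(idx, weights=flat**b, minlength=n_shoots)
        db = np.bincount(idx, weights=a * flat**b * np.log(flat), minlength=n_shoots)
        return np.column_stack([da, db])

    return _fit_power_law(
        totals, w, predict=predict, jac_fn=jac_fn, init=init,
        n_excluded=0, model="allometric_shoot",
    )


def fit_isometric_shoot(shoots: Sequence[ShootRecord]) -> FitResult:
    """Closed form c = sum(w_s*L_s)/sum(L_s^2) with L_s the shoot total length."""
    _, totals, w = _shoot_arrays(shoots, 2)
    return _fit_isometric(totals, w, totals, 0, "isometric_shoot")
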