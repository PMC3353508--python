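"""Model-selection battery for the two scaling models.

A single dataset is fitted with both models and judged on:

* fit quality: R^2 on raw weights and Lin's concordance correlation
  coefficient (CCC) between observed and predicted weights;
* information criteria: Gaussian-likelihood AIC, with the difference
  AIC_isometric - AIC_allometric graded by the conventional rule —
  a gap > 4 is positive evidence, > 10 strong evidence;
* lack of fit: the pure-error F test on replicate length groups;
* a paired test of observed vs predicted mean weight;
* residual diagnostics: normality and a Breusch-Pagan check of
  homoscedasticity.

Raw p-values are reported without multiplicity adjustment; the battery
is a diagnostic panel, not a family of confirmatory tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import DataError, PerfectFitError
from .fitting import (
    FitResult,
    fit_allometric_leaf,
    fit_allometric_shoot,
    fit_isometric_leaf,
    fit_isometric_shoot,
)
from .models import LeafRecord, ShootRecord
from .thresholds import (
    BiasProfile,
    ThresholdDiagnostics,
    bias_profile,
    compute_threshold_diagnostics,
)

logger = logging.getLogger(__name__)

__all__ = [
    "r_squared",
    "concordance_correlation",
    "aic",
    "LackOfFitResult",
    "lack_of_fit_test",
    "mean_difference_test",
    "residual_diagnostics",
    "ModelComparisonReport",
    "compare_models",
]


def _pair(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if o.size < 2:
        raise DataError("need at least 2 points")
    return o, p


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on raw weights.

    Can be negative for a fit worse than the observed mean; this is the
    convention for nonlinear fits where no intercept guarantees R^2 >= 0.
    """
    o, p = _pair(observed, predicted)
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("observed values have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def concordance_correlation(observed, predicted, *, bias_corrected: bool = False) -> float:
    """Lin's concordance correlation coefficient rho_hat.

    rho_hat = 2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with moment
    (n-denominator) variances and covariance, penalizing both scatter
    about the 45-degree line and location/scale shift. Never exceeds
    |Pearson r|. ``bias_corrected=True`` switches to n-1 denominators.
    """
    o, p = _pair(observed, predicted)
    ddof = 1 if bias_corrected else 0
    s_o = float(np.var(o, ddof=ddof))
    s_p = float(np.var(p, ddof=ddof))
    if s_o == 0 and s_p == 0:
        raise DataError("both vectors are constant; CCC undefined")
    n = o.size
    s_op = float(np.sum((o - o.mean()) * (p - p.mean()))) / (n - ddof)
    return 2.0 * s_op / (s_o + s_p + (o.mean() - p.mean()) ** 2)


def aic(fit: FitResult, n_params: Optional[int] = None) -> float:
    """Gaussian-likelihood AIC: n*ln(rss/n) + 2K with K = n_params + 1.

    The residual variance counts as a fitted parameter, so K is one more
    than the number of mean-function parameters. Absolute magnitudes
    depend on this convention (and on constants dropped from the
    likelihood); only within-dataset differences are meaningful.
    """
    k = (fit.n_params if n_params is None else n_params) + 1
    if fit.n <= k:
        raise DataError(f"AIC needs n > K; n={fit.n}, K={k}")
    if fit.rss == 0:
        raise PerfectFitError("rss = 0: AIC diverges to -inf (perfect fit)")
    return fit.n * float(np.log(fit.rss / fit.n)) + 2.0 * k


@dataclass(frozen=True)
class LackOfFitResult:
    """Pure-error F test. ``applicable`` is False when the design has no
    replicate length groups, in which case pure error is undefined and
    the test simply does not apply (distinct from a failure)."""

    applicable: bool
    f: Optional[float] = None
    df_lack_of_fit: Optional[int] = None
    df_pure_error: Optional[int] = None
    p_value: Optional[float] = None
    n_groups: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "F": self.f,
            "df_lack_of_fit": self.df_lack_of_fit,
            "df_pure_error": self.df_pure_error,
            "p_value": self.p_value,
            "n_groups": self.n_groups,
        }


def lack_of_fit_test(
    lengths,
    observed,
    predicted,
    n_params: int,
    *,
    resolution_mm: float = 1.0,
) -> LackOfFitResult:
    """Partition rss into pure error and lack of fit over replicate groups.

    Measured lengths are effectively discrete, so observations are
    grouped by length rounded to ``resolution_mm``. With m groups, n
    observations and p mean-function parameters:

        SS_pe  = sum over groups of within-group squared deviations,
        SS_lof = rss - SS_pe (floored at 0),
        F      = (SS_lof/(m - p)) / (SS_pe/(n - m))  ~  F(m-p, n-m).
    """
    l = np.asarray(lengths, dtype=float)
    o, p = _pair(observed, predicted)
    if l.shape != o.shape:
        raise ValueError("lengths must match observed/predicted in length")
    if resolution_mm <= 0:
        raise ValueError("resolution_mm must be > 0")
    groups = np.round(l / resolution_mm).astype(np.int64)
    _, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    m = counts.size
    n = o.size
    if not np.any(counts >= 2):
        return LackOfFitResult(applicable=False, n_groups=m)
    if m <= n_params or n <= m:
        return LackOfFitResult(applicable=False, n_groups=m)
    group_sums = np.bincount(inverse, weights=o)
    group_means = group_sums / counts
    ss_pe = float(np.sum((o - group_means[inverse]) ** 2))
    rss = float(np.sum((o - p) ** 2))
    ss_lof = max(rss - ss_pe, 0.0)
    df_lof = m - n_params
    df_pe = n - m
    if ss_pe == 0:
        return LackOfFitResult(applicable=False, n_groups=m)
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return LackOfFitResult(
        applicable=True,
        f=float(f),
        df_lack_of_fit=df_lof,
        df_pure_error=df_pe,
        p_value=float(stats.f.sf(f, df_lof, df_pe)),
        n_groups=m,
    )


def mean_difference_test(observed, predicted) -> float:
    """Two-sided paired t-test of observed vs predicted means; returns p.

    Degenerate cases: all differences zero -> p = 1 (no evidence of a
    mean shift); zero variance with a nonzero mean difference -> p = 0
    with a warning (the shift is certain under the paired model).
    """
    o, p = _pair(observed, predicted)
    d = o - p
    if np.all(d == 0):
        return 1.0
    if np.std(d) == 0:
        warnings.warn(
            "constant nonzero difference between observed and predicted; "
            "reporting p = 0",
            stacklevel=2,
        )
        return 0.0
    return float(stats.ttest_rel(o, p).pvalue)


def residual_diagnostics(fit: FitResult) -> dict:
    """Normality and homoscedasticity p-values for a fit's residuals.

    Normality: Shapiro-Wilk for n <= 5000, D'Agostino K^2 above that.
    Homoscedasticity: Breusch-Pagan of squared residuals on fitted
    values. Returns {'applicable': False} for n < 8 or constant
    residuals, where neither test is meaningful.
    """
    r = np.asarray(fit.residuals, dtype=float)
    if r.size < 8 or np.ptp(r) == 0:
        return {"applicable": False, "normality_p": None, "homoscedasticity_p": None}
    if r.size <= 5000:
        normality_p = float(stats.shapiro(r).pvalue)
    else:
        normality_p = float(stats.normaltest(r).pvalue)
    exog = np.column_stack([np.ones(r.size), np.asarray(fit.fitted, dtype=float)])
    _, bp_p, _, _ = het_breuschpagan(r, exog)
    return {
        "applicable": True,
        "normality_p": normality_p,
        "homoscedasticity_p": float(bp_p),
    }


def _verdict(delta_aic: float) -> str:
    if abs(delta_aic) > 10:
        return "strong"
    if abs(delta_aic) > 4:
        return "positive"
    return "indistinguishable"


@dataclass(frozen=True)
class ModelComparisonReport:
    """Side-by-side summary of both fits and all selection statistics."""

    allometric: FitResult
    isometric: FitResult
    allometric_stats: dict
    isometric_stats: dict
    delta_aic: float
    selection_verdict: str
    preferred_model: Optional[str]
    thresholds: Optional[ThresholdDiagnostics]
    bias: Optional[BiasProfile]
    notes: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "allometric": {**self.allometric.to_dict(), "stats": self.allometric_stats},
            "isometric": {**self.isometric.to_dict(), "stats": self.isometric_stats},
            "delta_aic": self.delta_aic,
            "selection_verdict": self.selection_verdict,
            "preferred_model": self.preferred_model,
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
            "bias": self.bias.to_dict() if self.bias else None,
            "notes": list(self.notes),
        }

    def to_table(self) -> str:
        """Plain-text summary table (one row per model)."""
        rows = []
        header = (
            f"{'model':<18}{'params':<36}{'R2':>8}{'CCC':>8}"
            f"{'se_fit':>10}{'AIC':>12}"
        )
        rows.append(header)
        rows.append("-" * len(header))
        for fit, st in (
            (self.allometric, self.allometric_stats),
            (self.isometric, self.isometric_stats),
        ):
            d = fit.to_dict()
            pstr = ", ".join(
                f"{k}={v:.6g}±{d['se'][k]:.2g}" for k, v in d["params"].items()
            )
            aic_v = st.get("aic")
            rows.append(
                f"{d['model']:<18}{pstr:<36}{st['r_squared']:>8.3f}"
                f"{st['ccc']:>8.3f}{fit.se_fit:>10.4g}"
                f"{(f'{aic_v:.1f}' if aic_v is not None else 'n/a'):>12}"
            )
        rows.append("")
        rows.append(
            f"delta AIC (iso - allo) = {self.delta_aic:.1f}  "
            f"[{self.selection_verdict}; prefers {self.preferred_model}]"
        )
        if self.thresholds is not None:
            t = self.thresholds
            rows.append(
                f"l* = {t.l_star:.1f} mm  ({t.pct_below:.0f}% below / "
                f"{t.pct_above:.0f}% above)   theta_max = {t.theta_max:.2g} g"
            )
        if self.bias is not None:
            rows.append(
                f"ratio proxy underestimates {100*self.bias.fraction_underestimated:.0f}% "
                f"of observed weights; mean |relative error| = "
                f"{100*self.bias.mean_abs_relative_error:.0f}%"
            )
        return "\n".join(rows)


def _stats_block(fit: FitResult, *, lof_resolution_mm: float) -> dict:
    block: dict = {
        "r_squared": r_squared(fit.observed, fit.fitted),
        "ccc": concordance_correlation(fit.observed, fit.fitted),
    }
    try:
        block["aic"] = aic(fit)
    except PerfectFitError:
        block["aic"] = None
        block["perfect_fit"] = True
    block["lack_of_fit"] = lack_of_fit_test(
        fit.x, fit.observed, fit.fitted, fit.n_params,
        resolution_mm=lof_resolution_mm,
    ).to_dict()
    block["mean_test_p"] = mean_difference_test(fit.observed, fit.fitted)
    block.update(
        {
            k: v
            for k, v in residual_diagnostics(fit).items()
            if k in ("normality_p", "homoscedasticity_p")
        }
    )
    return block


def compare_models(
    data: Sequence[Union[LeafRecord, ShootRecord]],
    *,
    lof_resolution_mm: float = 1.0,
    log_scale: bool = False,
) -> ModelComparisonReport:
    """Fit both models to leaf or shoot data and run the full battery.

    Deterministic given the data and configuration. The threshold
    diagnostics use the fitted (a, b, c); the bias profile of the ratio
    proxy is computed per leaf (leaf data) or per shoot total (shoot
    data, without the threshold restriction, which is a per-leaf notion).
    """
    if len(data) == 0:
        raise DataError("empty dataset")
    is_shoot = isinstance(data[0], ShootRecord)
    notes = []
    try:
        if is_shoot:
            allo = fit_allometric_shoot(data, log_scale=log_scale)
            iso = fit_isometric_shoot(data)
            lengths = np.concatenate(
                [np.asarray(s.leaf_lengths_mm, float) for s in data]
            )
        else:
            allo = fit_allometric_leaf(data, log_scale=log_scale)
            iso = fit_isometric_leaf(data)
            lengths = np.array(
                [r.length_mm for r in data if r.weight_g is not None]
            )
    except Exception as exc:
        raise type(exc)(f"fitting stage: {exc}") from exc

    try:
        allo_stats = _stats_block(allo, lof_resolution_mm=lof_resolution_mm)
        iso_stats = _stats_block(iso, lof_resolution_mm=lof_resolution_mm)
    except Exception as exc:
        raise type(exc)(f"statistics stage: {exc}") from exc

    if allo_stats.get("aic") is None or iso_stats.get("aic") is None:
        delta = float("nan")
        verdict = "indistinguishable"
        preferred = None
        notes.append("AIC unavailable for at least one model (perfect fit)")
    else:
        delta = iso_stats["aic"] - allo_stats["aic"]
        verdict = _verdict(delta)
        if verdict == "indistinguishable":
            preferred = None
        else:
            preferred = "allometric" if delta > 0 else "isometric"

    b_hat = allo.params.b
    thresholds = None
    if b_hat != 1:
        try:
            thresholds = compute_threshold_diagnostics(
                allo.params, iso.params, lengths
            )
        except Exception as exc:  # pragma: no cover - defensive
            notes.append(f"threshold stage failed: {exc}")
    else:
        notes.append("fitted b = 1 exactly; threshold diagnostics undefined")

    bias = None
    try:
        if is_shoot:
            # shoot totals stand in for leaf records; threshold restriction
            # is skipped because l* is a per-leaf quantity
            pseudo = [
                LeafRecord(site=s.site, shoot_id=s.shoot_id, leaf_rank=1,
                           length_mm=t, weight_g=w)
                for s, t, w in zip(data, allo.x, allo.observed)
            ]
            bias = bias_profile(pseudo, iso.params, allo.params)
            bias = BiasProfile(
                lengths_mm=bias.lengths_mm,
                theta_g=bias.theta_g,
                relative_error=bias.relative_error,
                fraction_underestimated=bias.fraction_underestimated,
                fraction_underestimated_beyond_threshold=None,
                mean_abs_relative_error=bias.mean_abs_relative_error,
                n_excluded=bias.n_excluded,
            )
        else:
            bias = bias_profile(
                [r for r in data if r.weight_g is not None],
                iso.params,
                allo.params,
            )
    except DataError as exc:
        notes.append(f"bias stage skipped: {exc}")

    return ModelComparisonReport(
        allometric=allo,
        isometric=iso,
        allometric_stats=allo_stats,
        isometric_stats=iso_stats,
        delta_aic=delta,
        selection_verdict=verdict,
        preferred_model=preferred,
        thresholds=thresholds,
        bias=bias,
        notes=tuple(notes),
    )
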