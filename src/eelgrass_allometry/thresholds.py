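"""Closed-form deviation diagnostics between the two scaling models.

The deviation function

    theta(l) = c*l - a*l**b = l*(c - a*l**(b-1))      (b != 1; 0 at b = 1)

measures how far the constant weight-to-length ratio strays from the
power law at leaf length l. For b != 1 the line c*l crosses the curve
a*l**b at the origin and at one positive threshold length

    l_star = (c/a)**(1/(b-1)),

and |theta| peaks inside (0, l_star) at

    l_theta_max = l_star * b**(-1/(b-1)),
    theta_max   = (c/(a*b))**(b/(b-1)) * a * |b - 1|.

For b > 1 the ratio proxy over-predicts below l_star and under-predicts
(underestimates biomass) beyond it; for b < 1 the signs reverse. When a
large share of measured lengths exceeds l_star, converting length to
biomass through the ratio c is systematically biased — the quantities
here put numbers on that bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError, UndefinedThresholdError
from .models import AllometricParams, IsometricParams, LeafRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdDiagnostics",
    "BiasProfile",
    "deviation",
    "threshold_length",
    "max_deviation_length",
    "max_abs_deviation",
    "threshold_partition",
    "compute_threshold_diagnostics",
    "bias_profile",
]


def _check_abc(a: float, b: float, c: float) -> None:
    if not (a > 0 and c > 0):
        raise ValueError("a and c must be > 0")
    if not b > 0:
        raise ValueError("b must be > 0")


def deviation(a: float, b: float, c: float, l):
    """theta(l) = c*l - a*l**b; identically 0 when b = 1 regardless of a, c."""
    _check_abc(a, b, c)
    arr = np.asarray(l, dtype=float)
    if np.any(arr < 0):
        raise ValueError("leaf length must be >= 0")
    if b == 1:
        out = np.zeros_like(arr)
    else:
        out = c * arr - a * arr**b
    return float(out) if np.isscalar(l) else out


def threshold_length(a: float, b: float, c: float) -> float:
    """Positive crossing point l_star = (c/a)**(1/(b-1)) of the two models."""
    _check_abc(a, b, c)
    if b == 1:
        raise UndefinedThresholdError(
            "b = 1: the models are proportional and never cross at a "
            "positive finite length"
        )
    return (c / a) ** (1.0 / (b - 1.0))


def max_deviation_length(a: float, b: float, c: float) -> float:
    """Length l_theta_max < l_star where |theta| is maximal on (0, l_star)."""
    _check_abc(a, b, c)
    if b == 1:
        raise UndefinedThresholdError("b = 1: theta vanishes identically")
    return (c / (a * b)) ** (1.0 / (b - 1.0))


def max_abs_deviation(a: float, b: float, c: float) -> float:
    """Maximum of |theta(l)| on (0, l_star); 0 when b = 1."""
    _check_abc(a, b, c)
    if b == 1:
        return 0.0
    return (c / (a * b)) ** (b / (b - 1.0)) * a * abs(b - 1.0)


def threshold_partition(lengths: Sequence[float], l_star: float):
    """Percentages of lengths below and above l_star (ties count as below)."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise DataError("cannot partition an empty length sample")
    if not l_star > 0:
        raise ValueError("l_star must be > 0")
    below = float(np.mean(arr <= l_star)) * 100.0
    return below, 100.0 - below


@dataclass(frozen=True)
class ThresholdDiagnostics:
    """l_star, l_theta_max, theta_max and the below/above-threshold split."""

    l_star: float
    l_theta_max: float
    theta_max: float
    pct_below: float
    pct_above: float

    def to_dict(self) -> dict:
        return {
            "l_star_mm": self.l_star,
            "l_theta_max_mm": self.l_theta_max,
            "theta_max_g": self.theta_max,
            "pct_below": self.pct_below,
            "pct_above": self.pct_above,
            # rounded as the field reports them: 0.1 mm and 2 significant figures
            "display": {
                "l_star_mm": round(self.l_star, 1),
                "theta_max_g": float(f"{self.theta_max:.2g}"),
            },
        }


def compute_threshold_diagnostics(
    allo: AllometricParams,
    iso: IsometricParams,
    lengths: Sequence[float],
) -> ThresholdDiagnostics:
    """All threshold quantities for one fitted parameter triple and a length sample."""
    l_star = threshold_length(allo.a, allo.b, iso.c)
    below, above = threshold_partition(lengths, l_star)
    return ThresholdDiagnostics(
        l_star=l_star,
        l_theta_max=max_deviation_length(allo.a, allo.b, iso.c),
        theta_max=max_abs_deviation(allo.a, allo.b, iso.c),
        pct_below=below,
        pct_above=above,
    )


@dataclass(frozen=True)
class BiasProfile:
    """Per-leaf deviation of the ratio proxy and its aggregate bias.

    ``fraction_underestimated`` is the share of observed weights that
    exceed the isometric prediction c*l; restricted to lengths beyond
    l_star it quantifies the systematic underestimation of long leaves.
    ``mean_abs_relative_error`` is the mean of |c*l - w| / w.
    """

    lengths_mm: np.ndarray
    theta_g: np.ndarray
    relative_error: np.ndarray
    fraction_underestimated: float
    fraction_underestimated_beyond_threshold: Optional[float]
    mean_abs_relative_error: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "fraction_underestimated": self.fraction_underestimated,
            "fraction_underestimated_beyond_threshold":
                self.fraction_underestimated_beyond_threshold,
            "mean_abs_relative_error": self.mean_abs_relative_error,
            "n_excluded": self.n_excluded,
        }


def bias_profile(
    records: Sequence[LeafRecord],
    iso: IsometricParams,
    allo: AllometricParams,
) -> BiasProfile:
    """Bias of the weight-to-length ratio proxy against observed weights.

    Records with zero observed weight are excluded (relative error is
    undefined there) with a logged warning.
    """
    usable = [r for r in records if r.weight_g is not None]
    if not usable:
        raise DataError("bias profile needs records with observed weights")
    n_zero = sum(1 for r in usable if r.weight_g == 0)
    if n_zero:
        logger.warning("bias profile excluded %d record(s) with zero weight", n_zero)
    usable = [r for r in usable if r.weight_g > 0]
    if not usable:
        raise DataError("all observed weights are zero")
    l = np.array([r.length_mm for r in usable])
    w = np.array([r.weight_g for r in usable])
    iso_pred = iso.c * l
    theta = deviation(allo.a, allo.b, iso.c, l)
    rel = (iso_pred - w) / w
    under = iso_pred < w
    frac_under = float(np.mean(under))
    frac_beyond: Optional[float] = None
    if allo.b != 1:
        l_star = threshold_length(allo.a, allo.b, iso.c)
        beyond = l > l_star
        if np.any(beyond):
            frac_beyond = float(np.mean(under[beyond]))
    return BiasProfile(
        lengths_mm=l,
        theta_g=theta,
        relative_error=rel,
        fraction_underestimated=frac_under,
        fraction_underestimated_beyond_threshold=frac_beyond,
        mean_abs_relative_error=float(np.mean(np.abs(rel))),
        n_excluded=n_zero,
    )
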