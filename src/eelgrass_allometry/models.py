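"""Scaling-law models for eelgrass leaf biomass.

Two competing descriptions of how the dry weight ``w`` (g) of a *Zostera
marina* leaf scales with its length ``l`` (mm):

* allometric: ``w = a * l**b`` with normalization constant ``a``
  (g·mm^-b) and dimensionless allometric exponent ``b``;
* isometric: ``w = c * l`` with a constant weight-to-length ratio ``c``
  (g·mm^-1), the proportionality that underlies the plastochrone
  method's length-to-biomass conversion.

When only shoot-level biomass is available, the per-leaf models
aggregate additively over the leaves of a shoot.

Units are fixed package-wide: grams and millimetres. Readers convert or
reject other units explicitly; nothing here rescales silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LeafRecord",
    "ShootRecord",
    "AllometricParams",
    "IsometricParams",
    "predict_leaf_weight_allometric",
    "predict_leaf_weight_isometric",
    "predict_shoot_weight_allometric",
    "predict_shoot_weight_isometric",
]


@dataclass(frozen=True)
class LeafRecord:
    """One leaf: length in mm and, when measured, dry weight in g.

    ``weight_g`` is ``None`` for leaves whose length was recorded
    nondestructively; such records can feed length-only diagnostics but
    not the fits.
    """

    site: str
    shoot_id: str
    leaf_rank: int
    length_mm: float
    weight_g: Optional[float] = None

    def __post_init__(self):
        if not self.site:
            raise ValueError("site label must be a nonempty string")
        if self.leaf_rank < 1:
            raise ValueError(f"leaf_rank must be >= 1, got {self.leaf_rank}")
        if not self.length_mm > 0:
            raise ValueError(f"length_mm must be > 0, got {self.length_mm}")
        if self.weight_g is not None and self.weight_g < 0:
            raise ValueError(f"weight_g must be >= 0, got {self.weight_g}")


@dataclass(frozen=True)
class ShootRecord:
    """One shoot: all leaf lengths (mm) plus the aggregate dry weight (g)."""

    site: str
    shoot_id: str
    leaf_lengths_mm: tuple = field()
    shoot_weight_g: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "leaf_lengths_mm", tuple(self.leaf_lengths_mm))
        if not self.site:
            raise ValueError("site label must be a nonempty string")
        if len(self.leaf_lengths_mm) == 0:
            raise ValueError("a shoot must contain at least one leaf")
        if any(not l > 0 for l in self.leaf_lengths_mm):
            raise ValueError("all leaf lengths must be > 0")
        if not self.shoot_weight_g > 0:
            raise ValueError(
                f"shoot_weight_g must be > 0, got {self.shoot_weight_g}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_lengths_mm)

    @property
    def total_length_mm(self) -> float:
        return float(sum(self.leaf_lengths_mm))


@dataclass(frozen=True)
class AllometricParams:
    """Power-law coefficients: ``a`` in g·mm^-b, ``b`` dimensionless."""

    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"normalization constant a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"allometric exponent b must be > 0, got {self.b}")


@dataclass(frozen=True)
class IsometricParams:
    """Weight-to-length ratio ``c`` in g·mm^-1."""

    c: float

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"weight-to-length ratio c must be > 0, got {self.c}")


def _check_lengths(l) -> np.ndarray:
    arr = np.asarray(l, dtype=float)
    if np.any(arr < 0):
        raise ValueError("leaf length must be >= 0")
    return arr


def predict_leaf_weight_allometric(p: AllometricParams, l):
    """Predicted dry weight a*l**b for a leaf of length ``l`` mm.

    Accepts a scalar or array of lengths; returns the same shape.
    l = 0 yields 0 (b > 0), so predictions extend continuously to the
    origin even though observed records require positive length.
    """
    arr = _check_lengths(l)
    w = p.a * arr**p.b
    return float(w) if np.isscalar(l) else w


def predict_leaf_weight_isometric(p: IsometricParams, l):
    """Predicted dry weight c*l for a leaf of length ``l`` mm."""
    arr = _check_lengths(l)
    w = p.c * arr
    return float(w) if np.isscalar(l) else w


def predict_shoot_weight_allometric(p: AllometricParams, lengths: Sequence[float]) -> float:
    """Aggregate prediction sum_k a*l_k**b over a shoot's leaves."""
    arr = _check_lengths(lengths)
    if arr.size == 0:
        raise ValueError("a shoot must contain at least one leaf length")
    return float(np.sum(p.a * arr**p.b))


def predict_shoot_weight_isometric(p: IsometricParams, lengths: Sequence[float]) -> float:
    """Aggregate prediction c * sum_k l_k over a shoot's leaves."""
    arr = _check_lengths(lengths)
    if arr.size == 0:
        raise ValueError("a shoot must contain at least one leaf length")
    return float(p.c * np.sum(arr))
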