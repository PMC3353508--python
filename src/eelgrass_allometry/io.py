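"""CSV readers and writers for leaf and shoot morphometry tables.

Leaf dialect (one file): columns site, shoot_id, leaf_rank, length_mm,
weight_g; weight may be empty (recorded nondestructively), never 0 as a
stand-in for missing. Shoot dialect (two files): a long leaf table
(site, shoot_id, length_mm) joined with a shoot table (site, shoot_id,
shoot_weight_g). UTF-8, dot decimal separator, mandatory header;
delimiter configurable (comma default, semicolon/tab accepted). Units
are fixed by the column names — no autodetection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, RowError, SchemaError
from .models import LeafRecord, ShootRecord

__all__ = [
    "Dataset",
    "read_leaf_csv",
    "write_leaf_csv",
    "read_shoot_csv",
    "write_shoot_csv",
]

_LEAF_COLUMNS = ["site", "shoot_id", "leaf_rank", "length_mm", "weight_g"]
_SHOOT_LEAF_COLUMNS = ["site", "shoot_id", "length_mm"]
_SHOOT_COLUMNS = ["site", "shoot_id", "shoot_weight_g"]


@dataclass(frozen=True)
class Dataset:
    """Leaf and/or shoot records with a provenance tag (source path or
    generator-config hash)."""

    leaves: tuple = field(default_factory=tuple)
    shoots: tuple = field(default_factory=tuple)
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(self, "shoots", tuple(self.shoots))
        if not self.leaves and not self.shoots:
            raise DataError("a dataset must contain leaves or shoots")


def _read_table(path, delimiter: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    return df


def _parse_float(value: str, row: int, column: str, *, optional: bool = False):
    if value == "":
        if optional:
            return None
        raise RowError(row, f"empty value in column {column!r}")
    try:
        return float(value)
    except ValueError:
        raise RowError(row, f"unparseable number {value!r} in column {column!r}")


def read_leaf_csv(path, *, delimiter: str = ",") -> Dataset:
    """Parse a leaf table into a Dataset; row errors carry the 1-based
    data-row number (header excluded)."""
    df = _read_table(path, delimiter, _LEAF_COLUMNS)
    leaves: List[LeafRecord] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        length = _parse_float(rec.length_mm, i, "length_mm")
        if length <= 0:
            raise RowError(i, f"length_mm must be > 0, got {length}")
        weight = _parse_float(rec.weight_g, i, "weight_g", optional=True)
        if weight is not None and weight < 0:
            raise RowError(i, f"weight_g must be >= 0, got {weight}")
        rank_f = _parse_float(rec.leaf_rank, i, "leaf_rank")
        if rank_f != int(rank_f) or rank_f < 1:
            raise RowError(i, f"leaf_rank must be a positive integer, got {rec.leaf_rank}")
        if not rec.site:
            raise RowError(i, "site label is empty")
        try:
            leaves.append(
                LeafRecord(
                    site=rec.site,
                    shoot_id=rec.shoot_id,
                    leaf_rank=int(rank_f),
                    length_mm=length,
                    weight_g=weight,
                )
            )
        except ValueError as exc:
            raise RowError(i, str(exc))
    if not leaves:
        raise DataError(f"{path}: no data rows")
    return Dataset(leaves=tuple(leaves), provenance=str(path))


def _format_float(x: Optional[float]) -> str:
    return "" if x is None else np.format_float_positional(x, trim="0")


def write_leaf_csv(leaves: Sequence[LeafRecord], path, *, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        {
            "site": [r.site for r in leaves],
            "shoot_id": [r.shoot_id for r in leaves],
            "leaf_rank": [r.leaf_rank for r in leaves],
            "length_mm": [_format_float(r.length_mm) for r in leaves],
            "weight_g": [_format_float(r.weight_g) for r in leaves],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_shoot_csv(leaf_path, shoot_path, *, delimiter: str = ",") -> Dataset:
    """Assemble ShootRecords from a long leaf table and a shoot-weight table.

    A shoot id appearing twice in the weight table, a weighted shoot
    with no leaves, or a leaf row with no matching shoot weight are all
    errors naming the offending shoot.
    """
    leaf_df = _read_table(leaf_path, delimiter, _SHOOT_LEAF_COLUMNS)
    shoot_df = _read_table(shoot_path, delimiter, _SHOOT_COLUMNS)

    weights = {}
    for i, rec in enumerate(shoot_df.itertuples(index=False), start=1):
        key = (rec.site, rec.shoot_id)
        if key in weights:
            raise RowError(i, f"duplicate shoot weight for shoot {rec.shoot_id!r}")
        w = _parse_float(rec.shoot_weight_g, i, "shoot_weight_g")
        if w <= 0:
            raise RowError(i, f"shoot_weight_g must be > 0, got {w}")
        weights[key] = w

    lengths: dict = {}
    for i, rec in enumerate(leaf_df.itertuples(index=False), start=1):
        key = (rec.site, rec.shoot_id)
        if key not in weights:
            raise RowError(
                i, f"leaf row for shoot {rec.shoot_id!r} has no shoot weight"
            )
        length = _parse_float(rec.length_mm, i, "length_mm")
        if length <= 0:
            raise RowError(i, f"length_mm must be > 0, got {length}")
        lengths.setdefault(key, []).append(length)

    orphans = [k for k in weights if k not in lengths]
    if orphans:
        raise DataError(
            "shoot(s) with weight but no leaves: "
            + ", ".join(repr(s) for _, s in orphans)
        )
    shoots = tuple(
        ShootRecord(
            site=site,
            shoot_id=sid,
            leaf_lengths_mm=tuple(lengths[(site, sid)]),
            shoot_weight_g=weights[(site, sid)],
        )
        for (site, sid) in weights
    )
    return Dataset(shoots=shoots, provenance=f"{leaf_path}+{shoot_path}")


def write_shoot_csv(
    shoots: Sequence[ShootRecord], leaf_path, shoot_path, *, delimiter: str = ","
) -> None:
    leaf_rows = {
        "site": [], "shoot_id": [], "length_mm": [],
    }
    for s in shoots:
        for l in s.leaf_lengths_mm:
            leaf_rows["site"].append(s.site)
            leaf_rows["shoot_id"].append(s.shoot_id)
            leaf_rows["length_mm"].append(_format_float(l))
    pd.DataFrame(leaf_rows).to_csv(leaf_path, sep=delimiter, index=False)
    pd.DataFrame(
        {
            "site": [s.site for s in shoots],
            "shoot_id": [s.shoot_id for s in shoots],
            "shoot_weight_g": [_format_float(s.shoot_weight_g) for s in shoots],
        }
    ).to_csv(shoot_path, sep=delimiter, index=False)


def config_hash(d: dict) -> str:
    """Stable short hash of a configuration dict, for provenance tags."""
    blob = repr(sorted(d.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
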