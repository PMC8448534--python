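"""Origin-destination trip matrices.

A :class:`TripMatrix` holds counts (or expected counts) for every ordered
pair of districts. Within-district travel is never modelled, so the diagonal
is structurally absent and stored as NaN. Off-diagonal NaN marks a route with
no observation at all (structurally missing), which is distinct from an
observed count of zero: zeros inform a Poisson likelihood, missing routes are
excluded from it.

Long-form CSV (``origin_id,dest_id,count``) is the canonical interchange
format: a row present with count 0 is an observed zero; an absent row is a
missing route. Wide CSV (districts x districts) uses empty cells for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geography import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) float; diagonal NaN; off-diagonal NaN = missing route

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"trip matrix shape {v.shape} does not match {n} ids")
        v = v.copy()
        np.fill_diagonal(v, np.nan)
        if np.any(v[np.isfinite(v)] < 0):
            raise ValidationError("trip counts must be non-negative")
        object.__setattr__(self, "ids", [str(i) for i in self.ids])
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean (n, n): True where a route has a value (off-diagonal, non-missing)."""
        return np.isfinite(self.values)

    @property
    def total(self) -> float:
        return float(np.nansum(self.values))

    def row_sums(self) -> np.ndarray:
        return np.nansum(self.values, axis=1)

    def rounded(self) -> "TripMatrix":
        """Round to integer counts for Poisson fitting; logs when rounding changes values."""
        v = self.values
        r = np.round(v)
        changed = int(np.sum(np.isfinite(v) & (r != v)))
        if changed:
            logger.info("rounded %d non-integer trip counts to nearest integer", changed)
        return TripMatrix(self.ids, r)

    def align_to(self, ids: Sequence[str]) -> "TripMatrix":
        """Reorder/subset to the given district ids (e.g. a geography's order)."""
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in self.ids]
        if missing:
            raise ValidationError(f"trip matrix lacks districts: {missing}")
        pos = [self.ids.index(i) for i in ids]
        return TripMatrix(list(ids), self.values[np.ix_(pos, pos)])

    def to_long(self, include_missing: bool = False) -> pd.DataFrame:
        rows = []
        for i, o in enumerate(self.ids):
            for j, d in enumerate(self.ids):
                if i == j:
                    continue
                v = self.values[i, j]
                if np.isfinite(v) or include_missing:
                    rows.append((o, d, v))
        return pd.DataFrame(rows, columns=["origin_id", "dest_id", "count"])

    def districts_without_data(self) -> list[str]:
        """Districts with no observed route in or out (candidates for dropping)."""
        m = self.observed_mask
        dead = ~(m.any(axis=0) | m.any(axis=1))
        return [i for i, flag in zip(self.ids, dead) if flag]


def from_long(df: pd.DataFrame, ids: Sequence[str] | None = None) -> TripMatrix:
    """Build a TripMatrix from long-form rows ``origin_id, dest_id, count``."""
    for c in ("origin_id", "dest_id", "count"):
        if c not in df.columns:
            raise ValidationError(f"long trip table missing column {c!r}")
    df = df.assign(origin_id=df.origin_id.astype(str), dest_id=df.dest_id.astype(str))
    if ids is None:
        ids = sorted(set(df.origin_id) | set(df.dest_id))
    ids = [str(i) for i in ids]
    index = {d: k for k, d in enumerate(ids)}
    unknown = sorted({x for x in pd.concat([df.origin_id, df.dest_id]) if x not in index})
    if unknown:
        raise ValidationError(f"trip table references unknown districts: {unknown}")
    n = len(ids)
    vals = np.full((n, n), np.nan)
    for r in df.itertuples(index=False):
        if r.origin_id == r.dest_id:
            continue
        vals[index[r.origin_id], index[r.dest_id]] = float(r.count)
    return TripMatrix(ids, vals)


def read_trip_csv(path, ids: Sequence[str] | None = None) -> TripMatrix:
    """Read a trip CSV in long form (``origin_id,dest_id,count``) or wide form.

    Wide form is detected by the absence of the long-form header; its first
    column holds origin ids and remaining columns destination ids.
    """
    df = pd.read_csv(path)
    if {"origin_id", "dest_id", "count"}.issubset(df.columns):
        return from_long(df, ids)
    wide = pd.read_csv(path, index_col=0)
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    if list(wide.index) != list(wide.columns):
        raise ValidationError("wide trip CSV must have identical row and column district ids")
    tm = TripMatrix(list(wide.index), wide.to_numpy(dtype=float))
    return tm if ids is None else tm.align_to(ids)


def write_trip_csv(trips: TripMatrix, path) -> None:
    trips.to_long().to_csv(path, index=False)
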