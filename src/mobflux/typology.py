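"""Trip-type classification for stratified gravity models.

Every ordered origin-destination pair is assigned a category under three
schemes:

* urbanicity ``k`` in 1..4: rural-rural, rural-urban, urban-rural, urban-urban
  (ordered by origin then destination urbanicity);
* regional ``m`` in 1..2: intra-regional (same level-1 region) vs
  inter-regional;
* regional-urbanicity ``n`` in 1..8: the full cross product, row-major in
  (m, k): ``n = 4*(m-1) + k``, so 1..4 are the intra-regional urbanicity cells
  and 5..8 the inter-regional ones. This ordering is declared in exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geography import District, Geography, RURAL, URBAN, ValidationError

K_LABELS = {1: "rural-rural", 2: "rural-urban", 3: "urban-rural", 4: "urban-urban"}
M_LABELS = {1: "intra-regional", 2: "inter-regional"}
N_LABELS = {4 * (m - 1) + k: f"{M_LABELS[m]}-{K_LABELS[k]}" for m in (1, 2) for k in (1, 2, 3, 4)}

SCHEME_CATEGORIES = {"basic": 1, "urbanicity": 4, "regional": 2, "regional_urbanicity": 8}


def _require_label(d: District) -> None:
    if d.urbanicity not in (URBAN, RURAL):
        raise ValidationError(f"district {d.id!r} has no urbanicity label")


def classify_urbanicity_pair(origin: District, dest: District) -> int:
    """k = 1 rural->rural, 2 rural->urban, 3 urban->rural, 4 urban->urban."""
    _require_label(origin)
    _require_label(dest)
    return 1 + 2 * (origin.urbanicity == URBAN) + (dest.urbanicity == URBAN)


def classify_region_pair(origin: District, dest: District) -> int:
    """m = 1 if origin and destination share a level-1 region, else 2."""
    if not origin.region_id or not dest.region_id:
        raise ValidationError("district missing region_id")
    return 1 if origin.region_id == dest.region_id else 2


def classify_region_urbanicity_pair(origin: District, dest: District) -> int:
    """n = 4*(m-1) + k: the regional x urbanicity cross product, 1..8."""
    return 4 * (classify_region_pair(origin, dest) - 1) + classify_urbanicity_pair(origin, dest)


@dataclass(frozen=True)
class TripTypology:
    """Per-ordered-pair category indices (n x n int arrays; diagonal entries are 0)."""

    ids: list[str]
    k_index: np.ndarray
    m_index: np.ndarray
    n_index: np.ndarray

    def index_for_scheme(self, scheme: str) -> np.ndarray:
        """0-based category index per pair for the given stratification scheme."""
        if scheme == "basic":
            out = np.zeros_like(self.k_index)
            np.fill_diagonal(out, -1)
            return out
        arr = {"urbanicity": self.k_index, "regional": self.m_index, "regional_urbanicity": self.n_index}.get(scheme)
        if arr is None:
            raise ValidationError(f"unknown scheme {scheme!r}")
        return arr - 1  # diagonal becomes -1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, o in enumerate(self.ids):
            for j, d in enumerate(self.ids):
                if i != j:
                    rows.append((o, d, self.k_index[i, j], self.m_index[i, j], self.n_index[i, j]))
        return pd.DataFrame(rows, columns=["origin_id", "dest_id", "k", "m", "n"])


def build_typology(geo: Geography) -> TripTypology:
    """Classify every ordered district pair under all three schemes."""
    urban = np.array([d.urbanicity == URBAN for d in geo.districts])
    for d in geo.districts:
        _require_label(d)
    regions = np.array(geo.region_ids)
    k = 1 + 2 * urban[:, None].astype(int) + urban[None, :].astype(int)
    m = np.where(regions[:, None] == regions[None, :], 1, 2)
    n = 4 * (m - 1) + k
    for a in (k, m, n):
        np.fill_diagonal(a, 0)
    return TripTypology(list(geo.ids), k, m, n)


def write_typology_csv(typ: TripTypology, path) -> None:
    """Export ``origin_id,dest_id,k,m,n`` with the category ordering in a header comment."""
    with open(path, "w") as fh:
        fh.write("# n = 4*(m-1)+k; n 1-4 intra-regional {rr,ru,ur,uu}, 5-8 inter-regional {rr,ru,ur,uu}\n")
        typ.to_frame().to_csv(fh, index=False)
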