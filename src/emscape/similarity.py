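"""Pairwise community comparison and the distance-overlap matrix layout.

Jaccard similarity on incidence, Morisita-Horn overlap (the incidence-safe
form of Morisita's overlap), haversine great-circle distances, and the
combined site x site matrix with distances below the diagonal and overlap
above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .incidence import IncidenceMatrix

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "jaccard",
    "morisita_overlap",
    "great_circle_km",
    "PairwiseMatrix",
    "distance_overlap_matrix",
]


def jaccard(a: Sequence[bool] | np.ndarray, b: Sequence[bool] | np.ndarray) -> float:
    """Jaccard similarity of two incidence vectors over the same species list.

    J = shared / (shared + unique to a + unique to b); two empty communities
    are defined as identical (J = 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("incidence vectors must share the species list")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def morisita_overlap(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Morisita-Horn overlap of two count vectors (incidence treated as 0/1).

    C = 2 sum(a_i b_i) / ((d_a + d_b) N_a N_b) with d = sum(x^2) / N^2.
    1 for identical relative compositions, 0 for disjoint supports.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the species list")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be nonnegative")
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        raise ValueError("zero-sum count vector")
    da = (a**2).sum() / na**2
    db = (b**2).sum() / nb**2
    return float(2.0 * (a * b).sum() / ((da + db) * na * nb))


def great_circle_km(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points in degrees."""
    for lat, lon in (p, q):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*p, *q))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


@dataclass
class PairwiseMatrix:
    """Square site matrix: distances (km) below the diagonal, overlap above."""

    site_ids: list[str]
    distance_km: np.ndarray  # full symmetric matrix
    overlap: np.ndarray  # full symmetric matrix

    def to_frame(self, distance_decimals: int = 1, overlap_decimals: int = 2) -> pd.DataFrame:
        """Combined table: lower triangle distance, upper overlap, empty diagonal."""
        n = len(self.site_ids)
        cells = np.full((n, n), "", dtype=object)
        for i in range(n):
            for j in range(n):
                if i > j:
                    cells[i, j] = f"{self.distance_km[i, j]:.{distance_decimals}f}"
                elif i < j:
                    cells[i, j] = f"{self.overlap[i, j]:.{overlap_decimals}f}"
        df = pd.DataFrame(cells, index=self.site_ids, columns=self.site_ids)
        df.index.name = "ID"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def distance_overlap_matrix(
    m: IncidenceMatrix,
    coords: Mapping[str, tuple[float, float]],
    reference_site: str | None = None,
) -> PairwiseMatrix:
    """Site x site distance (lower) / Morisita-Horn overlap (upper) matrix.

    ``coords`` maps site id -> (lat, lon) in decimal degrees; every site
    needs a coordinate. Rows are ordered by great-circle distance from
    ``reference_site`` (default: the first site of the matrix), mirroring
    the published layout ordered from site 1.
    """
    missing = [s for s in m.site_ids if s not in coords]
    if missing:
        raise ValueError(f"missing coordinates for sites: {missing}")
    ref = reference_site if reference_site is not None else m.site_ids[0]
    if ref not in m.site_ids:
        raise ValueError(f"unknown reference site {ref!r}")
    order = sorted(m.site_ids, key=lambda s: great_circle_km(coords[ref], coords[s]))
    idx = [m.site_ids.index(s) for s in order]
    occ = m.occupancy[:, idx].astype(float)
    n = len(order)
    dist = np.zeros((n, n))
    over = np.zeros((n, n))
    for i in range(n):
        over[i, i] = 1.0
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = great_circle_km(coords[order[i]], coords[order[j]])
            over[i, j] = over[j, i] = morisita_overlap(occ[:, i], occ[:, j])
    return PairwiseMatrix(order, dist, over)
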