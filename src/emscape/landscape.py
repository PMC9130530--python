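"""Categorical-raster landscape metrics (FRAGSTATS-style).

Implements the landscape-, class- and patch-level metrics used to describe
the 3-km land-use buffers around each monitoring site: number of patches
(NP), landscape shape index (LSI), Shannon's evenness index (SHEI),
aggregation index (AI), class proportions (P_i), number of native-forest
patches (N_NF), interspersion-juxtaposition index (IJI), mean Euclidean
nearest-neighbour distance (ENN_MN), perimeter-area ratio (PARA) and the
patch shape index (SHAPE).

Conventions (the raster FRAGSTATS ones): patches are 8-connected components
of one class; like-adjacencies for AI and edge segments for LSI/IJI are
counted under 4-neighbour (rook) adjacency; the raster boundary and nodata
cells count as edge for perimeters and total edge length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

DEFAULT_CLASS_NAMES = {
    1: "native_forest",
    2: "grassland",
    3: "timber",
    4: "crops",
    5: "water",
    6: "urban",
}
DEFAULT_EXCLUDED = ("water", "urban")

_EIGHT = np.ones((3, 3), dtype=int)

__all__ = [
    "LandscapeRaster",
    "Patch",
    "PatchSet",
    "label_patches",
    "class_proportion",
    "lsi",
    "shei",
    "ai",
    "iji",
    "enn_mn",
    "para",
    "shape_index",
    "summarize_buffer",
    "circular_mask",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_raster",
    "DEFAULT_CLASS_NAMES",
]


@dataclass
class LandscapeRaster:
    """Integer class codes on a rectangular lattice with a known cell size."""

    grid: np.ndarray
    cell_size: float
    nodata: int = -9999
    class_names: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_NAMES))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        codes = set(np.unique(self.grid)) - {self.nodata}
        unknown = codes - set(self.class_names)
        if unknown:
            raise ValueError(f"class codes without names: {sorted(unknown)}")

    @property
    def valid(self) -> np.ndarray:
        return self.grid != self.nodata

    @property
    def total_area(self) -> float:
        """A: total landscape area in m^2 (valid cells only)."""
        return float(self.valid.sum()) * self.cell_size**2

    def mask(self, keep: np.ndarray) -> "LandscapeRaster":
        """Raster with cells outside ``keep`` set to nodata."""
        g = self.grid.copy()
        g[~keep] = self.nodata
        return LandscapeRaster(g, self.cell_size, self.nodata, dict(self.class_names))

    def exclude_classes(self, names: Sequence[str]) -> "LandscapeRaster":
        """Raster with the named classes masked out (treated as background)."""
        drop = {c for c, n in self.class_names.items() if n in set(names)}
        keep = ~np.isin(self.grid, sorted(drop))
        return self.mask(keep)


@dataclass
class Patch:
    """One connected component of a single land-use class."""

    id: int
    class_code: int
    cells: np.ndarray  # (k, 2) array of (row, col)
    area: float  # a_ij, m^2
    perimeter: float  # P_ij, m


@dataclass
class PatchSet:
    """All patches of a raster plus the adjacency bookkeeping."""

    raster: LandscapeRaster
    patches: list[Patch]
    like_joins: dict[int, int]  # g_ii per class, rook pairs counted once
    edge_lengths: dict[tuple[int, int], float]  # e_ik (m), i < k, rook
    boundary_edge: float  # raster-border + nodata edge length (m)

    def by_class(self, code: int) -> list[Patch]:
        return [p for p in self.patches if p.class_code == code]

    def class_codes(self) -> list[int]:
        present = np.unique(self.raster.grid[self.raster.valid])
        return [int(c) for c in present]

    @property
    def np_total(self) -> int:
        return len(self.patches)

    def total_edge(self, include_boundary: bool = True) -> float:
        """E*: total edge length, by default including the landscape boundary."""
        e = sum(self.edge_lengths.values())
        if include_boundary:
            e += self.boundary_edge
        return float(e)

    def code_of(self, name: str) -> int:
        for c, n in self.raster.class_names.items():
            if n == name:
                return c
        raise KeyError(name)


def _perimeters(valid: np.ndarray, labels: np.ndarray, n_labels: int, cell: float) -> np.ndarray:
    """Perimeter per labelled patch: edges facing a different patch, nodata or border."""
    per = np.zeros(n_labels + 1)
    padded = np.pad(labels, 1, constant_values=0)
    padded[np.pad(~valid, 1, constant_values=True)] = 0
    core = padded[1:-1, 1:-1]
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = np.roll(padded, shift, axis=(0, 1))[1:-1, 1:-1]
        exposed = (core > 0) & (neigh != core)
        per += np.bincount(core[exposed], minlength=n_labels + 1)
    return per * cell


def label_patches(r: LandscapeRaster) -> PatchSet:
    """Find all patches (8-connected components per class) and adjacency tallies."""
    valid = r.valid
    if not valid.any():
        raise ValueError("all-nodata raster")
    grid = r.grid
    cell = r.cell_size

    patches: list[Patch] = []
    all_labels = np.zeros_like(grid)
    next_id = 0
    for code in np.unique(grid[valid]):
        lab, n = ndimage.label(grid == code, structure=_EIGHT)
        lab_global = np.where(lab > 0, lab + next_id, 0)
        all_labels = np.maximum(all_labels, lab_global)
        objs = ndimage.find_objects(lab)
        for k in range(1, n + 1):
            sl = objs[k - 1]
            cells = np.argwhere(lab[sl] == k) + [sl[0].start, sl[1].start]
            patches.append(
                Patch(
                    id=next_id + k,
                    class_code=int(code),
                    cells=cells,
                    area=float(cells.shape[0]) * cell**2,
                    perimeter=0.0,
                )
            )
        next_id += n

    per = _perimeters(valid, all_labels, next_id, cell)
    for p in patches:
        p.perimeter = float(per[p.id])

    # rook adjacency tallies, each cell pair counted once
    like: dict[int, int] = {}
    edges: dict[tuple[int, int], float] = {}
    boundary = 0.0
    for axis in (0, 1):
        a = grid.take(range(grid.shape[axis] - 1), axis=axis)
        b = grid.take(range(1, grid.shape[axis]), axis=axis)
        va = valid.take(range(grid.shape[axis] - 1), axis=axis)
        vb = valid.take(range(1, grid.shape[axis]), axis=axis)
        both = va & vb
        same = both & (a == b)
        for code in np.unique(a[same]):
            like[int(code)] = like.get(int(code), 0) + int((same & (a == code)).sum())
        diff = both & (a != b)
        pa, pb = a[diff], b[diff]
        for i, k in zip(pa, pb):
            key = (int(min(i, k)), int(max(i, k)))
            edges[key] = edges.get(key, 0.0) + cell
        # one side valid, the other nodata
        boundary += cell * int((va & ~vb).sum() + (~va & vb).sum())
    # raster border edges of valid cells
    boundary += cell * int(valid[0].sum() + valid[-1].sum() + valid[:, 0].sum() + valid[:, -1].sum())

    return PatchSet(r, patches, like, edges, boundary)


# ---------------------------------------------------------------------------
# landscape-level metrics


def class_proportion(ps: PatchSet, code: int) -> float:
    """P_i: percentage of the landscape occupied by class ``code``."""
    area = sum(p.area for p in ps.by_class(code))
    return 100.0 * area / ps.raster.total_area


def lsi(ps: PatchSet, include_boundary: bool = True) -> float:
    """Landscape shape index: LSI = 0.25 E* / sqrt(A).

    E* is the total edge length including (by default) the landscape
    boundary; equals 1 for a maximally compact single-class square.
    """
    return 0.25 * ps.total_edge(include_boundary) / math.sqrt(ps.raster.total_area)


def shei(ps: PatchSet) -> float:
    """Shannon's evenness index over class proportions; 0 for one class."""
    areas = np.array([sum(p.area for p in ps.by_class(c)) for c in ps.class_codes()])
    areas = areas[areas > 0]
    m = areas.size
    if m <= 1:
        return 0.0
    p = areas / areas.sum()
    return float(-(p * np.log(p)).sum() / math.log(m))


def _max_like_joins(n_cells: int) -> int:
    """Largest possible rook like-join count for a class of ``n_cells`` cells.

    The maximum is reached by the most square-like block: with
    n = floor(sqrt(a)) and m = a - n^2, it is 2n(n-1) + (0 if m = 0 else
    2m-1 if m <= n else 2m-2).
    """
    n = int(math.isqrt(n_cells))
    m = n_cells - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


def ai(ps: PatchSet, code: int | None = None) -> float:
    """Aggregation index, percent.

    Class level: AI = 100 g_ii / max g_ii with g_ii the rook like-join count
    and max g_ii the compact-block maximum. A single-cell class (max = 0) is
    reported as 100. ``code=None`` gives the landscape AI: the area-weighted
    mean of class AIs.
    """
    if code is None:
        codes = ps.class_codes()
        areas = np.array([sum(p.area for p in ps.by_class(c)) for c in codes])
        vals = np.array([ai(ps, c) for c in codes])
        return float((vals * areas).sum() / areas.sum())
    n_cells = sum(p.cells.shape[0] for p in ps.by_class(code))
    if n_cells == 0:
        raise ValueError(f"class {code} absent")
    max_g = _max_like_joins(n_cells)
    if max_g == 0:
        return 100.0
    return 100.0 * ps.like_joins.get(code, 0) / max_g


def iji(ps: PatchSet, code: int) -> float:
    """Interspersion-juxtaposition index of class ``code``, percent, or NaN.

    Evenness of the focal class's shared-edge apportionment among the other
    classes: 100 when the focal edge is split evenly among all m-1 others,
    0 when it all touches one class. Undefined (NaN) when fewer than 3
    classes are present or the focal class shares no edge.
    """
    m = len(ps.class_codes())
    if m < 3:
        return math.nan
    e = np.array(
        [length for (i, k), length in ps.edge_lengths.items() if code in (i, k)]
    )
    e = e[e > 0]
    if e.size == 0 or e.sum() == 0:
        return math.nan
    p = e / e.sum()
    return float(-(p * np.log(p)).sum() / math.log(m - 1) * 100.0)


def _edge_cells(patch: Patch) -> np.ndarray:
    """Cells of a patch with at least one rook neighbour outside the patch."""
    cells = patch.cells
    cell_set = set(map(tuple, cells))
    out = []
    for rc in cells:
        r0, c0 = int(rc[0]), int(rc[1])
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r0 + dr, c0 + dc) not in cell_set:
                out.append((r0, c0))
                break
    return np.array(out)


def enn_mn(ps: PatchSet, code: int) -> float:
    """Mean Euclidean nearest-neighbour distance between patches of a class (m).

    For each patch, the minimum centre-to-centre distance between its edge
    cells and the edge cells of any other patch of the same class; the mean
    of these per-patch minima. NaN when the class has fewer than 2 patches.
    """
    patches = ps.by_class(code)
    if len(patches) < 2:
        return math.nan
    cell = ps.raster.cell_size
    edges = [_edge_cells(p).astype(float) for p in patches]
    h = []
    for i, a in enumerate(edges):
        best = math.inf
        for j, b in enumerate(edges):
            if i == j:
                continue
            best = min(best, cdist(a, b).min())
        h.append(best * cell)
    return float(np.mean(h))


def para(p: Patch) -> float:
    """Perimeter-area ratio P_ij / a_ij (1/m); scale dependent."""
    if p.area <= 0:
        raise ValueError("patch area must be positive")
    return p.perimeter / p.area


def shape_index(p: Patch) -> float:
    """SHAPE = 0.25 P_ij / sqrt(a_ij): 1 for a square block, larger otherwise."""
    if p.area <= 0:
        raise ValueError("patch area must be positive")
    return 0.25 * p.perimeter / math.sqrt(p.area)


# ---------------------------------------------------------------------------
# report assembly


REPORT_COLUMNS = [
    "NP", "LSI", "SHEI", "AI",
    "P_NF", "P_GL", "P_TF", "P_C",
    "N_NF", "IJI", "ENN", "AREA", "PARA", "SHAPE",
]

_PROP_COLUMN = {"native_forest": "P_NF", "grassland": "P_GL", "timber": "P_TF", "crops": "P_C"}


def summarize_buffer(
    r: LandscapeRaster,
    focal_patch_id: int | None = None,
    exclude: Sequence[str] = DEFAULT_EXCLUDED,
) -> pd.Series:
    """Full per-site metric report over one (buffer) raster.

    Landscape metrics (NP, LSI, SHEI, AI) and class proportions are computed
    with the ``exclude`` classes (by default water and urban) masked out;
    native-forest class metrics (N_NF, IJI, ENN) and the focal-patch metrics
    (AREA, PARA, SHAPE) complete the report. ``focal_patch_id`` defaults to
    the largest native-forest patch; it must refer to a native-forest patch.
    """
    work = r.exclude_classes(exclude) if exclude else r
    ps = label_patches(work)
    nf = ps.code_of("native_forest")
    out: dict[str, float] = {
        "NP": ps.np_total,
        "LSI": lsi(ps),
        "SHEI": shei(ps),
        "AI": ai(ps),
    }
    for name, col in _PROP_COLUMN.items():
        try:
            out[col] = class_proportion(ps, ps.code_of(name))
        except KeyError:
            out[col] = 0.0
    nf_patches = ps.by_class(nf)
    out["N_NF"] = len(nf_patches)
    out["IJI"] = iji(ps, nf)
    out["ENN"] = enn_mn(ps, nf)
    if not nf_patches:
        raise ValueError("no native-forest patch in the buffer")
    if focal_patch_id is None:
        focal = max(nf_patches, key=lambda p: p.area)
    else:
        match = [p for p in ps.patches if p.id == focal_patch_id]
        if not match:
            raise ValueError(f"no patch with id {focal_patch_id}")
        focal = match[0]
        if focal.class_code != nf:
            raise ValueError(f"focal patch {focal_patch_id} is not native forest")
    out["AREA"] = focal.area
    out["PARA"] = para(focal)
    out["SHAPE"] = shape_index(focal)
    return pd.Series(out, index=REPORT_COLUMNS)


def circular_mask(shape: tuple[int, int], center: tuple[float, float], radius_cells: float) -> np.ndarray:
    """Boolean mask of cells whose centres fall within ``radius_cells`` of ``center``.

    Used to clip a raster to the circular analysis buffer (e.g. 3 km around
    the monitoring site, radius = 3000 / cell_size cells).
    """
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_cells**2


# ---------------------------------------------------------------------------
# raster I/O


def read_ascii_grid(path: str | Path, class_names: Mapping[int, str] | None = None) -> LandscapeRaster:
    """Read an ESRI ASCII grid of integer class codes."""
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req}")
    grid = np.array(rows, dtype=int)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid is {grid.shape}, header says "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = int(header.get("nodata_value", -9999))
    names = dict(class_names or DEFAULT_CLASS_NAMES)
    return LandscapeRaster(grid, header["cellsize"], nodata, names)


def write_ascii_grid(r: LandscapeRaster, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {r.grid.shape[1]}\n")
        fh.write(f"nrows {r.grid.shape[0]}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {r.cell_size:g}\n")
        fh.write(f"NODATA_value {r.nodata}\n")
        for row in r.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster(
    path: str | Path,
    cell_size: float | None = None,
    class_names: Mapping[int, str] | None = None,
) -> LandscapeRaster:
    """Read a categorical raster: ESRI ASCII grid (.asc/.txt) or GeoTIFF band 1."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 3:
            arr = arr[0]
        if cell_size is None:
            raise ValueError("cell_size is required for GeoTIFF input")
        return LandscapeRaster(arr.astype(int), cell_size, class_names=dict(class_names or DEFAULT_CLASS_NAMES))
    return read_ascii_grid(path, class_names)
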