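"""Synthetic data with known structure.

Two generator families make every stage of the pipeline testable without
external downloads:

* :func:`make_structure` builds incidence matrices realising each of the
  eight idealized (non-quasi) metacommunity structures — checkerboard,
  random, Clementsian, Gleasonian, evenly spaced, and the three nested
  variants — at a controllable cell-flip noise level. Matrices are built in
  their ideal row/column order and then randomly permuted, so downstream
  analyses must rediscover the gradient through ordination.
* :func:`make_scene` builds small categorical rasters from declarative
  rectangle lists, whose landscape metrics have closed forms.

:func:`table1_fixture` ships the transcribed published frequency/trait table
(101 woody species at 32 permanent monitoring sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .incidence import IncidenceMatrix, SpeciesRecord, round_half_up
from .landscape import DEFAULT_CLASS_NAMES, LandscapeRaster

STRUCTURE_KINDS = (
    "checkerboard",
    "random",
    "clementsian",
    "gleasonian",
    "evenly_spaced",
    "nested_clumped",
    "nested_random",
    "nested_evenly_spaced",
)

__all__ = [
    "StructureSpec",
    "SceneSpec",
    "STRUCTURE_KINDS",
    "make_structure",
    "make_scene",
    "table1_fixture",
]


@dataclass(frozen=True)
class StructureSpec:
    """Parameters for one idealized metacommunity pattern."""

    kind: str
    n_species: int = 30
    n_sites: int = 20
    n_compartments: int = 3
    fill: float = 0.3  # random generator only: Bernoulli occupancy probability
    noise: float = 0.0  # probability of flipping any cell, applied last
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.n_species < 2 or self.n_sites < 2:
            raise ValueError("need n_species >= 2 and n_sites >= 2")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if self.kind == "clementsian" and self.n_compartments > min(self.n_sites, self.n_species):
            raise ValueError("more compartments than sites or species")
        if self.kind == "checkerboard" and self.n_species % 2:
            raise ValueError("checkerboard needs an even number of species")
        if not 0 < self.fill < 1:
            raise ValueError("fill must lie in (0, 1)")


def _split_sizes(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (i < extra) for i in range(parts)]


def _top_ca_singular_value(x: np.ndarray) -> float:
    xf = x.astype(float)
    t = xf.sum()
    r = xf.sum(axis=1) / t
    c = xf.sum(axis=0) / t
    resid = (xf / t - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return float(np.linalg.svd(resid, compute_uv=False)[0])


def _checkerboard(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    """Mutually exclusive species pairs carrying no compositional gradient.

    Pure mutual exclusion: species come in pairs that never co-occur, and the
    community carries no site gradient at all. Random exclusive pairs still
    contain incidental gradient structure that reciprocal averaging can
    exploit, so after building balanced exclusive pairs the generator anneals
    single-presence moves (preserving pair exclusivity, per-species range
    size, and site coverage) to minimize the leading correspondence
    eigenvalue — the amount of one-dimensional gradient left in the matrix.
    """
    s, n = spec.n_species, spec.n_sites
    # per-species range size that maximizes the span-versus-fill contrast
    k = max(2, min(n // 2, round(math.sqrt(2.0 * (n + 1)) - 1.0)))
    occ = np.zeros((s, n), dtype=bool)
    load = np.zeros(n)
    for p in range(s // 2):
        sites = np.argsort(load + 0.25 * rng.random(n))[: 2 * k]
        sites = rng.permutation(sites)
        occ[2 * p, sites[:k]] = True
        occ[2 * p + 1, sites[k:]] = True
        load[sites] += 1

    current = _top_ca_singular_value(occ)
    for _ in range(100 * s):
        i = int(rng.integers(0, s))
        partner = i + 1 if i % 2 == 0 else i - 1
        ones = np.flatnonzero(occ[i])
        free = np.flatnonzero(~occ[i] & ~occ[partner])
        if ones.size == 0 or free.size == 0:
            continue
        a = int(rng.choice(ones))
        b = int(rng.choice(free))
        if occ[:, a].sum() <= 1:  # keep every site occupied
            continue
        occ[i, a], occ[i, b] = False, True
        candidate = _top_ca_singular_value(occ)
        if candidate <= current:
            current = candidate
        else:
            occ[i, a], occ[i, b] = True, False
    return occ


def _random(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.random((spec.n_species, spec.n_sites)) < spec.fill


def _clementsian(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    """Block-diagonal compartments: coincident range boundaries."""
    s, n, k = spec.n_species, spec.n_sites, spec.n_compartments
    occ = np.zeros((s, n), dtype=bool)
    site_edges = np.cumsum([0] + _split_sizes(n, k))
    sp_edges = np.cumsum([0] + _split_sizes(s, k))
    for c in range(k):
        occ[sp_edges[c] : sp_edges[c + 1], site_edges[c] : site_edges[c + 1]] = True
    return occ


def _gleasonian(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    """Contiguous ranges of random width at random positions (idiosyncratic).

    Widths span roughly 20-45% of the gradient: wide enough that range
    overlap produces clear positive turnover, narrow enough that range
    boundaries stay idiosyncratic rather than piling up at the axis ends.
    A draw only counts as the idealized pattern when its realized range
    boundaries are neither clumped nor evenly spaced (Morisita chi-square
    p >= 0.25 in the built order), so draws that happen to realize another
    structure are redrawn.
    """
    from .ems import _boundary_counts_array, morisita_boundary_index

    s, n = spec.n_species, spec.n_sites
    lo = max(2, n // 5)
    hi = max(lo + 1, round(0.45 * n))
    for _ in range(500):
        occ = np.zeros((s, n), dtype=bool)
        widths = rng.integers(lo, hi + 1, size=s)
        starts = rng.integers(0, n - widths + 1)
        for i in range(s):
            occ[i, starts[i] : starts[i] + widths[i]] = True
        if not occ.any(axis=0).all():
            continue
        if morisita_boundary_index(_boundary_counts_array(occ)).p >= 0.25:
            return occ
    raise RuntimeError("could not realize an idiosyncratic-range pattern")


def _evenly_spaced(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    """Equal-width contiguous ranges with maximally staggered boundaries."""
    s, n = spec.n_species, spec.n_sites
    width = max(2, round(n / 3))
    starts = np.rint(np.linspace(0, n - width, s)).astype(int)
    occ = np.zeros((s, n), dtype=bool)
    for i, st in enumerate(starts):
        occ[i, st : st + width] = True
    return occ


def _nested_widths(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    s, n = spec.n_species, spec.n_sites
    mode = spec.kind.removeprefix("nested_")
    if mode == "clumped":
        k = min(4, n)
        levels = np.rint(np.linspace(n / k, n, k)).astype(int)
        widths = np.repeat(levels, _split_sizes(s, k))
    elif mode == "random":
        # like the idiosyncratic-range generator, a draw whose realized loss
        # boundaries happen to be clumped or evenly spaced is redrawn
        from .ems import morisita_boundary_index

        for _ in range(500):
            widths = rng.integers(1, n + 1, size=s)
            widths[0] = n  # keep every site occupied
            counts = np.bincount(widths - 1, minlength=n)
            if morisita_boundary_index(counts).p >= 0.25:
                break
        else:
            raise RuntimeError("could not realize random species loss")
    else:  # evenly_spaced loss boundaries
        widths = np.rint(np.linspace(1, n, s)).astype(int)
    return np.sort(widths)[::-1]


def _nested(spec: StructureSpec, rng: np.random.Generator) -> np.ndarray:
    """Nested subsets: ranges share the rich end, widths set the loss boundaries."""
    widths = _nested_widths(spec, rng)
    occ = np.zeros((spec.n_species, spec.n_sites), dtype=bool)
    for i, w in enumerate(widths):
        occ[i, :w] = True
    return occ


_BUILDERS = {
    "checkerboard": _checkerboard,
    "random": _random,
    "clementsian": _clementsian,
    "gleasonian": _gleasonian,
    "evenly_spaced": _evenly_spaced,
    "nested_clumped": _nested,
    "nested_random": _nested,
    "nested_evenly_spaced": _nested,
}


def make_structure(spec: StructureSpec) -> IncidenceMatrix:
    """Generate an incidence matrix with the requested idealized structure.

    The ideal-order matrix is built, each cell is flipped with probability
    ``spec.noise``, and rows and columns are randomly permuted before
    returning (so ordination, not the generator, must recover the order).
    Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    occ = _BUILDERS[spec.kind](spec, rng)
    if spec.noise > 0:
        occ = occ ^ (rng.random(occ.shape) < spec.noise)
    occ = occ[rng.permutation(spec.n_species)][:, rng.permutation(spec.n_sites)]
    species = [f"sp{i + 1:03d}" for i in range(spec.n_species)]
    sites = [f"site{j + 1:02d}" for j in range(spec.n_sites)]
    return IncidenceMatrix(occ, species, sites, "total")


# ---------------------------------------------------------------------------
# toy rasters


@dataclass(frozen=True)
class SceneSpec:
    """Declarative toy raster: background plus rectangles, later ones on top."""

    nrows: int
    ncols: int
    cell_size: float = 30.0
    background: int = 2  # grassland
    regions: tuple[tuple[int, int, int, int, int], ...] = ()  # (code, r0, c0, h, w)
    speckle: tuple[int, float] | None = None  # (code, density)
    seed: int | None = None

    def __post_init__(self) -> None:
        for code, r0, c0, h, w in self.regions:
            if not (0 <= r0 and 0 <= c0 and r0 + h <= self.nrows and c0 + w <= self.ncols):
                raise ValueError(f"region {(code, r0, c0, h, w)} out of bounds")


def make_scene(spec: SceneSpec) -> LandscapeRaster:
    """Build the raster: deterministic from the region list; speckle under seed."""
    grid = np.full((spec.nrows, spec.ncols), spec.background, dtype=int)
    for code, r0, c0, h, w in spec.regions:
        grid[r0 : r0 + h, c0 : c0 + w] = code
    if spec.speckle is not None:
        code, density = spec.speckle
        rng = np.random.default_rng(spec.seed)
        grid[rng.random(grid.shape) < density] = code
    return LandscapeRaster(grid, spec.cell_size, class_names=dict(DEFAULT_CLASS_NAMES))


# ---------------------------------------------------------------------------
# published frequency/trait table


_TABLE1 = "table1_woody_species.csv"
N_SITES_TABLE1 = 32


def _load_table1() -> pd.DataFrame:
    with resources.files("emscape.data").joinpath(_TABLE1).open() as fh:
        return pd.read_csv(fh)


def table1_fixture() -> tuple[list[SpeciesRecord], pd.DataFrame]:
    """The transcribed published frequency and trait table.

    Returns the species trait records and a DataFrame with one row per
    species: family, species, growth form, origin, priority flag, and
    AF/RF/CRF for the total, adult and juvenile layers over the 32
    permanent monitoring sites. RF is rounded half-up to integer percent;
    CRF is the running sum of unrounded RF down the total-AF order.
    """
    df = _load_table1()
    records = [
        SpeciesRecord(
            name=r.species,
            family=r.family,
            growth_form=r.growth_form,
            origin=r.origin,
            conservation_priority=bool(r.priority),
            dispersal=r.dispersal,
        )
        for r in df.itertuples()
    ]
    out = df.copy()
    for layer in ("total", "adult", "juvenile"):
        af = out[f"AF_{layer}"].to_numpy()
        rf = 100.0 * af / N_SITES_TABLE1
        out[f"RF_{layer}"] = [round_half_up(x) for x in rf]
        out[f"CRF_{layer}"] = np.cumsum(rf)
    cols = ["family", "species", "growth_form", "origin", "priority", "dispersal"]
    for layer in ("total", "adult", "juvenile"):
        cols += [f"AF_{layer}", f"RF_{layer}", f"CRF_{layer}"]
    return records, out[cols]
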