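"""Site-by-species incidence matrices and the frequency/richness accounting.

The central container is :class:`IncidenceMatrix`: a boolean species x site
matrix tagged with an age class (``adult``: dbh >= 5 cm, ``juvenile``:
dbh < 5 cm, or ``total`` = union of both layers). Rows are species, columns
are sites, everywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AGE_CLASSES = ("adult", "juvenile", "total")
GROWTH_FORMS = ("tree", "shrub", "both", "mistletoe", "liana")
ORIGINS = ("native", "exotic")
DISPERSAL_MODES = ("zoochore", "anemochore", "autochore", "unknown")

__all__ = [
    "SpeciesRecord",
    "IncidenceMatrix",
    "read_incidence_csv",
    "write_incidence_csv",
    "merge_age_classes",
    "frequency_table",
    "count_exclusive_species",
    "exclusive_counts_from_frequencies",
    "taxon_counts",
    "richness_summary",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf.

    Matches the rounding of the printed relative frequencies
    (31/32 -> 97, 30/32 -> 94, 29/32 -> 91).
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SpeciesRecord:
    """Trait annotation for one woody species (one Table-1-style row)."""

    name: str
    family: str
    growth_form: str = "tree"
    origin: str = "native"
    conservation_priority: bool = False
    dispersal: str = "unknown"

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("species name must be nonempty")
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form {self.growth_form!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.dispersal not in DISPERSAL_MODES:
            raise ValueError(f"unknown dispersal mode {self.dispersal!r}")

    @property
    def genus(self) -> str:
        return self.name.split()[0]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class IncidenceMatrix:
    """Boolean species x site occurrence matrix for one age class."""

    occupancy: np.ndarray
    species_ids: list[str]
    site_ids: list[str]
    age_class: str = "total"

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.species_ids = [str(s) for s in self.species_ids]
        self.site_ids = [str(s) for s in self.site_ids]
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be 2-D (species x sites)")
        if self.occupancy.shape != (len(self.species_ids), len(self.site_ids)):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.site_ids)} sites"
            )
        _check_unique(self.species_ids, "species")
        _check_unique(self.site_ids, "site")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class must be one of {AGE_CLASSES}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def species_frequencies(self) -> np.ndarray:
        """Absolute frequency (number of occupied sites) per species."""
        return self.occupancy.sum(axis=1)

    def site_richness(self) -> np.ndarray:
        """Species richness per site."""
        return self.occupancy.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy.astype(int), index=self.species_ids, columns=self.site_ids
        )

    def drop_empty(self) -> tuple["IncidenceMatrix", list[str], list[str]]:
        """Drop all-absent species rows and all-empty site columns.

        Returns the reduced matrix plus the lists of dropped ids.
        """
        keep_sp = self.occupancy.any(axis=1)
        keep_si = self.occupancy.any(axis=0)
        dropped_sp = [s for s, k in zip(self.species_ids, keep_sp) if not k]
        dropped_si = [s for s, k in zip(self.site_ids, keep_si) if not k]
        if not dropped_sp and not dropped_si:
            return self, [], []
        sub = IncidenceMatrix(
            self.occupancy[np.ix_(keep_sp, keep_si)],
            [s for s, k in zip(self.species_ids, keep_sp) if k],
            [s for s, k in zip(self.site_ids, keep_si) if k],
            self.age_class,
        )
        return sub, dropped_sp, dropped_si

    def reorder(self, species_order: Sequence[int], site_order: Sequence[int]) -> "IncidenceMatrix":
        sp = list(species_order)
        si = list(site_order)
        return IncidenceMatrix(
            self.occupancy[np.ix_(sp, si)],
            [self.species_ids[i] for i in sp],
            [self.site_ids[j] for j in si],
            self.age_class,
        )


def read_incidence_csv(path: str | Path, age_class: str = "total") -> IncidenceMatrix:
    """Read an incidence CSV: header of site ids, first column species names, cells 0/1."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a species column plus at least one site column")
    species = df.iloc[:, 0].tolist()
    sites = [str(c) for c in df.columns[1:]]
    cells = df.iloc[:, 1:].to_numpy()
    occ = np.zeros(cells.shape, dtype=bool)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            v = str(cells[i, j]).strip()
            if v not in ("0", "1"):
                raise ValueError(
                    f"non-binary value {v!r} at (species {species[i]!r}, site {sites[j]!r})"
                )
            occ[i, j] = v == "1"
    return IncidenceMatrix(occ, species, sites, age_class)


def write_incidence_csv(m: IncidenceMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "species"
    df.to_csv(path)


def merge_age_classes(adult: IncidenceMatrix, juvenile: IncidenceMatrix) -> IncidenceMatrix:
    """Union of the adult and juvenile layers ('total' age class).

    Site sets must be identical (site order taken from the adult matrix);
    species are the union, adult order first then juvenile-only species.
    """
    if set(adult.site_ids) != set(juvenile.site_ids):
        raise ValueError("adult and juvenile matrices cover different site sets")
    site_ids = list(adult.site_ids)
    juv_cols = [juvenile.site_ids.index(s) for s in site_ids]
    juv_occ = juvenile.occupancy[:, juv_cols]
    species = list(adult.species_ids)
    extra = [s for s in juvenile.species_ids if s not in set(adult.species_ids)]
    species += extra
    occ = np.zeros((len(species), len(site_ids)), dtype=bool)
    occ[: adult.n_species] = adult.occupancy
    juv_index = {s: i for i, s in enumerate(juvenile.species_ids)}
    for row, name in enumerate(species):
        if name in juv_index:
            occ[row] |= juv_occ[juv_index[name]]
    return IncidenceMatrix(occ, species, site_ids, "total")


def frequency_table(m: IncidenceMatrix) -> pd.DataFrame:
    """AF/RF/CRF accounting in the layout of the published frequency table.

    AF is the number of occupied sites; RF = 100*AF/N_sites, reported rounded
    half-up to integer percent but kept unrounded for CRF; CRF is the running
    sum of unrounded RF down the AF-descending order (ties keep input order).
    """
    if m.n_sites < 1:
        raise ValueError("need at least one site")
    af = m.species_frequencies()
    order = np.argsort(-af, kind="stable")
    af_sorted = af[order]
    rf = 100.0 * af_sorted / m.n_sites
    return pd.DataFrame(
        {
            "species": [m.species_ids[i] for i in order],
            "AF": af_sorted,
            "RF": np.array([round_half_up(x) for x in rf]),
            "RF_unrounded": rf,
            "CRF": np.cumsum(rf),
        }
    )


def count_exclusive_species(
    adult: IncidenceMatrix, juvenile: IncidenceMatrix
) -> dict[str, int]:
    """Age-class-exclusive and single-site species counts.

    Keys: ``adult_only`` (present as adult, never as juvenile),
    ``juvenile_only`` (the regeneration-layer-only species), and the
    single-site splits ``single_site_both`` / ``single_site_adult`` /
    ``single_site_juvenile`` for species whose total range is one site.
    """
    if set(adult.site_ids) != set(juvenile.site_ids):
        raise ValueError("adult and juvenile matrices cover different site sets")
    total = merge_age_classes(adult, juvenile)
    a_af = {s: int(f) for s, f in zip(adult.species_ids, adult.species_frequencies())}
    j_af = {s: int(f) for s, f in zip(juvenile.species_ids, juvenile.species_frequencies())}
    t_af = {s: int(f) for s, f in zip(total.species_ids, total.species_frequencies())}
    return _exclusive_counts(
        {s: (t_af[s], a_af.get(s, 0), j_af.get(s, 0)) for s in total.species_ids}
    )


def _exclusive_counts(af: Mapping[str, tuple[int, int, int]]) -> dict[str, int]:
    out = dict.fromkeys(
        (
            "adult_only",
            "juvenile_only",
            "single_site_both",
            "single_site_adult",
            "single_site_juvenile",
        ),
        0,
    )
    for t, a, j in af.values():
        if a >= 1 and j == 0:
            out["adult_only"] += 1
        if j >= 1 and a == 0:
            out["juvenile_only"] += 1
        if t == 1:
            if a >= 1 and j >= 1:
                out["single_site_both"] += 1
            elif a >= 1:
                out["single_site_adult"] += 1
            else:
                out["single_site_juvenile"] += 1
    return out


def exclusive_counts_from_frequencies(freq: pd.DataFrame) -> dict[str, int]:
    """Same accounting from per-species AF columns (AF_total, AF_adult, AF_juvenile).

    A species with total AF = 1 recorded in both layers is necessarily
    recorded in both layers at that single site, so frequencies suffice.
    """
    return _exclusive_counts(
        {
            str(r.species): (int(r.AF_total), int(r.AF_adult), int(r.AF_juvenile))
            for r in freq.itertuples()
        }
    )


def taxon_counts(records: Iterable[SpeciesRecord]) -> dict[str, object]:
    """Distinct species/genus/family counts and the native percentage."""
    recs = list(records)
    if not recs:
        raise ValueError("no species records")
    names = [r.name for r in recs]
    _check_unique(names, "species")
    n = len(names)
    native = sum(1 for r in recs if r.origin == "native")
    return {
        "species": n,
        "genera": len({r.genus for r in recs}),
        "families": len({r.family for r in recs}),
        "pct_native": round_half_up(100.0 * native / n),
        "pct_native_unrounded": 100.0 * native / n,
    }


def richness_summary(
    m: IncidenceMatrix, groups: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-group min/max/mean/sample-sd of site richness.

    ``groups`` maps site id -> group label (e.g. forest type); omitted, all
    sites form one group ``all``. The sd uses denominator n-1 and is NaN for
    single-site groups.
    """
    if groups is None:
        groups = {s: "all" for s in m.site_ids}
    missing = [s for s in m.site_ids if s not in groups]
    if missing:
        raise ValueError(f"sites without group label: {missing}")
    rich = m.site_richness()
    df = pd.DataFrame({"richness": rich, "group": [groups[s] for s in m.site_ids]})
    out = df.groupby("group")["richness"].agg(
        min="min", max="max", mean="mean", sd=lambda x: x.std(ddof=1)
    )
    return out.reset_index()
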