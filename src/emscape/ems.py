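"""Elements of metacommunity structure (EMS).

The analysis follows the classic three-step procedure on a site-by-species
incidence matrix:

1. **Coherence** — ordinate the matrix by reciprocal averaging
   (correspondence analysis) and count *embedded absences*: 0-cells lying
   between the first and last presence of each species (and of each site)
   along the ordinated axis. Fewer absences than a null expectation means a
   coherent gradient ("positive" coherence); more means checkerboard-like
   mutual exclusion.
2. **Turnover** — on the range-filled ordinated matrix, count mutual
   *replacements*: species pairs x site pairs where each species is present
   at exactly one (different) site of the pair. More replacements than null
   indicates gradient turnover, fewer indicates nested subsets.
3. **Boundary clumping** — Morisita's index of dispersion on the tallies of
   species range boundaries per site, tested against 1 with a chi-square
   statistic (df = n_sites - 1). Clumped boundaries (MI > 1) indicate
   Clementsian compartments, hyperdispersed boundaries (MI < 1) evenly
   spaced ranges.

Null matrices fix each site's observed richness and draw that many species
equiprobably from the pool ("random 0"), and every null replicate is
re-ordinated before its statistics are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .incidence import IncidenceMatrix

logger = logging.getLogger(__name__)

STRUCTURE_LABELS = (
    "checkerboard",
    "random",
    "clementsian",
    "gleasonian",
    "evenly_spaced",
    "nested_clumped",
    "nested_random",
    "nested_evenly_spaced",
    "quasi_clementsian",
    "quasi_gleasonian",
    "quasi_evenly_spaced",
    "quasi_nested_clumped",
    "quasi_nested_random",
    "quasi_nested_evenly_spaced",
)

__all__ = [
    "DegenerateOrdinationError",
    "NullModelConfig",
    "OrdinationResult",
    "EMSStatistics",
    "EMSResult",
    "STRUCTURE_LABELS",
    "reciprocal_averaging",
    "embedded_absences",
    "fill_ranges",
    "replacements",
    "boundary_counts",
    "loss_boundary_counts",
    "morisita_boundary_index",
    "null_matrices",
    "montecarlo_test",
    "classify_structure",
    "ems_analyze",
    "coherence_rejection_rate",
]


class DegenerateOrdinationError(ValueError):
    """The first non-trivial correspondence axis does not exist."""


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for the random-0 Monte-Carlo null."""

    scheme: Literal["random0"] = "random0"
    iterations: int = 1000
    seed: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.scheme != "random0":
            raise ValueError(f"unknown null scheme {self.scheme!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class OrdinationResult:
    """First-axis reciprocal-averaging scores and the re-ordered matrix."""

    site_scores: np.ndarray
    species_scores: np.ndarray
    site_order: np.ndarray
    species_order: np.ndarray
    ordinated: IncidenceMatrix


@dataclass
class MorisitaResult:
    index: float
    statistic: float
    df: int
    p: float


@dataclass
class EMSStatistics:
    embedded_absences_obs: int
    embedded_absences_null_mean: float
    embedded_absences_null_sd: float
    embedded_absences_z: float
    embedded_absences_p: float
    replacements_obs: int
    replacements_null_mean: float
    replacements_null_sd: float
    replacements_z: float
    replacements_p: float
    morisita: MorisitaResult
    loss_morisita: MorisitaResult
    n_null: int


@dataclass
class EMSResult:
    statistics: EMSStatistics
    label: str
    ordination: OrdinationResult
    site_scores: pd.DataFrame
    dropped_species: list[str] = field(default_factory=list)
    dropped_sites: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ordination


def _first_axis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First non-trivial correspondence-analysis axis of a binary matrix.

    Returns (species_scores, site_scores) in standard coordinates: the
    site scores have weighted mean 0 (weights = site totals) and are the
    leading non-trivial eigenvector of the reciprocal-averaging operator.
    Sign is NOT fixed here.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise DegenerateOrdinationError("degenerate ordination: need >= 2 species and >= 2 sites")
    total = x.sum()
    r = x.sum(axis=1)
    c = x.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise DegenerateOrdinationError("degenerate ordination: empty row or column")
    p = x / total
    pr = r / total
    pc = c / total
    resid = (p - np.outer(pr, pc)) / np.sqrt(np.outer(pr, pc))
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    if s[0] <= 1e-10:
        raise DegenerateOrdinationError("degenerate ordination: matrix has no non-trivial axis")
    species = u[:, 0] / np.sqrt(pr)
    sites = vt[0] / np.sqrt(pc)
    return species, sites


def reciprocal_averaging(m: IncidenceMatrix) -> OrdinationResult:
    """Ordinate an incidence matrix by reciprocal averaging.

    Site and species scores are the first non-trivial correspondence axis;
    the sign is fixed so that site scores correlate non-negatively with the
    original column order (ties resolved so the first site's score is not
    greater than the last's). Equal scores keep input order (stable sort).
    """
    species_scores, site_scores = _first_axis(m.occupancy)
    idx = np.arange(len(site_scores), dtype=float)
    slope = np.dot(site_scores - site_scores.mean(), idx - idx.mean())
    if slope < 0 or (slope == 0 and site_scores[0] > site_scores[-1]):
        site_scores = -site_scores
        species_scores = -species_scores
    site_order = np.argsort(site_scores, kind="stable")
    species_order = np.argsort(species_scores, kind="stable")
    return OrdinationResult(
        site_scores=site_scores,
        species_scores=species_scores,
        site_order=site_order,
        species_order=species_order,
        ordinated=m.reorder(species_order, site_order),
    )


# ---------------------------------------------------------------------------
# counting statistics (all defined on the ordinated boolean matrix)


def _row_spans(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """first, last, rowsum for rows with at least one presence."""
    present = a.any(axis=1)
    first = a.argmax(axis=1)
    last = a.shape[1] - 1 - a[:, ::-1].argmax(axis=1)
    return first[present], last[present], a[present].sum(axis=1)


def _embedded_absences_array(a: np.ndarray, mode: str = "both") -> int:
    total = 0
    f, l, s = _row_spans(a)
    total += int(((l - f + 1) - s).sum())
    if mode == "both":
        f, l, s = _row_spans(a.T)
        total += int(((l - f + 1) - s).sum())
    return total


def embedded_absences(o: OrdinationResult, mode: Literal["both", "rows"] = "both") -> int:
    """Count of embedded absences in the ordinated matrix.

    ``mode='both'`` (default) sums gaps inside species ranges along sites and
    gaps inside site columns along species; ``'rows'`` counts species ranges
    only.
    """
    return _embedded_absences_array(o.ordinated.occupancy, mode)


def _fill_ranges_array(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    f, l, _ = _row_spans(a)
    rows = np.flatnonzero(a.any(axis=1))
    for i, fi, li in zip(rows, f, l):
        out[i, fi : li + 1] = True
    return out


def fill_ranges(o: OrdinationResult) -> IncidenceMatrix:
    """Make every species range contiguous along the ordinated site order."""
    m = o.ordinated
    return IncidenceMatrix(
        _fill_ranges_array(m.occupancy), list(m.species_ids), list(m.site_ids), m.age_class
    )


def _replacements_array(filled: np.ndarray) -> int:
    f = filled.astype(np.int64)
    # a[i, k] = number of sites where species i present and k absent
    a = f @ (1 - f).T
    return int((a * a.T).sum() // 2)


def replacements(o: OrdinationResult) -> int:
    """Mutual species replacements between site pairs, on the filled matrix.

    For every unordered species pair and unordered site pair, the pair of
    pairs counts when each species is present at exactly one, different,
    site of the site pair.
    """
    return _replacements_array(_fill_ranges_array(o.ordinated.occupancy))


def _boundary_counts_array(filled: np.ndarray) -> np.ndarray:
    n = filled.shape[1]
    f, l, _ = _row_spans(filled)
    # a one-site range has first == last and contributes 2 counts there
    return np.bincount(f, minlength=n) + np.bincount(l, minlength=n)


def boundary_counts(o: OrdinationResult) -> np.ndarray:
    """Per-site tallies of species range endpoints (both ends of each range).

    Each species range contributes one count at the site where it starts and
    one where it ends; a single-site range contributes both counts at its
    site, so the tallies always sum to twice the number of occupied species.
    """
    return _boundary_counts_array(_fill_ranges_array(o.ordinated.occupancy))


def _loss_boundary_counts_array(filled: np.ndarray) -> np.ndarray:
    n = filled.shape[1]
    f, l, _ = _row_spans(filled)
    richness = filled.sum(axis=0).astype(float)
    idx = np.arange(n, dtype=float)
    slope = np.dot(richness - richness.mean(), idx - idx.mean())
    # loss side = the end of each range pointing toward species-poorer sites
    ends = l if slope <= 0 else f
    return np.bincount(ends, minlength=n)


def loss_boundary_counts(o: OrdinationResult) -> np.ndarray:
    """Per-site tallies of species *loss* boundaries.

    Only the range endpoint on the species-poorer side of the ordination
    axis is tallied (one count per species). The poorer side is read from
    the site-richness gradient, so the tallies do not depend on the global
    orientation of the axis. Used for the nested sub-classification, where
    every range shares the rich-side endpoint and only the loss boundaries
    discriminate clumped, random, and evenly spaced species loss.
    """
    return _loss_boundary_counts_array(_fill_ranges_array(o.ordinated.occupancy))


def morisita_boundary_index(counts: Sequence[int] | np.ndarray) -> MorisitaResult:
    """Morisita's index of dispersion for boundary tallies, with chi-square p.

    MI = n * sum(b_j (b_j - 1)) / (B (B - 1)) for tallies b_j over n sites,
    B = sum(b_j). The chi-square statistic sum((b_j - B/n)^2 / (B/n)) with
    df = n - 1 is referred to its upper tail when MI >= 1 (clumping) and its
    lower tail when MI < 1 (hyperdispersion).
    """
    b = np.asarray(counts, dtype=float)
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 sites")
    big_b = b.sum()
    if big_b < 2:
        raise ValueError("too few boundaries")
    mi = n * (b * (b - 1)).sum() / (big_b * (big_b - 1))
    expected = big_b / n
    stat = float(((b - expected) ** 2 / expected).sum())
    df = n - 1
    p = float(sps.chi2.sf(stat, df) if mi >= 1 else sps.chi2.cdf(stat, df))
    return MorisitaResult(index=float(mi), statistic=stat, df=df, p=p)


# ---------------------------------------------------------------------------
# null model


def _null_occupancy(richness: np.ndarray, n_species: int, rng: np.random.Generator) -> np.ndarray:
    """One random-0 matrix: fixed column richness, equiprobable species."""
    out = np.zeros((n_species, richness.size), dtype=bool)
    for j, k in enumerate(richness):
        out[rng.choice(n_species, size=k, replace=False), j] = True
    return out


def null_matrices(m: IncidenceMatrix, cfg: NullModelConfig) -> Iterator[IncidenceMatrix]:
    """Stream of random-0 null matrices for the observed matrix.

    Every null fixes each site's richness at its observed value and fills
    the column with that many species drawn uniformly without replacement
    from the observed species pool. Reproducible under ``cfg.seed``.
    """
    richness = m.site_richness()
    if (richness > m.n_species).any():
        raise ValueError("site richness exceeds species pool")
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.iterations):
        yield IncidenceMatrix(
            _null_occupancy(richness, m.n_species, rng),
            list(m.species_ids),
            list(m.site_ids),
            m.age_class,
        )


def montecarlo_test(
    observed: float,
    nulls: Sequence[float] | np.ndarray,
    exact: bool = False,
) -> dict[str, float]:
    """Two-tailed z test of an observed statistic against Monte-Carlo nulls.

    z = (obs - null mean) / null sd (sample sd), p = 2 (1 - Phi(|z|)).
    For coherence a *negative* z (fewer embedded absences than chance) is the
    "positive coherence" branch of the decision tree; for turnover a positive
    z means more replacements than chance. With ``exact=True`` the p-value is
    instead the two-sided permutation p ``2 * min(P(null <= obs),
    P(null >= obs))`` with the +1 continuity correction, capped at 1.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least 2 null values")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: all null values identical")
    z = (observed - mean) / sd
    if exact:
        n = nulls.size
        lo = (np.count_nonzero(nulls <= observed) + 1) / (n + 1)
        hi = (np.count_nonzero(nulls >= observed) + 1) / (n + 1)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {"mean": mean, "sd": sd, "z": float(z), "p": p}


# ---------------------------------------------------------------------------
# classification


def _boundary_sublabel(mor: MorisitaResult, alpha: float) -> str:
    if mor.p < alpha:
        return "clementsian" if mor.index > 1 else "evenly_spaced"
    return "gleasonian"


def _nested_sublabel(mor: MorisitaResult, alpha: float) -> str:
    if mor.p < alpha:
        return "nested_clumped" if mor.index > 1 else "nested_evenly_spaced"
    return "nested_random"


def classify_structure(stats: EMSStatistics, alpha: float = 0.05) -> str:
    """Walk the three-step decision tree to a metacommunity structure label.

    Coherence not significant -> random; significant with more embedded
    absences than chance -> checkerboard. Otherwise turnover decides:
    significantly positive -> Clementsian / Gleasonian / evenly spaced by
    boundary clumping; significantly negative -> a nested structure with
    clumped / random / evenly spaced species loss; non-significant ->
    the corresponding quasi structure, chosen by the sign of the turnover z.
    """
    if stats.embedded_absences_p >= alpha:
        return "random"
    if stats.embedded_absences_z > 0:
        return "checkerboard"
    positive_turnover = stats.replacements_z > 0
    if stats.replacements_p < alpha:
        if positive_turnover:
            return _boundary_sublabel(stats.morisita, alpha)
        return _nested_sublabel(stats.loss_morisita, alpha)
    if positive_turnover:
        return "quasi_" + _boundary_sublabel(stats.morisita, alpha)
    return "quasi_" + _nested_sublabel(stats.loss_morisita, alpha)


# ---------------------------------------------------------------------------
# the full analysis


def _ordinate_array(x: np.ndarray) -> np.ndarray:
    """Reorder a boolean matrix by its first CA axis (fast path, no metadata)."""
    species_scores, site_scores = _first_axis(x)
    return x[np.ix_(np.argsort(species_scores, kind="stable"), np.argsort(site_scores, kind="stable"))]


def _null_statistics(
    m: IncidenceMatrix,
    cfg: NullModelConfig,
    rng: np.random.Generator,
    want_replacements: bool = True,
    mode: str = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """Embedded-absence and replacement counts over re-ordinated nulls.

    Nulls whose reduced matrix is degenerate (no non-trivial axis) are
    redrawn; this is vanishingly rare away from pathological margins.
    """
    richness = m.site_richness()
    ea = np.empty(cfg.iterations)
    rep = np.empty(cfg.iterations)
    draws = 0
    for i in range(cfg.iterations):
        while True:
            draws += 1
            if draws > 50 * cfg.iterations:
                raise DegenerateOrdinationError(
                    "null model keeps producing degenerate matrices"
                )
            x = _null_occupancy(richness, m.n_species, rng)
            x = x[x.any(axis=1)]  # a species can go undrawn; columns never empty
            try:
                ordd = _ordinate_array(x)
            except DegenerateOrdinationError:
                continue
            break
        ea[i] = _embedded_absences_array(ordd, mode)
        if want_replacements:
            rep[i] = _replacements_array(_fill_ranges_array(ordd))
    return ea, rep


def ems_analyze(
    m: IncidenceMatrix,
    cfg: NullModelConfig | None = None,
    coords: pd.DataFrame | None = None,
    mode: Literal["both", "rows"] = "both",
    exact_p: bool = False,
) -> EMSResult:
    """Run the complete EMS analysis on one incidence matrix.

    Empty species rows and site columns are dropped (and logged) before
    ordination. The observed matrix is ordinated by reciprocal averaging;
    embedded absences, replacements, and boundary clumping are computed on
    it; ``cfg.iterations`` random-0 nulls are generated, each re-ordinated
    before counting; and the structure label is read off the decision tree
    at ``cfg.alpha``.

    ``coords``, if given, is a DataFrame indexed by site id with columns
    ``latitude`` and ``longitude`` merged into the returned per-site
    first-axis score table.
    """
    cfg = cfg or NullModelConfig()
    reduced, dropped_sp, dropped_si = m.drop_empty()
    if dropped_sp:
        logger.info("dropping %d empty species rows: %s", len(dropped_sp), dropped_sp)
    if dropped_si:
        logger.info("dropping %d empty site columns: %s", len(dropped_si), dropped_si)

    ordn = reciprocal_averaging(reduced)
    ea_obs = embedded_absences(ordn, mode)
    filled = _fill_ranges_array(ordn.ordinated.occupancy)
    rep_obs = _replacements_array(filled)
    mor = morisita_boundary_index(_boundary_counts_array(filled))
    loss_mor = morisita_boundary_index(_loss_boundary_counts_array(filled))

    rng = np.random.default_rng(cfg.seed)
    ea_null, rep_null = _null_statistics(reduced, cfg, rng, mode=mode)
    ea_test = montecarlo_test(ea_obs, ea_null, exact=exact_p)
    rep_test = montecarlo_test(rep_obs, rep_null, exact=exact_p)

    stats = EMSStatistics(
        embedded_absences_obs=ea_obs,
        embedded_absences_null_mean=ea_test["mean"],
        embedded_absences_null_sd=ea_test["sd"],
        embedded_absences_z=ea_test["z"],
        embedded_absences_p=ea_test["p"],
        replacements_obs=rep_obs,
        replacements_null_mean=rep_test["mean"],
        replacements_null_sd=rep_test["sd"],
        replacements_z=rep_test["z"],
        replacements_p=rep_test["p"],
        morisita=mor,
        loss_morisita=loss_mor,
        n_null=cfg.iterations,
    )
    label = classify_structure(stats, cfg.alpha)

    scores = pd.DataFrame(
        {"ID": reduced.site_ids, "score": ordn.site_scores}
    )
    if coords is not None:
        scores = scores.merge(
            coords.reset_index().rename(columns={coords.index.name or "index": "ID"}),
            on="ID",
            how="left",
        )
        front = [c for c in ("ID", "latitude", "longitude") if c in scores.columns]
        scores = scores[front + [c for c in scores.columns if c not in front]]
    return EMSResult(
        statistics=stats,
        label=label,
        ordination=ordn,
        site_scores=scores,
        dropped_species=dropped_sp,
        dropped_sites=dropped_si,
    )


# ---------------------------------------------------------------------------
# calibration utility


def coherence_rejection_rate(
    richness: Sequence[int] | np.ndarray,
    n_species: int,
    reps: int = 10_000,
    iterations: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "both",
) -> float:
    """Type-I error of the coherence test on matrices drawn from random 0.

    Draws ``reps`` observed matrices from the random-0 null itself (given a
    site-richness template), runs the coherence z-test against ``iterations``
    fresh nulls each, and returns the two-tailed rejection rate at ``alpha``.
    Skips the turnover/boundary machinery for speed.
    """
    richness = np.asarray(richness, dtype=int)
    rng = np.random.default_rng(seed)
    crit = sps.norm.isf(alpha / 2.0)
    rejections = 0
    n_valid = 0
    while n_valid < reps:
        x = _null_occupancy(richness, n_species, rng)
        x = x[x.any(axis=1)]
        try:
            ea_obs = _embedded_absences_array(_ordinate_array(x), mode)
        except DegenerateOrdinationError:
            continue
        ea_null = np.empty(iterations)
        i = 0
        guard = 0
        while i < iterations:
            guard += 1
            if guard > 50 * iterations:
                raise DegenerateOrdinationError("degenerate null stream")
            y = _null_occupancy(richness, n_species, rng)
            y = y[y.any(axis=1)]
            try:
                ea_null[i] = _embedded_absences_array(_ordinate_array(y), mode)
            except DegenerateOrdinationError:
                continue
            i += 1
        sd = ea_null.std(ddof=1)
        if sd == 0:
            continue
        z = (ea_obs - ea_null.mean()) / sd
        n_valid += 1
        if abs(z) > crit:
            rejections += 1
    return rejections / reps
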