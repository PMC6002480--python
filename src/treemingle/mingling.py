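"""Nearest-neighbour species mingling.

The mingling index of a reference tree is the fraction of its ``k`` nearest
neighbours (default ``k = 4``) that belong to a different species.  For
``k = 4`` it takes the five values 0, 0.25, 0.5, 0.75, 1.  Because trees with
no heterospecific neighbour are typically rare (< 5% of stems in the plots
this package emulates), levels 0 and 0.25 are pooled into a single low-
mingling category for all level-wise summaries, leaving four grouped levels.

The module also provides the two community-level views built on the index:
pairwise rank-sum comparisons of dbh across grouped mingling levels (with a
compact letter display) and a bivariate dbh-by-mingling-level density in
which mingling is treated as a discrete factor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pattern import (
    InsufficientPointsError,
    MarkedPointPattern,
    k_nearest_neighbors,
    neighbor_index_matrix,
)

__all__ = [
    "MinglingSummary",
    "PairwiseTestResult",
    "BivariateDensity",
    "mingling_index",
    "mingling_summary",
    "dbh_by_mingling_test",
    "bivariate_density",
]

logger = logging.getLogger(__name__)

#: Grouped mingling levels for k = 4: {0, 0.25} pooled, then 0.5, 0.75, 1.
GROUPED_LEVEL_LABELS = ("0-0.25", "0.5", "0.75", "1")


def mingling_index(pattern: MarkedPointPattern, i: int, k: int = 4) -> float:
    """Fraction of tree ``i``'s k nearest neighbours of a different species."""
    nn = k_nearest_neighbors(pattern, i, k)
    pos = {tid: p for p, tid in enumerate(pattern.ids)}
    ref = pattern.species[pos[i]]
    return float(np.mean([pattern.species[pos[j]] != ref for j in nn]))


def _grouped_level(m: np.ndarray, k: int) -> np.ndarray:
    """Map raw mingling values onto grouped-level labels."""
    counts = np.rint(m * k).astype(int)
    labels = np.empty(m.shape, dtype=object)
    labels[counts <= 1] = GROUPED_LEVEL_LABELS[0]
    for c, lab in ((2, "0.5"), (3, "0.75"), (4, "1")):
        labels[counts == c] = lab
    return labels


@dataclass(frozen=True)
class MinglingSummary:
    """Per-tree mingling values and grouped-level bookkeeping."""

    m: np.ndarray  # per-tree mingling value in [0, 1]
    k: int
    grouped_level: np.ndarray  # per-tree grouped-level label
    level_counts: dict[str, int]

    @property
    def n(self) -> int:
        return self.m.size

    def to_dataframe(self, pattern: MarkedPointPattern) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": pattern.ids,
                "species": [str(s) for s in pattern.species],
                "dbh": pattern.dbh,
                "mingling": self.m,
                "grouped_level": self.grouped_level,
            }
        )


def mingling_summary(pattern: MarkedPointPattern, k: int = 4) -> MinglingSummary:
    """Mingling index of every tree plus grouped-level counts.

    Every tree serves as a reference, including those near the plot border
    whose neighbour sets may reach outside the window; no nearest-neighbour
    edge correction is applied (a known, documented border bias).
    """
    if pattern.n <= k:
        raise InsufficientPointsError(
            f"need more than k={k} trees, have {pattern.n}"
        )
    nn = neighbor_index_matrix(pattern, k)
    ref = pattern.species[:, None]
    m = (pattern.species[nn] != ref).mean(axis=1)
    grouped = _grouped_level(m, k)
    counts = {
        lab: int(np.sum(grouped == lab)) for lab in _level_labels(k)
    }
    return MinglingSummary(m=m, k=k, grouped_level=grouped, level_counts=counts)


def _level_labels(k: int) -> tuple[str, ...]:
    if k == 4:
        return GROUPED_LEVEL_LABELS
    # generic k: pool the two lowest admissible levels, keep the rest
    fracs = [c / k for c in range(2, k + 1)]
    return (f"0-{1 / k:g}",) + tuple(f"{f:g}" for f in fracs)


@dataclass(frozen=True)
class PairwiseTestResult:
    """Pairwise dbh comparisons across grouped mingling levels."""

    table: pd.DataFrame  # level_a, level_b, statistic, p, p_adj, significant
    letters: dict[str, str]  # compact letter display per level
    medians: dict[str, float]  # median dbh per level
    alpha: float


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value.

    Exact null distribution when both samples have at most 20 observations
    and the combined sample is tie-free; tie-corrected normal approximation
    otherwise.
    """
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _compact_letters(
    levels: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels that are **not** significantly different share at least one
    letter; significantly different levels share none.
    """
    groups: list[set[str]] = [set(levels)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            for drop in (a, b):
                cand = g - {drop}
                if cand and not any(cand <= other for other in groups):
                    groups.append(cand)
    # absorb: drop any group contained in another
    groups = [
        g for g in groups if not any(g < other for other in groups)
    ]
    # stable letter order: sort groups by position of their first level
    order = {lev: i for i, lev in enumerate(levels)}
    groups.sort(key=lambda g: min(order[x] for x in g))
    letters = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in g:
            letters[lev] += letter
    return {lev: "".join(sorted(s)) for lev, s in letters.items()}


def dbh_by_mingling_test(
    pattern: MarkedPointPattern,
    summary: MinglingSummary,
    alpha: float = 0.05,
) -> PairwiseTestResult:
    """Wilcoxon rank-sum comparison of dbh between all grouped-level pairs.

    Raw two-sided p-values are Holm-adjusted across the pairs and the
    adjusted decisions at ``alpha`` are rendered as a compact letter display
    (levels sharing a letter are not significantly different).  Levels with
    fewer than two trees are excluded with a logged warning.
    """
    levels = [
        lab
        for lab in _level_labels(summary.k)
        if summary.level_counts.get(lab, 0) >= 2
    ]
    skipped = [
        lab
        for lab in _level_labels(summary.k)
        if 0 < summary.level_counts.get(lab, 0) < 2
    ]
    for lab in skipped:
        logger.warning("mingling level %s has < 2 trees; excluded from tests", lab)
    dbh_by_level = {
        lab: pattern.dbh[summary.grouped_level == lab] for lab in levels
    }
    rows = []
    for a, b in itertools.combinations(levels, 2):
        u, p = _rank_sum_p(dbh_by_level[a], dbh_by_level[b])
        rows.append({"level_a": a, "level_b": b, "statistic": u, "p": p})
    table = pd.DataFrame(rows, columns=["level_a", "level_b", "statistic", "p"])
    if len(table):
        reject, p_adj, _, _ = multipletests(
            table["p"].to_numpy(), alpha=alpha, method="holm"
        )
        table["p_adj"] = p_adj
        table["significant"] = reject
    else:
        table["p_adj"] = []
        table["significant"] = []
    significant = {
        (r.level_a, r.level_b): bool(r.significant) for r in table.itertuples()
    }
    letters = _compact_letters(levels, significant)
    medians = {lab: float(np.median(v)) for lab, v in dbh_by_level.items()}
    return PairwiseTestResult(
        table=table, letters=letters, medians=medians, alpha=alpha
    )


@dataclass(frozen=True)
class BivariateDensity:
    """Joint density of dbh (continuous) and grouped mingling level (discrete).

    ``density[level, grid]`` integrates over the dbh grid to the level's
    relative frequency, so the full array has total mass ~ 1.
    """

    dbh_grid: np.ndarray
    levels: tuple[str, ...]
    density: np.ndarray  # shape (n_levels, n_grid)
    bandwidth: float

    def total_mass(self) -> float:
        return float(np.trapezoid(self.density, self.dbh_grid, axis=1).sum())

    def mode_dbh(self, level: str) -> float:
        row = self.density[self.levels.index(level)]
        return float(self.dbh_grid[int(np.argmax(row))])

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {"grouped_level": lev, "dbh": d, "density": v}
            for i, lev in enumerate(self.levels)
            for d, v in zip(self.dbh_grid, self.density[i])
        ]
        return pd.DataFrame(recs)


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        return 1.0  # degenerate sample: 1 cm floor keeps the kernel proper
    return 0.9 * scale * n ** (-1 / 5)


def bivariate_density(
    pattern: MarkedPointPattern,
    summary: MinglingSummary,
    bandwidth: float | str = "auto",
    grid_size: int = 256,
) -> BivariateDensity:
    """Gaussian-kernel density of dbh conditional on grouped mingling level.

    Mingling is a five-valued (grouped: four-valued) mark, so a continuous
    two-dimensional kernel is ill-posed; instead each level gets a
    one-dimensional Gaussian kernel density over dbh, weighted by the level's
    relative frequency.  ``bandwidth="auto"`` applies Silverman's rule to the
    pooled dbh sample (one common bandwidth keeps the level profiles
    comparable).
    """
    if pattern.n < 2:
        raise InsufficientPointsError("density needs at least two trees")
    if bandwidth == "auto":
        bw = _silverman_bandwidth(pattern.dbh)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    lo = float(pattern.dbh.min()) - 4 * bw
    hi = float(pattern.dbh.max()) + 4 * bw
    grid = np.linspace(lo, hi, grid_size)
    levels = tuple(
        lab for lab in _level_labels(summary.k) if summary.level_counts.get(lab, 0)
    )
    dens = np.zeros((len(levels), grid_size))
    for li, lab in enumerate(levels):
        vals = pattern.dbh[summary.grouped_level == lab]
        w = vals.size / pattern.n
        z = (grid[None, :] - vals[:, None]) / bw
        dens[li] = w * np.exp(-0.5 * z**2).sum(axis=0) / (
            vals.size * bw * np.sqrt(2 * np.pi)
        )
    return BivariateDensity(
        dbh_grid=grid, levels=levels, density=dens, bandwidth=bw
    )
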