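"""Core domain objects for stem-mapped forest plots.

A plot census is modelled as a marked point pattern: tree stem positions
``(x, y)`` in metres inside a rectangular observation window, each carrying a
species label and a diameter at breast height (dbh, cm).  Everything else in
the package — nearest-neighbour mingling, cumulative mark mingling functions,
null-model envelopes — operates on these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "MarkedPointPattern",
    "SizeClassScheme",
    "CensusFormatError",
    "CensusValidationError",
    "InsufficientPointsError",
    "load_census",
    "save_census",
    "k_nearest_neighbors",
    "translation_weight",
    "classify_size",
]

#: Census threshold: stems below this dbh (cm) are not tagged in the field.
CENSUS_MIN_DBH = 5.0


class CensusFormatError(ValueError):
    """The census table is structurally malformed (missing column, bad value)."""


class CensusValidationError(ValueError):
    """A census row violates a pattern invariant (e.g. lies outside the window)."""


class InsufficientPointsError(ValueError):
    """A query requires more trees than the pattern contains."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window in metres.

    Containment is closed on all four edges: a stem mapped exactly on the
    boundary belongs to the plot.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate window: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @property
    def a(self) -> float:
        """Side length along x (m)."""
        return self.xmax - self.xmin

    @property
    def b(self) -> float:
        """Side length along y (m)."""
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        """Window area (m^2)."""
        return self.a * self.b

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )


@dataclass(frozen=True)
class MarkedPointPattern:
    """Tree stems with species and dbh marks inside a rectangular window.

    Parameters
    ----------
    x, y
        Stem coordinates in metres.
    species
        Species label per stem (non-empty strings).
    dbh
        Diameter at breast height in cm, strictly positive.
    window
        Observation window; every stem must lie inside it (closed edges).
    ids
        Unique integer tree ids.  Default: ``0 .. n-1`` in input order.
    """

    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    dbh: np.ndarray
    window: Window
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x = np.ascontiguousarray(np.asarray(self.x, dtype=float))
        y = np.ascontiguousarray(np.asarray(self.y, dtype=float))
        species = np.asarray(self.species, dtype=object)
        dbh = np.asarray(self.dbh, dtype=float)
        n = x.size
        if not (y.size == species.size == dbh.size == n):
            raise CensusValidationError("x, y, species, dbh must have equal length")
        ids = self.ids
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        else:
            ids = np.asarray(ids, dtype=np.int64)
            if ids.size != n:
                raise CensusValidationError("ids length mismatch")
            if np.unique(ids).size != n:
                raise CensusValidationError("tree ids must be unique")
        if n:
            inside = self.window.contains(x, y)
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                raise CensusValidationError(
                    f"tree id {ids[bad]} at ({x[bad]}, {y[bad]}) lies outside "
                    f"the window"
                )
            if not (dbh > 0).all():
                bad = int(np.flatnonzero(~(dbh > 0))[0])
                raise CensusValidationError(
                    f"tree id {ids[bad]} has non-positive dbh {dbh[bad]}"
                )
            if any(not s for s in species):
                raise CensusValidationError("empty species label")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "dbh", dbh)
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def intensity(self) -> float:
        """Estimated point intensity (trees per m^2)."""
        return self.n / self.window.area

    def species_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.species, return_counts=True)
        return {str(s): int(c) for s, c in zip(labels, counts)}

    def with_locations(self, x: np.ndarray, y: np.ndarray) -> "MarkedPointPattern":
        """Return a copy with new coordinates, marks and ids retained."""
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))

    def subset(self, mask: np.ndarray) -> "MarkedPointPattern":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            x=self.x[mask],
            y=self.y[mask],
            species=self.species[mask],
            dbh=self.dbh[mask],
            ids=self.ids[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "species": [str(s) for s in self.species],
                "dbh": self.dbh,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkedPointPattern):
            return NotImplemented
        return (
            self.window == other.window
            and self.n == other.n
            and np.array_equal(self.ids, other.ids)
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and np.allclose(self.dbh, other.dbh)
            and all(a == b for a, b in zip(self.species, other.species))
        )


@dataclass(frozen=True)
class SizeClassScheme:
    """Partition of the dbh axis into ordered size classes.

    ``breaks`` are the interior boundaries in cm; ``boundary_belongs[k]``
    states whether a dbh exactly on ``breaks[k]`` goes to the ``"upper"`` or
    ``"lower"`` adjacent class.  The default three-class scheme is

    * small:  5 cm <= dbh < 10 cm
    * medium: 10 cm <= dbh <= 25 cm
    * large:  dbh > 25 cm

    so a 10 cm stem is medium and a 25 cm stem is medium.  Classes cover
    ``[min_dbh, inf)`` with no gaps or overlaps.
    """

    labels: tuple[str, ...] = ("small", "medium", "large")
    breaks: tuple[float, ...] = (10.0, 25.0)
    boundary_belongs: tuple[str, ...] = ("upper", "lower")
    min_dbh: float = CENSUS_MIN_DBH

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need one more label than interior breaks")
        if len(self.boundary_belongs) != len(self.breaks):
            raise ValueError("one boundary convention per break")
        if any(side not in ("upper", "lower") for side in self.boundary_belongs):
            raise ValueError("boundary_belongs entries must be 'upper' or 'lower'")
        bks = np.asarray(self.breaks, dtype=float)
        if bks.size and not (np.diff(bks) > 0).all():
            raise ValueError("breaks must be strictly increasing")
        if bks.size and bks[0] <= self.min_dbh:
            raise ValueError("first break must exceed the census threshold")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def classify(self, dbh) -> np.ndarray:
        """Vectorized class index per dbh value."""
        d = np.asarray(dbh, dtype=float)
        if np.any(d < self.min_dbh):
            raise ValueError(
                f"dbh below the census threshold of {self.min_dbh} cm"
            )
        idx = np.zeros(d.shape, dtype=np.int64)
        for k, (bk, side) in enumerate(zip(self.breaks, self.boundary_belongs)):
            if side == "upper":  # boundary value belongs to the class above
                idx = np.where(d >= bk, k + 1, idx)
            else:
                idx = np.where(d > bk, k + 1, idx)
        return idx

    def class_mask(self, pattern: MarkedPointPattern, label: str) -> np.ndarray:
        if label not in self.labels:
            raise KeyError(f"unknown size class {label!r}")
        return self.classify(pattern.dbh) == self.labels.index(label)


#: Two-class scheme used by the dependent-marking simulation experiment:
#: small (dbh <= 25 cm) versus large (dbh > 25 cm).
TWO_CLASS_SCHEME = SizeClassScheme(
    labels=("small", "large"), breaks=(25.0,), boundary_belongs=("lower",)
)


def classify_size(scheme: SizeClassScheme, dbh: float) -> str:
    """Size-class label for a single dbh value (cm)."""
    return scheme.labels[int(scheme.classify(dbh))]


def load_census(
    path,
    window: Window,
    min_dbh: float = CENSUS_MIN_DBH,
) -> MarkedPointPattern:
    """Read a census CSV into a validated :class:`MarkedPointPattern`.

    The file must be comma-separated with a header containing columns
    ``x, y, species, dbh`` (any order, extra columns ignored); coordinates in
    metres, dbh in cm.  Only stems with ``dbh > min_dbh`` (strict) are
    retained, mirroring the field protocol in which only stems exceeding the
    threshold were tagged.  Ids are assigned 0..n-1 in file order of the
    retained rows.
    """
    df = pd.read_csv(path)
    for col in ("x", "y", "species", "dbh"):
        if col not in df.columns:
            raise CensusFormatError(f"census file missing required column {col!r}")
    dbh_numeric = pd.to_numeric(df["dbh"], errors="coerce")
    bad = dbh_numeric.isna() & df["dbh"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CensusFormatError(
            f"non-numeric dbh {df['dbh'].iloc[row]!r} in row {row}"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CensusFormatError(f"non-numeric {col} in row {row}")
        df[col] = vals
    df = df.assign(dbh=dbh_numeric)
    keep = df["dbh"].to_numpy() > min_dbh
    kept = df.loc[keep].reset_index(drop=False)
    inside = window.contains(kept["x"].to_numpy(), kept["y"].to_numpy())
    if not np.asarray(inside).all():
        row = int(kept["index"].iloc[int(np.flatnonzero(~np.asarray(inside))[0])])
        raise CensusValidationError(
            f"row {row} lies outside the window "
            f"[{window.xmin}, {window.xmax}] x [{window.ymin}, {window.ymax}]"
        )
    return MarkedPointPattern(
        x=kept["x"].to_numpy(dtype=float),
        y=kept["y"].to_numpy(dtype=float),
        species=kept["species"].astype(str).to_numpy(dtype=object),
        dbh=kept["dbh"].to_numpy(dtype=float),
        window=window,
    )


def save_census(pattern: MarkedPointPattern, path) -> None:
    """Write a pattern as a census CSV (columns ``x,y,species,dbh``)."""
    pattern.to_dataframe().to_csv(path, index=False)


def k_nearest_neighbors(
    pattern: MarkedPointPattern, i: int, k: int
) -> np.ndarray:
    """Ids of the ``k`` nearest neighbours of tree ``i``, nearest first.

    Exact distance ties are broken by ascending tree id, so the result is
    deterministic and independent of input row order once ids are assigned.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k >= pattern.n:
        raise InsufficientPointsError(
            f"k={k} neighbours requested but pattern has only {pattern.n} trees"
        )
    pos = int(np.flatnonzero(pattern.ids == i)[0]) if i in pattern.ids else None
    if pos is None:
        raise KeyError(f"no tree with id {i}")
    d = np.hypot(pattern.x - pattern.x[pos], pattern.y - pattern.y[pos])
    d[pos] = np.inf
    # ids are sorted or arbitrary; lexsort: primary key distance, ties by id
    order = np.lexsort((pattern.ids, d))
    return pattern.ids[order[:k]].copy()


def neighbor_index_matrix(pattern: MarkedPointPattern, k: int) -> np.ndarray:
    """Row ``i`` holds the array positions of tree ``i``'s k nearest neighbours.

    Shared by the mingling summary; positions refer to array order, with the
    same distance-then-id tie rule as :func:`k_nearest_neighbors`.  Quadratic
    in memory — intended for plot-sized patterns (a few thousand stems).
    """
    if k >= pattern.n:
        raise InsufficientPointsError(
            f"k={k} neighbours requested but pattern has only {pattern.n} trees"
        )
    dx = pattern.x[:, None] - pattern.x[None, :]
    dy = pattern.y[:, None] - pattern.y[None, :]
    d = np.hypot(dx, dy)
    np.fill_diagonal(d, np.inf)
    if not np.array_equal(pattern.ids, np.sort(pattern.ids)):
        # reorder columns by id so that the stable sort's tie rule is "by id"
        col_order = np.argsort(pattern.ids, kind="stable")
        d = d[:, col_order]
        # stable sort keeps ascending-id order among equal distances
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        return col_order[nn]
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def translation_weight(window: Window, dx: float, dy: float) -> float:
    """Translation edge-correction weight for a pair displaced by (dx, dy).

    For a rectangular window with sides ``a x b`` the weight is
    ``a*b / ((a - |dx|) * (b - |dy|))`` — the reciprocal overlap fraction of
    the window with itself shifted by the pair displacement.  It equals 1 for
    coincident points and grows as the displacement approaches a window side,
    compensating pairs lost beyond the plot boundary.
    """
    a, b = window.a, window.b
    adx, ady = abs(dx), abs(dy)
    if adx >= a or ady >= b:
        raise ValueError(
            f"pair displacement ({dx}, {dy}) not observable in a {a} x {b} window"
        )
    return (a * b) / ((a - adx) * (b - ady))


def translation_weight_matrix(
    window: Window, dx: np.ndarray, dy: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`translation_weight` (no displacement validity check)."""
    a, b = window.a, window.b
    return (a * b) / ((a - np.abs(dx)) * (b - np.abs(dy)))
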