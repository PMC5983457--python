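"""Correlation-based feature-subset selection for chemical descriptor tables.

External 2D/3D descriptor tables (PaDEL CSV dialect: first column ``Name``,
remaining columns numeric) are ingested, cleaned (missing values and
zero-variance columns dropped, remainder standardized) and reduced with
correlation-based feature selection (CFS) driven by a forward best-first
search.

CFS scores a subset S of k features by

    merit(S) = k * mean|r_cf| / sqrt(k + k (k - 1) * mean|r_ff|)

where ``r_cf`` are the feature–target Pearson correlations and ``r_ff``
the pairwise feature–feature correlations within S.  For a single feature
the merit reduces to |r(feature, target)|.  This is the continuous-target
variant: correlations are plain Pearson r on standardized columns.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import FormatError

#: cell values treated as missing in descriptor CSVs
MISSING_MARKERS = ("", "NA", "NaN", "nan", "Infinity", "-Infinity", "null")


@dataclass
class DescriptorTable:
    """Peptides × chemical descriptors matrix with row/column labels."""

    ids: list[str]
    names: list[str]
    matrix: np.ndarray  # float, NaN marks missing before cleaning
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.ids)} ids x {len(self.names)} descriptors"
            )
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate molecule ids in descriptor table")

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.names)


def read_descriptor_table(path) -> DescriptorTable:
    """Read a PaDEL-dialect descriptor CSV (first column ``Name``)."""
    df = pd.read_csv(
        path, na_values=list(MISSING_MARKERS), keep_default_na=False, comment="#"
    )
    if df.shape[1] < 2 or str(df.columns[0]) != "Name":
        raise FormatError("descriptor CSV must start with a 'Name' column")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate Name entries in descriptor table")
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if body.shape[1] == 0:
        raise FormatError("descriptor table has no descriptor columns")
    return DescriptorTable(ids, [str(c) for c in body.columns], body.to_numpy(float))


def clean_descriptor_table(t: DescriptorTable) -> DescriptorTable:
    """Drop unusable columns and standardize the rest.

    Columns containing any missing value, or with zero variance, are
    dropped (their names recorded in ``dropped``); surviving columns are
    scaled to zero mean and unit (population) standard deviation.
    """
    keep, dropped = [], []
    for j, name in enumerate(t.names):
        col = t.matrix[:, j]
        if np.isnan(col).any() or np.ptp(col) == 0:
            dropped.append(name)
        else:
            keep.append(j)
    if not keep:
        raise ValueError("cleaning dropped every descriptor column")
    m = t.matrix[:, keep]
    m = (m - m.mean(axis=0)) / m.std(axis=0)
    return DescriptorTable(
        list(t.ids), [t.names[j] for j in keep], m, dropped=dropped
    )


# ---------------------------------------------------------------------------
# CFS merit and best-first search


def _correlation_arrays(t: DescriptorTable, y: np.ndarray):
    """|r| of every column vs y, and the |r| feature-feature matrix."""
    y = np.asarray(y, dtype=float)
    if len(y) != t.n_molecules:
        raise ValueError(
            f"target length {len(y)} != table rows {t.n_molecules}"
        )
    if len(y) < 3:
        raise ValueError("need at least 3 rows for correlation-based selection")
    X = t.matrix
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    x_norm = np.sqrt((Xc**2).sum(axis=0))
    y_norm = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_cf = np.abs(Xc.T @ yc / (x_norm * y_norm))
        denom = np.outer(x_norm, x_norm)
        r_ff = np.abs(Xc.T @ Xc / denom)
    return np.nan_to_num(r_cf), np.nan_to_num(r_ff)


def _merit_from_arrays(subset: tuple[int, ...], r_cf, r_ff) -> float:
    k = len(subset)
    mean_cf = float(r_cf[list(subset)].mean())
    if k == 1:
        return mean_cf
    pairs = list(itertools.combinations(subset, 2))
    mean_ff = float(np.mean([r_ff[i, j] for i, j in pairs]))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_merit(subset, t: DescriptorTable, y) -> float:
    """CFS merit of a descriptor subset (column indices) against target y."""
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    if any(i < 0 or i >= t.n_descriptors for i in subset):
        raise ValueError(f"column index out of range in {subset}")
    r_cf, r_ff = _correlation_arrays(t, np.asarray(y, dtype=float))
    return _merit_from_arrays(subset, r_cf, r_ff)


def best_first_cfs(
    t: DescriptorTable, y, stale_limit: int = 5
) -> list[int]:
    """Forward best-first search over descriptor subsets under CFS merit.

    Starting from the empty set, repeatedly expands the best open subset by
    every unused feature, keeping the best-merit subset seen anywhere; the
    search stops after ``stale_limit`` consecutive expansions that fail to
    improve the global best.  Ties in merit are broken by the lower column
    index (then lexicographic subset order), so the result is deterministic
    for a given column order.

    Returns the selected column indices in the order they entered the subset.
    """
    if t.n_descriptors < 1:
        raise ValueError("descriptor table has no columns")
    if stale_limit < 1:
        raise ValueError("stale_limit must be positive")
    r_cf, r_ff = _correlation_arrays(t, np.asarray(y, dtype=float))
    n = t.n_descriptors

    # heap entries: (-merit, subset-in-selection-order); frozenset dedup
    start: tuple[int, ...] = ()
    open_heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    visited = {frozenset(start)}
    best_subset: tuple[int, ...] = ()
    best_merit = -np.inf
    stale = 0

    while open_heap and stale < stale_limit:
        _, subset = heapq.heappop(open_heap)
        improved = False
        members = set(subset)
        for j in range(n):
            if j in members:
                continue
            child = subset + (j,)
            key = frozenset(child)
            if key in visited:
                continue
            visited.add(key)
            merit = _merit_from_arrays(child, r_cf, r_ff)
            heapq.heappush(open_heap, (-merit, child))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1
    return list(best_subset)


def exhaustive_cfs(t: DescriptorTable, y, max_columns: int = 12) -> tuple[list[int], float]:
    """Exhaustive CFS search (oracle for small tables): best subset + merit."""
    n = t.n_descriptors
    if n > max_columns:
        raise ValueError(f"exhaustive search capped at {max_columns} columns, got {n}")
    r_cf, r_ff = _correlation_arrays(t, np.asarray(y, dtype=float))
    best, best_merit = [], -np.inf
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            merit = _merit_from_arrays(subset, r_cf, r_ff)
            if merit > best_merit + 1e-12:
                best, best_merit = list(subset), merit
    return best, best_merit
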