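"""Subject-level connectome containers, edge indexing, QC and imputation.

A connectome for one subject is a symmetric ``N x N`` matrix of Fisher-z
transformed Pearson correlations between the BOLD time series of ``N``
atlas regions.  The diagonal carries no information and is never stored:
stacks are kept *edge-major*, a ``subjects x N(N-1)/2`` array whose columns
follow the lexicographic ordering of node pairs ``(i, j)`` with ``i < j``
(0-based).  Missing edges are tracked by a boolean mask of the same shape.

The quality-control step retains subjects with a low fraction of missing
edges and a per-subject edge standard deviation inside a plausible band;
remaining missing entries are imputed with the across-subject mean of the
edge, after which every downstream stage assumes a complete stack.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default clipping distance from |r| = 1 before the Fisher transform
CLIP_EPS = 1e-7


class EmptyCohortError(ValueError):
    """Raised when quality control removes every subject."""


class UnimputableEdgeError(ValueError):
    """Raised when an edge is missing for all subjects; carries ``edges``."""

    def __init__(self, edges):
        self.edges = list(edges)
        super().__init__(
            f"{len(self.edges)} edge(s) missing for every subject; "
            f"first few: {self.edges[:10]}"
        )


def edge_count(n_nodes) -> int:
    """Number of undirected edges ``N(N-1)/2`` between ``n_nodes`` regions."""
    if isinstance(n_nodes, bool) or not isinstance(n_nodes, numbers.Integral):
        raise TypeError(f"node count must be an integer, got {n_nodes!r}")
    if n_nodes < 1:
        raise ValueError(f"node count must be >= 1, got {n_nodes}")
    n = int(n_nodes)
    return n * (n - 1) // 2


def fisher_z(r, clip: float = CLIP_EPS):
    """Fisher z-transform ``atanh(r)``, clipping ``|r| >= 1`` to ``1 - clip``.

    Clipping keeps perfectly (anti)correlated pairs finite so downstream
    regression never sees infinities.
    """
    if not np.issubdtype(np.asarray(r).dtype, np.number):
        raise TypeError("fisher_z expects numeric input")
    arr = np.asarray(r, dtype=float)
    clipped = np.clip(arr, -1.0 + clip, 1.0 - clip)
    out = np.arctanh(clipped)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(out)
    return out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (``tanh``)."""
    out = np.tanh(np.asarray(z, dtype=float))
    if np.isscalar(z) or np.ndim(z) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class EdgeIndex:
    """Bijective map between node pairs ``(i, j), i < j`` and edge columns.

    Pairs are ordered lexicographically: (0,1), (0,2), ..., (0,N-1), (1,2), ...
    """

    n_nodes: int

    def __post_init__(self):
        if not isinstance(self.n_nodes, numbers.Integral) or self.n_nodes < 1:
            raise ValueError(f"n_nodes must be a positive integer, got {self.n_nodes}")

    @property
    def n_edges(self) -> int:
        return edge_count(self.n_nodes)

    @property
    def pairs(self) -> np.ndarray:
        """``(n_edges, 2)`` int array of (i, j) pairs in column order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return np.column_stack(iu)

    def index_of(self, i: int, j: int) -> int:
        """Column index of the undirected edge between nodes ``i`` and ``j``."""
        n = self.n_nodes
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"invalid edge ({i}, {j}) for {n} nodes")
        if i > j:
            i, j = j, i
        # offset of row i in the flattened upper triangle
        return i * (2 * n - i - 1) // 2 + (j - i - 1)


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Upper triangle (k=1) of a symmetric matrix in edge order."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def matrixize_vector(vec: np.ndarray, n_nodes: int, diagonal=np.nan) -> np.ndarray:
    """Symmetric ``N x N`` matrix from an edge-major vector.

    The diagonal is set to ``diagonal`` (NaN by default) as a sentinel; it is
    never consumed downstream.
    """
    vec = np.asarray(vec)
    if vec.shape[-1] != edge_count(n_nodes):
        raise ValueError(
            f"vector length {vec.shape[-1]} does not match edge_count({n_nodes})"
        )
    mat = np.full((n_nodes, n_nodes), diagonal, dtype=float)
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = vec
    mat[(iu[1], iu[0])] = vec
    return mat


@dataclass
class ConnectomeStack:
    """Edge-major stack of per-subject Fisher-z connectomes.

    Attributes
    ----------
    subject_ids
        Length-S list of subject identifiers, aligned with rows of ``values``.
    n_nodes
        Number of atlas regions N.
    values
        ``(S, N(N-1)/2)`` float array of Fisher-z correlations.
    missing
        Boolean mask of the same shape; True marks a missing edge value.
    """

    subject_ids: list
    n_nodes: int
    values: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x edges)")
        n_edges = edge_count(self.n_nodes)
        if self.values.shape != (len(self.subject_ids), n_edges):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.subject_ids)} subjects, {n_edges} edges)"
            )
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape must match values")
        # non-finite observed values are treated as missing
        self.missing |= ~np.isfinite(self.values)
        if not np.all(np.isfinite(self.values[~self.missing])):
            raise ValueError("non-missing values must be finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def edge_index(self) -> EdgeIndex:
        return EdgeIndex(self.n_nodes)

    def matrix(self, subject) -> np.ndarray:
        """Symmetric connectome of one subject (by index or id); missing -> NaN."""
        if not isinstance(subject, numbers.Integral):
            subject = self.subject_ids.index(str(subject))
        vec = self.values[subject].copy()
        vec[self.missing[subject]] = np.nan
        return matrixize_vector(vec, self.n_nodes)

    def subset(self, rows) -> "ConnectomeStack":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ConnectomeStack(
            subject_ids=[self.subject_ids[k] for k in rows],
            n_nodes=self.n_nodes,
            values=self.values[rows].copy(),
            missing=self.missing[rows].copy(),
        )

    @classmethod
    def from_matrices(cls, subject_ids, matrices) -> "ConnectomeStack":
        """Build a stack from per-subject symmetric matrices (NaN = missing)."""
        matrices = [np.asarray(m, dtype=float) for m in matrices]
        n_nodes = matrices[0].shape[0]
        rows = [vectorize_matrix(m) for m in matrices]
        values = np.vstack(rows)
        return cls(subject_ids=list(subject_ids), n_nodes=n_nodes, values=values)


def timeseries_to_connectome(ts: np.ndarray, clip: float = CLIP_EPS) -> np.ndarray:
    """Fisher-z correlation matrix of a ``T x N`` regional time-series array.

    Zero-variance columns do not raise: every edge touching such a column is
    flagged missing (NaN).  The diagonal is NaN (sentinel, unused).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("time series must be T x N with T >= 3")
    sd = ts.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    z = fisher_z(r, clip=clip)
    z[degenerate, :] = np.nan
    z[:, degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    return z


# ---------------------------------------------------------------------------
# covariates and parcellation


class SubjectTable:
    """Per-subject covariates aligned with a :class:`ConnectomeStack`.

    Required columns: ``subject_id``, ``age`` (years), ``sex`` (0/1), the five
    imaging confounds (:data:`SubjectTable.CONFOUNDS`: mean framewise
    displacement in mm and four scanner-position coordinates).  Optional:
    ``fa`` (mean white-matter fractional anisotropy), ``log_wmh``
    (log-transformed white-matter hyperintensity volume) and the nine-column
    cognitive battery (:data:`SubjectTable.COGNITIVE`, may contain NaN).
    """

    CONFOUNDS = ("fd_mean", "pos_x", "pos_y", "pos_z", "table_pos")
    COGNITIVE = tuple(f"cog_{k}" for k in range(1, 10))

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df).reset_index(drop=True)
        required = ["subject_id", "age", "sex", *self.CONFOUNDS]
        miss = [c for c in required if c not in df.columns]
        if miss:
            raise ValueError(f"SubjectTable missing required columns: {miss}")
        df["subject_id"] = df["subject_id"].astype(str)
        if (df["age"] <= 0).any():
            raise ValueError("ages must be strictly positive")
        if not df["sex"].isin([0, 1]).all():
            raise ValueError("sex must be coded 0/1")
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def subject_ids(self) -> list:
        return self.df["subject_id"].tolist()

    @property
    def age(self) -> np.ndarray:
        return self.df["age"].to_numpy(dtype=float)

    @property
    def age_sq(self) -> np.ndarray:
        return self.age**2

    @property
    def sex(self) -> np.ndarray:
        return self.df["sex"].to_numpy(dtype=float)

    @property
    def confounds(self) -> np.ndarray:
        return self.df[list(self.CONFOUNDS)].to_numpy(dtype=float)

    @property
    def fa(self) -> np.ndarray:
        return self.df["fa"].to_numpy(dtype=float)

    @property
    def log_wmh(self) -> np.ndarray:
        return self.df["log_wmh"].to_numpy(dtype=float)

    @property
    def cognitive_battery(self) -> pd.DataFrame:
        cols = [c for c in self.COGNITIVE if c in self.df.columns]
        return self.df[cols]

    def subset(self, rows) -> "SubjectTable":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SubjectTable(self.df.iloc[rows])

    def check_aligned(self, stack: ConnectomeStack) -> None:
        if self.subject_ids != stack.subject_ids:
            raise ValueError("subject order differs between covariates and stack")


class ParcellationInfo:
    """Region table: ``node_id``, ``label``, ``lobe``, ``network``.

    ``network`` assigns each region to a predefined functional network (e.g.
    the Yeo-7 names); an explicit "unassigned" token is allowed but an empty
    value is not.  Node ids must be exactly 0..N-1.
    """

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df).reset_index(drop=True)
        required = ["node_id", "label", "lobe", "network"]
        miss = [c for c in required if c not in df.columns]
        if miss:
            raise ValueError(f"parcellation missing columns: {miss}")
        ids = np.sort(df["node_id"].to_numpy(dtype=int))
        if not np.array_equal(ids, np.arange(len(df))):
            raise ValueError("node_ids must be exactly 0..N-1, no gaps or repeats")
        if df["network"].isna().any() or (df["network"].astype(str) == "").any():
            raise ValueError("every node needs a non-empty network assignment")
        self.df = df.sort_values("node_id").reset_index(drop=True)

    @property
    def n_nodes(self) -> int:
        return len(self.df)

    @property
    def networks(self) -> list:
        return sorted(self.df["network"].astype(str).unique())

    def network_of(self, nodes) -> pd.Series:
        return self.df.set_index("node_id").loc[list(nodes), "network"]


# ---------------------------------------------------------------------------
# quality control and imputation


def qc_filter(
    stack: ConnectomeStack,
    max_missing_ratio: float = 0.1,
    variation_bounds: tuple = (0.01, 2.0),
) -> ConnectomeStack:
    """Drop subjects with too many missing edges or implausible edge variation.

    A subject is kept when its missing-edge fraction is <= ``max_missing_ratio``
    and the standard deviation of its observed edge values lies inside
    ``variation_bounds``.  Counts removed per criterion are logged.
    """
    if not (0.0 <= max_missing_ratio <= 1.0):
        raise ValueError("max_missing_ratio must be in [0, 1]")
    lo, hi = variation_bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
        raise ValueError("variation_bounds must be finite with low <= high")

    frac_missing = stack.missing.mean(axis=1)
    vals = np.where(stack.missing, np.nan, stack.values)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(vals, axis=1)
    sd = np.where(np.isnan(sd), 0.0, sd)

    ok_missing = frac_missing <= max_missing_ratio
    ok_var = (sd >= lo) & (sd <= hi)
    keep = ok_missing & ok_var
    logger.info(
        "qc_filter: %d/%d subjects kept (%d over missing ratio, %d outside "
        "variation bounds)",
        keep.sum(), stack.n_subjects, (~ok_missing).sum(), (~ok_var).sum(),
    )
    if not keep.any():
        raise EmptyCohortError("quality control removed every subject")
    if keep.all():
        return stack
    return stack.subset(keep)


def impute_missing(stack: ConnectomeStack) -> ConnectomeStack:
    """Replace each missing edge value with that edge's across-subject mean."""
    if not stack.missing.any():
        return stack
    all_missing = stack.missing.all(axis=0)
    if all_missing.any():
        raise UnimputableEdgeError(np.flatnonzero(all_missing))
    vals = np.where(stack.missing, np.nan, stack.values)
    edge_means = np.nanmean(vals, axis=0)
    values = np.where(stack.missing, edge_means[None, :], stack.values)
    return ConnectomeStack(
        subject_ids=list(stack.subject_ids),
        n_nodes=stack.n_nodes,
        values=values,
        missing=np.zeros_like(stack.missing),
    )
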