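"""Correlation estimation, soft-threshold adjacency, and weighted network concepts.

A weighted network is represented by a symmetric adjacency matrix ``A`` with
entries in [0, 1] and unit diagonal.  For co-expression networks the adjacency
is derived from a correlation matrix by soft thresholding: unsigned networks
use ``|cor|**beta`` (anti-correlated nodes count as connected), signed networks
use ``((1 + cor)/2)**beta`` (anti-correlated nodes count as unconnected).

Undefined quantities (zero-variance profiles, isolated nodes, node pairs with
fewer than 3 complete observations) are carried as NaN markers and skipped by
downstream averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: minimum number of complete paired observations for a correlation
MIN_PAIR_OBS = 3

#: label aliases treated as "unassigned"
GREY_LABELS = ("grey", "gray", "0", "")
GREY = "grey"
GOLD = "gold"

DEFAULT_POWER = {"unsigned": 6.0, "signed": 12.0}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _as_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class ExpressionMatrix:
    """Samples x nodes numeric data; columns are node (gene) profiles."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        m, n = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i + 1}" for i in range(m)]
        if not self.node_ids:
            self.node_ids = [f"node_{i + 1}" for i in range(n)]
        self.sample_ids = _as_ids(self.sample_ids, "sample")
        self.node_ids = _as_ids(self.node_ids, "node")
        if len(self.sample_ids) != m or len(self.node_ids) != n:
            raise ValueError("id lengths do not match value dimensions")
        if m < 3:
            raise ValueError("need at least 3 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            sample_ids=list(self.sample_ids),
            node_ids=[self.node_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.node_ids)


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    node_ids: list[str]
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class AdjacencyMatrix:
    """Symmetric connection strengths in [0, 1] with unit diagonal."""

    values: np.ndarray
    node_ids: list[str]
    mode: str = "external"  # signed | unsigned | external
    power: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "AdjacencyMatrix":
        idx = np.asarray(idx)
        return AdjacencyMatrix(
            self.values[np.ix_(idx, idx)],
            node_ids=[self.node_ids[i] for i in idx],
            mode=self.mode,
            power=self.power,
        )


@dataclass
class ModuleAssignment:
    """Node -> module label map.  'grey' (alias '0') marks unassigned nodes."""

    node_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.node_ids = _as_ids(self.node_ids, "node")
        labels = [str(l) for l in self.labels]
        self.labels = [GREY if l.lower() in GREY_LABELS else l for l in labels]
        if len(self.labels) != len(self.node_ids):
            raise ValueError("labels and node_ids differ in length")
        if GOLD in self.labels:
            raise ValueError("'gold' is a reserved module label")

    @property
    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def proper_modules(self, min_size: int = 3) -> list[str]:
        """Proper (non-grey) module labels with at least ``min_size`` nodes,
        in order of first appearance."""
        seen: dict[str, int] = {}
        for l in self.labels:
            if l != GREY:
                seen[l] = seen.get(l, 0) + 1
        return [l for l, c in seen.items() if c >= min_size]

    def module_index(self, label: str) -> np.ndarray:
        arr = self.label_array
        return np.flatnonzero(arr == label)

    def reorder(self, node_ids: Sequence[str]) -> "ModuleAssignment":
        lookup = dict(zip(self.node_ids, self.labels))
        missing = [n for n in node_ids if n not in lookup]
        if missing:
            raise ValueError(f"labels missing for nodes: {missing[:5]}")
        return ModuleAssignment(list(node_ids), [lookup[n] for n in node_ids])


@dataclass
class NodeConcepts:
    """Per-node network concepts plus whole-(sub)network density."""

    connectivity: np.ndarray          # k_i, sum of adjacencies to other nodes
    mar: np.ndarray                   # maximum adjacency ratio
    clustering_coef: np.ndarray
    density: float
    intramodular_connectivity: Optional[np.ndarray] = None  # kIM (NaN for grey)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _bicor_transform_column(x: np.ndarray) -> np.ndarray:
    """Biweight midcovariance transform of one profile; NaN-free input.

    Weights follow Tukey's biweight around the median with a 9-MAD cutoff.
    Falls back to the Pearson (mean-centred) transform when MAD is zero.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("zero MAD; falling back to pearson for this profile")
        c = x - x.mean()
        return c
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    return (x - med) * w


def _transform_columns(X: np.ndarray, method: str) -> np.ndarray:
    """Column transform T with unit-norm columns such that corr = T.T @ T.

    Columns with zero variance (or all-NaN) become NaN columns.  Requires
    complete data; pairwise-complete handling takes the slow pandas path.
    """
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
        method = "pearson"
    if method == "pearson":
        T = X - X.mean(axis=0, keepdims=True)
    elif method == "bicor":
        T = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            T[:, j] = _bicor_transform_column(X[:, j])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    norms = np.sqrt((T**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(norms > 0, T / norms, np.nan)
    if np.any(norms == 0):
        warnings.warn("constant profile(s): correlations set to NaN")
    return T


def _pairwise_corr_frame(X: np.ndarray, method: str) -> np.ndarray:
    """Pairwise-complete correlation via pandas (slow path for missing data)."""
    df = pd.DataFrame(X)
    meth = method if method != "bicor" else "pearson"
    if method == "bicor":
        warnings.warn("bicor with missing values falls back to pearson pairwise")
    C = df.corr(method=meth, min_periods=MIN_PAIR_OBS).to_numpy()
    return C


def compute_correlation(X: ExpressionMatrix, method: str = "pearson") -> CorrelationMatrix:
    """Correlation matrix between node profiles.

    Missing values are handled pairwise-complete; a pair with fewer than 3
    complete observations, or a constant profile, yields NaN.
    """
    V = X.values
    if np.isnan(V).any():
        C = _pairwise_corr_frame(V, method)
    else:
        T = _transform_columns(V, method)
        C = T.T @ T
    C = np.clip(C, -1.0, 1.0, out=C)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    # constant columns keep NaN correlations but unit self-correlation
    return CorrelationMatrix(C, node_ids=list(X.node_ids), method=method)


def to_adjacency(C: CorrelationMatrix, mode: str = "unsigned",
                 power: Optional[float] = None) -> AdjacencyMatrix:
    """Soft-threshold a correlation matrix into a weighted adjacency."""
    if mode not in ("signed", "unsigned"):
        raise ValueError("mode must be 'signed' or 'unsigned'")
    beta = DEFAULT_POWER[mode] if power is None else float(power)
    if beta <= 0:
        raise ValueError("soft-threshold power must be positive")
    A = soft_threshold(C.values, mode, beta)
    return AdjacencyMatrix(A, node_ids=list(C.node_ids), mode=mode, power=beta)


def soft_threshold(C: np.ndarray, mode: str, beta: float) -> np.ndarray:
    """Raw array version of the signed/unsigned adjacency transform."""
    if mode == "unsigned":
        A = np.abs(C) ** beta
    else:
        A = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


# ---------------------------------------------------------------------------
# network concepts
# ---------------------------------------------------------------------------

def vectorize_upper(M: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular entries in row-major order (length n(n-1)/2)."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("vectorize_upper requires a square matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _concepts_arrays(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(k, MAR, cc, density) for an adjacency array; diagonal ignored."""
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    sumsq = (B**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mar = np.where(k > 0, sumsq / k, np.nan)
        # weighted clustering coefficient: closed triples over open triples
        tri = np.einsum("ij,ji->i", B @ B, B)
        denom = k**2 - sumsq
        cc = np.where(denom > 0, tri / denom, np.nan)
    density = float(B.sum() / (n * (n - 1))) if n > 1 else np.nan
    return k, mar, cc, density


def network_concepts(A: AdjacencyMatrix,
                     labels: Optional[ModuleAssignment] = None) -> NodeConcepts:
    """Connectivity, MAR, clustering coefficient, density and (optionally)
    intramodular connectivity.

    Isolated nodes (k == 0) receive NaN for MAR and the clustering coefficient.
    """
    k, mar, cc, density = _concepts_arrays(A.values)
    kim = None
    if labels is not None:
        lab = labels.reorder(A.node_ids)
        kim = np.full(A.n_nodes, np.nan)
        for q in lab.proper_modules(min_size=2):
            idx = lab.module_index(q)
            sub = A.values[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, 0.0)
            kim[idx] = sub.sum(axis=1)
    return NodeConcepts(connectivity=k, mar=mar, clustering_coef=cc,
                       density=density, intramodular_connectivity=kim)
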