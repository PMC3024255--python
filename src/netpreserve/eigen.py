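"""Module eigennodes (eigengenes), module membership (kME) and PVE.

The eigennode of a module is the first principal component of its
standardized (mean 0, sd 1 per node) expression data — the single profile
that explains the largest share of module variance.  ``kME`` is the
correlation of each node's profile with the eigennode and serves as a
continuous measure of module membership; the proportion of variance
explained (PVE) equals the mean squared kME over module members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .netcore import ExpressionMatrix, _transform_columns

logger = logging.getLogger(__name__)


@dataclass
class Eigennode:
    values: np.ndarray   # unit-norm vector over samples
    pve: float           # proportion of module variance explained


def standardize_columns(V: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0, sd 1 (sample sd, divisor m-1).

    Missing entries are mean-imputed per column first; zero-variance columns
    become NaN columns.
    """
    V = np.array(V, dtype=float)
    if np.isnan(V).any():
        logger.info("mean-imputing missing values before decomposition")
        col_mean = np.nanmean(V, axis=0)
        nan_pos = np.isnan(V)
        V[nan_pos] = np.take(col_mean, np.nonzero(nan_pos)[1])
    mu = V.mean(axis=0, keepdims=True)
    sd = V.std(axis=0, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (V - mu) / sd, np.nan)
    return Z


def module_eigennode(X_q: ExpressionMatrix) -> Eigennode:
    """Leading left singular vector of the standardized module data.

    The sign is oriented so the mean correlation between the eigennode and
    the module's node profiles is non-negative (ties keep the native sign).
    Raises for all-constant (degenerate) module data.
    """
    if X_q.n_nodes < 2 or X_q.n_samples < 3:
        raise ValueError("module needs >= 2 nodes and >= 3 samples")
    Z = standardize_columns(X_q.values)
    ok = ~np.isnan(Z).any(axis=0)
    if not ok.any():
        raise ValueError("degenerate module: all node profiles constant")
    if not ok.all():
        warnings.warn("dropping constant profiles from eigennode computation")
    Zok = Z[:, ok]
    U, s, _ = np.linalg.svd(Zok, full_matrices=False)
    E = U[:, 0]
    pve = float(s[0] ** 2 / (s**2).sum())
    # orientation: mean correlation with member profiles >= 0
    mean_cor = float(np.mean(Zok.T @ E))
    if mean_cor < 0:
        E = -E
    return Eigennode(values=E, pve=pve)


def kme(X: ExpressionMatrix, E: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Module membership: correlation of every node profile with eigennode E.

    Computed for all nodes of ``X`` (not only module members).  Constant
    profiles yield NaN.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[0] != X.n_samples:
        raise ValueError("eigennode length must equal the number of samples")
    if np.isnan(X.values).any():
        # pairwise-complete correlation per node
        out = np.full(X.n_nodes, np.nan)
        for j in range(X.n_nodes):
            x = X.values[:, j]
            ok = ~np.isnan(x)
            if ok.sum() < 3:
                continue
            xs, es = x[ok], E[ok]
            if xs.std() == 0 or es.std() == 0:
                continue
            out[j] = np.corrcoef(xs, es)[0, 1]
        return np.clip(out, -1.0, 1.0)
    T = _transform_columns(X.values, method)
    TE = _transform_columns(E[:, None], method)[:, 0]
    return np.clip(T.T @ TE, -1.0, 1.0)
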