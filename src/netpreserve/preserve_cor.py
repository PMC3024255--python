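"""Correlation-network preservation statistics and module quality statistics.

These statistics exploit the sign of the underlying correlations and the
module eigennode, and only exist when expression data (not just an
adjacency) is available for both networks:

* ``meanSignAwareCorDat`` — mean test-set correlation within the module,
  each pair weighted by the sign of its reference correlation, so sign flips
  count against preservation.
* ``propVarExplained`` — variance explained by the test-set eigennode,
  computed as mean squared kME over module members.
* ``meanSignAwareKME`` — mean test-set module membership weighted by the
  sign of the reference membership.
* ``cor.cor`` / ``cor.kME`` / ``cor.kMEall`` — correlation, across the
  module (or all nodes for kMEall), of intramodular correlations and module
  memberships between reference and test.
* ``separability.cor`` — one minus the (absolute) correlation of two module
  eigennodes in the test data.

Applied with the test set equal to the reference set, the density and
separability statistics measure module *quality* — how coherent and distinct
a module is in the network it was defined in.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .eigen import standardize_columns
from .netcore import (
    DEFAULT_POWER,
    ExpressionMatrix,
    ModuleAssignment,
    _concepts_arrays,
    _transform_columns,
    soft_threshold,
    vectorize_upper,
)
from .preserve_general import pearson_pairs, separability_from_blocks

logger = logging.getLogger(__name__)

COR_DENSITY_STATS = ("meanSignAwareCorDat", "propVarExplained", "meanSignAwareKME")
COR_CONNECTIVITY_STATS = ("cor.cor", "cor.kME", "cor.kMEall")
QUALITY_STATS = ("meanAdj", "meanSignAwareCorDat", "propVarExplained",
                 "meanSignAwareKME", "separability", "separability.cor")


def _leading_component(Z_sub: np.ndarray) -> tuple[np.ndarray, float]:
    """Oriented leading left singular vector and PVE of standardized data.

    Columns that are entirely NaN (constant profiles) are dropped.  Returns
    (NaN vector, NaN) when no usable column remains.
    """
    ok = ~np.isnan(Z_sub).any(axis=0)
    if not ok.any():
        return np.full(Z_sub.shape[0], np.nan), float("nan")
    Zok = Z_sub[:, ok]
    U, s, _ = np.linalg.svd(Zok, full_matrices=False)
    E = U[:, 0]
    if float(np.mean(Zok.T @ E)) < 0:
        E = -E
    pve = float(s[0] ** 2 / (s**2).sum())
    return E, pve


class PairedExpressionStudy:
    """Precomputed column transforms for fast repeated module evaluation.

    Missing values are mean-imputed per node up front (logged); strictly
    pairwise-complete correlations are available through
    :func:`netpreserve.netcore.compute_correlation` for one-off use.
    """

    def __init__(self, X_ref: ExpressionMatrix, X_test: ExpressionMatrix,
                 method: str = "pearson", mode: str = "unsigned",
                 power: Optional[float] = None):
        if list(X_ref.node_ids) != list(X_test.node_ids):
            raise ValueError("reference and test data must share the node universe "
                             "in the same order")
        if mode not in ("signed", "unsigned"):
            raise ValueError("mode must be 'signed' or 'unsigned'")
        self.method = method
        self.mode = mode
        self.beta = DEFAULT_POWER[mode] if power is None else float(power)
        if self.beta <= 0:
            raise ValueError("soft-threshold power must be positive")
        self.node_ids = list(X_ref.node_ids)
        self.n_nodes = len(self.node_ids)

        def prep(X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
            V = X.values
            if np.isnan(V).any():
                logger.info("mean-imputing missing expression values")
                col_mean = np.nanmean(V, axis=0)
                V = np.where(np.isnan(V), col_mean[None, :], V)
            return _transform_columns(V, method), standardize_columns(V)

        self.T_ref, self.Z_ref = prep(X_ref)
        self.T_test, self.Z_test = prep(X_test)

    # -- low-level pieces ---------------------------------------------------
    def corr_sub(self, side: str, idx: np.ndarray) -> np.ndarray:
        T = self.T_ref if side == "ref" else self.T_test
        C = T[:, idx].T @ T[:, idx]
        np.clip(C, -1.0, 1.0, out=C)
        np.fill_diagonal(C, 1.0)
        return C

    def eigennode_sub(self, side: str, idx: np.ndarray) -> tuple[np.ndarray, float]:
        Z = self.Z_ref if side == "ref" else self.Z_test
        return _leading_component(Z[:, idx])

    def _transform_vector(self, E: np.ndarray) -> np.ndarray:
        if np.isnan(E).any():
            return np.full_like(E, np.nan)
        return _transform_columns(E[:, None], self.method)[:, 0]

    def kme_all(self, side: str, E: np.ndarray) -> np.ndarray:
        """kME of every network node against eigennode E."""
        T = self.T_ref if side == "ref" else self.T_test
        TE = self._transform_vector(E)
        return np.clip(T.T @ TE, -1.0, 1.0)

    # -- per-module statistics ----------------------------------------------
    def ref_context(self, idx: np.ndarray, include_general: bool = True,
                    include_kme_all: bool = True) -> dict:
        """Reference-side quantities of one module, reusable across
        permutation replicates (the reference module is held fixed while the
        test-side node identity is permuted)."""
        C_ref = self.corr_sub("ref", idx)
        E_ref, _ = self.eigennode_sub("ref", idx)
        ctx = {
            "idx": idx,
            "v_ref": vectorize_upper(C_ref),
        }
        kme_ref_all = self.kme_all("ref", E_ref)
        ctx["kme_ref"] = kme_ref_all[idx]
        if include_kme_all:
            ctx["kme_ref_all"] = kme_ref_all
        if include_general:
            A_ref = soft_threshold(C_ref, self.mode, self.beta)
            k_r, mar_r, cc_r, _ = _concepts_arrays(A_ref)
            ctx.update(v_aref=vectorize_upper(A_ref), k_ref=k_r, mar_ref=mar_r,
                       cc_ref=cc_r)
        return ctx

    def module_stats(self, idx: np.ndarray, idx_test: Optional[np.ndarray] = None,
                     include_general: bool = True, include_kme_all: bool = True,
                     perm: Optional[np.ndarray] = None,
                     ref_ctx: Optional[dict] = None) -> dict[str, float]:
        """All per-module preservation statistics for one node set.

        ``idx_test`` (default ``idx``) gives the test-side node set, paired
        with the reference nodes by position — permutation replicates pass
        the module's image under a random relabeling of the test network.
        ``perm`` is that relabeling of the whole universe (needed only for
        cor.kMEall).
        """
        if idx_test is None:
            idx_test = idx
        if ref_ctx is None:
            ref_ctx = self.ref_context(idx, include_general, include_kme_all)
        C_test = self.corr_sub("test", idx_test)
        v_ref = ref_ctx["v_ref"]
        v_test = vectorize_upper(C_test)

        E_test, _ = self.eigennode_sub("test", idx_test)
        kme_test_all = self.kme_all("test", E_test)
        kme_ref = ref_ctx["kme_ref"]
        kme_test = kme_test_all[idx_test]

        with np.errstate(invalid="ignore"):
            stats: dict[str, float] = {
                "meanSignAwareCorDat": float(np.nanmean(np.sign(v_ref) * v_test)),
                "propVarExplained": float(np.nanmean(kme_test**2)),
                "meanSignAwareKME": float(np.nanmean(np.sign(kme_ref) * kme_test)),
                "cor.cor": pearson_pairs(v_ref, v_test),
                "cor.kME": pearson_pairs(kme_ref, kme_test),
            }
        if include_kme_all:
            paired = kme_test_all if perm is None else kme_test_all[perm]
            stats["cor.kMEall"] = pearson_pairs(ref_ctx["kme_ref_all"], paired)
        if include_general:
            A_test = soft_threshold(C_test, self.mode, self.beta)
            k_t, mar_t, cc_t, density = _concepts_arrays(A_test)
            stats["meanAdj"] = density
            stats["meanClusterCoef"] = (float(np.nanmean(cc_t))
                                        if np.isfinite(cc_t).any() else float("nan"))
            stats["meanMAR"] = (float(np.nanmean(mar_t))
                                if np.isfinite(mar_t).any() else float("nan"))
            stats["cor.adj"] = pearson_pairs(ref_ctx["v_aref"], vectorize_upper(A_test))
            stats["cor.kIM"] = pearson_pairs(ref_ctx["k_ref"], k_t)
            stats["cor.cc"] = pearson_pairs(ref_ctx["cc_ref"], cc_t)
            stats["cor.MAR"] = pearson_pairs(ref_ctx["mar_ref"], mar_t)
        return stats

    # -- separability across modules ----------------------------------------
    def separability_stats(self, index_sets: dict[str, np.ndarray],
                           side: str = "test",
                           include_general: bool = True) -> dict[str, dict[str, float]]:
        """Per-module separability (minimum over all other modules).

        ``separability.cor`` uses eigennode correlations: in unsigned mode
        two anti-correlated eigennodes are treated as connected, so the
        absolute correlation is used; signed mode uses the raw correlation.
        """
        mods = list(index_sets)
        out = {q: {} for q in mods}
        if len(mods) >= 2:
            eig = {q: self.eigennode_sub(side, i)[0] for q, i in index_sets.items()}
            pair_sep: dict[tuple[str, str], float] = {}
            for i, q1 in enumerate(mods):
                for q2 in mods[i + 1:]:
                    c = pearson_pairs(eig[q1], eig[q2])
                    if not np.isfinite(c):
                        pair_sep[(q1, q2)] = float("nan")
                    elif self.mode == "unsigned":
                        pair_sep[(q1, q2)] = 1.0 - abs(c)
                    else:
                        pair_sep[(q1, q2)] = 1.0 - c
            for q in mods:
                vals = [v for (a, b), v in pair_sep.items()
                        if q in (a, b) and np.isfinite(v)]
                out[q]["separability.cor"] = min(vals) if vals else float("nan")
            if include_general:
                T = self.T_ref if side == "ref" else self.T_test
                dens = {}
                for q, i in index_sets.items():
                    C = self.corr_sub(side, i)
                    A = soft_threshold(C, self.mode, self.beta)
                    np.fill_diagonal(A, 0.0)
                    s = len(i)
                    dens[q] = float(A.sum() / (s * (s - 1)))
                inter = {}
                for i, q1 in enumerate(mods):
                    for q2 in mods[i + 1:]:
                        block = T[:, index_sets[q1]].T @ T[:, index_sets[q2]]
                        np.clip(block, -1.0, 1.0, out=block)
                        if self.mode == "unsigned":
                            Ab = np.abs(block) ** self.beta
                        else:
                            Ab = ((1.0 + block) / 2.0) ** self.beta
                        inter[(q1, q2)] = float(Ab.mean())
                _, per_mod = separability_from_blocks(dens, inter)
                for q in mods:
                    out[q]["separability"] = per_mod[q]
        else:
            for q in mods:
                out[q]["separability.cor"] = float("nan")
                if include_general:
                    out[q]["separability"] = float("nan")
        return out


# ---------------------------------------------------------------------------
# public one-shot operations
# ---------------------------------------------------------------------------

def _proper_index_sets(labels: ModuleAssignment, node_ids, min_module_size: int):
    lab = labels.reorder(node_ids)
    return lab, {q: lab.module_index(q) for q in lab.proper_modules(min_module_size)}


def cor_density_stats(X_ref: ExpressionMatrix, X_test: ExpressionMatrix,
                      labels: ModuleAssignment, method: str = "pearson",
                      min_module_size: int = 3) -> dict[str, dict[str, float]]:
    """Sign-aware correlation density, PVE and sign-aware kME per module."""
    study = PairedExpressionStudy(X_ref, X_test, method=method)
    _, idxs = _proper_index_sets(labels, study.node_ids, min_module_size)
    out = {}
    for q, idx in idxs.items():
        s = study.module_stats(idx, include_general=False, include_kme_all=False)
        out[q] = {k: s[k] for k in COR_DENSITY_STATS}
    return out


def cor_connectivity_stats(X_ref: ExpressionMatrix, X_test: ExpressionMatrix,
                           labels: ModuleAssignment, method: str = "pearson",
                           min_module_size: int = 3) -> dict[str, dict[str, float]]:
    """cor.cor, cor.kME and cor.kMEall per module."""
    study = PairedExpressionStudy(X_ref, X_test, method=method)
    _, idxs = _proper_index_sets(labels, study.node_ids, min_module_size)
    out = {}
    for q, idx in idxs.items():
        s = study.module_stats(idx, include_general=False, include_kme_all=True)
        out[q] = {k: s[k] for k in COR_CONNECTIVITY_STATS}
    return out


def separability_eigennode(X_test: ExpressionMatrix, labels: ModuleAssignment,
                           mode: str = "unsigned", method: str = "pearson",
                           min_module_size: int = 3) -> dict[str, float]:
    """Eigennode-based separability of each proper module in the test data."""
    study = PairedExpressionStudy(X_test, X_test, method=method, mode=mode)
    _, idxs = _proper_index_sets(labels, study.node_ids, min_module_size)
    if len(idxs) < 2:
        raise ValueError("eigennode separability needs at least 2 proper modules")
    sep = study.separability_stats(idxs, side="test", include_general=False)
    return {q: v["separability.cor"] for q, v in sep.items()}


def quality_stats(X_ref: ExpressionMatrix, labels: ModuleAssignment,
                  method: str = "pearson", mode: str = "unsigned",
                  power: Optional[float] = None,
                  min_module_size: int = 3) -> dict[str, dict[str, float]]:
    """Reference-side density and separability statistics (module quality).

    Obtained by evaluating the preservation statistics with the test set
    equal to the reference set; the sign-aware kME statistic then reduces to
    the mean absolute module membership.
    """
    study = PairedExpressionStudy(X_ref, X_ref, method=method, mode=mode, power=power)
    _, idxs = _proper_index_sets(labels, study.node_ids, min_module_size)
    out = {}
    for q, idx in idxs.items():
        s = study.module_stats(idx, include_general=True, include_kme_all=False)
        out[q] = {k: s[k] for k in
                  ("meanAdj", "meanSignAwareCorDat", "propVarExplained",
                   "meanSignAwareKME")}
    if len(idxs) >= 2:
        sep = study.separability_stats(idxs, side="ref", include_general=True)
        for q in out:
            out[q].update(sep[q])
    return out
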