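"""Preservation statistics defined for any adjacency-specified network.

Density statistics ask whether a module stays densely interconnected in the
test network (mean adjacency, mean clustering coefficient, mean MAR of the
module sub-network).  Connectivity statistics ask whether the *pattern* of
connections is reproduced: correlations, across the module, of intramodular
adjacencies, intramodular connectivities, clustering coefficients and MARs
between the reference and test networks.  Separability contrasts
between-module adjacency with within-module density.
"""

from __future__ import annotations

import numpy as np

from .netcore import (
    AdjacencyMatrix,
    ModuleAssignment,
    _concepts_arrays,
    vectorize_upper,
)

GENERAL_DENSITY_STATS = ("meanAdj", "meanClusterCoef", "meanMAR")
GENERAL_CONNECTIVITY_STATS = ("cor.adj", "cor.kIM", "cor.cc", "cor.MAR")


def pearson_pairs(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two vectors, skipping NaN pairs.

    Returns NaN for fewer than 3 complete pairs or zero variance on either
    side (the undefined-marker contract).
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3:
        return float("nan")
    u, v = u[ok], v[ok]
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return float("nan")
    return float(np.clip(np.corrcoef(u, v)[0, 1], -1.0, 1.0))


def module_density_concepts(A_sub: np.ndarray) -> dict[str, float]:
    """meanAdj / meanClusterCoef / meanMAR of one module sub-adjacency."""
    k, mar, cc, density = _concepts_arrays(A_sub)
    return {
        "meanAdj": density,
        "meanClusterCoef": float(np.nanmean(cc)) if np.isfinite(cc).any() else float("nan"),
        "meanMAR": float(np.nanmean(mar)) if np.isfinite(mar).any() else float("nan"),
    }


def module_connectivity_correlations(A_ref_sub: np.ndarray,
                                     A_test_sub: np.ndarray) -> dict[str, float]:
    """cor.adj / cor.kIM / cor.cc / cor.MAR between two module sub-adjacencies."""
    k_r, mar_r, cc_r, _ = _concepts_arrays(A_ref_sub)
    k_t, mar_t, cc_t, _ = _concepts_arrays(A_test_sub)
    return {
        "cor.adj": pearson_pairs(vectorize_upper(A_ref_sub), vectorize_upper(A_test_sub)),
        "cor.kIM": pearson_pairs(k_r, k_t),
        "cor.cc": pearson_pairs(cc_r, cc_t),
        "cor.MAR": pearson_pairs(mar_r, mar_t),
    }


def general_density_stats(A_test: AdjacencyMatrix,
                          labels: ModuleAssignment,
                          min_module_size: int = 3) -> dict[str, dict[str, float]]:
    """Test-network density statistics per proper module."""
    lab = labels.reorder(A_test.node_ids)
    out: dict[str, dict[str, float]] = {}
    for q in lab.proper_modules(min_module_size):
        idx = lab.module_index(q)
        out[q] = module_density_concepts(A_test.values[np.ix_(idx, idx)])
    return out


def general_connectivity_stats(A_ref: AdjacencyMatrix,
                               A_test: AdjacencyMatrix,
                               labels: ModuleAssignment,
                               min_module_size: int = 3) -> dict[str, dict[str, float]]:
    """Reference-vs-test connectivity-pattern correlations per proper module."""
    if list(A_ref.node_ids) != list(A_test.node_ids):
        raise ValueError("reference and test networks must share the node universe")
    lab = labels.reorder(A_ref.node_ids)
    out: dict[str, dict[str, float]] = {}
    for q in lab.proper_modules(min_module_size):
        idx = lab.module_index(q)
        out[q] = module_connectivity_correlations(
            A_ref.values[np.ix_(idx, idx)], A_test.values[np.ix_(idx, idx)]
        )
    return out


def separability_from_blocks(densities: dict[str, float],
                             inter_mean: dict[tuple[str, str], float],
                             ) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Pairwise and per-module separability from module densities and mean
    inter-module adjacencies.

    sep(q1, q2) = 1 - meanInterAdj(q1, q2) / sqrt(D(q1) * D(q2)); the
    per-module value is the minimum (most stringent) over all other modules.
    Zero or undefined density yields NaN.
    """
    mods = list(densities)
    pairwise: dict[tuple[str, str], float] = {}
    for i, q1 in enumerate(mods):
        for q2 in mods[i + 1:]:
            d1, d2 = densities[q1], densities[q2]
            inter = inter_mean.get((q1, q2), inter_mean.get((q2, q1)))
            if (not np.isfinite(d1) or not np.isfinite(d2) or d1 <= 0 or d2 <= 0
                    or inter is None or not np.isfinite(inter)):
                val = float("nan")
            else:
                val = 1.0 - inter / float(np.sqrt(d1 * d2))
            pairwise[(q1, q2)] = val
    per_module: dict[str, float] = {}
    for q in mods:
        vals = [v for (a, b), v in pairwise.items() if q in (a, b) and np.isfinite(v)]
        per_module[q] = min(vals) if vals else float("nan")
    return pairwise, per_module


def separability_general(A_test: AdjacencyMatrix,
                         labels: ModuleAssignment,
                         min_module_size: int = 3,
                         ) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Adjacency-based separability of every proper module pair in the test
    network, plus the per-module minimum."""
    lab = labels.reorder(A_test.node_ids)
    mods = lab.proper_modules(min_module_size)
    if len(mods) < 2:
        raise ValueError("separability needs at least 2 proper modules")
    idxs = {q: lab.module_index(q) for q in mods}
    densities = {q: module_density_concepts(A_test.values[np.ix_(i, i)])["meanAdj"]
                 for q, i in idxs.items()}
    inter = {}
    for i, q1 in enumerate(mods):
        for q2 in mods[i + 1:]:
            block = A_test.values[np.ix_(idxs[q1], idxs[q2])]
            inter[(q1, q2)] = float(block.mean())
    return separability_from_blocks(densities, inter)
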