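"""Cross-tabulation preservation statistics.

These require independent module assignments in *both* networks and compare
the labelings directly: the contingency table of reference vs test modules,
hypergeometric (Fisher) overlap significance per cell, the co-clustering
proportion (how often reference co-members stay together in the test
labeling), and a best-match overlap proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .netcore import GREY, ModuleAssignment


def contingency(labels_ref: ModuleAssignment,
                labels_test: ModuleAssignment) -> pd.DataFrame:
    """Counts of nodes per (reference module, test module) pair.

    Rows are reference modules, columns test modules; grey is included as a
    regular category.  Node universes must coincide.
    """
    if set(labels_ref.node_ids) != set(labels_test.node_ids):
        raise ValueError("labelings must cover the same node universe")
    test = labels_test.reorder(labels_ref.node_ids)
    tab = pd.crosstab(pd.Series(labels_ref.labels, name="reference"),
                      pd.Series(test.labels, name="test"))
    return tab


def fisher_overlap_neglogp(tab: pd.DataFrame, q: str, q_test: str) -> float:
    """-log10 one-sided (over-representation) Fisher p for one overlap cell.

    The table is collapsed to 2x2 (in/out of reference module q vs in/out of
    test module q') and the upper hypergeometric tail evaluated.
    """
    if q not in tab.index or q_test not in tab.columns:
        raise KeyError(f"module {q!r} / {q_test!r} not in the contingency table")
    n = int(tab.values.sum())
    size_q = int(tab.loc[q].sum())
    size_qt = int(tab[q_test].sum())
    overlap = int(tab.loc[q, q_test])
    if size_q == 0 or size_qt == 0:
        return float("nan")
    # P(X >= overlap), X ~ Hypergeom(n, size_q, size_qt)
    p = float(hypergeom.sf(overlap - 1, n, size_q, size_qt))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return float(-np.log10(p))


def co_clustering(labels_ref: ModuleAssignment, labels_test: ModuleAssignment,
                  q: str) -> float:
    """Fraction of reference co-member pairs of module q that also share a
    common proper (non-grey) test module."""
    test = labels_test.reorder(labels_ref.node_ids)
    ref_arr = labels_ref.label_array
    idx = np.flatnonzero(ref_arr == q)
    if idx.size < 2:
        return float("nan")
    t = test.label_array[idx]
    n_pairs = idx.size * (idx.size - 1) // 2
    same = 0
    for lab, cnt in pd.Series(t).value_counts().items():
        if lab != GREY and cnt >= 2:
            same += cnt * (cnt - 1) // 2
    return same / n_pairs


def best_match_overlap(labels_ref: ModuleAssignment,
                       labels_test: ModuleAssignment, q: str) -> float:
    """max over test modules q' of |q intersect q'| / |q| (accuracy-style)."""
    test = labels_test.reorder(labels_ref.node_ids)
    idx = np.flatnonzero(labels_ref.label_array == q)
    if idx.size == 0:
        return float("nan")
    t = pd.Series(test.label_array[idx])
    t = t[t != GREY]
    if t.empty:
        return 0.0
    return float(t.value_counts().iloc[0] / idx.size)


def crosstab_report(labels_ref: ModuleAssignment,
                    labels_test: ModuleAssignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table plus per-cell -log10 Fisher overlap p-values."""
    tab = contingency(labels_ref, labels_test)
    logp = pd.DataFrame(index=tab.index, columns=tab.columns, dtype=float)
    for q in tab.index:
        for qt in tab.columns:
            logp.loc[q, qt] = fisher_overlap_neglogp(tab, q, qt)
    return tab, logp
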