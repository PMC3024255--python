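"""Permutation null distributions, Z statistics and composite summaries.

For each module-level statistic the null distribution is built by repeatedly
permuting the module labels over the nodes and re-evaluating the statistic
on the resulting random node set of the same size, recomputing *both*
reference- and test-side quantities on that set (so that correlation-type
statistics always compare matched node sets).  With null mean ``mu`` and
standard deviation ``sigma``,

    Z = (observed - mu) / sigma

which is approximately standard normal when the module carries no signal.
The density Zs and connectivity Zs are each summarized by their median and
averaged into ``Zsummary``; guideline thresholds: Zsummary > 10 strong
evidence of preservation, 2-10 weak to moderate, < 2 none.

``medianRank`` is a module-size-insensitive alternative built from the ranks
of the observed statistics across modules (rank 1 = most preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .netcore import (
    GOLD,
    GREY,
    AdjacencyMatrix,
    ExpressionMatrix,
    ModuleAssignment,
)
from .preserve_cor import PairedExpressionStudy
from .preserve_general import (
    module_connectivity_correlations,
    module_density_concepts,
    separability_from_blocks,
)

logger = logging.getLogger(__name__)

# statistics feeding the composite summaries (correlation networks)
COR_DENSITY_COMPOSITE = ("meanSignAwareCorDat", "propVarExplained", "meanSignAwareKME")
COR_CONNECTIVITY_COMPOSITE = ("cor.adj", "cor.kIM", "cor.cor", "cor.kME")
# statistics feeding Zsummary.adj (general networks)
ADJ_DENSITY_COMPOSITE = ("meanAdj",)
ADJ_CONNECTIVITY_COMPOSITE = ("cor.adj", "cor.kIM")

EVIDENCE_STRONG = "strong evidence"
EVIDENCE_MODERATE = "weak to moderate evidence"
EVIDENCE_NONE = "no evidence"


@dataclass
class PreservationConfig:
    """Tunable knobs of a preservation run."""

    correlation: str = "pearson"        # pearson | spearman | bicor
    network: str = "unsigned"           # unsigned | signed
    power: Optional[float] = None       # soft-threshold beta; None = mode default
    n_permutations: int = 100
    seed: int = 1
    gold_size: Optional[int] = None     # None = min(1000, n)
    min_module_size: int = 3
    permute_all_nodes: bool = True      # include grey nodes in the permutation pool
    include_general: bool = True        # adjacency-based statistics in expression runs


@dataclass
class PreservationResult:
    results: pd.DataFrame               # long format, one row per (module, statistic)
    composites: pd.DataFrame            # one row per module
    metadata: dict = field(default_factory=dict)

    def zsummary(self) -> pd.Series:
        col = "Zsummary" if "Zsummary" in self.composites else "Zsummary.adj"
        return self.composites.set_index("module")[col]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def permute_module_labels(labels: ModuleAssignment,
                          rng: np.random.Generator) -> ModuleAssignment:
    """Uniform random reassignment of the label multiset to the nodes."""
    perm = rng.permutation(len(labels.labels))
    return ModuleAssignment(list(labels.node_ids),
                            [labels.labels[i] for i in perm])


def z_statistic(observed: float, null_samples: np.ndarray
                ) -> tuple[float, float, float, float]:
    """(null mean, null sd, Z, log10 one-sided p) from null samples.

    Invalid (NaN) null replicates are dropped; fewer than 2 valid samples or
    zero null sd yields NaN markers.  The p-value is the upper-tail standard
    normal probability of Z; its base-10 logarithm is returned (<= 0).
    """
    null = np.asarray(null_samples, float)
    null = null[np.isfinite(null)]
    if null.size < 2:
        return float("nan"), float("nan"), float("nan"), float("nan")
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    # a statistic that is constant under permutation has sd 0 up to float
    # summation noise; Z is undefined there
    if sigma <= 1e-12 * max(1.0, abs(mu)) or not np.isfinite(observed):
        return mu, sigma, float("nan"), float("nan")
    z = (observed - mu) / sigma
    log10_p = float(norm.logsf(z) / np.log(10.0))
    return mu, sigma, float(z), log10_p


def composite_z(z_by_stat: dict[str, float], network_class: str = "correlation"
                ) -> dict[str, float]:
    """Median-based density/connectivity composites and their mean.

    Missing component Zs are dropped from the median; if all components on
    one side are missing the composite is NaN.
    """
    if network_class == "correlation":
        dens_set, conn_set = COR_DENSITY_COMPOSITE, COR_CONNECTIVITY_COMPOSITE
        names = ("Zdensity", "Zconnectivity", "Zsummary")
    else:
        dens_set, conn_set = ADJ_DENSITY_COMPOSITE, ADJ_CONNECTIVITY_COMPOSITE
        names = ("Zdensity.adj", "Zconnectivity.adj", "Zsummary.adj")

    def med(stat_names) -> float:
        vals = [z_by_stat[s] for s in stat_names
                if s in z_by_stat and np.isfinite(z_by_stat[s])]
        if len(vals) < len([s for s in stat_names if s in z_by_stat]):
            logger.warning("dropping missing composite components")
        return float(np.median(vals)) if vals else float("nan")

    zd, zc = med(dens_set), med(conn_set)
    zs = float(np.mean([zd, zc])) if np.isfinite(zd) and np.isfinite(zc) else float("nan")
    return dict(zip(names, (zd, zc, zs)))


def median_rank(observed: pd.DataFrame, network_class: str = "correlation"
                ) -> pd.DataFrame:
    """medianRank.density / medianRank.connectivity / medianRank per module.

    ``observed`` is a modules x statistics frame of observed values.  For
    each composite-feeding statistic, modules are ranked with rank 1 = the
    largest observed value; ties get average ranks and undefined values rank
    last.  The density and connectivity ranks are summarized by their median
    and the two medians averaged.
    """
    if len(observed) < 2:
        raise ValueError("median_rank needs at least 2 proper modules")
    if network_class == "correlation":
        dens_set, conn_set = COR_DENSITY_COMPOSITE, COR_CONNECTIVITY_COMPOSITE
    else:
        dens_set, conn_set = ADJ_DENSITY_COMPOSITE, ADJ_CONNECTIVITY_COMPOSITE

    def rank_block(stat_names) -> pd.DataFrame:
        cols = [s for s in stat_names if s in observed.columns]
        return observed[cols].rank(ascending=False, method="average",
                                   na_option="bottom")

    dens_ranks = rank_block(dens_set)
    conn_ranks = rank_block(conn_set)
    out = pd.DataFrame(index=observed.index)
    out["medianRank.density"] = dens_ranks.median(axis=1)
    out["medianRank.connectivity"] = conn_ranks.median(axis=1)
    out["medianRank"] = (out["medianRank.density"] + out["medianRank.connectivity"]) / 2
    return out


def summary_logp(log10_p_by_stat: dict[str, float],
                 network_class: str = "correlation") -> float:
    """Median of the per-statistic log10 p-values feeding Zsummary."""
    if network_class == "correlation":
        stats = COR_DENSITY_COMPOSITE + COR_CONNECTIVITY_COMPOSITE
    else:
        stats = ADJ_DENSITY_COMPOSITE + ADJ_CONNECTIVITY_COMPOSITE
    vals = [log10_p_by_stat[s] for s in stats
            if s in log10_p_by_stat and np.isfinite(log10_p_by_stat[s])]
    return float(np.median(vals)) if vals else float("nan")


def evidence_flag(zsummary: float) -> str:
    if not np.isfinite(zsummary):
        return "undefined"
    if zsummary > 10:
        return EVIDENCE_STRONG
    if zsummary >= 2:
        return EVIDENCE_MODERATE
    return EVIDENCE_NONE


# ---------------------------------------------------------------------------
# evaluation of one labeling (shared by observed and null replicates)
# ---------------------------------------------------------------------------

def _evaluate_expression_labeling(study: PairedExpressionStudy,
                                  index_sets: dict[str, np.ndarray],
                                  proper: list[str],
                                  include_general: bool,
                                  perm: Optional[np.ndarray] = None,
                                  ref_cache: Optional[dict] = None
                                  ) -> dict[str, dict[str, float]]:
    out = {}
    for q, idx in index_sets.items():
        ctx = None
        if ref_cache is not None:
            ctx = ref_cache.get(q)
            if ctx is None:
                ctx = ref_cache[q] = study.ref_context(idx, include_general)
        idx_test = idx if perm is None else perm[idx]
        out[q] = study.module_stats(idx, idx_test=idx_test,
                                    include_general=include_general,
                                    perm=perm, ref_ctx=ctx)
    proper_sets = {q: (index_sets[q] if perm is None else perm[index_sets[q]])
                   for q in proper}
    if len(proper_sets) >= 2:
        sep = study.separability_stats(proper_sets, side="test",
                                       include_general=include_general)
        for q in proper:
            out[q].update(sep[q])
    return out


def _evaluate_adjacency_labeling(A_ref: np.ndarray, A_test: np.ndarray,
                                 index_sets: dict[str, np.ndarray],
                                 proper: list[str],
                                 perm: Optional[np.ndarray] = None
                                 ) -> dict[str, dict[str, float]]:
    out = {}
    for q, idx in index_sets.items():
        idx_t = idx if perm is None else perm[idx]
        sub_ref = A_ref[np.ix_(idx, idx)]
        sub_test = A_test[np.ix_(idx_t, idx_t)]
        stats = module_density_concepts(sub_test)
        stats.update(module_connectivity_correlations(sub_ref, sub_test))
        out[q] = stats
    if len(proper) >= 2:
        dens = {q: out[q]["meanAdj"] for q in proper}
        inter = {}
        for i, q1 in enumerate(proper):
            for q2 in proper[i + 1:]:
                i1 = index_sets[q1] if perm is None else perm[index_sets[q1]]
                i2 = index_sets[q2] if perm is None else perm[index_sets[q2]]
                block = A_test[np.ix_(i1, i2)]
                inter[(q1, q2)] = float(block.mean())
        _, per_mod = separability_from_blocks(dens, inter)
        for q in proper:
            out[q]["separability"] = per_mod[q]
    return out


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _index_sets_for_labels(label_arr: np.ndarray, proper: list[str],
                           include_grey: bool) -> dict[str, np.ndarray]:
    sets = {q: np.flatnonzero(label_arr == q) for q in proper}
    if include_grey and (label_arr == GREY).sum() >= 3:
        sets[GREY] = np.flatnonzero(label_arr == GREY)
    return sets


def _run_permutation_engine(evaluate: Callable[..., dict],
                            labels: ModuleAssignment,
                            n_nodes: int,
                            config: PreservationConfig,
                            network_class: str) -> PreservationResult:
    """Shared observed + null + summary machinery for both input modes.

    ``evaluate(index_sets, proper, perm)`` maps {module: node index array}
    (with the proper-module subset used for separability) to
    {module: {statistic: value}}.  The null is built by randomly relabeling
    the test network's nodes: each replicate keeps every module's reference
    node set fixed and evaluates the test side on the module's image under a
    random permutation of the node universe, so the observed statistic is
    exchangeable with its null replicates when the test network carries no
    information about the module.
    """
    rng = np.random.default_rng(config.seed)
    lab_arr = labels.label_array
    proper = labels.proper_modules(config.min_module_size)
    if not proper:
        raise ValueError("no proper module of sufficient size")
    skipped = [q for q in set(labels.labels) - {GREY}
               if q not in proper]
    if skipped:
        logger.warning("modules below min size skipped: %s", sorted(skipped))

    gold_size = config.gold_size or min(1000, n_nodes)
    gold_idx = np.sort(rng.choice(n_nodes, size=gold_size, replace=False))

    observed_sets = _index_sets_for_labels(lab_arr, proper, include_grey=True)
    observed_sets[GOLD] = gold_idx
    observed = evaluate(observed_sets, proper, None)

    modules = list(observed)
    stat_names = sorted({s for v in observed.values() for s in v})
    sizes = {q: len(observed_sets[q]) for q in modules}

    # null samples: random relabelings of the test network
    nperm = config.n_permutations
    null = {q: {s: np.full(nperm, np.nan) for s in stat_names} for q in modules}
    if config.permute_all_nodes:
        pool = np.arange(n_nodes)
    else:
        pool = np.flatnonzero(lab_arr != GREY)
    for r in range(nperm):
        perm = np.arange(n_nodes)
        perm[pool] = pool[rng.permutation(len(pool))]
        vals_r = evaluate(observed_sets, proper, perm)
        for q in modules:
            if q not in vals_r:
                continue
            for s, v in vals_r[q].items():
                null[q][s][r] = v

    # long-format results
    rows = []
    z_tab: dict[str, dict[str, float]] = {q: {} for q in modules}
    p_tab: dict[str, dict[str, float]] = {q: {} for q in modules}
    n_tests = len(modules)
    for q in modules:
        for s in stat_names:
            obs = observed[q].get(s, float("nan"))
            if nperm > 0:
                mu, sigma, z, lp = z_statistic(obs, null[q][s])
                n_missing = int(np.sum(~np.isfinite(null[q][s])))
            else:
                mu = sigma = z = lp = float("nan")
                n_missing = 0
            z_tab[q][s] = z
            p_tab[q][s] = lp
            lp_bonf = min(0.0, lp + np.log10(n_tests)) if np.isfinite(lp) else float("nan")
            rows.append({
                "module": q, "module_size": sizes[q], "statistic": s,
                "observed": obs, "null_mean": mu, "null_sd": sigma, "Z": z,
                "log10_p": lp, "log10_p_bonferroni": lp_bonf,
                "n_null_missing": n_missing,
            })
    results = pd.DataFrame(rows)
    if nperm == 0:
        results = results.drop(columns=["null_mean", "null_sd", "Z",
                                        "log10_p", "log10_p_bonferroni",
                                        "n_null_missing"])

    # composites (ranks over proper modules only)
    obs_frame = pd.DataFrame({q: observed[q] for q in proper}).T
    ranks = median_rank(obs_frame, network_class) if len(proper) >= 2 else None
    comp_rows = []
    for q in modules:
        row: dict[str, object] = {"module": q, "module_size": sizes[q],
                                  "module_type": "proper" if q in proper else "improper"}
        if nperm > 0:
            row.update(composite_z(z_tab[q], network_class))
            row["summary_log10_p"] = summary_logp(p_tab[q], network_class)
            zsum_name = "Zsummary" if network_class == "correlation" else "Zsummary.adj"
            row["evidence"] = evidence_flag(row[zsum_name])
        if ranks is not None and q in ranks.index:
            row.update(ranks.loc[q].to_dict())
        comp_rows.append(row)
    composites = pd.DataFrame(comp_rows)

    metadata = {
        "n_nodes": n_nodes,
        "n_permutations": nperm,
        "seed": config.seed,
        "network_class": network_class,
        "correlation": config.correlation,
        "network": config.network,
        "power": config.power,
        "gold_size": gold_size,
        "min_module_size": config.min_module_size,
        "proper_modules": proper,
        "skipped_modules": sorted(skipped),
        "separability_aggregation": "min over other proper modules",
        "eigennode_separability_sign": ("1-|cor|" if config.network == "unsigned"
                                        else "1-cor"),
        "n_undefined_observed": int(sum(
            0 if np.isfinite(v) else 1
            for d in observed.values() for v in d.values())),
    }
    return PreservationResult(results=results, composites=composites,
                              metadata=metadata)


def run_preservation_expression(X_ref: ExpressionMatrix,
                                X_test: ExpressionMatrix,
                                labels: ModuleAssignment,
                                config: Optional[PreservationConfig] = None
                                ) -> PreservationResult:
    """Full preservation run for paired expression matrices."""
    config = config or PreservationConfig()
    study = PairedExpressionStudy(X_ref, X_test, method=config.correlation,
                                  mode=config.network, power=config.power)
    lab = labels.reorder(study.node_ids)
    ref_cache: dict = {}

    def evaluate(index_sets, proper, perm):
        return _evaluate_expression_labeling(study, index_sets, proper,
                                             config.include_general,
                                             perm=perm, ref_cache=ref_cache)

    res = _run_permutation_engine(evaluate, lab, study.n_nodes, config,
                                  network_class="correlation")
    res.metadata["input_mode"] = "expression"
    res.metadata["power"] = study.beta
    return res


def run_preservation_adjacency(A_ref: AdjacencyMatrix,
                               A_test: AdjacencyMatrix,
                               labels: ModuleAssignment,
                               config: Optional[PreservationConfig] = None
                               ) -> PreservationResult:
    """Full preservation run for a pair of adjacency matrices."""
    config = config or PreservationConfig()
    if list(A_ref.node_ids) != list(A_test.node_ids):
        raise ValueError("reference and test adjacencies must share the node universe")
    lab = labels.reorder(A_ref.node_ids)

    def evaluate(index_sets, proper, perm):
        return _evaluate_adjacency_labeling(A_ref.values, A_test.values,
                                            index_sets, proper, perm=perm)

    res = _run_permutation_engine(evaluate, lab, A_ref.n_nodes, config,
                                  network_class="general")
    res.metadata["input_mode"] = "adjacency"
    return res


def run_quality(X_ref: ExpressionMatrix, labels: ModuleAssignment,
                config: Optional[PreservationConfig] = None) -> PreservationResult:
    """Module quality run: density/separability statistics of the reference
    network itself, with Z scores from permuted reference labels."""
    from .preserve_cor import QUALITY_STATS
    config = config or PreservationConfig()
    study = PairedExpressionStudy(X_ref, X_ref, method=config.correlation,
                                  mode=config.network, power=config.power)
    lab = labels.reorder(study.node_ids)
    ref_cache: dict = {}

    def evaluate(index_sets, proper, perm):
        full = _evaluate_expression_labeling(study, index_sets, proper,
                                             include_general=True,
                                             perm=perm, ref_cache=ref_cache)
        return {q: {s: v for s, v in d.items() if s in QUALITY_STATS}
                for q, d in full.items()}

    res = _run_permutation_engine(evaluate, lab, study.n_nodes, config,
                                  network_class="correlation")
    res.metadata["input_mode"] = "quality"
    return res
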