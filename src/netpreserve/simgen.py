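"""Synthetic paired co-expression studies with known preservation truth.

Each proper module is seeded by a latent profile ("eigengene"): module node
``i`` is simulated as ``r_i * seed + sqrt(1 - r_i^2) * noise`` with the
membership correlations ``r_i`` evenly spaced over the module.  Whether and
how the module reappears in the test set defines its ground truth:

* ``both``              — same seed and membership assignment, fresh noise
                          (density and connectivity preserved);
* ``density_only``      — same module re-simulated but node identities
                          shuffled within the module (density kept,
                          connectivity destroyed);
* ``connectivity_only`` — "pathway" module assembled from several preserved
                          source clusters, so pairwise correlation patterns
                          persist while the module itself is sparse;
* ``none``              — independent noise (or membership permuted away)
                          in the test set.

Grey (unassigned) nodes are independent noise in both sets.  Seven stock
scenarios mirror common comparative co-expression situations; a 4-point
grading rule scores how well a statistic separates preserved from
non-preserved modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np

from .netcore import GREY, ExpressionMatrix, ModuleAssignment

SCENARIO_IDS = ("weak", "strong", "permuted", "half_permuted",
                "intramodular_permuted", "pathway_small", "pathway_large")

TRUTH_VALUES = ("both", "density_only", "connectivity_only", "none")


@dataclass
class ScenarioSpec:
    """Parameters of one simulation scenario."""

    scenario: str
    module_sizes: list[int]
    truth: list[str]                  # per module, parallel to module_sizes
    min_cor: float = 0.6
    max_cor: float = 0.95
    n_samples: int = 100
    grey_fraction: float = 0.25       # grey noise nodes / proper-module nodes
    seed: int = 0
    # pathway scenarios only: source clusters per truth class
    n_source_clusters: int = 4

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if len(self.truth) != len(self.module_sizes):
            raise ValueError("truth and module_sizes lengths differ")
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 3")
        if not (0 < self.min_cor <= self.max_cor < 1):
            raise ValueError("need 0 < min_cor <= max_cor < 1")
        if any(t not in TRUTH_VALUES for t in self.truth):
            raise ValueError(f"truth values must be in {TRUTH_VALUES}")


@dataclass
class SimulatedStudy:
    reference: ExpressionMatrix
    test: ExpressionMatrix
    labels: ModuleAssignment
    truth: dict[str, str]             # module label -> truth value
    spec: ScenarioSpec
    # pathway scenarios: reference-side source-cluster label per node
    source_clusters: Optional[ModuleAssignment] = None

    def preserved_modules(self) -> list[str]:
        return [q for q, t in self.truth.items() if t != "none"]


def _even_sizes(lo: int, hi: int, k: int) -> list[int]:
    """k integers evenly spaced in [lo, hi], both endpoints attained."""
    return [int(round(v)) for v in np.linspace(lo, hi, k)]


def scenario_spec(scenario: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Stock parameterization of one of the seven scenarios."""
    if scenario == "weak":
        sizes = [200] * 20
        truth = ["both"] * 10 + ["none"] * 10
        spec = ScenarioSpec(scenario, sizes, truth, min_cor=0.3, max_cor=0.6,
                            seed=seed)
    elif scenario == "strong":
        sizes = _even_sizes(100, 400, 10)
        truth = ["both"] * 5 + ["none"] * 5
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    elif scenario == "permuted":
        sizes = _even_sizes(100, 400, 10)
        truth = ["none"] * 10
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    elif scenario == "half_permuted":
        sizes = _even_sizes(100, 400, 10)
        truth = ["both"] * 5 + ["none"] * 5
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    elif scenario == "intramodular_permuted":
        sizes = _even_sizes(100, 400, 10)
        truth = ["density_only"] * 5 + ["none"] * 5
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    elif scenario == "pathway_small":
        sizes = _even_sizes(25, 100, 5) * 2
        truth = ["connectivity_only"] * 5 + ["none"] * 5
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    elif scenario == "pathway_large":
        sizes = _even_sizes(100, 500, 5) * 2
        truth = ["connectivity_only"] * 5 + ["none"] * 5
        spec = ScenarioSpec(scenario, sizes, truth, seed=seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if overrides:
        spec = replace(spec, **overrides)
    return spec


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _module_block(rng: np.random.Generator, seed_profile: np.ndarray,
                  r: np.ndarray) -> np.ndarray:
    """Node profiles r_i * seed + sqrt(1 - r_i^2) * noise (samples x nodes)."""
    m = seed_profile.shape[0]
    noise = rng.standard_normal((m, r.shape[0]))
    return seed_profile[:, None] * r[None, :] + np.sqrt(1.0 - r**2)[None, :] * noise


def _membership_grid(spec: ScenarioSpec, size: int) -> np.ndarray:
    return np.linspace(spec.min_cor, spec.max_cor, size)


def simulate_scenario(spec_or_name, seed: Optional[int] = None) -> SimulatedStudy:
    """Generate a paired reference/test study for one scenario.

    Accepts a :class:`ScenarioSpec` or a scenario name; an explicit ``seed``
    overrides the spec's.  Identical spec and seed give bit-identical output.
    """
    if isinstance(spec_or_name, str):
        spec = scenario_spec(spec_or_name, seed=seed if seed is not None else 0)
    else:
        spec = spec_or_name if seed is None else replace(spec_or_name, seed=seed)
    if spec.scenario in ("pathway_small", "pathway_large"):
        return _simulate_pathway(spec)
    return _simulate_clustered(spec)


def _simulate_clustered(spec: ScenarioSpec) -> SimulatedStudy:
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    labels_per_module = [str(i + 1) for i in range(len(spec.module_sizes))]
    n_proper = sum(spec.module_sizes)
    n_grey = int(round(spec.grey_fraction * n_proper))
    n = n_proper + n_grey

    ref = np.empty((m, n))
    test = np.empty((m, n))
    label_vec = [GREY] * n
    truth: dict[str, str] = {}

    col = 0
    module_cols: dict[str, np.ndarray] = {}
    for q, size, t in zip(labels_per_module, spec.module_sizes, spec.truth):
        idx = np.arange(col, col + size)
        module_cols[q] = idx
        col += size
        for i in idx:
            label_vec[i] = q
        truth[q] = t
        r = _membership_grid(spec, size)
        seed_ref = rng.standard_normal(m)
        ref[:, idx] = _module_block(rng, seed_ref, r)
        if spec.scenario == "permuted":
            # test has its own structured module here; the global column
            # permutation below breaks the correspondence
            seed_test = rng.standard_normal(m)
            test[:, idx] = _module_block(rng, seed_test, r)
        elif t == "both":
            test[:, idx] = _module_block(rng, seed_ref, r)
        elif t == "density_only":
            block = _module_block(rng, seed_ref, r)
            test[:, idx] = block[:, rng.permutation(size)]
        elif spec.scenario == "half_permuted":
            seed_test = rng.standard_normal(m)
            test[:, idx] = _module_block(rng, seed_test, r)
        else:  # none: independent noise
            test[:, idx] = rng.standard_normal((m, size))
    grey_idx = np.arange(col, n)
    ref[:, grey_idx] = rng.standard_normal((m, n_grey))
    test[:, grey_idx] = rng.standard_normal((m, n_grey))

    if spec.scenario == "permuted":
        test = test[:, rng.permutation(n)]
    elif spec.scenario == "half_permuted":
        scramble = np.concatenate([module_cols[q] for q, t in truth.items()
                                   if t == "none"])
        test[:, scramble] = test[:, rng.permutation(scramble)]

    node_ids = [f"node_{i + 1}" for i in range(n)]
    sample_ids_r = [f"ref_s{i + 1}" for i in range(m)]
    sample_ids_t = [f"test_s{i + 1}" for i in range(m)]
    return SimulatedStudy(
        reference=ExpressionMatrix(ref, sample_ids_r, node_ids),
        test=ExpressionMatrix(test, sample_ids_t, node_ids),
        labels=ModuleAssignment(node_ids, label_vec),
        truth=truth,
        spec=spec,
    )


def _simulate_pathway(spec: ScenarioSpec) -> SimulatedStudy:
    """Pathway modules: nodes sampled equally across several source clusters.

    Preserved source clusters reappear in the test set (same seed, fresh
    noise); non-preserved source clusters are re-simulated in the test set
    with their membership permuted among themselves.  Pathway modules sampled
    from preserved clusters therefore retain their pairwise correlation
    pattern (connectivity) while being sparse (low density).
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    n_src = spec.n_source_clusters
    if n_src < 3:
        raise ValueError("pathway scenarios need >= 3 source clusters")

    by_class = {"connectivity_only": [], "none": []}
    for q, size, t in zip(range(len(spec.module_sizes)), spec.module_sizes, spec.truth):
        key = "connectivity_only" if t == "connectivity_only" else "none"
        by_class[key].append((str(q + 1), size))

    blocks_ref, blocks_test, label_chunks, cluster_chunks = [], [], [], []
    truth: dict[str, str] = {}
    offset = 0
    for cls, modules in by_class.items():
        if not modules:
            continue
        total = sum(s for _, s in modules)
        cluster_size = math.ceil(total / n_src * 1.3)
        cluster_cols = []
        cls_ref = np.empty((m, cluster_size * n_src))
        cls_test = np.empty((m, cluster_size * n_src))
        cls_cluster_labels = np.empty(cluster_size * n_src, dtype=object)
        for c in range(n_src):
            idx = np.arange(c * cluster_size, (c + 1) * cluster_size)
            cluster_cols.append(idx)
            cls_cluster_labels[idx] = f"{cls}_cluster_{c + 1}"
            r = _membership_grid(spec, cluster_size)
            seed_ref = rng.standard_normal(m)
            cls_ref[:, idx] = _module_block(rng, seed_ref, r)
            if cls == "connectivity_only":
                cls_test[:, idx] = _module_block(rng, seed_ref, r)
            else:
                seed_test = rng.standard_normal(m)
                cls_test[:, idx] = _module_block(rng, seed_test, r)
        if cls == "none":
            n_cls = cls_test.shape[1]
            cls_test = cls_test[:, rng.permutation(n_cls)]
        # sample pathway module nodes equally across the source clusters
        avail = [list(rng.permutation(idx)) for idx in cluster_cols]
        cls_labels = np.array([GREY] * cls_ref.shape[1], dtype=object)
        for q, size in modules:
            take = [size // n_src] * n_src
            for j in range(size - sum(take)):
                take[j] += 1
            chosen = []
            for c in range(n_src):
                chosen.extend(avail[c][:take[c]])
                avail[c] = avail[c][take[c]:]
            chosen = np.asarray(sorted(chosen))
            cls_labels[chosen] = q
            truth[q] = cls if cls == "connectivity_only" else "none"
        blocks_ref.append(cls_ref)
        blocks_test.append(cls_test)
        label_chunks.append(cls_labels)
        cluster_chunks.append(cls_cluster_labels)
        offset += cls_ref.shape[1]

    n_struct = offset
    n_grey = int(round(spec.grey_fraction * sum(spec.module_sizes)))
    blocks_ref.append(rng.standard_normal((m, n_grey)))
    blocks_test.append(rng.standard_normal((m, n_grey)))
    label_chunks.append(np.array([GREY] * n_grey, dtype=object))
    cluster_chunks.append(np.array([GREY] * n_grey, dtype=object))

    ref = np.concatenate(blocks_ref, axis=1)
    test = np.concatenate(blocks_test, axis=1)
    label_vec = list(np.concatenate(label_chunks))
    cluster_vec = list(np.concatenate(cluster_chunks))
    n = n_struct + n_grey
    node_ids = [f"node_{i + 1}" for i in range(n)]
    return SimulatedStudy(
        reference=ExpressionMatrix(ref, [f"ref_s{i + 1}" for i in range(m)], node_ids),
        test=ExpressionMatrix(test, [f"test_s{i + 1}" for i in range(m)], node_ids),
        labels=ModuleAssignment(node_ids, label_vec),
        truth=truth,
        spec=spec,
        source_clusters=ModuleAssignment(node_ids, cluster_vec),
    )


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

def _best_cut_misclassification(pres: np.ndarray, non: np.ndarray,
                                higher_is_preserved: bool) -> int:
    """Minimum misclassification count over all thresholds.

    A module is called preserved when its value is on the preserved side of
    the cut; ties between equally accurate cuts are broken toward fewer
    false preserved calls (the stricter threshold).
    """
    if not higher_is_preserved:
        pres, non = -pres, -non
    values = np.concatenate([pres, non])
    cuts = np.concatenate([[-np.inf], np.sort(np.unique(values)), [np.inf]])
    best = len(values)
    for t in cuts:
        miss = int((pres < t).sum() + (non >= t).sum())
        # iterating cuts in increasing order: later (stricter) cuts win ties
        if miss <= best:
            best = miss
    return best


def grade_statistic(values: Mapping[str, float], preserved: Mapping[str, bool],
                    rule: str = "z_thresholds") -> int:
    """4-point grade for how well per-module values separate ground truth.

    ``z_thresholds`` (higher = more preserved): grade 4 when every preserved
    module has Z >= 10 and every non-preserved Z <= 2; grade 3 when preserved
    and non-preserved separate perfectly but violate a threshold; grade 2
    when at most 20% of modules are misclassified at the best separating
    cut; grade 1 otherwise.

    ``rank_separation`` (lower = more preserved, for medianRank): grade 4
    when every preserved module's value is below every non-preserved one's;
    otherwise the 2/1 rungs of the same ladder apply.
    """
    pres = np.array([v for q, v in values.items() if preserved[q]], float)
    non = np.array([v for q, v in values.items() if not preserved[q]], float)
    if pres.size == 0 or non.size == 0:
        raise ValueError("need at least one preserved and one non-preserved module")
    if not (np.isfinite(pres).all() and np.isfinite(non).all()):
        raise ValueError("grading requires finite values")
    n_total = pres.size + non.size

    if rule == "z_thresholds":
        if (pres >= 10).all() and (non <= 2).all():
            return 4
        if pres.min() > non.max():
            return 3
        miss = _best_cut_misclassification(pres, non, higher_is_preserved=True)
        return 2 if miss <= 0.2 * n_total else 1
    if rule == "rank_separation":
        if pres.max() < non.min():
            return 4
        miss = _best_cut_misclassification(pres, non, higher_is_preserved=False)
        return 2 if miss <= 0.2 * n_total else 1
    raise ValueError(f"unknown grading rule {rule!r}")
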