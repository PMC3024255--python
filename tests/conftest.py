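import numpy as np
import pytest

from netpreserve import ExpressionMatrix, ModuleAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_paired_study(rng):
    """Two modules of 4 nodes + 2 grey nodes, 12 samples, partial preservation.

    Small enough for brute-force loop oracles over every statistic.
    """
    m, n = 12, 10
    seed1 = rng.standard_normal(m)
    seed2 = rng.standard_normal(m)
    r = np.array([0.9, 0.8, 0.7, 0.6])

    def block(seed, r_):
        noise = rng.standard_normal((m, r_.size))
        return seed[:, None] * r_[None, :] + np.sqrt(1 - r_**2) * noise

    ref = np.hstack([block(seed1, r), block(seed2, r), rng.standard_normal((m, 2))])
    test = np.hstack([block(seed1, r),                      # module 1 preserved
                      rng.standard_normal((m, 4)),          # module 2 not
                      rng.standard_normal((m, 2))])
    nodes = [f"g{i}" for i in range(n)]
    X_ref = ExpressionMatrix(ref, node_ids=nodes)
    X_test = ExpressionMatrix(test, node_ids=nodes)
    labels = ModuleAssignment(nodes, ["1"] * 4 + ["2"] * 4 + ["grey"] * 2)
    return X_ref, X_test, labels
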