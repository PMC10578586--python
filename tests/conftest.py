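import numpy as np
import pandas as pd
import pytest

from colonyevo import surface_model as sm
from colonyevo import synth


@pytest.fixture(scope="session")
def small_domain():
    """Coarse, short domain for cheap physics tests."""
    return sm.Domain(R_max=10.0, n_r=101, D_N=0.01, N0=1.0)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic transcriptome with ground truth (seed 1)."""
    cfg = synth.default_config(seed=1)
    ann = synth.gen_regulons_operons(cfg)
    expr, truth = synth.gen_transcriptome(cfg, ann)
    return cfg, ann, expr, truth


@pytest.fixture(scope="session")
def normalized_synthetic(default_synthetic):
    from colonyevo.regulon import normalize_log, size_factors

    _, _, expr, _ = default_synthetic
    return normalize_log(expr.counts, size_factors(expr.counts))


def bh_stepup_reference(pvals):
    """Independent Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def fisher_two_sided_reference(table):
    """Two-sided Fisher p by full enumeration of hypergeometric tables."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n_total, row1, col1)
    support = range(max(0, row1 + col1 - n_total), min(row1, col1) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9)))
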