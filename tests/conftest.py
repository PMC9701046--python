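import itertools

import numpy as np
import pandas as pd
import pytest

from stcpipe import ExpressionMatrix, SimConfig, simulate_dataset

GROUPS = ("control", "challenged", "after_4w")


def make_matrix(linear_values, groups=GROUPS, reps=3, genes=None):
    """ExpressionMatrix from a G x (len(groups)*reps) array of linear signals."""
    arr = np.asarray(linear_values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"{g}_{j + 1}" for g in groups for j in range(reps)]
    values = pd.DataFrame(arr, index=pd.Index(genes, name="gene"),
                          columns=samples)
    design = pd.Series([g for g in groups for _ in range(reps)],
                       index=samples, name="group")
    return ExpressionMatrix(values, design, list(groups))


@pytest.fixture(scope="session")
def null_dataset():
    """All-flat genes with inverse-gamma variances: the type-I-error fixture."""
    config = SimConfig(n_genes=2000, profile_fractions={}, seed=0)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def planted_dataset():
    """Planted profiles 5 and 6, effect 1.0 log2/step, per-gene sd ~= 0.25."""
    config = SimConfig(n_genes=1000, profile_fractions={5: 0.2, 6: 0.1},
                       effect_size=1.0, variance_prior_shape=8.0,
                       variance_prior_scale=2.0, seed=11)
    return simulate_dataset(config)


# ---------------------------------------------------------------------
# independent oracles (deliberately naive; never call the implementation)
# ---------------------------------------------------------------------

def oneway_f_oracle(groups_of_values):
    """Textbook one-way ANOVA F and p from a list of per-group arrays."""
    from scipy import stats

    k = len(groups_of_values)
    ns = [len(g) for g in groups_of_values]
    n = sum(ns)
    grand = sum(float(np.sum(g)) for g in groups_of_values) / n
    ssb = sum(m * (float(np.mean(g)) - grand) ** 2
              for m, g in zip(ns, groups_of_values))
    ssw = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2))
              for g in groups_of_values)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, float(stats.f.sf(f, k - 1, n - k))


def hypergeom_tail_oracle(nf, n, Nf, N):
    """P(overlap >= nf) by exhaustive summation over the support."""
    from math import comb

    total = comb(N, n)
    upper = min(n, Nf)
    return sum(comb(Nf, k) * comb(N - Nf, n - k)
               for k in range(nf, upper + 1)) / total


def clustering_oracle(graph):
    """Clustering coefficients by counting edges among neighbor pairs."""
    out = {}
    for v in graph.nodes:
        nbrs = list(graph[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if graph.has_edge(a, b))
        out[v] = 2 * links / (k * (k - 1))
    return out


def kcore_oracle(graph):
    """Core numbers by exhaustive subgraph search (graphs <= ~12 nodes):
    core(v) = max over vertex subsets S containing v of the minimum degree
    of the induced subgraph G[S]."""
    nodes = list(graph.nodes)
    core = {v: 0 for v in nodes}
    for size in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            sub = graph.subgraph(subset)
            mindeg = min(dict(sub.degree).values())
            for v in subset:
                core[v] = max(core[v], mindeg)
    return core


def pearson_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
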