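"""Synthetic expression data with known ground truth.

Emulates the study design the pipeline targets — m ordered conditions
(default: control, allergen-challenged, four weeks after) with a few array
replicates each — so every stage has a recovery-based test surface:

* gene variances are drawn from an inverse-gamma prior (the reciprocal of a
  ``Gamma(a, scale=b)`` draw), the same hierarchical model the moderated
  F-test assumes;
* a configurable fraction of genes is planted on unit-change model
  profiles: their group log2 means are ``baseline + effect_size * position``;
  the remaining genes are flat at baseline;
* replicate log2 values are i.i.d. normal around the group means, and the
  matrix is exponentiated to linear scale — so the within-group geometric
  mean of the linear signals estimates the planted log2 mean exactly.

Also provides gene-set collections with planted enriched sets (GMT
serializable) and seeded Erdős–Rényi graphs as oracle fixtures for the
network metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .profiles import enumerate_profiles

logger = logging.getLogger("stcpipe")

VARIANCE_FLOOR = 1e-6

DEFAULT_GROUPS = ("control", "challenged", "after_4w")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    ``profile_fractions`` maps profile id (for the design's m and c=1) to
    the fraction of genes planted on that profile; the remainder are null
    (flat).  ``effect_size`` is the log2-units step per unit of profile
    change.  ``variance_prior_shape``/``variance_prior_scale`` are the
    (a, b) of the inverse-gamma variance prior.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    profile_fractions: Mapping[int, float] = field(default_factory=dict)
    effect_size: float = 1.0
    variance_prior_shape: float = 2.0
    variance_prior_scale: float = 1.0
    baseline_log2_mean: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.replicates_per_group < 1:
            raise ValueError("n_genes and replicates_per_group must be >= 1")
        if len(self.groups) < 2:
            raise ValueError("need m >= 2 ordered groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if self.variance_prior_shape <= 0 or self.variance_prior_scale <= 0:
            raise ValueError("variance prior a, b must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        total = sum(self.profile_fractions.values())
        if total > 1 + 1e-12:
            raise ValueError(f"profile fractions sum to {total} > 1")
        if any(f < 0 for f in self.profile_fractions.values()):
            raise ValueError("negative profile fraction")
        n_profiles = 3 ** (len(self.groups) - 1) - 1
        bad = [p for p in self.profile_fractions if not 0 <= p < n_profiles]
        if bad:
            raise ValueError(
                f"profile ids {bad} invalid for m={len(self.groups)}, c=1"
            )


def simulate_dataset(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one expression matrix plus its ground-truth table.

    The truth table is indexed by gene with columns ``profile`` (nullable
    integer, NA for null genes), ``mean_<group>`` (true group log2 means)
    and ``variance`` (true per-gene log2 variance).  Identical config and
    seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = len(config.groups)
    r = config.replicates_per_group
    G = config.n_genes
    profiles = enumerate_profiles(m, 1)
    positions = {p.id: np.array(p.positions, dtype=float) for p in profiles}

    genes = [f"gene_{i:05d}" for i in range(G)]
    samples = [f"{g}_{j + 1}" for g in config.groups for j in range(r)]
    sample_groups = pd.Series(
        [g for g in config.groups for _ in range(r)], index=samples, name="group"
    )

    # planted profile labels: contiguous blocks in ascending profile id
    labels = np.full(G, -1, dtype=int)
    start = 0
    for pid in sorted(config.profile_fractions):
        count = int(round(config.profile_fractions[pid] * G))
        labels[start:start + count] = pid
        start += count

    variances = 1.0 / rng.gamma(config.variance_prior_shape,
                                scale=config.variance_prior_scale, size=G)
    variances = np.maximum(variances, VARIANCE_FLOOR)

    group_means = np.full((G, m), config.baseline_log2_mean)
    for i in range(G):
        if labels[i] >= 0:
            group_means[i] += config.effect_size * positions[labels[i]]

    noise = rng.normal(size=(G, m * r)) * np.sqrt(variances)[:, None]
    log2_vals = np.repeat(group_means, r, axis=1) + noise
    values = pd.DataFrame(np.exp2(log2_vals), index=pd.Index(genes, name="gene"),
                          columns=samples)
    matrix = ExpressionMatrix(values, sample_groups, list(config.groups))

    truth = pd.DataFrame(index=values.index)
    truth["profile"] = pd.array([None if l < 0 else int(l) for l in labels],
                                dtype="Int64")
    for k, g in enumerate(config.groups):
        truth[f"mean_{g}"] = group_means[:, k]
    truth["variance"] = variances
    return matrix, truth


# ---------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe; GMT-serializable."""

    sets: dict[str, tuple[str, list[str]]]  # id -> (description, members)
    universe: list[str]

    def __len__(self) -> int:
        return len(self.sets)

    def harmonized(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Restrict members to ``universe``; empty sets are dropped."""
        uni = set(universe)
        sets = {}
        for sid, (desc, members) in self.sets.items():
            kept = [g for g in members if g in uni]
            if kept:
                sets[sid] = (desc, kept)
        return GeneSetCollection(sets, list(universe))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set id, description, tab-separated members).

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than 3 fields is an error citing its line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    universe: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT needs id, description and at least one member"
                )
            sid, desc, members = fields[0], fields[1], fields[2:]
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) < len([m for m in members if m]):
                logger.warning("GMT set %s: duplicate members deduplicated", sid)
            sets[sid] = (desc, deduped)
            for g in deduped:
                universe[g] = None
    return GeneSetCollection(sets, list(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


def simulate_gene_sets(truth: pd.DataFrame, n_sets: int, set_size: int,
                       planted: Sequence[int] = (), seed: int = 0,
                       planted_purity: float = 0.8) -> GeneSetCollection:
    """Random gene sets plus one planted (profile-enriched) set per
    requested profile id.

    A planted set draws at least ``planted_purity`` (default 80%) of its
    members from genes whose true profile is the requested one, the rest
    from other genes.
    """
    if len(truth) == 0:
        raise ValueError("empty truth table")
    if set_size > len(truth):
        raise ValueError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.index)
    sets: dict[str, tuple[str, list[str]]] = {}
    for pid in planted:
        on = genes[(truth["profile"] == pid).fillna(False).to_numpy(dtype=bool)]
        if len(on) == 0:
            raise ValueError(f"no genes planted on profile {pid}")
        k = min(math.ceil(planted_purity * set_size), len(on), set_size)
        if k < math.ceil(planted_purity * set_size):
            raise ValueError(
                f"profile {pid} has only {len(on)} genes; cannot reach "
                f"{planted_purity:.0%} of set_size={set_size}"
            )
        members = list(rng.choice(on, size=k, replace=False))
        off = genes[~np.isin(genes, members)]
        members += list(rng.choice(off, size=set_size - k, replace=False))
        sets[f"planted_profile_{pid}"] = (
            f"synthetic set enriched for profile {pid} genes", members)
    for i in range(n_sets):
        members = list(rng.choice(genes, size=set_size, replace=False))
        sets[f"random_set_{i:03d}"] = ("synthetic random set", members)
    return GeneSetCollection(sets, list(genes))


def simulate_hub_dataset(n_background: int = 80, n_module: int = 20,
                         groups: Sequence[str] = DEFAULT_GROUPS,
                         replicates_per_group: int = 3, hub_corr: float = 0.95,
                         baseline_log2_mean: float = 8.0,
                         seed: int = 0) -> tuple[ExpressionMatrix, str]:
    """Expression matrix with one planted correlated module and its hub.

    The hub gene gets unit-variance log2 fluctuations across samples; each
    of the ``n_module`` member genes is ``hub_corr`` correlated with it
    (``x = rho*hub + sqrt(1-rho^2)*noise``); background genes are
    independent noise.  Returns the matrix and the hub's gene id —
    a recovery fixture for hub ranking.
    """
    if not 0 < hub_corr <= 1:
        raise ValueError("hub_corr must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m, r = len(groups), replicates_per_group
    S = m * r
    samples = [f"{g}_{j + 1}" for g in groups for j in range(r)]
    sample_groups = pd.Series([g for g in groups for _ in range(r)],
                              index=samples, name="group")
    hub = rng.normal(size=S)
    module = hub_corr * hub + math.sqrt(1 - hub_corr ** 2) * \
        rng.normal(size=(n_module, S))
    background = rng.normal(size=(n_background, S))
    log2 = baseline_log2_mean + np.vstack([hub, module, background])
    genes = (["hub_00000"]
             + [f"module_{i:05d}" for i in range(n_module)]
             + [f"bg_{i:05d}" for i in range(n_background)])
    values = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"),
                          columns=samples)
    return ExpressionMatrix(values, sample_groups, list(groups)), "hub_00000"


def simulate_random_graph(n_nodes: int, edge_prob: float, seed: int = 0) -> nx.Graph:
    """Seeded Erdős–Rényi G(n, p) graph (oracle fixture for graph metrics)."""
    if n_nodes == 0:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    return nx.gnp_random_graph(n_nodes, edge_prob, seed=seed)
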