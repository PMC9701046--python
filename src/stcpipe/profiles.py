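"""Series test of cluster (STC): model-profile clustering of short
expression series.

A *model profile* over ``m`` ordered conditions is a vector of ``m - 1``
per-transition unit changes, each in ``{-c, …, +c}``, anchored at 0 in the
first condition (positions are cumulative sums of the changes).  The
all-constant profile is excluded, leaving ``(2c+1)**(m-1) - 1`` candidates
— 8 for the canonical three-condition design with c=1.

Genes (normally the differentially expressed set) are transformed to
first-group-anchored log2 ratios of within-group geometric means and each
is assigned to the profile whose position vector it correlates with best
(Pearson).  Profile significance compares the observed count under the
true condition ordering against the average count over all ``m!``
orderings of the conditions, via a one-sided Fisher exact test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("stcpipe")


@dataclass(frozen=True)
class ModelProfile:
    """One candidate expression trajectory.

    ``changes`` has length m-1 with entries in [-c, c]; ``positions`` has
    length m, starts at 0, and is the cumulative sum of the changes.
    """

    id: int
    changes: tuple[int, ...]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if all(ch == 0 for ch in self.changes):
            raise ValueError("constant profile is excluded")
        pos = (0, *itertools.accumulate(self.changes))
        if tuple(self.positions) != pos:
            raise ValueError("positions inconsistent with changes")


def enumerate_profiles(m: int, c: int = 1) -> list[ModelProfile]:
    """All non-constant unit-change profiles for ``m`` ordered groups.

    Change vectors are ordered lexicographically with -c < … < 0 < … < +c
    and ids assigned densely in that order, so for (m=3, c=1) profile 0 is
    (-1,-1) (steady decrease) and profile 7 is (+1,+1) (steady increase).
    """
    if m < 2:
        raise ValueError(f"need at least 2 ordered groups, got m={m}")
    if c < 1:
        raise ValueError(f"unit-change limit must be >= 1, got c={c}")
    profiles = []
    for changes in itertools.product(range(-c, c + 1), repeat=m - 1):
        if all(ch == 0 for ch in changes):
            continue
        positions = (0, *itertools.accumulate(changes))
        profiles.append(ModelProfile(len(profiles), changes, positions))
    return profiles


def profile_catalog(profiles: list[ModelProfile]) -> pd.DataFrame:
    """Profiles as a table (one row per profile, serialization-friendly)."""
    return pd.DataFrame(
        {
            "profile": [p.id for p in profiles],
            "changes": [",".join(map(str, p.changes)) for p in profiles],
            "positions": [",".join(map(str, p.positions)) for p in profiles],
        }
    )


def transform_to_log_ratios(matrix: ExpressionMatrix,
                            genes=None) -> pd.DataFrame:
    """First-group-anchored log2 ratios of within-group geometric means.

    For gene g the returned row is ``(0, log2(gm_2/gm_1), …, log2(gm_m/gm_1))``
    where ``gm_k`` is the geometric mean of the linear signals of group k —
    equivalently the mean of the log2 replicate values minus the group-1
    mean.  Requires strictly positive signals.
    """
    sub = matrix if genes is None else matrix.subset(genes)
    vals = sub.values.to_numpy(dtype=float)
    bad = (vals <= 0).any(axis=1)
    if bad.any():
        raise ValueError(
            f"non-positive signal for gene(s): {list(sub.values.index[bad][:10])}"
        )
    log2 = np.log2(vals)
    cols = list(sub.values.columns)
    group_means = np.column_stack([
        log2[:, [cols.index(s) for s in sub.samples_of(g)]].mean(axis=1)
        for g in sub.groups
    ])
    ratios = group_means - group_means[:, [0]]
    return pd.DataFrame(ratios, index=sub.values.index, columns=sub.groups)


def _correlations(ratios: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Pearson correlation of every ratio vector with every profile
    position vector (rows x profiles); rows with zero variance get NaN."""
    rc = ratios - ratios.mean(axis=1, keepdims=True)
    pc = positions - positions.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(rc, axis=1)
    pn = np.linalg.norm(pc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rc @ pc.T) / np.outer(rn, pn)
    corr[rn == 0, :] = np.nan
    return corr


def assign_profiles(ratios: pd.DataFrame,
                    profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each gene to its best-correlated model profile.

    Returns a frame indexed by gene with columns ``profile`` (nullable
    integer; NA for constant ratio vectors, whose correlation is
    undefined) and ``correlation``.  Exact ties go to the lowest profile
    id.
    """
    pos = np.array([p.positions for p in profiles], dtype=float)
    if ratios.shape[1] != pos.shape[1]:
        raise ValueError(
            f"ratio vectors have {ratios.shape[1]} groups but profiles were "
            f"enumerated for m={pos.shape[1]}"
        )
    corr = _correlations(ratios.to_numpy(dtype=float), pos)
    # round so that analytically tied correlations resolve to the lowest id
    best = np.nanargmax(np.where(np.isnan(corr), -np.inf, corr.round(12)),
                        axis=1).astype(float)
    unassigned = np.isnan(corr).all(axis=1)
    best[unassigned] = np.nan
    best_corr = np.where(
        unassigned, np.nan,
        corr[np.arange(len(corr)), np.nan_to_num(best).astype(int)],
    )
    return pd.DataFrame(
        {
            "profile": pd.array(
                [None if np.isnan(b) else int(b) for b in best], dtype="Int64"
            ),
            "correlation": best_corr,
        },
        index=ratios.index,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def profile_significance(assignment: pd.DataFrame, ratios: pd.DataFrame,
                         profiles: list[ModelProfile], alpha: float = 0.05,
                         method: str = "fisher") -> pd.DataFrame:
    """Permutation significance of per-profile gene counts.

    Every ordering of the condition columns (all m! of them, identity
    included) is applied to the ratio vectors, which are re-anchored so the
    permuted first group is 0, and genes are re-assigned; the expected
    count per profile is the mean over the orderings.  Each profile is then
    tested one-sided ("observed greater") with Fisher's exact test on the
    2x2 table [observed, n-observed; round(expected), n-round(expected)]
    (``method="binomial"`` swaps in an exact binomial test against
    expected/n).
    """
    n = len(ratios)
    if n == 0:
        raise ValueError("no genes to test (empty ratio table)")
    if method not in ("fisher", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    m = ratios.shape[1]
    pos = np.array([p.positions for p in profiles], dtype=float)
    rat = ratios.to_numpy(dtype=float)
    k = len(profiles)

    counts = np.zeros((0, k))
    observed = None
    for perm in itertools.permutations(range(m)):
        permuted = rat[:, perm] - rat[:, [perm[0]]]
        corr = _correlations(permuted, pos)
        best = np.nanargmax(np.where(np.isnan(corr), -np.inf, corr.round(12)),
                            axis=1)
        valid = ~np.isnan(corr).all(axis=1)
        cnt = np.bincount(best[valid], minlength=k).astype(float)
        counts = np.vstack([counts, cnt])
        if perm == tuple(range(m)):
            observed = cnt.astype(int)
    expected = counts.mean(axis=0)

    obs_from_assignment = (
        assignment["profile"].value_counts().reindex(range(k), fill_value=0)
    )
    if not np.array_equal(obs_from_assignment.to_numpy(), observed):
        logger.warning("assignment counts differ from identity-ordering "
                       "recount; using the recount")

    pvals = np.ones(k)
    for i in range(k):
        exp_i = _round_half_up(expected[i])
        if method == "fisher":
            table = [[int(observed[i]), n - int(observed[i])],
                     [exp_i, n - exp_i]]
            pvals[i] = stats.fisher_exact(table, alternative="greater")[1]
        else:
            pvals[i] = stats.binomtest(int(observed[i]), n,
                                       min(1.0, expected[i] / n),
                                       alternative="greater").pvalue
    return pd.DataFrame(
        {
            "profile": np.arange(k),
            "observed": observed,
            "expected": expected,
            "p_value": pvals,
            "significant": pvals < alpha,
        }
    )
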