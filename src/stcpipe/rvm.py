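"""Random-variance-model (RVM) moderated F-test for differential
expression across ordered groups.

With only a few replicates per condition, per-gene variance estimates are
unstable and the classical one-way F-test loses power.  The RVM places a
gamma prior on each gene's inverse variance: 1/sigma_g^2 ~ Gamma(a, scale=b).
Under this model the per-gene residual variance s_g^2 (pooled within
groups, d = S - m degrees of freedom) satisfies

    s_g^2 * a * b  ~  F(d, 2a),

which is how (a, b) are estimated — by maximizing the marginal likelihood
of the observed residual variances.  The moderated denominator shrinks
each s_g^2 toward the prior,

    sigma_tilde_g^2 = (d * s_g^2 + 2/b) / (d + 2a),

and the moderated statistic  F_g = MS_between_g / sigma_tilde_g^2  is
referred to an F distribution with (m - 1, d + 2a) degrees of freedom —
effectively adding 2a denominator df, the gain that matters at 3
replicates per group.  All variance computations are on log2 signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("stcpipe")

A_BOUNDS = (1e-3, 1e6)
B_BOUNDS = (1e-9, 1e9)


@dataclass(frozen=True)
class RVMPrior:
    """Fitted hyperparameters: 1/sigma^2 ~ Gamma(a, scale=b); d = S - m."""

    a: float
    b: float
    d: int

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.d < 1:
            raise ValueError("residual degrees of freedom must be >= 1")


def residual_variances(matrix: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Per-gene pooled within-group variance of log2 signals and its df."""
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    sizes = matrix.group_sizes()
    if min(sizes) < 2:
        bad = [g for g, n in zip(matrix.groups, sizes) if n < 2]
        raise ValueError(f"groups with < 2 replicates: {bad}")
    d = matrix.n_samples - matrix.n_groups
    log2 = matrix.log2_values().to_numpy(dtype=float)
    cols = list(matrix.values.columns)
    ss = np.zeros(matrix.n_genes)
    for g in matrix.groups:
        idx = [cols.index(s) for s in matrix.samples_of(g)]
        block = log2[:, idx]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return ss / d, d


def fit_rvm_prior(matrix: ExpressionMatrix) -> RVMPrior:
    """Estimate (a, b) by maximum likelihood on the residual variances.

    Uses the marginal law s^2*a*b ~ F(d, 2a); the optimizer starts from a
    method-of-moments point and runs L-BFGS-B on (log a, log b) with box
    constraints.  Raises on a constant matrix (all residual variances
    zero) and on optimizer non-convergence; warns when the fitted ``a``
    reaches its upper bound (the prior degenerates because the variances
    show no between-gene dispersion).
    """
    s2, d = residual_variances(matrix)
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero (constant matrix); "
                         "cannot fit a variance prior")
    # zero variances carry no density under the continuous marginal; clip
    s2 = np.maximum(s2, 1e-12)

    mean_s2 = float(np.mean(s2))
    if float(np.std(s2)) / mean_s2 < 1e-9:
        # no between-gene dispersion at all: the marginal likelihood
        # increases without bound in a, so the fit degenerates
        warnings.warn(
            "residual variances are identical across genes; the variance "
            "prior degenerates (shape parameter driven to its upper bound)",
            RuntimeWarning, stacklevel=2,
        )
        a = A_BOUNDS[1]
        return RVMPrior(a, 1.0 / (mean_s2 * (a - 1)), d)

    ratio = float(np.mean(s2 ** 2)) / mean_s2 ** 2
    denom = ratio * d - d - 2
    a0 = (2 * ratio * d - d - 2) / denom if denom > 0 else 50.0
    a0 = float(np.clip(a0, 0.1, 1e3))
    b0 = 1.0 / (mean_s2 * (a0 - 1)) if a0 > 1.05 else 1.0 / (mean_s2 * a0)
    b0 = float(np.clip(b0, B_BOUNDS[0] * 10, B_BOUNDS[1] / 10))

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        z = s2 * a * b
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.log(a * b) + stats.f.logpdf(z, d, 2 * a)
        if not np.isfinite(ll).all():
            return 1e12
        return -float(ll.sum())

    res = optimize.minimize(
        nll, x0=np.log([a0, b0]), method="L-BFGS-B",
        bounds=[tuple(np.log(A_BOUNDS)), tuple(np.log(B_BOUNDS))],
    )
    if not res.success:
        raise RuntimeError(f"RVM hyperparameter fit did not converge: {res.message}")
    a, b = np.exp(res.x)
    if a >= A_BOUNDS[1] * 0.99:
        warnings.warn(
            "fitted shape parameter a hit its upper bound: the residual "
            "variances show essentially no between-gene dispersion and the "
            "variance prior degenerates to a point mass",
            RuntimeWarning, stacklevel=2,
        )
    return RVMPrior(float(a), float(b), d)


def rvm_f_test(matrix: ExpressionMatrix, prior: RVMPrior,
               alpha_p: float = 0.05, alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Moderated F-test per gene; returns the DEG table.

    Columns: ``F`` (between-group mean square over the moderated
    variance), ``df1`` = m-1, ``df2`` = d+2a, ``p_value``, ``fdr``
    (Benjamini–Hochberg) and ``selected`` (p < alpha_p and FDR <
    alpha_fdr, the joint rule used for DEG calling).
    """
    s2, d = residual_variances(matrix)
    if d != prior.d:
        raise ValueError(f"prior fitted with d={prior.d} but matrix has d={d}")
    m = matrix.n_groups
    log2 = matrix.log2_values().to_numpy(dtype=float)
    cols = list(matrix.values.columns)
    sizes = np.array(matrix.group_sizes())
    gmeans = np.column_stack([
        log2[:, [cols.index(s) for s in matrix.samples_of(g)]].mean(axis=1)
        for g in matrix.groups
    ])
    grand = (gmeans * sizes).sum(axis=1) / sizes.sum()
    ms_between = ((gmeans - grand[:, None]) ** 2 * sizes).sum(axis=1) / (m - 1)

    moderated = (d * s2 + 2.0 / prior.b) / (d + 2 * prior.a)
    F = ms_between / moderated
    df2 = d + 2 * prior.a
    p = stats.f.sf(F, m - 1, df2)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "F": F,
            "df1": m - 1,
            "df2": df2,
            "p_value": p,
            "fdr": fdr,
            "selected": (p < alpha_p) & (fdr < alpha_fdr),
        },
        index=matrix.values.index,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(table: pd.DataFrame) -> list[str]:
    """Gene ids passing the joint p/FDR rule, in table order."""
    return list(table.index[table["selected"].to_numpy(dtype=bool)])
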