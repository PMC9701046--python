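"""Gene-set over-representation: Fisher exact and chi-square tests with an
enrichment ratio.

For a gene list of size n drawn from a universe of size N, and a gene set
with Nf members in the universe of which nf are in the list, the
enrichment ratio is Re = (nf/n) / (Nf/N) — how much more frequent the set
is in the list than in the background.  The Fisher p-value is the
one-sided (upper tail) hypergeometric probability of an overlap >= nf;
the chi-square p-value comes from the same 2x2 table without continuity
correction.  Fisher drives the significance flag.

The universe is the set of genes actually measured (the expression
matrix), not the annotation file — the standard background logic for
array data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rvm import bh_fdr
from .simulate import GeneSetCollection

logger = logging.getLogger("stcpipe")


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    description: str
    nf: int     # list genes in the set
    n: int      # list size
    Nf: int     # universe genes in the set
    N: int      # universe size
    Re: float   # (nf/n) / (Nf/N)
    fisher_p: float
    chi2_p: float
    significant: bool


def _fisher_upper(nf: int, n: int, Nf: int, N: int) -> float:
    # P(X >= nf) for X ~ Hypergeom(N, Nf, n)
    return float(stats.hypergeom.sf(nf - 1, N, Nf, n))


def _chi2_p(nf: int, n: int, Nf: int, N: int) -> float:
    table = np.array([[nf, n - nf], [Nf - nf, (N - n) - (Nf - nf)]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan")  # degenerate margin: chi-square undefined
    return float(stats.chi2_contingency(table, correction=False)[1])


def test_gene_set(gene_list: Sequence[str], gene_set: Sequence[str],
                  universe: Sequence[str], set_id: str = "set",
                  description: str = "", alpha: float = 0.05) -> EnrichmentRow:
    """Over-representation test of one gene set against one gene list."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    offenders = [g for g in gene_list if g not in uni]
    if offenders:
        raise ValueError(f"list genes outside the universe: {offenders[:10]}")
    members = set(gene_set) & uni
    lst = set(gene_list)
    nf, n, Nf, N = len(lst & members), len(lst), len(members), len(uni)
    re = (nf / n) / (Nf / N) if n > 0 and Nf > 0 else 0.0
    fisher_p = _fisher_upper(nf, n, Nf, N)
    return EnrichmentRow(set_id, description, nf, n, Nf, N, re, fisher_p,
                         _chi2_p(nf, n, Nf, N), fisher_p < alpha)


def run_enrichment(gene_list: Sequence[str], collection: GeneSetCollection,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Test every set in the collection against the list.

    The collection is harmonized to its universe first; list genes missing
    from the universe are dropped with a logged count.  Rows are sorted by
    Fisher p ascending (ties by set id); ``significant`` is raw Fisher
    p < alpha (no multiple-testing correction, a BH column is provided
    alongside).
    """
    cols = ["set_id", "description", "nf", "n", "Nf", "N", "Re",
            "fisher_p", "chi2_p", "fdr", "significant"]
    harmonized = collection.harmonized(collection.universe)
    uni = set(harmonized.universe)
    kept = [g for g in gene_list if g in uni]
    dropped = len(gene_list) - len(kept)
    if dropped:
        logger.warning("%d list gene(s) missing from the universe dropped",
                       dropped)
    if not kept:
        logger.warning("empty gene list: no enrichment computed")
        return pd.DataFrame(columns=cols)
    rows = [
        test_gene_set(kept, members, harmonized.universe, sid, desc, alpha)
        for sid, (desc, members) in harmonized.sets.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return pd.DataFrame(columns=cols)
    df["fdr"] = bh_fdr(df["fisher_p"])
    df = df.sort_values(["fisher_p", "set_id"], kind="mergesort",
                        ignore_index=True)
    return df[cols]
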