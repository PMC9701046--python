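"""Tabular I/O: expression matrices, designs, and result tables.

The on-disk formats are deliberately plain text so every output of the
pipeline can be re-read by these same functions (round-trip closure):

* expression matrix — TSV, first column ``gene`` (unique ids), remaining
  columns one per sample, positive linear-scale signals;
* design — two-column TSV ``sample<TAB>group``; group order of first
  appearance defines the ordered conditions (the first group anchors the
  log-ratio transform);
* result tables — TSV with a header, floats printed with ``%.10g``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("stcpipe")

FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionMatrix:
    """Positive linear-scale signals for G genes x S samples with an
    ordered group design.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids, one column per sample.
    sample_groups
        Series mapping each sample (index) to its condition label.
    groups
        Condition labels in their analysis order; the first group is the
        reference/anchor condition.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            # order of first appearance in the design
            self.groups = list(dict.fromkeys(self.sample_groups))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            bad = [c for c, dt in self.values.dtypes.items()
                   if not np.issubdtype(dt, np.number)]
            raise ValueError(f"non-numeric expression columns: {bad}")
        if (self.values.to_numpy() <= 0).any() or \
                not np.isfinite(self.values.to_numpy()).all():
            bad_genes = self.values.index[
                ((self.values <= 0) | ~np.isfinite(self.values)).any(axis=1)
            ]
            raise ValueError(
                "non-positive or non-finite signals for genes: "
                f"{list(bad_genes[:10])}"
            )
        missing = set(self.values.columns) - set(self.sample_groups.index)
        extra = set(self.sample_groups.index) - set(self.values.columns)
        if missing or extra:
            raise ValueError(
                f"sample/design mismatch: samples without group {sorted(missing)}, "
                f"design entries without sample {sorted(extra)}"
            )
        unknown = set(self.sample_groups) - set(self.groups)
        if unknown:
            raise ValueError(f"design groups not in group order: {sorted(unknown)}")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def group_sizes(self) -> list[int]:
        return [len(self.samples_of(g)) for g in self.groups]

    def log2_values(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)],
                                self.sample_groups, list(self.groups))


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def read_design(path: str | Path) -> pd.Series:
    """Read a two-column sample→group TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"design file {path} needs two tab-separated columns")
    if list(df.iloc[0]) == ["sample", "group"]:
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(),
                  name="group")
    if s.index.has_duplicates:
        dups = sorted(set(s.index[s.index.duplicated()]))
        raise ValueError(f"duplicate samples in design: {dups}")
    return s


def write_design(sample_groups: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in sample_groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_expression_table(path: str | Path,
                          design: pd.Series | str | Path) -> ExpressionMatrix:
    """Parse a gene × sample TSV and validate it against the design.

    Raises distinct errors for duplicate gene ids, non-numeric cells and
    sample/design mismatches.
    """
    if not isinstance(design, pd.Series):
        design = read_design(design)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric cells in column {col!r} of {path}")
    return ExpressionMatrix(df, design)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                         index_label="gene")


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = False,
                index_label: str | None = None) -> None:
    """Write a result table as TSV with deterministic float formatting."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index,
              index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
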