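"""Expression matrix I/O and normalization.

Reads genes × samples count tables with per-sample annotations, normalizes
to counts per million (CPM), and applies the log2(x + pseudocount)
transform. The matrix carries a unit tag (``counts`` | ``cpm`` | ``log2cpm``)
so downstream stages can enforce the scale they expect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("tratelis")

UNITS = ("counts", "cpm", "log2cpm")

#: relative tolerance on CPM column sums (1e6) required by the unit invariant
CPM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric table with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        Annotation table indexed by sample id. Must contain a ``group``
        column; any further columns are treated as covariates.
    unit
        One of ``counts``, ``cpm`` or ``log2cpm``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"
    #: gene ids whose row was constant at z-scoring time (filled downstream)
    constant_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression values must be numeric")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from annotations: {missing}")
        if "group" not in self.samples.columns:
            raise ValueError("annotation table must contain a 'group' column")
        if self.samples["group"].reindex(self.values.columns).isna().any():
            raise ValueError("every sample needs a group label")
        if self.unit == "counts" and (np.asarray(self.values) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def covariate_names(self) -> list:
        return [c for c in self.samples.columns if c != "group"]

    def annotations_for_samples(self) -> pd.DataFrame:
        """Annotations reindexed to the matrix sample order."""
        return self.samples.reindex(self.values.columns)


def read_counts_table(counts_path, annotations_path) -> ExpressionMatrix:
    """Read a TSV counts table plus a sample annotation TSV.

    The counts table has gene ids in the first column and one column per
    sample; the annotation table is keyed by sample id and must provide a
    ``group`` column. Genes that are zero in every sample are dropped (and
    logged); duplicate ids, non-numeric cells, or samples without
    annotations are errors.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {counts_path}: {dupes}")
    try:
        counts = counts.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {counts_path}: {exc}") from exc

    ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index = counts.index.astype(str)

    all_zero = (counts == 0).all(axis=1)
    if all_zero.any():
        logger.info(
            "dropping %d genes with zero counts in every sample", int(all_zero.sum())
        )
        counts = counts.loc[~all_zero]
    return ExpressionMatrix(values=counts, samples=ann, unit="counts")


def cpm_normalize(m: ExpressionMatrix, min_cpm: float | None = None) -> ExpressionMatrix:
    """Counts-per-million normalization: value / column-sum × 1e6.

    ``min_cpm``, when given, drops genes whose CPM is below the cutoff in
    every sample (off by default: no expression filter beyond all-zero
    genes).
    """
    if m.unit != "counts":
        raise ValueError(f"cpm_normalize expects counts, got unit={m.unit!r}")
    colsums = m.values.sum(axis=0)
    zero_cols = colsums.index[colsums == 0].tolist()
    if zero_cols:
        raise ValueError(f"zero library size for sample(s): {zero_cols}")
    cpm = m.values / colsums * 1e6
    if min_cpm is not None:
        keep = (cpm >= min_cpm).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("min_cpm=%g filter dropped %d genes", min_cpm, dropped)
            cpm = cpm.loc[keep]
            # re-normalize so column sums stay at 1e6 over retained genes
            cpm = cpm / cpm.sum(axis=0) * 1e6
    return replace(m, values=cpm, unit="cpm")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); pseudocount 1 keeps zeros at 0."""
    if m.unit != "cpm":
        raise ValueError(f"log2_transform expects cpm, got unit={m.unit!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (np.asarray(m.values) < 0).any():
        raise ValueError("negative CPM value encountered")
    return replace(m, values=np.log2(m.values + pseudocount), unit="log2cpm")


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Write the value table as TSV (gene id first column)."""
    m.values.to_csv(path, sep="\t", index_label="gene_id")
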