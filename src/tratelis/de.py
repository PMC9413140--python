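"""Fold-change-based differential expression selection.

Genes are selected by biological effect size alone — an adjusted log2 fold
change exceeding log2(fold_threshold) in magnitude (strict inequality) —
rather than by a test statistic or FDR. The per-gene log2FC is the group
coefficient of a least-squares fit of log2 expression on group plus any
covariates, so a confounder such as xenograft presence can be adjusted for;
with no covariates it equals the difference of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .tra import _design_matrix


def adjusted_log2fc(m: ExpressionMatrix, covariates: Sequence[str] = (),
                    reference: str | None = None) -> pd.Series:
    """Per-gene adjusted log2 fold change (exposed − control).

    One least-squares fit per gene of log2 expression ~ intercept + group
    (+ covariates), vectorized over genes via the shared design matrix.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"adjusted_log2fc expects log2cpm, got unit={m.unit!r}")
    samples = m.annotations_for_samples()
    X, _ = _design_matrix(samples, covariates, reference)
    Y = m.values.to_numpy(dtype=float).T          # samples × genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)  # p × genes
    return pd.Series(beta[1], index=m.values.index, name="log2fc")


@dataclass
class DESelection:
    fold_threshold: float
    log2fc: pd.Series
    up_genes: list
    down_genes: list

    def __post_init__(self):
        assert not set(self.up_genes) & set(self.down_genes)


def select_de_genes(log2fc: pd.Series, fold_threshold: float,
                    exclude: Iterable | None = None) -> DESelection:
    """Classify genes as up / down / neither by strict |log2FC| > log2(threshold).

    ``exclude`` lists genes barred from selection (e.g. constant genes).
    A gene at exactly the threshold is neither up nor down.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cut = math.log2(fold_threshold)
    excluded = [] if exclude is None else list(exclude)
    fc = log2fc.drop(index=[g for g in excluded if g in log2fc.index])
    up = fc.index[fc > cut].tolist()
    down = fc.index[fc < -cut].tolist()
    return DESelection(fold_threshold=fold_threshold, log2fc=log2fc,
                       up_genes=up, down_genes=down)


def write_de_selection(sel: DESelection, prefix) -> None:
    """Emit gene,log2fc TSV plus plain-text up/down gene lists."""
    sel.log2fc.to_frame().to_csv(f"{prefix}_log2fc.tsv", sep="\t", index_label="gene")
    for side, genes in (("up", sel.up_genes), ("down", sel.down_genes)):
        with open(f"{prefix}_{side}.txt", "w") as fh:
            fh.writelines(g + "\n" for g in genes)
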