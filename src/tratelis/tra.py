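"""Transcriptome Representation Analysis (TRA).

A TRA composite score summarizes a signed reference gene set in one number
per sample: each gene's expression is z-scored across samples (population
SD), down-regulated reference genes are reverse-scored (negated), and the
composite is the mean z over the set genes present in the matrix. Group
differences in the composite are tested by least squares (ANCOVA when
covariates such as xenograft presence are supplied).

Two parallel composites are computed: the z-scale composite carries the
significance test, while a mean-centered log2 composite (no variance
scaling) yields the reported fold change as 2^|adjusted difference|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .expression import ExpressionMatrix

logger = logging.getLogger("tratelis")


# ---------------------------------------------------------------------------
# signed gene sets (GMT dialect with _UP / _DN suffixes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedGeneSet:
    """A reference transcriptome signature: up- and down-regulated genes."""

    name: str
    up_genes: frozenset
    down_genes: frozenset = frozenset()

    def __post_init__(self):
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"gene set {self.name!r}: genes in both _UP and _DN: {sorted(overlap)}"
            )
        if not (self.up_genes or self.down_genes):
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def genes(self) -> frozenset:
        return self.up_genes | self.down_genes

    def swapped(self) -> "SignedGeneSet":
        """The same set with up and down lists exchanged."""
        return SignedGeneSet(self.name, self.down_genes, self.up_genes)


def read_signed_gene_sets(path) -> list[SignedGeneSet]:
    """Parse a GMT file whose set names end in ``_UP`` / ``_DN``.

    Lines ``NAME_UP`` and ``NAME_DN`` are merged into one
    :class:`SignedGeneSet` named ``NAME``; an ``_UP`` line without a
    matching ``_DN`` (or vice versa) leaves that side empty.
    """
    ups: dict[str, set] = {}
    downs: dict[str, set] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name.endswith("_UP"):
                base, side = name[:-3], ups
            elif name.endswith("_DN"):
                base, side = name[:-3], downs
            else:
                raise ValueError(
                    f"{path}:{lineno}: set name {name!r} lacks _UP/_DN suffix"
                )
            if base not in order:
                order.append(base)
            side.setdefault(base, set()).update(genes)
    return [
        SignedGeneSet(
            base,
            frozenset(ups.get(base, set())),
            frozenset(downs.get(base, set())),
        )
        for base in order
    ]


def write_signed_gene_sets(sets: Iterable[SignedGeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            if s.up_genes:
                fh.write("\t".join([f"{s.name}_UP", "na", *sorted(s.up_genes)]) + "\n")
            if s.down_genes:
                fh.write("\t".join([f"{s.name}_DN", "na", *sorted(s.down_genes)]) + "\n")


# ---------------------------------------------------------------------------
# per-gene standardization and composite scoring
# ---------------------------------------------------------------------------

def zscore_genes(m: ExpressionMatrix) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each gene row across samples (population SD).

    Returns the z-matrix and the index of constant (zero-variance) genes,
    whose rows are set to 0 so they contribute nothing to composites.
    """
    if m.values.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (vals - mean) / sd
    z[constant] = 0.0
    const_idx = m.values.index[constant]
    if len(const_idx):
        logger.info("%d constant genes set to z=0", len(const_idx))
    return pd.DataFrame(z, index=m.values.index, columns=m.values.columns), const_idx


def center_genes(m: ExpressionMatrix) -> pd.DataFrame:
    """Mean-center each gene row without variance scaling (log2-scale composite)."""
    vals = m.values.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=m.values.index, columns=m.values.columns)


class CompositeScores(NamedTuple):
    scores: pd.Series
    n_genes_used: int
    coverage: float


def composite_scores(z: pd.DataFrame, gene_set: SignedGeneSet) -> CompositeScores:
    """Per-sample composite: mean of set-gene rows, down genes negated."""
    up = [g for g in gene_set.up_genes if g in z.index]
    dn = [g for g in gene_set.down_genes if g in z.index]
    n_used = len(up) + len(dn)
    if n_used == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has zero overlap with the matrix"
        )
    coverage = n_used / len(gene_set.genes)
    missing = len(gene_set.genes) - n_used
    if missing:
        logger.info(
            "set %s: %d/%d genes absent from matrix", gene_set.name, missing,
            len(gene_set.genes),
        )
    parts = []
    if up:
        parts.append(z.loc[up].to_numpy())
    if dn:
        parts.append(-z.loc[dn].to_numpy())
    stacked = np.vstack(parts)
    scores = pd.Series(stacked.mean(axis=0), index=z.columns, name=gene_set.name)
    return CompositeScores(scores, n_used, coverage)


# ---------------------------------------------------------------------------
# group contrast (ANCOVA by least squares)
# ---------------------------------------------------------------------------

@dataclass
class LinearContrast:
    """Group coefficient of score ~ intercept + group + covariates."""

    diff: float          # exposed − control adjusted difference
    se: float
    t: float
    p: float             # two-sided; NaN when undefined (see p_undefined)
    df: int
    p_undefined: bool = False


def _design_matrix(samples: pd.DataFrame, covariates: Sequence[str],
                   reference: str | None) -> tuple[np.ndarray, list[str]]:
    groups = samples["group"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if reference is None:
        lowered = [lv.lower() for lv in levels]
        for guess in ("control", "vehicle", "ctrl"):
            if guess in lowered:
                reference = levels[lowered.index(guess)]
                break
        else:
            reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    exposed = [lv for lv in levels if lv != reference][0]
    indicator = (groups == exposed).astype(float).to_numpy()
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    cols = [np.ones(len(samples)), indicator]
    names = ["intercept", f"group[{exposed}]"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} missing from annotations")
        col = pd.to_numeric(samples[cov]).to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"covariate {cov!r} has missing values")
        cols.append(col)
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: covariates {list(covariates)} collinear "
            "with group/intercept"
        )
    return X, names


def group_contrast(scores: pd.Series, samples: pd.DataFrame,
                   covariates: Sequence[str] = (),
                   reference: str | None = None) -> LinearContrast:
    """Least-squares contrast of the composite between the two groups.

    With no covariates and equal variances this reduces to the pooled
    two-sample t-test. A zero-residual-variance fit reports the adjusted
    difference with ``p_undefined=True`` rather than a number.
    """
    samples = samples.reindex(scores.index)
    X, _names = _design_matrix(samples, covariates, reference)
    y = scores.to_numpy(dtype=float)
    df = len(y) - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    fit = sm.OLS(y, X).fit()
    diff = float(fit.params[1])
    scale = float(y @ y) + 1.0
    if fit.ssr <= 1e-12 * scale:  # perfect fit: no residual variance
        return LinearContrast(diff=diff, se=0.0, t=float("nan"), p=float("nan"),
                              df=df, p_undefined=True)
    return LinearContrast(diff=diff, se=float(fit.bse[1]), t=float(fit.tvalues[1]),
                          p=float(fit.pvalues[1]), df=df)


# ---------------------------------------------------------------------------
# full TRA for one signed set
# ---------------------------------------------------------------------------

@dataclass
class CompositeResult:
    set_name: str
    scores: pd.Series = field(repr=False)
    adjusted_diff: float
    log2_diff: float
    fold_change: float
    direction: str          # up | down | none
    p_value: float
    p_undefined: bool
    df: int
    n_genes_used: int
    coverage: float


def tra_analysis(m: ExpressionMatrix, gene_set: SignedGeneSet,
                 covariates: Sequence[str] = (),
                 reference: str | None = None) -> CompositeResult:
    """Run the full TRA for one signed set on a log2-scale matrix.

    The p-value comes from the ANCOVA on the z-score composite; the fold
    change is 2^|adjusted difference| of the mean-centered log2 composite.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"tra_analysis expects log2cpm, got unit={m.unit!r}")
    samples = m.annotations_for_samples()
    z, _const = zscore_genes(m)
    comp = composite_scores(z, gene_set)
    contrast = group_contrast(comp.scores, samples, covariates, reference)

    centered = center_genes(m)
    log2_comp = composite_scores(centered, gene_set)
    log2_contrast = group_contrast(log2_comp.scores, samples, covariates, reference)
    log2_diff = log2_contrast.diff
    fold = 2 ** abs(log2_diff)
    if log2_diff > 0:
        direction = "up"
    elif log2_diff < 0:
        direction = "down"
    else:
        direction = "none"
    return CompositeResult(
        set_name=gene_set.name,
        scores=comp.scores,
        adjusted_diff=contrast.diff,
        log2_diff=log2_diff,
        fold_change=fold,
        direction=direction,
        p_value=contrast.p,
        p_undefined=contrast.p_undefined,
        df=contrast.df,
        n_genes_used=comp.n_genes_used,
        coverage=comp.coverage,
    )
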