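"""Two-sample promoter TFBM prevalence-ratio inference.

For a motif and a pair of promoter sets (genes up- vs down-regulated by an
exposure), the prevalence of motif hits — mean hits per promoter — is
computed in each set, and their ratio taken, across a grid of parametric
variants: by default the 3 promoter windows × 3 MatSim stringencies (0.80,
0.90, 0.95) = 9 variants. The grid's log2 ratios are then tested against a
null mean ratio of 1 with a one-sample t-test; the reported fold change is
2^|mean log2 ratio| (a fold-down when the mean log ratio is negative).

Testing on the log scale keeps the procedure symmetric: swapping the up and
down sets inverts every ratio and flips the direction while preserving the
fold change and p-value exactly. Zero prevalence at a variant is handled by
a Haldane-style continuity correction (0.5 added to both total hit counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motif import (
    DEFAULT_WINDOWS,
    PositionWeightMatrix,
    PromoterSet,
    PromoterWindow,
    count_motif_hits,
    extract_promoters,
)

DEFAULT_THRESHOLDS = (0.80, 0.90, 0.95)


@dataclass(frozen=True)
class VariantGrid:
    """Promoter-window × MatSim-stringency grid (default 3 × 3 = 9 variants)."""

    windows: tuple = DEFAULT_WINDOWS
    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self):
        if not self.windows or not self.thresholds:
            raise ValueError("grid needs at least one window and one threshold")
        object.__setattr__(self, "windows", tuple(self.windows))
        object.__setattr__(self, "thresholds", tuple(self.thresholds))

    @property
    def n_variants(self) -> int:
        return len(self.windows) * len(self.thresholds)


@dataclass(frozen=True)
class VariantRecord:
    window: PromoterWindow
    threshold: float
    prevalence_up: float
    prevalence_dn: float
    ratio: float
    continuity_corrected: bool = False


@dataclass
class TFBMResult:
    motif_id: str
    variants: list = field(default_factory=list)  # VariantRecord per grid cell
    mean_log2_ratio: float = float("nan")
    fold_change: float = float("nan")
    direction: str = "none"   # up | down | none
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    df: int = 0
    p_undefined: bool = False

    @property
    def ratios(self) -> np.ndarray:
        return np.array([v.ratio for v in self.variants])


def motif_prevalence(promoters: PromoterSet | Sequence[str],
                     pwm: PositionWeightMatrix, threshold: float,
                     both_strands: bool = True) -> float:
    """Mean number of motif hits per promoter (total hits / n promoters)."""
    total, n = _total_hits(promoters, pwm, threshold, both_strands)
    if n == 0:
        raise ValueError("empty promoter set")
    return total / n


def _total_hits(promoters, pwm, threshold, both_strands) -> tuple[int, int]:
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else list(promoters)
    return sum(count_motif_hits(pwm, s, threshold, both_strands) for s in seqs), len(seqs)


def variant_ratio_grid(up_promoters: Mapping[PromoterWindow, PromoterSet],
                       dn_promoters: Mapping[PromoterWindow, PromoterSet],
                       pwm: PositionWeightMatrix,
                       grid: VariantGrid = VariantGrid(),
                       both_strands: bool = True) -> list[VariantRecord]:
    """Prevalence ratios (up / down) for every grid variant.

    ``up_promoters`` / ``dn_promoters`` map each grid window to its
    extracted :class:`PromoterSet`. A zero total hit count on either side
    triggers the continuity correction (0.5 added to both totals) so the
    ratio stays finite; the variant is flagged.
    """
    out = []
    for window in grid.windows:
        for key, mapping in (("up", up_promoters), ("dn", dn_promoters)):
            if window not in mapping:
                raise ValueError(f"no {key} promoter set extracted for window {window.label}")
        up_set, dn_set = up_promoters[window], dn_promoters[window]
        if len(up_set) == 0 or len(dn_set) == 0:
            raise ValueError(f"empty promoter set for window {window.label}")
        for thr in grid.thresholds:
            up_total, n_up = _total_hits(up_set, pwm, thr, both_strands)
            dn_total, n_dn = _total_hits(dn_set, pwm, thr, both_strands)
            corrected = up_total == 0 or dn_total == 0
            if corrected:
                up_total, dn_total = up_total + 0.5, dn_total + 0.5
            prev_up, prev_dn = up_total / n_up, dn_total / n_dn
            out.append(VariantRecord(
                window=window, threshold=thr,
                prevalence_up=prev_up, prevalence_dn=prev_dn,
                ratio=prev_up / prev_dn, continuity_corrected=corrected,
            ))
    return out


def ratio_t_test(ratios: Iterable[float], motif_id: str = "",
                 variants: list | None = None) -> TFBMResult:
    """One-sample two-sided t-test of log2 prevalence ratios against 0.

    All-equal ratios have zero variance: at mean ratio 1 the p-value is 1
    by convention; at any other mean the fold change is still reported but
    the p-value is flagged undefined.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 ratios")
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    log2r = np.log2(r)
    mean = float(log2r.mean())
    df = r.size - 1
    fold = 2 ** abs(mean)
    direction = "up" if mean > 0 else ("down" if mean < 0 else "none")
    res = TFBMResult(motif_id=motif_id, variants=variants or [],
                     mean_log2_ratio=mean, fold_change=fold,
                     direction=direction, df=df)
    sd = float(log2r.std(ddof=1))
    if sd == 0:
        if mean == 0:
            res.t_statistic, res.p_value = 0.0, 1.0
        else:
            res.p_undefined = True
        return res
    res.t_statistic = mean / (sd / math.sqrt(r.size))
    res.p_value = float(2 * stats.t.sf(abs(res.t_statistic), df))
    return res


def telis_analysis(up_genes: Iterable, dn_genes: Iterable, tss_bed, genome,
                   pwm: PositionWeightMatrix, grid: VariantGrid = VariantGrid(),
                   both_strands: bool = True) -> TFBMResult:
    """End-to-end TFBM analysis for one motif.

    Extracts per-window promoter sets for the up- and down-regulated gene
    lists, computes the prevalence-ratio grid, and runs the ratio t-test.
    Genes absent from the TSS annotation are dropped by extraction.
    """
    up_sets, dn_sets = {}, {}
    for window in grid.windows:
        up_sets[window] = extract_promoters(tss_bed, genome, window, genes=up_genes)
        dn_sets[window] = extract_promoters(tss_bed, genome, window, genes=dn_genes)
    variants = variant_ratio_grid(up_sets, dn_sets, pwm, grid, both_strands)
    return ratio_t_test([v.ratio for v in variants], motif_id=pwm.motif_id,
                        variants=variants)
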