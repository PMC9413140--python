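"""Promoter motif scanning: PWMs, MatSim similarity, promoter extraction.

A transcription-factor binding motif (TFBM) is a position weight matrix of
base frequencies with per-position information weights ci in [0, 100]
(0 for a fully uniform position, 100 for an invariant one). The similarity
of a sequence window to the matrix follows the MatInspector matrix-
similarity convention:

    MatSim = sum_i ci(i) * f(i, base_i)  /  sum_i ci(i) * max_b f(i, b)

so a consensus match scores exactly 1.0. Promoter windows are cut from a
genome FASTA around BED-annotated transcription start sites (0-based
half-open coordinates; minus-strand promoters are reverse-complemented so
sequences read 5'→3' toward the gene), and hits are counted on both strands
at a MatSim threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger("tratelis")

BASES = "ACGT"
_LN4 = np.log(4.0)
# base → frequency-column index; anything unknown behaves like N (column 4,
# frequency 0 at every position: can only lower a score, never an error)
_CODE = {b: i for i, b in enumerate(BASES)}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

def information_weights(freqs: np.ndarray) -> np.ndarray:
    """Per-position information weight ci on the 0–100 scale.

    ci(i) = (100 / ln 4) * (sum_b f(i,b) ln f(i,b) + ln 4), with
    0·ln 0 := 0; a uniform row gives 0, an invariant row gives 100.
    """
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    ci = (100.0 / _LN4) * (plogp.sum(axis=1) + _LN4)
    return np.clip(ci, 0.0, 100.0)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base frequencies plus information weights for one motif."""

    motif_id: str
    freqs: np.ndarray = field(repr=False)  # L × 4 over A,C,G,T, rows sum to 1
    ci: np.ndarray = field(repr=False)     # L information weights in [0, 100]

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("freqs must be L×4 over A,C,G,T")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: frequency rows must sum to 1")
        if (f < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative frequency")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "ci", np.asarray(self.ci, dtype=float))

    @classmethod
    def from_frequencies(cls, motif_id: str, freqs) -> "PositionWeightMatrix":
        f = np.asarray(freqs, dtype=float)
        return cls(motif_id, f, information_weights(f))

    @classmethod
    def from_counts(cls, motif_id: str, counts,
                    pseudocount: float = 0.0) -> "PositionWeightMatrix":
        c = np.asarray(counts, dtype=float) + pseudocount
        sums = c.sum(axis=1)
        bad = np.flatnonzero(sums == 0)
        if bad.size:
            raise ValueError(
                f"motif {motif_id}: count row(s) {bad.tolist()} sum to 0"
            )
        return cls.from_frequencies(motif_id, c / sums[:, None])

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str) -> "PositionWeightMatrix":
        """Degenerate matrix with frequency 1 on each consensus base."""
        counts = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus.upper()):
            if b not in _CODE:
                raise ValueError(f"consensus base {b!r} not in {BASES}")
            counts[i, _CODE[b]] = 1.0
        return cls.from_counts(motif_id, counts)

    def __len__(self) -> int:
        return self.freqs.shape[0]


def _sniff_format(path) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                return "jaspar"
            return "transfac"
    raise ValueError(f"{path}: empty motif file")


def parse_motif_matrices(path, fmt: str | None = None,
                         pseudocount: float = 0.0) -> list[PositionWeightMatrix]:
    """Parse TRANSFAC flat-file or JASPAR PFM motif matrices.

    Counts are row-normalized to frequencies (optional pseudocount for
    sparse matrices, default none).
    """
    fmt = fmt or _sniff_format(path)
    try:
        with open(path) as fh:
            records = bio_motifs.parse(fh, fmt)
            out = []
            for rec in records:
                name = None
                if isinstance(rec, dict):  # TRANSFAC motifs carry their fields as a dict
                    name = rec.get("ID") or rec.get("AC")
                name = (name or getattr(rec, "matrix_id", None)
                        or getattr(rec, "name", None) or "motif")
                counts = np.column_stack([rec.counts[b] for b in BASES])
                out.append(PositionWeightMatrix.from_counts(str(name), counts,
                                                            pseudocount=pseudocount))
    except ValueError:
        raise
    except Exception as exc:  # malformed record inside the Bio parser
        raise ValueError(f"{path}: malformed {fmt} motif record: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no motif records found")
    return out


def parse_motif_matrix(path, motif_id: str | None = None, fmt: str | None = None,
                       pseudocount: float = 0.0) -> PositionWeightMatrix:
    """Parse one motif; select by id when the file holds several."""
    all_m = parse_motif_matrices(path, fmt=fmt, pseudocount=pseudocount)
    if motif_id is not None:
        for m in all_m:
            if m.motif_id == motif_id:
                return m
        raise ValueError(f"{path}: motif {motif_id!r} not found")
    if len(all_m) > 1:
        raise ValueError(
            f"{path}: {len(all_m)} motifs present; pass motif_id to choose one"
        )
    return all_m[0]


# ---------------------------------------------------------------------------
# MatSim scoring and hit counting
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in seq.upper()), dtype=np.intp,
                       count=len(seq))


def _weight_table(pwm: PositionWeightMatrix) -> tuple[np.ndarray, float]:
    # L×5 table of ci·f with an all-zero N column; denominator of MatSim
    wt = pwm.ci[:, None] * np.hstack([pwm.freqs, np.zeros((len(pwm), 1))])
    denom = float((pwm.ci * pwm.freqs.max(axis=1)).sum())
    if denom == 0:
        raise ValueError(
            f"motif {pwm.motif_id}: all positions uniform, MatSim undefined"
        )
    return wt, denom


def matsim_score(pwm: PositionWeightMatrix, window: str) -> float:
    """MatSim similarity of one length-L window to the matrix, in [0, 1]."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    wt, denom = _weight_table(pwm)
    codes = _encode(window)
    return float(wt[np.arange(len(pwm)), codes].sum() / denom)


def scan_scores(pwm: PositionWeightMatrix, seq: str) -> np.ndarray:
    """MatSim scores of every length-L window of ``seq`` (forward strand)."""
    L = len(pwm)
    if len(seq) < L:
        return np.empty(0)
    wt, denom = _weight_table(pwm)
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return wt[np.arange(L)[None, :], windows].sum(axis=1) / denom


def count_motif_hits(pwm: PositionWeightMatrix, seq: str, threshold: float,
                     both_strands: bool = True) -> int:
    """Number of windows scoring ≥ threshold, summed over both strands.

    Overlapping hits each count; sequences shorter than the motif yield 0.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = int((scan_scores(pwm, seq) >= threshold).sum())
    if both_strands:
        n += int((scan_scores(pwm, reverse_complement(seq)) >= threshold).sum())
    return n


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWindow:
    """Extent of a promoter around the TSS: upstream_bp before, downstream_bp after."""

    upstream_bp: int
    downstream_bp: int = 0

    def __post_init__(self):
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_bp + self.downstream_bp == 0:
            raise ValueError("window must have positive length")

    @property
    def length(self) -> int:
        return self.upstream_bp + self.downstream_bp

    @property
    def label(self) -> str:
        return f"-{self.upstream_bp}..+{self.downstream_bp}"


#: the study's three promoter windows: 300 bp, 600 bp, and 1000 bp to +200
DEFAULT_WINDOWS = (
    PromoterWindow(300, 0),
    PromoterWindow(600, 0),
    PromoterWindow(1000, 200),
)


@dataclass(frozen=True)
class PromoterRecord:
    gene: str
    sequence: str
    contig: str
    start: int      # 0-based half-open genomic interval
    end: int
    strand: str
    truncated: bool = False


@dataclass
class PromoterSet:
    """Gene → promoter sequence mapping for one window."""

    window: PromoterWindow
    records: dict  # gene id → PromoterRecord

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records.values()]

    def genes(self) -> list[str]:
        return list(self.records)

    def trimmed(self, window: PromoterWindow) -> "PromoterSet":
        """Derive a smaller window from this extraction by slicing at the TSS.

        The TSS anchor is taken as ``len(seq) − downstream_bp``, which is
        exact for promoters not truncated on the downstream side.
        """
        if (window.upstream_bp > self.window.upstream_bp
                or window.downstream_bp > self.window.downstream_bp):
            raise ValueError(
                f"window {window.label} exceeds extracted extent {self.window.label}"
            )
        recs = {}
        for g, r in self.records.items():
            anchor = len(r.sequence) - self.window.downstream_bp
            start = max(anchor - window.upstream_bp, 0)
            end = min(anchor + window.downstream_bp, len(r.sequence))
            recs[g] = PromoterRecord(
                gene=g, sequence=r.sequence[start:end], contig=r.contig,
                start=r.start, end=r.end, strand=r.strand, truncated=r.truncated,
            )
        return PromoterSet(window=window, records=recs)


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 file of transcription start sites (one record per gene)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if bed.shape[1] < 6:
        raise ValueError(f"{path}: BED6 required (need a strand column)")
    bed = bed.iloc[:, :6]
    bed.columns = ["contig", "start", "end", "gene", "score", "strand"]
    bed["start"] = bed["start"].astype(int)
    bed["end"] = bed["end"].astype(int)
    bad = ~bed["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: missing/invalid strand for {bed.loc[bad, 'gene'].tolist()}")
    return bed


def extract_promoters(tss_bed, genome, window: PromoterWindow,
                      genes: Iterable | None = None) -> PromoterSet:
    """Cut promoter windows from a genome around BED-annotated TSSs.

    The TSS is the 5' end of each record (start for +, end for −). When a
    gene id has several TSS records the 5'-most on the gene strand is used.
    Intervals are truncated at contig edges with a warning. ``genes``
    restricts extraction to a subset of ids.
    """
    bed = tss_bed if isinstance(tss_bed, pd.DataFrame) else read_tss_bed(tss_bed)
    fa = genome if isinstance(genome, Fasta) else Fasta(
        str(genome), as_raw=True, sequence_always_upper=True)
    if genes is not None:
        wanted = set(genes)
        bed = bed[bed["gene"].isin(wanted)]

    records: dict[str, PromoterRecord] = {}
    chosen_tss: dict[str, int] = {}
    for row in bed.itertuples(index=False):
        if row.contig not in fa:
            raise ValueError(f"BED record for {row.gene} on unknown contig {row.contig!r}")
        tss = row.start if row.strand == "+" else row.end
        if row.gene in records:
            prev = chosen_tss[row.gene]
            # keep the 5'-most TSS on the gene strand
            keep_new = tss < prev if row.strand == "+" else tss > prev
            logger.warning("gene %s has multiple TSS records; keeping 5'-most", row.gene)
            if not keep_new:
                continue
        contig_len = len(fa[row.contig])
        if row.strand == "+":
            start, end = tss - window.upstream_bp, tss + window.downstream_bp
        else:
            start, end = tss - window.downstream_bp, tss + window.upstream_bp
        truncated = start < 0 or end > contig_len
        if truncated:
            logger.warning(
                "promoter of %s truncated at contig edge (%s:%d-%d)",
                row.gene, row.contig, start, end,
            )
        start_c, end_c = max(start, 0), min(end, contig_len)
        seq = str(fa[row.contig][start_c:end_c])
        if row.strand == "-":
            seq = reverse_complement(seq)
        records[row.gene] = PromoterRecord(
            gene=row.gene, sequence=seq, contig=row.contig,
            start=start_c, end=end_c, strand=row.strand, truncated=truncated,
        )
        chosen_tss[row.gene] = tss
    return PromoterSet(window=window, records=records)
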