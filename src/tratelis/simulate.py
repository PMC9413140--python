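"""Synthetic data with planted, recoverable structure.

Two generators make every pipeline stage testable without downloads:

* a two-group bulk RNA-seq counts matrix — negative-binomial counts with
  log-normal gene means, an optional confounding binary covariate, and
  signed gene sets whose up/down members are shifted by ± a planted log2
  effect δ in the exposed group;
* paired promoter sequence sets — uniform-background sequences carrying
  Poisson-distributed, non-overlapping insertions of an exact motif
  consensus at rates λ_up / λ_dn per promoter.

Each dataset is emitted with a ``SimTruth`` record of every planted
parameter, sufficient to compute all downstream expected values. Identical
seeds give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .motif import PromoterRecord, PromoterSet, PromoterWindow, reverse_complement
from .tra import SignedGeneSet, write_signed_gene_sets

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Expression defaults emulate a bulk 3'-tag RNA-seq experiment of the
    study's shape: two groups, a binary confounder, log-normal gene means
    (natural-log mean 4, SD 1.5 on a CPM-like scale) and negative-binomial
    dispersion 0.1. Promoter defaults give 1200 bp promoters (1000 bp
    upstream of the TSS to +200) with a 12-mer consensus planted at
    Poisson rates per arm.
    """

    seed: int
    # expression
    n_genes: int = 12_000
    n_exposed: int = 8
    n_control: int = 7
    mean_log: float = 4.0        # natural-log mean of gene baseline means
    sd_log: float = 1.5
    dispersion: float = 0.1      # NB: var = mu + dispersion * mu^2
    planted_sets: tuple = ()     # (SignedGeneSet, log2 effect δ) pairs
    covariate: str | None = "xenograft"
    cov_log2_effect: float = 0.5
    cov_affected_frac: float = 0.1
    # promoters
    n_promoters: int = 200
    upstream_bp: int = 1000
    downstream_bp: int = 200
    consensus: str = "TTTCACTTTCAC"
    lambda_up: float = 2.0
    lambda_dn: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_exposed", "n_control", "n_promoters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0 or self.sd_log <= 0:
            raise ValueError("dispersion and sd_log must be positive")
        if len(self.consensus) >= self.upstream_bp + self.downstream_bp:
            raise ValueError("consensus must be shorter than the promoter")

    @property
    def promoter_length(self) -> int:
        return self.upstream_bp + self.downstream_bp


@dataclass
class SimTruth:
    """Planted parameters emitted alongside every synthetic dataset."""

    seed: int
    true_log2fc: pd.Series | None = None          # per-gene group effect
    set_deltas: dict = field(default_factory=dict)
    covariate: pd.Series | None = None            # per-sample binary
    cov_log2_effect: pd.Series | None = None      # per-gene covariate effect
    planted_hits_up: dict = field(default_factory=dict)  # promoter id → count
    planted_hits_dn: dict = field(default_factory=dict)
    lambda_up: float | None = None
    lambda_dn: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "set_deltas": self.set_deltas,
            "lambda_up": self.lambda_up,
            "lambda_dn": self.lambda_dn,
            "true_log2fc": (self.true_log2fc.to_dict()
                            if self.true_log2fc is not None else None),
            "covariate": (self.covariate.to_dict()
                          if self.covariate is not None else None),
            "cov_log2_effect": (self.cov_log2_effect.to_dict()
                                if self.cov_log2_effect is not None else None),
            "planted_hits_up": self.planted_hits_up,
            "planted_hits_dn": self.planted_hits_dn,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Negative-binomial counts with planted signed-set shifts.

    Exposed-group means are multiplied by 2^δ for up genes and 2^−δ for
    down genes of each planted set; the covariate effect is applied
    multiplicatively to a random subset of genes in covariate-positive
    samples.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]
    gene_index = pd.Index(genes)
    sample_ids = ([f"exp{i}" for i in range(1, cfg.n_exposed + 1)]
                  + [f"ctl{i}" for i in range(1, cfg.n_control + 1)])
    group = ["exposed"] * cfg.n_exposed + ["control"] * cfg.n_control
    is_exposed = np.array([g == "exposed" for g in group], dtype=float)

    true_l2fc = pd.Series(0.0, index=gene_index)
    for gene_set, delta in cfg.planted_sets:
        unknown = sorted(g for g in gene_set.genes if g not in gene_index)
        if unknown:
            raise ValueError(
                f"planted set {gene_set.name!r} references unknown genes: {unknown[:5]}"
            )
        true_l2fc[list(gene_set.up_genes)] += delta
        true_l2fc[list(gene_set.down_genes)] -= delta

    samples = pd.DataFrame({"group": group}, index=sample_ids)
    cov_effect = pd.Series(0.0, index=gene_index)
    cov = None
    if cfg.covariate:
        # balanced-within-group binary confounder so the design stays full rank
        cov_vals = np.concatenate([
            _balanced_binary(cfg.n_exposed, rng),
            _balanced_binary(cfg.n_control, rng),
        ])
        cov = pd.Series(cov_vals, index=sample_ids, name=cfg.covariate)
        samples[cfg.covariate] = cov_vals
        n_affected = int(round(cfg.cov_affected_frac * cfg.n_genes))
        affected = rng.choice(cfg.n_genes, size=n_affected, replace=False)
        cov_effect.iloc[affected] = cfg.cov_log2_effect

    base = rng.lognormal(cfg.mean_log, cfg.sd_log, cfg.n_genes)
    mu = (base[:, None]
          * 2.0 ** (true_l2fc.to_numpy()[:, None] * is_exposed[None, :]))
    if cov is not None:
        mu = mu * 2.0 ** (cov_effect.to_numpy()[:, None] * cov.to_numpy()[None, :])
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(counts, index=gene_index, columns=sample_ids, dtype=float)
    truth = SimTruth(
        seed=cfg.seed, true_log2fc=true_l2fc,
        set_deltas={s.name: d for s, d in cfg.planted_sets},
        covariate=cov, cov_log2_effect=cov_effect if cfg.covariate else None,
    )
    return ExpressionMatrix(values=values, samples=samples, unit="counts"), truth


def _balanced_binary(n: int, rng) -> np.ndarray:
    vals = np.zeros(n, dtype=int)
    vals[: n // 2] = 1
    rng.shuffle(vals)
    if 0 < n and vals.sum() in (0, n):  # degenerate only for n == 1
        vals[0] = 1 - vals[0]
    return vals


def write_expression_files(m: ExpressionMatrix, truth: SimTruth, out_dir) -> dict:
    """Emit counts TSV, annotations TSV and truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth_expression.json",
    }
    m.values.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    m.samples.to_csv(paths["annotations"], sep="\t", index_label="sample_id")
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _place_insertions(seq: np.ndarray, k: int, motif: str, rng,
                      max_tries: int = 1000) -> np.ndarray:
    """Insert ``k`` non-overlapping copies of ``motif``; returns the array."""
    L, P = len(motif), len(seq)
    if k == 0:
        return seq
    for _ in range(max_tries):
        starts = np.sort(rng.integers(0, P - L + 1, size=k))
        if k == 1 or (np.diff(starts) >= L).all():
            motif_codes = np.array(list(motif))
            for s in starts:
                seq[s:s + L] = motif_codes
            return seq
    raise RuntimeError(f"could not place {k} non-overlapping insertions in {P} bp")


def simulate_promoter_sets(cfg: SimConfig) -> tuple[PromoterSet, PromoterSet, SimTruth]:
    """Uniform-background promoters with Poisson consensus insertions.

    Promoters alternate between + and − source strands so file round-trips
    exercise reverse-complement extraction. True inserted counts per
    promoter are recorded in the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    window = PromoterWindow(cfg.upstream_bp, cfg.downstream_bp)
    truth = SimTruth(seed=cfg.seed, lambda_up=cfg.lambda_up, lambda_dn=cfg.lambda_dn)
    sets = {}
    for arm, lam, hits_store in (("up", cfg.lambda_up, truth.planted_hits_up),
                                 ("dn", cfg.lambda_dn, truth.planted_hits_dn)):
        records = {}
        for i in range(1, cfg.n_promoters + 1):
            gene = f"{arm}_{i:04d}"
            seq = _BASES[rng.integers(0, 4, size=cfg.promoter_length)]
            k = int(rng.poisson(lam))
            seq = _place_insertions(seq, k, cfg.consensus, rng)
            sequence = "".join(seq)
            strand = "+" if i % 2 else "-"
            records[gene] = PromoterRecord(
                gene=gene, sequence=sequence, contig=gene,
                start=0, end=cfg.promoter_length, strand=strand,
            )
            hits_store[gene] = k
        sets[arm] = PromoterSet(window=window, records=records)
    return sets["up"], sets["dn"], truth


def write_promoter_files(up: PromoterSet, dn: PromoterSet, truth: SimTruth,
                         out_dir) -> dict:
    """Emit a genome FASTA (one contig per promoter), per-arm BED6 and truth.

    Contigs hold the promoter on its source strand (minus-strand promoters
    are stored reverse-complemented) with the TSS placed so that extraction
    with the generating window recovers the emitted sequence exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genome": out / "genome.fa", "up_bed": out / "up.bed",
             "dn_bed": out / "dn.bed", "truth": out / "truth_promoters.json"}
    with open(paths["genome"], "w") as fa:
        for pset in (up, dn):
            for rec in pset:
                contig_seq = (rec.sequence if rec.strand == "+"
                              else reverse_complement(rec.sequence))
                fa.write(f">{rec.contig}\n")
                for i in range(0, len(contig_seq), 70):
                    fa.write(contig_seq[i:i + 70] + "\n")
    for pset, key in ((up, "up_bed"), (dn, "dn_bed")):
        with open(paths[key], "w") as bed:
            for rec in pset:
                P, U = len(rec.sequence), pset.window.upstream_bp
                if rec.strand == "+":
                    start, end = U, P  # TSS at BED start
                else:
                    start, end = 0, P - U  # TSS at BED end on −
                bed.write(f"{rec.contig}\t{start}\t{end}\t{rec.gene}\t0\t{rec.strand}\n")
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# the documented default scenario
# ---------------------------------------------------------------------------

def default_scenario(seed: int) -> tuple[SimConfig, list[SignedGeneSet]]:
    """The study-shaped scenario: 12,000 genes, 8 vs 7 samples, one binary
    covariate, and three planted signatures — antioxidant (NFE2L2) up
    1.5-fold, NHEJ down 1.4-fold, cGAS-STING down 1.6-fold.
    """
    def block(name, lo, delta):
        up = frozenset(f"g{i:05d}" for i in range(lo, lo + 40))
        dn = frozenset(f"g{i:05d}" for i in range(lo + 40, lo + 50))
        return SignedGeneSet(name, up, dn), delta

    planted = (
        block("NFE2L2", 101, 0.6),
        block("NHEJ", 201, -np.log2(1.4)),
        block("CGAS_STING", 301, -np.log2(1.6)),
    )
    cfg = SimConfig(seed=seed, planted_sets=planted,
                    lambda_up=0.5, lambda_dn=1.4)
    return cfg, [s for s, _ in planted]


def write_scenario(seed: int, out_dir) -> dict:
    """Materialize the default scenario to files; returns all paths.

    Besides the per-arm BEDs, a combined ``tss.bed`` and plain-text
    up/dn promoter-gene lists are emitted so the TFBM stage can be run
    directly on the planted arms.
    """
    cfg, gene_sets = default_scenario(seed)
    m, truth_e = simulate_expression(cfg)
    up, dn, truth_p = simulate_promoter_sets(cfg)
    out = Path(out_dir)
    paths = write_expression_files(m, truth_e, out)
    paths.update(write_promoter_files(up, dn, truth_p, out))
    paths["gene_sets"] = out / "gene_sets.gmt"
    write_signed_gene_sets(gene_sets, paths["gene_sets"])
    paths["tss_bed"] = out / "tss.bed"
    paths["tss_bed"].write_text(paths["up_bed"].read_text()
                                + paths["dn_bed"].read_text())
    for arm, pset in (("up", up), ("dn", dn)):
        paths[f"{arm}_genes"] = out / f"{arm}_genes.txt"
        paths[f"{arm}_genes"].write_text("\n".join(pset.genes()) + "\n")
    return paths
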