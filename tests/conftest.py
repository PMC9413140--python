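import numpy as np
import pandas as pd
import pytest

from tratelis.expression import ExpressionMatrix


@pytest.fixture
def toy_counts(tmp_path):
    """2-sample counts TSV + annotations with a group label each."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene_id\ts1\ts2\n"
        "g1\t5\t1\n"
        "g2\t5\t3\n"
    )
    ann = tmp_path / "ann.tsv"
    ann.write_text("sample_id\tgroup\ns1\texposed\ns2\tcontrol\n")
    return counts, ann


def make_matrix(values, sample_groups, unit="log2cpm", covariates=None):
    """Build an ExpressionMatrix from a plain dict of gene → row values."""
    genes = list(values)
    samples = [f"s{i}" for i in range(len(next(iter(values.values()))))]
    vals = pd.DataFrame(
        np.array([values[g] for g in genes], dtype=float),
        index=genes, columns=samples,
    )
    ann = pd.DataFrame({"group": sample_groups}, index=samples)
    if covariates:
        for name, col in covariates.items():
            ann[name] = col
    return ExpressionMatrix(values=vals, samples=ann, unit=unit)


@pytest.fixture
def transfac_file(tmp_path):
    path = tmp_path / "toy.transfac"
    path.write_text(
        "ID  V$TOY_01\n"
        "P0      A      C      G      T\n"
        "01      7      1      1      1      R\n"
        "02      0      0      0      8      T\n"
        "03      4      4      0      0      M\n"
        "//\n"
    )
    return path


@pytest.fixture
def jaspar_file(tmp_path):
    path = tmp_path / "toy.jaspar"
    path.write_text(
        ">MA0001.1 TOYJ\n"
        "A [ 7 1 0 ]\n"
        "C [ 1 1 0 ]\n"
        "G [ 1 1 8 ]\n"
        "T [ 1 5 0 ]\n"
    )
    return path


@pytest.fixture
def tiny_genome(tmp_path):
    """Two contigs used by the hand-indexed promoter extraction examples."""
    fa = tmp_path / "genome.fa"
    fa.write_text(">chrA\nACGTACGTACGTACGTACGT\n>chrB\nAAAACCCGGT\n")
    return fa


def write_bed(tmp_path, rows, name="tss.bed"):
    path = tmp_path / name
    path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path
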