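import numpy as np
import pandas as pd
import pytest

from tratelis.tra import (
    SignedGeneSet,
    composite_scores,
    group_contrast,
    read_signed_gene_sets,
    tra_analysis,
    zscore_genes,
)

from conftest import make_matrix


class TestReadSignedGeneSets:
    def test_up_and_dn_lines_merge(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("NHEJ_UP\tdesc\tg1\tg2\nNHEJ_DN\tdesc\tg3\n")
        (s,) = read_signed_gene_sets(gmt)
        assert s.name == "NHEJ"
        assert s.up_genes == {"g1", "g2"} and s.down_genes == {"g3"}

    def test_up_only_gives_empty_down(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("STING_UP\tdesc\tg1\n")
        (s,) = read_signed_gene_sets(gmt)
        assert s.down_genes == frozenset()

    def test_gene_in_both_sides_is_an_error(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("STING_UP\tdesc\tg1\nSTING_DN\tdesc\tg1\n")
        with pytest.raises(ValueError, match="g1"):
            read_signed_gene_sets(gmt)

    def test_unsuffixed_name_is_an_error(self, tmp_path):
        gmt = tmp_path / "s.gmt"
        gmt.write_text("PLAIN\tdesc\tg1\n")
        with pytest.raises(ValueError, match="PLAIN"):
            read_signed_gene_sets(gmt)


class TestZscoreGenes:
    def test_examples(self):
        m = make_matrix({"a": [1, 3], "b": [2, 2]}, ["x", "y"])
        z, const = zscore_genes(m)
        np.testing.assert_allclose(z.loc["a"], [-1.0, 1.0])
        np.testing.assert_allclose(z.loc["b"], [0.0, 0.0])
        assert const.tolist() == ["b"]

    def test_population_sd_three_samples(self):
        m = make_matrix({"a": [1, 2, 3]}, ["x", "y", "z"])
        z, _ = zscore_genes(m)
        np.testing.assert_allclose(z.loc["a"], [-1.22474487, 0.0, 1.22474487])

    def test_single_sample_rejected(self):
        m = make_matrix({"a": [1]}, ["x"])
        with pytest.raises(ValueError):
            zscore_genes(m)


class TestCompositeScores:
    def test_down_genes_reverse_scored(self):
        z = pd.DataFrame([[-1, 1], [1, -1]], index=["g1", "g2"], columns=["s0", "s1"])
        s = SignedGeneSet("S", frozenset({"g1"}), frozenset({"g2"}))
        scores = composite_scores(z, s).scores
        np.testing.assert_allclose(scores, [-1.0, 1.0])

    def test_mean_of_identical_rows(self):
        z = pd.DataFrame([[1, -1], [1, -1]], index=["g1", "g2"], columns=["s0", "s1"])
        s = SignedGeneSet("S", frozenset({"g1", "g2"}))
        res = composite_scores(z, s)
        np.testing.assert_allclose(res.scores, [1.0, -1.0])
        assert res.n_genes_used == 2 and res.coverage == 1.0

    def test_disjoint_set_is_an_error(self):
        z = pd.DataFrame([[1, -1]], index=["g1"], columns=["s0", "s1"])
        s = SignedGeneSet("S", frozenset({"other"}))
        with pytest.raises(ValueError, match="zero overlap"):
            composite_scores(z, s)

    def test_swapping_up_and_down_negates_scores(self):
        rng = np.random.default_rng(7)
        z = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"g{i}" for i in range(20)],
                         columns=[f"s{i}" for i in range(6)])
        s = SignedGeneSet("S", frozenset({"g1", "g2", "g3"}), frozenset({"g4", "g5"}))
        a = composite_scores(z, s).scores
        b = composite_scores(z, s.swapped()).scores
        np.testing.assert_allclose(a, -b, atol=1e-12)


class TestGroupContrast:
    def test_pooled_t_toy(self):
        # closed-form pooled two-sample t: diff 1, sp^2 = 0.5, df = 2
        scores = pd.Series([-1.0, 0.0, 0.0, 1.0], index=list("abcd"))
        samples = pd.DataFrame({"group": ["control", "control", "exposed", "exposed"]},
                               index=list("abcd"))
        r = group_contrast(scores, samples)
        assert r.diff == pytest.approx(1.0)
        assert r.t == pytest.approx(np.sqrt(2), abs=1e-9)
        assert r.df == 2
        assert r.p == pytest.approx(0.29289, abs=1e-4)

    def test_identical_scores_in_both_groups_zero_diff(self):
        scores = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        samples = pd.DataFrame({"group": ["control", "control", "exposed", "exposed"]},
                               index=list("abcd"))
        r = group_contrast(scores, samples)
        assert r.diff == pytest.approx(0.0)
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_zero_residual_variance_flags_p_undefined(self):
        scores = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        samples = pd.DataFrame({"group": ["control", "control", "exposed", "exposed"]},
                               index=list("abcd"))
        r = group_contrast(scores, samples)
        assert r.diff == pytest.approx(1.0)
        assert r.p_undefined and np.isnan(r.p)

    def test_covariate_collinear_with_group_is_an_error(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        samples = pd.DataFrame(
            {"group": ["control", "control", "exposed", "exposed"],
             "cov": [0, 0, 1, 1]}, index=list("abcd"))
        with pytest.raises(ValueError, match="rank"):
            group_contrast(scores, samples, covariates=["cov"])


class TestTraAnalysis:
    def _matrix(self, rng, n_genes=40, n=8):
        vals = {f"g{i}": rng.normal(5, 1, 2 * n) for i in range(n_genes)}
        return make_matrix(vals, ["exposed"] * n + ["control"] * n)

    def test_composite_mean_over_samples_is_zero(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng)
        s = SignedGeneSet("S", frozenset({"g0", "g1", "g2"}), frozenset({"g3"}))
        res = tra_analysis(m, s)
        assert abs(res.scores.mean()) < 1e-9

    def test_affine_invariance_of_composites(self):
        # per-gene positive-affine transforms leave z-composites unchanged
        rng = np.random.default_rng(1)
        m = self._matrix(rng, n_genes=15, n=5)
        s = SignedGeneSet("S", frozenset({"g0", "g1"}), frozenset({"g2", "g3"}))
        base = tra_analysis(m, s)
        a = rng.uniform(0.5, 3.0, size=15)
        b = rng.normal(0, 4, size=15)
        m2 = make_matrix(
            {g: (a[i] * m.values.loc[g] + b[i]).tolist()
             for i, g in enumerate(m.gene_ids)},
            m.samples["group"].tolist(),
        )
        res = tra_analysis(m2, s)
        np.testing.assert_allclose(res.scores, base.scores, atol=1e-9)
        assert res.p_value == pytest.approx(base.p_value, abs=1e-9)

    def test_fold_change_at_least_one_and_direction(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng)
        s = SignedGeneSet("S", frozenset({"g0", "g1", "g2", "g3"}))
        res = tra_analysis(m, s)
        assert res.fold_change >= 1.0
        assert res.direction in {"up", "down", "none"}
        assert res.fold_change == pytest.approx(2 ** abs(res.log2_diff))
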