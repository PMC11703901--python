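import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import swarmnet as sn
from swarmnet.preprocess import GeneSet, LoadError


class TestReadExpression:
    def test_reads_tsv_fixture(self, expr_tsv):
        em = sn.read_expression(expr_tsv)
        assert em.data.shape == (3, 2)
        assert not em.normalized
        assert em.gene_ids == ["TP53", "MDM2", "CDK1"]

    def test_duplicate_gene_error_names_gene(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ts2\nTP53\t1\t3\nTP53\t3\t5\n")
        with pytest.raises(LoadError, match="TP53"):
            sn.read_expression(str(p), duplicate_policy="error")

    def test_duplicate_mean_merges_rows(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ts2\nTP53\t1\t3\nTP53\t3\t5\n")
        em = sn.read_expression(str(p), duplicate_policy="mean")
        assert em.data.loc["TP53"].tolist() == [2.0, 4.0]

    def test_duplicate_first_keeps_first(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ns\t1\nS\t9\nX\t2\n")
        em = sn.read_expression(str(p), duplicate_policy="first")
        assert em.data.loc["S", "s1"] == 1.0

    def test_missing_value_policies(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text("gene\ts1\ts2\nA\t1\t\nB\t2\t3\n")
        with pytest.raises(LoadError, match="A"):
            sn.read_expression(str(p), missing_policy="error")
        em = sn.read_expression(str(p), missing_policy="drop_gene")
        assert em.gene_ids == ["B"]

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "ds.tsv"
        p.write_text("gene\ts1\ts1\nA\t1\t2\n")
        with pytest.raises(LoadError, match="sample"):
            sn.read_expression(str(p))

    def test_comma_autodetect_and_roundtrip(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,s1,s2\nA,1,2\nB,3,4\n")
        em = sn.read_expression(str(p))
        out = tmp_path / "out.tsv"
        sn.write_expression(em, str(out))
        em2 = sn.read_expression(str(out))
        pd.testing.assert_frame_equal(em.data, em2.data)


class TestMinmaxNormalize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([2.0, 4.0, 6.0], [0.0, 0.5, 1.0]),
            ([-1.0, 0.0, 3.0], [0.0, 0.25, 1.0]),
        ],
    )
    def test_formula(self, row, expected):
        em = sn.ExpressionMatrix(
            pd.DataFrame([row], index=["G1"], columns=["a", "b", "c"])
        )
        out = sn.minmax_normalize(em, constant_gene_policy="midpoint")
        assert out.data.loc["G1"].tolist() == expected
        assert out.normalized

    def test_constant_gene_midpoint(self):
        em = sn.ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]],
                         index=["C", "V"], columns=list("abc"))
        )
        out = sn.minmax_normalize(em, constant_gene_policy="midpoint")
        assert out.data.loc["C"].tolist() == [0.5, 0.5, 0.5]

    def test_constant_gene_dropped_by_default(self):
        em = sn.ExpressionMatrix(
            pd.DataFrame([[5.0, 5.0], [0.0, 1.0]], index=["C", "V"],
                         columns=["a", "b"])
        )
        out = sn.minmax_normalize(em)
        assert out.gene_ids == ["V"]

    def test_all_constant_is_error(self):
        em = sn.ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0]], index=["C"], columns=["a", "b"])
        )
        with pytest.raises(ValueError, match="constant"):
            sn.minmax_normalize(em)

    def test_renormalizing_rejected_and_renorm_identical(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 10, (5, 8)),
                          index=[f"G{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(8)])
        em = sn.ExpressionMatrix(df)
        a = sn.minmax_normalize(em)
        b = sn.minmax_normalize(sn.ExpressionMatrix(df.copy()))
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError, match="already"):
            sn.minmax_normalize(a)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_permutation_equivariance(self, perm):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(0, 10, (6, 5)),
                          index=[f"G{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(5)])
        base = sn.minmax_normalize(sn.ExpressionMatrix(df))
        shuffled = sn.minmax_normalize(sn.ExpressionMatrix(df.iloc[perm]))
        pd.testing.assert_frame_equal(shuffled.data, base.data.iloc[perm])

    def test_commutes_with_gene_subsetting(self):
        # per-gene scaling: normalize-then-subset == subset-then-normalize
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 10, (6, 7)),
                          index=[f"G{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(7)])
        subset = GeneSet("x", ("G4", "G1", "G5"))
        a = sn.subset_to_genes(sn.minmax_normalize(sn.ExpressionMatrix(df)), subset)
        b = sn.minmax_normalize(
            sn.subset_to_genes(sn.ExpressionMatrix(df.copy()), subset))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_global_range_attained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 3, (4, 10)),
                          index=list("WXYZ"), columns=[f"s{i}" for i in range(10)])
        out = sn.minmax_normalize(sn.ExpressionMatrix(df))
        vals = out.values
        assert vals.min() == 0.0 and vals.max() == 1.0
        assert (vals.min(axis=1) == 0.0).all() and (vals.max(axis=1) == 1.0).all()


class TestSubsetToGenes:
    def test_order_follows_gene_set(self):
        df = pd.DataFrame(np.arange(10.0).reshape(5, 2),
                          index=list("ABCDE"), columns=["s1", "s2"])
        em = sn.ExpressionMatrix(df)
        out = sn.subset_to_genes(em, GeneSet("x", ("D", "A", "C")))
        assert out.gene_ids == ["D", "A", "C"]

    def test_warn_skip_drops_missing(self):
        df = pd.DataFrame(np.ones((3, 2)) * [[1], [2], [3]],
                          index=list("ABC"), columns=["s1", "s2"])
        em = sn.ExpressionMatrix(df)
        out = sn.subset_to_genes(em, GeneSet("x", ("A", "Z", "B")),
                                 missing_gene_policy="warn_skip")
        assert out.gene_ids == ["A", "B"]

    def test_zero_overlap_is_error(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        with pytest.raises(KeyError, match="none of the requested"):
            sn.subset_to_genes(sn.ExpressionMatrix(df), GeneSet("x", ("Q", "Z")))

    def test_missing_with_error_policy(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        with pytest.raises(KeyError, match="Z"):
            sn.subset_to_genes(sn.ExpressionMatrix(df), GeneSet("x", ("A", "Z")))


class TestGeneSet:
    def test_plain_file_with_comment(self, tmp_path):
        p = tmp_path / "gs.txt"
        p.write_text("# my pathway\nTP53\nmdm2\nCDK1\n\n")
        gs = sn.read_gene_set(str(p))
        assert list(gs) == ["TP53", "MDM2", "CDK1"]

    def test_gmt_first_record(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("TP53_PATHWAY\tdesc\tTP53\tMDM2\nOTHER\td\tX\n")
        gs = sn.read_gene_set(str(p))
        assert gs.name == "TP53_PATHWAY"
        assert set(gs) == {"TP53", "MDM2"}

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("\n# nothing\n")
        with pytest.raises(LoadError):
            sn.read_gene_set(str(p))

    def test_symbols_uppercased_and_deduped(self):
        gs = GeneSet("x", ("tp53", "TP53", " mdm2 "))
        assert list(gs) == ["TP53", "MDM2"]
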