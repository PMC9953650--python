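import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xorgan.exprio import (CellCountMatrix, ExpressionMatrix, GeneLengths,
                           Unit, counts_to_fpkm, counts_to_tpm,
                           expressed_genes, pseudobulk, read_expression_table,
                           read_lengths, read_organ_map)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# ExpressionMatrix invariants
# ---------------------------------------------------------------------------

class TestExpressionMatrix:
    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["s"])
        with pytest.raises(ValueError, match="duplicated gene"):
            ExpressionMatrix(df, Unit.FPKM, organ_of={"s": "o"})

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_matrix([[-1.0]])

    def test_missing_organ_label_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="without an organ label"):
            ExpressionMatrix(df, Unit.FPKM, organ_of={"a": "o"})

    def test_tpm_column_sum_enforced(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["g0", "g1"], columns=["s"])
        with pytest.raises(ValueError, match="sum to 1e6"):
            ExpressionMatrix(df, Unit.TPM, organ_of={"s": "o"})

    def test_valid_tpm_accepted(self):
        df = pd.DataFrame([[4e5], [6e5]], index=["g0", "g1"], columns=["s"])
        m = ExpressionMatrix(df, Unit.TPM, organ_of={"s": "o"})
        assert m.unit is Unit.TPM

    def test_organs_ordered_and_lookup(self):
        m = make_matrix(np.ones((2, 3)),
                        organ_of={"s0": "liver", "s1": "liver", "s2": "gill"})
        assert m.organs == ["liver", "gill"]
        assert m.samples_of_organ("liver") == ["s0", "s1"]
        with pytest.raises(KeyError):
            m.samples_of_organ("heart")


class TestIO:
    def test_round_trip_with_organ_map(self, tmp_path):
        table = tmp_path / "m.tsv"
        table.write_text("gene_id\tsA\tsB\ng1\t1.5\t2.0\ng2\t0.0\t3.25\n")
        omap = tmp_path / "organs.tsv"
        omap.write_text("sample_id\torgan\nsA\tliver\nsB\tgill\n")
        m = read_expression_table(table, unit="fpkm", species="x",
                                  organ_map_path=omap)
        assert m.values.shape == (2, 2)
        assert m.organ_of == {"sA": "liver", "sB": "gill"}
        assert m.values.loc["g2", "sB"] == 3.25

    def test_duplicated_gene_id_errors(self, tmp_path):
        table = tmp_path / "m.tsv"
        table.write_text("gene_id\ts\ng1\t1\ng1\t2\n")
        omap = tmp_path / "o.tsv"
        omap.write_text("sample_id\torgan\ns\to\n")
        with pytest.raises(ValueError, match="duplicated gene"):
            read_expression_table(table, unit="fpkm", organ_map_path=omap)

    def test_missing_sample_in_organ_map_errors(self, tmp_path):
        table = tmp_path / "m.tsv"
        table.write_text("gene_id\tsA\tsB\ng1\t1\t2\n")
        omap = tmp_path / "o.tsv"
        omap.write_text("sample_id\torgan\nsA\tliver\n")
        with pytest.raises(ValueError, match="without an organ label"):
            read_expression_table(table, unit="fpkm", organ_map_path=omap)

    def test_non_numeric_cell_errors(self, tmp_path):
        table = tmp_path / "m.tsv"
        table.write_text("gene_id\ts\ng1\tnot_a_number\n")
        omap = tmp_path / "o.tsv"
        omap.write_text("sample_id\torgan\ns\to\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression_table(table, unit="fpkm", organ_map_path=omap)

    def test_headerless_organ_map(self, tmp_path):
        omap = tmp_path / "o.tsv"
        omap.write_text("sA\tliver\nsB\tgill\n")
        assert read_organ_map(omap) == {"sA": "liver", "sB": "gill"}

    def test_read_lengths(self, tmp_path):
        p = tmp_path / "len.tsv"
        p.write_text("gene_id\tlength_bp\ng1\t500\ng2\t1200\n")
        assert read_lengths(p).length_of == {"g1": 500, "g2": 1200}


# ---------------------------------------------------------------------------
# counts -> TPM / FPKM
# ---------------------------------------------------------------------------

class TestCountsToTPM:
    def test_equal_rates_split_evenly(self):
        m = make_matrix([[10.0], [20.0]], unit=Unit.COUNTS)
        tpm = counts_to_tpm(m, GeneLengths({"g0": 500, "g1": 1000}))
        assert tpm.values["s0"].tolist() == [5e5, 5e5]
        assert tpm.unit is Unit.TPM

    def test_hand_evaluated_rates(self):
        # rates 10/1000=0.01 and 30/2000=0.015 -> shares 0.4 / 0.6
        m = make_matrix([[10.0], [30.0]], unit=Unit.COUNTS)
        tpm = counts_to_tpm(m, GeneLengths({"g0": 1000, "g1": 2000}))
        np.testing.assert_allclose(tpm.values["s0"], [4e5, 6e5])

    def test_all_zero_column_errors(self):
        m = make_matrix([[0.0], [0.0]], unit=Unit.COUNTS)
        with pytest.raises(ValueError, match="all-zero.*s0"):
            counts_to_tpm(m, GeneLengths({"g0": 100, "g1": 100}))

    def test_missing_length_errors(self):
        m = make_matrix([[1.0], [1.0]], unit=Unit.COUNTS)
        with pytest.raises(KeyError, match="g1"):
            counts_to_tpm(m, GeneLengths({"g0": 100}))

    def test_rejects_non_counts_input(self):
        m = make_matrix([[1.0]], unit=Unit.FPKM)
        with pytest.raises(ValueError, match="counts"):
            counts_to_tpm(m, GeneLengths({"g0": 100}))

    @given(counts=arrays(np.float64, (6, 3),
                         elements=st.integers(0, 10_000).map(float)),
           lens=st.lists(st.integers(100, 5000), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_1e6(self, counts, lens):
        if (counts.sum(axis=0) == 0).any():
            return
        m = make_matrix(counts, unit=Unit.COUNTS)
        lengths = GeneLengths({f"g{i}": l for i, l in enumerate(lens)})
        tpm = counts_to_tpm(m, lengths)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_invariant_under_column_scaling(self, rng):
        counts = rng.integers(1, 1000, size=(8, 2)).astype(float)
        m = make_matrix(counts, unit=Unit.COUNTS)
        scaled = make_matrix(counts * 7.0, unit=Unit.COUNTS)
        lengths = GeneLengths({f"g{i}": int(l) for i, l in
                               enumerate(rng.integers(100, 3000, 8))})
        np.testing.assert_allclose(counts_to_tpm(m, lengths).values,
                                   counts_to_tpm(scaled, lengths).values,
                                   rtol=1e-12)


class TestCountsToFPKM:
    def test_one_kb_one_million_reads(self):
        m = make_matrix([[10.0]], unit=Unit.COUNTS)
        # single gene is the whole library: force N = 1e6 via extra gene
        m2 = make_matrix([[10.0], [999990.0]], unit=Unit.COUNTS)
        fpkm = counts_to_fpkm(m2, GeneLengths({"g0": 1000, "g1": 1000}))
        assert fpkm.values.loc["g0", "s0"] == pytest.approx(10.0)
        del m

    def test_hand_evaluated(self):
        m = make_matrix([[10.0], [90.0]], unit=Unit.COUNTS)
        fpkm = counts_to_fpkm(m, GeneLengths({"g0": 500, "g1": 500}))
        # 10 * 1e9 / (500 * 100) = 2e5 ; 90 * 1e9 / (500 * 100) = 1.8e6
        np.testing.assert_allclose(fpkm.values["s0"], [2e5, 1.8e6])

    def test_rpkm_same_numbers_different_tag(self):
        m = make_matrix([[10.0], [90.0]], unit=Unit.COUNTS)
        lengths = GeneLengths({"g0": 500, "g1": 500})
        fpkm = counts_to_fpkm(m, lengths)
        rpkm = counts_to_fpkm(m, lengths, tag=Unit.RPKM)
        assert rpkm.unit is Unit.RPKM
        np.testing.assert_array_equal(fpkm.values, rpkm.values)

    def test_renormalized_fpkm_equals_tpm(self, rng):
        counts = rng.integers(0, 5000, size=(20, 4)).astype(float)
        counts[0] += 1  # avoid zero columns
        m = make_matrix(counts, unit=Unit.COUNTS)
        lengths = GeneLengths({f"g{i}": int(l) for i, l in
                               enumerate(rng.integers(200, 4000, 20))})
        fpkm = counts_to_fpkm(m, lengths).values
        tpm = counts_to_tpm(m, lengths).values
        renorm = 1e6 * fpkm / fpkm.sum(axis=0)
        np.testing.assert_allclose(renorm, tpm, rtol=1e-9)


class TestPseudobulk:
    def test_direct_summation(self):
        cells = CellCountMatrix(pd.DataFrame(
            [[1, 0, 2], [0, 3, 1]], index=["g1", "g2"],
            columns=["c1", "c2", "c3"]))
        bulk = pseudobulk(cells)
        assert bulk.values.iloc[:, 0].tolist() == [3.0, 4.0]
        assert bulk.unit is Unit.COUNTS

    def test_single_cell_identity(self):
        cells = CellCountMatrix(pd.DataFrame([[5], [7]], index=["a", "b"],
                                             columns=["c"]))
        assert pseudobulk(cells).values.iloc[:, 0].tolist() == [5.0, 7.0]

    def test_empty_matrix_errors(self):
        cells = CellCountMatrix(pd.DataFrame(index=["g"], columns=[]))
        with pytest.raises(ValueError, match="no cells"):
            pseudobulk(cells)

    def test_conserves_total_counts(self, rng):
        arr = rng.integers(0, 50, size=(30, 12)).astype(float)
        cells = CellCountMatrix(pd.DataFrame(
            arr, index=[f"g{i}" for i in range(30)],
            columns=[f"c{j}" for j in range(12)]))
        assert pseudobulk(cells).values.to_numpy().sum() == arr.sum()

    def test_pseudobulk_then_tpm_matches_direct(self, rng):
        arr = rng.integers(0, 50, size=(10, 5)).astype(float)
        arr[0] += 1
        cells = CellCountMatrix(pd.DataFrame(
            arr, index=[f"g{i}" for i in range(10)],
            columns=[f"c{j}" for j in range(5)]))
        lengths = GeneLengths({f"g{i}": int(l) for i, l in
                               enumerate(rng.integers(100, 2000, 10))})
        via_bulk = counts_to_tpm(pseudobulk(cells), lengths).values.to_numpy()
        direct = make_matrix(arr.sum(axis=1, keepdims=True), unit=Unit.COUNTS)
        np.testing.assert_allclose(
            via_bulk, counts_to_tpm(direct, lengths).values.to_numpy())

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            CellCountMatrix(pd.DataFrame([[1.5]], index=["g"], columns=["c"]))


class TestExpressedGenes:
    def test_strict_threshold_excludes_boundary(self):
        m = make_matrix([[1.5], [1.0], [0.2]], organ_of={"s0": "o"})
        assert expressed_genes(m, 1.0) == {"g0"}

    def test_zero_threshold_keeps_all_positive(self):
        m = make_matrix([[0.5], [2.0]], organ_of={"s0": "o"})
        assert expressed_genes(m, 0.0) == {"g0", "g1"}

    def test_rules_mean_vs_all(self):
        m = make_matrix([[0.5, 3.5]], organ_of={"s0": "o", "s1": "o"})
        assert expressed_genes(m, 1.0, organ="o", rule="mean") == {"g0"}
        assert expressed_genes(m, 1.0, organ="o", rule="all") == set()
        assert expressed_genes(m, 1.0, organ="o", rule="any") == {"g0"}

    def test_unknown_organ_errors(self):
        m = make_matrix([[1.0]], organ_of={"s0": "o"})
        with pytest.raises(KeyError):
            expressed_genes(m, 1.0, organ="nope")

    @given(t1=st.floats(0, 10), t2=st.floats(0, 10))
    @settings(max_examples=40, deadline=None)
    def test_antitone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(0, 10, size=(15, 2)))
        lo, hi = min(t1, t2), max(t1, t2)
        assert expressed_genes(m, hi) <= expressed_genes(m, lo)
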