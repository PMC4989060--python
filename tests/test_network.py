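"""Network construction: statuses, score filter, intersection, I/O."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import coexmark as cm
from coexmark import io
from coexmark.errors import ConfigurationError, FormatError


def matrix(values, genes=None, samples=None, condition="normal"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cm.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), condition=condition
    )


class TestReadExpression:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ts3\ts4\n"
            "g1\t1\t2\t3\t4\n"
            "g2\t2\t3\t4\t5\n"
            "g3\t0\t0\t1\t1\n"
        )
        m = cm.read_expression(path, "normal")
        assert m.data.shape == (3, 4)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.condition == "normal"

    def test_duplicate_gene_rows_collapse_by_mean_with_warning(self, tmp_path, caplog):
        path = tmp_path / "x.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ts3\n"
            "g1\t1\t1\t1\n"
            "g1\t3\t3\t3\n"
        )
        with caplog.at_level("WARNING"):
            m = cm.read_expression(path, "normal")
        assert m.data.shape == (1, 3)
        assert (m.data.loc["g1"] == 2.0).all()
        assert any("duplicated" in r.message for r in caplog.records)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ts3\n"
            "g1\t1\t2\t3\n"
            "g2\t1\toops\t3\n"
        )
        with pytest.raises(FormatError, match="g2.*s2"):
            cm.read_expression(path, "normal")

    def test_fewer_than_three_samples_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\n")
        with pytest.raises(FormatError, match="3 samples"):
            cm.read_expression(path, "normal")


class TestNormalize:
    def test_none_is_identity(self):
        m = matrix([[1, 4, 2], [3, 2, 8]])
        out = cm.normalize(m, method="none")
        assert out.data.equals(m.data)

    def test_quantile_makes_column_distributions_identical(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.normal(size=(20, 5)))
        out = cm.normalize(m, method="quantile")
        cols = [np.sort(out.data.iloc[:, j].to_numpy()) for j in range(5)]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], atol=1e-12)

    def test_two_sample_toy_matrix_matches_hand_computation(self):
        # columns (1,3) and (4,2); sorted-column row means are (1.5, 3.5)
        m = matrix([[1, 4], [3, 2]])
        out = cm.normalize(m, method="quantile").data.to_numpy()
        np.testing.assert_allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.normalize(matrix([[1, 2], [3, 4]]), method="bogus")


class TestCoexpressionStatus:
    def test_status_counts_equal_ceil_of_fraction(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.normal(size=(21, 30)))  # C(21,2) = 210 pairs
        table = cm.coexpression_status(m, top_fraction=0.01)
        k = math.ceil(0.01 * 210)
        assert len(table.positive_pairs) == k == 3
        assert len(table.negative_pairs) == k
        assert table.n_pairs_evaluated == 210

    def test_supplied_universe_of_200_pairs_gives_two_per_tail(self):
        rng = np.random.default_rng(2)
        m = matrix(rng.normal(size=(25, 30)))
        pairs = list(itertools.combinations(m.gene_ids, 2))[:200]
        table = cm.coexpression_status(m, pair_universe=pairs, top_fraction=0.01)
        assert len(table.positive_pairs) == 2
        assert len(table.negative_pairs) == 2

    def test_pair_never_both_positive_and_negative(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.normal(size=(10, 12)))
        table = cm.coexpression_status(m, top_fraction=0.4)
        assert not (table.positive_pairs & table.negative_pairs)

    def test_negating_a_gene_swaps_its_tail_memberships(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(12, 40))
        m = cm.coexpression_status(matrix(values), top_fraction=0.05, keep_pcc=True)
        flipped_values = values.copy()
        flipped_values[0] *= -1
        f = cm.coexpression_status(matrix(flipped_values), top_fraction=0.05, keep_pcc=True)
        g0 = "g0"
        for pair, pcc in m.pcc.items():
            expected = -pcc if g0 in pair else pcc
            assert f.pcc[pair] == pytest.approx(expected, abs=1e-12)

    def test_identical_gene_vectors_rank_top(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(15, 20))
        values[1] = values[0]
        table = cm.coexpression_status(matrix(values), top_fraction=0.01, keep_pcc=True)
        assert table.get("g0", "g1") == 1
        assert table.pcc[("g0", "g1")] == pytest.approx(1.0)

    def test_constant_gene_pairs_get_pcc_zero_with_warning(self, caplog):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(8, 10))
        values[2] = 5.0
        with caplog.at_level("WARNING"):
            table = cm.coexpression_status(matrix(values), top_fraction=0.05, keep_pcc=True)
        assert any("constant" in r.message for r in caplog.records)
        assert all(table.pcc[p] == 0.0 for p in table.pcc if "g2" in p)

    def test_pcc_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(10, 20))
        table = cm.coexpression_status(matrix(values), top_fraction=0.05, keep_pcc=True)

        def pcc(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())

        for (ga, gb), got in table.pcc.items():
            i, j = int(ga[1:]), int(gb[1:])
            assert got == pytest.approx(pcc(values[i], values[j]), abs=1e-12)

    def test_fraction_out_of_range_rejected(self):
        m = matrix(np.random.default_rng(8).normal(size=(5, 6)))
        for bad in (0.0, 0.5, -0.1, 0.9):
            with pytest.raises(ConfigurationError):
                cm.coexpression_status(m, top_fraction=bad)


class TestFilterFunctionalNetwork:
    def test_score_filter_is_strict(self):
        net = cm.FunctionalNetwork.from_edges(
            [("a", "b", 500), ("a", "c", 501), ("b", "c", 499), ("c", "d", 1000)]
        )
        kept = cm.filter_functional_network(net, min_score=500)
        assert ("a", "b") not in kept
        assert ("a", "c") in kept
        assert ("b", "c") not in kept
        assert ("c", "d") in kept

    def test_empty_network_stays_empty(self):
        assert cm.filter_functional_network(cm.FunctionalNetwork({})).n_edges == 0


class TestBuildSpecificNetwork:
    @staticmethod
    def status_table(condition, statuses):
        return cm.EdgeStatusTable(condition=condition, status=statuses)

    def test_inclusion_rules(self):
        filtered = cm.FunctionalNetwork.from_edges(
            [("a", "b", 900), ("a", "c", 501), ("b", "d", 700)]
        )
        sn = self.status_table("normal", {("a", "c"): 1})
        sc = self.status_table("cancer", {("b", "d"): -1, ("c", "e"): 1})
        spec = cm.build_specific_network(sn, sc, filtered)
        # (a,b): statuses (0,0) despite score 900 -> excluded
        # (a,c): (+1,0), score 501 -> included with that annotation
        # (b,d): (0,-1) -> included; (c,e): coexpressed but no edge -> excluded
        edges = {(u, v): (dn, dc) for u, v, dn, dc in spec.iter_edges()}
        assert edges == {("a", "c"): (1, 0), ("b", "d"): (0, -1)}
        assert "e" not in spec

    def test_score_filtered_edge_excluded_despite_coexpression(self):
        filtered = cm.filter_functional_network(
            cm.FunctionalNetwork.from_edges([("a", "b", 400)]), 500
        )
        sn = self.status_table("normal", {("a", "b"): 1})
        sc = self.status_table("cancer", {("a", "b"): 1})
        spec = cm.build_specific_network(sn, sc, filtered)
        assert spec.n_edges == 0

    def test_specific_subset_of_filtered_subset_of_input(self, built):
        functional, filtered, spec = built["functional"], built["filtered"], built["specific"]
        filtered_pairs = set(filtered.scores)
        spec_pairs = {(a, b) for a, b, _, _ in spec.iter_edges()}
        assert spec_pairs <= filtered_pairs <= set(functional.scores)

    def test_strongly_planted_module_edges_all_survive(self):
        # with guaranteed in-module STRING edges and strong correlation,
        # every within-module edge of the smallest-universe study appears
        cfg = cm.SimulationConfig(
            n_genes=60, n_modules=2, module_size_range=(5, 5),
            within_module_correlation=0.9, de_module_fraction=0.0,
            n_rewired_genes_per_de_module=0,
            in_module_edge_probability=1.0, background_edge_probability=0.0,
            n_samples_normal=100, n_samples_cancer=100, seed=13,
        )
        normal, cancer, truth = cm.simulate_expression(cfg)
        functional = cm.simulate_functional_network(truth, cfg)
        filtered = cm.filter_functional_network(functional, 500)
        spec = cm.build_specific_network(
            cm.coexpression_status(normal), cm.coexpression_status(cancer), filtered
        )
        spec_pairs = {(a, b) for a, b, _, _ in spec.iter_edges()}
        assert set(filtered.scores) == spec_pairs

    def test_specific_network_round_trip(self, built, tmp_path):
        path = tmp_path / "net.tsv"
        io.write_specific_network(built["specific"], path)
        back = io.read_specific_network(path)
        assert back.to_frame().equals(built["specific"].to_frame())


class TestStringIO:
    def test_round_trip(self, tmp_path):
        net = cm.FunctionalNetwork.from_edges(
            [("a", "b", 10), ("b", "c", 999), ("a", "d", 0)]
        )
        path = tmp_path / "string.tsv"
        io.write_string_network(net, path)
        assert io.read_string_network(path).scores == net.scores

    def test_bad_score_reports_line_number(self, tmp_path):
        path = tmp_path / "string.tsv"
        path.write_text("a\tb\t100\nb\tc\tNaN\n")
        with pytest.raises(FormatError, match="line 2"):
            io.read_string_network(path)
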