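import math

import numpy as np
import pytest

from mirmint import data_io
from mirmint.errors import FormatError, LabelingError, UsageError
from mirmint.networks import BipartiteNetwork


@pytest.fixture
def tsv_3x2(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "feature_id\tS1\tS2\n"
        "fA\t1.5\t2.5\n"
        "fB\t3\t4\n"
        "fC\t5.25\t6\n"
    )
    return path


GROUPS_2 = {"S1": "tumor", "S2": "normal"}


class TestReadExpression:
    def test_parses_3x2_tsv(self, tsv_3x2):
        m = data_io.read_expression(tsv_3x2, "tsv", GROUPS_2)
        assert m.feature_ids == ["fA", "fB", "fC"]
        assert m.sample_ids == ["S1", "S2"]
        assert m.groups == ["tumor", "normal"]
        assert m.values[0, 0] == 1.5 and m.values[2, 1] == 6.0

    def test_round_trip(self, tsv_3x2, tmp_path):
        m = data_io.read_expression(tsv_3x2, "tsv", GROUPS_2)
        out = tmp_path / "out.tsv"
        data_io.write_expression(m, out)
        m2 = data_io.read_expression(out, "tsv", GROUPS_2)
        assert m2.feature_ids == m.feature_ids
        assert m2.sample_ids == m.sample_ids
        np.testing.assert_allclose(m2.values, m.values)

    def test_series_matrix_equals_tsv(self, tsv_3x2, tmp_path):
        # same matrix in series-matrix encoding with quoted ids
        sm = tmp_path / "series.txt"
        sm.write_text(
            "!Series_title\t\"whatever\"\n"
            "!Sample_geo_accession\t\"S1\"\t\"S2\"\n"
            "!series_matrix_table_begin\n"
            "\"ID_REF\"\t\"S1\"\t\"S2\"\n"
            "\"fA\"\t1.5\t2.5\n"
            "\"fB\"\t3\t4\n"
            "\"fC\"\t5.25\t6\n"
            "!series_matrix_table_end\n"
        )
        a = data_io.read_expression(tsv_3x2, "tsv", GROUPS_2)
        b = data_io.read_expression(sm, "series_matrix", GROUPS_2)
        assert a.feature_ids == b.feature_ids
        assert a.sample_ids == b.sample_ids
        np.testing.assert_allclose(a.values, b.values)

    def test_missing_values_are_nan_not_zero(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("feature_id\tS1\tS2\nfA\t\t2.0\nfB\tNA\t4\n")
        m = data_io.read_expression(path, "tsv", GROUPS_2)
        assert math.isnan(m.values[0, 0]) and math.isnan(m.values[1, 0])
        assert m.values[0, 1] == 2.0

    def test_unlabeled_sample_raises(self, tsv_3x2):
        with pytest.raises(LabelingError, match="S2"):
            data_io.read_expression(tsv_3x2, "tsv", {"S1": "tumor"})

    def test_malformed_row_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tS1\tS2\nfA\t1.0\n")
        with pytest.raises(FormatError):
            data_io.read_expression(path, "tsv", GROUPS_2)

    def test_no_sentinel_raises(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("ID\tS1\nfA\t1\n")
        with pytest.raises(FormatError, match="sentinel"):
            data_io.read_expression(path, "series_matrix", GROUPS_2)

    def test_never_drops_rows(self, tmp_path):
        rng = np.random.default_rng(0)
        n = int(rng.integers(5, 40))
        lines = ["feature_id\tS1\tS2"]
        for i in range(n):
            lines.append(f"f{i}\t{rng.normal()}\t{rng.normal()}")
        path = tmp_path / "r.tsv"
        path.write_text("\n".join(lines) + "\n")
        m = data_io.read_expression(path, "tsv", GROUPS_2)
        assert m.n_features == n

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\tS1\tS1\nfA\t1\t2\n")
        with pytest.raises(UsageError):
            data_io.read_expression(path, "tsv", {"S1": "tumor"})


class TestPreprocessMissing:
    def test_drops_feature_with_excess_missing(self):
        values = np.array([[1.0, np.nan, np.nan, 4.0], [1.0, 2.0, 3.0, 4.0]])
        m = data_io.ExpressionMatrix(
            feature_ids=["a", "b"],
            sample_ids=["T1", "T2", "N1", "N2"],
            groups=["tumor", "tumor", "normal", "normal"],
            values=values,
            scale="log2",
        )
        out = data_io.preprocess_missing(m, max_missing_frac=0.2)
        assert out.feature_ids == ["b"]

    def test_imputes_within_group_mean(self):
        values = np.array([[1.0, np.nan, 3.0, 5.0, 7.0, np.nan]])
        m = data_io.ExpressionMatrix(
            feature_ids=["a"],
            sample_ids=["T1", "T2", "T3", "N1", "N2", "N3"],
            groups=["tumor"] * 3 + ["normal"] * 3,
            values=values,
            scale="log2",
        )
        out = data_io.preprocess_missing(m, max_missing_frac=0.5)
        assert out.values[0, 1] == pytest.approx(2.0)  # mean of 1, 3
        assert out.values[0, 5] == pytest.approx(6.0)  # mean of 5, 7


class TestGeneSets:
    def test_reads_two_sets(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "GO:1\tfirst\tA\tB\tC\n"
            "GO:2\tsecond\tA\tB\tC\tD\tE\n"
        )
        gs = data_io.read_gene_sets(path)
        assert len(gs) == 2
        assert len(gs.members("GO:1")) == 3
        assert len(gs.members("GO:2")) == 5

    def test_duplicate_member_counted_once(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:1\tfirst\tA\tB\tA\n")
        gs = data_io.read_gene_sets(path)
        assert gs.members("GO:1") == ["A", "B"]

    def test_short_line_raises_with_line_number(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:1\tfirst\tA\nGO:2\tbad\n")
        with pytest.raises(FormatError, match=":2"):
            data_io.read_gene_sets(path)

    def test_round_trip_random_collection(self, tmp_path):
        rng = np.random.default_rng(3)
        sets = {}
        genes = [f"G{i}" for i in range(50)]
        for t in range(8):
            size = int(rng.integers(3, 12))
            members = sorted(
                set(rng.choice(genes, size=size, replace=False))
            )
            sets[f"T{t}"] = (f"term {t}", members)
        gs = data_io.GeneSetCollection(sets=sets)
        path = tmp_path / "rt.gmt"
        data_io.write_gene_sets(gs, path)
        assert data_io.read_gene_sets(path) == gs

    def test_default_universe_is_member_union(self):
        gs = data_io.GeneSetCollection(
            sets={"t1": ("a", ["A", "B"]), "t2": ("b", ["B", "C"])}
        )
        assert sorted(gs.default_universe()) == ["A", "B", "C"]


class TestFasta:
    def test_two_records(self, tmp_path):
        path = tmp_path / "seqs.fa"
        path.write_text(">a desc\nACGU\n>b\nGGCC\n")
        seqs = data_io.read_fasta(path)
        assert seqs == {"a": "ACGU", "b": "GGCC"}

    def test_lowercase_and_t_normalized(self, tmp_path):
        path = tmp_path / "seqs.fa"
        path.write_text(">a\nacgt\n")
        assert data_io.read_fasta(path) == {"a": "ACGU"}

    def test_wrapped_equals_single_line(self, tmp_path):
        seq = "ACGUACGUACGUACGUACGU"
        one = tmp_path / "one.fa"
        one.write_text(f">x\n{seq}\n")
        wrapped = tmp_path / "wrapped.fa"
        wrapped.write_text(">x\n" + "\n".join(seq[i:i + 7] for i in range(0, len(seq), 7)) + "\n")
        assert data_io.read_fasta(one) == data_io.read_fasta(wrapped)

    def test_sequence_before_header_raises(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text("ACGU\n>a\nACGU\n")
        with pytest.raises(FormatError):
            data_io.read_fasta(path)

    def test_write_read_round_trip(self, tmp_path):
        seqs = {"m1": "ACGUACGUA" * 20, "m2": "GGGCCCAAA"}
        path = tmp_path / "rt.fa"
        data_io.write_fasta(seqs, path)
        assert data_io.read_fasta(path) == seqs


def _toy_network():
    return BipartiteNetwork(
        left_nodes={"m1": "up", "m2": "down"},
        right_nodes={"gA": "down", "gB": "up"},
        edges={("m1", "gA"): 1.0, ("m1", "gB"): 2.5, ("m2", "gB"): 1.0},
        right_type="mRNA",
    )


class TestNetworkIO:
    def test_edge_tsv_has_one_line_per_edge(self, tmp_path):
        path = tmp_path / "net.tsv"
        data_io.write_network(_toy_network(), path, "edge_tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 4  # header + 3 edges

    def test_empty_network_writes_header_only(self, tmp_path):
        net = BipartiteNetwork(left_nodes={}, right_nodes={}, edges={})
        path = tmp_path / "empty.tsv"
        data_io.write_network(net, path, "edge_tsv")
        assert path.read_text().splitlines() == ["mirna\tpartner\tweight"]

    def test_round_trip_edge_multiset(self, tmp_path):
        rng = np.random.default_rng(5)
        left = {f"m{i}": "up" for i in range(4)}
        right = {f"g{i}": "down" for i in range(6)}
        edges = {}
        for m in left:
            for g in right:
                if rng.random() < 0.4:
                    edges[(m, g)] = float(np.round(rng.uniform(0.5, 3), 4))
        net = BipartiteNetwork(left_nodes=left, right_nodes=right, edges=edges)
        path = tmp_path / "rt.tsv"
        data_io.write_network(net, path, "edge_tsv")
        back = data_io.read_network_edges(path)
        assert sorted(back) == sorted(
            (m, g, w) for (m, g), w in edges.items()
        )

    def test_graphml_attributes(self, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        data_io.write_network(_toy_network(), path, "graphml")
        g = nx.read_graphml(path)
        assert g.nodes["m1"]["node_type"] == "miRNA"
        assert g.nodes["gA"]["node_type"] == "mRNA"
        assert g.nodes["m1"]["direction"] == "up"
        assert g.edges[("m1", "gB")]["weight"] == 2.5

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(UsageError):
            data_io.write_network(_toy_network(), tmp_path / "x", "sif")


class TestPlatformMap:
    def test_read_many_to_one(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("p1\tGENE1\np2\tGENE1\np3\tGENE2\np3\tGENE3\n")
        pmap = data_io.read_platform_map(path)
        assert pmap.genes_for("p1") == ["GENE1"]
        assert pmap.genes_for("p3") == ["GENE2", "GENE3"]
        assert "p4" not in pmap

    def test_empty_value_rejected(self):
        with pytest.raises(FormatError):
            data_io.PlatformMap(mapping={"p1": [""]})


class TestMirnaIdCanonicalization:
    def test_hsa_prefix_lowercased(self):
        assert data_io.canonical_mirna_id("hsa-miR-923") == "hsa-mir-923"
        assert data_io.canonical_mirna_id("HSA-miR-923") == "hsa-mir-923"

    def test_other_ids_untouched(self):
        assert data_io.canonical_mirna_id("GENE1") == "GENE1"
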