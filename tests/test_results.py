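"""Output writers and the OTU network export."""

import random

import networkx as nx
import pytest

from ampliclust.amplicon_io import AbundanceDialect, build_pool
from ampliclust.cluster_engine import Parameters, cluster
from ampliclust.fastidious import fastidious_graft
from ampliclust.results import (
    build_network,
    export_network,
    render_network,
    write_internal_structure,
    write_otus,
    write_representatives,
    write_statistics,
)
from conftest import random_community_records


@pytest.fixture
def abc_result():
    pool = build_pool([("A", "AAAA", 10), ("B", "AAAT", 5), ("C", "AATT", 1)])
    return pool, cluster(pool, Parameters(d=1))


@pytest.fixture
def grafted_result(graft_pool):
    params = Parameters(d=1, fastidious=True)
    result = fastidious_graft(cluster(graft_pool, params), graft_pool, params)
    return graft_pool, result


class TestWriters:
    def test_otus_file_one_line_per_otu_seed_first(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "otus.txt"
        write_otus(result, pool, out)
        assert out.read_text() == "A_10 B_5 C_1\n"

    def test_d0_writes_one_line_per_amplicon(self, tmp_path):
        pool = build_pool([("a", "AAAA", 3), ("b", "CCCC", 2)])
        result = cluster(pool, Parameters(d=0))
        out = tmp_path / "otus.txt"
        write_otus(result, pool, out)
        assert len(out.read_text().splitlines()) == 2

    def test_grafted_members_appended_to_heavy_line(self, grafted_result, tmp_path):
        pool, result = grafted_result
        out = tmp_path / "otus.txt"
        write_otus(result, pool, out)
        assert out.read_text() == "X_50 Y_1\n"

    def test_representative_abundance_is_otu_total(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "reps.fasta"
        write_representatives(result, pool, out)
        assert out.read_text() == ">A_16\nAAAA\n"

    def test_grafted_representative_includes_graft(self, grafted_result, tmp_path):
        pool, result = grafted_result
        out = tmp_path / "reps.fasta"
        write_representatives(result, pool, out)
        assert out.read_text().splitlines()[0] == ">X_51"

    def test_size_annotation_dialect_respected(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "reps.fasta"
        write_representatives(result, pool, out, AbundanceDialect("size_annotation"))
        assert out.read_text().splitlines()[0] == ">A;size=16"

    def test_statistics_columns(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "stats.tsv"
        write_statistics(result, pool, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["3\t16\tA\t10\t1\t2\t0"]

    def test_statistics_singleton_and_graft_column(self, grafted_result, tmp_path):
        pool, result = grafted_result
        out = tmp_path / "stats.tsv"
        write_statistics(result, pool, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["2\t51\tX\t50\t1\t1\t1"]

    def test_internal_structure_chain(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "internal.tsv"
        write_internal_structure(result, pool, out)
        assert out.read_text() == "A\tB\t1\t1\t1\nB\tC\t1\t1\t2\n"

    def test_internal_structure_empty_for_d0(self, tmp_path):
        pool = build_pool([("a", "AAAA", 3), ("b", "CCCC", 2)])
        out = tmp_path / "internal.tsv"
        write_internal_structure(cluster(pool, Parameters(d=0)), pool, out)
        assert out.read_text() == ""

    def test_graft_edge_written(self, grafted_result, tmp_path):
        pool, result = grafted_result
        out = tmp_path / "internal.tsv"
        write_internal_structure(result, pool, out)
        assert out.read_text() == "X\tY\t2\t1\t1\n"

    def test_cross_file_consistency_on_random_community(self, tmp_path):
        rng = random.Random(13)
        pool = build_pool(random_community_records(rng, n_satellites=40))
        params = Parameters(d=1, fastidious=True)
        result = fastidious_graft(cluster(pool, params), pool, params)
        paths = {name: tmp_path / name for name in ("o", "r", "s", "i")}
        write_otus(result, pool, paths["o"])
        write_representatives(result, pool, paths["r"])
        write_statistics(result, pool, paths["s"])
        write_internal_structure(result, pool, paths["i"])
        n = len(result.otus)
        assert len(paths["o"].read_text().splitlines()) == n
        assert paths["r"].read_text().count(">") == n
        stat_lines = [
            l for l in paths["s"].read_text().splitlines() if not l.startswith("#")
        ]
        assert len(stat_lines) == n
        assert sum(int(l.split("\t")[1]) for l in stat_lines) == pool.total_abundance
        # each final OTU is a tree over its members (graft edges join the
        # absorbed light trees to the heavy tree): edges = amplicons - OTUs
        assert len(paths["i"].read_text().splitlines()) == len(pool) - n
        graft_lines = [
            l for l in paths["i"].read_text().splitlines() if int(l.split("\t")[2]) == 2
        ]
        assert len(graft_lines) >= len(
            [g for g in result.grafts if g.differences == 2]
        )


class TestNetwork:
    def test_chain_is_a_path_graph(self, abc_result):
        pool, result = abc_result
        net = build_network(result, pool, 1)
        assert [n for n, _ in net.nodes] == ["A", "B", "C"]
        assert len(net.edges) == 2
        assert all(not cut and not graft for _, _, _, cut, graft in net.edges)

    def test_refused_edge_flagged_cut_with_external_node(self, chain_pool):
        result = cluster(chain_pool, Parameters(d=1, break_chains=True))
        net = build_network(result, chain_pool, 1, include_cut_edges=True)
        assert {n for n, _ in net.nodes} == {"A", "B", "C"}  # C pulled in via the cut
        cut = [e for e in net.edges if e[3]]
        assert len(cut) == 1 and {cut[0][0], cut[0][1]} == {"B", "C"}

    def test_singleton_network(self):
        pool = build_pool([("a", "AAAA", 1)])
        net = build_network(cluster(pool, Parameters(d=1)), pool, 1)
        assert net.nodes == [("a", 1)] and net.edges == []

    def test_invalid_otu_index(self, abc_result):
        pool, result = abc_result
        with pytest.raises(ValueError):
            build_network(result, pool, 99)

    def test_graft_edge_flagged(self, grafted_result):
        pool, result = grafted_result
        net = build_network(result, pool, 1)
        assert net.edges == [("X", "Y", 2, False, True)]

    def test_include_cut_edges_adds_all_one_edit_pairs(self):
        # a triangle: tree holds 2 edges, the full graph has 3
        pool = build_pool([("a", "AAAA", 9), ("b", "AAAT", 5), ("c", "AAAG", 2)])
        result = cluster(pool, Parameters(d=1))
        assert len(build_network(result, pool, 1).edges) == 2
        assert len(build_network(result, pool, 1, include_cut_edges=True).edges) == 3


class TestExport:
    def test_edge_tsv_rows(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "net.tsv"
        export_network(build_network(result, pool, 1), out, format="edge_tsv")
        rows = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == 2

    def test_graphml_roundtrips_nodes_and_attributes(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "net.graphml"
        export_network(build_network(result, pool, 1), out, format="graphml")
        g = nx.read_graphml(out)
        assert sorted(g.nodes) == ["A", "B", "C"]
        assert g.nodes["A"]["abundance"] == 10

    def test_dot_export_mentions_cut_edges(self, chain_pool, tmp_path):
        result = cluster(chain_pool, Parameters(d=1))
        net = build_network(result, chain_pool, 1, include_cut_edges=True)
        out = tmp_path / "net.dot"
        export_network(net, out, format="dot")
        assert "color=red" in out.read_text()

    def test_unknown_format_rejected(self, abc_result, tmp_path):
        pool, result = abc_result
        with pytest.raises(ValueError):
            export_network(build_network(result, pool, 1), tmp_path / "x", "xml")

    def test_render_writes_an_image(self, abc_result, tmp_path):
        pool, result = abc_result
        out = tmp_path / "net.png"
        render_network(build_network(result, pool, 1), out)
        assert out.stat().st_size > 0
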