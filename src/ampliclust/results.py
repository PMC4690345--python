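"""Serialisation of clustering results: OTU lists, statistics, networks.

Output shapes follow amplicon-pipeline conventions: a membership file
(one OTU per line, annotated identifiers, seed first), a representatives
FASTA (the seed of each OTU with its abundance updated to the OTU total),
a seven-column statistics TSV, an internal-structure TSV listing every
attachment edge, and a per-OTU network export (GraphML / DOT / edge TSV,
plus a matplotlib rendering) where nodes are amplicons sized and coloured
by abundance and edge length carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import networkx as nx

from ampliclust.amplicon_io import AbundanceDialect, AmpliconPool
from ampliclust.cluster_engine import ClusterResult
from ampliclust.microvariants import iter_microvariants

#: nodes with at least this abundance get a text label when rendered
LABEL_ABUNDANCE_THRESHOLD = 10


@dataclass(frozen=True)
class OtuNetwork:
    """One OTU as a graph: (id, abundance) nodes; edges with flags.

    ``is_cut`` marks edges the chain-breaking gate refused; ``is_graft``
    marks fastidious graft edges (the only ones with 2 differences).
    """

    nodes: list[tuple[str, int]]
    edges: list[tuple[str, str, int, bool, bool]]  # (a, b, diff, is_cut, is_graft)


def write_otus(
    result: ClusterResult,
    pool: AmpliconPool,
    path: str | PathLike,
    dialect: AbundanceDialect | None = None,
) -> None:
    """One line per OTU: space-separated annotated member ids, seed first.

    Members appear in attachment order; grafted members come after the
    heavy OTU's own members.
    """
    dialect = dialect or AbundanceDialect()
    with open(path, "w") as fh:
        for otu in result.otus:
            ids = (
                dialect.format_id(pool[m.position].id, pool[m.position].abundance)
                for m in otu.members
            )
            fh.write(" ".join(ids) + "\n")


def write_representatives(
    result: ClusterResult,
    pool: AmpliconPool,
    path: str | PathLike,
    dialect: AbundanceDialect | None = None,
) -> None:
    """FASTA of OTU representatives.

    The representative is the most abundant amplicon of the OTU (its
    seed); its annotation is updated to the total OTU abundance, grafted
    members included.
    """
    dialect = dialect or AbundanceDialect()
    with open(path, "w") as fh:
        for otu in result.otus:
            seed = pool[otu.seed]
            fh.write(
                f">{dialect.format_id(seed.id, otu.total_abundance)}\n{seed.sequence}\n"
            )


def write_statistics(
    result: ClusterResult, pool: AmpliconPool, path: str | PathLike
) -> None:
    """Seven tab-separated columns per OTU.

    unique amplicons, total abundance, seed id, seed abundance, number of
    members with abundance 1, maximum generation, number of grafted
    members.  A header is written as a comment line.
    """
    with open(path, "w") as fh:
        fh.write(
            "#amplicons\ttotal_abundance\tseed_id\tseed_abundance\t"
            "singletons\tmax_generation\tgrafted\n"
        )
        for otu in result.otus:
            seed = pool[otu.seed]
            n_singleton = sum(
                1 for m in otu.members if pool[m.position].abundance == 1
            )
            fh.write(
                f"{len(otu.members)}\t{otu.total_abundance}\t{seed.id}\t"
                f"{seed.abundance}\t{n_singleton}\t{otu.max_generation}\t"
                f"{otu.n_grafted}\n"
            )


def write_internal_structure(
    result: ClusterResult, pool: AmpliconPool, path: str | PathLike
) -> None:
    """One line per attachment edge: parent id, child id, differences,
    OTU index (final numbering), child generation.  Graft edges included."""
    with open(path, "w") as fh:
        for e in result.internal_edges:
            fh.write(
                f"{pool[e.parent].id}\t{pool[e.child].id}\t{e.differences}\t"
                f"{e.otu_index}\t{e.generation}\n"
            )


def build_network(
    result: ClusterResult,
    pool: AmpliconPool,
    otu_index: int,
    include_cut_edges: bool = False,
) -> OtuNetwork:
    """Graph view of one OTU for visualisation.

    By default the attachment tree (plus any graft edges).  With
    ``include_cut_edges``, every one-edit pair among members is added, as
    well as refused (cut) edges — including those reaching members of
    adjacent OTUs, whose endpoints are then included as nodes — so the
    situation of two abundant OTUs joined through a rare amplicon with
    the cut shown in red is representable.
    """
    by_index = {o.otu_index: o for o in result.otus}
    if otu_index not in by_index:
        raise ValueError(f"no OTU with index {otu_index}")
    otu = by_index[otu_index]
    positions = {m.position for m in otu.members}
    node_pos = sorted(positions)
    edges: dict[tuple[int, int], tuple[int, bool, bool]] = {}

    def put(a: int, b: int, diff: int, is_cut: bool, is_graft: bool) -> None:
        key = (min(a, b), max(a, b))
        prev = edges.get(key)
        if prev is None or (prev[1] and not is_cut):  # tree/graft beats cut
            edges[key] = (diff, is_cut, is_graft)

    for e in result.internal_edges:
        if e.otu_index == otu_index:
            put(e.parent, e.child, e.differences, False, e.is_graft)

    if include_cut_edges:
        # all one-edit pairs among members (the tree shows only a subset)
        for pos in positions:
            for v in iter_microvariants(pool[pos].sequence):
                other = pool.index.get(v)
                if other is not None and other in positions and other != pos:
                    put(pos, other, 1, False, False)
        for parent, child, diff in result.cut_edges:
            if parent in positions or child in positions:
                put(parent, child, diff, True, False)
                node_pos = sorted(set(node_pos) | {parent, child})

    nodes = [(pool[p].id, pool[p].abundance) for p in node_pos]
    edge_list = [
        (pool[a].id, pool[b].id, diff, is_cut, is_graft)
        for (a, b), (diff, is_cut, is_graft) in sorted(edges.items())
    ]
    return OtuNetwork(nodes, edge_list)


def _to_networkx(network: OtuNetwork) -> nx.Graph:
    g = nx.Graph()
    for node_id, abundance in network.nodes:
        g.add_node(node_id, abundance=abundance)
    for a, b, diff, is_cut, is_graft in network.edges:
        g.add_edge(a, b, differences=diff, is_cut=is_cut, is_graft=is_graft)
    return g


def export_network(
    network: OtuNetwork, path: str | PathLike, format: str = "graphml"
) -> None:
    """Write the network as ``graphml``, ``dot`` or ``edge_tsv``.

    Abundance travels as a node attribute; is_cut/is_graft as edge
    attributes.
    """
    if format == "graphml":
        nx.write_graphml(_to_networkx(network), str(path))
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("graph otu {\n")
            for node_id, abundance in network.nodes:
                fh.write(f'  "{node_id}" [abundance={abundance}];\n')
            for a, b, diff, is_cut, is_graft in network.edges:
                attrs = f"differences={diff}"
                if is_cut:
                    attrs += ", color=red, is_cut=true"
                if is_graft:
                    attrs += ", style=dashed, is_graft=true"
                fh.write(f'  "{a}" -- "{b}" [{attrs}];\n')
            fh.write("}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("#node_a\tnode_b\tdifferences\tis_cut\tis_graft\n")
            for a, b, diff, is_cut, is_graft in network.edges:
                fh.write(
                    f"{a}\t{b}\t{diff}\t{str(is_cut).lower()}\t"
                    f"{str(is_graft).lower()}\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def render_network(network: OtuNetwork, path: str | PathLike) -> None:
    """Draw the OTU as a 2-D graph (best effort; layout is meaningless).

    Node area scales with abundance, colour maps abundance, labels are
    shown for abundances of 10 or more, and cut edges are drawn red.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = _to_networkx(network)
    layout = nx.spring_layout(g, seed=0)
    abundances = [g.nodes[n]["abundance"] for n in g.nodes]
    sizes = [60 + 40 * a for a in abundances]
    edge_colors = [
        "red" if g.edges[e]["is_cut"] else "grey" for e in g.edges
    ]
    edge_styles = [
        "dashed" if g.edges[e]["is_graft"] else "solid" for e in g.edges
    ]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_edges(g, layout, ax=ax, edge_color=edge_colors, style=edge_styles)
    nx.draw_networkx_nodes(
        g, layout, ax=ax, node_size=sizes, node_color=abundances, cmap="Reds"
    )
    labels = {
        n: n for n in g.nodes if g.nodes[n]["abundance"] >= LABEL_ABUNDANCE_THRESHOLD
    }
    nx.draw_networkx_labels(g, layout, labels=labels, ax=ax, font_size=8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
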