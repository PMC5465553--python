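"""Reaction graphs, host/microbe merging, and interface layering.

Nodes are merged reactions: any reactions with *identical* metabolite sets
collapse into a single node whose id is the lexicographically smallest
member reaction id.  Edges join nodes sharing at least one non-currency
metabolite and are labeled with the shared metabolites.  Host and microbial
graphs built at the same currency cutoff are joined by *interface edges*:
one host and one microbial node that each use a common interface metabolite
(interface metabolites bypass the currency exclusion).  Each node's *layer*
is the number of within-subnetwork hops to the interface frontier, so
interface-edge-incident nodes sit at layer 0 and distances grow outward;
nodes with no path to the frontier carry the ``None`` sentinel and are
excluded from layer statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .config import load_id_map
from .reaction_db import ReactionDatabase, currency_metabolites

#: Layer sentinel for nodes with no path to the other subnetwork.
UNREACHABLE = None


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    member_reaction_ids: frozenset[str]
    metabolite_ids: frozenset[str]
    subnetwork: str  # host | microbial


@dataclass
class MetabolicGraph:
    """Undirected shared-metabolite reaction graph at one currency cutoff."""

    graph: nx.Graph
    nodes: dict[str, NetworkNode]
    currency_cutoff: int
    currency_set: frozenset[str]
    subnetwork: str
    #: reaction id -> node id, for read-assignment lookup
    reaction_to_node: dict[str, str] = field(default_factory=dict)

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def carbon_sum(self, db: ReactionDatabase, node_id: str) -> int:
        node = self.nodes[node_id]
        return sum(db.metabolites[m].carbon_count for m in node.metabolite_ids)


@dataclass(frozen=True)
class InterfaceSet:
    name: str
    metabolite_ids: frozenset[str]


@dataclass
class MergedNetwork:
    host_graph: MetabolicGraph
    microbial_graph: MetabolicGraph
    interface: InterfaceSet
    #: sorted (host node id, microbial node id) cross-subnetwork pairs
    interface_edges: list[tuple[str, str]]
    layer: dict[str, int | None] = field(default_factory=dict)

    def layered_nodes(self, subnetwork: str | None = None) -> dict[str, int]:
        """Nodes with a defined layer, optionally restricted to one side."""
        graphs = {
            "host": self.host_graph.nodes,
            "microbial": self.microbial_graph.nodes,
        }
        keep = graphs.get(subnetwork, {**graphs["host"], **graphs["microbial"]})
        return {n: l for n, l in self.layer.items() if l is not None and n in keep}


def build_graph(db: ReactionDatabase, cutoff: int) -> MetabolicGraph:
    """Construct the shared-metabolite graph at one currency cutoff.

    Reactions with identical metabolite sets merge into one node; edges form
    only through metabolites occurring in fewer than ``cutoff`` reactions;
    isolated nodes are removed.
    """
    if not db.reactions:
        raise ValueError("cannot build a graph from an empty database")
    currency = frozenset(currency_metabolites(db, cutoff))

    by_metabolite_set: dict[frozenset[str], list[str]] = {}
    for rxn in db.reactions.values():
        by_metabolite_set.setdefault(rxn.metabolite_ids, []).append(rxn.id)

    nodes: dict[str, NetworkNode] = {}
    reaction_to_node: dict[str, str] = {}
    for mset, rids in by_metabolite_set.items():
        node_id = min(rids)
        nodes[node_id] = NetworkNode(
            node_id=node_id,
            member_reaction_ids=frozenset(rids),
            metabolite_ids=mset,
            subnetwork=db.source_label,
        )
        for rid in rids:
            reaction_to_node[rid] = node_id

    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    users: dict[str, list[str]] = {}
    for nid in sorted(nodes):
        for mid in nodes[nid].metabolite_ids:
            if mid not in currency:
                users.setdefault(mid, []).append(nid)
    for mid in sorted(users):
        group = users[mid]
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if g.has_edge(a, b):
                    g.edges[a, b]["shared"].add(mid)
                else:
                    g.add_edge(a, b, shared={mid})

    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    for n in isolated:
        node = nodes.pop(n)
        for rid in node.member_reaction_ids:
            reaction_to_node.pop(rid)

    return MetabolicGraph(
        graph=g,
        nodes=nodes,
        currency_cutoff=cutoff,
        currency_set=currency,
        subnetwork=db.source_label,
        reaction_to_node=reaction_to_node,
    )


def make_interface_set(
    name: str,
    id_map: dict[str, dict[str, str]] | None = None,
    all_list_path: str | Path | None = None,
) -> InterfaceSet:
    """Build one of the interface-metabolite sets.

    ``VFA`` is the three most abundant ruminal volatile fatty acids
    (acetate, propionate, butyrate); ``VFA_AA`` adds the 20 universal amino
    acids (23 compounds total); ``ALL`` is read from a caller-supplied id
    list (one id per line, duplicates collapse), standing in for the larger
    absorbed-compound catalogue.
    """
    id_map = id_map or load_id_map()
    vfa = frozenset(id_map["vfa"].values())
    if len(vfa) != 3:
        raise ValueError(f"VFA id map must resolve 3 distinct ids, got {len(vfa)}")
    if name == "VFA":
        return InterfaceSet("VFA", vfa)
    aa = frozenset(id_map["amino_acids"].values())
    if name == "VFA_AA":
        ids = vfa | aa
        if len(ids) != 23:
            missing = 23 - len(ids)
            raise ValueError(f"VFA_AA resolved {len(ids)} ids; {missing} collide or are missing")
        return InterfaceSet("VFA_AA", ids)
    if name == "ALL":
        if all_list_path is None:
            raise ValueError("ALL interface set requires a metabolite-id list file")
        ids = frozenset(
            line.strip()
            for line in Path(all_list_path).read_text().splitlines()
            if line.strip()
        )
        return InterfaceSet("ALL", vfa | aa | ids)
    raise ValueError(f"unknown interface set {name!r}; use VFA, VFA_AA or ALL")


def merge_networks(
    host: MetabolicGraph, microbial: MetabolicGraph, iface: InterfaceSet
) -> MergedNetwork:
    """Join host and microbial graphs through shared interface metabolites.

    An interface edge joins every (host node, microbial node) pair where
    both nodes use the *same* interface metabolite, evaluated on the full
    metabolite sets — the currency exclusion does not apply here.  Layers
    are assigned immediately (see :func:`assign_layers`).
    """
    if not iface.metabolite_ids:
        raise ValueError("empty interface set")
    if host.currency_cutoff != microbial.currency_cutoff:
        raise ValueError("host and microbial graphs built at different cutoffs")

    host_users: dict[str, set[str]] = {}
    for nid, node in host.nodes.items():
        for mid in node.metabolite_ids & iface.metabolite_ids:
            host_users.setdefault(mid, set()).add(nid)
    edges: set[tuple[str, str]] = set()
    for nid, node in microbial.nodes.items():
        for mid in node.metabolite_ids & iface.metabolite_ids:
            for h in host_users.get(mid, ()):
                edges.add((h, nid))

    merged = MergedNetwork(
        host_graph=host,
        microbial_graph=microbial,
        interface=iface,
        interface_edges=sorted(edges),
    )
    merged.layer = assign_layers(merged)
    return merged


def assign_layers(m: MergedNetwork) -> dict[str, int | None]:
    """Multi-source BFS layer assignment from the interface frontier.

    Layer 0 nodes are those incident to an interface edge; every other
    node's layer is its unweighted within-subnetwork shortest-path distance
    to that frontier (one less than the cross-network path length, which
    would also count the interface edge).  Unreached nodes get ``None``.
    """
    layer: dict[str, int | None] = {
        n: UNREACHABLE for n in list(m.host_graph.nodes) + list(m.microbial_graph.nodes)
    }
    host_frontier = sorted({h for h, _ in m.interface_edges})
    microbial_frontier = sorted({mic for _, mic in m.interface_edges})
    for graph, frontier in (
        (m.host_graph, host_frontier),
        (m.microbial_graph, microbial_frontier),
    ):
        if not frontier:
            continue
        dist = nx.multi_source_dijkstra_path_length(graph.graph, frontier, weight=None)
        for n, d in dist.items():
            layer[n] = int(d)
        for n in frontier:  # frontier nodes may be isolated-free but unlinked
            layer[n] = 0
    return layer


def export_graph_tables(m: MergedNetwork, out_dir: str | Path) -> None:
    """Write node/edge TSVs and a GraphML file for the merged network."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.tsv", "w") as fh:
        fh.write("node_id\tsubnetwork\tlayer\tdegree\n")
        for graph in (m.host_graph, m.microbial_graph):
            for nid in sorted(graph.nodes):
                lay = m.layer.get(nid)
                fh.write(
                    f"{nid}\t{graph.subnetwork}\t"
                    f"{'NA' if lay is None else lay}\t{graph.graph.degree(nid)}\n"
                )
    with open(out / "edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tkind\tshared_metabolites\n")
        for graph in (m.host_graph, m.microbial_graph):
            for a, b, data in sorted(graph.graph.edges(data=True)):
                fh.write(
                    f"{a}\t{b}\t{graph.subnetwork}\t{';'.join(sorted(data['shared']))}\n"
                )
        for h, mic in m.interface_edges:
            fh.write(f"{h}\t{mic}\tinterface\t\n")

    combined = nx.Graph()
    for graph in (m.host_graph, m.microbial_graph):
        for nid in graph.nodes:
            lay = m.layer.get(nid)
            combined.add_node(
                nid, subnetwork=graph.subnetwork, layer=-1 if lay is None else lay
            )
        for a, b, data in graph.graph.edges(data=True):
            combined.add_edge(a, b, kind=graph.subnetwork)
    for h, mic in m.interface_edges:
        combined.add_edge(h, mic, kind="interface")
    nx.write_graphml(combined, str(out / "network.graphml"))
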