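"""Mass isotopomer network G_m and its SCC decomposition.

Every mass isotopomer (an EMU together with a heavy-atom count, its
*weight*) is one node.  A directed edge runs from a reactant mass
isotopomer to a product mass isotopomer whenever some weight composition of
an EMU reaction connects them.  Because an EMU reaction can only add weight
contributed by co-reactants, edges never decrease weight, so every strongly
connected component (SCC) is weight-homogeneous.

The pipeline is: build the graph, prune it to the ancestors of the measured
mass isotopomers (their transitive closure on the transposed graph),
decompose into SCCs, sort the condensation DAG topologically (weight-major)
and optionally merge consecutive same-weight SCCs until each unit holds at
least ``lam`` mass isotopomers.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import product as iterproduct

import networkx as nx

from .emu_decomposition import EMU, EMUReaction, EMUReactionNetwork

__all__ = [
    "MassIsotopomerNode",
    "SCC",
    "SCCPartition",
    "build_graph",
    "prune_to_measured",
    "tarjan_scc",
    "topological_sort",
    "aggregate_lambda",
    "decompose",
    "graph_to_dot",
]


@dataclass(frozen=True, order=True)
class MassIsotopomerNode:
    """One mass isotopomer: an EMU carrying ``weight`` heavy atoms."""

    emu: EMU
    weight: int

    def __post_init__(self):
        if not 0 <= self.weight <= self.emu.size:
            raise ValueError(f"weight {self.weight} out of range for {self.emu}")

    def __str__(self) -> str:
        return f"{self.emu}.m{self.weight}"


def _node_key(node: MassIsotopomerNode):
    return (node.emu.metabolite, node.emu.atoms, node.weight)


def build_graph(network: EMUReactionNetwork) -> nx.DiGraph:
    """Directed graph of the network's non-input mass isotopomers.

    Substrate (input) mass isotopomers are constants of the system and are
    not represented as nodes; their contribution enters the ODEs as source
    terms.  Each edge stores the generating EMU reactions under the
    ``reactions`` attribute.
    """
    G = nx.DiGraph()
    inputs = set(network.input_emus)
    for emu in network.non_input_emus():
        for w in range(emu.size + 1):
            G.add_node(MassIsotopomerNode(emu, w))
    for er in network.reactions:
        ranges = [range(e.size + 1) for e in er.reactant_emus]
        for weights in iterproduct(*ranges):
            w = sum(weights)
            target = MassIsotopomerNode(er.product_emu, w)
            for emu, wk in zip(er.reactant_emus, weights):
                if emu in inputs:
                    continue
                source = MassIsotopomerNode(emu, wk)
                if G.has_edge(source, target):
                    G[source][target]["reactions"].append(er)
                else:
                    G.add_edge(source, target, reactions=[er])
    return G


def prune_to_measured(graph: nx.DiGraph, measured) -> nx.DiGraph:
    """Retain exactly the ancestors of the measured nodes (including the
    measured nodes themselves) and all induced edges.

    This is the transitive closure of the measured mass isotopomers on the
    transposed graph, computed by reverse breadth-first search; the retained
    set is identical to what an all-pairs (Floyd–Warshall) reachability
    computation would select.
    """
    measured = list(measured)
    for m in measured:
        if m not in graph:
            raise KeyError(f"measured node {m} not in graph")
    keep: set[MassIsotopomerNode] = set(measured)
    for m in measured:
        keep |= nx.ancestors(graph, m)
    return graph.subgraph(keep).copy()


@dataclass
class SCC:
    """A weight-homogeneous strongly connected component (possibly a merged
    aggregate of consecutive same-weight components)."""

    members: list[MassIsotopomerNode]
    weight: int
    topo_index: int = -1  # j within the weight class (1-based after sorting)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SCCPartition:
    sccs: list[SCC]
    graph: nx.DiGraph
    lam: int = 1
    node_scc: dict[MassIsotopomerNode, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.node_scc:
            self.reindex()

    def reindex(self) -> None:
        self.node_scc = {
            n: i for i, scc in enumerate(self.sccs) for n in scc.members
        }

    def condensation_edges(self) -> set[tuple[int, int]]:
        out = set()
        for u, v in self.graph.edges():
            a, b = self.node_scc[u], self.node_scc[v]
            if a != b:
                out.add((a, b))
        return out

    def parents_of(self, i: int) -> list[int]:
        return sorted({a for a, b in self.condensation_edges() if b == i})

    def validate(self) -> None:
        for scc in self.sccs:
            assert all(n.weight == scc.weight for n in scc.members), (
                "SCC mixes weights"
            )
        for a, b in self.condensation_edges():
            assert a < b, "condensation edge violates topological order"


def tarjan_scc(graph: nx.DiGraph) -> SCCPartition:
    """Decompose the (pruned) graph into maximal SCCs.

    A solitary mass isotopomer forms a singleton SCC.  The result is
    topologically sorted (weight-major) with deterministic tie-breaking.
    """
    sccs = []
    for comp in nx.strongly_connected_components(graph):
        members = sorted(comp, key=_node_key)
        weights = {n.weight for n in members}
        assert len(weights) == 1, "SCC spans multiple weights"
        sccs.append(SCC(members=members, weight=members[0].weight))
    partition = SCCPartition(sccs=sccs, graph=graph)
    return topological_sort(partition)


def topological_sort(partition: SCCPartition) -> SCCPartition:
    """Order SCCs by weight, then by a deterministic topological order of
    the condensation DAG within each weight; assign (weight, j) indices.

    Ties are broken by the smallest member key (metabolite, atoms, weight),
    so identical inputs always yield identical orderings.
    """
    sccs = partition.sccs
    node_scc = {n: i for i, scc in enumerate(sccs) for n in scc.members}
    succs: list[set[int]] = [set() for _ in sccs]
    indeg = [0] * len(sccs)
    for u, v in partition.graph.edges():
        a, b = node_scc[u], node_scc[v]
        if a != b and b not in succs[a]:
            succs[a].add(b)
            indeg[b] += 1
    heap = [
        (scc.weight, _node_key(scc.members[0]), i)
        for i, scc in enumerate(sccs)
        if indeg[i] == 0
    ]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, _, i = heapq.heappop(heap)
        order.append(i)
        for j in succs[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, (sccs[j].weight, _node_key(sccs[j].members[0]), j))
    assert len(order) == len(sccs), "cycle in SCC condensation (impossible)"
    sorted_sccs = [sccs[i] for i in order]
    j_counter: dict[int, int] = {}
    for scc in sorted_sccs:
        j_counter[scc.weight] = j_counter.get(scc.weight, 0) + 1
        scc.topo_index = j_counter[scc.weight]
    out = SCCPartition(sccs=sorted_sccs, graph=partition.graph, lam=partition.lam)
    out.validate()
    return out


def aggregate_lambda(partition: SCCPartition, lam: int) -> SCCPartition:
    """Greedily merge consecutive same-weight SCCs (head-to-tail in the
    topological order) until each merged unit holds >= ``lam`` mass
    isotopomers; the trailing unit of a weight class may stay smaller.

    The number of SCCs is non-increasing in ``lam``.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if lam == 1:
        return partition
    merged: list[SCC] = []
    acc: list[MassIsotopomerNode] = []
    acc_weight: int | None = None

    def flush():
        nonlocal acc, acc_weight
        if acc:
            merged.append(SCC(members=list(acc), weight=acc_weight))
        acc, acc_weight = [], None

    for scc in partition.sccs:
        if acc_weight is not None and scc.weight != acc_weight:
            flush()
        acc.extend(scc.members)
        acc_weight = scc.weight
        if len(acc) >= lam:
            flush()
    flush()
    j_counter: dict[int, int] = {}
    for scc in merged:
        j_counter[scc.weight] = j_counter.get(scc.weight, 0) + 1
        scc.topo_index = j_counter[scc.weight]
    out = SCCPartition(sccs=merged, graph=partition.graph, lam=lam)
    out.validate()
    return out


def measured_nodes(graph: nx.DiGraph, targets: list[EMU]) -> list[MassIsotopomerNode]:
    """All mass isotopomer nodes (every weight) of the target EMUs."""
    return [
        MassIsotopomerNode(emu, w) for emu in targets for w in range(emu.size + 1)
    ]


def decompose(network: EMUReactionNetwork, targets: list[EMU], lam: int = 1):
    """Full pipeline: graph -> prune -> SCC -> sort -> lambda-aggregate.

    Returns (pruned graph, partition).
    """
    G = build_graph(network)
    pruned = prune_to_measured(G, measured_nodes(G, targets))
    partition = tarjan_scc(pruned)
    if lam > 1:
        partition = aggregate_lambda(partition, lam)
    return pruned, partition


def graph_to_dot(graph: nx.DiGraph) -> str:
    lines = ["digraph mass_isotopomers {"]
    for n in sorted(graph.nodes, key=_node_key):
        lines.append(f'  "{n}";')
    for u, v in sorted(graph.edges, key=lambda e: (_node_key(e[0]), _node_key(e[1]))):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
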