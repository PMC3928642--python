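"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and
NetworkX isomorphism checks — and shares no code path with the
implementation it validates.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from bksim.molgraph import Molecule


def mol_to_nx(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for i, (elem, arom) in enumerate(mol.atom_labels()):
        g.add_node(i, label=(elem, arom))
    for i, j, lab in mol.bonds:
        g.add_edge(i, j, label=lab)
    return g


def pattern_to_nx(pattern) -> nx.Graph:
    g = nx.Graph()
    for i, label in enumerate(pattern.nodes):
        g.add_node(i, label=label)
    for i, j, lab in pattern.edges:
        g.add_edge(i, j, label=lab)
    return g


def _nm(a, b):
    return a["label"] == b["label"]


def _em(a, b):
    return a["label"] == b["label"]


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    return nx.is_isomorphic(g1, g2, node_match=_nm, edge_match=_em)


def monomorphic_embeds(pattern: nx.Graph, host: nx.Graph) -> bool:
    """Label-preserving injective map of pattern into host; host bonds
    between matched atoms that are absent from the pattern are fine."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        host, pattern, node_match=_nm, edge_match=_em
    )
    return gm.subgraph_is_monomorphic()


def connected_subgraphs(g: nx.Graph, max_nodes: int) -> list[nx.Graph]:
    """Every connected subgraph (any edge subset spanning its nodes,
    plus single nodes) with at most max_nodes nodes.  Exponential; only
    for tiny graphs."""
    out: list[nx.Graph] = []
    for i in g.nodes:
        sg = nx.Graph()
        sg.add_node(i, **g.nodes[i])
        out.append(sg)
    edges = list(g.edges)
    for k in range(1, len(edges) + 1):
        for subset in combinations(edges, k):
            sg = nx.Graph()
            for u, v in subset:
                sg.add_node(u, **g.nodes[u])
                sg.add_node(v, **g.nodes[v])
                sg.add_edge(u, v, **g.edges[u, v])
            if sg.number_of_nodes() <= max_nodes and nx.is_connected(sg):
                out.append(sg)
    return out


def enumerate_subtrees_oracle(mol: Molecule, max_nodes: int) -> list[nx.Graph]:
    """All distinct (up to isomorphism) connected acyclic subgraphs."""
    reps: list[nx.Graph] = []
    for sg in connected_subgraphs(mol_to_nx(mol), max_nodes):
        if sg.number_of_edges() != sg.number_of_nodes() - 1:
            continue  # keep free trees only
        if not any(graphs_isomorphic(sg, r) for r in reps):
            reps.append(sg)
    return reps


def mine_frequent_oracle(
    mols: list[Molecule], minsup: float, max_nodes: int
) -> list[nx.Graph]:
    """Enumerate-all-then-filter frequent-subtree miner."""
    hosts = [mol_to_nx(m) for m in mols]
    candidates: list[nx.Graph] = []
    for m in mols:
        for sg in enumerate_subtrees_oracle(m, max_nodes):
            if not any(graphs_isomorphic(sg, c) for c in candidates):
                candidates.append(sg)
    n = len(mols)
    out = []
    for cand in candidates:
        support = sum(1 for h in hosts if monomorphic_embeds(cand, h)) / n
        if support >= minsup - 1e-9:
            out.append(cand)
    return out


def mcs_size_oracle(a: Molecule, b: Molecule) -> int:
    """Maximum atoms over all connected common subgraphs, by exhausting
    the connected subgraphs of the smaller molecule."""
    ga, gb = mol_to_nx(a), mol_to_nx(b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    best = 0
    for sg in connected_subgraphs(ga, ga.number_of_nodes()):
        if sg.number_of_nodes() > best and monomorphic_embeds(sg, gb):
            best = sg.number_of_nodes()
    return best


def patterns_match_oracle(patterns, oracle_graphs) -> bool:
    """True iff the mined pattern list and the oracle's representative
    graphs are equal as sets of isomorphism classes."""
    if len(patterns) != len(oracle_graphs):
        return False
    remaining = list(oracle_graphs)
    for pat in patterns:
        pg = pattern_to_nx(pat)
        for k, og in enumerate(remaining):
            if graphs_isomorphic(pg, og):
                del remaining[k]
                break
        else:
            return False
    return not remaining
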