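"""Labeled free-tree pattern enumeration and frequent-subtree mining.

A *free tree* is an unrooted, connected, acyclic graph whose nodes are
labeled with (element, aromatic-flag) and whose edges carry a bond
label.  Free trees embed into arbitrary molecules by subgraph
monomorphism, so a tree pattern may match inside a ring (a 6-node
aromatic-carbon path embeds into benzene) even though patterns
themselves never contain ring closures.

Mining proceeds level-wise by pattern growth: frequent single-node
patterns are extended one node at a time using the (label, bond,
label) edge alphabet observed in the data, duplicates are eliminated
through a centroid-rooted canonical code, and infrequent branches are
pruned via the anti-monotonicity of transaction support.  Support is
transaction-based throughout: the fraction of molecules containing at
least one embedding, regardless of how many embeddings each contains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

from .molgraph import Molecule

__all__ = [
    "FreeTreePattern",
    "MiningResult",
    "canonical_code",
    "make_pattern",
    "embeds",
    "enumerate_subtrees",
    "mine_frequent",
    "calibrate_minsup",
]

logger = logging.getLogger(__name__)

NodeLabel = tuple[str, bool]  # (element symbol, aromatic flag)

_SMARTS_BOND = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


@dataclass(frozen=True)
class FreeTreePattern:
    """An unrooted labeled tree pattern with its canonical code.

    ``nodes[i]`` is an (element, aromatic) label; ``edges`` hold
    ``(i, j, bond_label)`` with ``len(edges) == len(nodes) - 1``.
    Construct through :func:`make_pattern`, which validates tree-ness
    and computes the code; two patterns are equal iff their canonical
    codes are equal.
    """

    nodes: tuple[NodeLabel, ...]
    edges: tuple[tuple[int, int, str], ...]
    canonical_code: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FreeTreePattern)
            and self.canonical_code == other.canonical_code
        )

    def __hash__(self) -> int:
        return hash(self.canonical_code)

    def to_smarts(self) -> str:
        """SMARTS with explicit bond orders and aromaticity constraints,
        suitable for monomorphism matching with RDKit."""
        adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(self.n_nodes)}
        for i, j, lab in self.edges:
            adj[i].append((j, lab))
            adj[j].append((i, lab))

        def atom_smarts(i: int) -> str:
            elem, arom = self.nodes[i]
            num = Chem.GetPeriodicTable().GetAtomicNumber(elem)
            return f"[#{num};{'a' if arom else 'A'}]"

        visited = {0}

        def walk(i: int) -> str:
            out = atom_smarts(i)
            branches = []
            for j, lab in adj[i]:
                if j in visited:
                    continue
                visited.add(j)
                branches.append(_SMARTS_BOND[lab] + walk(j))
            if not branches:
                return out
            return out + "".join(f"({b})" for b in branches[:-1]) + branches[-1]

        return walk(0)


def _validate_tree(nodes, edges) -> None:
    n = len(nodes)
    if n == 0:
        raise ValueError("empty pattern")
    if len(edges) != n - 1:
        raise ValueError(f"{len(edges)} edges on {n} nodes: not a tree")
    adj = {i: set() for i in range(n)}
    for i, j, _ in edges:
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bad edge ({i},{j})")
        if j in adj[i]:
            raise ValueError(f"duplicate edge ({i},{j})")
        adj[i].add(j)
        adj[j].add(i)
    # connectivity (with n-1 edges and no duplicates this also rules out cycles)
    stack, seen = [0], {0}
    while stack:
        for k in adj[stack.pop()]:
            if k not in seen:
                seen.add(k)
                stack.append(k)
    if len(seen) != n:
        raise ValueError("pattern graph is disconnected")


def canonical_code(
    nodes: tuple[NodeLabel, ...], edges: tuple[tuple[int, int, str], ...]
) -> str:
    """Canonical string for a labeled free tree.

    Root the tree at its centroid and emit an AHU-style encoding with
    children sorted by their own codes; a bicentroidal tree (two
    adjacent centroids) is encoded by splitting the central edge and
    combining the two rooted codes order-independently.  Two trees get
    the same string iff they are label-isomorphic.
    """
    _validate_tree(nodes, edges)
    n = len(nodes)
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
    for i, j, lab in edges:
        adj[i].append((j, lab))
        adj[j].append((i, lab))

    def centroids() -> list[int]:
        if n == 1:
            return [0]
        degree = {i: len(adj[i]) for i in range(n)}
        leaves = [i for i in range(n) if degree[i] == 1]
        removed = 0
        alive = set(range(n))
        while n - removed > 2:
            nxt = []
            for leaf in leaves:
                alive.discard(leaf)
                removed += 1
                for j, _ in adj[leaf]:
                    if j in alive:
                        degree[j] -= 1
                        if degree[j] == 1:
                            nxt.append(j)
            leaves = nxt
        return sorted(alive)

    def node_code(i: int) -> str:
        elem, arom = nodes[i]
        return f"{elem}{'*' if arom else ''}"

    def encode(i: int, parent: int) -> str:
        subs = sorted(
            _SMARTS_BOND[lab] + encode(j, i) for j, lab in adj[i] if j != parent
        )
        return node_code(i) + "(" + ",".join(subs) + ")" if subs else node_code(i)

    cs = centroids()
    if len(cs) == 1:
        return "C:" + encode(cs[0], -1)
    c1, c2 = cs
    lab = next(l for j, l in adj[c1] if j == c2)
    e1, e2 = encode(c1, c2), encode(c2, c1)
    lo, hi = sorted((e1, e2))
    return f"B:{_SMARTS_BOND[lab]}|{lo}|{hi}"


def make_pattern(nodes, edges) -> FreeTreePattern:
    """Validate and canonicalize a labeled tree into a pattern."""
    nodes = tuple((str(e), bool(a)) for e, a in nodes)
    edges = tuple((int(i), int(j), str(lab)) for i, j, lab in edges)
    return FreeTreePattern(nodes, edges, canonical_code(nodes, edges))


@lru_cache(maxsize=65536)
def _compiled_query(smarts: str) -> Chem.Mol:
    q = Chem.MolFromSmarts(smarts)
    if q is None:  # pragma: no cover - SMARTS is generated, always valid
        raise ValueError(f"bad pattern SMARTS {smarts!r}")
    return q


def embeds(pattern: FreeTreePattern, mol: Molecule) -> bool:
    """True iff *pattern* maps injectively into *mol* preserving node
    labels (element + aromaticity) and bond labels.

    Matching is monomorphism: bonds of the molecule between matched
    atoms that are not part of the pattern are allowed, which is what
    lets tree patterns match inside rings.
    """
    return mol.rdmol.HasSubstructMatch(_compiled_query(pattern.to_smarts()))


@dataclass(frozen=True)
class MiningResult:
    """Frequent patterns with their transaction supports.

    ``patterns`` is sorted by canonical code; ``support`` maps the
    canonical code to the fraction of molecules with an embedding.
    """

    patterns: tuple[FreeTreePattern, ...]
    support: dict[str, float]
    minsup: float
    n_molecules: int


def _edge_alphabet(mols) -> dict[NodeLabel, set[tuple[str, NodeLabel]]]:
    """For each node label, the (bond label, neighbour label) pairs seen
    anywhere in the data — the only candidate extensions worth trying."""
    alphabet: dict[NodeLabel, set[tuple[str, NodeLabel]]] = {}
    for mol in mols:
        labels = mol.atom_labels()
        for i, j, lab in mol.bonds:
            alphabet.setdefault(labels[i], set()).add((lab, labels[j]))
            alphabet.setdefault(labels[j], set()).add((lab, labels[i]))
    return alphabet


def _grow(
    mols: list[Molecule], min_count: int, max_nodes: int
) -> list[tuple[FreeTreePattern, int]]:
    """Level-wise pattern growth returning (pattern, transaction count).

    Each frequent size-k tree is extended by one leaf at every node
    using the data's edge alphabet; support counting is restricted to
    the parent's supporting transactions (anti-monotonicity).
    """
    alphabet = _edge_alphabet(mols)
    seen_labels: set[NodeLabel] = set()
    for mol in mols:
        seen_labels.update(mol.atom_labels())

    results: list[tuple[FreeTreePattern, int]] = []
    # frontier entries: (pattern, indices of supporting molecules)
    frontier: list[tuple[FreeTreePattern, list[int]]] = []
    for label in sorted(seen_labels):
        pat = make_pattern((label,), ())
        sup = [k for k, m in enumerate(mols) if label in m.atom_labels()]
        if len(sup) >= min_count:
            results.append((pat, len(sup)))
            frontier.append((pat, sup))

    size = 1
    while frontier and size < max_nodes:
        emitted: set[str] = set()
        nxt: list[tuple[FreeTreePattern, list[int]]] = []
        for pat, parent_sup in frontier:
            for anchor in range(pat.n_nodes):
                for bond_lab, new_lab in sorted(alphabet.get(pat.nodes[anchor], ())):
                    child = make_pattern(
                        pat.nodes + (new_lab,),
                        pat.edges + ((anchor, pat.n_nodes, bond_lab),),
                    )
                    if child.canonical_code in emitted:
                        continue
                    emitted.add(child.canonical_code)
                    sup = [k for k in parent_sup if embeds(child, mols[k])]
                    if len(sup) >= min_count:
                        nxt.append((child, sup))
        results.extend((pat, len(sup)) for pat, sup in nxt)
        frontier = nxt
        size += 1
    if frontier and size == max_nodes:
        logger.warning(
            "%d frequent pattern(s) at the %d-node size cap; larger frequent "
            "patterns may exist",
            len(frontier),
            max_nodes,
        )
    return results


def _min_count(minsup: float, n: int) -> int:
    return max(1, math.ceil(minsup * n - 1e-9))


def mine_frequent(
    mols: list[Molecule], minsup: float, max_nodes: int = 10
) -> MiningResult:
    """Mine all free-tree patterns of up to ``max_nodes`` nodes whose
    transaction support is at least ``minsup``.

    The result is independent of the input order of molecules and of
    atom numbering within them (patterns are identified by canonical
    code and sorted by it).
    """
    if not mols:
        raise ValueError("empty molecule list")
    if not 0.0 < minsup <= 1.0:
        raise ValueError(f"minsup must be in (0, 1], got {minsup}")
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    n = len(mols)
    found = _grow(mols, _min_count(minsup, n), max_nodes)
    found.sort(key=lambda pc: pc[0].canonical_code)
    return MiningResult(
        patterns=tuple(p for p, _ in found),
        support={p.canonical_code: c / n for p, c in found},
        minsup=minsup,
        n_molecules=n,
    )


def enumerate_subtrees(mol: Molecule, max_nodes: int) -> list[FreeTreePattern]:
    """All distinct free trees of up to ``max_nodes`` nodes embedding in
    *mol*: the exhaustive fragmentation used by the hand-selected
    substructure route (no frequency constraint)."""
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    return list(mine_frequent([mol], minsup=1.0, max_nodes=max_nodes).patterns)


def calibrate_minsup(
    mols: list[Molecule],
    target_fp_length: int,
    max_nodes: int = 10,
    grid_min: float = 0.50,
    grid_step: float = 0.01,
) -> float:
    """Largest minsup on the grid whose frequent-pattern count reaches
    ``target_fp_length``.

    Mirrors choosing the support threshold per dataset so that every
    dataset yields approximately the same number of substructural
    features.  If even the grid minimum yields too few patterns, the
    grid minimum is returned with a warning.
    """
    if not mols:
        raise ValueError("empty molecule list")
    if target_fp_length < 1:
        raise ValueError("target_fp_length must be >= 1")
    base = mine_frequent(mols, minsup=grid_min, max_nodes=max_nodes)
    counts = sorted(base.support.values(), reverse=True)
    n_grid = round((1.0 - grid_min) / grid_step)
    for k in range(n_grid + 1):
        s = 1.0 - k * grid_step
        n_at_s = sum(1 for c in counts if c >= s - 1e-9)
        if n_at_s >= target_fp_length:
            return round(s, 10)
    logger.warning(
        "target fp_length %d unreachable (only %d patterns at minsup %.2f); "
        "returning the grid minimum",
        target_fp_length,
        len(counts),
        grid_min,
    )
    return grid_min
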