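import itertools

import numpy as np
import pytest
from rdkit import Chem

from bksim.freetree import (
    calibrate_minsup,
    canonical_code,
    embeds,
    enumerate_subtrees,
    make_pattern,
    mine_frequent,
)
from bksim.molgraph import molecule_from_rdkit, parse_smiles
from conftest import random_molecule
from oracles import (
    enumerate_subtrees_oracle,
    graphs_isomorphic,
    mine_frequent_oracle,
    pattern_to_nx,
    patterns_match_oracle,
)

C, O = ("C", False), ("O", False)


class TestCanonicalCode:
    def test_path_encoded_from_either_end(self):
        p1 = make_pattern([C, C, O], [(0, 1, "single"), (1, 2, "single")])
        p2 = make_pattern([O, C, C], [(0, 1, "single"), (1, 2, "single")])
        assert p1.canonical_code == p2.canonical_code

    def test_rejects_cycle_and_disconnection(self):
        with pytest.raises(ValueError):
            canonical_code(
                (C, C, C),
                ((0, 1, "single"), (1, 2, "single"), (2, 0, "single")),
            )
        with pytest.raises(ValueError):
            canonical_code((C, C), ())

    def test_all_small_trees_get_distinct_codes(self):
        """Codes separate exactly the isomorphism classes of labeled
        trees on <= 3 nodes over {C, O}, checked pairwise against a
        brute-force isomorphism oracle."""
        trees = [make_pattern([lab], []) for lab in (C, O)]
        for a, b in itertools.product((C, O), repeat=2):
            trees.append(make_pattern([a, b], [(0, 1, "single")]))
        for mid, a, b in itertools.product((C, O), repeat=3):
            trees.append(
                make_pattern([a, mid, b], [(0, 1, "single"), (1, 2, "single")])
            )
        for t1, t2 in itertools.combinations(trees, 2):
            iso = graphs_isomorphic(pattern_to_nx(t1), pattern_to_nx(t2))
            assert (t1.canonical_code == t2.canonical_code) == iso

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_node_permutation(self, seed):
        rng = np.random.default_rng(seed)
        mol = random_molecule(rng, 9, "m")
        pats = enumerate_subtrees(mol, 5)
        for pat in pats[:: max(1, len(pats) // 10)]:
            perm = rng.permutation(pat.n_nodes)
            nodes = tuple(pat.nodes[int(k)] for k in np.argsort(perm))
            edges = tuple(
                (int(perm[i]), int(perm[j]), lab) for i, j, lab in pat.edges
            )
            relabeled = make_pattern(nodes, edges)
            assert relabeled.canonical_code == pat.canonical_code


class TestEmbeds:
    def test_simple_membership(self):
        cco = parse_smiles("CCO", "m")
        cc = make_pattern([C, C], [(0, 1, "single")])
        cn = make_pattern([C, ("N", False)], [(0, 1, "single")])
        assert embeds(cc, cco)
        assert not embeds(cn, cco)

    def test_tree_embeds_into_cycle(self):
        benzene = parse_smiles("c1ccccc1", "benz")
        ca = ("C", True)
        path6 = make_pattern(
            [ca] * 6, [(k, k + 1, "aromatic") for k in range(5)]
        )
        assert embeds(path6, benzene)

    def test_aromatic_does_not_match_aliphatic(self):
        hexane = parse_smiles("CCCCCC", "hex")
        ca = ("C", True)
        assert not embeds(make_pattern([ca], []), hexane)


class TestEnumerateSubtrees:
    def test_ethanol_five_patterns(self):
        mol = parse_smiles("CCO", "m")
        pats = enumerate_subtrees(mol, 3)
        assert patterns_match_oracle(pats, enumerate_subtrees_oracle(mol, 3))
        assert len(pats) == 5

    def test_single_atom(self):
        assert len(enumerate_subtrees(parse_smiles("C", "m"), 10)) == 1

    def test_benzene_paths(self):
        pats = enumerate_subtrees(parse_smiles("c1ccccc1", "m"), 6)
        assert len(pats) == 6  # aromatic-carbon paths of 1..6 nodes

    @pytest.mark.parametrize("n", [1, 2, 5, 8])
    def test_unlabeled_path_has_n_subtrees(self, n):
        mol = parse_smiles("C" * n, "m")
        assert len(enumerate_subtrees(mol, n)) == n


class TestMineFrequent:
    @pytest.fixture()
    def two_mols(self):
        return [parse_smiles("CCO", "a"), parse_smiles("CCN", "b")]

    def test_minsup_one(self, two_mols):
        res = mine_frequent(two_mols, minsup=1.0, max_nodes=5)
        assert len(res.patterns) == 2  # {C} and {C-C}
        assert all(res.support[p.canonical_code] == 1.0 for p in res.patterns)

    def test_minsup_half(self, two_mols):
        res = mine_frequent(two_mols, minsup=0.5, max_nodes=5)
        assert len(res.patterns) == 8
        assert patterns_match_oracle(
            res.patterns, mine_frequent_oracle(two_mols, 0.5, 5)
        )

    def test_single_transaction_equals_enumeration(self):
        mol = parse_smiles("CC(=O)O", "m")
        mined = mine_frequent([mol], minsup=1.0, max_nodes=4).patterns
        assert list(mined) == enumerate_subtrees(mol, 4)

    def test_validation(self, two_mols):
        with pytest.raises(ValueError):
            mine_frequent([], 0.5)
        with pytest.raises(ValueError):
            mine_frequent(two_mols, 0.0)
        with pytest.raises(ValueError):
            mine_frequent(two_mols, 1.5)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("minsup", [0.5, 1.0])
    def test_matches_bruteforce_oracle(self, seed, minsup):
        rng = np.random.default_rng(seed)
        mols = [
            random_molecule(rng, int(rng.integers(3, 9)), f"m{k}")
            for k in range(int(rng.integers(2, 6)))
        ]
        res = mine_frequent(mols, minsup=minsup, max_nodes=5)
        assert patterns_match_oracle(
            res.patterns, mine_frequent_oracle(mols, minsup, 5)
        )

    def test_anti_monotone_support(self, rng):
        mols = [random_molecule(rng, 8, f"m{k}") for k in range(5)]
        res = mine_frequent(mols, minsup=0.4, max_nodes=5)
        by_code = res.support
        for pat in res.patterns:
            if pat.n_nodes < 2:
                continue
            # drop each leaf; the smaller subtree can only be more frequent
            degree = {k: 0 for k in range(pat.n_nodes)}
            for i, j, _ in pat.edges:
                degree[i] += 1
                degree[j] += 1
            for leaf in (k for k, d in degree.items() if d == 1):
                keep = [k for k in range(pat.n_nodes) if k != leaf]
                remap = {old: new for new, old in enumerate(keep)}
                sub = make_pattern(
                    [pat.nodes[k] for k in keep],
                    [
                        (remap[i], remap[j], lab)
                        for i, j, lab in pat.edges
                        if leaf not in (i, j)
                    ],
                )
                assert by_code[sub.canonical_code] >= by_code[pat.canonical_code]

    def test_invariant_to_molecule_and_atom_order(self, rng):
        mols = [random_molecule(rng, 7, f"m{k}") for k in range(4)]
        res1 = mine_frequent(mols, minsup=0.5, max_nodes=4)
        shuffled = []
        for m in reversed(mols):
            order = [int(x) for x in rng.permutation(m.n_atoms)]
            renum = Chem.RenumberAtoms(m.rdmol, order)
            shuffled.append(molecule_from_rdkit(renum, m.id))
        res2 = mine_frequent(shuffled, minsup=0.5, max_nodes=4)
        assert [p.canonical_code for p in res1.patterns] == [
            p.canonical_code for p in res2.patterns
        ]


class TestCalibrateMinsup:
    def test_universal_label_reaches_target_one(self):
        mols = [parse_smiles(s, str(i)) for i, s in enumerate(["CCO", "CN", "CO"])]
        assert calibrate_minsup(mols, target_fp_length=1) == 1.0

    def test_picks_largest_qualifying_threshold(self):
        # 4 molecules share {C, C-C}; 3 of 4 share the C-C-O arm (support .75)
        mols = [
            parse_smiles(s, str(i))
            for i, s in enumerate(["CCO", "CCO", "CCO", "CCC"])
        ]
        got = calibrate_minsup(mols, target_fp_length=5, max_nodes=3)
        assert got == 0.75

    def test_unreachable_target_returns_grid_minimum(self, caplog):
        mols = [parse_smiles("C", "a"), parse_smiles("C", "b")]
        with caplog.at_level("WARNING"):
            got = calibrate_minsup(mols, target_fp_length=100)
        assert got == 0.50
        assert any("unreachable" in r.message for r in caplog.records)
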