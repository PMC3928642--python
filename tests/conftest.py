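import numpy as np
import pytest
from rdkit import Chem

from bksim.molgraph import Molecule, molecule_from_rdkit, parse_smiles

# Fixed panel of small molecules (<= 8 heavy atoms) mixing chains, rings,
# aromatics, heteroatoms and multiple bonds.
SMALL_PANEL = [
    "C",
    "N",
    "CCO",
    "CCN",
    "CC(C)O",
    "CC(=O)O",
    "c1ccccc1",
    "Cc1ccco1",
    "C1CC1",
    "C=CC=C",
    "CCSC",
    "OCC(N)C=O",
]


@pytest.fixture(scope="session")
def panel() -> list[Molecule]:
    return [parse_smiles(s, f"p{i}") for i, s in enumerate(SMALL_PANEL)]


def random_molecule(rng: np.random.Generator, n_atoms: int, mol_id: str) -> Molecule:
    """Random connected acyclic molecule over C/N/O/S with single and
    double bonds, for randomized oracle comparisons."""
    elements = ("C", "C", "C", "N", "O", "S")
    max_val = {"C": 4, "N": 3, "O": 2, "S": 2}
    rw = Chem.RWMol()
    rw.AddAtom(Chem.Atom("C"))
    used = [0]
    while rw.GetNumAtoms() < n_atoms:
        open_atoms = [
            i for i in range(rw.GetNumAtoms())
            if max_val[rw.GetAtomWithIdx(i).GetSymbol()] - used[i] >= 1
        ]
        if not open_atoms:
            break
        anchor = int(rng.choice(open_atoms))
        elem = str(rng.choice(elements))
        double = (
            rng.random() < 0.2
            and max_val[rw.GetAtomWithIdx(anchor).GetSymbol()] - used[anchor] >= 2
            and max_val[elem] >= 2
        )
        order = 2 if double else 1
        idx = rw.AddAtom(Chem.Atom(elem))
        rw.AddBond(anchor, idx, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)
        used[anchor] += order
        used.append(order)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return molecule_from_rdkit(mol, mol_id)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
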