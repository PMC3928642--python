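"""Molecular graph data model and SMILES/SDF readers.

Molecules are heavy-atom graphs: hydrogens are folded into per-atom
counts, aromaticity is perceived on input and encoded as a distinct
bond label, and multi-fragment records (salts, mixtures) are reduced
to their largest connected fragment.  The underlying RDKit ``Mol`` is
kept alongside a plain-Python view of atoms and bonds so that graph
algorithms (subtree mining, brute-force oracles) and substructure
matching can each use the representation that suits them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "AtomNode",
    "Molecule",
    "MoleculeParseError",
    "SkipRecord",
    "parse_smiles",
    "molecule_from_rdkit",
    "read_molecule_file",
    "write_molecule_file",
    "write_patterns",
]

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Bond labels used throughout: aromatic is distinct from the Kekulé orders.
BOND_LABELS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_TO_LABEL = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class MoleculeParseError(ValueError):
    """A record could not be parsed into a molecular graph."""

    def __init__(self, mol_id: str, reason: str):
        super().__init__(f"{mol_id}: {reason}")
        self.mol_id = mol_id
        self.reason = reason


@dataclass(frozen=True)
class SkipRecord:
    """A record skipped while reading a file, with the reason."""

    mol_id: str
    reason: str


@dataclass(frozen=True)
class AtomNode:
    """One heavy atom with the invariants used by circular fingerprints.

    ``degree`` counts heavy-atom neighbours only; ``valence_minus_h`` is
    the total valence minus the number of attached hydrogens.
    """

    element: str
    formal_charge: int
    n_hydrogens: int
    in_ring: bool
    degree: int
    valence_minus_h: int
    atomic_mass: float
    atomic_number: int
    aromatic: bool


@dataclass
class Molecule:
    """A connected heavy-atom molecular graph with an identifier."""

    id: str
    atoms: tuple[AtomNode, ...]
    bonds: tuple[tuple[int, int, str], ...]
    properties: dict[str, str] = field(default_factory=dict)
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_labels(self) -> list[tuple[str, bool]]:
        """Per-atom (element, aromatic) labels, the match criterion used
        by the free-tree patterns and the MCS."""
        return [(a.element, a.aromatic) for a in self.atoms]

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for i, j, label in self.bonds:
            if i == j:
                raise ValueError(f"{self.id}: self-bond on atom {i}")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"{self.id}: bond ({i},{j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"{self.id}: duplicate bond {key}")
            seen.add(key)
            if label not in BOND_LABELS:
                raise ValueError(f"{self.id}: unknown bond label {label!r}")


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest connected fragment; ties broken by more bonds, then
    lexicographically smaller canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    return min(
        frags,
        key=lambda f: (-f.GetNumAtoms(), -f.GetNumBonds(), Chem.MolToSmiles(f)),
    )


def molecule_from_rdkit(
    rdmol: Chem.Mol, mol_id: str, properties: dict[str, str] | None = None
) -> Molecule:
    """Build a :class:`Molecule` from a sanitized RDKit mol.

    Explicit hydrogens are removed, the largest fragment is kept and
    ring membership / aromaticity are taken from RDKit's perception.
    """
    mol = Chem.RemoveHs(rdmol)
    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags > 1:
        logger.warning("%s: %d fragments, keeping the largest", mol_id, n_frags)
        mol = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
    if mol.GetNumAtoms() == 0:
        raise MoleculeParseError(mol_id, "no heavy atoms")
    atoms = tuple(
        AtomNode(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
            degree=a.GetDegree(),
            valence_minus_h=a.GetTotalValence() - a.GetTotalNumHs(),
            atomic_mass=a.GetMass(),
            atomic_number=a.GetAtomicNum(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RDKIT_BOND_TO_LABEL[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return Molecule(
        id=mol_id,
        atoms=atoms,
        bonds=bonds,
        properties=dict(properties or {}),
        rdmol=mol,
    )


def parse_smiles(text: str, mol_id: str) -> Molecule:
    """Parse one SMILES into a heavy-atom :class:`Molecule`.

    Raises :class:`MoleculeParseError` on syntactically or chemically
    invalid input; callers reading files catch it and skip the record.
    """
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise MoleculeParseError(mol_id, f"unparsable SMILES {text!r}")
    return molecule_from_rdkit(rdmol, mol_id)


def _read_smi(path: Path) -> tuple[list[Molecule], list[SkipRecord]]:
    mols: list[Molecule] = []
    skips: list[SkipRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            if mol_id in seen_ids:
                logger.warning("%s: duplicate id %r kept", path, mol_id)
            seen_ids.add(mol_id)
            try:
                mols.append(parse_smiles(smiles, mol_id))
            except MoleculeParseError as exc:
                skips.append(SkipRecord(mol_id, exc.reason))
    return mols, skips


def _read_sdf(path: Path) -> tuple[list[Molecule], list[SkipRecord]]:
    mols: list[Molecule] = []
    skips: list[SkipRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            skips.append(SkipRecord(f"record{idx + 1}", "unparsable SDF record"))
            continue
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        mol_id = name.strip() or f"record{idx + 1}"
        props = {k: str(v) for k, v in rdmol.GetPropsAsDict().items()}
        try:
            mols.append(molecule_from_rdkit(rdmol, mol_id, props))
        except MoleculeParseError as exc:
            skips.append(SkipRecord(mol_id, exc.reason))
    return mols, skips


def read_molecule_file(
    path: str | Path, fmt: str | None = None
) -> tuple[list[Molecule], list[SkipRecord]]:
    """Read a ``.smi`` or SDF file, in file order.

    Returns ``(molecules, skips)`` where *skips* records unparsable
    entries (id + reason) instead of aborting, so a handful of bad
    records never kills a screening run.  ``fmt`` may be ``"smi"`` or
    ``"sdf"``; by default it is inferred from the suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smi"
    if fmt not in {"smi", "sdf"}:
        raise ValueError(f"unknown format {fmt!r}")
    mols, skips = (_read_smi if fmt == "smi" else _read_sdf)(path)
    if not mols and not skips:
        logger.warning("%s: empty file", path)
    if skips:
        logger.warning("%s: skipped %d unparsable record(s)", path, len(skips))
    return mols, skips


def write_molecule_file(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as ``SMILES<space>id`` lines (canonical SMILES)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for mol in mols:
            fh.write(f"{mol.to_smiles()} {mol.id}\n")


def write_patterns(patterns: Sequence, path: str | Path, supports=None) -> None:
    """Write patterns as SMARTS, one per line, in canonical-code order.

    ``supports`` is an optional parallel mapping from canonical code to
    support fraction, appended as a ``# support=`` comment.
    """
    if not patterns:
        raise ValueError("no patterns to write")
    ordered = sorted(patterns, key=lambda p: p.canonical_code)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pat in ordered:
            line = pat.to_smarts()
            if supports is not None:
                line += f" # support={supports[pat.canonical_code]:.6g}"
            fh.write(line + "\n")
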