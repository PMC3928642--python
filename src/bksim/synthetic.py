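"""Reproducible synthetic ligand/decoy benchmarks with a planted
binding-relevant scaffold.

Actives are the scaffold plus random acyclic decorations (atoms from
C/N/O/S attached by single or double bonds).  Decoys mimic the
composition-matched design of curated decoy sets: each is a random
reconnection of the scaffold's own atom multiset, decorated exactly
like the actives, so decoys overlap the actives in size and elemental
composition and a plain structural similarity cannot separate the
classes trivially — only the precise scaffold topology distinguishes
them.  A configurable fraction of decoys additionally contains the
intact scaffold (label noise, emulating decoy sets that are only
presumed inactive); the rest are verified scaffold-free.  Decorations
are acyclic so every planted feature is reachable by the free-tree
miner, while decoys may carry rings so substructure matching is
exercised inside cycles.  Generation is fully determined by the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .molgraph import Molecule, parse_smiles, write_molecule_file

__all__ = ["BenchmarkSpec", "generate_benchmark", "write_benchmark", "read_manifest"]

#: Default planted scaffold: a dihydroxy-acid chain of the kind that
#: anchors statins in their binding pocket (no stereochemistry).
DEFAULT_SCAFFOLD = "OC(=O)CC(O)CC(O)C=C"

_ELEMENTS = ("C", "C", "C", "N", "O", "S")  # carbon-biased alphabet
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


@dataclass(frozen=True)
class BenchmarkSpec:
    """Conditions of one synthetic ligand/decoy benchmark."""

    n_actives: int = 20
    n_decoys: int = 600
    scaffold: str = DEFAULT_SCAFFOLD
    decoration_depth: int = 8
    decoy_scaffold_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("n_actives and n_decoys must be >= 1")
        if not 0.0 <= self.decoy_scaffold_rate < 1.0:
            raise ValueError("decoy_scaffold_rate must be in [0, 1)")
        if self.decoration_depth < 0:
            raise ValueError("decoration_depth must be >= 0")


def _free_valence(rwmol: Chem.RWMol, idx: int) -> int:
    atom = rwmol.GetAtomWithIdx(idx)
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    used += abs(atom.GetFormalCharge())
    return _MAX_VALENCE.get(atom.GetSymbol(), 0) - used

def _attach_random_atoms(
    rwmol: Chem.RWMol, n_new: int, rng: np.random.Generator
) -> None:
    """Grow *rwmol* by ``n_new`` atoms via random acyclic attachment,
    respecting fixed valence caps."""
    for _ in range(n_new):
        candidates = [
            i for i in range(rwmol.GetNumAtoms()) if _free_valence(rwmol, i) >= 1
        ]
        if not candidates:
            break
        anchor = int(rng.choice(candidates))
        elem = str(rng.choice(_ELEMENTS))
        double = (
            rng.random() < 0.15
            and _free_valence(rwmol, anchor) >= 2
            and _MAX_VALENCE[elem] >= 2
        )
        new_idx = rwmol.AddAtom(Chem.Atom(elem))
        rwmol.AddBond(
            anchor, new_idx, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE
        )


def _finalize(rwmol: Chem.RWMol, mol_id: str) -> Molecule:
    mol = rwmol.GetMol()
    Chem.SanitizeMol(mol)
    # round-trip through canonical SMILES so the artifact equals its file form
    return parse_smiles(Chem.MolToSmiles(mol), mol_id)


def _decorated_scaffold(
    scaffold: Chem.Mol, depth: int, rng: np.random.Generator, mol_id: str
) -> Molecule:
    rw = Chem.RWMol(scaffold)
    n_new = int(rng.integers(max(1, depth // 2), depth + 1)) if depth else 0
    _attach_random_atoms(rw, n_new, rng)
    return _finalize(rw, mol_id)


def _rewire_once(rw: Chem.RWMol, rng: np.random.Generator) -> bool:
    """Relocate one random acyclic bond: detach a fragment and reattach
    it at a different atom with spare valence.  Returns False when no
    move was possible."""
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondType())
        for b in rw.GetBonds()
        if not b.IsInRing()
    ]
    if not bonds:
        return False
    u, v, btype = bonds[int(rng.integers(len(bonds)))]
    rw.RemoveBond(u, v)
    frags = Chem.GetMolFrags(rw.GetMol())
    side_v = next(f for f in frags if v in f)
    # reattach the v-side fragment somewhere on the u-side (not back at u)
    order = 2 if btype == Chem.BondType.DOUBLE else 1
    targets = [
        i
        for f in frags
        if v not in f
        for i in f
        if i != u and _free_valence(rw, i) >= order
    ]
    if not targets:
        rw.AddBond(u, v, btype)  # undo
        return False
    anchors = [i for i in side_v if _free_valence(rw, i) >= order]
    if not anchors:
        rw.AddBond(u, v, btype)
        return False
    rw.AddBond(
        int(rng.choice(targets)),
        int(rng.choice(anchors)),
        btype,
    )
    return True


def _random_decoy(
    scaffold: Chem.Mol, depth: int, rng: np.random.Generator, mol_id: str
) -> Molecule:
    """Hard decoy: the scaffold with one or two bonds relocated (same
    atom composition, perturbed topology), then decorated like an
    active."""
    rw = Chem.RWMol(scaffold)
    n_moves = int(rng.integers(1, 3))
    for _ in range(n_moves):
        _rewire_once(rw, rng)
    n_new = int(rng.integers(max(1, depth // 2), depth + 1)) if depth else 0
    _attach_random_atoms(rw, n_new, rng)
    # occasionally close a ring between two distant atoms with spare valence
    if rng.random() < 0.3 and rw.GetNumAtoms() >= 5:
        openv = [i for i in range(rw.GetNumAtoms()) if _free_valence(rw, i) >= 1]
        rng.shuffle(openv)
        for a in openv:
            partners = [
                b
                for b in openv
                if b != a
                and rw.GetBondBetweenAtoms(a, b) is None
                and len(Chem.GetShortestPath(rw.GetMol(), a, b)) >= 4
            ]
            if partners:
                rw.AddBond(a, int(partners[0]), Chem.BondType.SINGLE)
                break
    return _finalize(rw, mol_id)


def generate_benchmark(spec: BenchmarkSpec) -> tuple[list[Molecule], list[Molecule]]:
    """Generate (actives, decoys) per the benchmark spec.

    Every active contains the scaffold by construction; exactly
    ``round(rate * n_decoys)`` decoys contain it and the rest are
    verified not to (resampled on accidental hits).
    """
    scaffold = Chem.MolFromSmiles(spec.scaffold)
    if scaffold is None:
        raise ValueError(f"unparsable scaffold SMILES {spec.scaffold!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed))
    actives = [
        _decorated_scaffold(scaffold, spec.decoration_depth, rng, f"lig{k + 1}")
        for k in range(spec.n_actives)
    ]
    n_with = int(round(spec.decoy_scaffold_rate * spec.n_decoys))
    decoys: list[Molecule] = []
    for k in range(spec.n_decoys):
        mol_id = f"dec{k + 1}"
        if k < n_with:
            decoys.append(
                _decorated_scaffold(scaffold, spec.decoration_depth, rng, mol_id)
            )
        else:
            for _ in range(100):
                cand = _random_decoy(scaffold, spec.decoration_depth, rng, mol_id)
                if not cand.rdmol.HasSubstructMatch(scaffold):
                    decoys.append(cand)
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not sample a scaffold-free decoy")
    return actives, decoys


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_benchmark(
    actives: list[Molecule], decoys: list[Molecule], out_dir: str | Path,
    spec: BenchmarkSpec | None = None,
) -> Path:
    """Write ``ligands.smi``, ``decoys.smi`` and a ``manifest.json``
    carrying the spec and file checksums; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lig_path = out / "ligands.smi"
    dec_path = out / "decoys.smi"
    write_molecule_file(actives, lig_path)
    write_molecule_file(decoys, dec_path)
    manifest = {
        "spec": asdict(spec) if spec is not None else None,
        "n_actives": len(actives),
        "n_decoys": len(decoys),
        "checksums": {
            "ligands.smi": _checksum(lig_path),
            "decoys.smi": _checksum(dec_path),
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest_path


def read_manifest(path: str | Path) -> dict:
    """Load a manifest and verify the recorded checksums."""
    path = Path(path)
    manifest = json.loads(path.read_text(encoding="utf-8"))
    for fname, digest in manifest["checksums"].items():
        actual = _checksum(path.parent / fname)
        if actual != digest:
            raise ValueError(f"{fname}: checksum mismatch")
    return manifest
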