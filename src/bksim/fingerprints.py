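"""Binary substructure-occurrence fingerprints and circular (ECFP-style)
fingerprints, with the Tanimoto and Dice coefficients.

The occurrence fingerprint sets bit *i* when the *i*-th pattern of a
fixed, canonically ordered pattern list embeds in the molecule; it is
the carrier of the mined background knowledge.  The circular
fingerprint hashes, per atom, the seven atom-numbering-independent
invariants (heavy-neighbour count, valence minus hydrogens, atomic
number, atomic mass, formal charge, attached hydrogens, ring
membership) and then iteratively folds in sorted neighbour
environments up to a radius (default 2, i.e. ECFP4-equivalent
diameter).  Identifiers are kept as a set; environments whose bond
set duplicates an already-captured environment are dropped, matching
the published deduplication convention.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .freetree import FreeTreePattern, embeds
from .molgraph import Molecule

__all__ = [
    "BinaryFingerprint",
    "EcfpFingerprint",
    "bind_fp",
    "tanimoto",
    "dice",
    "ecfp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryFingerprint:
    """Bit vector over a shared, ordered pattern list."""

    bits: tuple[bool, ...]
    pattern_list: tuple[FreeTreePattern, ...]

    @property
    def length(self) -> int:
        return len(self.bits)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


@dataclass(frozen=True)
class EcfpFingerprint:
    """Set of circular-environment identifiers up to a radius."""

    identifiers: frozenset[int]
    radius: int


def bind_fp(
    mol: Molecule, pattern_list: Sequence[FreeTreePattern]
) -> BinaryFingerprint:
    """Binary occurrence fingerprint of *mol* over *pattern_list*."""
    if not pattern_list:
        raise ValueError("empty pattern list")
    return BinaryFingerprint(
        bits=tuple(embeds(p, mol) for p in pattern_list),
        pattern_list=tuple(pattern_list),
    )


def tanimoto(a: BinaryFingerprint, b: BinaryFingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| on shared pattern lists.

    Two all-zero fingerprints give 0, not 1: a pair about which the
    patterns say nothing should not look maximally similar.
    """
    if a.pattern_list != b.pattern_list:
        raise ValueError("fingerprints built over different pattern lists")
    va = np.asarray(a.bits, dtype=bool)
    vb = np.asarray(b.bits, dtype=bool)
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        logger.debug("two empty occurrence fingerprints compared; similarity 0")
        return 0.0
    return int(np.count_nonzero(va & vb)) / union


def dice(a: "EcfpFingerprint | Iterable[int]", b: "EcfpFingerprint | Iterable[int]") -> float:
    """Dice coefficient 2|a∩b| / (|a|+|b|) on identifier sets; 0 when
    both are empty."""
    sa = a.identifiers if isinstance(a, EcfpFingerprint) else frozenset(a)
    sb = b.identifiers if isinstance(b, EcfpFingerprint) else frozenset(b)
    denom = len(sa) + len(sb)
    if denom == 0:
        logger.debug("two empty identifier sets compared; similarity 0")
        return 0.0
    return 2.0 * len(sa & sb) / denom


_BOND_CODE = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}


def _stable_hash(payload: str) -> int:
    """Stable 64-bit hash (blake2b); independent of PYTHONHASHSEED."""
    return int.from_bytes(
        hashlib.blake2b(payload.encode(), digest_size=8).digest(), "big"
    )


def ecfp(mol: Molecule, radius: int = 2) -> EcfpFingerprint:
    """Circular fingerprint of *mol* as an identifier set.

    Round 0 hashes each atom's seven invariants; round k combines the
    atom's previous identifier with the sorted (bond code, neighbour
    identifier) pairs.  Every round's identifiers are collected, but an
    environment covering exactly the same bond set as one already
    captured (in any earlier round, or by a lower-identifier atom in
    the same round) contributes nothing new and is dropped; such atoms
    stop growing.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = mol.n_atoms
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(n)]  # (bond code, atom)
    incident: list[list[int]] = [[] for _ in range(n)]  # bond indices
    for bidx, (i, j, lab) in enumerate(mol.bonds):
        code = _BOND_CODE[lab]
        neighbors[i].append((code, j))
        neighbors[j].append((code, i))
        incident[i].append(bidx)
        incident[j].append(bidx)

    codes = [
        _stable_hash(
            "|".join(
                str(x)
                for x in (
                    a.degree,
                    a.valence_minus_h,
                    a.atomic_number,
                    round(a.atomic_mass, 3),
                    a.formal_charge,
                    a.n_hydrogens,
                    int(a.in_ring),
                )
            )
        )
        for a in mol.atoms
    ]
    identifiers: set[int] = set(codes)
    envs: list[frozenset[int]] = [frozenset() for _ in range(n)]
    seen_envs: set[frozenset[int]] = {frozenset()}
    dead = [len(neighbors[i]) == 0 for i in range(n)]

    for _ in range(radius):
        round_items: list[tuple[int, int, frozenset[int]]] = []
        new_codes = list(codes)
        new_envs = list(envs)
        for i in range(n):
            if dead[i]:
                continue
            parts = sorted((bc, codes[j]) for bc, j in neighbors[i])
            payload = str(codes[i]) + "".join(f"|{bc}:{cj}" for bc, cj in parts)
            new_codes[i] = _stable_hash(payload)
            env = envs[i].union(incident[i], *(envs[j] for _, j in neighbors[i]))
            new_envs[i] = env
            round_items.append((new_codes[i], i, env))
        codes = new_codes
        envs = new_envs
        for code, i, env in sorted(round_items, key=lambda t: (t[0], t[1])):
            if env in seen_envs:
                dead[i] = True
            else:
                seen_envs.add(env)
                identifiers.add(code)
    return EcfpFingerprint(identifiers=frozenset(identifiers), radius=radius)
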