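"""Base structural similarities and their background-knowledge extension.

Two base measures are provided: the Wallis graph similarity driven by
the size of the maximum common substructure,

    sim_mcs(a, b) = |mcs(a, b)| / (|a| + |b| - |mcs(a, b)|),

where |.| counts heavy atoms and the MCS is the largest *connected*
common subgraph (atoms matched on element + aromaticity, bonds on
exact bond label), and the Dice coefficient on circular-fingerprint
identifier sets.  The extended similarity blends a base measure with
the Tanimoto coefficient of binary substructure-occurrence
fingerprints built over a list of binding-relevant patterns:

    sim_ext(a, b) = (1 - alpha) * sim_base(a, b) + alpha * sim_fp(a, b)

with alpha defaulting to 1/3 so the base similarity outweighs its
extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from rdkit.Chem import rdFMCS

from .fingerprints import bind_fp, dice, ecfp, tanimoto
from .freetree import FreeTreePattern
from .molgraph import Molecule

__all__ = [
    "DEFAULT_ALPHA",
    "SimilarityConfig",
    "McsResult",
    "mcs_size",
    "mcs_similarity",
    "base_similarity",
    "extended_similarity",
]

#: Default fingerprint weight, kept exact as a rational.
DEFAULT_ALPHA = Fraction(1, 3)


@dataclass(frozen=True)
class SimilarityConfig:
    """Configuration of the (extended) similarity measure.

    ``alpha`` weighs the fingerprint part; ``extension_patterns`` must
    be present by the time a similarity with ``alpha > 0`` is actually
    computed (screening pipelines fill them in after the mining
    stage).  ``mcs_timeout`` (seconds) caps
    a single exact MCS computation; exceeding it flags the pair as
    inexact rather than silently under-reporting.
    """

    alpha: float = float(DEFAULT_ALPHA)
    base: str = "mcs"
    extension_patterns: tuple[FreeTreePattern, ...] | None = None
    ecfp_radius: int = 2
    mcs_timeout: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.base not in {"mcs", "ecfp"}:
            raise ValueError(f"base must be 'mcs' or 'ecfp', got {self.base!r}")


@dataclass(frozen=True)
class McsResult:
    """Size of the maximum common substructure of a pair."""

    size: int
    a_size: int
    b_size: int
    exact: bool = True


class _ElementAromaticCompare(rdFMCS.MCSAtomCompare):
    """Atom match on element and aromatic flag."""

    def __call__(self, params, mol1, a1, mol2, a2):  # noqa: D102
        x = mol1.GetAtomWithIdx(a1)
        y = mol2.GetAtomWithIdx(a2)
        return (
            x.GetAtomicNum() == y.GetAtomicNum()
            and x.GetIsAromatic() == y.GetIsAromatic()
        )


def _has_aromatic(mol: Molecule) -> bool:
    return any(a.aromatic for a in mol.atoms)


def _best_single_atom(a: Molecule, b: Molecule) -> int:
    return 1 if set(a.atom_labels()) & set(b.atom_labels()) else 0


def mcs_size(a: Molecule, b: Molecule, timeout: float = 10.0) -> McsResult:
    """Atom count of the largest connected common subgraph.

    Exact search (maximising atoms, not bonds); when neither molecule
    is aromatic the match reduces to element + exact bond order and a
    fast built-in comparator is used.  A timeout marks the result
    inexact (a lower bound) instead of failing.
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("MCS of an empty molecule")
    if a.n_atoms == 1 or b.n_atoms == 1:
        return McsResult(_best_single_atom(a, b), a.n_atoms, b.n_atoms)
    params = rdFMCS.MCSParameters()
    if _has_aromatic(a) or _has_aromatic(b):
        params.AtomTyper = _ElementAromaticCompare()
    else:
        params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrderExact
    params.MaximizeBonds = False
    params.Timeout = max(1, int(round(timeout)))
    res = rdFMCS.FindMCS([a.rdmol, b.rdmol], params)
    size = res.numAtoms
    if size < 1:
        # no common bonded fragment; a shared atom label still counts as size 1
        size = _best_single_atom(a, b)
    return McsResult(size, a.n_atoms, b.n_atoms, exact=not res.canceled)


def mcs_similarity(a: Molecule, b: Molecule, timeout: float = 10.0) -> float:
    """Wallis similarity |mcs| / (|a| + |b| - |mcs|), in [0, 1]."""
    r = mcs_size(a, b, timeout=timeout)
    return r.size / (r.a_size + r.b_size - r.size)


def base_similarity(a: Molecule, b: Molecule, cfg: SimilarityConfig) -> float:
    """The configured base similarity (MCS-based or circular-fingerprint
    Dice)."""
    if cfg.base == "mcs":
        return mcs_similarity(a, b, timeout=cfg.mcs_timeout)
    return dice(ecfp(a, cfg.ecfp_radius), ecfp(b, cfg.ecfp_radius))


def extended_similarity(a: Molecule, b: Molecule, cfg: SimilarityConfig) -> float:
    """Convex blend of the base similarity and the occurrence-fingerprint
    Tanimoto; reduces exactly to the base at alpha=0 and to the
    fingerprint part at alpha=1."""
    alpha = cfg.alpha
    if alpha > 0 and not cfg.extension_patterns:
        raise ValueError("alpha > 0 requires extension_patterns")
    s_fp = 0.0
    if alpha > 0:
        s_fp = tanimoto(
            bind_fp(a, cfg.extension_patterns), bind_fp(b, cfg.extension_patterns)
        )
        if alpha == 1.0:
            return s_fp
    s_base = base_similarity(a, b, cfg)
    return (1.0 - alpha) * s_base + alpha * s_fp
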