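"""Virtual-screening orchestration: ranking a database against a query
and the hand-selected (A) and mining-based (B1/B2) experiment designs.

A screening run ranks every database compound by its (extended)
similarity to one query ligand, in descending order with ties broken
by input position.  The mining-based designs repeat this over several
randomly chosen query ligands: B1 mines background-knowledge patterns
from all remaining ligands (optionally calibrating the support
threshold to hit a target fingerprint length), while B2 mines from
only a small random fraction of them at a fixed support of 0.9 —
the harder, more realistic setting where few actives are known.
All randomness derives from one master seed through per-trial spawn
keys, so adding trials never perturbs earlier ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .fingerprints import bind_fp, tanimoto
from .freetree import calibrate_minsup, enumerate_subtrees, mine_frequent
from .molgraph import Molecule
from .similarity import SimilarityConfig, base_similarity, mcs_size

__all__ = [
    "RankEntry",
    "RankedScreen",
    "TrialDesign",
    "rank_database",
    "rerank",
    "run_approach_a",
    "run_approach_b",
    "alpha_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankEntry:
    rank: int
    mol_id: str
    sim_base: float
    sim_bind_fp: float
    sim_ext: float
    is_active: bool
    input_index: int = 0


@dataclass(frozen=True)
class RankedScreen:
    """One ranked database with the similarity components per entry."""

    query_id: str
    entries: tuple[RankEntry, ...]
    config: SimilarityConfig
    inexact_count: int = 0
    mining_minsup: float | None = None
    n_patterns: int | None = None

    def ids(self) -> list[str]:
        return [e.mol_id for e in self.entries]


@dataclass(frozen=True)
class TrialDesign:
    """Repeated-trial design for the mining-based experiments."""

    n_queries: int = 10
    ligand_fraction_for_mining: float = 0.10
    minsup: float = 0.9
    seed: int = 0
    fractions: tuple[float, ...] = (1.0, 5.0, 10.0)
    target_fp_length: int | None = None
    max_nodes: int = 10

    def __post_init__(self) -> None:
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")
        if not all(0.0 < f <= 100.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 100]")
        if not 0.0 < self.ligand_fraction_for_mining <= 1.0:
            raise ValueError("ligand_fraction_for_mining must be in (0, 1]")

    def trial_rng(self, trial: int) -> np.random.Generator:
        """Counter-based per-trial generator derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(trial,))
        )


def _combine(alpha: float, s_base: float, s_fp: float) -> float:
    return (1.0 - alpha) * s_base + alpha * s_fp


def rank_database(
    query: Molecule,
    db: list[Molecule],
    cfg: SimilarityConfig,
    active_ids: set[str] | frozenset[str] = frozenset(),
) -> RankedScreen:
    """Rank *db* by extended similarity to *query*, descending.

    The query must not itself be in the database (checked by id); ties
    are broken by input position, so reruns are byte-identical.  The
    base and fingerprint components are retained per entry, which lets
    an alpha sweep recombine them without recomputation.
    """
    if not db:
        raise ValueError("empty screening database")
    if any(m.id == query.id for m in db):
        raise ValueError(f"query id {query.id!r} present in database")
    alpha = cfg.alpha
    if alpha > 0 and not cfg.extension_patterns:
        raise ValueError("alpha > 0 requires extension_patterns")
    q_fp = bind_fp(query, cfg.extension_patterns) if cfg.extension_patterns else None
    scored = []
    inexact = 0
    for idx, mol in enumerate(db):
        if cfg.base == "mcs":
            r = mcs_size(query, mol, timeout=cfg.mcs_timeout)
            if not r.exact:
                inexact += 1
            s_base = r.size / (r.a_size + r.b_size - r.size)
        else:
            s_base = base_similarity(query, mol, cfg)
        s_fp = (
            tanimoto(q_fp, bind_fp(mol, cfg.extension_patterns)) if q_fp else 0.0
        )
        scored.append((idx, mol.id, s_base, s_fp, _combine(alpha, s_base, s_fp)))
    scored.sort(key=lambda t: (-t[4], t[0]))
    entries = tuple(
        RankEntry(
            rank=r,
            mol_id=mid,
            sim_base=s_base,
            sim_bind_fp=s_fp,
            sim_ext=s_ext,
            is_active=mid in active_ids,
            input_index=idx,
        )
        for r, (idx, mid, s_base, s_fp, s_ext) in enumerate(scored, start=1)
    )
    return RankedScreen(
        query_id=query.id, entries=entries, config=cfg, inexact_count=inexact
    )


def rerank(screen: RankedScreen, alpha: float) -> RankedScreen:
    """Re-rank a screen at a different fingerprint weight by linearly
    recombining the cached base and fingerprint components."""
    scored = sorted(
        screen.entries,
        key=lambda e: (
            -_combine(alpha, e.sim_base, e.sim_bind_fp),
            e.input_index,
        ),
    )
    entries = tuple(
        RankEntry(
            rank=r,
            mol_id=e.mol_id,
            sim_base=e.sim_base,
            sim_bind_fp=e.sim_bind_fp,
            sim_ext=_combine(alpha, e.sim_base, e.sim_bind_fp),
            is_active=e.is_active,
            input_index=e.input_index,
        )
        for r, e in enumerate(scored, start=1)
    )
    cfg = replace(screen.config, alpha=alpha)
    return RankedScreen(
        query_id=screen.query_id,
        entries=entries,
        config=cfg,
        inexact_count=screen.inexact_count,
        mining_minsup=screen.mining_minsup,
        n_patterns=screen.n_patterns,
    )


def run_approach_a(
    substructure: Molecule,
    query: Molecule,
    db: list[Molecule],
    cfg: SimilarityConfig,
    active_ids: set[str] | frozenset[str] = frozenset(),
) -> RankedScreen:
    """Hand-selected-substructure pipeline: exhaustively fragment the
    given binding-relevant substructure into all its free subtrees,
    use them as the occurrence-fingerprint patterns, and rank."""
    if substructure.n_atoms == 0:
        raise ValueError("empty substructure")
    patterns = tuple(enumerate_subtrees(substructure, max_nodes=substructure.n_atoms))
    cfg = replace(cfg, extension_patterns=patterns)
    screen = rank_database(query, db, cfg, active_ids=active_ids)
    return replace(screen, n_patterns=len(patterns))


def run_approach_b(
    ligands: list[Molecule],
    decoys: list[Molecule],
    design: TrialDesign,
    cfg: SimilarityConfig,
    variant: str = "B2",
) -> list[RankedScreen]:
    """Mining-based pipeline, one ranked screen per random query.

    Per trial a query ligand is drawn at random; patterns are mined
    from the other ligands — all of them (B1, with optional support
    calibration to a target fingerprint length) or a random fraction
    (B2, fixed support threshold) — and the database (decoys plus the
    remaining ligands) is ranked by the extended similarity.  The
    query is excluded from the mining set as well as from the
    database, so no information about it leaks into its own trial.
    """
    if variant not in {"B1", "B2"}:
        raise ValueError(f"variant must be 'B1' or 'B2', got {variant!r}")
    if len(ligands) < 2:
        raise ValueError("need at least 2 ligands")
    active_ids = frozenset(m.id for m in ligands)
    screens: list[RankedScreen] = []
    for trial in range(design.n_queries):
        rng = design.trial_rng(trial)
        q_idx = int(rng.integers(len(ligands)))
        query = ligands[q_idx]
        others = [m for k, m in enumerate(ligands) if k != q_idx]
        if variant == "B1":
            mining_set = others
            if design.target_fp_length is not None:
                minsup = calibrate_minsup(
                    mining_set, design.target_fp_length, max_nodes=design.max_nodes
                )
            else:
                minsup = design.minsup
        else:
            n_mine = max(
                1, math.ceil(design.ligand_fraction_for_mining * len(others))
            )
            picked = rng.choice(len(others), size=n_mine, replace=False)
            mining_set = [others[int(k)] for k in sorted(picked)]
            minsup = design.minsup
        result = mine_frequent(mining_set, minsup=minsup, max_nodes=design.max_nodes)
        trial_cfg = cfg
        if result.patterns:
            trial_cfg = replace(cfg, extension_patterns=result.patterns)
        else:
            logger.warning(
                "trial %d: no frequent patterns at minsup %.2f; "
                "falling back to the base similarity (alpha=0)",
                trial,
                minsup,
            )
            trial_cfg = replace(cfg, alpha=0.0, extension_patterns=None)
        db = decoys + others
        screen = rank_database(query, db, trial_cfg, active_ids=active_ids)
        screens.append(
            replace(screen, mining_minsup=minsup, n_patterns=len(result.patterns))
        )
    return screens


def alpha_sweep(
    screens: list[RankedScreen], alphas: list[float]
) -> dict[float, list[RankedScreen]]:
    """Re-rank every screen at each alpha on the grid, reusing the
    cached per-pair base and fingerprint similarities."""
    if not all(0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    return {a: [rerank(s, a) for s in screens] for a in alphas}
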