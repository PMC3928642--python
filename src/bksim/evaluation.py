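"""Enrichment-factor evaluation of similarity rankings.

The enrichment factor at a database fraction x% is

    EF(x%) = (N_active(x%) / N(x%)) / (N_active / N_all),

the active rate in the top N(x%) ranks relative to the database-wide
active rate, with N(x%) = max(1, floor(x/100 * N_all)).  Its best
attainable value at that fraction,

    EF_max = (min(N_active, N(x%)) / N(x%)) / (N_active / N_all),

is reached by any ranking placing all actives first, and the reported
score is the shortfall Delta_EF = EF_max - EF(x%), for which smaller
is better and 0 is optimal.  Paired method comparisons are summarised
as win/draw/loss counts on Delta_EF and assessed with the exact
two-sided sign test (draws excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev

from scipy.stats import binomtest

from .screening import RankedScreen

__all__ = [
    "FractionMetrics",
    "EnrichmentReport",
    "WinLossRecord",
    "subset_size",
    "enrichment_factor",
    "ef_max",
    "delta_ef",
    "evaluate_screen",
    "aggregate_delta_ef",
    "win_loss",
    "sign_test",
]


@dataclass(frozen=True)
class FractionMetrics:
    """EF bookkeeping at one database fraction."""

    fraction_pct: float
    n_subset: int
    n_active_subset: int
    ef: float
    ef_max: float
    delta_ef: float


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-fraction enrichment metrics for one ranked screen."""

    query_id: str
    n_all: int
    n_active: int
    fractions: tuple[FractionMetrics, ...]

    def delta(self, fraction_pct: float) -> float:
        for fm in self.fractions:
            if math.isclose(fm.fraction_pct, fraction_pct):
                return fm.delta_ef
        raise KeyError(f"no metrics at fraction {fraction_pct}")


@dataclass(frozen=True)
class WinLossRecord:
    """Paired comparison of two methods on a smaller-is-better score."""

    wins: int
    draws: int
    losses: int
    comparison: tuple[str, str] = ("A", "B")
    sign_test_p: float | None = None

    @property
    def n(self) -> int:
        return self.wins + self.draws + self.losses


def subset_size(n_all: int, fraction_pct: float) -> int:
    """Number of top-ranked compounds inspected at a fraction:
    max(1, floor(fraction/100 * N_all)), never exceeding the stated
    fraction of the database (floor), but at least one compound."""
    if not 0.0 < fraction_pct <= 100.0:
        raise ValueError(f"fraction_pct must be in (0, 100], got {fraction_pct}")
    return max(1, math.floor(fraction_pct / 100.0 * n_all + 1e-9))


def enrichment_factor(
    screen: RankedScreen, fraction_pct: float
) -> tuple[float, int, int]:
    """EF at a fraction; returns (EF, N_subset, N_active_in_subset)."""
    n_all = len(screen.entries)
    if n_all == 0:
        raise ValueError("empty screen")
    n_active = sum(1 for e in screen.entries if e.is_active)
    if n_active == 0:
        raise ValueError("no actives in screen; EF undefined")
    n_sub = subset_size(n_all, fraction_pct)
    n_active_sub = sum(1 for e in screen.entries[:n_sub] if e.is_active)
    ef = (n_active_sub / n_sub) / (n_active / n_all)
    return ef, n_sub, n_active_sub


def ef_max(n_active: int, n_all: int, fraction_pct: float) -> float:
    """Maximum possible EF at a fraction (all actives ranked first)."""
    if not 1 <= n_active <= n_all:
        raise ValueError("need 1 <= n_active <= n_all")
    n_sub = subset_size(n_all, fraction_pct)
    return (min(n_active, n_sub) / n_sub) / (n_active / n_all)


def delta_ef(ef: float, efmax: float) -> float:
    """EF shortfall EF_max - EF, clamped at 0 against rounding residue."""
    if ef > efmax + 1e-9:
        raise ValueError(f"EF {ef} exceeds EF_max {efmax}")
    return max(0.0, efmax - ef)


def evaluate_screen(
    screen: RankedScreen, fractions: tuple[float, ...] = (1.0, 5.0, 10.0)
) -> EnrichmentReport:
    """Per-fraction EF / EF_max / Delta_EF for one ranked screen."""
    n_all = len(screen.entries)
    n_active = sum(1 for e in screen.entries if e.is_active)
    out = []
    for f in fractions:
        ef, n_sub, n_act_sub = enrichment_factor(screen, f)
        em = ef_max(n_active, n_all, f)
        out.append(
            FractionMetrics(
                fraction_pct=f,
                n_subset=n_sub,
                n_active_subset=n_act_sub,
                ef=ef,
                ef_max=em,
                delta_ef=delta_ef(ef, em),
            )
        )
    return EnrichmentReport(
        query_id=screen.query_id,
        n_all=n_all,
        n_active=n_active,
        fractions=tuple(out),
    )


def aggregate_delta_ef(
    reports: list[EnrichmentReport], fraction_pct: float
) -> tuple[float, float]:
    """Mean and sample standard deviation of Delta_EF across trials."""
    deltas = [r.delta(fraction_pct) for r in reports]
    return mean(deltas), (stdev(deltas) if len(deltas) > 1 else 0.0)


def win_loss(
    delta_a: list[float],
    delta_b: list[float],
    comparison: tuple[str, str] = ("A", "B"),
    with_sign_test: bool = True,
) -> WinLossRecord:
    """Paired win/draw/loss counts on Delta_EF (smaller is better for
    method A to win); draws on exact equality are excluded from the
    attached sign test."""
    if len(delta_a) != len(delta_b):
        raise ValueError("paired lists must have equal length")
    wins = sum(1 for x, y in zip(delta_a, delta_b) if x < y)
    losses = sum(1 for x, y in zip(delta_a, delta_b) if x > y)
    draws = len(delta_a) - wins - losses
    p = None
    if with_sign_test and wins + losses >= 1:
        p = sign_test(wins, losses)
    return WinLossRecord(
        wins=wins, draws=draws, losses=losses, comparison=comparison, sign_test_p=p
    )


def sign_test(wins: int, losses: int) -> float:
    """Exact two-sided sign test p-value for a win/loss split.

    Under the null the two methods are equally likely to win each pair,
    so wins ~ Binomial(wins + losses, 1/2); the two-sided p-value is
    2 * P(X >= max(wins, losses)), capped at 1.
    """
    n = wins + losses
    if n < 1:
        raise ValueError("sign test needs at least one non-draw pair")
    return binomtest(wins, n, 0.5, alternative="two-sided").pvalue
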