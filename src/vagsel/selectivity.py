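"""Selectivity index of bipolar cuff-pair stimulation.

Selectivity is the ability to evoke responses in MEA channels through one
bipolar pair of cuff contacts but not the other.  With T_12 and T_34 the
channel counts responding to each pair, T_S the overlap (channels
responding to both) and T_R the union, the selectivity index is

    SI = 0.5 * (T_R - T_S) / n_channels + 0.5 * (1 - |T_12 - T_34| / T_R)

The first term rewards many exclusively responding channels; the second
penalizes imbalance between the pairs.  SI lies in [0, 1], reaching 1 only
for a balanced, fully selective split covering the whole array.  SI is
defined as 0 when there are no responses at all (T_R = 0).

Optimization evaluates SI over the Cartesian product of tested amplitudes
for the two pairs, discarding combinations whose overlap exceeds 3 channels
(10% of the 32-channel array).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .core import CuffPair
from .responses import ResponseSet

__all__ = [
    "SelectivityCounts",
    "SelectivityResult",
    "count_responses",
    "selectivity_index",
    "optimize_selectivity",
    "selective_channel_summary",
]


@dataclass(frozen=True)
class SelectivityCounts:
    """Channel tallies for one amplitude combination."""

    t_12: int
    t_34: int
    t_s: int
    n_channels: int = 32

    def __post_init__(self) -> None:
        if min(self.t_12, self.t_34, self.t_s) < 0:
            raise ValueError("counts must be nonnegative")
        if self.t_s > min(self.t_12, self.t_34):
            raise ValueError("overlap cannot exceed either pair's count")
        if self.t_r > self.n_channels:
            raise ValueError("union exceeds the number of channels")

    @property
    def t_r(self) -> int:
        """Channels responding to either pair (inclusion-exclusion)."""
        return self.t_12 + self.t_34 - self.t_s


@dataclass
class SelectivityResult:
    counts: SelectivityCounts
    si: float
    amplitude_pair_uA: tuple[float, float]  # (pair 1:2, pair 3:4)
    pulse_width_ms: float | None
    selective_channels: dict[CuffPair, frozenset[int]]
    feasible: bool = True


def count_responses(
    resp12: ResponseSet, resp34: ResponseSet, n_channels: int = 32
) -> SelectivityCounts:
    """Set algebra over the two pairs' responding channels."""
    s12 = resp12.responding_channels
    s34 = resp34.responding_channels
    for ch in s12 | s34:
        if ch >= n_channels:
            raise ValueError(f"channel {ch} outside 0..{n_channels - 1}")
    return SelectivityCounts(
        t_12=len(s12), t_34=len(s34), t_s=len(s12 & s34), n_channels=n_channels
    )


def selectivity_index(c: SelectivityCounts) -> float:
    """SI in [0, 1]; 0 by definition when no channel responds."""
    if c.t_r == 0:
        return 0.0
    coverage = (c.t_r - c.t_s) / c.n_channels
    balance = 1.0 - abs(c.t_12 - c.t_34) / c.t_r
    return 0.5 * coverage + 0.5 * balance


def optimize_selectivity(
    grid: dict[CuffPair, dict[float, ResponseSet]],
    overlap_limit: int = 3,
    n_channels: int = 32,
    pulse_width_ms: float | None = None,
) -> SelectivityResult:
    """Exhaustive SI maximization over the tested amplitude product.

    Combinations with more than ``overlap_limit`` overlapping channels are
    excluded.  Ties break toward the lowest summed amplitude, then the
    lowest pair-1:2 amplitude.  If every combination is excluded the result
    carries ``feasible=False`` (with the least-overlapping combination's
    counts for reference).
    """
    amps12 = grid.get(CuffPair.PAIR_1_2, {})
    amps34 = grid.get(CuffPair.PAIR_3_4, {})
    if not amps12 or not amps34:
        raise ValueError("grid must hold at least one tested amplitude per pair")

    best = None          # (si, -total, -a12) maximized
    best_result = None
    fallback = None      # least overlap among infeasible, for reporting
    for a12, a34 in itertools.product(sorted(amps12), sorted(amps34)):
        r12, r34 = amps12[a12], amps34[a34]
        counts = count_responses(r12, r34, n_channels)
        si = selectivity_index(counts)
        result = SelectivityResult(
            counts=counts,
            si=si,
            amplitude_pair_uA=(a12, a34),
            pulse_width_ms=pulse_width_ms,
            selective_channels={
                CuffPair.PAIR_1_2: r12.responding_channels - r34.responding_channels,
                CuffPair.PAIR_3_4: r34.responding_channels - r12.responding_channels,
            },
        )
        if counts.t_s > overlap_limit:
            if fallback is None or counts.t_s < fallback.counts.t_s:
                fallback = result
            continue
        key = (si, -(a12 + a34), -a12)
        if best is None or key > best:
            best, best_result = key, result
    if best_result is None:
        fallback.feasible = False
        return fallback
    return best_result


def selective_channel_summary(
    resp12: ResponseSet, resp34: ResponseSet, overlap_allowance: int = 0
) -> dict[CuffPair, int]:
    """Per-pair selective channel counts under an overlap allowance.

    With allowance 0 only channels exclusive to each pair count; with a
    positive allowance, shared channels are included in both pairs' counts
    as long as the total overlap does not exceed the allowance (otherwise
    the excess overlap is excluded from both).
    """
    s12 = resp12.responding_channels
    s34 = resp34.responding_channels
    shared = s12 & s34
    included_shared = len(shared) if len(shared) <= overlap_allowance else 0
    return {
        CuffPair.PAIR_1_2: len(s12 - shared) + included_shared,
        CuffPair.PAIR_3_4: len(s34 - shared) + included_shared,
    }
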