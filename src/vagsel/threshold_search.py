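"""Binary search for the minimum amplitude evoking an MEA response.

For each cuff pair and pulse width the search probes stimulation amplitudes
between 0 and 3000 uA with a 20 uA target resolution.  The first probe is
at the maximum amplitude: a negative there means no response (NR) is
attainable at all, matching the reporting convention "no response up to
3 mA".  Otherwise the search maintains a bracket (highest negative, lowest
positive) and tests midpoints until the bracket width reaches the
resolution; the reported threshold is the lowest amplitude with a detected
response.  Probed amplitudes are rounded to a 1 uA lattice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CuffPair

__all__ = [
    "SearchConfig",
    "ThresholdRecord",
    "binary_search_threshold",
    "mean_threshold_by_pulse_width",
    "run_threshold_campaign",
    "ferret_threshold_table",
    "NR",
    "NT",
]

logger = logging.getLogger(__name__)

NR = "NR"  #: no response detected at any amplitude up to the maximum
NT = "NT"  #: condition not tested


@dataclass(frozen=True)
class SearchConfig:
    response_predicate: Callable[[float], bool]
    amp_min_uA: float = 0.0
    amp_max_uA: float = 3000.0
    resolution_uA: float = 20.0

    def __post_init__(self) -> None:
        if self.amp_min_uA >= self.amp_max_uA:
            raise ValueError("amp_min must be below amp_max")
        if self.resolution_uA <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class ThresholdRecord:
    """Outcome of one threshold search for (animal, pair, pulse width)."""

    threshold_uA: float | None          # None <=> NR
    tested_amplitudes: list[tuple[float, bool]] = field(default_factory=list)
    animal: str | None = None
    pair: CuffPair | None = None
    pulse_width_ms: float | None = None
    non_monotone: bool = False

    @property
    def is_nr(self) -> bool:
        return self.threshold_uA is None

    @property
    def n_calls(self) -> int:
        return len(self.tested_amplitudes)


def binary_search_threshold(cfg: SearchConfig, **labels) -> ThresholdRecord:
    """Bisect the recruitment threshold of a response predicate.

    ``labels`` (animal, pair, pulse_width_ms) are carried into the record.
    For a monotone predicate with true threshold T the returned value lies
    in [T, T + resolution) using at most
    ceil(log2((amp_max - amp_min) / resolution)) + 1 predicate calls.
    A positive probe below a recorded negative flags non-monotonicity; the
    bracket result is returned anyway with the flag set.
    """
    tested: list[tuple[float, bool]] = []

    def probe(a: float) -> bool:
        a = float(round(a))
        res = bool(cfg.response_predicate(a))
        tested.append((a, res))
        return res

    if not probe(cfg.amp_max_uA):
        return ThresholdRecord(threshold_uA=None, tested_amplitudes=tested, **labels)

    lo, hi = cfg.amp_min_uA, float(round(cfg.amp_max_uA))
    while hi - lo > cfg.resolution_uA:
        mid = round((lo + hi) / 2.0)
        if probe(mid):
            hi = float(mid)
        else:
            lo = float(mid)

    non_monotone = _check_monotone(tested)
    if non_monotone:
        logger.warning("non-monotone response predicate detected; bracket returned")
    return ThresholdRecord(
        threshold_uA=hi,
        tested_amplitudes=tested,
        non_monotone=non_monotone,
        **labels,
    )


def _check_monotone(tested: Sequence[tuple[float, bool]]) -> bool:
    positives = [a for a, r in tested if r]
    negatives = [a for a, r in tested if not r]
    return bool(positives and negatives and min(positives) < max(negatives))


def mean_threshold_by_pulse_width(
    records: Iterable[ThresholdRecord], pulse_width_ms: float
) -> float:
    """Arithmetic mean threshold (uA) over all tested, responding entries.

    Each cuff pair counts separately; NR entries are excluded.  Raises if no
    record at this pulse width has a threshold.
    """
    vals = [
        r.threshold_uA
        for r in records
        if r.pulse_width_ms is not None
        and math.isclose(r.pulse_width_ms, pulse_width_ms)
        and not r.is_nr
    ]
    if not vals:
        raise ValueError(f"no responding records at pulse width {pulse_width_ms} ms")
    return float(np.mean(vals))


def run_threshold_campaign(
    predicate_factory: Callable[[CuffPair, float], Callable[[float], bool]],
    pulse_widths_ms: Sequence[float] = (0.1, 0.5, 1.0),
    pairs: Sequence[CuffPair] = (CuffPair.PAIR_1_2, CuffPair.PAIR_3_4),
    amp_min_uA: float = 0.0,
    amp_max_uA: float = 3000.0,
    resolution_uA: float = 20.0,
    animal: str | None = None,
) -> list[ThresholdRecord]:
    """One binary search per (cuff pair, pulse width).

    ``predicate_factory(pair, pulse_width_ms)`` returns the amplitude ->
    detected? predicate for that condition (typically a full simulated
    stimulation trial followed by CAP detection).
    """
    records = []
    for pair in pairs:
        for pw in pulse_widths_ms:
            cfg = SearchConfig(
                response_predicate=predicate_factory(pair, pw),
                amp_min_uA=amp_min_uA,
                amp_max_uA=amp_max_uA,
                resolution_uA=resolution_uA,
            )
            records.append(
                binary_search_threshold(cfg, animal=animal, pair=pair, pulse_width_ms=pw)
            )
    return records


def records_to_table(records: Iterable[ThresholdRecord]) -> pd.DataFrame:
    """Long-format threshold table (animal, pair, pulse_width_ms, threshold_uA, flag)."""
    rows = []
    for r in records:
        rows.append({
            "animal": r.animal,
            "pair": r.pair.value if r.pair else None,
            "pulse_width_ms": r.pulse_width_ms,
            "threshold_uA": r.threshold_uA if not r.is_nr else np.nan,
            "flag": NR if r.is_nr else "",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundled reference dataset: per-animal thresholds (uA) from a six-ferret
# abdominal vagus stimulation study (cuff pairs 1:2 / 3:4 at four pulse
# widths; NR = no response up to 3 mA, NT = not tested).
# ---------------------------------------------------------------------------

_FERRET_THRESHOLDS: list[tuple[str, str, dict[float, tuple[object, object]]]] = [
    ("F21-19", "ventral", {0.1: (400, 400), 0.4: (NT, NT), 0.5: (620, 140), 1.0: (460, 140)}),
    ("F22-19", "ventral", {0.1: (1500, NR), 0.4: (NT, 1500), 0.5: (400, 400), 1.0: (400, 400)}),
    ("F19-19", "ventral", {0.1: (1500, 1500), 0.4: (NT, NT), 0.5: (400, 400), 1.0: (220, 220)}),
    ("F25-19", "dorsal", {0.1: (NR, NR), 0.4: (320, 180), 0.5: (140, 140), 1.0: (140, 140)}),
    ("F26-19", "dorsal", {0.1: (1500, 1500), 0.4: (NT, NT), 0.5: (400, 400), 1.0: (400, 220)}),
    ("F34-19", "dorsal", {0.1: (540, 400), 0.4: (NT, NT), 0.5: (140, 100), 1.0: (140, 100)}),
]


def ferret_threshold_table() -> list[ThresholdRecord]:
    """The bundled per-animal threshold dataset as ThresholdRecords.

    NT (not tested) entries are omitted; NR entries carry ``threshold_uA
    = None``.  Mean thresholds over this table are 1026.7, 306.7 and
    248.3 uA at 0.1, 0.5 and 1.0 ms.
    """
    records = []
    for animal, _trunk, by_pw in _FERRET_THRESHOLDS:
        for pw, (v12, v34) in by_pw.items():
            for pair, v in ((CuffPair.PAIR_1_2, v12), (CuffPair.PAIR_3_4, v34)):
                if v == NT:
                    continue
                records.append(
                    ThresholdRecord(
                        threshold_uA=None if v == NR else float(v),
                        animal=animal,
                        pair=pair,
                        pulse_width_ms=pw,
                    )
                )
    return records
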