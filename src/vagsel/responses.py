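"""Evoked-response containers shared by the detector and the simulator.

A ResponseEvent is one detected (or ground-truth) compound action potential
on one MEA channel, characterized by its post-stimulus latency and the
conduction velocity CV = cuff distance / latency.  CVs are binned in
0.5 m/s increments; at most one response exists per (channel, bin).
Fibers with CV below 3 m/s are unmyelinated C fibers, 3-30 m/s thinly
myelinated A-delta fibers (boundary 3.0 assigned to A-delta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import CuffPair, StimPulse

__all__ = ["FiberClass", "ResponseEvent", "ResponseSet", "classify_fiber", "cv_bin_index"]

C_FIBER = "C"
ADELTA_FIBER = "Adelta"
FiberClass = str

#: Upper bound of physiological conduction velocities considered (m/s).
CV_MAX_MPS = 30.0


def classify_fiber(cv_mps: float) -> FiberClass:
    """Classify a conduction velocity as C (< 3 m/s) or A-delta (3-30 m/s)."""
    if not 0.0 < cv_mps <= CV_MAX_MPS:
        raise ValueError(f"cv {cv_mps} m/s outside (0, {CV_MAX_MPS}]")
    return ADELTA_FIBER if cv_mps >= 3.0 else C_FIBER


def cv_bin_index(cv_mps: float, cv_bin_mps: float = 0.5) -> int:
    """Index of the CV bin [i*bin, (i+1)*bin) containing ``cv_mps``.

    The top edge (30 m/s exactly) folds into the highest bin.
    """
    n_bins = int(round(CV_MAX_MPS / cv_bin_mps))
    return min(int(cv_mps / cv_bin_mps), n_bins - 1)


@dataclass(frozen=True, order=True)
class ResponseEvent:
    channel: int
    latency_ms: float
    cv_mps: float
    cv_bin: int
    fiber_class: FiberClass

    def __post_init__(self) -> None:
        if self.latency_ms <= 0:
            raise ValueError("latency must be positive")


@dataclass
class ResponseSet:
    """All evoked responses for one (pulse, cuff pair) stimulation condition."""

    pulse: StimPulse
    pair: CuffPair
    events: list[ResponseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.channel, e.cv_bin) for e in self.events]
        if len(keys) != len(set(keys)):
            raise ValueError("at most one response per (channel, cv_bin)")

    @property
    def responding_channels(self) -> frozenset[int]:
        return frozenset(e.channel for e in self.events)

    def channel_class_set(self) -> frozenset[tuple[int, FiberClass]]:
        """(channel, fiber class) pairs — the granularity at which a detected
        set is compared with simulator ground truth."""
        return frozenset((e.channel, e.fiber_class) for e in self.events)

    def channel_bin_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((e.channel, e.cv_bin) for e in self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __bool__(self) -> bool:
        return bool(self.events)
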