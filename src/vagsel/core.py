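"""Shared domain types for vagus-nerve stimulation selectivity analysis.

The experimental substrate is a nerve-cuff electrode with two bipolar contact
pairs wrapped around the abdominal vagus trunk, and a 4x8 penetrating
microelectrode array (MEA, 400 um pitch) in the nodose ganglion recording
stimulation-evoked compound action potentials (CAPs) at 30 kHz.  Gastric
myoelectric activity is recorded from planar serosal electrodes with four
contacts each.

All voltages are expressed in microvolts throughout the package; thresholds
quoted in mV (e.g. the 8 mV artifact blanking level) are converted at the
call boundary.  Conduction distance between cuff and ganglion is a
per-recording scalar in meters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import h5py
import numpy as np

__all__ = [
    "CuffPair",
    "StimPulse",
    "StimTrain",
    "ChannelGeometry",
    "MEARecording",
    "GIRecording",
    "Epoch",
    "MAX_AMPLITUDE_UA",
    "DEFAULT_CUFF_DISTANCE_M",
    "ANALYSIS_WINDOW_END_S",
    "validate_recording",
    "channel_distance",
    "read_container",
    "write_container",
]

#: Hardware ceiling for stimulation amplitude (uA).
MAX_AMPLITUDE_UA = 3000.0

#: Default cuff-to-ganglion conduction distance (m) used by fixtures and the
#: synthetic-data generator.  In a real preparation this is measured per
#: animal; it scales every latency-to-velocity conversion.
DEFAULT_CUFF_DISTANCE_M = 0.15

#: End of the post-stimulus analysis window (s).  With pulses at 2 Hz this
#: leaves a 2 ms guard before the next pulse.
ANALYSIS_WINDOW_END_S = 0.498


class CuffPair(str, Enum):
    """Bipolar cuff contact pair used for stimulation."""

    PAIR_1_2 = "pair_1_2"
    PAIR_3_4 = "pair_3_4"

    @property
    def other(self) -> "CuffPair":
        return CuffPair.PAIR_3_4 if self is CuffPair.PAIR_1_2 else CuffPair.PAIR_1_2


@dataclass(frozen=True)
class StimPulse:
    """A single biphasic symmetric stimulus pulse.

    Parameters
    ----------
    amplitude_uA:
        Pulse amplitude in microamps, 0..`max_amplitude_uA`.
    pulse_width_ms:
        Per-phase pulse width in milliseconds (> 0).
    """

    amplitude_uA: float
    pulse_width_ms: float
    shape: str = "biphasic_symmetric"
    max_amplitude_uA: float = MAX_AMPLITUDE_UA

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_uA <= self.max_amplitude_uA:
            raise ValueError(
                f"amplitude {self.amplitude_uA} uA outside [0, {self.max_amplitude_uA}]"
            )
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.shape != "biphasic_symmetric":
            raise ValueError(f"unsupported pulse shape {self.shape!r}")


@dataclass(frozen=True)
class StimTrain:
    """A train of identical pulses delivered through one bipolar cuff pair."""

    pulse: StimPulse
    n_pulses: int = 120
    rate_hz: float = 2.0
    cuff_pair: CuffPair = CuffPair.PAIR_1_2

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def interval_s(self) -> float:
        return 1.0 / self.rate_hz


@dataclass(frozen=True)
class ChannelGeometry:
    """Planar MEA grid geometry.

    Channels are indexed row-major over (row, col), 0-based.  The anatomical
    orientation of the grid (caudal-to-rostral) is metadata only; every
    analysis here depends only on relative geometry.
    """

    n_rows: int = 4
    n_cols: int = 8
    pitch_um: float = 400.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def row_col(self, channel: int) -> tuple[int, int]:
        self._check(channel)
        return divmod(int(channel), self.n_cols)

    def channel_of(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row, col)=({row}, {col}) outside grid")
        return row * self.n_cols + col

    def position_um(self, channel: int) -> tuple[float, float]:
        """(x, y) position in um; x runs along columns, y along rows."""
        row, col = self.row_col(channel)
        return (col * self.pitch_um, row * self.pitch_um)

    def positions_um(self) -> np.ndarray:
        """Array (n_channels, 2) of grid positions in um, channel order."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([cols, rows]).astype(float) * self.pitch_um

    def _check(self, channel: int) -> None:
        if not 0 <= int(channel) < self.n_channels:
            raise ValueError(f"channel {channel} outside 0..{self.n_channels - 1}")


def channel_distance(geom: ChannelGeometry, a: int, b: int) -> float:
    """Euclidean distance (um) between two MEA channels on the grid."""
    xa, ya = geom.position_um(a)
    xb, yb = geom.position_um(b)
    return float(np.hypot(xa - xb, ya - yb))


@dataclass
class MEARecording:
    """Multichannel MEA recording with stimulation event markers.

    ``samples`` has shape (n_channels, n_samples) in uV. ``stim_events`` are
    sample indices of pulse onsets, strictly increasing.
    """

    samples: np.ndarray
    fs_hz: float
    stim_events: np.ndarray
    geometry: ChannelGeometry
    cuff_distance_m: float
    stim: StimTrain

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(float)
        self.stim_events = np.asarray(self.stim_events, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("epoch end must follow start")


@dataclass
class GIRecording:
    """Serosal gastric myoelectric recording.

    ``data`` has shape (n_electrodes, n_contacts, n_samples) in uV; each
    planar electrode carries 4 contacts.  Epochs label baseline vs
    stimulation periods in seconds from recording start.
    """

    data: np.ndarray
    fs_hz: float
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (electrodes, contacts, samples)")
        if self.data.shape[1] != 4:
            raise ValueError("each planar electrode has exactly 4 contacts")
        labels = [e.label for e in self.epochs]
        if "baseline" in labels and "stimulation" in labels:
            b = next(e for e in self.epochs if e.label == "baseline")
            s = next(e for e in self.epochs if e.label == "stimulation")
            if b.start_s >= s.start_s:
                raise ValueError("baseline epoch must precede stimulation epoch")

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"no epoch labeled {label!r}")


def validate_recording(
    rec: MEARecording, window_end_s: float = ANALYSIS_WINDOW_END_S
) -> MEARecording:
    """Check MEA recording invariants; return ``rec`` unchanged if they hold.

    Raises ``ValueError`` for non-increasing stim events, events whose
    post-stimulus analysis window overruns the recording, nonpositive
    conduction distance, or a stimulation rate whose inter-pulse interval
    does not exceed the analysis window.
    """
    if rec.cuff_distance_m <= 0:
        raise ValueError("cuff_distance_m must be positive")
    if rec.fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    ev = rec.stim_events
    if ev.size == 0:
        raise ValueError("recording has no stimulation events")
    if np.any(np.diff(ev) <= 0):
        raise ValueError("events not increasing")
    if ev[0] < 0:
        raise ValueError("negative event index")
    window_samples = int(round(window_end_s * rec.fs_hz))
    if ev[-1] + window_samples > rec.n_samples:
        raise ValueError("window overrun: last event's analysis window exceeds recording")
    if rec.stim.interval_s <= window_end_s:
        raise ValueError(
            f"inter-pulse interval {rec.stim.interval_s} s must exceed "
            f"analysis window end {window_end_s} s"
        )
    return rec


# ---------------------------------------------------------------------------
# HDF5 container I/O
#
# Layout:
#   /mea/data            (n_channels, n_samples) float64, uV
#   /mea/stim_events     (n_events,) int64
#   /mea  attrs: fs_hz, cuff_distance_m, n_rows, n_cols, pitch_um,
#                amplitude_uA, pulse_width_ms, shape, n_pulses, rate_hz,
#                cuff_pair
#   /gi/data             (n_electrodes, 4, n_samples) float64, uV
#   /gi/epoch_labels, /gi/epoch_starts, /gi/epoch_ends
#   /gi  attrs: fs_hz
# ---------------------------------------------------------------------------

_MEA_ATTRS = ("fs_hz", "cuff_distance_m")


def _write_mea(group: h5py.Group, rec: MEARecording) -> None:
    group.create_dataset("data", data=rec.samples)
    group.create_dataset("stim_events", data=rec.stim_events)
    group.attrs["fs_hz"] = rec.fs_hz
    group.attrs["cuff_distance_m"] = rec.cuff_distance_m
    g = rec.geometry
    group.attrs["n_rows"] = g.n_rows
    group.attrs["n_cols"] = g.n_cols
    group.attrs["pitch_um"] = g.pitch_um
    t = rec.stim
    group.attrs["amplitude_uA"] = t.pulse.amplitude_uA
    group.attrs["pulse_width_ms"] = t.pulse.pulse_width_ms
    group.attrs["pulse_shape"] = t.pulse.shape
    group.attrs["n_pulses"] = t.n_pulses
    group.attrs["rate_hz"] = t.rate_hz
    group.attrs["cuff_pair"] = t.cuff_pair.value


def _read_mea(group: h5py.Group) -> MEARecording:
    if "fs_hz" not in group.attrs:
        raise KeyError("missing sampling rate (fs_hz)")
    for key in _MEA_ATTRS:
        if key not in group.attrs:
            raise KeyError(f"missing required metadata key {key!r}")
    geometry = ChannelGeometry(
        n_rows=int(group.attrs["n_rows"]),
        n_cols=int(group.attrs["n_cols"]),
        pitch_um=float(group.attrs["pitch_um"]),
    )
    stim = StimTrain(
        pulse=StimPulse(
            amplitude_uA=float(group.attrs["amplitude_uA"]),
            pulse_width_ms=float(group.attrs["pulse_width_ms"]),
            shape=str(group.attrs["pulse_shape"]),
        ),
        n_pulses=int(group.attrs["n_pulses"]),
        rate_hz=float(group.attrs["rate_hz"]),
        cuff_pair=CuffPair(str(group.attrs["cuff_pair"])),
    )
    return MEARecording(
        samples=group["data"][()],
        fs_hz=float(group.attrs["fs_hz"]),
        stim_events=group["stim_events"][()],
        geometry=geometry,
        cuff_distance_m=float(group.attrs["cuff_distance_m"]),
        stim=stim,
    )


def _write_gi(group: h5py.Group, rec: GIRecording) -> None:
    group.create_dataset("data", data=rec.data)
    group.attrs["fs_hz"] = rec.fs_hz
    group.create_dataset(
        "epoch_labels", data=np.array([e.label for e in rec.epochs], dtype="S32")
    )
    group.create_dataset("epoch_starts", data=[e.start_s for e in rec.epochs])
    group.create_dataset("epoch_ends", data=[e.end_s for e in rec.epochs])


def _read_gi(group: h5py.Group) -> GIRecording:
    if "fs_hz" not in group.attrs:
        raise KeyError("missing sampling rate (fs_hz)")
    labels = [s.decode() for s in group["epoch_labels"][()]]
    starts = group["epoch_starts"][()]
    ends = group["epoch_ends"][()]
    epochs = [Epoch(l, float(a), float(b)) for l, a, b in zip(labels, starts, ends)]
    return GIRecording(data=group["data"][()], fs_hz=float(group.attrs["fs_hz"]), epochs=epochs)


def write_container(path, *recordings: MEARecording | GIRecording) -> None:
    """Write one or more recordings to an HDF5 container.

    At most one MEA and one GI recording per container.
    """
    with h5py.File(path, "w") as f:
        for rec in recordings:
            if isinstance(rec, MEARecording):
                _write_mea(f.create_group("mea"), rec)
            elif isinstance(rec, GIRecording):
                _write_gi(f.create_group("gi"), rec)
            else:
                raise TypeError(f"cannot serialize {type(rec).__name__}")


def read_container(path):
    """Read a recording container.

    Returns the MEARecording or GIRecording it holds; if the container holds
    both, returns the tuple ``(mea, gi)``.
    """
    with h5py.File(path, "r") as f:
        mea = _read_mea(f["mea"]) if "mea" in f else None
        gi = _read_gi(f["gi"]) if "gi" in f else None
    if mea is not None and gi is not None:
        return mea, gi
    if mea is not None:
        return mea
    if gi is not None:
        return gi
    raise ValueError("malformed container: neither /mea nor /gi group present")
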