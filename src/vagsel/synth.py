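"""Ground-truth-labeled synthetic MEA and gastric myoelectric recordings.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without animal data:

* a population of vagal afferent fibers, mostly unmyelinated C fibers
  (conduction velocity < 3 m/s) with a minority of thinly myelinated
  A-delta fibers (3-30 m/s), each terminating on one MEA channel;
* per-fiber recruitment thresholds that follow the Weiss hyperbolic
  strength-duration law I(PW) = rheobase * (1 + chronaxie / PW) and differ
  between the two bipolar cuff contact pairs, so each pair preferentially
  (not exclusively) recruits its own fiber subset;
* stimulus-locked biphasic CAP deflections at latency distance / CV on the
  fiber's channel after every pulse, on top of Gaussian background noise,
  60 Hz line interference, occasional large (>8 mV) EMG-like artifacts,
  and packet-loss dropouts;
* gastric slow waves near 9.6 cycles per minute on four 4-contact planar
  electrodes, with 1/f-type background noise, whose amplitude is multiplied
  by a suppression factor during the stimulation epoch.

Recruitment is deterministic threshold crossing (supra-threshold pulses
reliably evoke responses), and every ``simulate_*`` call is bit-reproducible
given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ANALYSIS_WINDOW_END_S,
    DEFAULT_CUFF_DISTANCE_M,
    ChannelGeometry,
    CuffPair,
    Epoch,
    GIRecording,
    MEARecording,
    StimPulse,
    StimTrain,
)
from .responses import ResponseEvent, ResponseSet, classify_fiber, cv_bin_index

__all__ = [
    "StrengthDuration",
    "Fiber",
    "FiberPopulation",
    "NoiseModel",
    "GISimConfig",
    "make_population",
    "recruitment_threshold",
    "recruited_fibers",
    "ground_truth_responses",
    "simulate_sta_experiment",
    "simulate_gi_session",
    "cap_template",
]


@dataclass(frozen=True)
class StrengthDuration:
    """Weiss-law parameters: threshold(PW) = rheobase * (1 + chronaxie/PW)."""

    rheobase_uA: float
    chronaxie_ms: float

    def __post_init__(self) -> None:
        if self.rheobase_uA <= 0 or self.chronaxie_ms <= 0:
            raise ValueError("rheobase and chronaxie must be positive")

    def threshold_uA(self, pulse_width_ms: float) -> float:
        if pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        return self.rheobase_uA * (1.0 + self.chronaxie_ms / pulse_width_ms)


@dataclass(frozen=True)
class Fiber:
    """One simulated vagal afferent terminating on an MEA channel."""

    id: int
    cv_mps: float
    channel: int
    strength_duration: dict[CuffPair, StrengthDuration]
    cap_amplitude_uV: float
    latency_jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cv_mps <= 30.0:
            raise ValueError("cv_mps must be in (0, 30]")
        if self.cap_amplitude_uV <= 0:
            raise ValueError("cap_amplitude_uV must be positive")
        if self.latency_jitter_ms < 0:
            raise ValueError("latency_jitter_ms must be nonnegative")


@dataclass
class FiberPopulation:
    fibers: list[Fiber]
    clustering: float = 0.0

    def __post_init__(self) -> None:
        if not self.fibers:
            raise ValueError("population must contain at least one fiber")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering must be in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise for MEA simulations.

    ``gaussian_sd_uV`` is white background noise; ``line_*`` a common-mode
    mains component; artifacts are large transient excursions (EMG-like,
    amplitude in mV so they exercise the 8 mV blanking stage); dropouts are
    packet-loss gaps zeroed simultaneously on all channels.
    """

    gaussian_sd_uV: float = 8.0
    line_freq_hz: float = 60.0
    line_amplitude_uV: float = 0.0
    artifact_rate_per_s: float = 0.0
    artifact_amplitude_mV: float = 10.0
    dropout_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gaussian_sd_uV", "artifact_rate_per_s", "dropout_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Noise defaults emulating an in-vivo session (artifacts + dropouts on).
SESSION_NOISE = NoiseModel(
    gaussian_sd_uV=8.0,
    line_amplitude_uV=2.0,
    artifact_rate_per_s=0.02,
    artifact_amplitude_mV=10.0,
    dropout_rate_per_s=0.005,
)


@dataclass(frozen=True)
class GISimConfig:
    """Gastric slow-wave simulation parameters.

    The default 9.6 cpm fundamental matches the normogastric rhythm of the
    anesthetized ferret stomach; stimulation multiplies the slow-wave
    amplitude by ``suppression_factor`` starting ``suppression_onset_s``
    after stimulation onset.
    """

    slow_wave_cpm: float = 9.6
    harmonics: tuple[tuple[float, float], ...] = ((2.0, 0.2),)
    amplitude_uV: float = 150.0
    noise_exponent: float = 1.5
    noise_sd_uV: float = 60.0
    suppression_factor: float = 0.1
    suppression_onset_s: float = 0.0
    #: Cosine transition time of the suppression envelope.  Gastric
    #: amplitude does not collapse instantaneously; a short ramp also keeps
    #: the envelope step from injecting broadband splatter that no real
    #: preparation shows.
    suppression_ramp_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must be in [0, 1]")
        if self.suppression_onset_s < 0 or self.suppression_ramp_s < 0:
            raise ValueError("suppression onset and ramp must be >= 0")


def recruitment_threshold(fiber: Fiber, pair: CuffPair, pulse_width_ms: float) -> float:
    """Threshold amplitude (uA) to recruit ``fiber`` via ``pair`` at this width.

    Strictly decreasing in pulse width, approaching the rheobase as the
    pulse widens (Weiss strength-duration law).
    """
    return fiber.strength_duration[pair].threshold_uA(pulse_width_ms)


def _draw_cv(rng: np.random.Generator, n_c: int, n_adelta: int,
             c_range: tuple[float, float], adelta_range: tuple[float, float]) -> np.ndarray:
    cvs = np.concatenate([
        rng.uniform(*c_range, size=n_c),
        rng.uniform(*adelta_range, size=n_adelta),
    ])
    return cvs


def make_population(
    n_c: int = 22,
    n_adelta: int = 2,
    geometry: ChannelGeometry | None = None,
    clustering: float = 0.0,
    seed: int = 0,
    *,
    c_cv_range: tuple[float, float] = (0.32, 2.85),
    adelta_cv_range: tuple[float, float] = (3.0, 30.0),
    rheobase_range_uA: tuple[float, float] = (120.0, 800.0),
    chronaxie_range_ms: tuple[float, float] = (0.3, 0.8),
    separation_factor: tuple[float, float] = (2.5, 6.0),
    overlap_fraction: float = 0.15,
    overlap_factor: tuple[float, float] = (1.05, 1.6),
    cap_amplitude_range_uV: tuple[float, float] = (4.0, 8.0),
    latency_jitter_ms: float = 0.1,
) -> FiberPopulation:
    """Draw a labeled fiber population.

    C-fiber conduction velocities are drawn below 3 m/s and A-delta above;
    the C upper bound leaves a margin under the 3 m/s class boundary so the
    true class stays identifiable under the <=1 ms latency-measurement bias
    of threshold-crossing detection.  The lower C bound keeps every latency
    inside the 498 ms analysis window at the default 0.15 m cuff distance.

    Each fiber prefers one cuff pair: its rheobase for the preferred pair is
    drawn from ``rheobase_range_uA`` and its rheobase for the opposite pair
    is that value times a separation factor, except for an ``overlap_fraction``
    of fibers whose two rheobases nearly coincide (non-selective fibers).

    ``clustering`` controls somatotopy: with probability ``clustering`` a
    fiber's channel is drawn from its preferred pair's half of the grid
    (pair 1:2 -> left columns, pair 3:4 -> right columns), otherwise
    uniformly.  At 1.0 the two pairs' preferred channel sets are fully
    segregated blocks; at 0.0 assignment is uniform.

    When the population fits on the array (n <= n_channels) channels are
    assigned without replacement: each MEA site records one dominant CV
    component, matching the observation that individual channels almost
    always record exclusively one response type.
    """
    if n_c + n_adelta < 1:
        raise ValueError("population must contain at least one fiber")
    if geometry is None:
        geometry = ChannelGeometry()
    rng = np.random.default_rng(seed)
    n = n_c + n_adelta
    cvs = _draw_cv(rng, n_c, n_adelta, c_cv_range, adelta_cv_range)

    # Preferred pair: balanced split, shuffled.
    preferred = np.array(
        [CuffPair.PAIR_1_2] * ((n + 1) // 2) + [CuffPair.PAIR_3_4] * (n // 2),
        dtype=object,
    )
    rng.shuffle(preferred)

    # Channel blocks per preferred pair: left / right halves of the grid.
    cols = np.arange(geometry.n_channels) % geometry.n_cols
    left = np.flatnonzero(cols < geometry.n_cols // 2)
    right = np.flatnonzero(cols >= geometry.n_cols // 2)
    block = {CuffPair.PAIR_1_2: left, CuffPair.PAIR_3_4: right}

    unique = n <= geometry.n_channels
    used: set[int] = set()
    channels = np.empty(n, dtype=int)
    for i in range(n):
        in_block = rng.random() < clustering
        candidates = block[preferred[i]] if in_block else np.arange(geometry.n_channels)
        if unique:
            free = [c for c in candidates if c not in used]
            if not free:  # preferred block exhausted; fall back to any free site
                free = [c for c in range(geometry.n_channels) if c not in used]
            channels[i] = free[rng.integers(len(free))]
            used.add(int(channels[i]))
        else:
            channels[i] = candidates[rng.integers(len(candidates))]

    fibers = []
    for i in range(n):
        rb_pref = rng.uniform(*rheobase_range_uA)
        if rng.random() < overlap_fraction:
            factor = rng.uniform(*overlap_factor)
        else:
            factor = rng.uniform(*separation_factor)
        chron = rng.uniform(*chronaxie_range_ms)
        sd = {
            preferred[i]: StrengthDuration(rb_pref, chron),
            preferred[i].other: StrengthDuration(rb_pref * factor, chron),
        }
        fibers.append(
            Fiber(
                id=i,
                cv_mps=float(cvs[i]),
                channel=int(channels[i]),
                strength_duration=sd,
                cap_amplitude_uV=float(rng.uniform(*cap_amplitude_range_uV)),
                latency_jitter_ms=latency_jitter_ms,
            )
        )
    return FiberPopulation(fibers=fibers, clustering=clustering)


def recruited_fibers(pop: FiberPopulation, pulse: StimPulse, pair: CuffPair) -> list[Fiber]:
    """Fibers recruited by ``pulse`` through ``pair`` (threshold crossing)."""
    return [
        f for f in pop.fibers
        if pulse.amplitude_uA >= recruitment_threshold(f, pair, pulse.pulse_width_ms)
    ]


def ground_truth_responses(
    pop: FiberPopulation,
    pulse: StimPulse,
    pair: CuffPair,
    cuff_distance_m: float = DEFAULT_CUFF_DISTANCE_M,
    cv_bin_mps: float = 0.5,
) -> ResponseSet:
    """The exact response set implied by the recruitment thresholds.

    One event per recruited fiber's (channel, CV bin); two recruited fibers
    on the same channel whose CVs fall in the same 0.5 m/s bin collapse to
    one event (the detector can report at most one response per bin).
    """
    events: dict[tuple[int, int], ResponseEvent] = {}
    for f in sorted(recruited_fibers(pop, pulse, pair), key=lambda f: -f.cv_mps):
        latency_ms = cuff_distance_m / f.cv_mps * 1000.0
        key = (f.channel, cv_bin_index(f.cv_mps, cv_bin_mps))
        if key not in events:
            events[key] = ResponseEvent(
                channel=f.channel,
                latency_ms=latency_ms,
                cv_mps=f.cv_mps,
                cv_bin=key[1],
                fiber_class=classify_fiber(f.cv_mps),
            )
    return ResponseSet(pulse=pulse, pair=pair, events=sorted(events.values()))


# ---------------------------------------------------------------------------
# CAP waveform template
# ---------------------------------------------------------------------------

def cap_template(fs_hz: float, width_ms: float, peak_uV: float) -> np.ndarray:
    """Stereotyped biphasic CAP: one sine period under a Hann-squared taper.

    Compactly supported on [0, width]; the first sample is the arrival time.
    Normalized so the absolute peak equals ``peak_uV``.
    """
    n = max(int(round(width_ms * 1e-3 * fs_hz)), 4)
    u = np.arange(1, n + 1) / (n + 1)
    w = np.sin(2 * np.pi * u) * np.sin(np.pi * u) ** 2
    return peak_uV * w / np.max(np.abs(w))


def _cap_width_ms(latency_ms: float) -> float:
    """CAP duration grows with latency (temporal dispersion), clamped 1-3 ms."""
    return float(np.clip(0.02 * latency_ms, 1.0, 3.0))


def simulate_sta_experiment(
    pop: FiberPopulation,
    train: StimTrain,
    noise: NoiseModel | None,
    geometry: ChannelGeometry | None = None,
    distance_m: float = DEFAULT_CUFF_DISTANCE_M,
    duration_s: float | None = None,
    seed: int = 0,
    fs_hz: float = 30000.0,
    first_event_s: float = 0.5,
    dtype=np.float32,
) -> MEARecording:
    """Simulate one stimulus-triggered-averaging trial.

    Each fiber recruited by the train's pulse contributes a biphasic CAP at
    latency ``distance_m / cv`` (plus per-pulse Gaussian jitter) on its
    channel after every pulse.  ``noise=None`` yields a noise-free recording
    (zeros outside the CAPs).  Deterministic per seed.  Samples are stored
    in single precision by default — far beyond the quantization floor of a
    16-bit acquisition front end at uV scale.
    """
    if geometry is None:
        geometry = ChannelGeometry()
    rng = np.random.default_rng(seed)
    train_span = first_event_s + (train.n_pulses - 1) * train.interval_s
    min_duration = train_span + ANALYSIS_WINDOW_END_S + 0.01
    if duration_s is None:
        duration_s = min_duration + 1.0
    if duration_s < min_duration:
        raise ValueError("train does not fit requested duration")
    n = int(round(duration_s * fs_hz))
    events = (np.round((first_event_s + np.arange(train.n_pulses) * train.interval_s)
                       * fs_hz)).astype(np.int64)

    if noise is not None and noise.gaussian_sd_uV > 0:
        samples = rng.standard_normal((geometry.n_channels, n), dtype=dtype)
        samples *= dtype(noise.gaussian_sd_uV)
    else:
        samples = np.zeros((geometry.n_channels, n), dtype=dtype)

    if noise is not None and noise.line_amplitude_uV > 0:
        t = np.arange(n) / fs_hz
        phase = rng.uniform(0, 2 * np.pi)
        samples += (noise.line_amplitude_uV * np.sin(
            2 * np.pi * noise.line_freq_hz * t + phase
        )).astype(dtype)

    # Evoked CAPs.
    for f in recruited_fibers(pop, train.pulse, train.cuff_pair):
        latency_s = distance_m / f.cv_mps
        width_ms = _cap_width_ms(latency_s * 1000.0)
        tmpl = cap_template(fs_hz, width_ms, f.cap_amplitude_uV)
        if f.latency_jitter_ms > 0:
            jit = rng.normal(0.0, f.latency_jitter_ms * 1e-3, size=train.n_pulses)
        else:
            jit = np.zeros(train.n_pulses)
        onsets = events + np.round((latency_s + jit) * fs_hz).astype(np.int64)
        row = samples[f.channel]
        for o in onsets:
            if 0 <= o and o + tmpl.size <= n:
                row[o:o + tmpl.size] += tmpl

    if noise is not None and noise.artifact_rate_per_s > 0:
        amp_uv = noise.artifact_amplitude_mV * 1000.0
        for ch in range(geometry.n_channels):
            for _ in range(rng.poisson(noise.artifact_rate_per_s * duration_s)):
                w = int(rng.uniform(0.002, 0.008) * fs_hz)
                start = rng.integers(0, max(n - w, 1))
                sign = rng.choice([-1.0, 1.0])
                burst = sign * amp_uv * np.hanning(w)
                samples[ch, start:start + w] += burst

    if noise is not None and noise.dropout_rate_per_s > 0:
        for _ in range(rng.poisson(noise.dropout_rate_per_s * duration_s)):
            w = int(rng.uniform(0.005, 0.05) * fs_hz)
            start = rng.integers(0, max(n - w, 1))
            samples[:, start:start + w] = 0.0

    return MEARecording(
        samples=samples,
        fs_hz=fs_hz,
        stim_events=events,
        geometry=geometry,
        cuff_distance_m=distance_m,
        stim=train,
    )


# ---------------------------------------------------------------------------
# Gastric myoelectric session
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng: np.random.Generator, n: int, fs_hz: float,
                    exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with 1/f**exponent power spectrum, scaled to ``sd``."""
    white = rng.standard_normal(n)
    if exponent == 0 or sd == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs_hz)
    f_ref = max(f[1], 0.005)  # flatten below ~0.005 Hz to avoid DC blowup
    shape = np.maximum(f, f_ref) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_gi_session(
    cfg: GISimConfig,
    baseline_s: float = 300.0,
    stim_s: float = 120.0,
    seed: int = 0,
    fs_hz: float = 30000.0,
    n_electrodes: int = 4,
) -> GIRecording:
    """Simulate a baseline-then-stimulation gastric myoelectric session.

    Four contacts per planar electrode share the electrode's slow-wave
    signal and carry independent power-law noise, so planar averaging
    raises SNR.  During stimulation the slow-wave amplitude is multiplied by
    ``cfg.suppression_factor`` starting ``cfg.suppression_onset_s`` after
    stimulation onset.  Deterministic per seed.
    """
    if baseline_s <= 0 or stim_s <= 0:
        raise ValueError("baseline_s and stim_s must be positive")
    rng = np.random.default_rng(seed)
    total_s = baseline_s + stim_s
    n = int(round(total_s * fs_hz))
    t = np.arange(n) / fs_hz
    f0 = cfg.slow_wave_cpm / 60.0

    envelope = np.ones(n)
    onset = baseline_s + cfg.suppression_onset_s
    if cfg.suppression_ramp_s > 0:
        ramp = (t >= onset) & (t < onset + cfg.suppression_ramp_s)
        u = (t[ramp] - onset) / cfg.suppression_ramp_s
        envelope[ramp] = 1.0 + (cfg.suppression_factor - 1.0) * (1 - np.cos(np.pi * u)) / 2
    envelope[t >= onset + cfg.suppression_ramp_s] = cfg.suppression_factor

    data = np.empty((n_electrodes, 4, n))
    for e in range(n_electrodes):
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * f0 * t + phase)
        for mult, rel in cfg.harmonics:
            wave += rel * np.sin(2 * np.pi * mult * f0 * t + rng.uniform(0, 2 * np.pi))
        signal = cfg.amplitude_uV * envelope * wave
        for c in range(4):
            data[e, c] = signal + _powerlaw_noise(
                rng, n, fs_hz, cfg.noise_exponent, cfg.noise_sd_uV
            )

    epochs = [
        Epoch("baseline", 0.0, baseline_s),
        Epoch("stimulation", baseline_s, total_s),
    ]
    return GIRecording(data=data, fs_hz=fs_hz, epochs=epochs)
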