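"""Gastric myoelectric (electrogastrogram-like) spectral pipeline.

The gastric slow wave of the anesthetized ferret sits near 9-10 cycles per
minute (cpm); the normogastric band is 8-11 cpm.  Processing per planar
serosal electrode:

1. average the four contacts into one waveform (common gastric signal,
   independent contact noise);
2. low-pass Butterworth 2.5 Hz (150 cpm, 4th order), zero-phase; decimate
   to 10 Hz (the filter is the anti-alias stage); low-pass Butterworth
   0.3 Hz (18 cpm, 2nd order), zero-phase;
3. partition into 60 s segments with 54 s (90%) overlap; per segment a
   Hann-tapered, zero-padded FFT on a 0.1 cpm grid gives the power
   spectrum;
4. the dominant frequency is the median over segments of the per-segment
   spectral argmax in 0-15 cpm, flagged significant when the epoch-mean
   peak exceeds an exponential (periodogram) null for the band;
5. the normogastric fraction is the power in 8-11 cpm over the total power
   in 0.5-15 cpm (DC excluded), compared between baseline and stimulation
   epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, get_window, sosfiltfilt

from .core import GIRecording

__all__ = [
    "GIFilterConfig",
    "GISpectrogram",
    "GISummary",
    "EpochComparison",
    "planar_average",
    "preprocess",
    "segment_spectra",
    "dominant_frequency",
    "normogastric_fraction",
    "analyze_epoch",
    "compare_epochs",
]

NORMOGASTRIC_CPM = (8.0, 11.0)
TOTAL_BAND_CPM = (0.5, 15.0)
WATERFALL_BAND_CPM = (6.0, 15.0)


@dataclass(frozen=True)
class GIFilterConfig:
    lp1_hz: float = 2.5
    lp1_order: int = 4
    downsample_to_hz: float = 10.0
    lp2_hz: float = 0.3
    lp2_order: int = 2

    def __post_init__(self) -> None:
        if self.lp1_hz >= self.downsample_to_hz / 2:
            raise ValueError("lp1 cutoff must sit below the decimated Nyquist")
        if self.lp2_hz >= self.lp1_hz:
            raise ValueError("lp2 cutoff must sit below lp1 cutoff")


@dataclass
class GISpectrogram:
    """Per-segment power spectra on a 0.1 cpm grid."""

    segment_starts_s: np.ndarray   # (n_segments,)
    freqs_cpm: np.ndarray          # (n_freqs,)
    power: np.ndarray              # (n_segments, n_freqs), >= 0
    segment_len_s: float = 60.0
    overlap_s: float = 54.0

    @property
    def mean_power(self) -> np.ndarray:
        return self.power.mean(axis=0)


@dataclass
class GISummary:
    dominant_frequency_cpm: float
    significant: bool
    normogastric_fraction: float
    spectrogram: GISpectrogram


@dataclass
class EpochComparison:
    baseline: GISummary
    stimulation: GISummary
    fraction_ratio: float
    waterfall_times_s: np.ndarray
    waterfall_freqs_cpm: np.ndarray
    waterfall_power: np.ndarray    # (n_segments, n_freqs) over 6-15 cpm
    waterfall_epoch: list[str]


def planar_average(contacts: np.ndarray) -> np.ndarray:
    """Pointwise mean of the four contact waveforms of one planar electrode."""
    contacts = np.asarray(contacts, dtype=float)
    if contacts.ndim != 2:
        raise ValueError("contacts must be 2-D (n_contacts, n_samples)")
    lengths = {contacts.shape[1]}
    if len(lengths) != 1:
        raise ValueError("contact waveforms must share one length")
    return contacts.mean(axis=0)


def preprocess(
    waveform: np.ndarray, fs_hz: float, cfg: GIFilterConfig = GIFilterConfig()
) -> tuple[np.ndarray, float]:
    """Two-stage zero-phase low-pass filtering with decimation to 10 Hz.

    Returns (filtered waveform, new sampling rate).  Zero-phase
    (forward-backward) filtering doubles the effective order of each stage;
    the analysis is offline, so no group delay is acceptable.
    """
    waveform = np.asarray(waveform, dtype=float)
    if fs_hz < 2 * cfg.lp1_hz:
        raise ValueError("input rate must be at least twice the first cutoff")
    q = fs_hz / cfg.downsample_to_hz
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError("input rate must be an integer multiple of 10 Hz")
    min_len = int(3 * fs_hz / cfg.lp2_hz * 0.1)  # ~3x longest impulse span
    if waveform.size < max(min_len, int(3 * fs_hz)):
        raise ValueError("signal shorter than filter warm-up")
    sos1 = butter(cfg.lp1_order, cfg.lp1_hz, fs=fs_hz, output="sos")
    y = sosfiltfilt(sos1, waveform)
    y = y[:: int(round(q))]
    sos2 = butter(cfg.lp2_order, cfg.lp2_hz, fs=cfg.downsample_to_hz, output="sos")
    return sosfiltfilt(sos2, y), cfg.downsample_to_hz


def segment_spectra(
    signal: np.ndarray,
    fs_hz: float = 10.0,
    segment_len_s: float = 60.0,
    overlap_s: float = 54.0,
    bin_cpm: float = 0.1,
    window: str = "hann",
    t0_s: float = 0.0,
) -> GISpectrogram:
    """Overlapped, zero-padded FFT power spectra.

    The FFT length is derived from the requested bin spacing
    (nfft = fs / (bin_cpm / 60)), zero-padding each 60 s segment as needed;
    a Hann taper controls leakage.  Segments are mean-subtracted (the DC
    bin is excluded from every downstream band anyway).
    """
    signal = np.asarray(signal, dtype=float)
    seg = int(round(segment_len_s * fs_hz))
    hop = int(round((segment_len_s - overlap_s) * fs_hz))
    if signal.size < seg:
        raise ValueError("signal shorter than one segment")
    nfft = int(round(fs_hz / (bin_cpm / 60.0)))
    starts = np.arange(0, signal.size - seg + 1, hop)
    taper = get_window(window, seg) if window else np.ones(seg)
    power = np.empty((starts.size, nfft // 2 + 1))
    for i, s in enumerate(starts):
        x = signal[s: s + seg]
        x = (x - x.mean()) * taper
        power[i] = np.abs(np.fft.rfft(x, nfft)) ** 2
    freqs_cpm = np.fft.rfftfreq(nfft, 1.0 / fs_hz) * 60.0
    return GISpectrogram(
        segment_starts_s=t0_s + starts / fs_hz,
        freqs_cpm=freqs_cpm,
        power=power,
        segment_len_s=segment_len_s,
        overlap_s=overlap_s,
    )


def _band_mask(freqs_cpm: np.ndarray, band: tuple[float, float],
               exclude_dc: bool = True) -> np.ndarray:
    m = (freqs_cpm >= band[0]) & (freqs_cpm <= band[1])
    if exclude_dc:
        m &= freqs_cpm > 0
    return m


def dominant_frequency(
    spectrogram: GISpectrogram,
    band_cpm: tuple[float, float] = (0.0, 15.0),
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Median per-segment spectral peak in the band, with a significance flag.

    Significance: the epoch-mean spectrum's peak is tested against an
    exponential null whose scale is the band's median power (robust to the
    peak itself), Bonferroni-corrected by the number of *independent* bins
    (band width over the 1/segment-length natural resolution).  Ties in the
    per-segment argmax resolve to the lower-frequency bin.
    """
    if spectrogram.power.shape[0] < 3:
        raise ValueError("need at least 3 segments")
    m = _band_mask(spectrogram.freqs_cpm, band_cpm)
    freqs = spectrogram.freqs_cpm[m]
    peaks = freqs[np.argmax(spectrogram.power[:, m], axis=1)]
    dominant = float(np.median(peaks))

    mean_spec = spectrogram.mean_power[m]
    peak = mean_spec.max()
    scale = np.median(mean_spec) / np.log(2.0)  # exponential median -> mean
    natural_res_cpm = 60.0 / spectrogram.segment_len_s
    n_indep = max(int((band_cpm[1] - band_cpm[0]) / natural_res_cpm), 1)
    p_peak = n_indep * np.exp(-peak / scale) if scale > 0 else 0.0
    return dominant, bool(p_peak < alpha)


def normogastric_fraction(
    mean_power: np.ndarray,
    freqs_cpm: np.ndarray,
    normo_band: tuple[float, float] = NORMOGASTRIC_CPM,
    total_band: tuple[float, float] = TOTAL_BAND_CPM,
) -> float:
    """Fraction of spectral power in the normogastric band (8-11 cpm)."""
    total = mean_power[_band_mask(freqs_cpm, total_band)].sum()
    if total <= 0:
        raise ValueError("zero total power in the reference band")
    normo = mean_power[_band_mask(freqs_cpm, normo_band)].sum()
    return float(normo / total)


def analyze_epoch(
    signal_10hz: np.ndarray,
    fs_hz: float = 10.0,
    t0_s: float = 0.0,
    alpha: float = 0.05,
) -> GISummary:
    """Spectrogram + dominant frequency + normogastric fraction of one epoch."""
    spg = segment_spectra(signal_10hz, fs_hz, t0_s=t0_s)
    dom, sig = dominant_frequency(spg, alpha=alpha)
    frac = normogastric_fraction(spg.mean_power, spg.freqs_cpm)
    return GISummary(
        dominant_frequency_cpm=dom,
        significant=sig,
        normogastric_fraction=frac,
        spectrogram=spg,
    )


def compare_epochs(
    rec: GIRecording,
    electrode: int = 0,
    cfg: GIFilterConfig = GIFilterConfig(),
    alpha: float = 0.05,
) -> EpochComparison:
    """Baseline-vs-stimulation comparison for one planar electrode.

    The planar-averaged waveform is filtered once over the full session and
    then split at the epoch boundary, so filter transients do not land at
    the boundary.  Returns per-epoch summaries, the stimulation/baseline
    normogastric-fraction ratio, and a waterfall-ready per-segment 6-15 cpm
    power series across the whole session.
    """
    wave = planar_average(rec.data[electrode])
    filtered, fs10 = preprocess(wave, rec.fs_hz, cfg)

    base = rec.epoch("baseline")
    stim = rec.epoch("stimulation")

    def segment(e):
        i0 = int(round(e.start_s * fs10))
        i1 = int(round(e.end_s * fs10))
        return filtered[i0:i1]

    summary_base = analyze_epoch(segment(base), fs10, t0_s=base.start_s, alpha=alpha)
    summary_stim = analyze_epoch(segment(stim), fs10, t0_s=stim.start_s, alpha=alpha)
    ratio = (
        summary_stim.normogastric_fraction / summary_base.normogastric_fraction
        if summary_base.normogastric_fraction > 0 else np.inf
    )

    full = segment_spectra(filtered, fs10)
    wmask = _band_mask(full.freqs_cpm, WATERFALL_BAND_CPM)
    seg_centers = full.segment_starts_s + full.segment_len_s / 2
    epoch_label = ["stimulation" if t >= stim.start_s else "baseline"
                   for t in seg_centers]
    return EpochComparison(
        baseline=summary_base,
        stimulation=summary_stim,
        fraction_ratio=float(ratio),
        waterfall_times_s=full.segment_starts_s,
        waterfall_freqs_cpm=full.freqs_cpm[wmask],
        waterfall_power=full.power[:, wmask],
        waterfall_epoch=epoch_label,
    )
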