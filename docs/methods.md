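# Methods

This note documents the models, parameter choices and numerical
conventions behind `vagsel`, in the spirit of a methods appendix: what is
assumed, what is configurable, and what the synthetic validation does and
does not demonstrate about real recordings.

## Recording model

An MEA recording is a (32 × n) array of voltages in µV sampled at 30 kHz,
with stimulation-event sample indices, a 4×8 grid geometry (400 µm pitch,
row-major channel indexing) and a per-recording cuff-to-ganglion
conduction distance in meters. The distance scales every
latency-to-velocity conversion; it is measured per animal in a real
preparation and defaults to 0.15 m in fixtures. Voltages are µV
throughout; thresholds quoted in mV (artifact blanking) are converted at
the call boundary to avoid silent unit errors. Grid orientation relative
to anatomy is metadata only — all analyses depend on relative geometry.

Containers are HDF5: `/mea/{data, stim_events}` plus scalar attributes,
`/gi/{data, epoch_*}`. Round-trips are bit-exact (verified by property
tests over random recordings).

## Synthetic fiber populations

Each simulated afferent has a conduction velocity (C fibers uniform in
0.32–2.85 m/s, Aδ in 3–30 m/s), an MEA channel, per-cuff-pair
strength-duration parameters, a CAP amplitude (peak 4–8 µV, i.e.
peak-to-peak up to ~16 µV, matching the few-µV scale of nodose CAPs), and
a latency jitter (0.1 ms SD by default).

Choices that need justification:

* **Weiss (hyperbolic) strength-duration law**, threshold =
  rheobase · (1 + chronaxie/PW). Thresholds must decrease with pulse
  width; Weiss gives a closed-form chronaxie and is the standard
  hyperbolic form. Rheobases 120–800 µA and chronaxies 0.3–0.8 ms put
  thresholds at the hundreds-of-µA scale of abdominal VNS. The law is a
  per-fiber deterministic threshold: supra-threshold pulses recruit
  reliably, consistent with the near-perfect per-pulse reliability of
  evoked responses at peri-threshold amplitudes.
* **Pair selectivity** is encoded in the rheobases: each fiber prefers one
  cuff pair; its rheobase for the other pair is multiplied by a separation
  factor of 2.5–6, except for a 15 % non-selective subset whose two
  rheobases nearly coincide. No quantitative recruitment-overlap data
  exist to calibrate this; the defaults reproduce the qualitative pattern
  of few selective channels at low amplitude and ~20 responding channels
  at 3 mA, and are flagged as assumptions.
* **C-fiber dominance**: the default population is 22 C + 2 Aδ fibers,
  chosen so that a saturating stimulus yields a C-fiber response share
  near the ~92 % reported for abdominal vagal recruitment at maximum
  amplitude.
* **One fiber per channel** when the population fits on the array.
  Individual MEA channels almost always record exclusively one response
  type, and a single dominant CV component per site keeps the simulator's
  ground truth well defined when two same-channel CAPs would otherwise
  merge into one threshold crossing.
* **C-velocity bounds**: the lower bound (0.32 m/s) keeps every latency
  inside the 498 ms analysis window at the default distance; the upper
  bound (2.85 m/s) leaves a margin below the 3 m/s class boundary so the
  true fiber class remains identifiable under the detector's ≤1 ms
  latency-measurement bias (below).
* **CAP template**: one sine period under a Hann² taper, compactly
  supported, peak-normalized; duration 2 % of the latency, clamped to
  1–3 ms (temporal dispersion broadens late CAPs). The first nonzero
  sample is the arrival time.
* **Noise**: white Gaussian background (8 µV SD — CAPs are invisible in
  single trials and emerge only in the 120-trial average), optional
  common-mode 60 Hz line, EMG-like >8 mV artifacts (to exercise
  blanking), and all-channel packet-loss dropouts.

## Detector conventions

* Threshold = mean + gain·SD of the *raw* ensemble-averaged baseline
  trace, gain 2.5 by default (usable range 2.4–2.6 established by ROC
  calibration against labeled data; `calibrate_gain` reproduces that
  procedure on synthetic labels). With white noise this puts the
  threshold ≈2.5× the RMS level of the averaged trace and drives the
  pure-noise false-positive rate to effectively zero.
* The baseline ensemble uses as many windows as there are stimulation
  events (120 for the standard protocol): the baseline average must have
  the same averaging depth as the stimulus-triggered average for its SD
  to describe the same noise scale.
* Baseline windows are drawn uniformly over all positions that fit the
  recording, after blanking a pulse-width + 3 ms span around each
  stimulus. Windows as long as the analysis window cannot avoid every
  blanked span in a 2 Hz train — constraining them to do so would
  phase-lock the "baseline" to the stimulus and re-align the evoked CAPs
  it is meant to exclude.
* A response is an upward crossing: the first RMS sample strictly above
  threshold with its predecessor at or below. Latency is the crossing
  window's start time on the 0.1 ms RMS grid (no sub-sample
  interpolation). This convention underestimates the true arrival by up
  to the 1 ms RMS window, so CV estimates carry a small positive bias.
  For C fibers the bias is negligible (bins dwell tens of ms); for fast
  Aδ fibers a CV bin can dwell less than 1 ms, so bin-level agreement
  with ground truth is not achievable by construction and validation
  compares (channel, fiber-class) sets — the unit at which selectivity
  and fiber-type conclusions are drawn.
* The 3.0 m/s class boundary is assigned to Aδ (the quoted ranges 0–3 and
  3–30 m/s overlap at 3); 30 m/s closes the top bin. Both are
  configurable.
* Artifact blanking is applied per trial before averaging, because
  packet-loss and EMG artifacts are trial-local; blanking the average
  instead would smear single-trial artifacts across the whole window.
* The acquisition chain's 150–7500 Hz band-pass and 50–70 Hz notch are
  treated as properties of the input data; an optional preprocessing step
  reproduces them (4th-order, zero-phase) for raw synthetic input.

## Threshold search

The first probe is at the maximum amplitude (3000 µA): a negative there
is the no-response (NR) outcome in a single trial, matching the reporting
convention "no response up to 3 mA". The bracket (highest negative,
lowest positive) is bisected until its width reaches the 20 µA
resolution; the reported threshold is the lowest amplitude with a
detected response, giving at most ⌈log₂(3000/20)⌉ + 1 = 9 trials.
Midpoints are rounded to a 1 µA lattice (hardware-realistic; avoids
irrational amplitudes). Table aggregation averages all responding entries
per pulse width, each cuff pair counted separately.

## Selectivity

SI is computed exactly as defined, with SI ≔ 0 when no channel responds
(the formula is 0/0 there; no responses means no selectivity). The
balance term uses the pair counts *including* shared channels (literal
reading of the definitions). Optimization enumerates the full Cartesian
product of tested amplitudes per pair — reported optima include unequal
pairs, so matched-amplitude-only search would be wrong — excluding
combinations with more than 3 overlapping channels. Ties break to the
lowest summed amplitude, then the lowest pair-1:2 amplitude (lower charge
injection preferred).

## Somatotopy

Centroids are 2-D means of responding-channel grid positions, and the
inter-centroid separation is the planar Euclidean distance. A scalar
corner-distance construction is also implemented (`method="corner"`)
since the textual description of the procedure is ambiguous; the 2-D
reading is the default because a scalar mean of corner distances cannot
yield a Euclidean distance between centroids. Channels responding to both
pairs contribute no cross-pair distance (it would be trivially zero);
singleton same-pair sets contribute no same-pair distance. Trials where a
pair retains no selective channel at the SI optimum are excluded.

The Wilcoxon signed-rank test is exact by full enumeration of the 2ⁿ sign
assignments on the ranked absolute differences (ties get average ranks,
zeros are dropped); the two-sided p is the probability of a positive-rank
sum at least as far from n(n+1)/4 as observed. For n = 3, 4, 5
consistent-sign differences this gives the analytic minima 0.25, 0.125,
0.0625.

## Gastric myoelectric pipeline

Filtering is zero-phase (forward–backward `sosfiltfilt`), so each
Butterworth stage acts at twice its design order; the analysis is offline
and group delay would shift segment boundaries. Decimation to 10 Hz takes
every k-th sample after the 2.5 Hz stage (that filter is the anti-alias
stage, in that order). The FFT length is derived from the requested
0.1 cpm bin spacing (nfft = fs/Δf = 6000 for 60 s segments at 10 Hz, a
10× zero-padding), never hard-coded. Segments are mean-subtracted and
Hann-tapered: with a rectangular window ~10 % of a sinusoid's energy
leaks outside the main lobe, which would corrupt band-power fractions;
with Hann the in-band fraction of a pure normogastric sine exceeds 0.95.

The dominant frequency is the median over segments of the per-segment
argmax in 0–15 cpm (ties to the lower bin). Its significance test is not
specified in the source procedure; here the epoch-mean peak is tested
against an exponential periodogram null whose scale is the band's median
power (robust to the peak itself), Bonferroni-corrected by the number of
independent bins (band width / natural resolution), α = 0.05 — an
assumption, exposed in the API. The normogastric fraction uses total-band
denominator 0.5–15 cpm with DC excluded (the reference band is likewise
unspecified); epoch spectra are averaged before the fraction is taken.
Waterfall exports cover 6–15 cpm.

The slow-wave simulator uses a 9.6 cpm fundamental with a weak second
harmonic, per-electrode random phase, shared electrode signal across the
four contacts with independent 1/f^1.5 noise per contact (so planar
averaging halves the noise SD), and a stimulation-epoch amplitude
envelope: suppression factor 0.1 by default, with a 5 s cosine ramp
starting at the suppression onset — gastric amplitude does not collapse
instantaneously, and a hard step would inject broadband splatter no real
preparation shows.

## Problem sizes and scaled-down validation

Simulation sizes in the test suite and acceptance script are chosen so
each check still exercises the full pipeline:

* Noise-free detector/ground-truth sweeps use 3-pulse trains — averaging
  is a no-op without noise, and recruitment is amplitude-determined.
* The pure-noise false-positive check uses full 120-pulse, 30 kHz
  recordings (the threshold calibration depends on the real averaging
  depth), 32 recordings × 32 channels ≥ 1000 channel-trials.
* Selectivity-recovery trials use 40-pulse trains: the shallower average
  raises the detection threshold and drops the weakest CAPs, which
  perturbs channel counts but not the overlap structure the optimizer
  keys on.
* Gastric sessions are simulated at 500–1000 Hz in tests (the default
  remains 30 kHz): the first analog stage cuts at 2.5 Hz, so nothing
  above a few hertz survives into the analysis.
* The full synthetic study driver defaults to 60-pulse trains and 3
  animals.

## What passing tests do and do not show

The synthetic generator matches the statistical structure the analysis
assumes: stimulus-locked stereotyped CAPs, threshold recruitment with a
strength-duration law, stationary Gaussian background plus large
artifacts, and a narrowband gastric rhythm. Real recordings violate
several of these — CAP shape varies across fibers and with amplitude,
thresholds are probabilistic near threshold, noise is nonstationary, and
polysynaptic pathways can delay Aδ responses into the C-velocity range
(a recognized confound of latency-based classification). Passing the
suite therefore demonstrates correctness of the *analysis* under its own
model, and the detector's calibrated false-positive behavior under
Gaussian noise; it does not validate the biological fidelity of the
simulator's defaults.

## Known limitations

* No sub-sample latency interpolation; CV bias up to the RMS window.
* No spike sorting, impedance bookkeeping, or anatomical registration.
* The exact-Wilcoxon enumerator is limited to n ≤ 25 pairs.
* The binary search assumes a monotone response predicate; stochastic
  detection near threshold can make the measured threshold depend on the
  probe path (a non-monotone probe history is flagged, not resolved).
* Spatial statistics are limited to nearest-neighbor distances and
  centroids; no Ripley's-K-style cluster inference.
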