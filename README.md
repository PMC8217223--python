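# vagsel

Selectivity analysis of multi-contact vagus nerve stimulation (VNS).

Clinical VNS cuffs engage the whole nerve at once, which limits therapy and
drives off-target effects. A multi-contact cuff on the abdominal vagus can
steer current through different bipolar contact pairs and recruit different
sub-populations of fibers. `vagsel` implements the analysis used to
quantify that selectivity when the readout is a 32-channel microelectrode
array (MEA) in the nodose ganglion recording stimulation-evoked compound
action potentials (CAPs), plus the functional readout of gastric
myoelectric (slow-wave) activity from serosal electrodes. A bundled
ground-truth-labeled synthetic-data generator makes every stage testable
end to end without animal data.

## What it computes

**CAP detection.** For each amplitude/pulse-width combination, 120 pulses
at 2 Hz are delivered through one bipolar cuff pair. Each MEA channel is
blanked above 8 mV (EMG/packet-loss artifacts, linear interpolation),
stimulus-triggered averaged over the window from the 30 m/s latency to
498 ms post-stimulus, and smoothed by a sliding 1 ms RMS window (0.1 ms
step). The detection threshold is the mean + 2.5 SD of an ensemble average
of randomly placed baseline windows. The window is divided into 0.5 m/s
conduction-velocity (CV) bins, at most one response per bin, with
CV = cuff-to-ganglion distance / latency; CV < 3 m/s is a C-fiber
response, 3–30 m/s Aδ.

**Threshold search.** A binary search over 0–3000 µA with 20 µA resolution
finds, per cuff pair and pulse width, the minimum amplitude that evokes a
response on any MEA channel.

**Selectivity index.** With T₁:₂ and T₃:₄ the channel counts responding to
each pair, T_S the overlap and T_R the union:

    SI = 0.5 · (T_R − T_S)/32 + 0.5 · (1 − |T₁:₂ − T₃:₄| / T_R)

maximized over the tested amplitude product subject to T_S ≤ 3 (10 % of
the array).

**Somatotopy.** Nearest-neighbor distances between responding channels
(same-pair vs opposing-pair, with non-selective channels excluded from the
cross-pair lists), activation centroids per pair, and an exact
(full-enumeration) Wilcoxon signed-rank test on inter-centroid distances
between stimulation conditions.

**Gastric myoelectric analysis.** Planar-contact averaging, zero-phase
Butterworth low-pass stages (2.5 Hz/4th order, then 0.3 Hz/2nd order after
decimation to 10 Hz), 60 s spectral segments with 90 % overlap on a
0.1 cpm grid, dominant-frequency detection in 0–15 cpm, and the fraction
of power in the normogastric band (8–11 cpm) compared between baseline and
stimulation.

## Worked example

Simulate a fully segregated fiber population (the two cuff pairs prefer
disjoint halves of the MEA), stimulate both pairs at 1000 µA / 0.5 ms
inside the selective amplitude window, detect CAPs, and score selectivity:

```python
from vagsel import CuffPair, StimPulse, StimTrain
from vagsel.synth import NoiseModel, make_population, simulate_sta_experiment
from vagsel.cap_detection import detect
from vagsel.selectivity import count_responses, selectivity_index

pop = make_population(n_c=22, n_adelta=2, clustering=1.0, seed=0,
                      rheobase_range_uA=(150, 300),
                      separation_factor=(4, 6), overlap_fraction=0.0)
responses = {}
for pair in (CuffPair.PAIR_1_2, CuffPair.PAIR_3_4):
    train = StimTrain(pulse=StimPulse(1000.0, 0.5), n_pulses=120, cuff_pair=pair)
    rec = simulate_sta_experiment(pop, train, NoiseModel(), seed=1)
    responses[pair] = detect(rec)

counts = count_responses(responses[CuffPair.PAIR_1_2], responses[CuffPair.PAIR_3_4])
print(f"T_1:2={counts.t_12}  T_3:4={counts.t_34}  T_S={counts.t_s}  "
      f"SI={selectivity_index(counts):.3f}")
for e in sorted(responses[CuffPair.PAIR_1_2].events)[:3]:
    print(f"channel {e.channel:2d}  latency {e.latency_ms:6.1f} ms  "
          f"cv {e.cv_mps:4.2f} m/s  {e.fiber_class}")
```

Output:

```
T_1:2=12  T_3:4=12  T_S=0  SI=0.875
channel  0  latency   55.3 ms  cv 2.71 m/s  C
channel  1  latency  138.9 ms  cv 1.08 m/s  C
channel  9  latency  414.3 ms  cv 0.36 m/s  C
```

Each pair drives 12 channels with zero overlap: every detected response is
selective. SI is 0.875 rather than 1.0 because only 24 of the 32 channels
respond at this amplitude (the coverage term), while the balance term is
maximal. The per-event lines show the latency of each evoked CAP and the
conduction velocity it implies over the 0.15 m cuff-to-ganglion distance —
all C fibers here.

The same stages are exposed as a CLI (`vagsel simulate sta`, `vagsel
detect`, `vagsel simulate gi`, `vagsel gi`, `vagsel run-all`); `vagsel
run-all --seed 1 --out report/` chains the whole synthetic study and
writes threshold, selectivity, somatotopy and gastric-myoelectric tables
with a reproducibility manifest.

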