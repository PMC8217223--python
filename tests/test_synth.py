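"""Synthetic-data generator: strength-duration law, populations, simulations."""

import numpy as np
import pytest

from vagsel.core import ChannelGeometry, CuffPair, StimPulse, StimTrain
from vagsel.synth import (
    GISimConfig,
    NoiseModel,
    StrengthDuration,
    ground_truth_responses,
    make_population,
    recruitment_threshold,
    simulate_gi_session,
    simulate_sta_experiment,
)

from conftest import single_fiber_population

PAIRS = (CuffPair.PAIR_1_2, CuffPair.PAIR_3_4)


class TestStrengthDuration:
    def test_weiss_law_closed_form(self):
        """rheobase 200, chronaxie 0.5: threshold doubles at PW = chronaxie."""
        sd = StrengthDuration(rheobase_uA=200.0, chronaxie_ms=0.5)
        assert sd.threshold_uA(0.5) == pytest.approx(400.0)
        assert sd.threshold_uA(1.0) == pytest.approx(300.0)

    def test_threshold_decreases_with_pulse_width(self):
        pop = make_population(n_c=6, n_adelta=2, seed=11)
        for f in pop.fibers:
            for pair in PAIRS:
                t = [recruitment_threshold(f, pair, pw) for pw in (0.1, 0.5, 1.0)]
                assert t[0] > t[1] > t[2]
                # approaches rheobase from above
                assert recruitment_threshold(f, pair, 1e6) == pytest.approx(
                    f.strength_duration[pair].rheobase_uA, rel=1e-3
                )


class TestMakePopulation:
    def test_counts_and_cv_classes(self):
        pop = make_population(n_c=18, n_adelta=2, seed=7)
        assert len(pop.fibers) == 20
        assert sum(f.cv_mps < 3 for f in pop.fibers) == 18
        assert all(0 < f.cv_mps <= 30 for f in pop.fibers)

    def test_deterministic_given_seed(self):
        a = make_population(n_c=10, n_adelta=3, seed=42)
        b = make_population(n_c=10, n_adelta=3, seed=42)
        assert a.fibers == b.fibers

    def test_full_clustering_segregates_channel_blocks(self, geometry):
        pop = make_population(n_c=20, n_adelta=4, clustering=1.0, seed=5)
        cols_by_pair = {p: set() for p in PAIRS}
        for f in pop.fibers:
            pref = min(PAIRS, key=lambda p: f.strength_duration[p].rheobase_uA)
            cols_by_pair[pref].add(geometry.row_col(f.channel)[1])
        assert cols_by_pair[CuffPair.PAIR_1_2].isdisjoint(cols_by_pair[CuffPair.PAIR_3_4])

    def test_unique_channels_when_population_fits(self):
        pop = make_population(n_c=28, n_adelta=4, seed=9)
        channels = [f.channel for f in pop.fibers]
        assert len(set(channels)) == len(channels)

    def test_zero_fibers_rejected(self):
        with pytest.raises(ValueError):
            make_population(n_c=0, n_adelta=0)


class TestGroundTruth:
    def test_amplitude_zero_recruits_nothing(self):
        pop = make_population(seed=1)
        rs = ground_truth_responses(pop, StimPulse(0.0, 0.5), CuffPair.PAIR_1_2)
        assert len(rs) == 0

    def test_saturating_amplitude_recruits_every_channel(self):
        pop = make_population(seed=1, rheobase_range_uA=(100, 300),
                              separation_factor=(1.5, 2.0))
        rs = ground_truth_responses(pop, StimPulse(3000.0, 1.0), CuffPair.PAIR_1_2)
        assert rs.responding_channels == frozenset(f.channel for f in pop.fibers)

    def test_amplitude_between_two_thresholds_selects_cheaper_fiber(self):
        pop = make_population(n_c=2, n_adelta=0, seed=3)
        pair, pw = CuffPair.PAIR_1_2, 0.5
        t = sorted(
            (recruitment_threshold(f, pair, pw), f.channel) for f in pop.fibers
        )
        mid = (t[0][0] + t[1][0]) / 2
        rs = ground_truth_responses(pop, StimPulse(min(mid, 3000.0), pw), pair)
        assert rs.responding_channels == {t[0][1]}

    @pytest.mark.parametrize("pair", PAIRS)
    @pytest.mark.parametrize("pw", [0.1, 0.5, 1.0])
    def test_response_sets_monotone_in_amplitude(self, pair, pw):
        pop = make_population(seed=13)
        prev = frozenset()
        for amp in range(0, 3001, 250):
            cur = ground_truth_responses(pop, StimPulse(float(amp), pw), pair)
            cur_keys = cur.channel_bin_set()
            assert prev <= cur_keys
            prev = cur_keys


class TestSimulateSTA:
    def test_noise_free_deflection_at_conduction_latency(self):
        """cv = 1.5 m/s over 0.15 m puts the CAP exactly 100 ms post-pulse."""
        pop = single_fiber_population(cv_mps=1.5, channel=5)
        train = StimTrain(pulse=StimPulse(500.0, 0.5), n_pulses=120,
                          cuff_pair=CuffPair.PAIR_1_2)
        rec = simulate_sta_experiment(pop, train, None, seed=0)
        fs = rec.fs_hz
        onset = int(round(0.100 * fs))
        for ev in rec.stim_events[::20]:
            window = rec.samples[5, ev:ev + int(0.498 * fs)]
            nz = np.flatnonzero(window)
            assert nz[0] == onset
        # all other channels silent
        others = np.delete(np.arange(32), 5)
        assert not rec.samples[others].any()

    def test_subthreshold_train_gives_pure_noise(self):
        pop = single_fiber_population(cv_mps=1.5, rheobase_uA=2900.0)
        train = StimTrain(pulse=StimPulse(100.0, 0.5), n_pulses=5,
                          cuff_pair=CuffPair.PAIR_1_2)
        rec = simulate_sta_experiment(pop, train, None, duration_s=5.0, seed=0)
        assert not rec.samples.any()

    def test_artifacts_exceed_blanking_threshold(self):
        pop = single_fiber_population(cv_mps=1.5, rheobase_uA=2900.0)
        train = StimTrain(pulse=StimPulse(0.0, 0.5), n_pulses=5,
                          cuff_pair=CuffPair.PAIR_1_2)
        noise = NoiseModel(gaussian_sd_uV=2.0, artifact_rate_per_s=1.0,
                           artifact_amplitude_mV=10.0)
        rec = simulate_sta_experiment(pop, train, noise, duration_s=5.0, seed=4)
        assert np.abs(rec.samples).max() > 8000.0

    def test_bit_reproducible_per_seed(self):
        pop = make_population(n_c=4, n_adelta=1, seed=2)
        train = StimTrain(pulse=StimPulse(3000.0, 0.5), n_pulses=5,
                          cuff_pair=CuffPair.PAIR_3_4)
        noise = NoiseModel(gaussian_sd_uV=8.0, artifact_rate_per_s=0.1,
                           dropout_rate_per_s=0.1)
        a = simulate_sta_experiment(pop, train, noise, duration_s=5.0, seed=9)
        b = simulate_sta_experiment(pop, train, noise, duration_s=5.0, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.stim_events, b.stim_events)

    def test_train_must_fit_duration(self):
        pop = single_fiber_population(cv_mps=1.0)
        train = StimTrain(pulse=StimPulse(100.0, 0.5), n_pulses=120,
                          cuff_pair=CuffPair.PAIR_1_2)
        with pytest.raises(ValueError, match="duration"):
            simulate_sta_experiment(pop, train, None, duration_s=10.0)


class TestSimulateGI:
    def test_bit_reproducible_per_seed(self):
        cfg = GISimConfig()
        a = simulate_gi_session(cfg, baseline_s=60, stim_s=30, seed=5, fs_hz=250.0)
        b = simulate_gi_session(cfg, baseline_s=60, stim_s=30, seed=5, fs_hz=250.0)
        assert np.array_equal(a.data, b.data)

    def test_no_suppression_keeps_stim_epoch_amplitude(self):
        cfg = GISimConfig(suppression_factor=1.0, noise_sd_uV=0.0)
        rec = simulate_gi_session(cfg, baseline_s=120, stim_s=120, seed=1, fs_hz=250.0)
        x = rec.data[0, 0]
        half = x.size // 2
        assert np.std(x[:half]) == pytest.approx(np.std(x[half:]), rel=0.05)

    def test_full_suppression_silences_slow_wave(self):
        cfg = GISimConfig(suppression_factor=0.0, noise_sd_uV=0.0,
                          suppression_onset_s=0.0, suppression_ramp_s=0.0)
        rec = simulate_gi_session(cfg, baseline_s=60, stim_s=60, seed=1, fs_hz=250.0)
        x = rec.data[0, 0]
        assert np.abs(x[x.size // 2:]).max() == 0.0
        assert np.abs(x[: x.size // 2]).max() > 0.0

    def test_planar_averaging_raises_snr(self):
        """Contacts share the slow wave; averaging 4 contacts halves noise SD."""
        cfg = GISimConfig(amplitude_uV=0.0, noise_exponent=0.0, noise_sd_uV=40.0,
                          suppression_factor=1.0)
        rec = simulate_gi_session(cfg, baseline_s=120, stim_s=60, seed=8, fs_hz=250.0)
        single_sd = rec.data[0, 0].std()
        avg_sd = rec.data[0].mean(axis=0).std()
        assert avg_sd == pytest.approx(single_sd / 2.0, rel=0.1)
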