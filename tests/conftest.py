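"""Shared fixtures: geometries, reusable simulated recordings, helpers."""

from __future__ import annotations

import numpy as np
import pytest

from vagsel.core import ChannelGeometry, CuffPair, StimPulse, StimTrain
from vagsel.responses import ResponseEvent, ResponseSet, classify_fiber, cv_bin_index
from vagsel.synth import Fiber, FiberPopulation, NoiseModel, StrengthDuration, simulate_sta_experiment


@pytest.fixture(scope="session")
def geometry() -> ChannelGeometry:
    return ChannelGeometry()


@pytest.fixture(scope="session")
def pure_noise_recording():
    """One full-scale (120 pulses, 30 kHz) recording of pure Gaussian noise.

    Sub-threshold stimulation of a single expensive fiber recruits nothing,
    so the recording is background noise only.  Shared by the averaging /
    baseline statistics tests.
    """
    fiber = Fiber(
        id=0, cv_mps=1.0, channel=0,
        strength_duration={
            CuffPair.PAIR_1_2: StrengthDuration(2900.0, 0.5),
            CuffPair.PAIR_3_4: StrengthDuration(2900.0, 0.5),
        },
        cap_amplitude_uV=6.0,
    )
    pop = FiberPopulation(fibers=[fiber])
    train = StimTrain(pulse=StimPulse(0.0, 0.5), n_pulses=120,
                      cuff_pair=CuffPair.PAIR_1_2)
    return simulate_sta_experiment(
        pop, train, NoiseModel(gaussian_sd_uV=8.0), seed=2024
    )


def make_response_set(channels, pair=CuffPair.PAIR_1_2, amplitude_uA=500.0,
                      pulse_width_ms=0.5, cv_mps=1.0) -> ResponseSet:
    """Build a ResponseSet with one C-fiber event per listed channel."""
    events = [
        ResponseEvent(
            channel=int(ch),
            latency_ms=150.0,
            cv_mps=cv_mps,
            cv_bin=cv_bin_index(cv_mps),
            fiber_class=classify_fiber(cv_mps),
        )
        for ch in channels
    ]
    return ResponseSet(
        pulse=StimPulse(amplitude_uA, pulse_width_ms), pair=pair, events=events
    )


def single_fiber_population(
    cv_mps: float,
    channel: int = 5,
    rheobase_uA: float = 100.0,
    chronaxie_ms: float = 0.5,
    cap_amplitude_uV: float = 8.0,
    jitter_ms: float = 0.0,
) -> FiberPopulation:
    sd = StrengthDuration(rheobase_uA, chronaxie_ms)
    fiber = Fiber(
        id=0, cv_mps=cv_mps, channel=channel,
        strength_duration={CuffPair.PAIR_1_2: sd, CuffPair.PAIR_3_4: sd},
        cap_amplitude_uV=cap_amplitude_uV,
        latency_jitter_ms=jitter_ms,
    )
    return FiberPopulation(fibers=[fiber])
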