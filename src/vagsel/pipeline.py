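"""End-to-end synthetic-study orchestration with reproducibility plumbing.

``run_full_synthetic_study`` chains simulate -> detect -> threshold search ->
selectivity -> somatotopy for a cohort of synthetic animals, and separately
simulate-GI -> spectral pipeline, writing threshold, selectivity-index,
selective-channel-count, nearest-neighbor, centroid-shift and GI summary
tables as CSV plus a manifest recording the tool version, a configuration
hash, all derived seeds and per-stage runtimes.

One master seed fans out deterministically: every stochastic stage draws its
seed from ``numpy.random.SeedSequence(master, spawn_key=...)`` keyed by the
stage's identity (animal index, cuff pair, pulse width, amplitude), so any
stage can be re-run in isolation and two runs with the same configuration
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cap_detection import DetectorConfig, detect
from .core import ChannelGeometry, CuffPair, StimPulse, StimTrain
from .gi import compare_epochs
from .selectivity import (
    count_responses,
    optimize_selectivity,
    selective_channel_summary,
)
from .somatotopy import (
    centroid_shift_analysis,
    inter_centroid_distance,
    nearest_neighbor_analysis,
)
from .synth import (
    GISimConfig,
    NoiseModel,
    make_population,
    simulate_gi_session,
    simulate_sta_experiment,
)
from .threshold_search import SearchConfig, binary_search_threshold, records_to_table

__all__ = ["RunConfig", "run_full_synthetic_study", "version_and_manifest", "load_config"]

_PAIRS = (CuffPair.PAIR_1_2, CuffPair.PAIR_3_4)


@dataclass
class RunConfig:
    """Study configuration; every stochastic stage derives from ``seed``."""

    seed: int
    n_animals: int = 3
    pulse_widths_ms: tuple[float, ...] = (0.1, 0.5, 1.0)
    amplitude_ladder_uA: tuple[float, ...] = (100, 200, 400, 800, 1600, 3000)
    n_pulses: int = 60
    fs_hz: float = 30000.0
    n_c: int = 22
    n_adelta: int = 2
    clustering: float = 0.0
    gaussian_sd_uV: float = 8.0
    gain: float = 2.5
    resolution_uA: float = 20.0
    overlap_limit: int = 3
    gi_fs_hz: float = 1000.0
    gi_baseline_s: float = 300.0
    gi_stim_s: float = 120.0
    gi_suppression_factor: float = 0.1

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; a missing seed is an error."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "seed" not in raw:
        raise ValueError("unseeded stochastic stage: config must set 'seed'")
    for key in ("pulse_widths_ms", "amplitude_ladder_uA"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _stage_seed(master: int, *key: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def _pair_code(pair: CuffPair) -> int:
    return 0 if pair is CuffPair.PAIR_1_2 else 1


class _Study:
    """Internal driver holding shared state across stages."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.geometry = ChannelGeometry()
        self.noise = NoiseModel(gaussian_sd_uV=cfg.gaussian_sd_uV)
        self.detector = DetectorConfig(gain=cfg.gain)

    def responses(self, pop, animal: int, pair: CuffPair, pw: float, amp: float):
        train = StimTrain(
            pulse=StimPulse(amplitude_uA=amp, pulse_width_ms=pw),
            n_pulses=self.cfg.n_pulses,
            cuff_pair=pair,
        )
        seed = _stage_seed(
            self.cfg.seed, 1, animal, _pair_code(pair), int(round(pw * 10)), int(round(amp))
        )
        rec = simulate_sta_experiment(
            pop, train, self.noise, self.geometry, seed=seed, fs_hz=self.cfg.fs_hz
        )
        return detect(rec, self.detector)


def run_full_synthetic_study(cfg: RunConfig, outdir) -> dict:
    """Run the whole synthetic study and write its report CSVs + manifest.

    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = _Study(cfg)
    timings: dict[str, float] = {}
    t_start = time.perf_counter()

    threshold_records = []
    selectivity_rows = []
    count_rows = []
    nn_rows = []
    shift_by_pw: dict[float, list[tuple[float, float]]] = {pw: [] for pw in cfg.pulse_widths_ms}

    for animal in range(cfg.n_animals):
        name = f"sim-{animal:02d}"
        pop = make_population(
            n_c=cfg.n_c,
            n_adelta=cfg.n_adelta,
            geometry=study.geometry,
            clustering=cfg.clustering,
            seed=_stage_seed(cfg.seed, 0, animal),
        )

        # --- threshold search ---------------------------------------------
        t0 = time.perf_counter()
        for pair in _PAIRS:
            for pw in cfg.pulse_widths_ms:
                predicate = lambda amp, _pair=pair, _pw=pw: bool(
                    study.responses(pop, animal, _pair, _pw, amp)
                )
                rec = binary_search_threshold(
                    SearchConfig(
                        response_predicate=predicate,
                        resolution_uA=cfg.resolution_uA,
                    ),
                    animal=name, pair=pair, pulse_width_ms=pw,
                )
                threshold_records.append(rec)
        timings["threshold_search"] = timings.get("threshold_search", 0.0) + (
            time.perf_counter() - t0
        )

        # --- amplitude grid + selectivity + somatotopy --------------------
        t0 = time.perf_counter()
        for pw in cfg.pulse_widths_ms:
            grid = {
                pair: {
                    float(a): study.responses(pop, animal, pair, pw, float(a))
                    for a in cfg.amplitude_ladder_uA
                }
                for pair in _PAIRS
            }
            result = optimize_selectivity(
                grid, overlap_limit=cfg.overlap_limit, pulse_width_ms=pw
            )
            c = result.counts
            selectivity_rows.append({
                "animal": name, "pulse_width_ms": pw,
                "amp_12_uA": result.amplitude_pair_uA[0],
                "amp_34_uA": result.amplitude_pair_uA[1],
                "T12": c.t_12, "T34": c.t_34, "TS": c.t_s, "TR": c.t_r,
                "SI": round(result.si, 6), "feasible": result.feasible,
            })

            max_amp = float(max(cfg.amplitude_ladder_uA))
            r12_si = grid[CuffPair.PAIR_1_2][result.amplitude_pair_uA[0]]
            r34_si = grid[CuffPair.PAIR_3_4][result.amplitude_pair_uA[1]]
            r12_max = grid[CuffPair.PAIR_1_2][max_amp]
            r34_max = grid[CuffPair.PAIR_3_4][max_amp]
            for cond, r12, r34 in (("si_max", r12_si, r34_si),
                                   ("max_amplitude", r12_max, r34_max)):
                for allowance in (0, cfg.overlap_limit):
                    counts = selective_channel_summary(r12, r34, allowance)
                    count_rows.append({
                        "animal": name, "pulse_width_ms": pw, "condition": cond,
                        "overlap_allowance": allowance,
                        "n_12": counts[CuffPair.PAIR_1_2],
                        "n_34": counts[CuffPair.PAIR_3_4],
                        "all_12": len(r12.responding_channels),
                        "all_34": len(r34.responding_channels),
                    })

            # Somatotopy: only trials where both pairs kept selective responses.
            sel12 = r12_si.responding_channels - r34_si.responding_channels
            sel34 = r34_si.responding_channels - r12_si.responding_channels
            if result.feasible and sel12 and sel34:
                nn = nearest_neighbor_analysis(r12_si, r34_si, study.geometry)
                for d in nn.same_pair_distances:
                    nn_rows.append({"animal": name, "pulse_width_ms": pw,
                                    "category": "same", "distance_um": round(d, 3)})
                for d in nn.cross_pair_distances:
                    nn_rows.append({"animal": name, "pulse_width_ms": pw,
                                    "category": "cross", "distance_um": round(d, 3)})
                if r12_max and r34_max:
                    shift_by_pw[pw].append((
                        inter_centroid_distance(r12_si, r34_si, study.geometry),
                        inter_centroid_distance(r12_max, r34_max, study.geometry),
                    ))
        timings["selectivity_somatotopy"] = timings.get("selectivity_somatotopy", 0.0) + (
            time.perf_counter() - t0
        )

    # --- centroid-shift statistics ----------------------------------------
    shift_rows = []
    for pw, paired in shift_by_pw.items():
        if len(paired) >= 2:
            res = centroid_shift_analysis(paired)
            shift_rows.append({
                "pulse_width_ms": pw, "n_animals": res.n,
                "p_value": round(res.p_value, 6),
                "mean_difference_um": round(float(res.differences_um.mean()), 3),
            })
        else:
            shift_rows.append({"pulse_width_ms": pw, "n_animals": len(paired),
                               "p_value": np.nan, "mean_difference_um": np.nan})

    # --- gastric myoelectric arm ------------------------------------------
    t0 = time.perf_counter()
    gi_cfg = GISimConfig(suppression_factor=cfg.gi_suppression_factor)
    gi_rec = simulate_gi_session(
        gi_cfg,
        baseline_s=cfg.gi_baseline_s,
        stim_s=cfg.gi_stim_s,
        seed=_stage_seed(cfg.seed, 2),
        fs_hz=cfg.gi_fs_hz,
    )
    gi_rows = []
    waterfall_rows = []
    for electrode in range(gi_rec.data.shape[0]):
        comp = compare_epochs(gi_rec, electrode)
        gi_rows.append({
            "electrode": electrode,
            "baseline_dominant_cpm": round(comp.baseline.dominant_frequency_cpm, 2),
            "baseline_significant": comp.baseline.significant,
            "baseline_normogastric_fraction": round(comp.baseline.normogastric_fraction, 4),
            "stim_normogastric_fraction": round(comp.stimulation.normogastric_fraction, 4),
            "fraction_ratio": round(comp.fraction_ratio, 4),
        })
        if electrode == 0:
            band = comp.waterfall_power.sum(axis=1)
            for t, p, ep in zip(comp.waterfall_times_s, band, comp.waterfall_epoch):
                waterfall_rows.append({
                    "segment_start_s": round(float(t), 1),
                    "band_power_6_15_cpm": float(f"{p:.6g}"),
                    "epoch": ep,
                })
    timings["gi_myoelectric"] = time.perf_counter() - t0

    # --- serialize ----------------------------------------------------------
    tables = {
        "thresholds.csv": records_to_table(threshold_records),
        "selectivity.csv": pd.DataFrame(selectivity_rows),
        "selective_counts.csv": pd.DataFrame(count_rows),
        "nn_distances.csv": pd.DataFrame(nn_rows),
        "centroid_shift.csv": pd.DataFrame(shift_rows),
        "gi_summary.csv": pd.DataFrame(gi_rows),
        "gi_waterfall.csv": pd.DataFrame(waterfall_rows),
    }
    digests = {}
    for fname, df in tables.items():
        text = df.to_csv(index=False, float_format="%.6g")
        (outdir / fname).write_text(text)
        digests[fname] = hashlib.sha256(text.encode()).hexdigest()[:16]

    timings["total"] = time.perf_counter() - t_start
    manifest = version_and_manifest(cfg, digests, timings)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def version_and_manifest(cfg: RunConfig, digests: dict | None = None,
                         timings: dict | None = None) -> dict:
    """Manifest record: version, config hash, seeds, digests, runtimes."""
    return {
        "tool": "vagsel",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": yaml.safe_load(cfg.canonical_yaml()),
        "master_seed": cfg.seed,
        "output_digests": digests or {},
        "stage_runtime_s": {k: round(v, 3) for k, v in (timings or {}).items()},
    }
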