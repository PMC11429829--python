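"""End-to-end pipeline: simulate -> segment -> TRF -> statistics.

The "paper" preset pins every numeric analysis parameter in one place:
filter presets, the 64 Hz analysis rate, the -400..600 ms lag window, the
decade ridge grid with the fixed lambda of 1e2, 100 null permutations, 1000
cluster permutations at 0.025 per tail, and the two focal electrode sets.
A run writes per-stage outputs under the output directory plus a JSON
manifest (config snapshot, seeds, stage outputs) sufficient to reproduce the
run bit for bit; completed stages are skipped on re-run unless forced.

For simulated data the stimulus and response are aligned by construction,
so segmentation uses a zero onset delay; the 89 ms sound-to-marker delay
applies when segmenting real recordings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io, montage, stats, synth, trf
from .envelope import TactileEnvelope, concatenate_and_segment
from .preprocessing import EEGSegment, RawEEG, align_and_segment, zscore_segment
from .synth import ACTIVE_CONDITIONS, SimulationConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

#: every printed analysis parameter, pinned once
PAPER_PRESET: dict = {
    "analysis_fs_hz": 64.0,
    "stage1_band_hz": (1.0, 40.0),
    "stage1_orders": (500, 100),          # high-pass, low-pass
    "stage2_band_hz": (0.5, 6.0),
    "stage2_orders": (2000, 200),
    "intermediate_fs_hz": 250.0,
    "envelope_cutoff_hz": 6.0,
    "envelope_filter_order": 3,
    "onset_delay_ms": 89.0,
    "segment_minutes": 1.0,
    "segments_per_condition": 9,
    "lag_window_ms": (-400.0, 600.0),
    "ridge_grid": tuple(float(x) for x in trf.default_ridge_grid()),
    "ridge_lambda": 1e2,
    "null_permutations": 100,
    "cluster_permutations": 1000,
    "cluster_alpha_per_tail": 0.025,
    "cluster_forming_alpha": 0.05,
    "test_window_vs_null_ms": (0.0, 400.0),
    "test_window_between_conditions_ms": (50.0, 400.0),
    "min_data_minutes": (2, 9),
    "min_data_alpha": 0.05 / 8,
    "focal_right_stimulation": montage.LEFT_CENTRAL,
    "focal_left_stimulation": montage.RIGHT_CENTRAL,
    "n_subjects": 27,
    "n_conditions": 5,
    "trials_per_condition": 3,
    "trial_minutes": 3.0,
}

_CONFIG_KEYS = {
    "preset", "seed", "out_dir", "in_dir", "simulate", "n_subjects",
    "conditions", "trials_per_condition", "trial_minutes", "snr_db",
    "cluster_permutations", "null_permutations", "ridge_lambda",
    "run_min_data", "force",
}


@dataclass
class PipelineConfig:
    """Resolved run configuration. Unknown keys are rejected at load time."""

    out_dir: str
    preset: str = "paper"
    seed: int = 0
    simulate: bool = True
    in_dir: str | None = None
    n_subjects: int = 27
    conditions: tuple[str, ...] = synth.ALL_CONDITIONS
    trials_per_condition: int = 3
    trial_minutes: float = 3.0
    snr_db: float = -10.0
    cluster_permutations: int = 1000
    null_permutations: int = 100
    ridge_lambda: float = 1e2
    run_min_data: bool = False
    force: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        unknown = set(mapping) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "conditions" in mapping:
            mapping = dict(mapping, conditions=tuple(mapping["conditions"]))
        return cls(**mapping)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects,
            conditions=self.conditions,
            trials_per_condition=self.trials_per_condition,
            trial_minutes=self.trial_minutes,
            snr_db=self.snr_db,
            seed=self.seed,
        )


def simulated_subject_segments(
    config: SimulationConfig,
    subject: int,
    conditions: tuple[str, ...] | None = None,
) -> dict[str, list[tuple[TactileEnvelope, EEGSegment]]]:
    """Simulate one subject and cut aligned one-minute analysis segments.

    Envelope trials are concatenated and segmented; each simulated EEG trial
    is segmented with zero onset delay (simulation is aligned by
    construction) and z-scored per channel. Returns condition -> list of
    nine (envelope segment, EEG segment) pairs under the default design.
    """
    per_cond = synth.simulate_subject(config, subject, conditions=conditions)
    out: dict[str, list[tuple[TactileEnvelope, EEGSegment]]] = {}
    for cond, trials in per_cond.items():
        env_segments = concatenate_and_segment([env for env, _ in trials])
        eeg_segments: list[EEGSegment] = []
        for t_i, (_, eeg_arr) in enumerate(trials):
            raw = RawEEG(
                data=eeg_arr, fs=64.0, channel_labels=montage.channel_labels(),
                events=[("stim_onset", 0)],
            )
            segs = align_and_segment(
                raw, delay_ms=0.0, subject=subject, condition=cond,
                segment_index_offset=len(eeg_segments),
            )
            eeg_segments.extend(zscore_segment(s) for s in segs)
        if len(env_segments) != len(eeg_segments):
            raise RuntimeError("envelope/EEG segment count mismatch")
        out[cond] = list(zip(env_segments, eeg_segments))
    return out


def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").write_text("ok")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and return the run manifest.

    Stages: simulate (writes per-trial envelope/EEG arrays) -> trf (subject
    and null TRFs per active condition) -> stats (tactile-vs-null cluster
    tests, optional minimum-data analysis). Stage outputs land under
    ``out_dir/<stage>/``; a completed stage (marker file present) is skipped
    unless ``force``. The manifest is written to ``out_dir/manifest.json``.
    """
    if not config.simulate:
        if config.in_dir is None or not Path(config.in_dir).exists():
            raise FileNotFoundError(f"input directory not found: {config.in_dir}")
        raise NotImplementedError(
            "only the simulated path is wired end-to-end; preprocess real "
            "recordings with tactrf.preprocessing and fit with tactrf.trf"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "preset": config.preset,
        "preset_values": {k: v for k, v in PAPER_PRESET.items()},
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    sim_config = config.simulation_config()
    lags = trf.LagWindow()
    active = [c for c in config.conditions if c != synth.CONTROL_CONDITION]

    t0 = time.time()
    stage = out / "simulate"
    stage.mkdir(exist_ok=True)
    if config.force or not _stage_done(stage):
        for subject in range(config.n_subjects):
            per_cond = synth.simulate_subject(sim_config, subject)
            for cond, trials in per_cond.items():
                for t_i, (env, eeg_arr) in enumerate(trials):
                    base = stage / f"sub{subject:02d}_{cond}_trial{t_i}"
                    io.write_envelope(base.with_name(base.name + "_env"), env)
                    io.write_array(
                        base.with_name(base.name + "_eeg"), eeg_arr,
                        dict(fs=64.0, subject=subject, condition=cond, trial=t_i),
                    )
        _mark_done(stage)
    manifest["stages"]["simulate"] = {"dir": str(stage), "seconds": round(time.time() - t0, 2)}

    t0 = time.time()
    stage = out / "trf"
    stage.mkdir(exist_ok=True)
    if config.force or not _stage_done(stage):
        for subject in range(config.n_subjects):
            segments = simulated_subject_segments(sim_config, subject)
            for cond in active:
                stats_cache = trf.LaggedStats(
                    [env for env, _ in segments[cond]],
                    [seg.data for _, seg in segments[cond]],
                    lags,
                )
                pairs = [(i, i) for i in range(stats_cache.n)]
                w, b = stats_cache.loo_average(pairs, config.ridge_lambda)
                io.write_array(
                    stage / f"sub{subject:02d}_{cond}_trf", w,
                    dict(subject=subject, condition=cond, lam=config.ridge_lambda,
                         lag_axis_ms=list(lags.lag_axis_ms)),
                )
                null = stats.make_null_trf(
                    stats_cache, lam=config.ridge_lambda, lags=lags,
                    n_permutations=config.null_permutations,
                    seed=np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(subject, active.index(cond), 7)
                    ),
                    subject=subject, condition=cond,
                )
                io.write_array(
                    stage / f"sub{subject:02d}_{cond}_null", null.weights,
                    dict(subject=subject, condition=cond,
                         n_permutations=config.null_permutations),
                )
        _mark_done(stage)
    manifest["stages"]["trf"] = {"dir": str(stage), "seconds": round(time.time() - t0, 2)}

    t0 = time.time()
    stage = out / "stats"
    stage.mkdir(exist_ok=True)
    if config.force or not _stage_done(stage):
        adjacency = stats.build_adjacency()
        trf_dir = out / "trf"
        for cond in active:
            tactile = np.stack([
                io.read_array(trf_dir / f"sub{s:02d}_{cond}_trf")[0]
                for s in range(config.n_subjects)
            ])
            null = np.stack([
                io.read_array(trf_dir / f"sub{s:02d}_{cond}_null")[0]
                for s in range(config.n_subjects)
            ])
            result = stats.cluster_permutation_test(
                tactile, null, adjacency,
                lag_axis_ms=lags.lag_axis_ms,
                lag_window_ms=PAPER_PRESET["test_window_vs_null_ms"],
                n_permutations=config.cluster_permutations,
                seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(active.index(cond), 11)),
            )
            io.write_tsv(stage / f"{cond}_vs_null_clusters.tsv", stats.cluster_table(result))
            (stage / f"{cond}_vs_null_clusters.json").write_text(json.dumps(
                [dataclasses.asdict(c) for c in result.clusters], default=str,
            ))
        _mark_done(stage)
    manifest["stages"]["stats"] = {"dir": str(stage), "seconds": round(time.time() - t0, 2)}

    io.write_manifest(out / "manifest.json", manifest)
    return manifest
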