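"""End-to-end experiment orchestration and configuration.

Binds the stages into the full study design: synthesize a cohort of
constant-speed rotation trials, train the angle regressor leave-one-subject-
out (LOSO: each subject's trials are predicted by a network trained on all
other subjects), correct the predicted trajectories with the
constant-velocity Kalman smoother, and aggregate tracking errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .evaluate import (
    DEFAULT_REL_WINDOW,
    ErrorSummary,
    TrackingResult,
    align,
    summarize,
)
from .features import (
    DEFAULT_DFT_BAND,
    FeatureMatrix,
    WaveletSpec,
    WindowingSpec,
    extract_features,
)
from .kalman import KalmanConfig, smooth_angles
from .preprocess import FilterSpec, preprocess
from .regressor import NetworkSpec, TrainedModel, TrainingSpec, init_network, predict, train
from .signal_core import AngleTrajectory, EmgRecording
from .synthetic import TrialConfig, default_activation_profile, make_dataset

__all__ = [
    "PipelineConfig",
    "ExperimentResult",
    "load_config",
    "config_to_dict",
    "config_hash",
    "interpolate_reference",
    "trial_features",
    "estimate_trial",
    "run_loso",
    "run_experiment",
]

logger = logging.getLogger(__name__)

Dataset = Sequence[Sequence[tuple[EmgRecording, AngleTrajectory]]]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the cohort layout and master seed."""

    preprocess: FilterSpec = field(default_factory=FilterSpec)
    windowing: WindowingSpec = field(default_factory=WindowingSpec)
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    dft_band: tuple[float, float] = DEFAULT_DFT_BAND
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainingSpec = field(default_factory=TrainingSpec)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    rel_window: tuple[float, float] = DEFAULT_REL_WINDOW
    n_subjects: int = 8
    trials_per_subject: int = 5
    seed: int = 0


_SECTION_TYPES = {
    "preprocess": FilterSpec,
    "windowing": WindowingSpec,
    "wavelet": WaveletSpec,
    "network": NetworkSpec,
    "training": TrainingSpec,
    "kalman": KalmanConfig,
    "trial": TrialConfig,
}


def _build_section(cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or a nested dict.

    Unknown keys, at the top level or inside a section, are rejected by
    name.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], dict(value))
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration, for provenance manifests."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def interpolate_reference(traj: AngleTrajectory, times: np.ndarray) -> np.ndarray:
    """Reference angles (degrees) linearly interpolated at arbitrary times."""
    return np.interp(times, traj.timestamps, traj.angles)


def trial_features(rec: EmgRecording, cfg: PipelineConfig) -> FeatureMatrix:
    """Preprocess one recording and extract its windowed feature matrix."""
    conditioned = preprocess(rec, cfg.preprocess)
    return extract_features(conditioned, cfg.windowing, cfg.wavelet, cfg.dft_band)


def estimate_trial(
    model: TrainedModel, rec: EmgRecording, cfg: PipelineConfig
) -> tuple[AngleTrajectory, AngleTrajectory]:
    """Predict one trial's angle trajectory: (raw network, Kalman-corrected)."""
    fm = trial_features(rec, cfg)
    raw = predict(model, fm)
    corrected = smooth_angles(raw, cfg.kalman)
    return raw, corrected


@dataclass(frozen=True)
class ExperimentResult:
    """LOSO experiment output: summaries for raw and corrected estimates."""

    summary_raw: ErrorSummary
    summary_kalman: ErrorSummary
    results_raw: list[list[TrackingResult]]
    results_kalman: list[list[TrackingResult]]
    fold_models: list[TrainedModel]


def run_loso(
    dataset: Dataset, cfg: PipelineConfig, seed: int | None = None
) -> ExperimentResult:
    """Leave-one-subject-out evaluation of the full pipeline.

    For each held-out subject a fresh network is trained on every other
    subject's windows, its predictions on the held-out trials are Kalman-
    corrected, and both raw and corrected estimates are aligned against the
    reference trajectories.
    """
    if len(dataset) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    seed = cfg.seed if seed is None else seed
    features = [
        [trial_features(rec, cfg) for rec, _ in subject] for subject in dataset
    ]
    targets = [
        [
            interpolate_reference(traj, fm.window_centers)
            for (_, traj), fm in zip(subject, fms)
        ]
        for subject, fms in zip(dataset, features)
    ]

    results_raw: list[list[TrackingResult]] = []
    results_kal: list[list[TrackingResult]] = []
    fold_models: list[TrainedModel] = []
    for held_out in range(len(dataset)):
        X = np.vstack(
            [
                fm.values
                for s, fms in enumerate(features)
                if s != held_out
                for fm in fms
            ]
        )
        y = np.concatenate(
            [t for s, ts in enumerate(targets) if s != held_out for t in ts]
        )
        fold_seed = int(
            np.random.SeedSequence([seed, 5, held_out]).generate_state(1)[0]
            % (2**31)
        )
        tspec = dataclasses.replace(cfg.training, seed=fold_seed)
        model = train(init_network(cfg.network, fold_seed), X, y, tspec)
        fold_models.append(model)
        logger.info(
            "fold %d: trained on %d windows, final MSE %.4g (%d epochs)",
            held_out,
            X.shape[0],
            model.history[-1],
            len(model.history),
        )
        raw_group, kal_group = [], []
        for (rec, ref), fm in zip(dataset[held_out], features[held_out]):
            raw = predict(model, fm)
            corrected = smooth_angles(raw, cfg.kalman)
            raw_group.append(align(ref, raw))
            kal_group.append(align(ref, corrected))
        results_raw.append(raw_group)
        results_kal.append(kal_group)

    return ExperimentResult(
        summary_raw=summarize(results_raw, cfg.rel_window),
        summary_kalman=summarize(results_kal, cfg.rel_window),
        results_raw=results_raw,
        results_kalman=results_kal,
        fold_models=fold_models,
    )


def run_experiment(cfg: PipelineConfig | None = None) -> ExperimentResult:
    """Synthesize the cohort and run the LOSO evaluation."""
    cfg = cfg or PipelineConfig()
    trial_cfg = dataclasses.replace(cfg.trial, seed=cfg.seed)
    dataset = make_dataset(
        cfg.n_subjects, cfg.trials_per_subject, trial_cfg, default_activation_profile()
    )
    return run_loso(dataset, cfg, cfg.seed)
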