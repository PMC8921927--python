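"""Synthetic trial generator: constant-speed 180-degree forearm rotations
with five-channel sEMG whose statistics match what the pipeline assumes.

The trial template is a 5.0 s supination-to-pronation rotation (palm up to
palm down) at constant speed, with the reference angle sampled at 100 Hz by
a sensor of 0.1 deg accuracy and sEMG sampled at 1,000 Hz.

Each EMG channel is modeled as

    bias + mains_amplitude * sin(2*pi*50*t) + gain * a(t) * n_act(t) + floor(t)

where ``n_act`` and ``floor`` are independent unit-variance Gaussian noises
bandpass-shaped to 20-200 Hz (the standard amplitude-modulated
interference-pattern model of surface EMG), ``a(t)`` is the muscle's
activation template evaluated at the normalized trial phase, and the
modulated component's in-band power over the fixed noise-floor power sets
the configured SNR at unit subject gain.  Pronator-group activations ramp up
with pronation phase and supinator-group activations ramp down, following
the muscles' roles in forearm rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .preprocess import FilterSpec, design_bandpass
from .signal_core import AngleConvention, AngleTrajectory, EmgRecording

__all__ = [
    "TrialConfig",
    "ActivationProfile",
    "default_activation_profile",
    "make_trajectory",
    "synthesize_emg",
    "make_dataset",
]

#: Standard deviation (volts) of the fixed in-band noise floor every channel
#: carries regardless of muscle activity.
NOISE_FLOOR_V = 0.01


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of one synthetic rotation trial."""

    duration_s: float = 5.0
    rotation_deg: float = 180.0
    emg_rate_hz: float = 1000.0
    angle_rate_hz: float = 100.0
    snr_db: float = 10.0
    mains_amplitude_v: float = 0.05
    bias_v: float = 2.5
    angle_sensor_sd_deg: float = 0.1
    seed: int = 0
    subject_gain: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not (self.emg_rate_hz > 0 and self.angle_rate_hz > 0):
            raise ValueError("sample rates must be positive")
        if not 0 <= self.rotation_deg <= 180:
            raise ValueError("rotation_deg must lie in [0, 180]")


class ActivationProfile:
    """Per-muscle activation templates over normalized trial phase.

    Maps each muscle label to a function of phase p in [0, 1] returning an
    activation in [0, 1].
    """

    def __init__(self, templates: Mapping[str, Callable[[np.ndarray], np.ndarray]]):
        self.templates = dict(templates)

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.templates)

    def __call__(self, muscle: str, phase: np.ndarray) -> np.ndarray:
        phase = np.clip(np.asarray(phase, dtype=float), 0.0, 1.0)
        act = np.asarray(self.templates[muscle](phase), dtype=float)
        if np.any(act < 0) or np.any(act > 1):
            raise ValueError(f"activation of {muscle!r} left [0, 1]")
        return act


def default_activation_profile() -> ActivationProfile:
    """Anatomy-informed templates for the five default electrode sites.

    Pronator teres and flexor carpi radialis recruit with pronation;
    supinator and brachioradialis are most active near supination; extensor
    carpi radialis longus acts as a low-level stabilizer throughout.
    """
    return ActivationProfile(
        {
            "pronator_teres": lambda p: 0.1 + 0.8 * p,
            "flexor_carpi_radialis": lambda p: 0.1 + 0.8 * p,
            "extensor_carpi_radialis_longus": lambda p: np.full_like(p, 0.2),
            "supinator": lambda p: 0.9 - 0.8 * p,
            "brachioradialis": lambda p: 0.9 - 0.8 * p,
        }
    )


def make_trajectory(cfg: TrialConfig) -> AngleTrajectory:
    """Constant-speed reference rotation with additive sensor noise.

    The noiseless ramp starts at exactly 0 deg and ends at exactly
    ``rotation_deg`` (palm-up-zero convention); Gaussian noise of sd
    ``angle_sensor_sd_deg`` emulates the attitude sensor's 0.1 deg accuracy.
    """
    n = int(round(cfg.angle_rate_hz * cfg.duration_s))
    ts = np.linspace(0.0, cfg.duration_s, n)
    ramp = cfg.rotation_deg * ts / cfg.duration_s
    if cfg.angle_sensor_sd_deg > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        ramp = ramp + rng.normal(0.0, cfg.angle_sensor_sd_deg, size=n)
    return AngleTrajectory(ts, ramp, AngleConvention.PALM_UP_ZERO)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, coeffs: np.ndarray
) -> np.ndarray:
    """Unit-variance Gaussian noise shaped to the 20-200 Hz band."""
    from scipy.signal import filtfilt

    white = rng.standard_normal(n + 2 * len(coeffs))
    shaped = filtfilt(coeffs, [1.0], white)[len(coeffs) : len(coeffs) + n]
    return shaped / shaped.std()


def synthesize_emg(
    traj: AngleTrajectory,
    profile: ActivationProfile | None = None,
    cfg: TrialConfig | None = None,
) -> EmgRecording:
    """Five-channel sEMG consistent with a reference trajectory.

    Deterministic given ``cfg.seed``.  Per channel the modulated activity
    amplitude is scaled so that, at unit subject gain, the trial-average
    in-band power of the activation component over the fixed noise floor
    equals ``cfg.snr_db``.
    """
    cfg = cfg or TrialConfig()
    profile = profile or default_activation_profile()
    muscles = profile.muscles
    gains = (
        np.ones(len(muscles))
        if cfg.subject_gain is None
        else np.asarray(cfg.subject_gain, dtype=float)
    )
    if gains.size != len(muscles):
        raise ValueError("subject_gain length must match the muscle count")
    expected_traj_len = int(round(cfg.angle_rate_hz * cfg.duration_s))
    if len(traj) != expected_traj_len:
        raise ValueError(
            f"trajectory has {len(traj)} samples but cfg implies "
            f"{expected_traj_len} at {cfg.angle_rate_hz} Hz"
        )

    n = int(round(cfg.emg_rate_hz * cfg.duration_s))
    t = np.arange(n) / cfg.emg_rate_hz
    phase = np.clip(t / cfg.duration_s, 0.0, 1.0)
    coeffs = design_bandpass(FilterSpec(), cfg.emg_rate_hz)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    mains = cfg.mains_amplitude_v * np.sin(2 * np.pi * 50.0 * t)
    amp_ratio = 10.0 ** (cfg.snr_db / 20.0)

    samples = np.empty((n, len(muscles)))
    for c, muscle in enumerate(muscles):
        act = profile(muscle, phase)
        carrier = _bandlimited_noise(rng, n, coeffs)
        floor = NOISE_FLOOR_V * _bandlimited_noise(rng, n, coeffs)
        act_rms = np.sqrt(np.mean(act**2))
        scale = NOISE_FLOOR_V * amp_ratio / act_rms if act_rms > 0 else 0.0
        samples[:, c] = cfg.bias_v + mains + gains[c] * scale * act * carrier + floor
    return EmgRecording(cfg.emg_rate_hz, muscles, samples)


def make_dataset(
    n_subjects: int,
    trials_per_subject: int,
    cfg: TrialConfig | None = None,
    profile: ActivationProfile | None = None,
) -> list[list[tuple[EmgRecording, AngleTrajectory]]]:
    """Generate a cohort: per-subject muscle gains, per-trial fresh noise.

    Inter-individual variation is modeled by log-normal per-muscle gain
    vectors (sd 0.2 on the log scale).  Returns one list of
    ``(recording, trajectory)`` pairs per subject; fully reproducible from
    ``cfg.seed`` as the master seed.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValueError("counts must be >= 1")
    cfg = cfg or TrialConfig()
    profile = profile or default_activation_profile()
    n_muscles = len(profile.muscles)
    dataset: list[list[tuple[EmgRecording, AngleTrajectory]]] = []
    for s in range(n_subjects):
        gain_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3, s]))
        gains = tuple(np.exp(gain_rng.normal(0.0, 0.2, size=n_muscles)))
        trials = []
        for tr in range(trials_per_subject):
            # fold subject/trial indices into the seed so subsets are stable
            trial_seed = int(
                np.random.SeedSequence([cfg.seed, 4, s, tr]).generate_state(1)[0]
                % (2**31)
            )
            trial_cfg = TrialConfig(
                duration_s=cfg.duration_s,
                rotation_deg=cfg.rotation_deg,
                emg_rate_hz=cfg.emg_rate_hz,
                angle_rate_hz=cfg.angle_rate_hz,
                snr_db=cfg.snr_db,
                mains_amplitude_v=cfg.mains_amplitude_v,
                bias_v=cfg.bias_v,
                angle_sensor_sd_deg=cfg.angle_sensor_sd_deg,
                seed=trial_seed,
                subject_gain=gains,
            )
            traj = make_trajectory(trial_cfg)
            rec = synthesize_emg(traj, profile, trial_cfg)
            trials.append((rec, traj))
        dataset.append(trials)
    return dataset
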