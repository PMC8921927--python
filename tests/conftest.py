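import dataclasses

import numpy as np
import pytest

import emgangle as eg


@pytest.fixture(scope="session")
def default_cfg() -> eg.PipelineConfig:
    return eg.PipelineConfig()


@pytest.fixture(scope="session")
def clean_trial():
    """One 20 dB synthetic trial: (trajectory, recording, trial config)."""
    cfg = eg.TrialConfig(snr_db=20.0, seed=7)
    traj = eg.make_trajectory(cfg)
    rec = eg.synthesize_emg(traj, cfg=cfg)
    return traj, rec, cfg


@pytest.fixture(scope="session")
def trial_features_target(clean_trial, default_cfg):
    """Feature matrix and interpolated reference angles for one trial."""
    traj, rec, _ = clean_trial
    fm = eg.trial_features(rec, default_cfg)
    target = np.interp(fm.window_centers, traj.timestamps, traj.angles)
    return fm, target


@pytest.fixture(scope="session")
def within_subject_model(default_cfg):
    """Network trained on five unit-gain trials of one synthetic subject."""
    cfg = default_cfg
    X_parts, y_parts = [], []
    for t in range(5):
        tc = dataclasses.replace(cfg.trial, snr_db=20.0, seed=100 + t)
        traj = eg.make_trajectory(tc)
        rec = eg.synthesize_emg(traj, cfg=tc)
        fm = eg.trial_features(rec, cfg)
        X_parts.append(fm.values)
        y_parts.append(np.interp(fm.window_centers, traj.timestamps, traj.angles))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    return eg.train(eg.init_network(cfg.network, seed=0), X, y, cfg.training)
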