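"""Shared fixtures: synthetic cohorts and event-matching helpers.

The 10-subject, 2-hour cohort is expensive (full-night audio + IMU per
subject) and is generated once per session; end-to-end tests share it.
"""

import numpy as np
import pytest

from somnostage.pipeline import extract_night_features
from somnostage.synthetic import SimConfig, StagePhysiology, simulate_cohort
from somnostage.validation import loocv

COHORT_SEED = 1


def match_events(truth: np.ndarray, detected: np.ndarray, tol_s: float):
    """Greedy nearest matching of detected events to truth events.

    Returns (recall, dict truth_index -> detected time) for truth events
    with a detection within ``tol_s``.
    """
    matched = {}
    for i, t in enumerate(np.asarray(truth)):
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            matched[i] = float(detected[j])
    recall = len(matched) / max(1, len(truth))
    return recall, matched


@pytest.fixture(scope="session")
def single_stage_night():
    """5-minute single-stage recording: 15 breaths/min (BB CV 0.15),
    60 bpm (SDNN 50 ms), SNR 10 dB -- with ground-truth events."""
    from somnostage.io_core import Hypnogram
    from somnostage.synthetic import simulate_audio

    cfg = SimConfig(night_minutes=5, snr_db=10.0)
    cfg.physiology = dict(cfg.physiology)
    cfg.physiology["N2"] = StagePhysiology(
        breath_rate=15.0, bb_cv=0.15, heart_rate=60.0, sdnn_ms=50.0,
        lf_hf=2.0, move_rate_per_h=0.0, pos_change_p=0.0,
    )
    hyp = Hypnogram(["N2"] * 10, "raw")
    rng = np.random.default_rng(7)
    audio, breath_onsets, beat_times = simulate_audio(hyp, cfg, rng)
    return audio, breath_onsets, beat_times


@pytest.fixture(scope="session")
def synthetic_cohort():
    """10 subjects x 2 h at default effect sizes, features extracted."""
    cfg = SimConfig(n_subjects=10, night_minutes=120.0)
    nights = simulate_cohort(cfg, seed=COHORT_SEED)
    cohort = []
    for night in nights:
        m = extract_night_features(night.audio, night.imu, subject_id=night.subject_id)
        cohort.append((m, night.truth_hypnogram))
    return cohort


@pytest.fixture(scope="session")
def cohort_loocv(synthetic_cohort):
    """LOOCV results for the shared cohort in all three stage systems."""
    return {s: loocv(synthetic_cohort, s) for s in ("s2", "s3", "s4")}
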