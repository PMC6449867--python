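"""Synthetic stage-annotated nights: hypnogram + tracheal audio + IMU.

The generator emulates the statistical structure the extraction chain
assumes: a first-order Markov hypnogram over 30-s epochs; breathing as
band-limited (200-2000 Hz) noise bursts whose onsets follow the stage's
breath-to-breath mean and variability; heart beats as paired 20 Hz
Gabor pulses (S1 and a weaker S2, 0.3 s apart) whose NN intervals carry
stage-dependent mean heart rate, SDNN and LF/HF-shaped modulation;
white background noise at a configured SNR; and an IMU stream with
gravity-consistent accelerometer readings for the current sleeping
position, roll transitions between positions, and movement bursts
concentrated in wake.

Per-stage defaults encode the physiology the staging method relies on:
regular respiration and low HRV in deep sleep, irregular respiration
and the highest HRV in REM, elevated heart rate and movement in wake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_core import AudioRecording, EPOCH_SECONDS, Hypnogram, ImuRecording

__all__ = [
    "StagePhysiology",
    "SimConfig",
    "SyntheticNight",
    "simulate_hypnogram",
    "simulate_audio",
    "simulate_imu",
    "simulate_night",
    "simulate_cohort",
]

RAW_STAGES = ("W", "REM", "N1", "N2", "N3")


@dataclass
class StagePhysiology:
    """Per-stage generative parameters."""

    breath_rate: float      # breaths/min
    bb_cv: float            # coefficient of variation of BB intervals
    heart_rate: float       # bpm
    sdnn_ms: float          # SD of NN intervals, ms
    lf_hf: float            # LF/HF power ratio of the NN modulation
    move_rate_per_h: float  # movement-artefact bursts per hour
    pos_change_p: float     # probability of a position change per epoch


#: Literature-motivated per-stage defaults (see docs/methods.md).
DEFAULT_PHYSIOLOGY: dict[str, StagePhysiology] = {
    "W": StagePhysiology(16.0, 0.25, 70.0, 55.0, 3.0, 60.0, 0.10),
    "REM": StagePhysiology(17.0, 0.30, 64.0, 70.0, 3.5, 2.0, 0.01),
    "N1": StagePhysiology(15.0, 0.15, 62.0, 50.0, 2.0, 6.0, 0.02),
    "N2": StagePhysiology(14.0, 0.08, 58.0, 40.0, 1.0, 2.0, 0.01),
    "N3": StagePhysiology(13.0, 0.05, 55.0, 25.0, 0.5, 0.5, 0.003),
}

#: Epoch-to-epoch stage transition probabilities (rows: from W,REM,N1,N2,N3).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.85, 0.01, 0.12, 0.02, 0.00],
        [0.05, 0.88, 0.02, 0.05, 0.00],
        [0.08, 0.03, 0.70, 0.19, 0.00],
        [0.03, 0.03, 0.03, 0.85, 0.06],
        [0.01, 0.01, 0.00, 0.08, 0.90],
    ]
)


@dataclass
class SimConfig:
    """Conditions of a simulated night / cohort."""

    n_subjects: int = 10
    night_minutes: float = 120.0
    audio_rate: float = 5000.0
    imu_rate: float = 250.0
    snr_db: float = 10.0
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    physiology: dict[str, StagePhysiology] = field(
        default_factory=lambda: dict(DEFAULT_PHYSIOLOGY)
    )
    #: per-subject wake-propensity multipliers are drawn log-uniformly from
    #: this range, spreading sleep efficiency across the cohort
    wake_bias_range: tuple[float, float] = (0.3, 5.0)
    breath_duration_s: float = 1.5
    beat_s1s2_gap_s: float = 0.30
    beat_amplitude: float = 0.35
    gravity: float = 9.81

    def validate(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (5, 5) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 5x5 row-stochastic")
        for name, phys in self.physiology.items():
            if phys.breath_rate <= 0 or phys.heart_rate <= 0:
                raise ValueError(f"stage {name}: rates must be positive")


@dataclass
class SyntheticNight:
    """One simulated subject: truth labels, raw signals, truth events."""

    subject_id: str
    truth_hypnogram: Hypnogram
    audio: AudioRecording
    imu: ImuRecording
    truth_breath_onsets: np.ndarray
    truth_beat_times: np.ndarray
    truth_positions: np.ndarray  # per-IMU-sample position codes
    truth_position_changes: int
    wake_bias: float = 1.0


def _biased_transitions(base: np.ndarray, wake_bias: float) -> np.ndarray:
    """Scale the subject's wake propensity.

    Transitions into wake from sleep scale linearly with the bias,
    P'(i -> W) = clip(b * P(i -> W), 0, 0.5), while the wake dwell time
    scales sub-linearly through the exit probability,
    1 - P'(W -> W) = (1 - P(W -> W)) / sqrt(b).  Rows are renormalized
    over their non-wake entries.  This maps log-spaced biases onto a
    smooth, wide range of sleep efficiencies.
    """
    t = np.array(base, dtype=float, copy=True)
    for i in range(t.shape[0]):
        rest = t[i, 1:].sum()
        if rest <= 0:  # degenerate row (e.g. absorbing): leave unchanged
            continue
        if i == 0:
            pw = float(np.clip(1.0 - (1.0 - t[0, 0]) / np.sqrt(wake_bias), 0.0, 0.98))
        else:
            pw = min(0.5, wake_bias * t[i, 0])
        t[i, 1:] *= (1.0 - pw) / rest
        t[i, 0] = pw
    return t


def simulate_hypnogram(
    cfg: SimConfig, rng: np.random.Generator, n_epochs: int | None = None,
    wake_bias: float = 1.0,
) -> Hypnogram:
    """First-order Markov hypnogram over 30-s epochs, starting in wake."""
    cfg.validate()
    if n_epochs is None:
        n_epochs = int(cfg.night_minutes * 60 // EPOCH_SECONDS)
    t = _biased_transitions(np.asarray(cfg.transitions, dtype=float), wake_bias)
    labels = []
    state = 0  # W
    for _ in range(n_epochs):
        labels.append(RAW_STAGES[state])
        state = int(rng.choice(5, p=t[state]))
    return Hypnogram(labels, "raw")


_SOS_CACHE: dict = {}


def _breath_sos(fs: float, band: tuple[float, float]):
    key = (fs, band)
    if key not in _SOS_CACHE:
        _SOS_CACHE[key] = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return _SOS_CACHE[key]


def _breath_burst(rng, fs, duration_s, band=(200.0, 2000.0)):
    n = int(duration_s * fs)
    noise = rng.standard_normal(n)
    burst = signal.sosfilt(_breath_sos(fs, band), noise)
    # fast attack, slower release: resolves onsets sharply
    env = np.ones(n)
    attack = int(0.10 * fs)
    release = int(0.40 * fs)
    env[:attack] = np.linspace(0.0, 1.0, attack)
    env[-release:] *= np.linspace(1.0, 0.0, release)
    burst *= env
    rms = np.sqrt(np.mean(burst**2))
    return burst / rms if rms > 0 else burst


def _gabor(fs: float, f0: float = 20.0, sigma_s: float = 0.025) -> np.ndarray:
    half = int(4 * sigma_s * fs)
    t = np.arange(-half, half + 1) / fs
    return np.exp(-(t**2) / (2 * sigma_s**2)) * np.cos(2 * np.pi * f0 * t)


def _add(buf: np.ndarray, start_idx: int, x: np.ndarray) -> None:
    i0 = max(0, start_idx)
    i1 = min(buf.size, start_idx + x.size)
    if i1 > i0:
        buf[i0:i1] += x[i0 - start_idx : i1 - start_idx]


def simulate_audio(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator
) -> tuple[AudioRecording, np.ndarray, np.ndarray]:
    """Tracheal audio for a hypnogram; returns (audio, breath onsets, beat times).

    Breath bursts have unit in-burst RMS; the white-noise floor is set
    from ``snr_db`` relative to that, so ``snr_db`` is the in-burst
    breathing-band SNR.  Heart-beat Gabor pairs ride on top with fixed
    relative amplitude; movement artefacts (broadband bursts) occur at
    the stage's rate.
    """
    cfg.validate()
    fs = cfg.audio_rate
    duration = hyp.n_epochs * EPOCH_SECONDS
    n = int(duration * fs)
    buf = np.zeros(n, dtype=np.float64)
    phys = cfg.physiology

    def stage_of(t: float) -> StagePhysiology:
        k = min(int(t // EPOCH_SECONDS), hyp.n_epochs - 1)
        return phys[hyp.labels[k]]

    # --- breathing -------------------------------------------------------
    breath_onsets = []
    t = float(rng.uniform(0.0, 1.0))
    while t < duration - cfg.breath_duration_s:
        p = stage_of(t)
        breath_onsets.append(t)
        amp = float(np.exp(rng.normal(0.0, 0.1)))
        burst = _breath_burst(rng, fs, cfg.breath_duration_s) * amp
        _add(buf, int(t * fs), burst)
        bb_mean = 60.0 / p.breath_rate
        bb = rng.normal(bb_mean, p.bb_cv * bb_mean)
        t += float(np.clip(bb, max(1.0, cfg.breath_duration_s + 0.2), 14.0))
    breath_onsets = np.asarray(breath_onsets)

    # --- heart beats -----------------------------------------------------
    pulse = _gabor(fs)
    beat_times = []
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    t = float(rng.uniform(0.2, 1.0))
    while t < duration - 1.0:
        beat_times.append(t)
        p = stage_of(t)
        _add(buf, int(t * fs) - pulse.size // 2, pulse * cfg.beat_amplitude)
        _add(
            buf,
            int((t + cfg.beat_s1s2_gap_s) * fs) - pulse.size // 2,
            pulse * cfg.beat_amplitude * 0.6,
        )
        nn_mean = 60.0 / p.heart_rate
        sdnn = p.sdnn_ms / 1000.0
        lf_frac = p.lf_hf / (1.0 + p.lf_hf)
        osc_var = 0.8 * sdnn**2
        a_lf = np.sqrt(2.0 * osc_var * lf_frac)
        a_hf = np.sqrt(2.0 * osc_var * (1.0 - lf_frac))
        jitter = rng.normal(0.0, np.sqrt(0.2) * sdnn)
        nn = (
            nn_mean
            + a_lf * np.sin(2 * np.pi * 0.10 * t + phi1)
            + a_hf * np.sin(2 * np.pi * 0.27 * t + phi2)
            + jitter
        )
        t += float(np.clip(nn, 0.4, 1.4))
    beat_times = np.asarray(beat_times)

    # --- movement artefacts & noise floor --------------------------------
    for k in range(hyp.n_epochs):
        p = phys[hyp.labels[k]]
        lam = p.move_rate_per_h * EPOCH_SECONDS / 3600.0
        for _ in range(rng.poisson(lam)):
            t0 = k * EPOCH_SECONDS + rng.uniform(0, EPOCH_SECONDS - 0.6)
            m = rng.standard_normal(int(0.5 * fs)) * 1.5
            win = signal.get_window("hann", m.size)
            _add(buf, int(t0 * fs), m * win)
    if np.isfinite(cfg.snr_db):
        noise_rms = 10.0 ** (-cfg.snr_db / 20.0)
        buf += rng.standard_normal(n) * noise_rms
    return AudioRecording(buf, fs), breath_onsets, beat_times


# position codes match movement.POSITION_LABELS
_POS_SUPINE, _POS_PRONE, _POS_LEFT, _POS_RIGHT = 0, 1, 2, 3
_ROLL_ANGLE = {_POS_SUPINE: 0.0, _POS_LEFT: 90.0, _POS_PRONE: 180.0, _POS_RIGHT: 270.0}


def simulate_imu(
    hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator
) -> tuple[ImuRecording, np.ndarray, int]:
    """IMU stream for a hypnogram; returns (imu, per-sample positions, change count).

    The subject starts supine and rolls about the body's longitudinal
    (y) axis between positions; each change is a smooth 2-s rotation
    with a consistent gyroscope trace.  The accelerometer reads the
    gravity reaction for the current roll angle plus sensor noise, and
    broadband bursts at the stage's movement rate.
    """
    cfg.validate()
    fs = cfg.imu_rate
    n = int(hyp.n_epochs * EPOCH_SECONDS * fs)
    # roll-angle timeline (degrees), piecewise linear over 2-s transitions
    angle = np.empty(n)
    positions = np.empty(n, dtype=np.int64)
    cur_pos = _POS_SUPINE
    cur_angle = 0.0
    changes = 0
    events = []  # sample indices of scheduled position changes
    for k in range(hyp.n_epochs):
        p = cfg.physiology[hyp.labels[k]]
        if rng.random() < p.pos_change_p:
            t0 = k * EPOCH_SECONDS + rng.uniform(1.0, EPOCH_SECONDS - 3.0)
            events.append(int(t0 * fs))
    i_prev = 0
    for idx in events:
        if idx < i_prev:  # overlapping transition: skip this change
            continue
        new_pos = int(rng.choice([q for q in range(4) if q != cur_pos]))
        angle[i_prev:idx] = cur_angle
        positions[i_prev:idx] = cur_pos
        new_angle = _ROLL_ANGLE[new_pos]
        # roll the short way around
        delta = (new_angle - cur_angle + 180.0) % 360.0 - 180.0
        n_tr = int(2.0 * fs)
        i_end = min(idx + n_tr, n)
        ramp = np.linspace(0.0, 1.0, i_end - idx, endpoint=False)
        angle[idx:i_end] = cur_angle + delta * ramp
        half = idx + (i_end - idx) // 2
        positions[idx:half] = cur_pos
        positions[half:i_end] = new_pos
        cur_angle = (cur_angle + delta) % 360.0
        cur_pos = new_pos
        changes += 1
        i_prev = i_end
    angle[i_prev:] = cur_angle
    positions[i_prev:] = cur_pos

    phi = np.deg2rad(angle)
    g = cfg.gravity
    accel = np.column_stack([-g * np.sin(phi), np.zeros(n), g * np.cos(phi)])
    gyro = np.zeros((n, 3))
    dphi = np.diff(phi, prepend=phi[0]) * fs  # rad/s roll rate
    gyro[:, 1] = dphi
    accel += rng.standard_normal((n, 3)) * 0.05
    gyro += rng.standard_normal((n, 3)) * 0.005
    # movement bursts (stage-dependent rate)
    for k in range(hyp.n_epochs):
        p = cfg.physiology[hyp.labels[k]]
        lam = p.move_rate_per_h * EPOCH_SECONDS / 3600.0
        for _ in range(rng.poisson(lam)):
            i0 = int((k * EPOCH_SECONDS + rng.uniform(0, EPOCH_SECONDS - 1.2)) * fs)
            m = int(1.0 * fs)
            win = signal.get_window("hann", m)
            accel[i0 : i0 + m] += (rng.standard_normal((m, 3)) * 3.0) * win[:, None]
            gyro[i0 : i0 + m] += (rng.standard_normal((m, 3)) * 1.0) * win[:, None]
    imu = ImuRecording(accel=accel, gyro=gyro, sample_rate=fs)
    return imu, positions, changes


def simulate_night(
    cfg: SimConfig,
    seed_or_rng,
    subject_id: str = "s0",
    wake_bias: float = 1.0,
) -> SyntheticNight:
    """One complete synthetic subject (hypnogram + audio + IMU + truth)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    hyp = simulate_hypnogram(cfg, rng, wake_bias=wake_bias)
    audio, breath_onsets, beat_times = simulate_audio(hyp, cfg, rng)
    imu, positions, changes = simulate_imu(hyp, cfg, rng)
    return SyntheticNight(
        subject_id=subject_id,
        truth_hypnogram=hyp,
        audio=audio,
        imu=imu,
        truth_breath_onsets=breath_onsets,
        truth_beat_times=beat_times,
        truth_positions=positions,
        truth_position_changes=changes,
        wake_bias=wake_bias,
    )


def simulate_cohort(cfg: SimConfig, seed: int) -> list[SyntheticNight]:
    """A cohort of subjects; subject index partitions the RNG stream.

    Wake-propensity multipliers are spread deterministically (log-evenly
    over ``wake_bias_range`` with a small seeded shuffle) so cohort
    sleep efficiencies cover a wide range.
    """
    cfg.validate()
    lo, hi = cfg.wake_bias_range
    biases = np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_subjects))
    np.random.default_rng([seed, 97]).shuffle(biases)
    nights = []
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng([seed, i])
        nights.append(
            simulate_night(cfg, rng, subject_id=f"s{i}", wake_bias=float(biases[i]))
        )
    return nights
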