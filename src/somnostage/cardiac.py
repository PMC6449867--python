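"""Cardiac chain: heart beats from the 5-30 Hz body-sound band, HRV features.

Each heart beat produces a pair of acoustic peaks (the S1 and S2 heart
sounds) in the low-frequency band of the tracheal microphone.  Peaks are
detected on the analytic envelope, paired into beats by minimal-gap
matching within the physiologic S1-S2 window, gaps are repaired by
interpolation from preceding intervals, and per-epoch heart-rate
variability (HRV) features are computed from the NN interval series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import interp1d

from .config import CardiacConfig
from .io_core import AudioRecording, EpochGrid

log = logging.getLogger(__name__)

__all__ = [
    "BeatSeries",
    "bandpass_cardiac",
    "detect_peaks",
    "pair_peaks_to_beats",
    "interpolate_beats",
    "cardiac_features",
    "cardiac_feature_block",
    "extract_beats",
    "CARDIAC_FEATURE_NAMES",
]

CARDIAC_FEATURE_NAMES = [
    "card_hr_bpm",
    "card_nn_mean_s",
    "card_sdnn_s",
    "card_rmssd_s",
    "card_pnn50",
    "card_nn_cv",
    "card_nn_autocorr1",
    "card_lf_power",
    "card_hf_power",
    "card_lf_hf",
    "card_lf_norm",
    "card_frac_interpolated",
    "card_nn_range_s",
]


@dataclass
class BeatSeries:
    """Detected heart beats (timed at the first peak of each S1-S2 pair)."""

    beat_times: np.ndarray
    interpolated_mask: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=np.float64)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if self.interpolated_mask.size != self.beat_times.size:
            raise ValueError("mask length must equal beat count")
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def nn_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


def bandpass_cardiac(
    audio: AudioRecording,
    band_hz: tuple[float, float] = (5.0, 30.0),
    working_rate_hz: float = 250.0,
) -> AudioRecording:
    """Zero-phase 5-30 Hz bandpass after anti-aliased decimation.

    High-rate audio is first decimated to ``working_rate_hz`` (heart
    sounds in this band need no more), then filtered forward-backward
    with a 4th-order Butterworth design so that peak timing is preserved.
    """
    x = audio.samples
    fs = audio.sample_rate
    if fs > working_rate_hz:
        from fractions import Fraction

        frac = Fraction(working_rate_hz / fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
        fs = working_rate_hz
    if fs < 2 * band_hz[1]:
        raise ValueError(f"rate {fs} Hz cannot represent {band_hz[1]} Hz")
    sos = signal.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, x)
    return AudioRecording(out, fs, audio.start_time)


def detect_peaks(
    filtered: AudioRecording,
    k_mad: float = 3.0,
    refractory_s: float = 0.08,
    min_rel_height: float = 0.35,
) -> np.ndarray:
    """Peak times (s) of the analytic envelope above an adaptive threshold.

    Threshold = median + ``k_mad`` * MAD of the envelope; peaks closer
    than the refractory separation are suppressed (keep the larger).
    A second, relative gate drops peaks below ``min_rel_height`` times
    the 80th percentile of detected peak heights: the MAD threshold
    tracks the noise floor while the relative gate tracks the S1/S2
    amplitude scale, rejecting spurious noise excursions that barely
    clear the floor.  Peak times are refined to sub-sample precision by
    the energy (squared-envelope) centroid over a +/-60 ms window,
    which is far less noise-sensitive than the raw envelope maximum.
    """
    x = filtered.samples
    fs = filtered.sample_rate
    env = np.abs(signal.hilbert(x))
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    thr = med + k_mad * mad
    if not np.any(env > thr):
        return np.array([])
    idx, _ = signal.find_peaks(env, height=thr, distance=max(1, int(refractory_s * fs)))
    if idx.size == 0:
        return np.array([])
    if min_rel_height > 0 and idx.size >= 2:
        gate = min_rel_height * np.percentile(env[idx], 80)
        idx = idx[env[idx] >= max(gate, thr)]
    if idx.size == 0:
        return np.array([])
    half = max(1, int(0.06 * fs))
    times = np.empty(idx.size)
    e2 = env**2
    for j, i in enumerate(idx):
        lo = max(0, i - half)
        hi = min(env.size, i + half + 1)
        w = e2[lo:hi] - min(e2[lo], e2[hi - 1])  # shave the noise pedestal
        w = np.maximum(w, 0.0)
        s = w.sum()
        times[j] = (np.arange(lo, hi) @ w) / s if s > 0 else float(i)
    return filtered.start_time + times / fs


def pair_peaks_to_beats(
    peaks: np.ndarray,
    s1s2_window_s: tuple[float, float] = (0.15, 0.45),
    nn_bounds_s: tuple[float, float] = (0.33, 1.5),
) -> BeatSeries:
    """Group acoustic peaks into beats by minimal-distance S1-S2 pairing.

    Each beat manifests as two adjacent peaks (S1 then S2).  Among all
    ways of pairing *adjacent* peaks into disjoint pairs whose gap lies
    within the S1-S2 plausibility window, the matching with the maximum
    number of pairs and, among those, the minimal total gap is chosen
    (dynamic program over the sorted peaks; ties prefer the earlier
    pair).  Each pair yields one beat timed at its first peak; leftover
    peaks are discarded.  Beats violating the minimum NN bound are
    pruned (keep-first); long NN gaps are left for interpolation.
    """
    peaks = np.sort(np.asarray(peaks, dtype=np.float64))
    n = peaks.size
    if n < 2:
        return BeatSeries(np.array([]), np.array([], dtype=bool))
    lo, hi = s1s2_window_s
    # dp over suffix i..n-1: value = (-n_pairs, total_gap), lexicographic min
    best: list[tuple[int, float]] = [(0, 0.0)] * (n + 1)
    paired: list[bool] = [False] * n  # peak i pairs with peak i+1
    for i in range(n - 1, -1, -1):
        b = best[i + 1]  # skip peak i
        c = False
        if i + 1 < n:
            gap = peaks[i + 1] - peaks[i]
            if lo <= gap <= hi:
                cand = (best[i + 2][0] - 1, best[i + 2][1] + gap)
                if cand <= b:  # on exact tie, pair the earlier peak
                    b = cand
                    c = True
        best[i] = b
        paired[i] = c
    beats = []
    i = 0
    while i < n:
        if paired[i]:
            beats.append(peaks[i])
            i += 2
        else:
            i += 1
    beats = np.asarray(beats)
    # prune NN intervals below the physiologic minimum (keep the earlier beat)
    nn_lo = nn_bounds_s[0]
    keep = []
    last = -np.inf
    for t in beats:
        if t - last >= nn_lo:
            keep.append(t)
            last = t
    beats = np.asarray(keep)
    return BeatSeries(beats, np.zeros(beats.size, dtype=bool))


def interpolate_beats(
    beats: BeatSeries, gap_factor: float = 1.5, history: int = 10
) -> BeatSeries:
    """Fill detection gaps with synthetic beats from preceding intervals.

    A gap is an NN interval exceeding ``gap_factor`` times the rolling
    median of the preceding ``history`` intervals; it is filled with
    beats spaced at that median.  Inserted beats are flagged in
    ``interpolated_mask``.  Gaps with no preceding context stay unfilled.
    """
    t = beats.beat_times
    if t.size < 5:
        log.warning("fewer than 5 beats: interpolation skipped")
        return beats
    out_times: list[float] = [t[0]]
    out_mask: list[bool] = [False]
    prev_nn: list[float] = []
    for i in range(1, t.size):
        nn = t[i] - t[i - 1]
        if prev_nn:
            med = float(np.median(prev_nn[-history:]))
            if nn > gap_factor * med and med > 0:
                n_insert = max(0, int(round(nn / med)) - 1)
                for j in range(1, n_insert + 1):
                    tj = t[i - 1] + j * med
                    if tj < t[i] - 0.5 * med:
                        out_times.append(tj)
                        out_mask.append(True)
                prev_nn.append(med)  # gap epochs contribute the typical interval
            else:
                prev_nn.append(nn)
        else:
            prev_nn.append(nn)
        out_times.append(t[i])
        out_mask.append(False)
    return BeatSeries(np.asarray(out_times), np.asarray(out_mask, dtype=bool))


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    band = (f >= lo) & (f < hi)
    if band.sum() < 2:
        return float(p[band].sum()) if band.any() else 0.0
    return float(np.trapezoid(p[band], f[band]))


def cardiac_features(
    beats: BeatSeries,
    grid: EpochGrid,
    k: int,
    cfg: CardiacConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """13 HRV features for epoch ``k``.

    Time-domain statistics use beats from the epoch +/- 60 s; spectral
    powers (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz) use +/- 120 s, the standard
    short-term HRV length, on the NN series resampled at 4 Hz.
    Degenerate epochs return NaN cells and a raised flag.
    """
    cfg = cfg or CardiacConfig()
    t0, t1 = grid.start(k), grid.end(k)
    feats = np.full(13, np.nan)
    flag = False

    bt = beats.beat_times
    m = beats.interpolated_mask
    sel = (bt >= t0 - cfg.time_context_s) & (bt < t1 + cfg.time_context_s)
    tt = bt[sel]
    nn = np.diff(tt)
    lo, hi = cfg.nn_bounds_s
    ok = (nn >= lo) & (nn <= hi)
    nn = nn[ok]
    if nn.size >= 3:
        mean_nn = float(nn.mean())
        sd = float(nn.std(ddof=1))
        dn = np.diff(nn)
        feats[0] = 60.0 / mean_nn
        feats[1] = mean_nn
        feats[2] = sd
        feats[3] = float(np.sqrt(np.mean(dn**2))) if dn.size else 0.0
        feats[4] = float(np.mean(np.abs(dn) > 0.050)) if dn.size else 0.0
        feats[5] = sd / mean_nn
        x = nn - nn.mean()
        d = float(np.dot(x, x))
        feats[6] = float(np.dot(x[:-1], x[1:]) / d) if d > 0 and nn.size > 3 else 0.0
        feats[11] = float(np.mean(m[sel]))
        feats[12] = float(nn.max() - nn.min())
    else:
        flag = True

    sel2 = (bt >= t0 - cfg.spectral_context_s) & (bt < t1 + cfg.spectral_context_s)
    ts = bt[sel2]
    if ts.size >= 8:
        nn2 = np.diff(ts)
        mid = ts[1:]
        ok2 = (nn2 >= lo) & (nn2 <= hi)
        if ok2.sum() >= 8:
            mid, nn2 = mid[ok2], nn2[ok2]
            fs = cfg.nn_resample_hz
            grid_t = np.arange(mid[0], mid[-1], 1.0 / fs)
            if grid_t.size >= 32:
                series = interp1d(mid, nn2, kind="linear")(grid_t)
                f, p = signal.periodogram(series - series.mean(), fs=fs)
                lf = _band_power(f, p, 0.04, 0.15)
                hf = _band_power(f, p, 0.15, 0.40)
                feats[7] = lf
                feats[8] = hf
                feats[9] = lf / hf if hf > 0 else np.nan
                feats[10] = lf / (lf + hf) if (lf + hf) > 0 else np.nan
    if not np.isfinite(feats[7]):
        flag = True
    return feats, flag


def cardiac_feature_block(
    beats: BeatSeries, grid: EpochGrid, cfg: CardiacConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Feature rows for every epoch; returns (n_epochs x 13, flags)."""
    rows, flags = [], []
    for k in range(grid.n_epochs):
        v, f = cardiac_features(beats, grid, k, cfg)
        rows.append(v)
        flags.append(f)
    return np.asarray(rows), np.asarray(flags, dtype=bool)


def extract_beats(audio: AudioRecording, cfg: CardiacConfig | None = None) -> BeatSeries:
    """Full cardiac chain: decimate+bandpass -> peaks -> pair -> interpolate."""
    cfg = cfg or CardiacConfig()
    banded = bandpass_cardiac(audio, cfg.band_hz, cfg.working_rate_hz)
    peaks = detect_peaks(banded, cfg.peak_k_mad, cfg.refractory_s)
    beats = pair_peaks_to_beats(peaks, cfg.s1s2_window_s, cfg.nn_bounds_s)
    return interpolate_beats(beats, cfg.gap_factor, cfg.gap_history)
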