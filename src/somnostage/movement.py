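"""Movement chain: IMU fusion, sleeping position and activity features.

Accelerometer and gyroscope streams are fused into a quaternion
orientation estimate with Madgwick's gradient-descent complementary
filter.  The gravity direction in the sensor frame then yields the
sleeping position (supine/prone/left/right/upright given the declared
mounting), and per-epoch activity is summarized by position changes and
mean acceleration / angular-velocity magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import ImuConfig
from .io_core import EpochGrid, ImuRecording

__all__ = [
    "OrientationSeries",
    "PositionSeries",
    "madgwick_fuse",
    "classify_position",
    "position_series",
    "movement_features",
    "movement_feature_block",
    "POSITION_LABELS",
    "POSITION_CODES",
]

POSITION_LABELS = ("supine", "prone", "left", "right", "upright")
POSITION_CODES = {label: i for i, label in enumerate(POSITION_LABELS)}

# gravity (pointing down) direction in the sensor frame for each position,
# under the default mounting: z dorsal-ventral (ventral out of the chest),
# y cranial-caudal (toward the head).  Order doubles as tie priority.
_POSITION_GRAVITY = np.array(
    [
        [0.0, 0.0, -1.0],  # supine: lying on the back, gravity into the back
        [0.0, 0.0, 1.0],   # prone
        [1.0, 0.0, 0.0],   # left side
        [-1.0, 0.0, 0.0],  # right side
        [0.0, -1.0, 0.0],  # upright: gravity toward the feet
    ]
)


@dataclass
class OrientationSeries:
    """Unit quaternions (w, x, y, z), sensor-to-earth, one per IMU sample."""

    quaternions: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=np.float64)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4)")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm within 1e-6")

    def __len__(self) -> int:
        return self.quaternions.shape[0]


@dataclass
class PositionSeries:
    """Per-sample sleeping-position labels and their transition times."""

    labels: np.ndarray  # integer codes into POSITION_LABELS
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def change_times(self) -> np.ndarray:
        idx = np.flatnonzero(np.diff(self.labels) != 0) + 1
        return self.start_time + idx / self.sample_rate

    def __len__(self) -> int:
        return self.labels.size


@njit(cache=True)
def _madgwick_loop(accel, gyro, dt, beta, q0):  # pragma: no cover - jitted
    n = accel.shape[0]
    out = np.empty((n, 4))
    qw, qx, qy, qz = q0[0], q0[1], q0[2], q0[3]
    for i in range(n):
        gx, gy, gz = gyro[i, 0], gyro[i, 1], gyro[i, 2]
        # quaternion rate from gyroscope: 0.5 * q x (0, omega)
        dqw = 0.5 * (-qx * gx - qy * gy - qz * gz)
        dqx = 0.5 * (qw * gx + qy * gz - qz * gy)
        dqy = 0.5 * (qw * gy - qx * gz + qz * gx)
        dqz = 0.5 * (qw * gz + qx * gy - qy * gx)
        ax, ay, az = accel[i, 0], accel[i, 1], accel[i, 2]
        anorm = np.sqrt(ax * ax + ay * ay + az * az)
        if anorm > 0.0 and beta > 0.0:
            ax /= anorm
            ay /= anorm
            az /= anorm
            # objective: predicted gravity direction minus measured
            f1 = 2.0 * (qx * qz - qw * qy) - ax
            f2 = 2.0 * (qw * qx + qy * qz) - ay
            f3 = 2.0 * (0.5 - qx * qx - qy * qy) - az
            # gradient J^T f
            sw = -2.0 * qy * f1 + 2.0 * qx * f2
            sx = 2.0 * qz * f1 + 2.0 * qw * f2 - 4.0 * qx * f3
            sy = -2.0 * qw * f1 + 2.0 * qz * f2 - 4.0 * qy * f3
            sz = 2.0 * qx * f1 + 2.0 * qy * f2
            # project onto the tangent space of the unit sphere: the
            # radial component is cancelled by renormalization anyway and
            # would otherwise dominate the step far from the solution
            rad = sw * qw + sx * qx + sy * qy + sz * qz
            sw -= rad * qw
            sx -= rad * qx
            sy -= rad * qy
            sz -= rad * qz
            snorm = np.sqrt(sw * sw + sx * sx + sy * sy + sz * sz)
            if snorm > 0.0:
                dqw -= beta * sw / snorm
                dqx -= beta * sx / snorm
                dqy -= beta * sy / snorm
                dqz -= beta * sz / snorm
        qw += dqw * dt
        qx += dqx * dt
        qy += dqy * dt
        qz += dqz * dt
        qnorm = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw /= qnorm
        qx /= qnorm
        qy /= qnorm
        qz /= qnorm
        out[i, 0] = qw
        out[i, 1] = qx
        out[i, 2] = qy
        out[i, 3] = qz
    return out


def _init_from_accel(accel: np.ndarray) -> np.ndarray:
    """Tilt quaternion aligning earth-up with the first accel direction.

    Avoids the antipodal saddle of the gradient objective and gives the
    filter a warm start; yaw is unobservable and left at zero.
    """
    for a in accel:
        norm = np.linalg.norm(a)
        if norm > 1e-9:
            ahat = a / norm
            ez = np.array([0.0, 0.0, 1.0])
            c = float(np.dot(ez, ahat))
            if c < -1.0 + 1e-12:  # upside down: 180 deg about x
                return np.array([0.0, 1.0, 0.0, 0.0])
            axis = np.cross(ahat, ez)
            s = np.linalg.norm(axis)
            if s < 1e-12:
                return np.array([1.0, 0.0, 0.0, 0.0])
            axis /= s
            angle = np.arctan2(s, c)
            q = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
            return q / np.linalg.norm(q)
    return np.array([1.0, 0.0, 0.0, 0.0])


def madgwick_fuse(
    imu: ImuRecording,
    beta: float = 0.1,
    q0: np.ndarray | None = None,
) -> OrientationSeries:
    """Madgwick gradient-descent orientation filter (IMU variant).

    Per sample the quaternion rate is the gyroscope term 0.5 q x (0, w)
    minus ``beta`` times the normalized gradient of the accelerometer
    gravity-alignment objective; the quaternion is renormalized each
    step.  Zero-norm accelerometer samples fall back to a gyro-only
    update.  ``beta`` (1/s) trades gyro smoothness against accelerometer
    convergence; 0.1 is Madgwick's published stable default.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if q0 is None:
        q0 = _init_from_accel(imu.accel)
    q0 = np.asarray(q0, dtype=np.float64)
    if abs(np.linalg.norm(q0) - 1.0) > 1e-6:
        raise ValueError("q0 must be unit norm")
    dt = 1.0 / imu.sample_rate
    quats = _madgwick_loop(
        np.ascontiguousarray(imu.accel),
        np.ascontiguousarray(imu.gyro),
        dt,
        float(beta),
        q0,
    )
    # guard against numeric drift before the container's unit-norm check
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    return OrientationSeries(quats, imu.sample_rate, imu.start_time)


def gravity_in_sensor(quaternions: np.ndarray) -> np.ndarray:
    """Unit gravity direction (pointing down) in the sensor frame."""
    q = np.atleast_2d(np.asarray(quaternions, dtype=np.float64))
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # earth up-axis rotated into the sensor frame, negated
    up = np.column_stack(
        [2 * (x * z - w * y), 2 * (w * x + y * z), w * w - x * x - y * y + z * z]
    )
    return -up


def classify_position(quaternion: np.ndarray) -> str:
    """Sleeping-position label from one unit quaternion.

    Gravity is rotated into the sensor frame and the nearest of the five
    canonical body directions wins; exact ties fall to the earlier label
    in priority order (supine, prone, left, right, upright).
    """
    g = gravity_in_sensor(quaternion)[0]
    dots = _POSITION_GRAVITY @ g
    # earliest label within rounding distance of the maximum wins the tie
    best = float(dots.max())
    return POSITION_LABELS[int(np.argmax(dots >= best - 1e-9))]


def position_series(
    orient: OrientationSeries, hysteresis_samples: int = 5
) -> PositionSeries:
    """Per-sample position labels with transition debouncing.

    A new label is accepted only once it has persisted for
    ``hysteresis_samples`` consecutive samples, so sensor jitter at a
    classification boundary does not inflate the change count.
    """
    g = gravity_in_sensor(orient.quaternions)
    raw = np.argmax(g @ _POSITION_GRAVITY.T, axis=1)
    if hysteresis_samples <= 1:
        labels = raw
    else:
        labels = np.empty_like(raw)
        current = raw[0]
        run_label, run_len = raw[0], 0
        for i, r in enumerate(raw):
            if r == current:
                run_len = 0
            elif r == run_label:
                run_len += 1
                if run_len >= hysteresis_samples:
                    current = r
                    run_len = 0
            else:
                run_label, run_len = r, 1
            labels[i] = current
    return PositionSeries(labels, orient.sample_rate, orient.start_time)


MOVEMENT_FEATURE_NAMES = [
    "move_dominant_position",
    "move_position_changes",
    "move_accel_activity",
    "move_gyro_activity",
]


def movement_features(
    imu: ImuRecording,
    positions: PositionSeries,
    grid: EpochGrid,
    k: int,
    cfg: ImuConfig | None = None,
) -> np.ndarray:
    """4 movement features for epoch ``k``.

    (1) dominant position (mode of per-sample labels, as integer code),
    (2) number of position changes, (3) mean |  ||accel|| - g  | --
    deviation of the acceleration magnitude from gravity, robust to
    fusion errors during vigorous movement -- and (4) mean ||gyro||.
    """
    cfg = cfg or ImuConfig()
    t0, t1 = grid.start(k), grid.end(k)
    fs = imu.sample_rate
    i0 = max(0, int(np.ceil((t0 - imu.start_time) * fs)))
    i1 = min(imu.n_samples, int(np.ceil((t1 - imu.start_time) * fs)))
    if i1 <= i0:
        return np.array([np.nan] * 4)
    seg_labels = positions.labels[i0:i1]
    counts = np.bincount(seg_labels, minlength=len(POSITION_LABELS))
    dominant = int(np.argmax(counts))
    changes = int(np.count_nonzero(np.diff(seg_labels)))
    amag = np.linalg.norm(imu.accel[i0:i1], axis=1)
    gmag = np.linalg.norm(imu.gyro[i0:i1], axis=1)
    return np.array(
        [
            float(dominant),
            float(changes),
            float(np.mean(np.abs(amag - cfg.gravity))),
            float(np.mean(gmag)),
        ]
    )


def movement_feature_block(
    imu: ImuRecording,
    positions: PositionSeries,
    grid: EpochGrid,
    cfg: ImuConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature rows for every epoch; returns (n_epochs x 4, flags)."""
    rows = [movement_features(imu, positions, grid, k, cfg) for k in range(grid.n_epochs)]
    block = np.asarray(rows)
    return block, ~np.isfinite(block).all(axis=1)


def extract_movement(
    imu: ImuRecording, cfg: ImuConfig | None = None
) -> tuple[OrientationSeries, PositionSeries]:
    """Full movement chain: fuse orientation, classify positions."""
    cfg = cfg or ImuConfig()
    orient = madgwick_fuse(imu, beta=cfg.beta)
    positions = position_series(orient, cfg.hysteresis_samples)
    return orient, positions
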