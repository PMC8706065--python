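"""Synthetic VORx1 trial generation.

Produces metronome-paced head-angle traces with the statistical structure
the compliance analysis assumes: a phase-modulated sinusoid whose
instantaneous tempo performs a reflected Gaussian random walk around the
goal, linear range-of-motion reduction at higher tempo, Gaussian
frame-time jitter, additive angle noise, and a DC offset.  Paired
camera/IMU trials share one latent motion; the IMU trace is mean-removed
(no DC component) and leads the camera trace by an injected lag.  Also
generates 2D landmark projections of a rigid 6-point face model and binary
gaze label sequences for testing the pose and gaze metrics.

One metronome beat corresponds to a half-cycle, so the full-cycle period
is ``120 / goal_bpm`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .compliance import GazeSeries, HeadAngleSeries
from . import pose as _pose

__all__ = [
    "SimConfig",
    "PairedTrialConfig",
    "PairedTrialTruth",
    "CanonicalFaceModel",
    "DEFAULT_FACE_MODEL",
    "simulate_head_motion",
    "simulate_paired_trial",
    "simulate_landmarks",
    "simulate_gaze_sequence",
]

#: tempo anchoring the linear amplitude-decay model (deg of amplitude lost
#: per bpm above this anchor)
AMPLITUDE_DECAY_ANCHOR_BPM = 80.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a single synthetic VORx1 trial.

    Defaults form the "default noise profile" used by the validation
    harness: 30 fps camera-like sampling, 2 ms frame jitter, 1 deg angle
    noise, mild tempo drift and a 5 deg neutral-pose bias.
    """

    goal_bpm: float
    duration_s: float = 30.0
    amplitude_deg: float = 15.0
    amplitude_decay_per_bpm: float = 0.05
    nominal_fps: float = 30.0
    frame_jitter_sd_s: float = 0.002
    angle_noise_sd_deg: float = 1.0
    speed_drift_sd_bpm: float = 1.5
    dc_offset_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.goal_bpm > 0, "goal_bpm", "must be > 0", self.goal_bpm)
        _require(self.duration_s > 0, "duration_s", "must be > 0", self.duration_s)
        _require(self.amplitude_deg >= 0, "amplitude_deg", "must be >= 0", self.amplitude_deg)
        _require(
            self.amplitude_decay_per_bpm >= 0,
            "amplitude_decay_per_bpm", "must be >= 0", self.amplitude_decay_per_bpm,
        )
        _require(self.nominal_fps > 0, "nominal_fps", "must be > 0", self.nominal_fps)
        _require(
            self.frame_jitter_sd_s >= 0, "frame_jitter_sd_s", "must be >= 0", self.frame_jitter_sd_s
        )
        _require(
            self.angle_noise_sd_deg >= 0,
            "angle_noise_sd_deg", "must be >= 0", self.angle_noise_sd_deg,
        )
        _require(
            self.speed_drift_sd_bpm >= 0,
            "speed_drift_sd_bpm", "must be >= 0", self.speed_drift_sd_bpm,
        )
        _require(float(self.seed) == int(self.seed), "seed", "must be an integer", self.seed)

    @property
    def effective_amplitude_deg(self) -> float:
        """Amplitude after linear decay above the anchor tempo, clamped at 0."""
        a = self.amplitude_deg - self.amplitude_decay_per_bpm * (
            self.goal_bpm - AMPLITUDE_DECAY_ANCHOR_BPM
        )
        return max(a, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PairedTrialConfig:
    """A camera/IMU trial pair sharing one latent motion."""

    base: SimConfig
    lag_s: float = 0.15
    imu_fps: float = 100.0
    camera_extra_noise_sd_deg: float = 0.5

    def __post_init__(self) -> None:
        _require(
            abs(self.lag_s) < self.base.duration_s / 4,
            "lag_s", "must satisfy |lag_s| < duration_s / 4", self.lag_s,
        )
        _require(self.imu_fps > 0, "imu_fps", "must be > 0", self.imu_fps)
        _require(
            self.camera_extra_noise_sd_deg >= 0,
            "camera_extra_noise_sd_deg", "must be >= 0", self.camera_extra_noise_sd_deg,
        )


@dataclass(frozen=True)
class PairedTrialTruth:
    """Injected ground truth of a paired trial, for test assertions."""

    lag_s: float
    dc_offset_deg: float
    imu_mean_removed_deg: float


def _require(cond: bool, fieldname: str, rule: str, value) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {rule} (got {value!r})")


def _sample_times(
    rng: np.random.Generator, duration_s: float, fps: float, jitter_sd_s: float
) -> np.ndarray:
    n = int(np.floor(duration_s * fps)) + 1
    t = np.arange(n) / fps
    if jitter_sd_s > 0:
        t = np.sort(t + rng.normal(0.0, jitter_sd_s, size=n))
        # sorting can leave exact ties only with probability zero, but make
        # strict monotonicity unconditional
        eps = 1e-9
        t = np.maximum.accumulate(t + eps * np.arange(n))
    return t


class _LatentMotion:
    """Noise-free latent head angle theta(t) on a dense grid, interpolable."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, pad_s: float = 0.0):
        fine_hz = 1000.0
        t0, t1 = -pad_s, config.duration_s + pad_s
        n = int(np.ceil((t1 - t0) * fine_hz)) + 1
        self.t = t0 + np.arange(n) / fine_hz
        dt = 1.0 / fine_hz
        if config.speed_drift_sd_bpm > 0:
            steps = rng.normal(0.0, config.speed_drift_sd_bpm * np.sqrt(dt), size=n)
            steps[0] = 0.0
            drift = np.cumsum(steps)
            bound = 3.0 * config.speed_drift_sd_bpm
            # reflect the walk into [-bound, bound] about the goal tempo
            drift = bound - np.abs(np.mod(drift - bound, 4.0 * bound) - 2.0 * bound)
            bpm = config.goal_bpm + drift
        else:
            bpm = np.full(n, config.goal_bpm)
        # full-cycle frequency is bpm/120 Hz
        phase = 2.0 * np.pi * np.cumsum(bpm / 120.0) * dt
        # anchor phase so that phi(0) = 0 regardless of padding
        phi0 = np.interp(0.0, self.t, phase)
        self.phase = phase - phi0
        self.amp = config.effective_amplitude_deg
        self.dc = config.dc_offset_deg

    def __call__(self, times: np.ndarray) -> np.ndarray:
        phi = np.interp(times, self.t, self.phase)
        return self.dc + self.amp * np.sin(phi)


def simulate_head_motion(config: SimConfig) -> HeadAngleSeries:
    """Generate one synthetic head-angle trial.

    The sampled signal is ``theta(t) = dc + A * sin(phi(t)) + noise`` where
    the phase advances at the drifting instantaneous tempo and one
    metronome beat spans a half-cycle.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    motion = _LatentMotion(config, rng)
    t = _sample_times(rng, config.duration_s, config.nominal_fps, config.frame_jitter_sd_s)
    angles = motion(t)
    if config.angle_noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, config.angle_noise_sd_deg, size=len(t))
    return HeadAngleSeries(t, angles, plane="yaw", source="synthetic")


def simulate_paired_trial(
    config: PairedTrialConfig,
) -> tuple[HeadAngleSeries, HeadAngleSeries, PairedTrialTruth]:
    """Generate a camera/IMU pair observing the same latent motion.

    The IMU samples the latent motion on its own uniform grid and has its
    mean removed (no DC component); the camera observes the motion delayed
    by ``lag_s``, keeps the DC offset, and carries extra sensor noise.
    """
    base = config.base
    rng = np.random.default_rng(base.seed)
    motion = _LatentMotion(base, rng, pad_s=abs(config.lag_s) + 0.5)

    # camera: jittered grid, delayed view of the latent motion
    t_cam = _sample_times(rng, base.duration_s, base.nominal_fps, base.frame_jitter_sd_s)
    cam_noise_sd = base.angle_noise_sd_deg + config.camera_extra_noise_sd_deg
    cam_angles = motion(t_cam - config.lag_s)
    if cam_noise_sd > 0:
        cam_angles = cam_angles + rng.normal(0.0, cam_noise_sd, size=len(t_cam))

    # IMU: uniform grid, no lag, mean removed
    t_imu = _sample_times(rng, base.duration_s, config.imu_fps, 0.0)
    imu_angles = motion(t_imu)
    if base.angle_noise_sd_deg > 0:
        imu_angles = imu_angles + rng.normal(0.0, base.angle_noise_sd_deg, size=len(t_imu))
    imu_mean = float(np.mean(imu_angles))
    imu_angles = imu_angles - imu_mean

    camera = HeadAngleSeries(t_cam, cam_angles, plane="yaw", source="camera")
    imu = HeadAngleSeries(t_imu, imu_angles, plane="yaw", source="imu")
    truth = PairedTrialTruth(
        lag_s=config.lag_s, dc_offset_deg=base.dc_offset_deg, imu_mean_removed_deg=imu_mean
    )
    return camera, imu, truth


@dataclass(frozen=True)
class CanonicalFaceModel:
    """Rigid 3D landmark model, centered at its centroid.

    Arbitrary length units; the projection scale carries pixels/unit.
    """

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        if len(pts) < 4:
            raise ValueError("face model needs at least 4 points")
        for k, v in pts.items():
            if v.shape != (3,):
                raise ValueError(f"model point {k!r} must be a 3-vector")
        X = np.stack(list(pts.values()))
        centroid = X.mean(axis=0)
        pts = {k: v - centroid for k, v in pts.items()}
        Xc = np.stack(list(pts.values()))
        if np.linalg.matrix_rank(Xc, tol=1e-9) < 3:
            raise ValueError("degenerate face model: centered points must span 3 dimensions")
        object.__setattr__(self, "points", pts)

    @property
    def names(self) -> list[str]:
        return list(self.points.keys())

    def as_json_dict(self) -> dict:
        return {k: [float(x) for x in v] for k, v in self.points.items()}


# fixed 6-point rigid model (x: subject's left, y: up, z: toward camera);
# the nose tip sits off the eye/mouth plane so the model has full rank
DEFAULT_FACE_MODEL = CanonicalFaceModel(
    {
        "right_eye_outer": np.array([-60.0, 40.0, -30.0]),
        "right_eye_inner": np.array([-25.0, 40.0, -35.0]),
        "left_eye_inner": np.array([25.0, 40.0, -35.0]),
        "left_eye_outer": np.array([60.0, 40.0, -30.0]),
        "nose_tip": np.array([0.0, 0.0, 15.0]),
        "mouth_right": np.array([-30.0, -40.0, -25.0]),
        "mouth_left": np.array([30.0, -40.0, -25.0]),
    }
)


def simulate_landmarks(
    pose: "_pose.RotationTriple",
    model: CanonicalFaceModel = DEFAULT_FACE_MODEL,
    scale: float = 1.0,
    noise_sd_px: float = 0.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Orthographic 2D projection of the rotated face model.

    2D point = ``scale * (R(pose) @ X)[:2]`` plus isotropic Gaussian pixel
    noise; the rotation uses the pose module's Euler convention.
    """
    if scale <= 0:
        raise ValueError(f"invalid scale: must be > 0 (got {scale!r})")
    if noise_sd_px < 0:
        raise ValueError(f"invalid noise_sd_px: must be >= 0 (got {noise_sd_px!r})")
    R = _pose.rotation_matrix(pose)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in model.names:
        p2 = scale * (R @ model.points[name])[:2]
        if noise_sd_px > 0:
            p2 = p2 + rng.normal(0.0, noise_sd_px, size=2)
        out[name] = p2
    return out


def simulate_gaze_sequence(
    n_frames: int, on_target_fraction: float, seed: int = 0, fps: float = 30.0
) -> GazeSeries:
    """Binary gaze labels with an exact on-target count.

    The number of on-target frames is ``round(n_frames * fraction)``
    (banker's rounding, e.g. 1 frame at fraction 0.5 yields 0); their
    positions are shuffled by the seed.
    """
    if n_frames < 1:
        raise ValueError(f"invalid n_frames: must be >= 1 (got {n_frames!r})")
    if not 0.0 <= on_target_fraction <= 1.0:
        raise ValueError(
            f"invalid on_target_fraction: must be in [0, 1] (got {on_target_fraction!r})"
        )
    n_on = int(round(n_frames * on_target_fraction))
    labels = np.zeros(n_frames, dtype=bool)
    labels[:n_on] = True
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    times = np.arange(n_frames) / fps
    return GazeSeries(times, labels)
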