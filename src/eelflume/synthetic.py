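"""Synthetic flume scenes with known ground truth.

Everything the analysis pipeline consumes can be generated here: a swaying
anchored eel polyline with strike lunges, passively advected prey
particles, noisy multi-camera pixel observations via the DLT projectors,
and Poisson trial capture counts produced by the semicircular feeding-area
forward model. All generators are pure functions of (parameters, seed).

The emulated conditions follow the flume study this pipeline targets:
60 Hz recording, a 0.30 x 0.30 m test-section cross-section, flow speeds
of 0.10-0.25 m/s, prey densities of 100-1000 m^-3, ~0.1 m of body out of
the burrow, and three cameras on one flume side (two side by side, one
above).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np
import pandas as pd

from .exceptions import EelflumeError
from .foraging import DEFAULT_FLUME_VOLUME, released_count
from .geometry3d import CameraDLT, dlt_project
from .kinematics import BodyTrack3D, StrikeEvent

__all__ = [
    "EelSimParams",
    "PreySimParams",
    "PreyField",
    "BODY_LABELS",
    "gen_eel_track",
    "gen_prey_particles",
    "gen_camera_obs",
    "gen_trial_counts",
    "make_pinhole_camera",
    "default_camera_rig",
]

#: Ordered labels of the 8-point body polyline, burrow base to snout. The
#: first large black spot sits just behind the head; the eye is the snout
#: end tracked throughout trials.
BODY_LABELS = ("base", "body1", "body2", "body3", "body4", "body5", "spot1", "eye")


@dataclass(frozen=True)
class EelSimParams:
    """Parameters of the simulated anchored eel.

    ``base_length`` is the arc length of body outside the burrow (m);
    sway is a sinusoidal lateral oscillation whose amplitude grows
    linearly from the burrow (0) to the eye (``sway_amplitude``); strikes
    arrive as a Poisson process and lunge straight toward a sampled prey
    position at ``strike_speed``.
    """

    base_length: float = 0.10  # m out of the burrow
    sway_amplitude: float = 0.005  # m at the eye
    sway_freq: float = 1.0  # Hz
    strike_rate: float = 0.3  # strikes s^-1
    strike_speed: float = 0.15  # m s^-1
    strike_reach: float = 0.04  # m, max lunge distance
    bend_angle: float = 0.6  # rad, total downstream bend of the arc posture
    fps: float = 60.0
    duration: float = 10.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.base_length, self.sway_amplitude, self.sway_freq,
               self.strike_rate, self.strike_speed, self.strike_reach) < 0:
            raise ValueError("magnitudes must be >= 0")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")


@dataclass(frozen=True)
class PreySimParams:
    """Parameters of the advected prey-particle field."""

    rho: float  # m^-3
    U: float  # m s^-1
    y_range: tuple[float, float] = (-0.15, 0.15)  # m (0.30 m wide section)
    z_range: tuple[float, float] = (0.0, 0.30)  # m (0.30 m high section)
    x_span: float | None = None  # m upstream of x=0; default U*T at generation
    dt: float = 1.0 / 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho < 0 or self.U < 0:
            raise ValueError("rho and U must be >= 0")
        if self.y_range[1] <= self.y_range[0] or self.z_range[1] <= self.z_range[0]:
            raise ValueError("ranges must have positive extent")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def cross_section_area(self) -> float:
        return (self.y_range[1] - self.y_range[0]) * (self.z_range[1] - self.z_range[0])


@dataclass(frozen=True)
class PreyField:
    """Prey tracer positions at t=0, advected at (-U, 0, 0)."""

    positions0: np.ndarray  # (n, 3) m
    U: float

    def positions(self, t: float) -> np.ndarray:
        return self.positions0 + np.array([-self.U * t, 0.0, 0.0])

    def count_crossings(self, T: float, plane_x: float = 0.0) -> int:
        """Particles crossing the y-z plane at ``plane_x`` within [0, T]."""
        x0 = self.positions0[:, 0]
        return int(np.count_nonzero((x0 > plane_x) & (x0 - self.U * T <= plane_x)))


def _arc_posture(length: float, bend_angle: float, arc_s: np.ndarray) -> np.ndarray:
    """Circular-arc posture in the x-z plane, bending downstream (-x).

    The arc starts at the origin with a vertical tangent; ``bend_angle``
    is the total tangent rotation over arc length ``length``.
    """
    if length == 0:
        return np.zeros((len(arc_s), 3))
    if bend_angle < 1e-9:
        pts = np.zeros((len(arc_s), 3))
        pts[:, 2] = arc_s
        return pts
    kappa = bend_angle / length
    x = -(1.0 - np.cos(kappa * arc_s)) / kappa
    z = np.sin(kappa * arc_s) / kappa
    return np.column_stack([x, np.zeros_like(arc_s), z])


def gen_eel_track(
    p: EelSimParams,
) -> tuple[BodyTrack3D, list[StrikeEvent], np.ndarray]:
    """Simulate an anchored eel's 8-point body track.

    Returns the track, the ground-truth strike events, and the per-frame
    length-out-of-burrow series (arc length of the generated polyline).
    The base posture is a circular arc bending downstream; lateral sway is
    sinusoidal; strikes are Poisson-timed straight lunges of the head
    toward sampled prey positions, ramped linearly out and back. The
    output is deterministic given the seed.
    """
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration * p.fps))
    t = np.arange(n_frames) / p.fps
    n_pts = len(BODY_LABELS)
    arc_s = np.linspace(0.0, p.base_length, n_pts)
    base = _arc_posture(p.base_length, p.bend_angle, arc_s)  # (8, 3)
    taper = arc_s / p.base_length if p.base_length > 0 else np.zeros(n_pts)

    # positions[frame, point, xyz]
    pos = np.broadcast_to(base, (n_frames, n_pts, 3)).copy()
    sway = p.sway_amplitude * np.sin(2.0 * pi * p.sway_freq * t)  # (n_frames,)
    pos[:, :, 1] += sway[:, None] * taper[None, :]

    # Poisson strike schedule; lunges never overlap (skipped if they would).
    strike_windows: list[tuple[int, int, np.ndarray]] = []
    if p.strike_rate > 0 and p.strike_speed > 0:
        n_events = rng.poisson(p.strike_rate * p.duration)
        starts = np.sort(rng.uniform(0.0, p.duration, size=n_events))
        busy_until = -np.inf
        for t0 in starts:
            dist = rng.uniform(0.3, 1.0) * p.strike_reach
            # random direction biased upstream/upward where prey arrive
            direction = rng.normal(size=3) + np.array([1.0, 0.0, 0.5])
            direction /= np.linalg.norm(direction)
            dur = dist / p.strike_speed
            i0 = int(np.ceil(t0 * p.fps))
            i_cap = i0 + max(2, int(round(dur * p.fps)))
            i_end = i_cap + (i_cap - i0)  # symmetric return
            if t0 < busy_until or i_end >= n_frames:
                continue
            busy_until = i_end / p.fps
            strike_windows.append((i0, i_cap, dist * direction))

    # apply lunge displacement, scaled quadratically along the body so the
    # burrow end stays anchored
    lunge_scale = taper**2
    for i0, i_cap, lunge_vec in strike_windows:
        i_end = i_cap + (i_cap - i0)
        for i in range(i0, i_end):
            if i < i_cap:  # outbound: linear ramp to the prey
                frac = (i - i0) / (i_cap - i0)
            else:  # return: linear ramp back
                frac = (i_end - i) / (i_cap - i0)
            pos[i] += frac * lunge_vec[None, :] * lunge_scale[:, None]

    data = {label: pos[:, k, :].copy() for k, label in enumerate(BODY_LABELS)}
    track = BodyTrack3D(fps=p.fps, frames=np.arange(n_frames), data=data)

    eye = data["eye"]
    strikes = [
        StrikeEvent(
            t_init=i0 / p.fps,
            t_capture=i_cap / p.fps,
            eye_init=eye[i0],
            eye_capture=eye[i_cap],
            prey_capture=eye[i_cap],
        )
        for i0, i_cap, _ in strike_windows
    ]
    lengths = np.sum(
        np.linalg.norm(np.diff(pos, axis=1), axis=2), axis=1
    )  # (n_frames,)
    return track, strikes, lengths


def gen_prey_particles(p: PreySimParams, T: float) -> PreyField:
    """Seed a spatially homogeneous (Poisson) prey field and advect it.

    Particles occupy ``x in (0, x_span]`` upstream of the burrow plane
    (default span ``U*T`` so every particle crosses x=0 within ``T``),
    uniformly in the cross-section. The number crossing x=0 over ``T`` has
    mean ``rho * U * A * T``.
    """
    rng = np.random.default_rng(p.seed)
    span = p.x_span if p.x_span is not None else p.U * T
    volume = span * p.cross_section_area
    n = rng.poisson(p.rho * volume) if volume > 0 else 0
    x = rng.uniform(0.0, span, size=n) if span > 0 else np.zeros(n)
    y = rng.uniform(*p.y_range, size=n)
    z = rng.uniform(*p.z_range, size=n)
    return PreyField(positions0=np.column_stack([x, y, z]), U=p.U)


def make_pinhole_camera(
    camera_id: str,
    center,
    look_at=(0.0, 0.0, 0.1),
    focal_px: float = 1500.0,
    principal=(960.0, 540.0),
    image_size=(1920, 1080),
    up=(0.0, 0.0, 1.0),
) -> CameraDLT:
    """Exact DLT coefficients of an ideal pinhole camera.

    Built from the 3x4 projection matrix P = K [R | -R C] normalized so
    its last entry is 1, which is the 11-coefficient DLT form.
    """
    c = np.asarray(center, dtype=float)
    fwd = np.asarray(look_at, dtype=float) - c
    fwd /= np.linalg.norm(fwd)
    right = np.cross(fwd, np.asarray(up, dtype=float))
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)  # image v grows downward
    R = np.vstack([right, down, fwd])
    K = np.array(
        [[focal_px, 0.0, principal[0]], [0.0, focal_px, principal[1]], [0.0, 0.0, 1.0]]
    )
    P = K @ np.hstack([R, (-R @ c)[:, None]])
    if abs(P[2, 3]) < 1e-12:
        raise ValueError("degenerate camera placement: cannot normalize DLT")
    P = P / P[2, 3]
    coeffs = np.concatenate([P[0], P[1], P[2, :3]])
    return CameraDLT(camera_id=camera_id, coeffs=coeffs, image_size=tuple(image_size))


def default_camera_rig() -> list[CameraDLT]:
    """Three-camera rig on one flume side: two side by side, one above."""
    return [
        make_pinhole_camera("cam1", (-0.25, -0.85, 0.15)),
        make_pinhole_camera("cam2", (0.25, -0.85, 0.15)),
        make_pinhole_camera("cam3", (0.0, -0.85, 0.55)),
    ]


def gen_camera_obs(
    track: BodyTrack3D,
    cams: list[CameraDLT],
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Project a body track through each camera with Gaussian pixel noise.

    Returns the plain 2D-observation table (frame, camera_id, label, u, v,
    confidence). Raises a descriptive error if any point is unprojectable.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for cam in cams:
        for label in track.labels:
            pts = track.positions(label)
            try:
                uv = dlt_project(cam, pts)
            except Exception as exc:
                raise EelflumeError(
                    f"projection failed for camera {cam.camera_id!r}, "
                    f"label {label!r}: {exc}"
                ) from exc
            if pixel_noise_sd > 0:
                uv = uv + rng.normal(0.0, pixel_noise_sd, size=uv.shape)
            parts.append(
                pd.DataFrame(
                    {
                        "frame": track.frames,
                        "camera_id": cam.camera_id,
                        "label": label,
                        "u": uv[:, 0],
                        "v": uv[:, 1],
                        "confidence": 1.0,
                    }
                )
            )
    return (
        pd.concat(parts, ignore_index=True)
        .sort_values(["frame", "camera_id", "label"], kind="stable")
        .reset_index(drop=True)
    )


def gen_trial_counts(
    rho: float,
    U: float,
    L: float,
    T: float,
    seed: int = 0,
    control_loss: float = 0.03,
    volume: float = DEFAULT_FLUME_VOLUME,
) -> tuple[int, int]:
    """Forward-simulate one trial's (released, recovered) counts.

    Captures are Poisson with mean ``rho * U * (pi L^2 / 2) * T`` (the
    semicircular feeding-area model); control losses are Binomial over the
    released prey. Deterministic given the seed.
    """
    if min(rho, U, L, T) < 0:
        raise ValueError("inputs must be >= 0")
    rng = np.random.default_rng(seed)
    released = released_count(rho, volume)
    mean_captures = rho * U * (pi * L**2 / 2.0) * T
    if mean_captures > released:
        raise ValueError(
            f"unphysical parameters: mean captures {mean_captures:.1f} exceeds "
            f"released count {released}"
        )
    captures = rng.poisson(mean_captures)
    losses = rng.binomial(released, control_loss) if released > 0 else 0
    recovered = max(0, released - int(captures) - int(losses))
    return released, recovered
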