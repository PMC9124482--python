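"""Direct linear transformation (DLT) camera model and multi-view triangulation.

The 11-coefficient DLT maps flume coordinates ``(X, Y, Z)`` in meters to
image pixels::

    u = (L1*X + L2*Y + L3*Z + L4) / D
    v = (L5*X + L6*Y + L7*Z + L8) / D
    D = L9*X + L10*Y + L11*Z + 1

The flume frame is right-handed with x streamwise (upstream positive),
y lateral, and z upward from the sand bed; the origin sits at the burrow.
Calibration fits the 11 coefficients from >=6 non-coplanar 3D-2D
correspondences by linear least squares; reconstruction inverts the map
from >=2 camera views, again by linear least squares, and reports the RMS
reprojection residual as a quality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ProjectionError, ReconstructionError

#: Condition-number threshold above which a triangulation is flagged as
#: ill-conditioned (near-parallel rays).
CONDITION_THRESHOLD = 1e6

#: Observations with confidence below this are dropped before triangulation.
DEFAULT_MIN_CONFIDENCE = 0.6

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class CameraDLT:
    """One camera's 11 DLT coefficients (L1..L11).

    Parameters
    ----------
    camera_id
        Identifier used to join observations with coefficients.
    coeffs
        The 11 coefficients, ordered L1..L11.
    image_size
        Optional ``(width_px, height_px)``.
    """

    camera_id: str
    coeffs: np.ndarray
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (11,):
            raise ValueError(
                f"expected exactly 11 DLT coefficients, got shape {coeffs.shape}"
            )
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("DLT coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)


@dataclass(frozen=True)
class ReconstructionResult:
    """Triangulated 3D point with reprojection diagnostics."""

    point: np.ndarray  # (3,) meters
    residual_px: float  # RMS reprojection error over contributing views
    n_views: int
    well_conditioned: bool  # False when rays are near-parallel

    def __iter__(self):
        # allow ``point, residual = dlt_reconstruct(...)`` unpacking
        yield self.point
        yield self.residual_px


def dlt_project(cam: CameraDLT, p) -> np.ndarray:
    """Project 3D point(s) ``p`` (meters, shape ``(..., 3)``) to pixels.

    Returns an array of shape ``(..., 2)``. Raises
    :class:`~eelflume.exceptions.ProjectionError` if the projective
    denominator is not positive at any point.
    """
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    pts = np.atleast_2d(p)
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 components")
    L = cam.coeffs
    D = pts @ L[8:11] + 1.0
    if np.any(D <= _DENOM_TOL):
        raise ProjectionError(
            f"camera {cam.camera_id!r}: projection denominator <= {_DENOM_TOL} "
            "(point on or behind the focal plane)"
        )
    u = (pts @ L[0:3] + L[3]) / D
    v = (pts @ L[4:7] + L[7]) / D
    uv = np.stack([u, v], axis=-1)
    return uv[0] if squeeze else uv


def dlt_calibrate(
    correspondences: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> tuple[CameraDLT, float]:
    """Fit 11 DLT coefficients from (3D point, 2D pixel) correspondences.

    Requires at least 6 non-coplanar 3D points. Returns the fitted camera
    and the RMS reprojection error (px) over the training correspondences.
    """
    if len(correspondences) < 6:
        raise CalibrationError(
            f"DLT calibration needs >=6 correspondences, got {len(correspondences)}"
        )
    xyz = np.asarray([c[0] for c in correspondences], dtype=float)
    uv = np.asarray([c[1] for c in correspondences], dtype=float)
    if xyz.shape[1] != 3 or uv.shape[1] != 2:
        raise CalibrationError("correspondences must pair 3D points with 2D pixels")

    # coplanarity check: centered points must span 3 dimensions
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1e-30):
        raise CalibrationError("3D calibration points are coplanar or collinear")

    n = len(xyz)
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    X, Y, Z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    u, v = uv[:, 0], uv[:, 1]
    A[0::2, 0:3] = xyz
    A[0::2, 3] = 1.0
    A[0::2, 8] = -u * X
    A[0::2, 9] = -u * Y
    A[0::2, 10] = -u * Z
    A[1::2, 4:7] = xyz
    A[1::2, 7] = 1.0
    A[1::2, 8] = -v * X
    A[1::2, 9] = -v * Y
    A[1::2, 10] = -v * Z
    b[0::2] = u
    b[1::2] = v

    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise CalibrationError(
            "degenerate point configuration: DLT system is rank deficient"
        )
    cam = CameraDLT(camera_id="calibrated", coeffs=coeffs)
    reproj = dlt_project(cam, xyz)
    rms = float(np.sqrt(np.mean(np.sum((reproj - uv) ** 2, axis=1))))
    return cam, rms


def dlt_reconstruct(
    observations: Sequence[tuple[CameraDLT, Sequence[float]]],
    condition_threshold: float = CONDITION_THRESHOLD,
) -> ReconstructionResult:
    """Triangulate one 3D point from >=2 ``(camera, (u, v))`` observations.

    Each camera contributes two linear equations in (X, Y, Z); the point is
    the least-squares solution. The residual is the RMS of per-camera
    reprojection distances (px). If the row-normalized design matrix has a
    condition number above ``condition_threshold`` (near-parallel rays) the
    result is flagged ``well_conditioned=False``.
    """
    if len(observations) < 2:
        raise ReconstructionError(
            f"triangulation needs >=2 camera views, got {len(observations)}"
        )
    m = len(observations)
    A = np.empty((2 * m, 3))
    b = np.empty(2 * m)
    for i, (cam, px) in enumerate(observations):
        L = cam.coeffs
        u, v = float(px[0]), float(px[1])
        A[2 * i] = L[0:3] - u * L[8:11]
        b[2 * i] = u - L[3]
        A[2 * i + 1] = L[4:7] - v * L[8:11]
        b[2 * i + 1] = v - L[7]

    norms = np.linalg.norm(A, axis=1)
    norms[norms == 0] = 1.0
    cond = np.linalg.cond(A / norms[:, None])
    point, *_ = np.linalg.lstsq(A, b, rcond=None)

    sq = 0.0
    for cam, px in observations:
        reproj = dlt_project(cam, point)
        sq += float(np.sum((reproj - np.asarray(px, dtype=float)) ** 2))
    rms = float(np.sqrt(sq / m))
    return ReconstructionResult(
        point=point,
        residual_px=rms,
        n_views=m,
        well_conditioned=bool(cond <= condition_threshold),
    )


def triangulate_tracks(
    observations: pd.DataFrame,
    cameras: dict[str, CameraDLT] | Sequence[CameraDLT],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> pd.DataFrame:
    """Triangulate every (frame, label) across cameras in a 2D track table.

    ``observations`` has columns frame, camera_id, label, u, v and optional
    confidence; rows with confidence below ``min_confidence`` are dropped.
    Returns a table with columns frame, label, x_m, y_m, z_m, residual_px,
    n_views, well_conditioned, skipping (frame, label) pairs seen by fewer
    than two cameras.
    """
    if not isinstance(cameras, dict):
        cameras = {c.camera_id: c for c in cameras}
    obs = observations.copy()
    if "confidence" in obs.columns:
        obs = obs[obs["confidence"].fillna(1.0) >= min_confidence]

    missing = set(obs["camera_id"].unique()) - set(cameras)
    if missing:
        raise ReconstructionError(
            f"no DLT coefficients for camera(s): {sorted(missing)}"
        )

    records = []
    for (frame, label), group in obs.groupby(["frame", "label"], sort=True):
        views = [
            (cameras[row.camera_id], (row.u, row.v))
            for row in group.itertuples(index=False)
        ]
        if len(views) < 2:
            continue
        res = dlt_reconstruct(views)
        records.append(
            {
                "frame": int(frame),
                "label": label,
                "x_m": res.point[0],
                "y_m": res.point[1],
                "z_m": res.point[2],
                "residual_px": res.residual_px,
                "n_views": res.n_views,
                "well_conditioned": res.well_conditioned,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "frame",
            "label",
            "x_m",
            "y_m",
            "z_m",
            "residual_px",
            "n_views",
            "well_conditioned",
        ],
    )
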