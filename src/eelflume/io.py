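"""CSV/JSON readers and writers for the pipeline's file dialects.

All on-disk units are SI (meters, seconds) unless a reader is told
``units="cm"``, in which case lengths are converted to meters on read.
Schemas are strict: unknown or missing columns raise
:class:`~eelflume.exceptions.SchemaError` listing the expected layout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .geometry3d import CameraDLT
from .kinematics import BodyTrack3D, StrikeEvent

OBS_COLUMNS = ["frame", "camera_id", "label", "u", "v", "confidence"]
TRACK3D_COLUMNS = ["frame", "label", "x_m", "y_m", "z_m"]
STRIKE_COLUMNS = [
    "t_init_s", "t_capture_s",
    "eye_init_x_m", "eye_init_y_m", "eye_init_z_m",
    "eye_capture_x_m", "eye_capture_y_m", "eye_capture_z_m",
    "prey_x_m", "prey_y_m", "prey_z_m",
]
TRIAL_COLUMNS = [
    "eel_id", "U_mps", "rho_per_m3", "released", "recovered",
    "control_loss_fraction",
]

_FLOAT_FMT = "%.9g"


def _unit_scale(units: str) -> float:
    if units == "m":
        return 1.0
    if units == "cm":
        return 0.01
    raise ValueError("units must be 'm' or 'cm'")


def _check_schema(df: pd.DataFrame, expected: list[str], what: str,
                  allow_optional: tuple[str, ...] = ()) -> None:
    cols = list(df.columns)
    missing = [c for c in expected if c not in cols and c not in allow_optional]
    extra = [c for c in cols if c not in expected and c not in allow_optional]
    if missing or extra:
        raise SchemaError(
            f"{what}: expected columns {expected}"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
        )


# ---------------------------------------------------------------- DLT files

def write_dlt_coefficients(path, cameras: list[CameraDLT]) -> None:
    """One column per camera, 11 rows in L1..L11 order, header of camera ids."""
    df = pd.DataFrame({c.camera_id: c.coeffs for c in cameras})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dlt_coefficients(path) -> dict[str, CameraDLT]:
    df = pd.read_csv(path)
    if len(df) != 11:
        raise SchemaError(
            f"DLT coefficient file must have 11 rows (L1..L11), got {len(df)}"
        )
    return {
        cam_id: CameraDLT(camera_id=str(cam_id), coeffs=df[cam_id].to_numpy(float))
        for cam_id in df.columns
    }


# ----------------------------------------------------------- 2D observations

def write_observations(path, obs: pd.DataFrame) -> None:
    _check_schema(obs, OBS_COLUMNS, "2D observation table")
    obs.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, OBS_COLUMNS, "2D observation table",
                  allow_optional=("confidence",))
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    bad = df[df[["frame", "u", "v"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise SchemaError(
            f"corrupt observation row(s) at line(s) "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    df["frame"] = df["frame"].astype(int)
    return df


def read_pose_estimation_csv(path, camera_id: str) -> pd.DataFrame:
    """Read the common pose-estimation CSV dialect (three header rows:
    scorer / bodyparts / coords) into the plain observation schema.

    Likelihood columns become ``confidence``; the first column is the
    frame index.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    records = []
    bodyparts = []
    for col in df.columns:
        if col[1] not in bodyparts:
            bodyparts.append(col[1])
    scorer = df.columns[0][0]
    for part in bodyparts:
        sub = df[scorer][part]
        rec = pd.DataFrame(
            {
                "frame": df.index.astype(int),
                "camera_id": camera_id,
                "label": part,
                "u": sub["x"].to_numpy(float),
                "v": sub["y"].to_numpy(float),
                "confidence": (
                    sub["likelihood"].to_numpy(float)
                    if "likelihood" in sub.columns
                    else 1.0
                ),
            }
        )
        records.append(rec)
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["frame", "label"], kind="stable").reset_index(drop=True)


# -------------------------------------------------------------- 3D tracks

def write_track3d(path, track: pd.DataFrame | BodyTrack3D) -> None:
    if isinstance(track, BodyTrack3D):
        track = track.to_frame()
    extra = [c for c in ("residual_px", "n_views", "well_conditioned")
             if c in track.columns]
    _check_schema(track[ [c for c in track.columns if c not in extra] ],
                  TRACK3D_COLUMNS, "3D track table")
    track.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_track3d(path, units: str = "m") -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, TRACK3D_COLUMNS, "3D track table",
                  allow_optional=("residual_px", "n_views", "well_conditioned"))
    scale = _unit_scale(units)
    if scale != 1.0:
        df[["x_m", "y_m", "z_m"]] *= scale
    df["frame"] = df["frame"].astype(int)
    return df


def track3d_to_body_track(df: pd.DataFrame, fps: float = 60.0) -> BodyTrack3D:
    """Assemble a BodyTrack3D from the long-format table (complete frames only)."""
    wide = df.pivot(index="frame", columns="label", values=["x_m", "y_m", "z_m"])
    wide = wide.dropna()
    frames = wide.index.to_numpy(int)
    data = {
        label: np.column_stack(
            [wide[("x_m", label)], wide[("y_m", label)], wide[("z_m", label)]]
        )
        for label in df["label"].unique()
    }
    return BodyTrack3D(fps=fps, frames=frames, data=data)


# ---------------------------------------------------------------- strikes

def write_strikes(path, strikes: list[StrikeEvent]) -> None:
    rows = [
        {
            "t_init_s": s.t_init,
            "t_capture_s": s.t_capture,
            "eye_init_x_m": s.eye_init[0], "eye_init_y_m": s.eye_init[1],
            "eye_init_z_m": s.eye_init[2],
            "eye_capture_x_m": s.eye_capture[0],
            "eye_capture_y_m": s.eye_capture[1],
            "eye_capture_z_m": s.eye_capture[2],
            "prey_x_m": s.prey_capture[0], "prey_y_m": s.prey_capture[1],
            "prey_z_m": s.prey_capture[2],
        }
        for s in strikes
    ]
    pd.DataFrame(rows, columns=STRIKE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_strikes(path, units: str = "m") -> list[StrikeEvent]:
    df = pd.read_csv(path)
    _check_schema(df, STRIKE_COLUMNS, "strike annotation table")
    scale = _unit_scale(units)
    return [
        StrikeEvent(
            t_init=r.t_init_s,
            t_capture=r.t_capture_s,
            eye_init=np.array([r.eye_init_x_m, r.eye_init_y_m, r.eye_init_z_m]) * scale,
            eye_capture=np.array(
                [r.eye_capture_x_m, r.eye_capture_y_m, r.eye_capture_z_m]
            ) * scale,
            prey_capture=np.array([r.prey_x_m, r.prey_y_m, r.prey_z_m]) * scale,
        )
        for r in df.itertuples(index=False)
    ]


# ------------------------------------------------------------ trial tables

def write_trial_table(path, table: pd.DataFrame) -> None:
    extra = [c for c in ("cycle_s", "feeding_rate_per_min") if c in table.columns]
    base = table[[c for c in table.columns if c not in extra]]
    _check_schema(base, TRIAL_COLUMNS, "trial table")
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, TRIAL_COLUMNS, "trial table")
    return df


# ------------------------------------------------------------- provenance

def write_provenance(path, config: dict, seed: int | None) -> None:
    """Machine-readable run record: config hash, seed, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "eelflume_version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
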