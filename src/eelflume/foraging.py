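"""Functional-response and prey-flux foraging models plus flume-trial bookkeeping.

Two feeding-rate models:

* the Holling disk equation ``F = a*rho / (1 + a*rho*h)`` (type II
  functional response; attack rate ``a`` in m^3 s^-1, prey density ``rho``
  in m^-3, handling time ``h`` in s);
* a prey-flux model for an anchored ambush feeder that captures all prey
  crossing a semicircular feeding area of radius ``L`` (the third quartile
  of the body length extended from the burrow):
  ``F = 60 * P * pi * L**2 / 2`` prey per minute, with prey flux
  ``P = rho * U`` (m^-2 s^-1).

Trial bookkeeping mirrors a recirculating-flume protocol: a trial lasts
one "water cycle" (circuit length / flow speed), prey released as
density x 1.24 m^3 flume volume, captures estimated as released minus
recovered minus a control-loss correction, and converted to prey min^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import pi
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DiskParams",
    "CycleAnchor",
    "TrialSpec",
    "ModelPrediction",
    "ExperimentDesign",
    "DESIGN_I",
    "DESIGN_II",
    "disk_equation",
    "fit_disk",
    "prey_flux",
    "model_feeding_rate",
    "cycle_time",
    "frames_for_trials",
    "released_count",
    "trial_feeding_rate",
    "trial_table_rates",
    "DEFAULT_FLUME_VOLUME",
]

#: Flume volume (m^3) used to convert a target prey density into a
#: released head count.
DEFAULT_FLUME_VOLUME = 1.24


class CycleAnchor(NamedTuple):
    """Observed (speed, frame count) pair fixing the flume circuit length.

    ``frames0`` frames cover ``n_trials`` full water cycles at speed ``U0``
    and frame rate ``fps``, so circuit_length = U0 * frames0 / (n_trials * fps).
    """

    U0: float
    frames0: int
    n_trials: int = 2
    fps: float = 60.0

    @property
    def circuit_length(self) -> float:
        return self.U0 * self.frames0 / (self.n_trials * self.fps)


#: Default anchor: two trials at 0.10 m/s spanned 6720 frames at 60 Hz,
#: i.e. a 5.6 m circuit.
DEFAULT_ANCHOR = CycleAnchor(U0=0.10, frames0=6720, n_trials=2, fps=60.0)


@dataclass(frozen=True)
class DiskParams:
    """Disk-equation parameters: attack rate a, handling time h, density rho."""

    a: float  # m^3 s^-1
    h: float  # s
    rho: float  # m^-3

    def __post_init__(self) -> None:
        if self.a < 0 or self.h < 0 or self.rho < 0:
            raise ValueError("a, h, rho must all be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """One flume trial's physical parameters."""

    U: float  # m s^-1
    rho: float  # prey m^-3
    flume_volume: float = DEFAULT_FLUME_VOLUME
    circuit_anchor: CycleAnchor | None = DEFAULT_ANCHOR
    circuit_length: float | None = None
    control_loss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.flume_volume <= 0:
            raise ValueError("flume_volume must be positive")
        if not 0.0 <= self.control_loss_fraction <= 1.0:
            raise ValueError("control_loss_fraction must lie in [0, 1]")
        if self.control_loss_fraction > 0.05:
            warnings.warn(
                "control_loss_fraction above 5% is outside the range seen in "
                "control trials",
                stacklevel=2,
            )
        if self.circuit_length is None and self.circuit_anchor is None:
            raise ValueError("need circuit_length or circuit_anchor")

    @property
    def resolved_circuit_length(self) -> float:
        if self.circuit_length is not None:
            return self.circuit_length
        return self.circuit_anchor.circuit_length


@dataclass(frozen=True)
class ModelPrediction:
    """Semicircular feeding-area model output."""

    P: float  # prey flux, m^-2 s^-1
    L: float  # feeding radius (Q3 length out of burrow), m
    area: float  # pi L^2 / 2, m^2
    F_per_min: float  # prey min^-1


@dataclass(frozen=True)
class ExperimentDesign:
    """A full factorial block of flume trials."""

    eels: tuple
    densities: tuple  # m^-3
    speeds: tuple  # m s^-1
    replicates: int

    @property
    def n_trials(self) -> int:
        return len(self.eels) * len(self.densities) * len(self.speeds) * self.replicates


_EELS = ("A", "B", "C", "D", "E")
#: Design I: density effects at two flow speeds.
DESIGN_I = ExperimentDesign(_EELS, (100, 200, 300, 600, 1000), (0.10, 0.20), 2)
#: Design II: flow-speed effects at two densities.
DESIGN_II = ExperimentDesign(_EELS, (300, 1000), (0.10, 0.15, 0.20, 0.25), 2)


def disk_equation(p: DiskParams) -> float:
    """Type II functional response F = a*rho / (1 + a*rho*h), in s^-1."""
    return p.a * p.rho / (1.0 + p.a * p.rho * p.h)


def fit_disk(rho, F) -> tuple[float, float]:
    """Least-squares fit of (a, h) to observed (density, feeding rate) pairs.

    Both parameters are bounded below by zero. In a linear (low-density)
    regime the handling time is weakly identified; the point estimate is
    returned regardless.
    """
    rho = np.asarray(rho, dtype=float)
    F = np.asarray(F, dtype=float)
    if rho.size < 2:
        raise ValueError("need >=2 observations to fit the disk equation")

    def model(r, a, h):
        return a * r / (1.0 + a * r * h)

    a0 = max(float(np.polyfit(rho, F, 1)[0]), 1e-9)
    (a, h), _ = curve_fit(
        model, rho, F, p0=[a0, 0.01], bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    return float(a), float(h)


def prey_flux(rho: float, U: float) -> float:
    """Prey flux P = rho * U (prey m^-2 s^-1)."""
    if rho < 0 or U < 0:
        raise ValueError("rho and U must be >= 0")
    return rho * U


def model_feeding_rate(rho: float, U: float, L: float) -> ModelPrediction:
    """Feeding rate predicted by the semicircular feeding-area model.

    All prey crossing a semicircle of radius L (flat side on the bed, in
    the cross-flow y-z plane) are captured: F = 60 * rho * U * pi L^2 / 2
    prey per minute.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    P = prey_flux(rho, U)
    area = pi * L**2 / 2.0
    return ModelPrediction(P=P, L=L, area=area, F_per_min=60.0 * P * area)


def cycle_time(spec: TrialSpec, U: float | None = None) -> float:
    """One water cycle (s): circuit length / flow speed."""
    U = spec.U if U is None else U
    if U <= 0:
        raise ValueError("U must be positive to compute a cycle time")
    return spec.resolved_circuit_length / U


def frames_for_trials(spec: TrialSpec, n_trials: int, U: float | None = None) -> int:
    """Video frames spanning ``n_trials`` water cycles at speed U.

    Rounded to the nearest integer (half to even).
    """
    U = spec.U if U is None else U
    fps = spec.circuit_anchor.fps if spec.circuit_anchor is not None else 60.0
    return round(n_trials * fps * cycle_time(spec, U))


def released_count(rho: float, volume: float = DEFAULT_FLUME_VOLUME) -> int:
    """Prey released to reach density ``rho`` in a flume of ``volume`` m^3."""
    if rho < 0 or volume < 0:
        raise ValueError("rho and volume must be >= 0")
    return round(rho * volume)


def trial_feeding_rate(spec: TrialSpec, released: int, recovered: int) -> float:
    """Feeding rate (prey min^-1) from released/recovered counts of one trial.

    Captures = released - recovered, corrected by the mean control loss
    (control_loss_fraction * released); negative corrected captures clamp
    to zero with a warning. The rate divides by the trial duration of one
    water cycle, in minutes.
    """
    if recovered > released:
        raise ValueError("recovered cannot exceed released")
    if recovered < 0 or released < 0:
        raise ValueError("counts must be >= 0")
    adjusted = released - recovered - spec.control_loss_fraction * released
    if adjusted < 0:
        warnings.warn(
            "control-loss correction exceeds apparent captures; clamping to 0",
            stacklevel=2,
        )
        adjusted = 0.0
    minutes = cycle_time(spec) / 60.0
    return adjusted / minutes


def trial_table_rates(table: pd.DataFrame, anchor: CycleAnchor = DEFAULT_ANCHOR,
                      flume_volume: float = DEFAULT_FLUME_VOLUME) -> pd.DataFrame:
    """Per-trial feeding rates for a trial table.

    Expects columns eel_id, U_mps, rho_per_m3, released, recovered,
    control_loss_fraction; appends cycle_s and feeding_rate_per_min.
    """
    out = table.copy()
    rates, cycles = [], []
    for row in table.itertuples(index=False):
        spec = TrialSpec(
            U=row.U_mps,
            rho=row.rho_per_m3,
            flume_volume=flume_volume,
            circuit_anchor=anchor,
            control_loss_fraction=row.control_loss_fraction,
        )
        cycles.append(cycle_time(spec))
        rates.append(trial_feeding_rate(spec, int(row.released), int(row.recovered)))
    out["cycle_s"] = cycles
    out["feeding_rate_per_min"] = rates
    return out
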