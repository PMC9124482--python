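"""Drag on an anchored slender body modeled as cylindrical segments.

The body polyline outside the burrow is split into 7-8 straight segments,
each treated as a circular cylinder of diameter 0.5 cm in cross-flow. By
the cross-flow principle only the velocity component normal to a segment's
axis generates pressure drag; the parallel (skin-friction) component is
neglected. Per segment::

    U_n = U * sin(theta)          # theta: angle between axis and flow
    Re  = U_n * d / nu
    F   = 0.5 * rho_w * Cd(Re) * (d * l) * U_n**2

with the subcritical smooth-cylinder correlation ``Cd = 1 + 10 Re^(-2/3)``
by default. The whole-body drag coefficient normalizes the summed force by
the reference area ``d * (total arc length)``, which reduces to the
single-cylinder definition for a straight body perpendicular to the flow.

Two counterfactual posture scenarios quantify how posture and length
modulation reduce drag at high flow: (1) keep the low-flow posture and
length unchanged and evaluate at the high flow speed; (2) keep a straight
posture but shorten to the high-flow length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FluidContext",
    "Segment",
    "SegmentedBody",
    "DragResult",
    "cylinder_cd",
    "segment_body",
    "resample_polyline",
    "segment_drag",
    "body_drag",
    "scenario_transform",
    "SCENARIOS",
]

#: Free-stream direction: water flows downstream, i.e. toward -x.
FLOW_DIRECTION = np.array([-1.0, 0.0, 0.0])

#: Upper Reynolds number of the subcritical regime the default Cd
#: correlation is valid for.
RE_SUBCRITICAL_MAX = 2e5

SCENARIOS = ("actual", "fixed_posture_and_length", "shortened_straight")


@dataclass(frozen=True)
class FluidContext:
    """Free-stream speed and water properties (seawater at 25 degC)."""

    U: float
    rho_w: float = 1025.0  # kg m^-3
    nu: float = 9.7e-7  # m^2 s^-1

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("U must be >= 0")
        if self.rho_w <= 0 or self.nu <= 0:
            raise ValueError("rho_w and nu must be positive")


@dataclass(frozen=True)
class Segment:
    """A straight cylindrical body segment.

    ``length`` defaults to the chord |end - start| but may carry the arc
    length of a resampled polyline portion so that total body length is
    conserved under resampling.
    """

    start: np.ndarray
    end: np.ndarray
    length: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.start, dtype=float)
        e = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)
        chord = float(np.linalg.norm(e - s))
        if chord <= 0:
            raise ValueError("segment has zero length")
        object.__setattr__(
            self, "length", chord if self.length is None else float(self.length)
        )
        if self.length <= 0:
            raise ValueError("segment length must be positive")

    @property
    def axis(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class SegmentedBody:
    """Ordered cylindrical segments approximating the body out of the burrow."""

    segments: tuple[Segment, ...]
    diameter: float = 0.005  # m

    def __post_init__(self) -> None:
        if not 1 <= len(self.segments) <= 12:
            raise ValueError("body must have 1-12 segments")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))


@dataclass(frozen=True)
class DragResult:
    """Per-segment and whole-body drag at one posture and flow speed."""

    per_segment_force: np.ndarray  # N
    total_force: float  # N
    body_cd: float | None  # None when U = 0 (undefined)
    reference_area: float  # m^2
    scenario: str = "actual"
    cd_defined: bool = True


def cylinder_cd(Re: float, correlation: Callable[[float], float] | None = None) -> float:
    """Drag coefficient of a smooth circular cylinder in cross-flow.

    Default subcritical correlation: ``Cd = 1 + 10 * Re**(-2/3)``. Valid
    for ``0 < Re < 2e5``; larger Re triggers a validity warning.
    """
    if Re <= 0:
        raise ValueError("Reynolds number must be positive")
    if Re > RE_SUBCRITICAL_MAX:
        warnings.warn(
            f"Re={Re:.3g} exceeds the subcritical validity range of the "
            "default Cd correlation",
            stacklevel=2,
        )
    if correlation is not None:
        return float(correlation(Re))
    return float(1.0 + 10.0 * Re ** (-2.0 / 3.0))


def resample_polyline(points, n_segments: int) -> np.ndarray:
    """Resample a polyline to ``n_segments + 1`` vertices at equal arc length."""
    pts = np.asarray(points, dtype=float)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    target = np.linspace(0.0, s[-1], n_segments + 1)
    return np.column_stack([np.interp(target, s, pts[:, k]) for k in range(3)])


def segment_body(
    polyline, n_segments: int | None = None, diameter: float = 0.005
) -> SegmentedBody:
    """Split an ordered body polyline into cylindrical segments.

    Without ``n_segments``, consecutive point pairs become segments. With
    it, the polyline is first resampled to arc-length-uniform vertices;
    each resampled segment is then assigned the arc length of its polyline
    portion (total/n) so total body length is conserved exactly, while its
    axis is the chord between the resampled vertices.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline needs >=2 3D points")
    if n_segments is None:
        segs = [Segment(a, b) for a, b in zip(pts[:-1], pts[1:])]
    else:
        total = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        res = resample_polyline(pts, n_segments)
        piece = total / n_segments
        segs = [Segment(a, b, length=piece) for a, b in zip(res[:-1], res[1:])]
    return SegmentedBody(segments=tuple(segs), diameter=diameter)


def segment_drag(
    segment: Segment,
    fluid: FluidContext,
    diameter: float = 0.005,
    correlation: Callable[[float], float] | None = None,
) -> float:
    """Drag force (N) on one cylindrical segment via the cross-flow principle."""
    axis = segment.axis
    cos_theta = abs(float(axis @ FLOW_DIRECTION))
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta**2))
    U_n = fluid.U * sin_theta
    if U_n == 0.0:
        return 0.0
    Re = U_n * diameter / fluid.nu
    Cd = cylinder_cd(Re, correlation)
    return 0.5 * fluid.rho_w * Cd * (diameter * segment.length) * U_n**2


def body_drag(
    body: SegmentedBody,
    fluid: FluidContext,
    scenario: str = "actual",
    correlation: Callable[[float], float] | None = None,
) -> DragResult:
    """Total drag and whole-body drag coefficient of a segmented body.

    The reference area is diameter x total arc length; ``body_cd`` is
    ``2 F / (rho_w U^2 A_ref)``, undefined (None, flagged) at U = 0.
    """
    forces = np.array(
        [
            segment_drag(s, fluid, diameter=body.diameter, correlation=correlation)
            for s in body.segments
        ]
    )
    total = float(forces.sum())
    a_ref = body.diameter * body.total_length
    if fluid.U == 0.0:
        warnings.warn("U=0: whole-body drag coefficient is undefined", stacklevel=2)
        return DragResult(forces, total, None, a_ref, scenario, cd_defined=False)
    cd = 2.0 * total / (fluid.rho_w * fluid.U**2 * a_ref)
    return DragResult(forces, total, cd, a_ref, scenario)


def scenario_transform(
    body_lowU: SegmentedBody,
    scenario: str,
    length_highU: float | None = None,
    orientation: str = "vertical",
) -> SegmentedBody:
    """Build the counterfactual geometry for a posture scenario.

    ``fixed_posture_and_length`` returns the low-flow geometry unchanged
    (to be evaluated at the higher flow speed). ``shortened_straight``
    returns a straight body of arc length ``length_highU``, oriented
    vertically by default or along the low-flow body's mean (chord) axis
    with ``orientation='mean_axis'``.
    """
    if scenario == "fixed_posture_and_length":
        return body_lowU
    if scenario != "shortened_straight":
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of "
            f"{SCENARIOS[1:]}"
        )
    if length_highU is None or length_highU <= 0:
        raise ValueError("shortened_straight requires length_highU > 0")
    if orientation == "vertical":
        axis = np.array([0.0, 0.0, 1.0])
    elif orientation == "mean_axis":
        chord = body_lowU.segments[-1].end - body_lowU.segments[0].start
        norm = np.linalg.norm(chord)
        axis = chord / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError("orientation must be 'vertical' or 'mean_axis'")
    n = len(body_lowU.segments)
    start = body_lowU.segments[0].start
    verts = start[None, :] + np.linspace(0.0, length_highU, n + 1)[:, None] * axis
    segs = tuple(Segment(a, b) for a, b in zip(verts[:-1], verts[1:]))
    return SegmentedBody(segments=segs, diameter=body_lowU.diameter)
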