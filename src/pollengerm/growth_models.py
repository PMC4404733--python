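"""Kinematic geometries of pollen tube emergence.

Two extreme morphological models describe how a pollen tube (PT) can emerge
from the grain:

* **protrusion** -- a constant-width, dome-tipped cylinder elongates linearly
  from the germination site from the outset. The width of the junction
  between grain and tube stays constant.
* **bulging** -- germination begins as an isodiametrically inflating circle
  anchored at the germination site; after a fixed number of frames the distal
  region of the bulge turns into a dome-shaped tip that elongates as a
  cylinder. The junction diameter grows during the bulge phase.

Geometry is held as exact vector polygons (shapely); the grain ellipse is
approximated by a 720-gon, so vector areas serve as ground truth for
rasterized measurements. Both models are *kinematic*: no turgor or cell-wall
mechanics is implied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

from ._geom import arc_points, rasterize

__all__ = [
    "GrainGeometry",
    "ProtrusionParams",
    "BulgingParams",
    "ShapeFrame",
    "ModelTrajectory",
    "TrajectoryClassification",
    "DEFAULT_GRAIN",
    "protrusion_shape",
    "bulging_shape",
    "model_trajectory",
    "match_net_area",
    "classify_trajectory",
]

_ELLIPSE_N = 720  # vertices of the grain-ellipse polygon
_ARC_N = 180  # vertices per circular arc of tube outlines


class ParameterError(ValueError):
    """Raised for geometrically invalid model parameters."""


class InsufficientDataError(ValueError):
    """Raised when an input series is too short for the requested analysis."""


@dataclass(frozen=True)
class GrainGeometry:
    """Elliptical pollen grain with a germination site on its boundary.

    Parameters are in micrometers; ``germination_angle`` is the direction
    (radians) from the grain center to the germination site.
    """

    semi_major: float = 12.5
    semi_minor: float = 10.0
    center: tuple[float, float] = (0.0, 0.0)
    germination_angle: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ParameterError(
                f"require semi_major >= semi_minor > 0, got "
                f"{self.semi_major}, {self.semi_minor}"
            )

    def polygon(self) -> Polygon:
        t = np.linspace(0.0, 2.0 * np.pi, _ELLIPSE_N, endpoint=False)
        xs = self.center[0] + self.semi_major * np.cos(t)
        ys = self.center[1] + self.semi_minor * np.sin(t)
        return Polygon(np.column_stack([xs, ys]))

    def germination_point(self) -> np.ndarray:
        """Point on the ellipse boundary in the direction of the germination angle."""
        th = self.germination_angle
        a, b = self.semi_major, self.semi_minor
        r = a * b / np.hypot(b * np.cos(th), a * np.sin(th))
        return np.array(self.center) + r * np.array([np.cos(th), np.sin(th)])

    def outward_direction(self) -> np.ndarray:
        th = self.germination_angle
        return np.array([np.cos(th), np.sin(th)])


DEFAULT_GRAIN = GrainGeometry()


@dataclass(frozen=True)
class ProtrusionParams:
    """Constant-width dome-tipped cylinder elongating linearly."""

    tube_width: float = 5.5
    elongation_per_frame: float = 1.0
    n_frames: int = 40

    def __post_init__(self) -> None:
        if self.tube_width <= 0:
            raise ParameterError("tube_width must be > 0")
        if self.elongation_per_frame < 0:
            raise ParameterError("elongation_per_frame must be >= 0")


@dataclass(frozen=True)
class BulgingParams:
    """Inflating bulge anchored at the germination site, then a dome-tipped tube.

    During the first ``bulge_frames`` frames a circle whose lowermost point is
    fixed at the germination site grows by ``radius_increment_per_frame`` per
    frame. Afterwards the bulge outline is frozen and a capped cylinder of
    width ``tube_width`` elongates from its distal point.
    """

    tube_width: float = 5.5
    radius_increment_per_frame: float = 0.1375
    bulge_frames: int = 20
    elongation_per_frame: float = 1.0
    n_frames: int = 40

    def __post_init__(self) -> None:
        if self.tube_width <= 0:
            raise ParameterError("tube_width must be > 0")
        if self.radius_increment_per_frame <= 0:
            raise ParameterError("radius_increment_per_frame must be > 0")
        if self.bulge_frames < 1:
            raise ParameterError("bulge_frames must be >= 1")


@dataclass(frozen=True)
class ShapeFrame:
    """Tube region of one frame, after subtraction of the grain ellipse."""

    frame_index: int
    region: BaseGeometry

    @property
    def area(self) -> float:
        return 0.0 if self.region is None or self.region.is_empty else self.region.area


@dataclass
class ModelTrajectory:
    """Per-frame area, roundness, and junction width of a simulated model."""

    frames: np.ndarray
    area: np.ndarray  # um^2
    roundness: np.ndarray
    junction_width: np.ndarray  # um
    frame_interval: float = 3.0  # min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_min": self.frames * self.frame_interval,
                "area_um2": self.area,
                "roundness": self.roundness,
                "junction_width_um": self.junction_width,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _capped_cylinder(
    base: np.ndarray, direction: np.ndarray, length: float, width: float
) -> Polygon:
    """Rectangle of the given length capped by a semicircular dome of diameter
    ``width``, extending from ``base`` along the unit vector ``direction``."""
    d = direction / np.linalg.norm(direction)
    n = np.array([-d[1], d[0]])  # left normal
    w2 = width / 2.0
    tip = base + length * d
    phi = np.arctan2(d[1], d[0])
    dome = arc_points(tip, w2, phi - np.pi / 2.0, phi + np.pi / 2.0, _ARC_N)
    # ring: right base corner, dome arc right-to-left, left base corner
    coords = np.vstack([base - w2 * n, dome, base + w2 * n])
    return Polygon(coords)


def protrusion_shape(
    grain: GrainGeometry, p: ProtrusionParams, frame: int
) -> ShapeFrame:
    """Tube region of the protrusion model at a given frame.

    A rectangle of width ``tube_width`` and length
    ``frame * elongation_per_frame`` capped by a semicircular dome emerges
    outward along the germination direction; the grain ellipse is subtracted.
    Frame 0 is pre-emergence (empty region).
    """
    if frame < 0:
        raise ParameterError("frame must be >= 0")
    if frame == 0 or p.elongation_per_frame == 0:
        return ShapeFrame(frame, Polygon())
    base = grain.germination_point()
    direction = grain.outward_direction()
    length = frame * p.elongation_per_frame
    tube = _capped_cylinder(base, direction, length, p.tube_width)
    region = tube.difference(grain.polygon())
    return ShapeFrame(frame, region)


def bulging_shape(grain: GrainGeometry, p: BulgingParams, frame: int) -> ShapeFrame:
    """Tube region of the bulging model at a given frame.

    For ``frame <= bulge_frames`` the region is a circle of radius
    ``frame * radius_increment_per_frame`` whose lowermost (proximal) point is
    anchored at the germination site, minus the grain. Afterwards the bulge
    outline is frozen and a dome-tipped cylinder of width ``tube_width``
    elongates from the distal point of the bulge.
    """
    if frame < 0:
        raise ParameterError("frame must be >= 0")
    base = grain.germination_point()
    direction = grain.outward_direction()
    r = min(frame, p.bulge_frames) * p.radius_increment_per_frame
    if r <= 0:
        return ShapeFrame(frame, Polygon())
    center = base + r * direction
    bulge = Point(center).buffer(r, quad_segs=_ARC_N // 2)
    region: BaseGeometry = bulge
    if frame > p.bulge_frames and p.elongation_per_frame > 0:
        distal = base + 2.0 * r * direction
        length = (frame - p.bulge_frames) * p.elongation_per_frame
        tube = _capped_cylinder(distal, direction, length, p.tube_width)
        region = bulge.union(tube)
    region = region.difference(grain.polygon())
    return ShapeFrame(frame, region)


def shape_fn(
    params: ProtrusionParams | BulgingParams,
) -> Callable[[GrainGeometry, int], ShapeFrame]:
    """Return the shape constructor bound to the parameter type."""
    if isinstance(params, ProtrusionParams):
        return lambda grain, f: protrusion_shape(grain, params, f)
    if isinstance(params, BulgingParams):
        return lambda grain, f: bulging_shape(grain, params, f)
    raise ParameterError(f"unknown growth parameter type: {type(params)!r}")


def junction_width_vector(
    region: BaseGeometry, grain: GrainGeometry, offset: float = 0.25
) -> float:
    """Junction width of a vector tube region: length of the region's chord
    along the grain boundary offset slightly outward (mirrors the raster
    measurement over a 1-px dilated boundary band)."""
    if region is None or region.is_empty:
        return 0.0
    curve = grain.polygon().buffer(offset, quad_segs=64).exterior
    inter = curve.intersection(region)
    return float(inter.length) if not inter.is_empty else 0.0


def model_trajectory(
    grain: GrainGeometry,
    params: ProtrusionParams | BulgingParams,
    measure_fn: Callable | None = None,
    pixel_size: float = 0.1,
    frame_interval: float = 3.0,
) -> ModelTrajectory:
    """Measure a model's per-frame area, roundness, and junction width.

    By default each frame is rasterized at ``pixel_size`` um/px and measured
    with :func:`pollengerm.segmentation.measure_region` -- the same
    measurement applied to real images -- so both models are measured
    identically. ``measure_fn(mask, pixel_size, grain_mask)`` may be supplied
    to override the measurement.
    """
    from .segmentation import measure_region

    fn = shape_fn(params)
    n = params.n_frames
    # fixed grid covering grain plus maximal tube extent
    reach = (
        grain.semi_major
        + params.tube_width
        + n * params.elongation_per_frame
        + (
            2 * params.bulge_frames * params.radius_increment_per_frame
            if isinstance(params, BulgingParams)
            else 0.0
        )
        + 4.0
    )
    half = max(reach, grain.semi_major + 4.0, grain.semi_minor + 4.0)
    origin = (grain.center[0] - half, grain.center[1] - half)
    npx = int(np.ceil(2 * half / pixel_size))
    grain_mask = rasterize(grain.polygon(), (npx, npx), pixel_size, origin)
    measure = measure_fn or (
        lambda mask, px, gm: measure_region(mask, px, grain_mask=gm, tube_length=False)
    )
    frames = np.arange(n + 1)
    area = np.zeros(n + 1)
    roundness = np.full(n + 1, np.nan)
    junction = np.zeros(n + 1)
    for f in frames:
        sf = fn(grain, int(f))
        mask = rasterize(sf.region, (npx, npx), pixel_size, origin)
        m = measure(mask, pixel_size, grain_mask)
        area[f] = m.area
        roundness[f] = m.roundness
        junction[f] = m.junction_width if np.isfinite(m.junction_width) else 0.0
    return ModelTrajectory(frames, area, roundness, junction, frame_interval)


def match_net_area(
    protrusion: ProtrusionParams,
    bulging: BulgingParams,
    grain: GrainGeometry = DEFAULT_GRAIN,
) -> tuple[ProtrusionParams, BulgingParams]:
    """Set the protrusion elongation rate so both models end at the same area.

    The net increase in PT area over ``n_frames`` is made identical for both
    models (within 1 percent) while the dome width (``tube_width``) is kept
    identical and unchanged. The bulging schedule is the reference; only the
    protrusion elongation rate is adjusted. Idempotent.
    """
    if protrusion.n_frames != bulging.n_frames:
        raise ParameterError("both models must use the same n_frames")
    if protrusion.tube_width != bulging.tube_width:
        raise ParameterError("both models must use the same tube_width")
    if bulging.tube_width >= 2.0 * grain.semi_minor:
        raise ParameterError("tube wider than grain: infeasible geometry")
    target = bulging_shape(grain, bulging, bulging.n_frames).area
    # protrusion final area is affine in the elongation rate: fit on two probes
    w = protrusion.tube_width
    n = protrusion.n_frames
    probes = []
    for rate in (0.5, 1.5):
        p = dataclasses.replace(protrusion, elongation_per_frame=rate)
        probes.append(protrusion_shape(grain, p, n).area)
    slope = (probes[1] - probes[0]) / 1.0
    intercept = probes[0] - slope * 0.5
    if slope <= 0:
        raise ParameterError("degenerate protrusion geometry")
    rate = (target - intercept) / slope
    if rate <= 0:
        raise ParameterError(
            "bulging final area too small to match with a positive elongation rate"
        )
    matched = dataclasses.replace(protrusion, elongation_per_frame=float(rate))
    final = protrusion_shape(grain, matched, n).area
    if abs(final - target) / target > 0.01:
        raise ParameterError("area matching failed to converge within 1%")
    return matched, bulging


@dataclass
class TrajectoryClassification:
    """Outcome of matching an observed roundness course against both models."""

    label: str  # "bulging", "protrusion", or "tie"
    residuals: dict[str, float]
    junction_increased: bool | None = None


def _template_roundness(model: str, n_frames: int = 40) -> np.ndarray:
    """Canonical roundness course of a model under default parameters."""
    if model == "protrusion":
        params: ProtrusionParams | BulgingParams = ProtrusionParams(n_frames=n_frames)
    else:
        params = BulgingParams(n_frames=n_frames)
    traj = model_trajectory(DEFAULT_GRAIN, params, pixel_size=0.2)
    r = traj.roundness.copy()
    r[~np.isfinite(r)] = 0.0
    return r


_TEMPLATE_CACHE: dict[str, np.ndarray] = {}


def _templates() -> dict[str, np.ndarray]:
    if not _TEMPLATE_CACHE:
        for m in ("protrusion", "bulging"):
            _TEMPLATE_CACHE[m] = _template_roundness(m)
    return _TEMPLATE_CACHE


def classify_trajectory(
    roundness_series: Sequence[float],
    area_series: Sequence[float] | None = None,
    junction_width_series: Sequence[float] | None = None,
    tie_margin: float = 0.05,
) -> TrajectoryClassification:
    """Match an observed roundness course against both morphological models.

    The model templates are time-rescaled to the observed series length
    (germination frames aligned, time normalized by total duration) and the
    amplitude is fit by least squares; the label is the model with the lower
    mean-squared residual. A flat (near-constant) series, or residuals within
    ``tie_margin`` of each other, is reported as a tie rather than silently
    labeled. If a junction-width series is given, whether it increased (the
    bulging signature) is reported as corroborating evidence.
    """
    obs = np.asarray(roundness_series, dtype=float)
    obs = np.where(np.isfinite(obs), obs, 0.0)
    if obs.size < 10:
        raise InsufficientDataError(
            f"need >= 10 frames spanning germination, got {obs.size}"
        )
    residuals: dict[str, float] = {}
    x_obs = np.linspace(0.0, 1.0, obs.size)
    stretches = np.geomspace(1.0 / 3.0, 3.0, 13)
    for name, tmpl in _templates().items():
        x_t = np.linspace(0.0, 1.0, tmpl.size)
        best = np.inf
        # the observed window need not span the same fraction of the course
        # as the template, so the time axis is additionally stretched; the
        # label then depends on curve shape, not on growth rate
        for s in stretches:
            t = np.interp(np.minimum(x_obs / s, 1.0), x_t, tmpl)
            denom = float(np.dot(t, t))
            amp = float(np.dot(obs, t) / denom) if denom > 0 else 0.0
            best = min(best, float(np.mean((obs - amp * t) ** 2)))
        residuals[name] = best
    junction_increased = None
    if junction_width_series is not None:
        jw = np.asarray(junction_width_series, dtype=float)
        jw = jw[np.isfinite(jw) & (jw > 0)]
        if jw.size >= 2:
            junction_increased = bool(jw[-1] > 1.05 * jw[0])
    r_b, r_p = residuals["bulging"], residuals["protrusion"]
    flat = np.std(obs) < 0.01 * max(1.0, np.mean(np.abs(obs)))
    close = abs(r_b - r_p) <= tie_margin * max(r_b, r_p, 1e-12)
    if flat or close:
        label = "tie"
    else:
        label = "bulging" if r_b < r_p else "protrusion"
    return TrajectoryClassification(label, residuals, junction_increased)
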