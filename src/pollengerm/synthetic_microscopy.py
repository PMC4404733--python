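"""Ground-truthed synthetic time-lapse renderer for germinating pollen.

Renders multi-channel z-stack time-lapse images (axes T, Z, Y, X per
channel) from vector growth-model geometry, emulating a spinning-disc
acquisition: 11 optical slices per time point, 3-min frame interval,
distance-dependent Gaussian z-blur, and Poisson-Gaussian camera noise.

Channel behaviors:

* ``cytoplasm`` -- uniformly fills grain and tube.
* ``vesicle`` -- dim cytoplasmic baseline, transient Gaussian blobs at
  scheduled pre-germination peak events near the grain cortex, and an
  inverted-cone tip accumulation ramping up from the transition phase.
* ``actin`` -- cortical band with a von-Mises angular intensity profile
  peaked at the scheduled polarity angle (opposite the germination site by
  default), plus longitudinal cables after the scheduled onset.
* ``sperm_nuclei`` / ``sperm_membrane`` -- two nuclear blobs and a thin
  membrane-extension curve whose tip crosses the grain boundary at the
  scheduled translocation frame and stays outside.
* ``brightfield`` -- simple edge-enhanced rendering for visual QC only.

Every rendered feature has a ground-truth record, so downstream detectors
can be scored without real microscope data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, sobel
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

from ._geom import polygon_roundness, rasterize
from .growth_models import (
    BulgingParams,
    GrainGeometry,
    ProtrusionParams,
    shape_fn,
)

__all__ = [
    "AcquisitionSpec",
    "ChannelSpec",
    "VesiclePeak",
    "EventSchedule",
    "RegionSchedule",
    "GroundTruth",
    "TimeLapse",
    "DEFAULT_CHANNELS",
    "schedule_from_params",
    "render_timelapse",
    "render_abnormal_scenario",
]

CHANNEL_NAMES = (
    "cytoplasm",
    "vesicle",
    "actin",
    "sperm_nuclei",
    "sperm_membrane",
    "brightfield",
)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging geometry and camera noise of one acquisition."""

    pixel_size: float = 0.33  # um/px
    frame_interval: float = 3.0  # min
    n_slices: int = 11
    z_spacing: float = 0.8  # um
    gaussian_sd: float = 8.0  # read noise, counts
    poisson_scale: float = 1.0  # photons per count; 0 disables shot noise
    frame_shape: tuple[int, int] = (512, 512)  # (Y, X) px
    origin: tuple[float, float] = (-84.48, -84.48)  # world coords of px (0,0) corner
    z_blur_px_per_um: float = 0.6  # blur sigma growth with defocus distance
    z_attenuation_um: float = 2.5  # confocal sectioning: out-of-focus falloff scale

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @classmethod
    def centered(cls, pixel_size: float = 0.33, frame_shape: tuple[int, int] = (512, 512), **kwargs) -> "AcquisitionSpec":
        """Acquisition whose field of view is centered on the world origin."""
        ny, nx = frame_shape
        origin = (-nx * pixel_size / 2.0, -ny * pixel_size / 2.0)
        return cls(pixel_size=pixel_size, frame_shape=frame_shape, origin=origin, **kwargs)


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel: a marker name and its baseline intensity."""

    name: str
    baseline: float = 1000.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.name!r}; use one of {CHANNEL_NAMES}")
        if self.baseline < 0:
            raise ValueError("baseline intensity must be >= 0")


DEFAULT_CHANNELS = {
    "cytoplasm": ChannelSpec("cytoplasm", 1000.0),
    "vesicle": ChannelSpec("vesicle", 400.0),
    "actin": ChannelSpec("actin", 600.0),
    "sperm_nuclei": ChannelSpec("sperm_nuclei", 800.0),
    "sperm_membrane": ChannelSpec("sperm_membrane", 700.0),
    "brightfield": ChannelSpec("brightfield", 2000.0),
}


@dataclass(frozen=True)
class VesiclePeak:
    """A transient vesicle-accumulation event near the grain cortex."""

    time_min: float  # relative to germination; negative = before
    angle: float  # radians (direction from grain center)
    amplitude: float = 5.0  # peak intensity, in units of the channel baseline
    sigma_um: float = 1.2


@dataclass
class EventSchedule:
    """Scheduled marker events of one tube, in germination-relative minutes."""

    vesicle_peaks: list[VesiclePeak] = field(default_factory=list)
    actin_polarity_angle: float | None = None  # default: opposite germination
    actin_onset_time_min: float | None = None  # longitudinal cables appear
    mgu_time_min: float | None = None  # sperm membrane tip exits the grain
    tip_cone: bool = True
    cone_amplitude: float = 6.0  # x baseline at full ramp
    cone_depth_um: float = 3.0
    cone_ramp_frames: int = 4
    tip_amplitude_schedule: np.ndarray | None = None  # per-frame override


@dataclass
class RegionSchedule:
    """Precomputed per-frame tube regions with timing annotations."""

    regions: list[BaseGeometry]
    germination_frame: int
    transition_frame: int | None = None


@dataclass
class GroundTruth:
    """True per-frame geometry and scheduled events of a rendered tube."""

    time_min: np.ndarray
    area_um2: np.ndarray
    roundness: np.ndarray
    germination_frame: int
    germination_angle: float
    grain: GrainGeometry
    peak_events: list[tuple[int, float, float]]  # (frame, angle, amplitude)
    actin_polarity_angle: float | None = None
    actin_onset_frame: int | None = None
    mgu_frame: int | None = None
    mgu_area_um2: float | None = None
    transition_frame: int | None = None
    scenario: str = "normal"
    germination_events: list[tuple[int, float]] = field(default_factory=list)
    branch_frame: int | None = None


@dataclass
class TimeLapse:
    """Multi-channel image data with axes T, Z, Y, X per named channel."""

    channels: dict[str, np.ndarray]
    acq: AcquisitionSpec

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels must share T,Z,Y,X extents, got {shapes}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]


def schedule_from_params(
    grain: GrainGeometry,
    params: ProtrusionParams | BulgingParams,
    n_frames: int,
    germination_frame: int = 2,
) -> RegionSchedule:
    """Expand growth-model parameters into per-frame tube regions.

    The model's frame 1 (first non-empty shape) is placed at
    ``germination_frame`` of the acquisition.
    """
    fn = shape_fn(params)
    regions = []
    for f in range(n_frames):
        rel = f - germination_frame + 1
        regions.append(fn(grain, max(rel, 0)).region)
    transition = None
    if isinstance(params, BulgingParams):
        transition = germination_frame - 1 + params.bulge_frames
    return RegionSchedule(regions, germination_frame, transition)


def _ellipse_boundary_point(grain: GrainGeometry, angle: float, inward: float = 0.0) -> np.ndarray:
    a, b = grain.semi_major, grain.semi_minor
    r = a * b / np.hypot(b * np.cos(angle), a * np.sin(angle))
    return np.array(grain.center) + (r - inward) * np.array(
        [np.cos(angle), np.sin(angle)]
    )


def _tip_point(region: BaseGeometry, grain: GrainGeometry) -> np.ndarray | None:
    """Distal point of the tube region along the germination axis."""
    if region is None or region.is_empty:
        return None
    base = grain.germination_point()
    u = grain.outward_direction()
    coords = _region_coords(region)
    proj = (coords - base) @ u
    return coords[int(np.argmax(proj))]


def _region_coords(region: BaseGeometry) -> np.ndarray:
    geoms = getattr(region, "geoms", [region])
    pts = []
    for g in geoms:
        if isinstance(g, Polygon):
            pts.append(np.asarray(g.exterior.coords))
    return np.vstack(pts) if pts else np.zeros((1, 2))


class _FrameCanvas:
    """Accumulates intensity primitives for one frame of one channel."""

    def __init__(self, acq: AcquisitionSpec):
        self.acq = acq
        ny, nx = acq.frame_shape
        self.img = np.zeros((ny, nx), dtype=np.float64)
        self._xs = acq.origin[0] + (np.arange(nx) + 0.5) * acq.pixel_size
        self._ys = acq.origin[1] + (np.arange(ny) + 0.5) * acq.pixel_size

    def add_mask(self, mask_or_geom, intensity: float) -> None:
        if isinstance(mask_or_geom, np.ndarray):
            self.img += intensity * mask_or_geom
        elif mask_or_geom is not None and not mask_or_geom.is_empty:
            self.img += intensity * rasterize(
                mask_or_geom, self.acq.frame_shape, self.acq.pixel_size, self.acq.origin
            )

    def add_gaussian(self, center: np.ndarray, sigma_um: float, peak: float) -> None:
        dx = (self._xs - center[0]) / sigma_um
        dy = (self._ys - center[1]) / sigma_um
        self.img += peak * np.exp(-0.5 * (dy[:, None] ** 2 + dx[None, :] ** 2))

    def add_line(self, coords: np.ndarray, width_um: float, intensity: float) -> None:
        geom = LineString(coords).buffer(width_um / 2.0, quad_segs=8)
        self.add_mask(geom, intensity)


def _zstack(base: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    """Replicate a focal-plane image across z with defocus blur and falloff.

    Out-of-focus slices are blurred with a sigma growing linearly with the
    defocus distance and attenuated with a Gaussian falloff
    (``z_attenuation_um``), emulating the optical sectioning of a spinning-
    disc confocal; the focal slice is passed through unchanged.
    """
    focus = (acq.n_slices - 1) / 2.0
    slices = []
    for s in range(acq.n_slices):
        dz = abs(s - focus) * acq.z_spacing
        sigma = acq.z_blur_px_per_um * dz
        atten = (
            float(np.exp(-0.5 * (dz / acq.z_attenuation_um) ** 2))
            if acq.z_attenuation_um > 0
            else 1.0
        )
        slices.append(base * atten if sigma == 0 else gaussian_filter(base, sigma) * atten)
    return np.stack(slices)


def _apply_noise(stack: np.ndarray, acq: AcquisitionSpec, rng: np.random.Generator) -> np.ndarray:
    out = stack
    if acq.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0.0) * acq.poisson_scale) / acq.poisson_scale
    if acq.gaussian_sd > 0:
        out = out + rng.normal(0.0, acq.gaussian_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def render_timelapse(
    grain: GrainGeometry,
    growth: ProtrusionParams | BulgingParams | RegionSchedule,
    channels: list[ChannelSpec] | list[str],
    acq: AcquisitionSpec,
    events: EventSchedule | None = None,
    seed: int = 0,
    n_frames: int | None = None,
    germination_frame: int = 2,
    scenario: str = "normal",
) -> tuple[TimeLapse, GroundTruth]:
    """Render a multi-channel z-stack time-lapse with its ground truth.

    ``growth`` is either a growth-model parameter set (expanded via
    :func:`schedule_from_params`) or a precomputed :class:`RegionSchedule`.
    ``seed`` fixes all randomness; a fixed seed yields bit-identical output.
    """
    events = events or EventSchedule()
    specs = [
        c if isinstance(c, ChannelSpec) else DEFAULT_CHANNELS[c] for c in channels
    ]
    if isinstance(growth, RegionSchedule):
        schedule = growth
        n_frames = len(schedule.regions)
    else:
        if n_frames is None:
            n_frames = growth.n_frames + germination_frame
        schedule = schedule_from_params(grain, growth, n_frames, germination_frame)
    g = schedule.germination_frame
    dt = acq.frame_interval
    time_min = (np.arange(n_frames) - (g - 1)) * dt  # t=0 at last pre-emergence frame

    def frame_of(t_rel_min: float) -> int:
        return int(round(t_rel_min / dt)) + (g - 1)

    for pk in events.vesicle_peaks:
        f = frame_of(pk.time_min)
        if not 0 <= f < n_frames:
            raise ValueError(
                f"vesicle peak at {pk.time_min} min maps to frame {f}, "
                f"outside the 0..{n_frames - 1} frame range"
            )
    transition = schedule.transition_frame
    actin_onset = (
        frame_of(events.actin_onset_time_min)
        if events.actin_onset_time_min is not None
        else None
    )
    mgu_frame = (
        frame_of(events.mgu_time_min) if events.mgu_time_min is not None else None
    )
    if mgu_frame is not None and not 0 <= mgu_frame < n_frames:
        raise ValueError(f"MGU translocation frame {mgu_frame} outside frame range")

    rng = np.random.default_rng(seed)
    grain_poly = grain.polygon()
    grain_mask = rasterize(grain_poly, acq.frame_shape, acq.pixel_size, acq.origin)
    band_geom = grain_poly.difference(grain_poly.buffer(-1.2))
    band_mask = rasterize(band_geom, acq.frame_shape, acq.pixel_size, acq.origin)
    polarity = (
        events.actin_polarity_angle
        if events.actin_polarity_angle is not None
        else grain.germination_angle + np.pi
    )
    areas = np.zeros(n_frames)
    roundness = np.full(n_frames, np.nan)
    out = {
        spec.name: np.empty(
            (n_frames, acq.n_slices, *acq.frame_shape), dtype=np.uint16
        )
        for spec in specs
    }
    gp = grain.germination_point()
    u = grain.outward_direction()
    peak_records: list[tuple[int, float, float]] = []
    for pk in events.vesicle_peaks:
        peak_records.append((frame_of(pk.time_min), pk.angle, pk.amplitude))
    # precompute cortical angular weight map for the actin channel
    ny, nx = acq.frame_shape
    xs = acq.origin[0] + (np.arange(nx) + 0.5) * acq.pixel_size
    ys = acq.origin[1] + (np.arange(ny) + 0.5) * acq.pixel_size
    theta = np.arctan2(ys[:, None] - grain.center[1], xs[None, :] - grain.center[0])
    kappa = 3.0
    vm = np.exp(kappa * (np.cos(theta - polarity) - 1.0))

    for f in range(n_frames):
        region = schedule.regions[f]
        areas[f] = 0.0 if region is None or region.is_empty else region.area
        roundness[f] = polygon_roundness(region) if areas[f] > 0 else np.nan
        tube_mask = rasterize(region, acq.frame_shape, acq.pixel_size, acq.origin)
        cell_mask = grain_mask | tube_mask
        tip = _tip_point(region, grain)
        for spec in specs:
            canvas = _FrameCanvas(acq)
            b = spec.baseline
            if spec.name == "cytoplasm":
                canvas.add_mask(cell_mask, b)
            elif spec.name == "vesicle":
                canvas.add_mask(cell_mask, 0.15 * b)
                for pk in events.vesicle_peaks:
                    pf = frame_of(pk.time_min)
                    w = {0: 1.0, 1: 0.35}.get(abs(f - pf), 0.0)
                    if w > 0:
                        pos = _ellipse_boundary_point(grain, pk.angle, inward=1.0)
                        canvas.add_gaussian(pos, pk.sigma_um, w * pk.amplitude * b)
                cone_w = _cone_weight(f, transition, events, n_frames)
                if cone_w > 0 and tip is not None:
                    cone = _inverted_cone(tip, u, events.cone_depth_um)
                    cone_mask = rasterize(
                        cone, acq.frame_shape, acq.pixel_size, acq.origin
                    )
                    canvas.add_mask(
                        cone_mask & cell_mask, cone_w * events.cone_amplitude * b
                    )
            elif spec.name == "actin":
                fade = 1.0 if (transition is None or f < transition) else 0.3
                canvas.img += band_mask * b * (0.25 + 1.5 * vm) * fade
                if actin_onset is not None and f >= actin_onset and tip is not None:
                    for off in (-1.2, 0.0, 1.2):
                        n_vec = np.array([-u[1], u[0]])
                        start = np.array(grain.center) + off * n_vec
                        end = tip - 1.0 * u + off * n_vec
                        canvas.add_line(np.vstack([start, end]), 0.5, 2.0 * b)
            elif spec.name == "sperm_nuclei":
                for off in (-2.0, 2.0):
                    n_vec = np.array([-u[1], u[0]])
                    pos = np.array(grain.center) + off * n_vec
                    if mgu_frame is not None and f >= mgu_frame:
                        pos = pos + min(1.5 * (f - mgu_frame), 8.0) * u
                    canvas.add_gaussian(pos, 1.5, b)
            elif spec.name == "sperm_membrane":
                tip_m = _membrane_tip(grain, f, mgu_frame, tip)
                coords = np.vstack([np.array(grain.center), tip_m])
                canvas.add_line(coords, 0.7, 1.5 * b)
                canvas.add_gaussian(tip_m, 0.6, 1.5 * b)
            elif spec.name == "brightfield":
                edges = np.hypot(
                    sobel(cell_mask.astype(float), 0), sobel(cell_mask.astype(float), 1)
                )
                canvas.img += 0.5 * b + 0.25 * b * edges
            stack = _zstack(canvas.img, acq)
            out[spec.name][f] = _apply_noise(stack, acq, rng)

    gt = GroundTruth(
        time_min=time_min,
        area_um2=areas,
        roundness=roundness,
        germination_frame=g,
        germination_angle=grain.germination_angle,
        grain=grain,
        peak_events=peak_records,
        actin_polarity_angle=polarity,
        actin_onset_frame=actin_onset,
        mgu_frame=mgu_frame,
        mgu_area_um2=float(areas[mgu_frame]) if mgu_frame is not None else None,
        transition_frame=transition,
        scenario=scenario,
        germination_events=[(g, grain.germination_angle)],
    )
    return TimeLapse(out, acq), gt


def _cone_weight(
    f: int, transition: int | None, events: EventSchedule, n_frames: int
) -> float:
    if events.tip_amplitude_schedule is not None:
        return float(events.tip_amplitude_schedule[f])
    if not events.tip_cone or transition is None:
        return 0.0
    return float(np.clip((f - transition + 1) / events.cone_ramp_frames, 0.0, 1.0))


def _inverted_cone(tip: np.ndarray, u: np.ndarray, depth: float, width: float = 5.5) -> Polygon:
    n = np.array([-u[1], u[0]])
    return Polygon(
        [tip + 0.5 * width * n, tip - 0.5 * width * n, tip - depth * u]
    )


def _membrane_tip(
    grain: GrainGeometry, f: int, mgu_frame: int | None, tube_tip: np.ndarray | None
) -> np.ndarray:
    gp = grain.germination_point()
    u = grain.outward_direction()
    if mgu_frame is None or f < mgu_frame:
        return gp - 2.0 * u  # inside the grain, pointing at the germination site
    dist = 1.0 + 1.2 * (f - mgu_frame)
    tip_m = gp + dist * u
    if tube_tip is not None:
        max_d = float((tube_tip - gp) @ u) - 1.0
        if max_d > 0:
            tip_m = gp + min(dist, max_d) * u
    return tip_m


def render_abnormal_scenario(
    kind: str,
    grain: GrainGeometry | None = None,
    acq: AcquisitionSpec | None = None,
    channels: list[str] | None = None,
    seed: int = 0,
    n_frames: int = 24,
) -> tuple[TimeLapse, GroundTruth]:
    """Render one of the rare abnormal germination patterns.

    * ``arrest`` -- the bulge stops growing and the vesicle signal decays to
      at most 10% of its maximum.
    * ``second_tube`` -- the first bulge arrests; a second germination site
      at a distant angle later proceeds to rapid growth.
    * ``branching`` -- the tip signal relocates to a second growth site on
      the bulge, giving two simultaneous tip ROIs.
    """
    if kind not in ("arrest", "second_tube", "branching"):
        raise ValueError(f"unknown scenario {kind!r}")
    grain = grain or GrainGeometry(center=(30.0, 42.0))
    acq = acq or AcquisitionSpec(
        pixel_size=0.5, frame_shape=(168, 256), origin=(0.0, 0.0), n_slices=5
    )
    channels = channels or ["cytoplasm", "vesicle"]
    g = 4
    rng = np.random.default_rng(seed)
    theta1 = grain.germination_angle
    base_grain = grain

    def bulge_regions(grain_, n, g_, r_max, grow_frames):
        out = []
        for f in range(n):
            rel = f - g_ + 1
            r = r_max * min(max(rel, 0), grow_frames) / grow_frames
            if r <= 0:
                out.append(Polygon())
                continue
            base = grain_.germination_point()
            u_ = grain_.outward_direction()
            out.append(
                Point(base + r * u_).buffer(r, quad_segs=90).difference(grain_.polygon())
            )
        return out

    if kind == "arrest":
        regions = bulge_regions(base_grain, n_frames, g, 2.75, 5)
        amp = np.zeros(n_frames)
        peak_f = g + 5
        for f in range(n_frames):
            if f <= peak_f:
                amp[f] = max(0.0, (f - g + 1) / 6.0)
            else:
                amp[f] = max(0.05, 1.0 * 0.45 ** (f - peak_f))  # decays below 10%
        events = EventSchedule(
            vesicle_peaks=[VesiclePeak(-6.0, theta1, 4.0)],
            tip_amplitude_schedule=amp,
            cone_amplitude=6.0,
        )
        schedule = RegionSchedule(regions, g, transition_frame=None)
        tl, gt = render_timelapse(
            base_grain, schedule, channels, acq, events, seed=seed, scenario="arrest"
        )
        return tl, gt

    if kind == "second_tube":
        theta2 = theta1 + np.deg2rad(120.0)
        grain2 = dataclasses.replace(base_grain, germination_angle=theta2)
        g2 = g + 8
        first = bulge_regions(base_grain, n_frames, g, 2.2, 4)
        second = _capsule_schedule(grain2, n_frames, g2, 2.75, 4, 2.5)
        regions = [a.union(b) for a, b in zip(first, second)]
        amp = np.zeros(n_frames)
        amp[g : g + 4] = np.linspace(0.3, 0.8, 4)
        events = EventSchedule(
            vesicle_peaks=[
                VesiclePeak(-6.0, theta1, 4.0),
                # second polarization event, just before the second germination
                VesiclePeak((g2 - g) * acq.frame_interval, theta2, 5.0),
            ],
            tip_amplitude_schedule=amp,
        )
        schedule = RegionSchedule(regions, g, transition_frame=None)
        tl, gt = render_timelapse(
            base_grain, schedule, channels, acq, events, seed=seed,
            scenario="second_tube",
        )
        gt.germination_events = [(g, theta1), (g2, theta2)]
        return tl, gt

    # branching: bulge, short tube, then a second tip on the bulge
    theta_b = theta1 + np.deg2rad(40.0)
    regions = []
    branch_frame = g + 8
    bulge = bulge_regions(base_grain, n_frames, g, 2.75, 5)
    main = _capsule_schedule(base_grain, n_frames, g + 5, 2.75, 0, 1.2)
    grain_b = dataclasses.replace(base_grain, germination_angle=theta_b)
    branch = _capsule_schedule(grain_b, n_frames, branch_frame, 2.75, 0, 1.8)
    for f in range(n_frames):
        r = bulge[f].union(main[f]).union(branch[f])
        regions.append(r)
    amp = np.clip((np.arange(n_frames) - g - 3) / 4.0, 0.0, 1.0)
    events = EventSchedule(
        vesicle_peaks=[VesiclePeak(-6.0, theta1, 4.0)],
        tip_amplitude_schedule=amp,
    )
    schedule = RegionSchedule(regions, g, transition_frame=g + 5)
    tl, gt = render_timelapse(
        base_grain, schedule, channels, acq, events, seed=seed, scenario="branching"
    )
    gt.branch_frame = branch_frame
    # render the second tip accumulation into the vesicle channel directly
    if "vesicle" in tl.channels:
        rng2 = np.random.default_rng(seed + 1)
        spec = DEFAULT_CHANNELS["vesicle"]
        for f in range(branch_frame, n_frames):
            tip_b = _tip_point(branch[f], grain_b)
            if tip_b is None:
                continue
            canvas = _FrameCanvas(acq)
            canvas.add_gaussian(tip_b, 1.0, 5.0 * spec.baseline)
            stack = _zstack(canvas.img, acq)
            extra = _apply_noise(stack, acq, rng2).astype(np.uint32)
            tl.channels["vesicle"][f] = np.clip(
                tl.channels["vesicle"][f].astype(np.uint32) + extra, 0, 65535
            ).astype(np.uint16)
    return tl, gt


def _capsule_schedule(
    grain: GrainGeometry,
    n_frames: int,
    start_frame: int,
    radius: float,
    bulge_grow_frames: int,
    elongation_per_frame: float,
) -> list[BaseGeometry]:
    """Bulge growing to ``radius`` then a round-capped capsule elongating."""
    out = []
    base = grain.germination_point()
    u = grain.outward_direction()
    gpoly = grain.polygon()
    for f in range(n_frames):
        rel = f - start_frame + 1
        if rel <= 0:
            out.append(Polygon())
            continue
        if bulge_grow_frames > 0 and rel <= bulge_grow_frames:
            r = radius * rel / bulge_grow_frames
            out.append(Point(base + r * u).buffer(r, quad_segs=90).difference(gpoly))
            continue
        length = elongation_per_frame * (rel - bulge_grow_frames)
        c0 = base + radius * u
        seg = LineString([c0, c0 + length * u])
        out.append(seg.buffer(radius, quad_segs=90).difference(gpoly))
    return out
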