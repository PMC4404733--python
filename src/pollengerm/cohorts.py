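"""Calibrated synthetic cohorts of germinating pollen tubes.

A cohort emulates the study conditions of a live-imaging experiment: each
tube germinates after a short pre-germination interval, grows a slowly
inflating bulge, passes a transition, and switches to rapid tip growth.
Frames are 3 min apart and each time point is an 11-slice z-stack.

Because the slow-phase area, the late-window increase, and the hourly
cumulative rate reported for real cohorts are not mutually consistent under
a single schedule, each cohort is calibrated to exactly one target quantity
(see :func:`kinetics_cohort`); tube-to-tube variability is multiplicative
log-normal-like jitter around the calibrated schedule.

Geometry: the bulge is a circle anchored at the germination site whose area
grows linearly (radius ~ sqrt(time)) during the slow phase, inflates to half
the tube width at the transition, and then continues as a round-capped
capsule of constant width, so the area course is continuous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .growth_models import GrainGeometry
from .synthetic_microscopy import (
    AcquisitionSpec,
    EventSchedule,
    GroundTruth,
    RegionSchedule,
    TimeLapse,
    VesiclePeak,
    render_timelapse,
)

__all__ = [
    "COHORT_ACQ",
    "TubeSchedule",
    "build_tube_schedule",
    "kinetics_cohort",
    "vesicle_peak_cohort",
]

#: Cohort imaging geometry: 256 x 128 px frames at 0.5 um/px leave room for
#: an hour of rapid growth while keeping cohort renders tractable.
COHORT_ACQ = AcquisitionSpec(
    pixel_size=0.5,
    frame_shape=(128, 288),
    origin=(0.0, 0.0),
    n_slices=11,
)

TUBE_WIDTH = 5.5  # um; dome/tube width of the default cohort schedule
SLOW_FRAMES = 5  # bulge area grows linearly for 5 frames (15 min)
TRANSITION_FRAMES = 3  # radius inflates to tube_width/2 over 3 more frames


@dataclass
class TubeSchedule:
    """Vector growth schedule of one cohort tube."""

    grain: GrainGeometry
    schedule: RegionSchedule
    area_um2: np.ndarray  # ground-truth area per frame
    rapid_rate: float  # um^2 per frame during rapid growth


def _bulge_or_capsule(
    grain: GrainGeometry, r: float, length: float, width: float
) -> Polygon:
    base = grain.germination_point()
    u = grain.outward_direction()
    if length <= 0:
        return Point(base + r * u).buffer(r, quad_segs=90).difference(grain.polygon())
    c0 = base + (width / 2.0) * u
    seg = LineString([c0, c0 + length * u])
    return seg.buffer(width / 2.0, quad_segs=90).difference(grain.polygon())


def build_tube_schedule(
    grain: GrainGeometry,
    n_frames: int,
    germination_frame: int,
    area_15min: float,
    rapid_rate_um2_per_frame: float,
    tube_width: float = TUBE_WIDTH,
) -> TubeSchedule:
    """Per-frame tube regions following the slow-bulge/fast-rapid schedule.

    The bulge area rises linearly to ``area_15min`` over the first
    ``SLOW_FRAMES`` post-emergence frames, the radius then inflates to
    ``tube_width / 2`` over ``TRANSITION_FRAMES`` frames, after which a
    capsule elongates at ``rapid_rate_um2_per_frame / tube_width`` um/frame.
    """
    g = germination_frame
    r15 = float(np.sqrt(area_15min / np.pi))
    r_trans = tube_width / 2.0
    if r15 > r_trans:
        r15 = r_trans  # very large slow-phase targets merge into the capsule
    regions = []
    areas = np.zeros(n_frames)
    v = rapid_rate_um2_per_frame / tube_width  # um per frame of tip advance
    for f in range(n_frames):
        rel = f - g + 1
        if rel <= 0:
            regions.append(Polygon())
            continue
        if rel <= SLOW_FRAMES:
            r = r15 * np.sqrt(rel / SLOW_FRAMES)
            geom = _bulge_or_capsule(grain, r, 0.0, tube_width)
        elif rel <= SLOW_FRAMES + TRANSITION_FRAMES:
            r = r15 + (r_trans - r15) * (rel - SLOW_FRAMES) / TRANSITION_FRAMES
            geom = _bulge_or_capsule(grain, r, 0.0, tube_width)
        else:
            length = v * (rel - SLOW_FRAMES - TRANSITION_FRAMES)
            geom = _bulge_or_capsule(grain, r_trans, length, tube_width)
        regions.append(geom)
        areas[f] = geom.area
    schedule = RegionSchedule(
        regions, g, transition_frame=g + SLOW_FRAMES + TRANSITION_FRAMES - 1
    )
    return TubeSchedule(grain, schedule, areas, rapid_rate_um2_per_frame)


def _calibrated_rapid_rate(calibration: tuple[str, float], frame_interval: float = 3.0) -> float:
    """Rapid-phase rate (um^2/frame) hitting exactly one cohort target."""
    mode, target = calibration
    w = TUBE_WIDTH
    r = w / 2.0
    a_trans = np.pi * r**2  # capsule area at zero length
    frames_per_hour = 60.0 / frame_interval
    rapid_frames_to_60 = frames_per_hour - SLOW_FRAMES - TRANSITION_FRAMES
    if mode == "rate_at_60":
        return float((target - a_trans) / rapid_frames_to_60)
    if mode == "late_window":
        # target is the area increase over the 45-60 min window (5 frames)
        return float(target / (15.0 / frame_interval))
    if mode == "rate":
        return float(target)
    raise ValueError(f"unknown calibration mode {calibration[0]!r}")


def _cohort_grain(rng: np.random.Generator) -> GrainGeometry:
    return GrainGeometry(
        semi_major=float(np.clip(rng.normal(12.5, 0.5), 11.0, 14.0)),
        semi_minor=float(np.clip(rng.normal(10.0, 0.4), 8.8, 11.0)),
        # centered off the pixel grid so straight tube edges cannot align
        # exactly with pixel-center rows (a degenerate rasterization case)
        center=(24.0 + float(rng.uniform(0.05, 0.45)), 32.1),
        germination_angle=float(rng.normal(0.0, np.deg2rad(6.0))),
    )


def kinetics_cohort(
    n_tubes: int = 66,
    seed: int = 0,
    calibration: tuple[str, float] = ("rate_at_60", 400.2),
    area_15min: float = 16.7,
    jitter: float = 0.15,
    n_post_frames: int = 22,
    acq: AcquisitionSpec = COHORT_ACQ,
    channels: tuple[str, ...] = ("cytoplasm",),
    event: tuple[str, float] | None = None,
):
    """Yield ``(TimeLapse, GroundTruth)`` for a slow-then-fast cohort.

    ``calibration`` fixes the rapid-phase rate so that, at the cohort mean,
    exactly one quantity hits its target: ``("rate_at_60", X)`` sets the
    cumulative area at 60 min post-germination to X um^2;
    ``("late_window", X)`` sets the 45-60 min area increase to X um^2;
    ``("rate", X)`` uses X um^2/frame directly. ``area_15min`` is the mean
    slow-phase area reached 15 min after emergence. Per-tube rates are
    jittered multiplicatively (sd ``jitter``, clipped to [0.6, 1.4]).

    ``event`` schedules a marker event at the frame whose ground-truth area
    is closest to the stated target: ``("actin", 300.0)`` records the F-actin
    bundling onset, ``("mgu", 350.0)`` schedules the male-germ-unit
    translocation (rendering requires the sperm channels for the latter).
    """
    rng = np.random.default_rng(seed)
    base_rate = _calibrated_rapid_rate(calibration, acq.frame_interval)
    for i in range(n_tubes):
        grain = _cohort_grain(rng)
        g = int(rng.integers(2, 4))
        m_rate = float(np.clip(rng.normal(1.0, jitter), 0.6, 1.4))
        m_early = float(np.clip(rng.normal(1.0, jitter), 0.6, 1.4))
        n_frames = g + n_post_frames
        tube = build_tube_schedule(
            grain,
            n_frames,
            g,
            area_15min * m_early,
            base_rate * m_rate,
        )
        events = EventSchedule(tip_cone="vesicle" in channels)
        gt_extra = {}
        if event is not None:
            kind, target = event
            frame = int(np.argmin(np.abs(tube.area_um2 - target)))
            if kind == "actin":
                events.actin_onset_time_min = float(
                    (frame - (g - 1)) * acq.frame_interval
                )
            elif kind == "mgu":
                events.mgu_time_min = float((frame - (g - 1)) * acq.frame_interval)
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        tl, gt = render_timelapse(
            grain,
            tube.schedule,
            list(channels),
            acq,
            events,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        yield tl, gt


def vesicle_peak_cohort(
    n_tubes: int = 30,
    n_concordant: int = 25,
    seed: int = 0,
    acq: AcquisitionSpec = COHORT_ACQ,
    amplitude: float = 5.0,
    n_post_frames: int = 4,
):
    """Yield ``(TimeLapse, GroundTruth)`` for a pre-germination peak cohort.

    In ``n_concordant`` of ``n_tubes`` grains, one or two high-intensity
    vesicle peaks (amplitude x baseline, default 5) are injected within 25
    degrees of the germination angle between -20 and -3 min; the remaining
    grains receive a peak on the opposite side of the grain instead, so every
    grain shows pre-germination vesicle activity but only the known subset is
    site-concordant. Cytoplasm and vesicle channels are rendered.
    """
    rng = np.random.default_rng(seed)
    concordant_flags = np.zeros(n_tubes, dtype=bool)
    concordant_flags[:n_concordant] = True
    rng.shuffle(concordant_flags)
    peak_times = (-18.0, -15.0, -12.0, -9.0, -6.0)
    for i in range(n_tubes):
        grain = _cohort_grain(rng)
        g = 8  # frame 0 sits 21 min before germination
        n_frames = g + n_post_frames
        tube = build_tube_schedule(grain, n_frames, g, 16.7, 5.0)
        peaks = []
        if concordant_flags[i]:
            n_peaks = 1 + int(rng.random() < 0.5)
            times = sorted(rng.choice(peak_times, size=n_peaks, replace=False))
            if n_peaks == 2 and times[1] - times[0] < 6.0:
                times = [times[0], times[0] + 6.0]
            for t in times:
                lim = np.deg2rad(25.0)
                ang = grain.germination_angle + float(
                    np.clip(rng.normal(0.0, np.deg2rad(8.0)), -lim, lim)
                )
                peaks.append(VesiclePeak(float(t), ang, amplitude))
        else:
            ang = grain.germination_angle + np.pi + float(rng.normal(0.0, np.deg2rad(15.0)))
            peaks.append(VesiclePeak(float(rng.choice(peak_times)), ang, amplitude))
        events = EventSchedule(vesicle_peaks=peaks, tip_cone=False)
        tl, gt = render_timelapse(
            grain,
            tube.schedule,
            ["cytoplasm", "vesicle"],
            acq,
            events,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        gt.scenario = "concordant" if concordant_flags[i] else "discordant"
        yield tl, gt
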