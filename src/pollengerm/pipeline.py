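"""End-to-end analysis of one tube or a cohort of time-lapse stacks.

The measurement chain mirrors the classical workflow: the cytoplasm channel
is maximum-intensity projected, binarized at a global (Otsu) threshold
pooled over the tube's frames, the grain area (from the first frame, before
emergence) is subtracted, and the remaining tube region is measured per
frame. The vesicle channel is quantified with the per-tube stack-histogram
thresholds (brightest 70% for shape, 0.5% for intensity peaks); actin
polarity and MGU translocation are analyzed when their channels are
present, and skipped otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import kinetics, polarization, segmentation
from .kinetics import GrowthTrack
from .polarization import MGUEvent, PeakEvent, PolarityProfile
from .segmentation import RegionMeasurement, StackThresholds
from .synthetic_microscopy import TimeLapse

__all__ = ["TubeAnalysis", "CohortStats", "analyze_tube", "cohort_stats"]


@dataclass
class TubeAnalysis:
    """All per-tube pipeline outputs."""

    tube_id: str
    track: GrowthTrack
    measurements: list[RegionMeasurement]
    grain_mask: np.ndarray
    shape_threshold: float
    germination_direction: float | None  # radians, estimated from images
    vesicle_thresholds: StackThresholds | None = None
    peak_series: pd.DataFrame | None = None
    peak_events: list[PeakEvent] = field(default_factory=list)
    polarity: PolarityProfile | None = None
    mgu: MGUEvent | None = None
    skipped: list[str] = field(default_factory=list)

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for m, t in zip(self.measurements, self.track.time_min):
            rows.append(
                {
                    "frame": m.frame_index,
                    "time_min": float(t),
                    "area_um2": m.area,
                    "major_axis_um": m.major_axis,
                    "roundness": m.roundness,
                    "junction_width_um": m.junction_width,
                    "tube_length_um": m.tube_length,
                }
            )
        return pd.DataFrame(rows)


def _estimate_germination_direction(
    measurements: list[RegionMeasurement],
    track: GrowthTrack,
    grain_mask: np.ndarray,
) -> float | None:
    """Direction from the grain centroid to the early tube centroid."""
    if not track.germinated:
        return None
    gy, gx = np.argwhere(grain_mask).mean(axis=0)
    post = track.post_germination()
    pts = []
    for i in post[:3]:
        c = measurements[i].centroid
        if np.isfinite(c[0]):
            pts.append(c)
    if not pts:
        return None
    cy, cx = np.mean(pts, axis=0)
    return float(np.arctan2(cy - gy, cx - gx))


def analyze_tube(
    tl: TimeLapse,
    tube_id: str = "tube",
    min_area_px: int = 10,
    measure_tube_length: bool = False,
    unobstructed: bool = True,
) -> TubeAnalysis:
    """Run the full measurement chain on one multi-channel time-lapse.

    Requires a ``cytoplasm`` channel; vesicle/actin/sperm analyses run only
    when their channels are present and are otherwise recorded in
    ``skipped``.
    """
    if "cytoplasm" not in tl.channels:
        raise ValueError("analysis requires a 'cytoplasm' channel")
    acq = tl.acq
    proj = segmentation.project(tl.channels["cytoplasm"], "max")
    thr = float(threshold_otsu(proj.ravel()))
    grain_mask = segmentation.extract_grain_mask(proj[0], thr)
    measurements = []
    for f in range(proj.shape[0]):
        mask = segmentation.binarize_and_extract(proj[f], thr, grain_mask)
        m = segmentation.measure_region(
            mask,
            acq.pixel_size,
            grain_mask=grain_mask,
            frame_index=f,
            tube_length=measure_tube_length,
        )
        measurements.append(m)
    track = kinetics.build_track(
        measurements,
        acq.pixel_size,
        frame_interval=acq.frame_interval,
        min_area_px=min_area_px,
        tube_id=tube_id,
        unobstructed=unobstructed,
    )
    germ_dir = _estimate_germination_direction(measurements, track, grain_mask)
    analysis = TubeAnalysis(
        tube_id=tube_id,
        track=track,
        measurements=measurements,
        grain_mask=grain_mask,
        shape_threshold=thr,
        germination_direction=germ_dir,
    )
    gy, gx = np.argwhere(grain_mask).mean(axis=0) if grain_mask.any() else (0.0, 0.0)
    if "vesicle" in tl.channels:
        vproj = segmentation.project(tl.channels["vesicle"], "max")
        vthr = segmentation.compute_thresholds(vproj)
        series = polarization.peak_series(
            vproj, vthr, (gy, gx), time_min=track.time_min
        )
        analysis.vesicle_thresholds = vthr
        analysis.peak_series = series
        if germ_dir is not None:
            analysis.peak_events = polarization.detect_peaks(series, germ_dir)
        else:
            analysis.skipped.append("peak_events (no germination direction)")
    else:
        analysis.skipped.append("vesicle (channel missing)")
    if "actin" in tl.channels:
        aproj = segmentation.project(tl.channels["actin"], "max")
        pre = aproj[track.time_min <= 0] if track.germinated else aproj
        if len(pre) and germ_dir is not None:
            analysis.polarity = polarization.actin_polarity(pre, grain_mask, germ_dir)
        else:
            analysis.skipped.append("actin polarity (no pre-germination frames)")
    else:
        analysis.skipped.append("actin (channel missing)")
    if "sperm_membrane" in tl.channels:
        sproj = segmentation.project(tl.channels["sperm_membrane"], "max")
        analysis.mgu = polarization.detect_mgu(sproj, grain_mask, track)
    else:
        analysis.skipped.append("mgu (sperm_membrane channel missing)")
    return analysis


@dataclass
class CohortStats:
    """Cohort-level statistics assembled from per-tube analyses."""

    n_tubes: int
    population: pd.DataFrame | None = None
    growth_rate_um2_per_h: float = float("nan")
    friedman: kinetics.FriedmanResult | None = None
    conversion_factor_um: float = float("nan")
    peak_stats: dict | None = None
    mgu_mean_area_um2: float = float("nan")
    mgu_se_um2: float = float("nan")
    mgu_n: int = 0


def cohort_stats(
    analyses: list[TubeAnalysis],
    friedman_frames: int = 10,
    min_minutes: float = 60.0,
) -> CohortStats:
    """Summary statistics over a cohort of analyzed tubes.

    Each statistic is computed over the tubes that qualify for it (QC for
    kinetics, vesicle channel for peak stats, sperm channel for MGU).
    """
    tracks = [a.track for a in analyses]
    kept = kinetics.qc_filter(tracks, min_minutes=min_minutes)
    stats = CohortStats(n_tubes=len(analyses))
    if len(kept) >= 2:
        stats.population, stats.growth_rate_um2_per_h = kinetics.population_summary(kept)
    eligible = [
        t for t in kept if t.post_germination().size >= 2 * friedman_frames
    ]
    if len(eligible) >= 3:
        stats.friedman = kinetics.first_last_comparison(eligible, friedman_frames)
    with_length = [
        t for t in kept if np.any((t.tube_length > 0) & (t.area >= 100.0))
    ]
    if with_length:
        stats.conversion_factor_um = kinetics.conversion_factor(with_length)
    with_peaks = [a for a in analyses if a.peak_series is not None]
    if with_peaks:
        stats.peak_stats = polarization.population_peak_stats(
            [a.peak_events for a in with_peaks]
        )
    mgu_areas = [a.mgu.area_at_translocation for a in analyses if a.mgu is not None]
    if mgu_areas:
        v = np.asarray(mgu_areas)
        stats.mgu_mean_area_um2 = float(v.mean())
        stats.mgu_se_um2 = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        stats.mgu_n = int(v.size)
    return stats
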