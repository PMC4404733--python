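"""Vesicle-marker peaks, actin polarity, abnormal growth, MGU translocation.

Quantifies the transient polarization events that accompany pollen
germination: high-intensity maxima of a vesicle marker (e.g. ARO1-GFP)
appearing subjacent to the future germination site before emergence, the
cortical F-actin polarity profile, abnormal growth patterns (growth arrest,
second-tube initiation, tube branching), and the translocation of the male
germ unit (MGU) into the tube, defined by the frame from which the tip of
the sperm-membrane extension remains permanently outside the grain.

Intensity quantification mirrors the variable-ROI convention: per frame the
ROI is the connected component of pixels above the tube's 0.5% stack-
histogram gray value, its integrated intensity is mean gray times ROI size,
and series are normalized per tube to their maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.signal import find_peaks
from skimage.measure import label as cc_label

from ._geom import ang_dist, circular_mean
from .kinetics import GrowthTrack
from .segmentation import StackThresholds

__all__ = [
    "PeakEvent",
    "PolarityProfile",
    "MGUEvent",
    "AbnormalCall",
    "peak_series",
    "detect_peaks",
    "population_peak_stats",
    "classify_abnormal",
    "actin_polarity",
    "detect_mgu",
]


@dataclass(frozen=True)
class PeakEvent:
    """A detected vesicle-signal intensity maximum."""

    frame: int
    time_min: float  # relative to germination (negative = before)
    integrated_intensity: float  # counts * px
    normalized_intensity: float  # in [0, 1], per-tube
    direction: float  # radians, from grain centroid to ROI centroid
    site_concordant: bool


@dataclass
class PolarityProfile:
    """Angular profile of cortical actin intensity around the grain."""

    bin_centers: np.ndarray  # radians, 36 bins
    bin_intensity: np.ndarray
    polarity_direction: float  # radians (circular mean)
    polarity_index: float  # resultant length in [0, 1]
    angle_to_germination: float  # radians


@dataclass(frozen=True)
class MGUEvent:
    """Male-germ-unit translocation: first frame from which the tip of the
    sperm-membrane extension stays outside the grain."""

    frame: int
    time_min: float
    area_at_translocation: float  # um^2


@dataclass
class AbnormalCall:
    label: str  # normal | arrest | second_tube | branching
    evidence: dict


def peak_series(
    frames: np.ndarray,
    thresholds: StackThresholds,
    grain_centroid: tuple[float, float],
    time_min: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame integrated and normalized vesicle-peak intensity.

    ``frames`` is the max-projected vesicle channel (T, Y, X); the ROI of a
    frame is the largest connected component of pixels above the 0.5% stack-
    histogram gray value. Integrated intensity is the ROI mean gray value
    multiplied by the ROI size (counts * px); the series is normalized to the
    per-tube maximum. Frames with an empty ROI report intensity 0. The
    direction column is the angle (radians) from the grain centroid (row,
    col) to the intensity-weighted ROI centroid.
    """
    frames = np.asarray(frames)
    t = frames.shape[0]
    integrated = np.zeros(t)
    cx = np.full(t, np.nan)
    cy = np.full(t, np.nan)
    direction = np.full(t, np.nan)
    n_rois = np.zeros(t, dtype=int)
    gr, gc = grain_centroid
    for i in range(t):
        img = frames[i]
        mask = img > thresholds.peak_gray
        labels = cc_label(mask)
        if labels.max() == 0:
            continue
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        n_rois[i] = int(np.sum(counts > 0))
        roi = labels == int(np.argmax(counts))
        vals = img[roi].astype(float)
        integrated[i] = float(vals.sum())  # == mean gray * ROI size
        rr, cc = np.nonzero(roi)
        w = vals / vals.sum()
        cy[i] = float(np.sum(rr * w))
        cx[i] = float(np.sum(cc * w))
        direction[i] = float(np.arctan2(cy[i] - gr, cx[i] - gc))
    peak = integrated.max()
    normalized = integrated / peak if peak > 0 else integrated
    out = pd.DataFrame(
        {
            "frame": np.arange(t),
            "integrated": integrated,
            "normalized": normalized,
            "centroid_row": cy,
            "centroid_col": cx,
            "direction": direction,
            "n_rois": n_rois,
        }
    )
    if time_min is not None:
        out["time_min"] = np.asarray(time_min, dtype=float)
    return out


def roi_directions(
    image: np.ndarray,
    peak_gray: float,
    grain_centroid: tuple[float, float],
    min_px: int = 4,
    min_frac: float = 0.25,
) -> list[float]:
    """Directions (radians from the grain centroid) of every above-threshold
    ROI in one frame with at least ``min_px`` pixels and at least
    ``min_frac`` of the largest ROI's size (so isolated noise clusters do
    not masquerade as a second signal focus)."""
    labels = cc_label(np.asarray(image) > peak_gray)
    if labels.max() == 0:
        return []
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    floor = max(min_px, min_frac * counts.max())
    out = []
    gr, gc = grain_centroid
    for k in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == k)
        if rr.size < floor:
            continue
        out.append(float(np.arctan2(rr.mean() - gr, cc.mean() - gc)))
    return out


def detect_peaks(
    series: pd.DataFrame,
    germination_angle: float,
    prominence: float = 0.2,
    concordance_deg: float = 30.0,
) -> list[PeakEvent]:
    """Local maxima of the normalized intensity series with the stated
    prominence (as a fraction of the per-tube maximum).

    Each event carries its time relative to germination (the series must
    include a germination-aligned ``time_min`` column; negative = before
    germination), the ROI direction, and whether it is concordant with the
    germination site (angular distance <= ``concordance_deg``).
    """
    norm = series["normalized"].to_numpy(dtype=float)
    idx, _ = find_peaks(norm, prominence=prominence)
    events = []
    cone = np.deg2rad(concordance_deg)
    for i in idx:
        d = float(series["direction"].iloc[i])
        concordant = bool(
            np.isfinite(d) and ang_dist(d, germination_angle) <= cone + 1e-12
        )
        events.append(
            PeakEvent(
                frame=int(series["frame"].iloc[i]),
                time_min=float(series["time_min"].iloc[i]),
                integrated_intensity=float(series["integrated"].iloc[i]),
                normalized_intensity=float(norm[i]),
                direction=d,
                site_concordant=concordant,
            )
        )
    return events


#: Reporting windows (min before germination), closed at both ends.
PEAK_TIME_BINS = ((-60.0, -36.0), (-12.0, -9.0), (-6.0, -3.0))


def population_peak_stats(
    events_per_tube: list[list[PeakEvent]],
) -> dict[str, object]:
    """Cohort frequency table of concordant pre-germination vesicle peaks.

    Counts, with denominators: tubes with at least one site-concordant
    pre-germination peak; tubes with a concordant peak inside each reporting
    window ([-60,-36], [-12,-9], [-6,-3] min, bins closed on both ends with
    the earlier bin taking boundary ties); and tubes with exactly one versus
    two or more concordant pre-germination peaks.
    """
    n = len(events_per_tube)
    if n < 1:
        raise ValueError("need at least one tube")
    any_concordant = 0
    bin_counts = [0] * len(PEAK_TIME_BINS)
    one_peak = 0
    two_plus = 0
    for events in events_per_tube:
        pre = [e for e in events if e.time_min < 0 and e.site_concordant]
        if pre:
            any_concordant += 1
        if len(pre) == 1:
            one_peak += 1
        elif len(pre) >= 2:
            two_plus += 1
        for b, (lo, hi) in enumerate(PEAK_TIME_BINS):
            for e in pre:
                t = e.time_min
                # earlier (more negative) bin takes a tie on a shared boundary
                in_bin = lo <= t <= hi
                if in_bin and b > 0 and t == lo and PEAK_TIME_BINS[b - 1][1] == lo:
                    in_bin = False
                if in_bin:
                    bin_counts[b] += 1
                    break
    return {
        "n_tubes": n,
        "concordant_pre_germination": any_concordant,
        "bins_min": [list(b) for b in PEAK_TIME_BINS],
        "bin_counts": bin_counts,
        "one_peak": one_peak,
        "two_or_more_peaks": two_plus,
    }


def classify_abnormal(
    track: GrowthTrack,
    series: pd.DataFrame,
    cohort_median_increase: float,
    germination_events: list[tuple[float, float]] | None = None,
    roi_angles_per_frame: list[list[float]] | None = None,
    decay_fraction: float = 0.10,
    growth_fraction: float = 0.10,
    min_frames: int = 5,
    second_tube_deg: float = 45.0,
    branch_deg: float = 30.0,
) -> AbnormalCall:
    """Label a tube's growth pattern as normal, arrest, second_tube, or branching.

    * ``second_tube``: two sustained germination events at angular distance
      greater than ``second_tube_deg`` (``germination_events`` is a list of
      (time_min, angle) pairs).
    * ``branching``: some frame shows two simultaneous above-peak-threshold
      vesicle ROIs separated by more than ``branch_deg``.
    * ``arrest``: the normalized vesicle intensity falls below
      ``decay_fraction`` of its maximum while the frame-wise area increase
      stays below ``growth_fraction`` of the cohort median for at least
      ``min_frames`` consecutive frames (the joint criterion avoids calling
      photobleaching alone).
    """
    evidence: dict = {}
    if germination_events and len(germination_events) >= 2:
        angles = [a for _, a in germination_events]
        sep = max(
            ang_dist(a, b) for i, a in enumerate(angles) for b in angles[i + 1 :]
        )
        if sep > np.deg2rad(second_tube_deg):
            evidence["germination_angles"] = angles
            evidence["angular_separation_deg"] = float(np.rad2deg(sep))
            return AbnormalCall("second_tube", evidence)
    if roi_angles_per_frame is not None:
        for f, angles in enumerate(roi_angles_per_frame):
            if len(angles) >= 2:
                sep = max(
                    ang_dist(a, b)
                    for i, a in enumerate(angles)
                    for b in angles[i + 1 :]
                )
                if sep > np.deg2rad(branch_deg):
                    evidence["branch_frame"] = f
                    evidence["tip_separation_deg"] = float(np.rad2deg(sep))
                    return AbnormalCall("branching", evidence)
    norm = series["normalized"].to_numpy(dtype=float)
    post = track.post_germination()
    low_signal = norm < decay_fraction
    low_growth = np.zeros_like(low_signal)
    low_growth[post] = (
        track.frame_wise_increase[post] < growth_fraction * cohort_median_increase
    )
    joint = low_signal & low_growth
    run = 0
    for i in post:
        run = run + 1 if joint[i] else 0
        if run >= min_frames:
            evidence["signal_decay_fraction"] = float(norm[post].min())
            evidence["arrest_frame"] = int(i - min_frames + 1)
            return AbnormalCall("arrest", evidence)
    return AbnormalCall("normal", evidence)


def actin_polarity(
    frames: np.ndarray,
    grain_mask: np.ndarray,
    germination_angle: float,
    n_bins: int = 36,
    band_px: int = 3,
) -> PolarityProfile:
    """Angular intensity profile of cortical actin around the grain.

    Mean intensity per angular bin over a ``band_px``-wide band just inside
    the grain boundary, averaged over the supplied (pre-germination) frames.
    The polarity direction is the intensity-weighted circular mean and the
    polarity index its resultant length (0 for a uniform ring, 1 for a point
    mass); the angular distance to the germination site is reported.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    mean_img = frames.mean(axis=0)
    band = grain_mask & ~binary_erosion(grain_mask, iterations=band_px)
    rr, cc = np.nonzero(band)
    if rr.size == 0:
        raise ValueError("empty cortical band: grain mask too small")
    gy, gx = np.argwhere(grain_mask).mean(axis=0)
    theta = np.arctan2(rr - gy, cc - gx)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    intensity = np.zeros(n_bins)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            intensity[b] = float(mean_img[rr[sel], cc[sel]].mean())
    centers = 0.5 * (edges[:-1] + edges[1:])
    direction, index = circular_mean(centers, intensity)
    return PolarityProfile(
        bin_centers=centers,
        bin_intensity=intensity,
        polarity_direction=direction,
        polarity_index=index,
        angle_to_germination=ang_dist(direction, germination_angle),
    )


def detect_mgu(
    frames: np.ndarray,
    grain_mask: np.ndarray,
    track: GrowthTrack,
    threshold: float | None = None,
) -> MGUEvent | None:
    """Male-germ-unit translocation from the sperm-membrane channel.

    Per frame the tip is the farthest above-threshold pixel from the grain
    centroid; the translocation frame t* is the first frame from which the
    tip lies outside the grain mask for every subsequent frame. The
    cumulative tube area at t* is read from the track. Returns None when the
    tip never becomes permanently external.
    """
    frames = np.asarray(frames)
    if threshold is None:
        vals = frames[frames > 0]
        if vals.size == 0:
            return None
        from .segmentation import _background_floor

        # half-maximum above the background floor: the membrane extension is
        # a thin bright curve, and a floor-level threshold would let its
        # defocus halo masquerade as the tip
        floor = _background_floor(frames.ravel())
        peak = float(np.quantile(frames, 0.999))
        threshold = floor + 0.5 * (peak - floor)
    gy, gx = np.argwhere(grain_mask).mean(axis=0)
    t = frames.shape[0]
    outside = np.zeros(t, dtype=bool)
    for i in range(t):
        rr, cc = np.nonzero(frames[i] > threshold)
        if rr.size == 0:
            outside[i] = False
            continue
        d2 = (rr - gy) ** 2 + (cc - gx) ** 2
        tip = int(np.argmax(d2))
        outside[i] = not grain_mask[rr[tip], cc[tip]]
    if not outside[-1]:
        return None
    # last run of outside frames extending to the end
    inside_idx = np.nonzero(~outside)[0]
    t_star = int(inside_idx[-1] + 1) if inside_idx.size else 0
    return MGUEvent(
        frame=t_star,
        time_min=float(track.time_min[t_star]),
        area_at_translocation=float(track.area[t_star]),
    )
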