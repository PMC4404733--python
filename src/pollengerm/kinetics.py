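"""Per-tube growth tracks, kinetics, phases, and cohort statistics.

Time is germination-aligned: t = 0 min is assigned to the last frame before
the tube emerged. Growth is quantified as tube area (um^2) because the tube
is a three-dimensional cylindrical object measured on 2-D projections; an
approximate conversion factor (um^-1) transfers area to length.

The early-vs-late growth comparison uses Friedman's two-way analysis of
variance by ranks with k = 2 paired conditions (mean frame-wise area increase
over the first and the last 10 frames of each tube), mid-ranks for ties and
the standard tie-corrected chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import chi2, rankdata

from .segmentation import RegionMeasurement

__all__ = [
    "GrowthTrack",
    "PhaseLabels",
    "FriedmanResult",
    "DecelerationEvent",
    "build_track",
    "qc_filter",
    "friedman_test",
    "first_last_comparison",
    "conversion_factor",
    "phase_annotate",
    "detect_deceleration",
    "population_summary",
]

PHASES = ("pre-germination", "bulging", "transition", "rapid", "translocation")


class InsufficientDataError(ValueError):
    pass


@dataclass
class GrowthTrack:
    """Germination-aligned growth series of one tube.

    ``time_min[i]`` is relative to t = 0 at the last frame before emergence;
    ``area`` is the cumulative tube area (um^2) and ``frame_wise_increase``
    its first difference. ``germinated`` is False when no frame ever reached
    the emergence threshold (a valid "no germination" result).
    """

    tube_id: str
    time_min: np.ndarray
    area: np.ndarray
    roundness: np.ndarray
    junction_width: np.ndarray
    tube_length: np.ndarray
    frame_wise_increase: np.ndarray
    frame_interval: float
    germination_index: int | None
    germinated: bool = True
    observed_minutes: float = 0.0
    unobstructed: bool = True

    @property
    def cumulative_area(self) -> np.ndarray:
        return self.area

    def post_germination(self) -> np.ndarray:
        """Indices of frames strictly after t = 0."""
        return np.nonzero(self.time_min > 0)[0]

    def area_at(self, t_min: float) -> float:
        """Cumulative area at a given post-germination time (interpolated)."""
        return float(np.interp(t_min, self.time_min, self.area))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "area_um2": self.area,
                "increase_um2": self.frame_wise_increase,
                "cumulative_um2": self.area,
                "roundness": self.roundness,
                "junction_width_um": self.junction_width,
                "tube_length_um": self.tube_length,
            }
        )


@dataclass
class PhaseLabels:
    """Contiguous phase labels with the boundary frames that produced them."""

    labels: np.ndarray | None
    boundaries: dict[str, int]
    rules: dict[str, str]
    degenerate: bool = False


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float  # Q
    df: int
    p_value: float
    n: int
    group_means: tuple[float, float]  # (first window, last window), um^2/frame


@dataclass(frozen=True)
class DecelerationEvent:
    frame: int
    time_min: float
    area_um2: float
    increase_um2: float


def build_track(
    measurements: list[RegionMeasurement],
    pixel_size: float,
    frame_interval: float = 3.0,
    min_area_px: int = 10,
    tube_id: str = "tube",
    unobstructed: bool = True,
) -> GrowthTrack:
    """Assemble a germination-aligned track from per-frame measurements.

    The germination frame is the first frame whose tube area reaches
    ``min_area_px`` pixels sustained for at least two consecutive frames;
    t = 0 is assigned to the preceding frame. A single-frame blip does not
    count. If no frame qualifies the track is returned with
    ``germinated=False`` rather than raising.
    """
    if len(measurements) < 2:
        raise InsufficientDataError("need at least 2 frames")
    area = np.array([m.area for m in measurements], dtype=float)
    area_px = area / pixel_size**2
    thr = float(min_area_px)
    sustained = (area_px[:-1] >= thr) & (area_px[1:] >= thr)
    hits = np.nonzero(sustained)[0]
    n = len(measurements)
    roundness = np.array([m.roundness for m in measurements], dtype=float)
    junction = np.array([m.junction_width for m in measurements], dtype=float)
    length = np.array([m.tube_length for m in measurements], dtype=float)
    increase = np.diff(area, prepend=area[0])
    if hits.size == 0:
        return GrowthTrack(
            tube_id=tube_id,
            time_min=np.arange(n) * frame_interval,
            area=area,
            roundness=roundness,
            junction_width=junction,
            tube_length=length,
            frame_wise_increase=increase,
            frame_interval=frame_interval,
            germination_index=None,
            germinated=False,
            observed_minutes=0.0,
            unobstructed=unobstructed,
        )
    g = int(hits[0])  # first frame of the sustained pair
    t0 = max(g - 1, 0)
    time_min = (np.arange(n) - t0) * frame_interval
    return GrowthTrack(
        tube_id=tube_id,
        time_min=time_min,
        area=area,
        roundness=roundness,
        junction_width=junction,
        tube_length=length,
        frame_wise_increase=increase,
        frame_interval=frame_interval,
        germination_index=t0,
        germinated=True,
        observed_minutes=float((n - 1 - t0) * frame_interval),
        unobstructed=unobstructed,
    )


def qc_filter(tracks: list[GrowthTrack], min_minutes: float = 60.0) -> list[GrowthTrack]:
    """Keep tubes observed for at least an hour after germination and whose
    growth was not disturbed by any other object."""
    return [
        t
        for t in tracks
        if t.germinated and t.unobstructed and t.observed_minutes >= min_minutes
    ]


def friedman_test(data: np.ndarray) -> tuple[float, int, float]:
    """Friedman two-way analysis of variance by ranks (subjects x conditions).

    Mid-ranks are used for within-subject ties and the chi-square
    approximation includes the standard tie correction. Returns (Q, df, p).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3:
        raise InsufficientDataError("Friedman test needs at least 3 subjects")
    ranks = np.vstack([rankdata(row) for row in data])
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * float(np.sum((rj - n * (k + 1) / 2.0) ** 2))
    # tie correction over within-subject tie groups
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, k - 1, 1.0
    q /= c
    return q, k - 1, float(chi2.sf(q, k - 1))


def first_last_comparison(
    tracks: list[GrowthTrack], n_frames: int = 10
) -> FriedmanResult:
    """Compare mean frame-wise area increase of the first vs last 10 frames.

    For each tube the mean frame-wise increase over the first ``n_frames``
    and the last ``n_frames`` post-germination frames forms one paired
    observation; the Friedman test (k = 2) is run across tubes.
    """
    if len(tracks) < 3:
        raise InsufficientDataError("need at least 3 tracks")
    firsts, lasts = [], []
    for t in tracks:
        post = t.post_germination()
        if post.size < 2 * n_frames:
            raise InsufficientDataError(
                f"track {t.tube_id}: need >= {2 * n_frames} post-germination "
                f"frames, got {post.size}"
            )
        inc = t.frame_wise_increase[post]
        firsts.append(float(np.mean(inc[:n_frames])))
        lasts.append(float(np.mean(inc[-n_frames:])))
    data = np.column_stack([firsts, lasts])
    q, df, p = friedman_test(data)
    return FriedmanResult(
        statistic=q,
        df=df,
        p_value=p,
        n=len(tracks),
        group_means=(float(np.mean(firsts)), float(np.mean(lasts))),
    )


def conversion_factor(tracks: list[GrowthTrack], min_area: float = 100.0) -> float:
    """Approximate factor (um^-1) transferring tube area (um^2) to length (um).

    Through-origin least-squares slope of tube length versus area, pooled
    over all frames with area >= ``min_area`` um^2. For a pure cylinder of
    width w the slope tends to 1/w as the tube elongates.
    """
    areas, lengths = [], []
    for t in tracks:
        ok = (t.area >= min_area) & np.isfinite(t.tube_length) & (t.tube_length > 0)
        areas.append(t.area[ok])
        lengths.append(t.tube_length[ok])
    a = np.concatenate(areas) if areas else np.array([])
    l = np.concatenate(lengths) if lengths else np.array([])
    if a.size == 0:
        raise InsufficientDataError(f"no frames with area >= {min_area} um^2")
    return float(np.dot(a, l) / np.dot(a, a))


def phase_annotate(
    track: GrowthTrack,
    bulge_window_min: float = 30.0,
    mgu_time_min: float | None = None,
) -> PhaseLabels:
    """Assign contiguous growth-phase labels to a germination-aligned track.

    Rules (each boundary is reported with the rule that produced it):
    bulging runs from t = 0 to the global roundness maximum within the first
    ``bulge_window_min`` minutes; transition runs until the frame-wise
    increase first exceeds 50% of the track's late-phase mean (last 10
    frames); rapid growth follows; an optional translocation phase starts at
    ``mgu_time_min``. A track with constant roundness (or an increase series
    that never reaches the rapid criterion) is flagged as degenerate and no
    phases are forced.
    """
    post = track.post_germination()
    early = post[track.time_min[post] <= bulge_window_min]
    if early.size == 0:
        return PhaseLabels(None, {}, {}, degenerate=True)
    r_early = track.roundness[early]
    missing = ~np.isfinite(r_early)
    if missing.mean() > 0.30:
        raise InsufficientDataError(
            "roundness missing on more than 30% of early frames; "
            "annotation declined"
        )
    r_filled = np.where(np.isfinite(r_early), r_early, -np.inf)
    if np.nanstd(r_early[np.isfinite(r_early)]) < 1e-3:
        return PhaseLabels(None, {}, {}, degenerate=True)
    i_round_max = int(early[np.argmax(r_filled)])
    late_mean = float(np.mean(track.frame_wise_increase[post][-10:]))
    after = post[post > i_round_max]
    rapid_hits = after[track.frame_wise_increase[after] > 0.5 * late_mean]
    if late_mean <= 0 or rapid_hits.size == 0:
        return PhaseLabels(None, {}, {}, degenerate=True)
    i_rapid = int(rapid_hits[0])
    n = track.time_min.size
    labels = np.empty(n, dtype=object)
    labels[:] = "pre-germination"
    labels[(track.time_min > 0)] = "bulging"
    labels[i_round_max + 1 :] = "transition"
    labels[i_rapid:] = "rapid"
    boundaries = {"bulging_end": i_round_max, "transition_end": i_rapid - 1}
    rules = {
        "bulging_end": f"global roundness maximum within first {bulge_window_min:g} min",
        "transition_end": "frame-wise increase first exceeds 50% of last-10-frame mean",
    }
    if mgu_time_min is not None:
        i_mgu = int(np.searchsorted(track.time_min, mgu_time_min))
        if i_mgu < n:
            labels[i_mgu:] = "translocation"
            boundaries["translocation_start"] = i_mgu
            rules["translocation_start"] = "scheduled MGU translocation time"
    return PhaseLabels(labels, boundaries, rules, degenerate=False)


def detect_deceleration(
    track: GrowthTrack,
    window: int = 3,
    phases: PhaseLabels | None = None,
    min_prominence_frac: float = 0.10,
) -> list[DecelerationEvent]:
    """Short phases of decelerated growth within the rapid phase.

    The frame-wise increase is smoothed with a centered moving average of
    ``window`` frames; local minima with prominence at least
    ``min_prominence_frac`` of the peak smoothed increase are reported, each
    with the cumulative area at which it occurs.
    """
    if phases is None:
        phases = phase_annotate(track)
    if phases.degenerate or phases.labels is None:
        return []
    rapid = np.nonzero((phases.labels == "rapid") | (phases.labels == "translocation"))[0]
    if rapid.size < window + 2:
        return []
    inc = track.frame_wise_increase.astype(float)
    kernel = np.ones(window) / window
    smooth = np.convolve(inc, kernel, mode="same")
    seg = smooth[rapid]
    prom = min_prominence_frac * float(seg.max()) if seg.max() > 0 else 0.0
    minima, _ = find_peaks(-seg, prominence=max(prom, 1e-9))
    events = []
    for m in minima:
        i = int(rapid[m])
        events.append(
            DecelerationEvent(
                frame=i,
                time_min=float(track.time_min[i]),
                area_um2=float(track.area[i]),
                increase_um2=float(inc[i]),
            )
        )
    return events


def population_summary(
    tracks: list[GrowthTrack], rate_time_min: float = 60.0
) -> tuple[pd.DataFrame, float]:
    """Pointwise mean +- SE of cumulative area over germination-aligned tracks.

    Returns the per-time-point table (time_min, mean, se, n) and the overall
    growth rate, defined as the mean cumulative area at ``rate_time_min``
    minutes post-germination expressed per hour.
    """
    if len(tracks) < 2:
        raise InsufficientDataError("need at least 2 tracks")
    times = np.unique(np.concatenate([t.time_min for t in tracks]))
    rows = []
    for tt in times:
        vals = []
        for t in tracks:
            hit = np.nonzero(np.isclose(t.time_min, tt))[0]
            if hit.size:
                vals.append(float(t.area[hit[0]]))
        if len(vals) >= 2:
            v = np.array(vals)
            rows.append(
                {
                    "time_min": float(tt),
                    "mean_area_um2": float(v.mean()),
                    "se_um2": float(v.std(ddof=1) / np.sqrt(len(v))),
                    "n": len(v),
                }
            )
    table = pd.DataFrame(rows)
    at_60 = [t.area_at(rate_time_min) for t in tracks if t.observed_minutes >= rate_time_min]
    rate = float(np.mean(at_60)) * 60.0 / rate_time_min if at_60 else float("nan")
    return table, rate
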