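"""Vesicle peak quantification, actin polarity, abnormal calls, MGU timing."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from pollengerm.polarization import (
    PeakEvent,
    actin_polarity,
    classify_abnormal,
    detect_mgu,
    detect_peaks,
    peak_series,
    population_peak_stats,
)
from pollengerm.segmentation import StackThresholds
from test_kinetics import _track


def _thr(peak_gray: float) -> StackThresholds:
    return StackThresholds(
        shape_gray=peak_gray / 2, peak_gray=peak_gray, background_floor=0.0
    )


def _frames_with_rois(sums, peak_gray=100.0, size=100):
    """One square ROI per frame whose pixel sum is controlled exactly."""
    side = int(np.sqrt(size))
    t = len(sums)
    frames = np.zeros((t, 64, 64))
    for i, s in enumerate(sums):
        if s > 0:
            frames[i, 10 : 10 + side, 40 : 40 + side] = s / (side * side)
    return frames


class TestPeakSeries:
    def test_integrated_is_mean_gray_times_roi_size(self):
        frames = np.zeros((1, 64, 64))
        frames[0, 5:15, 20:30] = 2000.0  # 100 px ROI, mean gray 2000
        s = peak_series(frames, _thr(100.0), grain_centroid=(32.0, 32.0))
        assert s["integrated"].iloc[0] == pytest.approx(200_000.0)

    def test_normalization_to_per_tube_maximum(self):
        frames = _frames_with_rois([2e5, 1e6, 5e5], peak_gray=100.0)
        s = peak_series(frames, _thr(10.0), grain_centroid=(32.0, 32.0))
        assert np.allclose(s["normalized"], [0.2, 1.0, 0.5])
        assert s["normalized"].max() == 1.0

    def test_empty_roi_reports_zero(self):
        frames = np.zeros((3, 32, 32))
        frames[1, 4:8, 4:8] = 500.0
        s = peak_series(frames, _thr(100.0), grain_centroid=(16.0, 16.0))
        assert s["integrated"].iloc[0] == 0.0 and s["integrated"].iloc[2] == 0.0

    def test_roi_centroid_near_blob_center(self):
        frames = np.zeros((1, 64, 64))
        yy, xx = np.mgrid[:64, :64]
        frames[0] = 3000.0 * np.exp(-(((yy - 20) ** 2 + (xx - 44) ** 2) / 18.0))
        s = peak_series(frames, _thr(300.0), grain_centroid=(32.0, 32.0))
        assert abs(s["centroid_row"].iloc[0] - 20) < 3
        assert abs(s["centroid_col"].iloc[0] - 44) < 3


class TestDetectPeaks:
    @staticmethod
    def _series(norm, directions=None, t0=5):
        n = len(norm)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "integrated": np.asarray(norm) * 1e6,
                "normalized": norm,
                "direction": directions if directions is not None else np.zeros(n),
                "time_min": (np.arange(n) - t0) * 3.0,
            }
        )

    def test_flat_series_no_events(self):
        assert detect_peaks(self._series(np.full(12, 0.5)), 0.0) == []

    def test_peak_directions_and_concordance(self):
        norm = np.array([0.0, 0.1, 1.0, 0.1, 0.0, 0.9, 0.1, 0.0])
        directions = np.array([0, 0, 0.2, 0, 0, np.pi, 0, 0])
        events = detect_peaks(self._series(norm, directions), germination_angle=0.0)
        assert len(events) == 2
        assert events[0].site_concordant  # 0.2 rad < 30 degrees
        assert not events[1].site_concordant  # opposite side
        assert events[0].time_min == pytest.approx(-9.0)

    def test_prominence_threshold(self):
        norm = np.array([0.0, 0.1, 0.18, 0.1, 0.0, 1.0, 0.0])
        events = detect_peaks(self._series(norm), 0.0, prominence=0.2)
        assert [e.frame for e in events] == [5]

    def test_affine_rescaling_of_stack_leaves_peaks_unchanged(self, small_peak_cohort):
        from pollengerm import segmentation
        from pollengerm.pipeline import analyze_tube

        tl, gt = small_peak_cohort[3]
        a1 = analyze_tube(tl)
        scaled = {
            c: np.clip(3 * arr.astype(np.int64) + 50, 0, 65535).astype(np.uint16)
            for c, arr in tl.channels.items()
        }
        from pollengerm.synthetic_microscopy import TimeLapse

        a2 = analyze_tube(TimeLapse(scaled, tl.acq))
        assert [e.frame for e in a1.peak_events] == [e.frame for e in a2.peak_events]


class TestPopulationPeakStats:
    @staticmethod
    def _event(t, concordant=True):
        return PeakEvent(0, t, 1e5, 1.0, 0.0, concordant)

    def test_frequency_table(self):
        tubes = []
        for i in range(30):
            if i < 25:
                tubes.append([self._event(-12.0)])
            else:
                tubes.append([self._event(-12.0, concordant=False)])
        stats = population_peak_stats(tubes)
        assert stats["concordant_pre_germination"] == 25
        assert stats["n_tubes"] == 30

    def test_boundary_minus_nine_falls_in_earlier_bin(self):
        stats = population_peak_stats([[self._event(-9.0)]])
        assert stats["bin_counts"] == [0, 1, 0]  # [-12, -9] closed at -9

    def test_no_events_all_zero(self):
        stats = population_peak_stats([[], [], []])
        assert stats["concordant_pre_germination"] == 0
        assert stats["bin_counts"] == [0, 0, 0]
        assert stats["one_peak"] == 0 and stats["two_or_more_peaks"] == 0

    def test_one_vs_two_peak_counts(self):
        tubes = [
            [self._event(-12.0)],
            [self._event(-18.0), self._event(-6.0)],
            [self._event(5.0)],  # post-germination only
        ]
        stats = population_peak_stats(tubes)
        assert stats["one_peak"] == 1
        assert stats["two_or_more_peaks"] == 1


class TestActinPolarity:
    @staticmethod
    def _ring_image(profile_fn, shape=(96, 96), r=30):
        grain = np.zeros(shape, bool)
        rr, cc = disk((48, 48), r)
        grain[rr, cc] = True
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        theta = np.arctan2(yy - 48, xx - 48)
        img = np.where(grain, 100.0 + profile_fn(theta), 0.0)
        return img, grain

    def test_uniform_ring_low_index(self):
        img, grain = self._ring_image(lambda th: 500.0)
        prof = actin_polarity(img[None], grain, germination_angle=0.0)
        assert prof.polarity_index < 0.05

    def test_von_mises_direction_recovered(self):
        for theta0 in (0.5, 2.0, -2.5):
            img, grain = self._ring_image(
                lambda th: 800.0 * np.exp(3.0 * (np.cos(th - theta0) - 1.0))
            )
            prof = actin_polarity(img[None], grain, germination_angle=0.0)
            err = np.abs(np.angle(np.exp(1j * (prof.polarity_direction - theta0))))
            assert np.rad2deg(err) < 10.0

    def test_profile_opposite_germination_site(self):
        img, grain = self._ring_image(
            lambda th: 800.0 * np.exp(3.0 * (np.cos(th - np.pi) - 1.0))
        )
        prof = actin_polarity(img[None], grain, germination_angle=0.0)
        assert np.rad2deg(prof.angle_to_germination) == pytest.approx(180.0, abs=12.0)


class TestDetectMGU:
    @staticmethod
    def _frames(sequence, shape=(48, 64)):
        # grain disc on the left; tip pixel inside or outside per flag
        grain = np.zeros(shape, bool)
        rr, cc = disk((24, 16), 12)
        grain[rr, cc] = True
        frames = np.zeros((len(sequence), *shape))
        for i, outside in enumerate(sequence):
            frames[i, 24, 40 if outside else 20] = 1000.0
            frames[i, 24, 10] = 800.0  # body of the membrane inside the grain
        return frames, grain

    def test_permanence_rule(self):
        seq = [False, False, True, False, True, True, True]
        frames, grain = self._frames(seq)
        track = _track(np.linspace(0, 60, len(seq)))
        ev = detect_mgu(frames, grain, track, threshold=500.0)
        assert ev is not None and ev.frame == 4

    def test_never_outside_gives_no_event(self):
        frames, grain = self._frames([False] * 5)
        ev = detect_mgu(frames, grain, _track(np.zeros(5)), threshold=500.0)
        assert ev is None

    def test_adding_later_frames_never_advances_t_star(self):
        seq = [False, True, True, True]
        frames, grain = self._frames(seq + [False, True, True])
        short = detect_mgu(
            frames[:4], grain, _track(np.zeros(4)), threshold=500.0
        )
        long = detect_mgu(frames, grain, _track(np.zeros(7)), threshold=500.0)
        assert short.frame == 1
        assert long.frame >= short.frame  # delayed, never advanced

    def test_area_read_from_track(self):
        seq = [False, False, True, True]
        frames, grain = self._frames(seq)
        track = _track(np.array([0.0, 100.0, 350.0, 420.0]))
        ev = detect_mgu(frames, grain, track, threshold=500.0)
        assert ev.area_at_translocation == 350.0


class TestClassifyAbnormal:
    @staticmethod
    def _series(norm):
        return pd.DataFrame({"normalized": np.asarray(norm, dtype=float)})

    def test_arrest_requires_joint_criteria(self):
        n = 20
        areas = np.concatenate([np.zeros(2), np.full(n - 2, 20.0)])
        track = _track(areas, t0=1)
        decayed = np.concatenate([np.linspace(0.2, 1.0, 8), np.full(n - 8, 0.05)])
        call = classify_abnormal(track, self._series(decayed), cohort_median_increase=10.0)
        assert call.label == "arrest"
        # same decay but sustained growth: photobleaching, not arrest
        growing = np.concatenate([np.zeros(2), np.cumsum(np.full(n - 2, 12.0))])
        call2 = classify_abnormal(
            _track(growing, t0=1), self._series(decayed), cohort_median_increase=10.0
        )
        assert call2.label == "normal"

    def test_second_tube_angle_rule(self):
        track = _track(np.linspace(0, 100, 15))
        series = self._series(np.full(15, 0.5))
        call = classify_abnormal(
            track, series, 10.0,
            germination_events=[(0.0, 0.0), (30.0, np.deg2rad(120.0))],
        )
        assert call.label == "second_tube"
        close = classify_abnormal(
            track, series, 10.0,
            germination_events=[(0.0, 0.0), (30.0, np.deg2rad(20.0))],
        )
        assert close.label != "second_tube"

    def test_branching_from_simultaneous_rois(self):
        track = _track(np.linspace(0, 100, 15))
        series = self._series(np.full(15, 0.5))
        rois = [[0.0]] * 10 + [[0.0, np.deg2rad(40.0)]] + [[0.0]] * 4
        call = classify_abnormal(track, series, 10.0, roi_angles_per_frame=rois)
        assert call.label == "branching"
        assert call.evidence["branch_frame"] == 10
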