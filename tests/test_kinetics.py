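"""Growth tracks, Friedman comparison, conversion factor, phases."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollengerm.kinetics import (
    GrowthTrack,
    InsufficientDataError,
    build_track,
    conversion_factor,
    detect_deceleration,
    first_last_comparison,
    friedman_test,
    phase_annotate,
    population_summary,
    qc_filter,
)
from pollengerm.segmentation import RegionMeasurement


def _measurements(areas_px, pixel_size=0.5, roundness=None):
    out = []
    for i, a in enumerate(areas_px):
        r = roundness[i] if roundness is not None else (0.9 if a > 0 else np.nan)
        out.append(
            RegionMeasurement(
                frame_index=i,
                area=a * pixel_size**2,
                roundness=r,
                tube_length=0.0,
            )
        )
    return out


def _track(areas, roundness=None, lengths=None, interval=3.0, t0=0, tube_id="t"):
    areas = np.asarray(areas, dtype=float)
    n = areas.size
    return GrowthTrack(
        tube_id=tube_id,
        time_min=(np.arange(n) - t0) * interval,
        area=areas,
        roundness=np.asarray(roundness, float) if roundness is not None else np.full(n, 0.9),
        junction_width=np.full(n, np.nan),
        tube_length=np.asarray(lengths, float) if lengths is not None else np.zeros(n),
        frame_wise_increase=np.diff(areas, prepend=areas[0]),
        frame_interval=interval,
        germination_index=t0,
        observed_minutes=(n - 1 - t0) * interval,
    )


class TestBuildTrack:
    def test_germination_rule(self):
        m = _measurements([0, 0, 0, 12, 30, 55], pixel_size=1.0)
        t = build_track(m, pixel_size=1.0)
        assert t.germinated and t.germination_index == 2
        assert t.time_min[2] == 0.0

    def test_single_frame_blip_is_not_germination(self):
        m = _measurements([0, 15, 0, 0], pixel_size=1.0)
        t = build_track(m, pixel_size=1.0)
        assert not t.germinated and t.germination_index is None

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            build_track(_measurements([5.0]), pixel_size=1.0)

    def test_telescoping_increase(self):
        rng = np.random.default_rng(0)
        areas = np.cumsum(rng.uniform(0, 5, 30))
        m = _measurements(areas, pixel_size=1.0)
        t = build_track(m, pixel_size=1.0)
        for i, j in [(0, 29), (3, 11), (10, 20)]:
            assert np.sum(t.frame_wise_increase[i + 1 : j + 1]) == pytest.approx(
                t.area[j] - t.area[i]
            )

    def test_recovers_known_germination_frame_from_renders(self, fast_acq, grain):
        from pollengerm.cohorts import build_tube_schedule
        from pollengerm.pipeline import analyze_tube
        from pollengerm.synthetic_microscopy import render_timelapse

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            tube = build_tube_schedule(grain, 10, 3, 16.7, 31.0)
            tl, gt = render_timelapse(
                grain, tube.schedule, ["cytoplasm"], fast_acq, seed=seed
            )
            a = analyze_tube(tl)
            assert a.track.germinated
            if abs(a.track.germination_index - (gt.germination_frame - 1)) <= 1:
                hits += 1
        assert hits == n_seeds


class TestQcFilter:
    def test_minimum_observation_and_obstruction(self):
        t59 = _track(np.linspace(0, 100, 21), interval=2.95)  # 59 min observed
        t60 = _track(np.linspace(0, 100, 21))  # 60 min observed
        blocked = _track(np.linspace(0, 200, 41))
        blocked.unobstructed = False
        kept = qc_filter([t59, t60, blocked])
        assert kept == [t60]


class TestFriedman:
    def test_unanimous_twelve_subjects(self):
        # all 12 subjects rank condition 2 above condition 1: Q = n = 12
        data = np.column_stack([np.zeros(12), np.ones(12)])
        q, df, p = friedman_test(data)
        assert q == pytest.approx(12.0)
        assert df == 1
        assert p == pytest.approx(5.32e-4, rel=0.01)

    def test_all_ties(self):
        data = np.ones((8, 2))
        q, df, p = friedman_test(data)
        assert q == 0.0 and p == 1.0

    def test_sixtysix_tubes_fifty_nine_greater(self):
        # 59 of 66 pairs increase, 7 reverse, no ties
        first = np.zeros(66)
        last = np.ones(66)
        last[:7] = -1.0
        q, df, p = friedman_test(np.column_stack([first, last]))
        assert q == pytest.approx(40.97, abs=0.01)
        assert p < 1e-9

    def test_matches_scipy_for_three_conditions(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(5)
        data = rng.normal(size=(15, 3))
        q, df, p = friedman_test(data)
        ref = friedmanchisquare(*data.T)
        assert q == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_permutation_oracle_in_tail_regime(self, seed):
        # exact null: all 2^n within-pair orderings equally likely (k = 2).
        # The chi-square approximation tracks the exact permutation p only
        # in the strong-separation tail (the regime of the slow-vs-fast
        # growth comparison); at moderate p the exact null is too discrete
        # for any continuous approximation to follow within 0.005.
        rng = np.random.default_rng(seed)
        n = 12
        data = np.column_stack([rng.normal(0, 1, n), rng.normal(4.0, 1, n)])
        assert np.sum(data[:, 1] > data[:, 0]) >= 11  # near-unanimous
        q_obs, _, p_chi2 = friedman_test(data)
        count = 0
        total = 0
        for signs in itertools.product([0, 1], repeat=n):
            perm = data.copy()
            flip = np.array(signs, bool)
            perm[flip] = perm[flip][:, ::-1]
            q, _, _ = friedman_test(perm)
            count += q >= q_obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.005

    def test_first_last_comparison_on_tracks(self):
        tracks = []
        rng = np.random.default_rng(3)
        for i in range(12):
            slow = rng.uniform(0.5, 2.0, 10)
            fast = rng.uniform(8.0, 12.0, 10)
            areas = np.concatenate([[0.0], np.cumsum(np.concatenate([slow, fast]))])
            tracks.append(_track(areas))
        res = first_last_comparison(tracks)
        assert res.n == 12
        assert res.statistic == pytest.approx(12.0)
        assert res.p_value < 0.001
        assert res.group_means[1] > res.group_means[0]

    def test_insufficient_tracks(self):
        with pytest.raises(InsufficientDataError):
            first_last_comparison([_track(np.arange(25.0))] * 2)


class TestConversionFactor:
    def test_pure_cylinder_limit(self):
        # cylinder of width w: length/area -> 1/w; within 3% once L >= 10 w
        w = 5.5
        lengths = np.linspace(10 * w, 20 * w, 30)
        areas = w * lengths + np.pi * w**2 / 8.0
        t = _track(areas, lengths=lengths)
        assert conversion_factor([t]) == pytest.approx(1 / w, rel=0.03)

    def test_pixel_size_invariance(self):
        # the same physical bar sampled at two pixel sizes gives one factor
        from pollengerm.segmentation import measure_region

        factors = []
        for px, n in ((0.5, 1), (0.25, 2)):
            tracks = []
            areas, lengths = [], []
            for length_px in (240 * n, 320 * n, 400 * n):
                m = np.zeros((40 * n, 440 * n), bool)
                m[15 * n : 15 * n + 10 * n, 10 * n : 10 * n + length_px] = True
                r = measure_region(m, px, tube_length=True)
                areas.append(r.area)
                lengths.append(r.tube_length)
            tracks.append(_track(np.array(areas), lengths=np.array(lengths)))
            factors.append(conversion_factor(tracks))
        assert factors[0] == pytest.approx(factors[1], rel=0.02)

    def test_no_qualifying_frames(self):
        with pytest.raises(InsufficientDataError):
            conversion_factor([_track(np.linspace(0, 50, 10), lengths=np.ones(10))])


class TestPhases:
    @staticmethod
    def _schedule_track(rng=None, noise=0.0):
        # slow bulge (5 frames), transition (3), then rapid elongation
        from pollengerm.cohorts import SLOW_FRAMES, TRANSITION_FRAMES, build_tube_schedule
        from pollengerm.growth_models import GrainGeometry

        grain = GrainGeometry(center=(24.3, 24.2))
        tube = build_tube_schedule(grain, 20, 2, 16.7, 31.0)
        from pollengerm._geom import polygon_roundness

        areas = tube.area_um2.copy()
        roundness = np.array(
            [polygon_roundness(r) if not r.is_empty else np.nan for r in tube.schedule.regions]
        )
        if rng is not None and noise > 0:
            areas = areas + rng.normal(0, noise, areas.size) * np.maximum(areas, 1)
            roundness = roundness + rng.normal(0, 0.02, roundness.size)
        t = _track(areas, roundness=roundness, t0=1)
        return t, tube.schedule.transition_frame

    def test_transition_boundary_recovered(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            track, true_transition = self._schedule_track(rng, noise=0.02)
            phases = phase_annotate(track)
            assert not phases.degenerate
            if abs(phases.boundaries["transition_end"] - true_transition) <= 2:
                hits += 1
        assert hits >= 45

    def test_phase_order_and_contiguity(self):
        track, _ = self._schedule_track()
        phases = phase_annotate(track)
        order = ["pre-germination", "bulging", "transition", "rapid"]
        labels = list(phases.labels)
        seen = [k for k, _ in itertools.groupby(labels)]
        assert seen == order

    def test_degenerate_flat_series_flagged(self):
        track = _track(np.linspace(0, 300, 25), roundness=np.full(25, 0.8))
        phases = phase_annotate(track)
        assert phases.degenerate and phases.labels is None

    def test_missing_roundness_declined(self):
        roundness = np.full(25, np.nan)
        track = _track(np.linspace(0, 300, 25), roundness=roundness)
        with pytest.raises(InsufficientDataError):
            phase_annotate(track)


class TestDeceleration:
    @staticmethod
    def _dip_track(dip_areas=(200.0,)):
        rng = np.random.default_rng(2)
        inc = np.concatenate([np.full(5, 1.0), np.full(3, 4.0), np.full(30, 12.0)])
        areas = np.concatenate([[0.0], np.cumsum(inc)])
        for dip in dip_areas:
            i = int(np.argmin(np.abs(areas - dip)))
            areas[i] = areas[i - 1] + 1.0  # local slowdown around the dip area
        roundness = np.concatenate([[np.nan], np.linspace(0.5, 1.0, 8), np.linspace(1.0, 0.3, 30)])
        return _track(areas, roundness=roundness)

    def test_injected_dip_recovered_at_its_area(self):
        events = detect_deceleration(self._dip_track((200.0,)))
        assert len(events) == 1
        assert events[0].area_um2 == pytest.approx(200.0, abs=15.0)

    def test_strictly_increasing_series_has_no_events(self):
        events = detect_deceleration(self._dip_track(()))
        assert events == []

    def test_two_dips_two_events(self):
        events = detect_deceleration(self._dip_track((150.0, 280.0)))
        assert len(events) == 2


class TestPopulationSummary:
    def test_identical_tracks_zero_se(self):
        t = _track(np.linspace(0, 400, 21))
        table, rate = population_summary([t, _track(np.linspace(0, 400, 21))])
        assert np.allclose(table["se_um2"], 0.0)
        assert rate == pytest.approx(400.0)

    def test_two_track_formulas(self):
        a = _track(np.full(21, 100.0))
        b = _track(np.full(21, 140.0))
        table, _ = population_summary([a, b])
        assert np.allclose(table["mean_area_um2"], 120.0)
        assert np.allclose(table["se_um2"], 20.0)  # |a-b|/2 for n=2
        assert (table["n"] == 2).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=3, max_size=20
    )
)
def test_friedman_statistic_nonnegative_and_p_valid(pairs):
    data = np.array(pairs)
    q, df, p = friedman_test(data)
    assert q >= 0.0
    assert df == 1
    assert 0.0 <= p <= 1.0
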