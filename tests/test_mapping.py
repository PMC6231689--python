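"""Segment-relative event mapping, midline exclusion, tabulation, t test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apomap import (
    BoundarySkeleton,
    EventRecord,
    MappingError,
    SyntheticEmbryoSpec,
    compare_mean_intensity,
    detect_events,
    exclude_midline,
    generate_embryo_image,
    map_event,
    map_events,
    order_boundaries,
    segment_stripes,
    skeletonize_stripes,
    tabulate_histogram,
)
from conftest import brute_force_distance


def _vertical_skeleton(xs, height=100):
    """BoundarySkeleton of straight vertical single-pixel lines at columns xs."""
    stripes = [np.array([(r, x) for r in range(height)]) for x in xs]
    return BoundarySkeleton(stripes=stripes)


class TestOrderBoundaries:
    def test_two_segments_from_three_stripes(self):
        b = order_boundaries(_vertical_skeleton([30, 90, 150]))
        assert list(b.median_x) == [30, 90, 150]

    def test_shuffled_input_same_order(self):
        a = order_boundaries(_vertical_skeleton([150, 30, 90]))
        b = order_boundaries(_vertical_skeleton([30, 90, 150]))
        assert np.array_equal(a.median_x, b.median_x)

    def test_single_stripe_raises(self):
        with pytest.raises(MappingError, match="cannot define a segment"):
            order_boundaries(_vertical_skeleton([50]))

    def test_ambiguous_order_raises(self):
        sk = BoundarySkeleton(
            stripes=[
                np.array([(r, 50) for r in range(50)]),
                np.array([(r, 50) for r in range(50, 100)]),
                np.array([(r, 120) for r in range(100)]),
            ]
        )
        with pytest.raises(MappingError, match="ambiguous"):
            order_boundaries(sk)


class TestMapEvent:
    def test_symmetric_event_is_at_fifty_percent(self):
        b = order_boundaries(_vertical_skeleton([100, 200]))
        rec = map_event(0, 150.0, 40.0, b)
        assert rec.rel_pos_pct == pytest.approx(50.0)
        assert rec.segment_index == 0

    def test_event_on_boundary_pixel_is_zero(self):
        b = order_boundaries(_vertical_skeleton([100, 200, 300]))
        rec = map_event(0, 200.0, 40.0, b)
        assert rec.rel_pos_pct == 0.0
        assert rec.segment_index == 1  # anterior boundary of posterior segment

    def test_outside_events_unmappable(self):
        b = order_boundaries(_vertical_skeleton([100, 200]))
        assert map_event(0, 50.0, 10.0, b).unmappable
        assert map_event(1, 250.0, 10.0, b).unmappable
        assert map_event(2, 200.0, 10.0, b).unmappable  # on last boundary

    def test_curved_boundaries_match_exhaustive_scan(self):
        spec = SyntheticEmbryoSpec(
            image_height_px=200, image_width_px=420, n_segments=6,
            event_count=0, noise_sd=0.0, stripe_wiggle_amplitude_px=5.0, seed=3,
        )
        img, _ = generate_embryo_image(spec)
        sk = skeletonize_stripes(segment_stripes(img[0], spec.stripe_intensity / 2))
        b = order_boundaries(sk)
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [rng.uniform(b.median_x[0], b.median_x[-1], 200), rng.uniform(0, 199, 200)]
        )
        for rec in map_events([tuple(p) for p in pts], b):
            if rec.unmappable:
                continue
            i = rec.segment_index
            assert rec.d_anterior_px == pytest.approx(
                brute_force_distance(rec.x_px, rec.y_px, sk.stripes[i]), abs=1e-9
            )
            assert rec.d_posterior_px == pytest.approx(
                brute_force_distance(rec.x_px, rec.y_px, sk.stripes[i + 1]), abs=1e-9
            )

    def test_position_recovery_straight_stripes(self, clean_embryo, clean_spec):
        img, gt = clean_embryo
        sk = skeletonize_stripes(segment_stripes(img[0], clean_spec.stripe_intensity / 2))
        b = order_boundaries(sk)
        ev = detect_events(img[1], clean_spec.stripe_intensity / 2)
        seg_w = np.diff(clean_spec.boundary_x_px)[0]
        recs = map_events(ev.events, b)
        truth = np.array([(e.x_px, e.y_px, e.true_rel_pos) for e in gt.events])
        for rec in recs:
            if not rec.retained:
                continue
            d = np.abs(truth[:, :2] - [rec.x_px, rec.y_px]).max(axis=1)
            true_rel = truth[np.argmin(d), 2]
            assert abs(rec.rel_pos_pct / 100 - true_rel) <= 2.0 / seg_w

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        x=st.floats(0, 419), y=st.floats(0, 199),
        wig=st.floats(0, 6),
    )
    def test_rel_pos_always_in_range(self, x, y, wig):
        xs = [60, 120, 180, 240, 300, 360]
        stripes = [
            np.array([(r, int(round(bx + wig * np.sin(r / 30)))) for r in range(200)])
            for bx in xs
        ]
        rec = map_event(0, x, y, order_boundaries(BoundarySkeleton(stripes=stripes)))
        if not rec.unmappable:
            assert 0.0 <= rec.rel_pos_pct <= 100.0


class TestExcludeMidline:
    def _records(self, ys):
        return [EventRecord(i, 10.0, float(y), rel_pos_pct=50.0, segment_index=0)
                for i, y in enumerate(ys)]

    def test_zero_fraction_excludes_nothing(self):
        recs = self._records([10, 100, 190])
        assert len(exclude_midline(recs, 0, 200, fraction=0.0)) == 3

    def test_full_fraction_excludes_everything(self):
        recs = self._records([10, 100, 190])
        assert exclude_midline(recs, 0, 200, fraction=1.0) == []

    def test_invalid_fraction_raises(self):
        with pytest.raises(ValueError):
            exclude_midline([], 0, 200, fraction=1.5)
        with pytest.raises(ValueError):
            exclude_midline([], 200, 0, fraction=0.5)

    def test_matches_generator_flags_exactly(self, small_embryo, small_spec):
        _, gt = small_embryo
        recs = [
            EventRecord(i, e.x_px, e.y_px, rel_pos_pct=50.0, segment_index=0)
            for i, e in enumerate(gt.events)
        ]
        exclude_midline(recs, 0.0, small_spec.image_height_px, small_spec.midline_fraction)
        for rec, truth in zip(recs, gt.events):
            assert rec.excluded_midline == truth.is_midline


class TestTabulate:
    def _recs(self, vals):
        return [EventRecord(i, 0, 0, rel_pos_pct=v, segment_index=0)
                for i, v in enumerate(vals)]

    def test_hand_counted_single_embryo(self):
        h = tabulate_histogram([self._recs([10.0, 10.0, 90.0])], n_bins=10,
                               normalize=False)
        expected = np.zeros(10)
        expected[1] = 2  # 10 falls in [10, 20)
        expected[9] = 1
        assert np.array_equal(h.per_embryo_counts[0], expected)
        assert np.array_equal(h.mean_frequency, expected)
        assert np.all(h.sd == 0)

    def test_last_bin_closed(self):
        h = tabulate_histogram([self._recs([100.0])], n_bins=10, normalize=False)
        assert h.per_embryo_counts[0, 9] == 1

    def test_identical_embryos_zero_sd(self):
        recs = self._recs([5.0, 42.0, 77.0])
        h = tabulate_histogram([recs, self._recs([5.0, 42.0, 77.0])], n_bins=10)
        assert np.all(h.sd == 0)

    def test_row_sums_equal_retained_counts(self):
        recs = self._recs([5.0, 42.0, 77.0, 77.5])
        recs[0].excluded_midline = True
        recs[1].unmappable = True
        h = tabulate_histogram([recs], n_bins=5, normalize=False)
        assert h.per_embryo_counts[0].sum() == 2

    def test_beta_positions_peak_mid_segment(self):
        rng = np.random.default_rng(42)
        embryos = [self._recs(100 * rng.beta(2, 2, 500)) for _ in range(20)]
        h = tabulate_histogram(embryos, n_bins=10)
        mid = h.mean_frequency[4:6].mean()
        assert mid > h.mean_frequency[0]
        assert mid > h.mean_frequency[9]
        # non-increasing from center toward both edges, within sampling noise
        left = h.mean_frequency[:5]
        right = h.mean_frequency[5:]
        assert np.all(np.diff(left) >= -0.01)
        assert np.all(np.diff(right) <= 0.01)

    def test_zero_embryos_raises(self):
        with pytest.raises(MappingError):
            tabulate_histogram([], n_bins=10)


class TestCompareMeanIntensity:
    def test_identical_groups(self):
        r = compare_mean_intensity([1, 2, 3], [1, 2, 3])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_closed_form_example(self):
        r = compare_mean_intensity([1, 2, 3], [4, 5, 6])
        # pooled variance = 1, se = sqrt(2/3), df = 4
        t_expected = -3.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert r.t == pytest.approx(t_expected, abs=1e-9)
        assert round(r.t, 3) == -3.674
        assert r.p == pytest.approx(p_expected, abs=1e-9)
        assert r.p == pytest.approx(0.0214, abs=5e-4)
        assert (r.mean_a, r.mean_b) == (2.0, 5.0)
        assert r.sd_a == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.01, 1e4))
    def test_scale_invariance(self, c):
        base = compare_mean_intensity([1, 2, 3], [2, 4, 8])
        scaled = compare_mean_intensity([c, 2 * c, 3 * c], [2 * c, 4 * c, 8 * c])
        assert scaled.t == pytest.approx(base.t, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            compare_mean_intensity([1], [2, 3])
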