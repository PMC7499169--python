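import numpy as np
import pytest

from plaquant import (
    GBHistogram,
    Label,
    UVImage,
    auto_delta,
    auto_l,
    classify,
    gb_histogram,
    gb_map,
    nonvisible_histogram,
)
from plaquant.classification import GB_MIN, N_BINS
from plaquant.errors import DegenerateSegmentationError, ParameterError

from conftest import classify_loop, random_uv_image


def uniform_image(shape, r, g, b):
    px = np.empty(shape + (3,), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return UVImage(px)


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestGBMap:
    @pytest.mark.parametrize("g,b,expected", [(200, 50, 150), (50, 200, -150)])
    def test_signed_difference(self, g, b, expected):
        img = uniform_image((4, 4), 10, g, b)
        assert (gb_map(img, full_mask((4, 4))).values == expected).all()

    def test_matches_scalar_loop(self, rng):
        img = random_uv_image(rng, (25, 25))
        mask = rng.random((25, 25)) < 0.6
        gb = gb_map(img, mask)
        for y, x in zip(*np.nonzero(mask)):
            assert gb.values[y, x] == int(img.pixels[y, x, 1]) - int(img.pixels[y, x, 2])


class TestAutoDelta:
    def test_uniform_channels(self):
        img = uniform_image((8, 8), 0, 100, 160)
        assert auto_delta(img, full_mask((8, 8))) == -60.0

    def test_equal_means_give_zero(self):
        img = uniform_image((8, 8), 0, 120, 120)
        assert auto_delta(img, full_mask((8, 8))) == 0.0

    def test_matches_mean_accumulation_oracle(self, rng):
        img = random_uv_image(rng, (30, 30))
        mask = rng.random((30, 30)) < 0.5
        sb = sg = n = 0
        for y, x in zip(*np.nonzero(mask)):
            sg += int(img.pixels[y, x, 1])
            sb += int(img.pixels[y, x, 2])
            n += 1
        assert auto_delta(img, mask) == pytest.approx(-abs(sb / n - sg / n))

    def test_empty_mask_raises(self):
        img = uniform_image((4, 4), 0, 10, 10)
        with pytest.raises(DegenerateSegmentationError):
            auto_delta(img, np.zeros((4, 4), dtype=bool))

    def test_always_non_positive(self, rng):
        for _ in range(20):
            img = random_uv_image(rng, (16, 16))
            assert auto_delta(img, full_mask((16, 16))) <= 0


def hist_from_counts(pairs):
    counts = np.zeros(N_BINS, dtype=np.int64)
    for v, c in pairs:
        counts[v - GB_MIN] = c
    return GBHistogram(counts)


class TestAutoL:
    def test_identical_histograms_fall_back_to_delta(self):
        h = hist_from_counts([(-80, 5), (-10, 3)])
        assert auto_l(h, h, delta=-25.0) == -25.0

    def test_single_exceeding_bin(self):
        ref = hist_from_counts([])
        cur = hist_from_counts([(-80, 5)])
        assert auto_l(cur, ref, delta=-10.0) == -80

    def test_scan_direction_most_negative_first(self):
        ref = hist_from_counts([(-120, 1), (-40, 1)])
        cur = hist_from_counts([(-120, 5), (-40, 5)])
        assert auto_l(cur, ref, delta=0.0) == -120

    def test_positive_side_ignored(self):
        ref = hist_from_counts([])
        cur = hist_from_counts([(50, 99)])
        assert auto_l(cur, ref, delta=-5.0) == -5.0

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(200):
            cur = GBHistogram(rng.integers(0, 4, size=N_BINS))
            ref = GBHistogram(rng.integers(0, 4, size=N_BINS))
            delta = -float(rng.integers(0, 100))
            expected = delta
            for v in range(-255, 1):
                if cur.count(v) > ref.count(v):
                    expected = v
                    break
            assert auto_l(cur, ref, delta) == expected


class TestClassify:
    def test_boundary_semantics(self):
        # one pixel per case, delta=-30, l=-90
        gbs = [+1, 0, -30, -31, -90, -91]
        expect = [Label.VISIBLE, Label.NV1, Label.NV1, Label.NV2,
                  Label.NV2, Label.NONPLAQUE]
        px = np.zeros((1, 6, 3), dtype=np.uint8)
        px[..., 2] = 120
        px[0, :, 1] = [120 + v for v in gbs]
        img = UVImage(px)
        mask = full_mask((1, 6))
        labels = classify(gb_map(img, mask), img, mask, -30.0, -90.0)
        assert labels.labels[0].tolist() == [int(e) for e in expect]

    def test_collapsed_thresholds(self, rng):
        img = random_uv_image(rng, (32, 32))
        mask = full_mask((32, 32))
        labels = classify(gb_map(img, mask), img, mask, 0.0, 0.0)
        present = set(np.unique(labels.labels))
        assert Label.NV2 not in present
        # NV1 may only occur exactly at G-B = 0
        nv1 = labels.labels == Label.NV1
        assert (gb_map(img, mask).values[nv1] == 0).all()

    def test_zero_channel_guard_labels_nonplaque(self):
        px = np.zeros((1, 2, 3), dtype=np.uint8)
        px[0, 0] = (0, 0, 0)      # black dental pixel
        px[0, 1] = (0, 0, 100)    # G == 0
        img = UVImage(px)
        mask = full_mask((1, 2))
        labels = classify(gb_map(img, mask), img, mask, -200.0, -250.0)
        assert (labels.labels == Label.NONPLAQUE).all()

    def test_invalid_thresholds_raise(self, rng):
        img = random_uv_image(rng, (4, 4))
        mask = full_mask((4, 4))
        gb = gb_map(img, mask)
        with pytest.raises(ParameterError):
            classify(gb, img, mask, -10.0, -5.0)  # l > delta
        with pytest.raises(ParameterError):
            classify(gb, img, mask, 5.0, -5.0)    # delta > 0

    def test_matches_per_pixel_oracle(self, rng):
        img = random_uv_image(rng, (48, 48))
        mask = rng.random((48, 48)) < 0.7
        delta, l = -40.0, -120.0
        labels = classify(gb_map(img, mask), img, mask, delta, l)
        assert (labels.labels == classify_loop(img, mask, delta, l)).all()

    def test_idempotent_and_deterministic(self, rng):
        img = random_uv_image(rng, (20, 20))
        mask = full_mask((20, 20))
        gb = gb_map(img, mask)
        a = classify(gb, img, mask, -20.0, -60.0)
        b = classify(gb, img, mask, -20.0, -60.0)
        assert (a.labels == b.labels).all()

    def test_partition_on_random_pairs(self, rng):
        # every (G, B) pair lands in exactly one class given l <= delta <= 0
        n = 10 ** 6
        g = rng.integers(0, 256, size=n)
        b = rng.integers(0, 256, size=n)
        v = g - b
        delta, l = -35.0, -110.0
        guard = (g > 0) & (b > 0)
        visible = v > 0
        nv1 = ~visible & guard & (v >= delta)
        nv2 = ~visible & guard & (v < delta) & (v >= l)
        nonplaque = ~(visible | nv1 | nv2)
        counts = visible.astype(int) + nv1 + nv2 + nonplaque
        assert (counts == 1).all()

    def test_delta_monotonicity(self, plaque_scene):
        from plaquant import segment_dental_area

        img, _, _ = plaque_scene
        mask = segment_dental_area(img)
        gb = gb_map(img, mask)
        prev_nv1 = -1
        visible0 = nonplaque0 = None
        l = -200.0
        for delta in [0.0, -25.0, -50.0, -75.0, -100.0]:
            labels = classify(gb, img, mask, delta, min(l, delta))
            nv1 = labels.count(Label.NV1)
            assert nv1 >= prev_nv1
            prev_nv1 = nv1
            if visible0 is None:
                visible0 = labels.count(Label.VISIBLE)
                nonplaque0 = labels.count(Label.NONPLAQUE)
            assert labels.count(Label.VISIBLE) == visible0
            assert labels.count(Label.NONPLAQUE) == nonplaque0


class TestHistograms:
    def test_single_bin(self):
        img = uniform_image((10, 10), 0, 60, 100)  # G-B = -40 everywhere
        gb = gb_map(img, full_mask((10, 10)))
        h = gb_histogram(gb)
        assert h.count(-40) == 100 and h.total == 100

    def test_empty_mask_all_zero(self):
        img = uniform_image((5, 5), 0, 10, 20)
        h = gb_histogram(gb_map(img, np.zeros((5, 5), dtype=bool)))
        assert h.total == 0

    def test_matches_tally_loop(self, rng):
        img = random_uv_image(rng, (30, 30))
        mask = rng.random((30, 30)) < 0.5
        h = gb_histogram(gb_map(img, mask))
        tally = {}
        for y, x in zip(*np.nonzero(mask)):
            v = int(img.pixels[y, x, 1]) - int(img.pixels[y, x, 2])
            tally[v] = tally.get(v, 0) + 1
        for v, c in tally.items():
            assert h.count(v) == c
        assert h.total == int(np.count_nonzero(mask))

    def test_nonvisible_histogram_applies_guard(self):
        px = np.zeros((1, 3, 3), dtype=np.uint8)
        px[0, 0] = (0, 50, 90)   # G-B = -40, counted
        px[0, 1] = (0, 0, 90)    # G = 0, excluded
        px[0, 2] = (0, 120, 90)  # G-B > 0, excluded
        img = UVImage(px)
        mask = full_mask((1, 3))
        h = nonvisible_histogram(img, gb_map(img, mask))
        assert h.total == 1 and h.count(-40) == 1

    def test_visible_mass_non_decreasing_over_growing_series(self):
        from datetime import datetime, timedelta

        from plaquant import default_scene, render_series, segment_dental_area

        ts = [datetime(2025, 1, 6) + timedelta(hours=24 * i) for i in range(4)]
        series = render_series(default_scene(seed=7), rate=0.8, timestamps=ts)
        prev = -1
        for moment, _ in series:
            img = moment.images[0]
            mask = segment_dental_area(img)
            h = gb_histogram(gb_map(img, mask))
            positive_mass = int(h.counts[-255:].sum()) / h.total
            assert positive_mass >= prev - 1e-9
            prev = positive_mass
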