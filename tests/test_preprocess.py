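"""Window extraction, skewing and the floor-quantized image conversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ecgvision as ev
from ecgvision.preprocess import EmptyDatasetError


def brute_force_image(samples, min_limit, max_limit, h):
    """Independent per-pixel oracle: loop, floor, clamp."""
    d = max_limit - min_limit
    pixels = []
    for c, v in enumerate(samples):
        v = min(max(float(v), min_limit), max_limit)
        r = math.floor((v - min_limit) / d * h)
        r = min(max(r, 0), h - 1)
        pixels.append((c, r))
    return pixels


def _record(n_samples, ann_indices, fs=360.0):
    rng = np.random.default_rng(0)
    return ev.EcgRecord(
        "t", rng.normal(size=(1, n_samples)), fs, ["MLII"],
        annotations=[ev.BeatAnnotation(i, "N") for i in ann_indices],
    )


class TestExtractWindows:
    def test_window_near_start_discarded(self):
        rec = _record(1000, [50])
        assert ev.extract_windows(rec, 180) == []

    def test_boundary_discard_matches_bounds_check(self):
        rec = _record(1000, [200, 500, 950])
        wins = ev.extract_windows(rec, 180)
        assert [w.center_index for w in wins] == [200, 500]

    def test_window_length_and_center_identity(self):
        rec = _record(2000, [400, 1000, 1500])
        for w in ev.extract_windows(rec, 180):
            assert w.n == 180
            assert w.samples[90] == rec.signal[0][w.center_index]
            assert w.skew_offset == 0

    def test_no_annotations_gives_empty_list(self):
        assert ev.extract_windows(_record(1000, []), 180) == []

    def test_odd_window_length_rejected(self):
        with pytest.raises(ValueError):
            ev.extract_windows(_record(1000, [500]), 181)

    def test_nonbeat_class_windows_kept(self):
        rec = ev.EcgRecord(
            "z", np.zeros((1, 1000)), 360.0, ["MLII"],
            annotations=[ev.BeatAnnotation(500, "Z")],
        )
        wins = ev.extract_windows(rec, 180)
        assert len(wins) == 1 and wins[0].label == "Z"


class TestApplySkew:
    def test_offset_bounded_by_quarter_window(self, rng):
        rec = _record(10000, [5000])
        w = ev.extract_windows(rec, 180)[0]
        for _ in range(200):
            s = ev.apply_skew(w, rec, rng)
            assert abs(s.skew_offset) <= 45
            assert s.n == 180

    def test_zero_offset_is_identity(self, rng):
        rec = _record(10000, [5000])
        w = ev.extract_windows(rec, 180)[0]
        for _ in range(500):
            s = ev.apply_skew(w, rec, rng)
            if s.skew_offset == 0:
                np.testing.assert_array_equal(s.samples, w.samples)
                break
        else:
            pytest.fail("no zero offset drawn in 500 tries")

    def test_seeded_determinism(self):
        rec = _record(10000, [5000])
        w = ev.extract_windows(rec, 180)[0]
        offs1 = [ev.apply_skew(w, rec, np.random.default_rng(9)).skew_offset
                 for _ in range(1)]
        offs2 = [ev.apply_skew(w, rec, np.random.default_rng(9)).skew_offset
                 for _ in range(1)]
        assert offs1 == offs2

    def test_boundary_fallback_to_zero(self):
        # annotation exactly n/2 from the start: any negative offset overruns
        rec = _record(600, [90])
        w = ev.extract_windows(rec, 180)[0]
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = ev.apply_skew(w, rec, rng)
            assert 0 <= s.center_index + s.skew_offset - 90

    def test_skew_offsets_uniform_over_range(self):
        """10,000 draws cover [-45, 45] and pass a chi-square check."""
        rec = _record(10000, [5000])
        w = ev.extract_windows(rec, 180)[0]
        rng = np.random.default_rng(2024)
        offs = np.array(
            [ev.apply_skew(w, rec, rng).skew_offset for _ in range(10000)]
        )
        assert offs.min() == -45 and offs.max() == 45
        counts = np.bincount(offs + 45, minlength=91)
        assert stats.chisquare(counts).pvalue > 0.01


class TestSignalToImage:
    def test_worked_five_sample_example(self):
        img = ev.signal_to_image([300, 325, 600, 100, 300], 0, 700, 5)
        assert img.lit_pixels() == [(0, 2), (1, 2), (2, 4), (3, 0), (4, 2)]

    def test_constant_signal_at_min_limit_lights_row_zero(self):
        img = ev.signal_to_image(np.zeros(10), 0.0, 1.0, 8)
        assert all(r == 0 for _, r in img.lit_pixels())

    def test_max_limit_clamps_to_top_row(self):
        img = ev.signal_to_image([1.0, 2.0, 0.5], 0.0, 1.0, 8)
        assert img.lit_pixels() == [(0, 7), (1, 7), (2, 4)]

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            ev.signal_to_image([1.0], 1.0, 1.0, 5)

    def test_agrees_with_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            lo = rng.uniform(-5, 5)
            hi = lo + rng.uniform(0.5, 10)
            h = int(rng.integers(1, 33))
            n = int(rng.integers(1, 51))
            samples = rng.uniform(lo - 1, hi + 1, n)  # includes out-of-range
            img = ev.signal_to_image(samples, lo, hi, h)
            assert img.lit_pixels() == brute_force_image(samples, lo, hi, h)
            # conservation: exactly one lit pixel per column, all in range
            assert (img.grid == 255).sum(axis=0).tolist() == [1] * n
            assert img.grid.shape == (h, n)

    @given(
        v1=st.floats(0, 1), v2=st.floats(0, 1),
        h=st.integers(1, 64),
    )
    def test_monotone_per_column(self, v1, v2, h):
        lo_v, hi_v = sorted([v1, v2])
        img = ev.signal_to_image([lo_v, hi_v], 0.0, 1.0, h)
        rows = [r for _, r in img.lit_pixels()]
        assert rows[0] <= rows[1]


class TestImageToSignal:
    def test_round_trip_error_bounded_by_bin_width(self, rng):
        for h in (5, 16, 64, 512):
            samples = rng.uniform(0, 1, 100)
            img = ev.signal_to_image(samples, 0.0, 1.0, h)
            back = ev.image_to_signal(img)
            assert np.abs(back - samples).max() <= 1.0 / h

    def test_worked_example_decodes_within_bin_width(self):
        samples = [300, 325, 600, 100, 300]
        img = ev.signal_to_image(samples, 0, 700, 5)
        back = ev.image_to_signal(img)
        assert np.abs(back - np.array(samples)).max() <= 700 / 5


class TestBuildDataset:
    def test_split_arithmetic_and_determinism(self, two_class_record):
        train, test = ev.build_dataset([two_class_record], 180, 64, seed=5)
        total = len(train) + len(test)
        assert len(train) == int(total * 0.9)
        train2, test2 = ev.build_dataset([two_class_record], 180, 64, seed=5)
        for (a, ia), (b, ib) in zip(train + test, train2 + test2):
            assert ia == ib
            np.testing.assert_array_equal(a.grid, b.grid)

    def test_aligned_dataset_images_match_center_cut(self, normal_record):
        train, test = ev.build_dataset([normal_record], 180, 64, skewed=False,
                                       seed=0)
        assert all(img.width == 180 and img.height == 64
                   for img, _ in train + test)

    def test_skewed_flag_changes_images(self, two_class_record):
        a_train, _ = ev.build_dataset([two_class_record], 180, 64,
                                      skewed=False, seed=1)
        s_train, _ = ev.build_dataset([two_class_record], 180, 64,
                                      skewed=True, seed=1)
        diff = sum(
            not np.array_equal(a.grid, b.grid)
            for (a, _), (b, _) in zip(a_train, s_train)
        )
        assert diff > 0

    def test_empty_dataset_is_an_error(self):
        rec = ev.EcgRecord("e", np.zeros((1, 100)) + 0.5, 360.0, ["MLII"])
        with pytest.raises(EmptyDatasetError):
            ev.build_dataset([rec], 180, 64)

    def test_save_and_load_round_trip(self, small_dataset, tmp_path):
        train, test = small_dataset
        ev.preprocess.save_dataset(train[:5], tmp_path, split="train")
        ev.preprocess.save_dataset(test[:3], tmp_path, split="test")
        back = ev.preprocess.load_dataset(tmp_path, "train")
        assert len(back) == 5
        np.testing.assert_array_equal(back[0][0].grid, train[0][0].grid)
        assert back[0][1] == train[0][1]
        assert len(ev.preprocess.load_dataset(tmp_path, "test")) == 3
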