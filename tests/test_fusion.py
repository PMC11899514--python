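import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smwbf.clustering import Cluster, ClusterParams, Detection
from smwbf.fusion import (
    OutlierParams,
    PaddingParams,
    filter_outliers,
    fuse_cluster,
    optimize_image,
    pad_box,
)
from smwbf.geometry import NormBox, to_pixel
from smwbf.weighting import DetectorProfile, softmax_weights


def make_cluster(boxes, detectors=None):
    detectors = detectors or [f"net{i:02d}" for i in range(len(boxes))]
    return Cluster(0, tuple(Detection(b, d) for b, d in zip(boxes, detectors)))


class TestFilterOutliers:
    def test_identical_boxes_unchanged(self):
        c = make_cluster([NormBox(0.5, 0.5, 0.2, 0.2)] * 4)
        assert filter_outliers(c).members == c.members

    def test_oversized_member_removed(self):
        # widths {0.10, 0.10, 0.30}: mean 1/6, band [1/12, 1/4) drops the third
        c = make_cluster(
            [NormBox(0.5, 0.5, w, 0.2) for w in (0.10, 0.10, 0.30)]
        )
        kept = filter_outliers(c, OutlierParams(threshold=0.5))
        assert [d.box.w for d in kept.members] == [0.10, 0.10]

    def test_band_is_inclusive_below_exclusive_above(self):
        # mean width 0.5, band [0.25, 0.75): a box exactly at the lower bound
        # stays, one exactly at the upper bound goes (dyadic values keep the
        # bound arithmetic exact in floating point).
        lower = make_cluster([NormBox(0.5, 0.5, w, 0.2) for w in (0.25, 0.75)])
        kept = filter_outliers(lower)
        assert [d.box.w for d in kept.members] == [0.25]

    def test_all_removed_keeps_nearest_to_mean_with_tie_break(self):
        # widths {0.10, 0.40}: mean 0.25, band [0.125, 0.375) excludes both;
        # equidistant from the mean, so the smaller box wins the tie.
        c = make_cluster([NormBox(0.5, 0.5, w, 0.2) for w in (0.10, 0.40)])
        kept = filter_outliers(c)
        assert len(kept.members) == 1
        assert kept.members[0].box.w == 0.10

    def test_means_use_all_members_in_one_pass(self):
        # Exhaustive check of the size band over every member.
        widths = (0.12, 0.18, 0.5, 0.21)
        heights = (0.2, 0.2, 0.2, 0.45)
        c = make_cluster(
            [NormBox(0.5, 0.5, w, h) for w, h in zip(widths, heights)]
        )
        t = 0.5
        wm, hm = np.mean(widths), np.mean(heights)
        expected = [
            (w, h)
            for w, h in zip(widths, heights)
            if (1 - t) * wm <= w < (1 + t) * wm and (1 - t) * hm <= h < (1 + t) * hm
        ]
        kept = filter_outliers(c, OutlierParams(threshold=t))
        assert [(d.box.w, d.box.h) for d in kept.members] == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            OutlierParams(threshold=0.0)
        with pytest.raises(ValueError):
            OutlierParams(threshold=1.0)


class TestFuseCluster:
    def test_singleton_returns_member_box_exactly(self):
        box = NormBox(0.123456, 0.654321, 0.111, 0.222)
        c = make_cluster([box])
        w = softmax_weights([DetectorProfile("net00", 0.7)])
        assert fuse_cluster(c, w) is box

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        c = make_cluster([NormBox(0.3, 0.3, 0.2, 0.2), NormBox(0.5, 0.5, 0.4, 0.4)])
        w = softmax_weights(
            [DetectorProfile("net00", 0.6), DetectorProfile("net01", 0.6)]
        )
        fused = fuse_cluster(c, w)
        assert (fused.cx, fused.cy, fused.w, fused.h) == pytest.approx(
            (0.4, 0.4, 0.3, 0.3), abs=1e-12
        )

    def test_unequal_weights_closed_form(self):
        # Higher-mAP detector (0.9) at cx=1, lower (0.8) at cx=0: the fused
        # center equals the stronger detector's weight, 1/(1+e^-0.1).
        c = Cluster(
            0,
            (
                Detection(NormBox(1.0, 0.5, 0.2, 0.2), "a"),
                Detection(NormBox(0.0, 0.5, 0.2, 0.2), "b"),
            ),
        )
        w = softmax_weights([DetectorProfile("a", 0.9), DetectorProfile("b", 0.8)])
        expected = 1.0 / (1.0 + math.exp(-0.1))
        assert fuse_cluster(c, w).cx == pytest.approx(expected, abs=1e-12)
        assert fuse_cluster(c, w).cx == pytest.approx(0.52498, abs=5e-6)

    def test_same_detector_boxes_each_carry_its_weight(self):
        # One detector contributing twice: plain mean of its two boxes.
        c = Cluster(
            0,
            (
                Detection(NormBox(0.2, 0.5, 0.2, 0.2), "a"),
                Detection(NormBox(0.4, 0.5, 0.2, 0.2), "a"),
            ),
        )
        w = softmax_weights([DetectorProfile("a", 0.9), DetectorProfile("b", 0.1)])
        assert fuse_cluster(c, w).cx == pytest.approx(0.3, abs=1e-12)

    def test_unknown_detector_raises(self):
        c = make_cluster([NormBox(0.5, 0.5, 0.2, 0.2)], ["ghost"])
        w = softmax_weights([DetectorProfile("a", 0.5)])
        with pytest.raises(KeyError):
            fuse_cluster(c, w)

    def test_confidence_is_ignored(self):
        boxes = [NormBox(0.3, 0.3, 0.2, 0.2), NormBox(0.5, 0.5, 0.4, 0.4)]
        low = Cluster(0, tuple(
            Detection(b, f"net{i:02d}", confidence=0.01) for i, b in enumerate(boxes)
        ))
        high = Cluster(0, tuple(
            Detection(b, f"net{i:02d}", confidence=0.99) for i, b in enumerate(boxes)
        ))
        w = softmax_weights(
            [DetectorProfile("net00", 0.4), DetectorProfile("net01", 0.8)]
        )
        assert fuse_cluster(low, w) == fuse_cluster(high, w)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.1, 0.9), st.floats(0.1, 0.9),
                st.floats(0.02, 0.2), st.floats(0.02, 0.2),
                st.floats(0.01, 0.99),
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_convexity_and_permutation_invariance(self, data):
        boxes = [NormBox(cx, cy, w, h) for cx, cy, w, h, _ in data]
        profiles = [DetectorProfile(f"d{i}", m) for i, (_, _, _, _, m) in enumerate(data)]
        weights = softmax_weights(profiles)
        c = Cluster(0, tuple(
            Detection(b, p.detector_id) for b, p in zip(boxes, profiles)
        ))
        fused = fuse_cluster(c, weights)
        for attr in ("cx", "cy", "w", "h"):
            vals = [getattr(b, attr) for b in boxes]
            assert min(vals) - 1e-12 <= getattr(fused, attr) <= max(vals) + 1e-12
        shuffled = Cluster(0, tuple(reversed(c.members)))
        refused = fuse_cluster(shuffled, weights)
        assert (refused.cx, refused.cy, refused.w, refused.h) == pytest.approx(
            (fused.cx, fused.cy, fused.w, fused.h), abs=1e-12
        )


class TestPadBox:
    def test_zero_padding_is_exact_identity(self):
        b = NormBox(0.123456, 0.5, 0.1, 0.1)
        assert pad_box(b, PaddingParams(p=0, image_w=100, image_h=100)) is b

    def test_five_pixel_padding_in_pixel_space(self):
        # pixel box (10, 20, 50, 60) in 100x100 -> (5, 15, 55, 65)
        b = NormBox(0.3, 0.4, 0.4, 0.4)
        assert to_pixel(b, 100, 100) == to_pixel(
            NormBox(0.3, 0.4, 0.4, 0.4), 100, 100
        )
        padded = pad_box(b, PaddingParams(p=5, image_w=100, image_h=100))
        pix = to_pixel(padded, 100, 100)
        assert (pix.xmin, pix.ymin, pix.xmax, pix.ymax) == (5, 15, 55, 65)

    def test_pad_unpad_round_trip_in_pixels(self):
        b = NormBox(0.3, 0.4, 0.4, 0.4)
        params = PaddingParams(p=7, image_w=200, image_h=200)
        padded_pix = to_pixel(pad_box(b, params), 200, 200)
        unpadded = (
            padded_pix.xmin + 7, padded_pix.ymin + 7,
            padded_pix.xmax - 7, padded_pix.ymax - 7,
        )
        orig = to_pixel(b, 200, 200)
        assert unpadded == (orig.xmin, orig.ymin, orig.xmax, orig.ymax)

    def test_padding_may_exceed_unit_square(self):
        b = NormBox(0.02, 0.5, 0.04, 0.2)
        padded = pad_box(b, PaddingParams(p=10, image_w=100, image_h=100))
        assert padded.corners[0] < 0.0

    def test_negative_padding_rejected(self):
        with pytest.raises(ValueError):
            PaddingParams(p=-1)


class TestOptimizeImage:
    def test_empty_input(self):
        assert optimize_image([], [DetectorProfile("a", 0.5)]) == []

    def test_single_box_identity_with_zero_padding(self):
        box = NormBox(0.4, 0.6, 0.2, 0.1)
        out = optimize_image(
            [Detection(box, "a")],
            [DetectorProfile("a", 0.5)],
            padding_params=PaddingParams(p=0),
        )
        assert out == [box]

    def test_tight_ensemble_collapses_to_one_box(self, rng):
        # Ten detectors jittered well inside eps/2 of one lesion center.
        profiles = [DetectorProfile(f"net{i:02d}", 0.5 + 0.02 * i) for i in range(10)]
        dets = [
            Detection(
                NormBox(
                    0.5 + float(rng.uniform(-0.02, 0.02)),
                    0.5 + float(rng.uniform(-0.02, 0.02)),
                    0.2, 0.2,
                ),
                p.detector_id,
            )
            for p in profiles
        ]
        out = optimize_image(dets, profiles, ClusterParams(eps=0.1))
        assert len(out) == 1
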