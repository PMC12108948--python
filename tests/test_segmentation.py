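"""Jaw splitting, tooth-gap detection, and the end-to-end pipeline."""

import numpy as np
import pytest

from bwseg import (BinaryImage, DetectionError, ParameterError, PhantomSpec,
                   PipelineConfig, Radiograph, find_tooth_gaps, generate_phantom,
                   iou, segment_bitewing, segment_teeth, split_halves, split_jaws,
                   vertical_projection)
from bwseg.rotation import ProjectionProfile
from bwseg.segmentation import ToothSegment


class TestSplitJaws:
    def test_even_split(self, rng):
        img = Radiograph(rng.random((10, 6)))
        upper, lower = split_jaws(img, 5)
        assert upper.height == lower.height == 5

    def test_boundary_split(self, rng):
        img = Radiograph(rng.random((10, 6)))
        upper, _ = split_jaws(img, 1)
        assert upper.height == 1

    def test_stack_reconstructs_input(self, random_radiograph):
        upper, lower = split_jaws(random_radiograph, 17)
        stacked = np.vstack([upper.pixels, lower.pixels])
        assert np.array_equal(stacked, random_radiograph.pixels)

    @pytest.mark.parametrize("y", [0, 40, 99])  # image height is 40
    def test_out_of_range_rejected(self, random_radiograph, y):
        with pytest.raises(ParameterError):
            split_jaws(random_radiograph, y)


class TestVerticalProjection:
    def test_full_mask_counts_height(self):
        p = vertical_projection(BinaryImage(np.ones((7, 4), dtype=np.uint8)))
        assert p.axis == "column" and np.all(p.values == 7)

    def test_zero_mask(self):
        p = vertical_projection(BinaryImage(np.zeros((7, 4), dtype=np.uint8)))
        assert np.all(p.values == 0)

    def test_matches_per_column_loop_sum(self, rng):
        m = (rng.random((9, 13)) < 0.5).astype(np.uint8)
        p = vertical_projection(BinaryImage(m))
        oracle = [sum(m[y, x] for y in range(9)) for x in range(13)]
        assert list(p.values) == oracle


def profile(values):
    v = np.asarray(values)
    return ProjectionProfile("column", v, (0, len(v)))


class TestFindToothGaps:
    def test_single_deep_valley(self):
        assert find_tooth_gaps(profile([9, 9, 0, 9, 9]), min_separation=1) == [2]

    def test_flat_profile_single_tooth(self):
        assert find_tooth_gaps(profile([5] * 20), expected_teeth=1) == []

    def test_comb_profile_matches_valley_enumeration_oracle(self):
        # 4 plateaus of height 9 separated by 3 zero-valleys of width 3
        values = []
        for i in range(4):
            values += [9] * 6
            if i < 3:
                values += [0] * 3
        p = profile(values)
        seps = find_tooth_gaps(p, min_separation=2)
        # oracle: centers of the zero runs
        v = np.array(values)
        runs, start = [], None
        for i, x in enumerate(v):
            if x == 0 and start is None:
                start = i
            elif x != 0 and start is not None:
                runs.append((start + i - 1) // 2)
                start = None
        assert seps == runs == [7, 16, 25]

    def test_expected_teeth_selects_most_prominent(self):
        # two deep valleys, one shallow bump: ask for 3 teeth -> 2 separators
        values = [9] * 5 + [0] * 2 + [9] * 5 + [7] + [9] * 5 + [1] * 2 + [9] * 5
        seps = find_tooth_gaps(profile(values), expected_teeth=3, min_separation=2)
        assert len(seps) == 2 and 5 <= seps[0] <= 6 and 17 <= seps[1] <= 19

    def test_too_few_valleys_is_detection_error(self):
        with pytest.raises(DetectionError):
            find_tooth_gaps(profile([5] * 20), expected_teeth=3)


class TestSegmentTeeth:
    def test_single_cut(self, rng):
        row = Radiograph(rng.random((8, 20)))
        segs = segment_teeth(row, [10], trim=False)
        assert [s.box.width for s in segs] == [10, 10]

    def test_no_separators_one_segment(self, rng):
        row = Radiograph(rng.random((8, 20)))
        segs = segment_teeth(row, [], trim=False)
        assert len(segs) == 1 and segs[0].box.width == 20

    def test_widths_tile_the_row(self, rng):
        row = Radiograph(rng.random((8, 50)))
        segs = segment_teeth(row, [7, 20, 33], trim=True)
        assert sum(s.box.width for s in segs) == 50
        assert [s.index for s in segs] == [0, 1, 2, 3]

    def test_unsorted_separators_rejected(self, rng):
        row = Radiograph(rng.random((8, 20)))
        with pytest.raises(ParameterError):
            segment_teeth(row, [10, 5])

    def test_trim_clips_to_foreground_extent(self):
        px = np.full((10, 10), 0.1)
        px[3:7, :] = 0.9
        segs = segment_teeth(Radiograph(px), [], trim=True)
        assert segs[0].box.as_tuple() == (0, 3, 10, 7)


class TestSplitHalves:
    @pytest.mark.parametrize("width,left_w,right_w", [(10, 5, 5), (11, 5, 6)])
    def test_width_rule(self, rng, width, left_w, right_w):
        from bwseg import Box
        crop = Radiograph(rng.random((6, width)))
        seg = ToothSegment("upper", 0, "whole", Box(0, 0, width, 6), crop)
        left, right = split_halves(seg)
        assert (left.box.width, right.box.width) == (left_w, right_w)
        assert (left.half, right.half) == ("left", "right")

    def test_halves_reconstruct_whole(self, rng):
        from bwseg import Box
        crop = Radiograph(rng.random((6, 9)))
        seg = ToothSegment("lower", 2, "whole", Box(3, 1, 12, 7), crop)
        left, right = split_halves(seg)
        stitched = np.hstack([left.crop.pixels, right.crop.pixels])
        assert np.array_equal(stitched, crop.pixels)
        assert left.box.x1 == right.box.x0

    def test_narrow_segment_rejected(self):
        from bwseg import Box
        seg = ToothSegment("upper", 0, "whole", Box(0, 0, 1, 5),
                           Radiograph(np.zeros((5, 1))))
        with pytest.raises(ParameterError):
            split_halves(seg)


class TestSegmentBitewing:
    def test_tilted_phantom_counts_and_angle(self, tilted_phantom):
        img, _ = tilted_phantom
        res = segment_bitewing(img, PipelineConfig(halves=True))
        assert abs(res.rotation_deg - 7) <= 1
        assert len(res.whole_teeth()) == 8
        assert sum(s.half != "whole" for s in res.segments) == 16

    def test_single_tooth_per_jaw(self):
        img, _ = generate_phantom(PhantomSpec(n_upper=1, n_lower=1, seed=2))
        res = segment_bitewing(img)
        assert res.upper_separators == [] and res.lower_separators == []
        assert len(res.whole_teeth()) == 2

    def test_mean_iou_against_phantom_truth(self, tilted_phantom):
        img, truth = tilted_phantom
        res = segment_bitewing(img)
        ious = []
        for jaw in ("upper", "lower"):
            det = sorted(res.whole_teeth(jaw), key=lambda s: s.index)
            for seg, gt in zip(det, truth.boxes(jaw)):
                ious.append(iou(seg.box, gt))
        assert np.mean(ious) >= 0.7

    def test_structural_invariants(self, tilted_phantom):
        img, _ = tilted_phantom
        res = segment_bitewing(img, PipelineConfig(halves=True))
        for jaw, seps in (("upper", res.upper_separators), ("lower", res.lower_separators)):
            whole = sorted(res.whole_teeth(jaw), key=lambda s: s.index)
            # n teeth <=> n-1 separators
            assert len(seps) == len(whole) - 1
            assert seps == sorted(seps) and len(set(seps)) == len(seps)
            # horizontal tiling of the jaw row
            assert whole[0].box.x0 == 0
            assert whole[-1].box.x1 == img.width
            for a, b in zip(whole[:-1], whole[1:]):
                assert a.box.x1 == b.box.x0
            # indices consecutive from 0
            assert [s.index for s in whole] == list(range(len(whole)))
            # every whole tooth has exactly one left and one right half
            for s in whole:
                halves = [h for h in res.segments
                          if h.jaw == jaw and h.index == s.index and h.half != "whole"]
                assert sorted(h.half for h in halves) == ["left", "right"]

    def test_determinism(self, tilted_phantom):
        img, _ = tilted_phantom
        r1 = segment_bitewing(img)
        r2 = segment_bitewing(img)
        assert r1.to_dict() == r2.to_dict()
        assert all(np.array_equal(a.crop.pixels, b.crop.pixels)
                   for a, b in zip(r1.segments, r2.segments))
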