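import math

import numpy as np
import pytest

from retodr import graph, odr, pipeline, synthetic
from retodr.io import RunConfig, VesselMask


def make_block(iroi, eroi, segment_id=0, block_index=0):
    b = odr.BlockROI(segment_id=segment_id, block_index=block_index,
                     centerline_pixels=np.zeros((3, 2), int),
                     local_diameter_px=5.0)
    b.iroi_pixels = np.asarray(iroi, int)
    b.eroi_pixels = np.asarray(eroi, int)
    return b


def constant_channel(shape, iroi, eroi, iroi_val, eroi_val):
    ch = np.full(shape, 1.0)
    for (r, c) in iroi:
        ch[r, c] = iroi_val
    for (r, c) in eroi:
        ch[r, c] = eroi_val
    return ch


def segments_for(mask, config=None):
    sk = graph.skeletonize(mask)
    return graph.extract_segments(sk, mask, config=config)


class TestPartitionBlocks:
    @pytest.mark.parametrize("n_px,expected_blocks", [(9, 3), (11, 3), (3, 1)])
    def test_block_count(self, n_px, expected_blocks):
        seg = graph.VesselSegment(
            segment_id=0,
            centerline=np.stack([np.zeros(n_px, int), np.arange(n_px)], axis=1),
            diameters_px=np.full(n_px, 5.0))
        blocks = odr.partition_blocks(seg, RunConfig())
        assert len(blocks) == expected_blocks
        assert all(len(b.centerline_pixels) == 3 for b in blocks)

    def test_blocks_are_consecutive_and_ordered(self):
        seg = graph.VesselSegment(
            segment_id=0,
            centerline=np.stack([np.zeros(12, int), np.arange(12)], axis=1),
            diameters_px=np.arange(12, dtype=float))
        blocks = odr.partition_blocks(seg, RunConfig())
        cols = np.concatenate([b.centerline_pixels[:, 1] for b in blocks])
        np.testing.assert_array_equal(cols, np.arange(12))
        # local diameter = mean of that block's per-pixel diameters
        assert blocks[1].local_diameter_px == pytest.approx(np.mean([3, 4, 5]))


class TestComputeOD:
    @pytest.mark.parametrize("eroi_val,iroi_val,expected", [
        (100, 100, 0.0),
        (100, 10, 1.0),
        (200, 50, math.log10(4)),
    ])
    def test_hand_cases(self, eroi_val, iroi_val, expected):
        iroi = [(5, c) for c in range(5, 10)]
        eroi = [(2, c) for c in range(5, 10)]
        block = make_block(iroi, eroi)
        ch = constant_channel((12, 12), iroi, eroi, iroi_val, eroi_val)
        od, reason = odr.compute_od(block, ch)
        assert reason == odr.VALID
        assert od == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        """OD equals an independently coded per-pixel mean + log10."""
        rng = np.random.default_rng(42)
        cfg = RunConfig()
        for _ in range(50):
            ch = rng.uniform(1, 254, size=(20, 20))
            iroi = rng.choice(400, size=12, replace=False)
            eroi = rng.choice(400, size=20, replace=False)
            iroi = np.stack(np.unravel_index(iroi, (20, 20)), axis=1)
            eroi = np.stack(np.unravel_index(eroi, (20, 20)), axis=1)
            block = make_block(iroi, eroi)
            od, reason = odr.compute_od(block, ch, cfg)
            # oracle: explicit python-loop means
            mi = sum(ch[r, c] for r, c in iroi) / len(iroi)
            me = sum(ch[r, c] for r, c in eroi) / len(eroi)
            expected = math.log10(me / mi)
            assert reason == odr.VALID
            assert abs(od - expected) <= 1e-12 * abs(expected)

    def test_scale_invariance(self):
        """Multiplying a channel by any positive constant leaves OD unchanged."""
        iroi = [(5, c) for c in range(5, 10)]
        eroi = [(2, c) for c in range(5, 10)]
        block = make_block(iroi, eroi)
        rng = np.random.default_rng(3)
        ch = rng.uniform(10, 20, size=(12, 12))
        cfg = RunConfig(exclude_saturated=False)
        od1, _ = odr.compute_od(block, ch, cfg)
        od2, _ = odr.compute_od(block, ch * 7.3, cfg, saturation_level=1e9)
        assert od2 == pytest.approx(od1, rel=1e-12)

    def test_saturated_and_zero_pixels_excluded(self):
        iroi = [(5, 5), (5, 6), (5, 7)]
        eroi = [(2, 5), (2, 6), (2, 7)]
        ch = constant_channel((12, 12), iroi, eroi, 10, 100)
        ch[5, 7] = 255  # saturated IROI pixel ignored
        ch[2, 7] = 0    # zero EROI pixel ignored
        od, reason = odr.compute_od(make_block(iroi, eroi), ch)
        assert od == pytest.approx(1.0)

    def test_all_saturated_gives_invalid(self):
        iroi = [(5, 5)]
        eroi = [(2, 5)]
        ch = np.full((12, 12), 255.0)
        od, reason = odr.compute_od(make_block(iroi, eroi), ch)
        assert od is None and reason == odr.ALL_SATURATED

    def test_empty_roi_gives_invalid(self):
        block = make_block(np.zeros((0, 2)), [(2, 5)])
        od, reason = odr.compute_od(block, np.full((12, 12), 10.0))
        assert od is None and reason == odr.EMPTY_ROI


class TestComputeODR:
    @pytest.mark.parametrize("od_r,od_g,expected", [
        (0.3, 0.3, 1.0), (0.3, 0.4, 0.75)])
    def test_ratio(self, od_r, od_g, expected):
        val, reason = odr.compute_odr(od_r, od_g)
        assert reason == odr.VALID and val == pytest.approx(expected)

    def test_low_green_contrast_guard(self):
        val, reason = odr.compute_odr(0.2, 1e-6)
        assert val is None and reason == odr.LOW_GREEN_CONTRAST


class TestVariability:
    def make_profile(self, odrs, seg_id=0, valid=None):
        valid = valid if valid is not None else [True] * len(odrs)
        return odr.ODRProfile(segment_id=seg_id, odr=list(odrs), valid=valid,
                              od_red=list(odrs), od_green=[1.0] * len(odrs),
                              reasons=[odr.VALID] * len(odrs))

    def test_constant_sequence_gives_zero(self):
        assert odr.odr_variability([self.make_profile([0.7, 0.7, 0.7])]) == 0.0

    def test_hand_case(self):
        # |0.7-0.5| + |0.6-0.7| over 2 pairs
        v = odr.odr_variability([self.make_profile([0.5, 0.7, 0.6])])
        assert v == pytest.approx(0.15)

    def test_pairs_never_cross_segments(self):
        profs = [self.make_profile([0.5, 0.7], seg_id=0),
                 self.make_profile([0.9, 0.9], seg_id=1)]
        assert odr.odr_variability(profs) == pytest.approx(0.10)

    def test_invalid_member_skips_pair(self):
        p = self.make_profile([0.5, 99.0, 0.6], valid=[True, False, True])
        assert math.isnan(odr.odr_variability([p]))

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(7)
        vals = [list(rng.uniform(0.4, 1.0, size=5)) for _ in range(3)]
        profs = [self.make_profile(v, seg_id=i) for i, v in enumerate(vals)]
        base = odr.odr_variability(profs)
        shifted = [self.make_profile([x + 2.5 for x in v], seg_id=i)
                   for i, v in enumerate(vals)]
        scaled = [self.make_profile([x * 3.0 for x in v], seg_id=i)
                  for i, v in enumerate(vals)]
        assert odr.odr_variability(shifted) == pytest.approx(base, rel=1e-12)
        assert odr.odr_variability(scaled) == pytest.approx(3.0 * base, rel=1e-12)


class TestAggregate:
    def test_single_arterial_main_segment(self):
        seg = graph.VesselSegment(0, np.zeros((6, 2), int), np.full(6, 8.0),
                                  vessel_class=graph.ARTERIOLE,
                                  caliber_class=graph.MAIN)
        prof = TestVariability().make_profile([0.7, 0.8])
        feats = odr.aggregate_subgroups([prof], [seg])
        assert feats.odr_all == pytest.approx(0.75)
        assert feats.odr_a == pytest.approx(0.75)
        assert feats.odr_main_a == pytest.approx(0.75)
        assert math.isnan(feats.odr_v) and feats.n_valid_blocks["odr_v"] == 0

    def test_mean_pools_blocks_not_segments(self):
        segs = [graph.VesselSegment(i, np.zeros((3, 2), int), np.full(3, 8.0),
                                    vessel_class=graph.ARTERIOLE,
                                    caliber_class=graph.MAIN) for i in (0, 1)]
        profs = [TestVariability().make_profile([0.6], 0),
                 TestVariability().make_profile([0.8], 1)]
        feats = odr.aggregate_subgroups(profs, segs)
        assert feats.odr_all == pytest.approx(0.7)

    def test_all_invalid_gives_missing_features(self):
        seg = graph.VesselSegment(0, np.zeros((3, 2), int), np.full(3, 8.0))
        prof = TestVariability().make_profile([0.5, 0.5], valid=[False, False])
        feats = odr.aggregate_subgroups([prof], [seg])
        assert all(math.isnan(v) for v in feats.as_dict().values())
        assert feats.n_valid_blocks["odr_all"] == 0


class TestROIs:
    def test_iroi_partitions_segment_mask(self, bar_mask):
        (seg,) = segments_for(bar_mask)
        blocks = odr.partition_blocks(seg, RunConfig())
        odr.assign_mask_pixels(blocks, bar_mask)
        sizes = sum(len(b.iroi_pixels) for b in blocks)
        assert sizes == bar_mask.mask.sum()
        seen = set()
        for b in blocks:
            px = set(map(tuple, b.iroi_pixels))
            assert not (px & seen)
            seen |= px

    def test_eroi_disjoint_from_vessels_and_near_vessel(self, bar_mask):
        cfg = RunConfig()
        (seg,) = segments_for(bar_mask)
        blocks = odr.partition_blocks(seg, cfg)
        odr.build_rois(blocks, bar_mask, bar_mask, cfg)
        from scipy import ndimage
        dist_to_vessel = ndimage.distance_transform_edt(~bar_mask.mask)
        for b in blocks:
            assert b.valid
            ev = b.eroi_pixels
            assert not bar_mask.mask[ev[:, 0], ev[:, 1]].any()
            # every EROI pixel lies within one diameter + guard of the vessel
            d = dist_to_vessel[ev[:, 0], ev[:, 1]]
            assert d.max() <= round(b.local_diameter_px) + 1

    def test_guard_ring_excludes_gap_between_parallel_vessels(self):
        m = np.zeros((40, 80), bool)
        m[18:21, 5:75] = True   # vessel 1
        m[22:25, 5:75] = True   # vessel 2, 1-px gap at row 21
        mask = VesselMask(m)
        cfg = RunConfig(min_blocks_per_segment=1)
        segs = segments_for(mask, cfg)
        blocks = []
        for s in segs:
            blocks.extend(odr.partition_blocks(s, cfg))
        odr.assign_mask_pixels(blocks, mask)
        odr.build_rois(blocks, mask, mask, cfg)
        gap = {(21, c) for c in range(5, 75)}
        for b in blocks:
            if b.eroi_pixels is None:
                continue
            assert not (set(map(tuple, b.eroi_pixels)) & gap)


class TestPipelineProperties:
    def test_identical_channels_give_unit_odr_and_zero_variability(self):
        spec = synthetic.straight_vessel_spec(t_red=0.4, t_green=0.4, seed=5)
        image, mask, labels, _ = synthetic.render_phantom(spec)
        res = pipeline.extract_features(image, mask, labels)
        valid_odrs = [o for p in res.profiles
                      for o, v in zip(p.odr, p.valid) if v]
        assert valid_odrs and all(o == 1.0 for o in valid_odrs)
        assert res.features.odr_var == 0.0

    def test_darker_red_interior_increases_every_block_odr(self):
        base = synthetic.straight_vessel_spec(t_red=0.5, t_green=0.25)
        dark = synthetic.straight_vessel_spec(t_red=0.35, t_green=0.25)
        odrs = []
        for spec in (base, dark):
            image, mask, labels, _ = synthetic.render_phantom(spec)
            res = pipeline.extract_features(image, mask, labels)
            odrs.append([o for p in res.profiles
                         for o, v in zip(p.odr, p.valid) if v])
        assert len(odrs[0]) == len(odrs[1])
        assert all(d > b for b, d in zip(odrs[0], odrs[1]))

    def test_phantom_recovery_noiseless(self):
        spec = synthetic.straight_vessel_spec(width_px=8, t_red=0.5, t_green=0.25)
        image, mask, labels, truth = synthetic.render_phantom(spec)
        res = pipeline.extract_features(image, mask, labels)
        expected = truth["analytic_odr"].iloc[0]
        for p in res.profiles:
            for o, v in zip(p.odr, p.valid):
                if v:
                    assert o == pytest.approx(expected, rel=0.02)
        assert res.features.odr_all == pytest.approx(expected, abs=0.01)
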