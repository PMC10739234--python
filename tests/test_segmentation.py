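"""Volume growing, sub-volume segmentation, mask edits and label assembly."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse.phantom import tube_axial_voxels
from neurofuse.segmentation import (
    MaskEditScript,
    SeedSet,
    apply_edits,
    assemble_labels,
    mark_nerves,
    region_grow,
    segment_brainstem,
    segment_csf,
    segment_tof_vessels,
)
from neurofuse.volumes import BRAINSTEM, CSF, NERVE, REST, VESSEL, Volume


def vol(values, spacing=1.0):
    return Volume(np.asarray(values, dtype=np.float32), spacing)


def flood_fill_oracle(values, seeds, tolerance, connectivity=6):
    """Brute-force reference: BFS over voxels within the band around the seed
    mean, reachable from the seeds."""
    values = np.asarray(values, float)
    mean = values[tuple(np.asarray(seeds).T)].mean()
    offsets = []
    for d in (-1, 0, 1):
        for e in (-1, 0, 1):
            for f in (-1, 0, 1):
                if (d, e, f) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(d) + abs(e) + abs(f) != 1:
                    continue
                offsets.append((d, e, f))
    mask = np.zeros(values.shape, bool)
    frontier = [tuple(s) for s in seeds]
    for s in frontier:
        mask[s] = True
    while frontier:
        x = frontier.pop()
        for o in offsets:
            n = tuple(np.add(x, o))
            if any(c < 0 or c >= values.shape[i] for i, c in enumerate(n)):
                continue
            if not mask[n] and abs(values[n] - mean) <= tolerance:
                mask[n] = True
                frontier.append(n)
    return mask


class TestRegionGrow:
    def test_constant_volume_grows_to_full_grid(self):
        v = vol(np.full((5, 5, 5), 3.0))
        mask = region_grow(v, SeedSet([(2, 2, 2)], tolerance=0.5))
        assert mask.all()

    def test_two_intensity_blocks(self):
        values = np.zeros((5, 5, 5))
        values[:, :, 3:] = 100.0
        mask = region_grow(vol(values), SeedSet([(0, 0, 0)], tolerance=10.0))
        assert np.array_equal(mask, values == 0.0)

    def test_tolerance_below_noise_keeps_connected_plateau(self):
        values = np.zeros((5, 5, 5))
        values += np.arange(5)[None, None, :] * 50.0   # steep ramp
        values[2, 2, 1:4] = 7.0                        # 3-voxel plateau
        mask = region_grow(vol(values), SeedSet([(2, 2, 2)], tolerance=1.0))
        expect = np.zeros((5, 5, 5), bool)
        expect[2, 2, 1:4] = True
        assert np.array_equal(mask, expect)

    def test_seed_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            region_grow(vol(np.zeros((4, 4, 4))), SeedSet([(4, 0, 0)], 1.0))

    def test_seed_violating_its_own_criterion_rejected(self):
        values = np.zeros((4, 4, 4))
        values[0, 0, 0] = 100.0
        with pytest.raises(ValueError, match="seed violates"):
            region_grow(vol(values),
                        SeedSet([(0, 0, 0), (1, 1, 1)], tolerance=10.0))

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_volumes(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = tuple(rng.integers(4, 7, size=3))
            values = rng.integers(0, 6, size=shape).astype(float)
            seed = tuple(int(rng.integers(0, s)) for s in shape)
            tol = float(rng.uniform(0.5, 3.0))
            got = region_grow(vol(values), SeedSet([seed], tol, connectivity))
            want = flood_fill_oracle(values, [seed], tol, connectivity)
            assert np.array_equal(got, want)

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_tolerance(self, data):
        shape = (5, 5, 5)
        values = np.asarray(
            data.draw(st.lists(st.integers(0, 8), min_size=125, max_size=125))
        ).reshape(shape).astype(float)
        seed = (data.draw(st.integers(0, 4)), data.draw(st.integers(0, 4)),
                data.draw(st.integers(0, 4)))
        lo = data.draw(st.floats(0.5, 4.0))
        hi = lo + data.draw(st.floats(0.1, 4.0))
        small = region_grow(vol(values), SeedSet([seed], lo))
        large = region_grow(vol(values), SeedSet([seed], hi))
        assert not (small & ~large).any()   # growing never shrinks


class TestSegmentCSF:
    def test_mask_superset_of_truth_csf_and_vessels(self, clean_bundle,
                                                    clean_segmentation):
        csf = clean_segmentation[0]
        truth = clean_bundle.truth.values
        target = (truth == CSF) | (truth == VESSEL)
        assert not (target & ~csf).any()
        dice = 2 * (csf & target).sum() / (csf.sum() + target.sum())
        assert dice >= 0.99

    def test_flow_gap_voxels_remain_inside_mask(self, default_bundle,
                                                session_config):
        cfg = session_config.segmentation
        from neurofuse.evaluation import segment_phantom

        csf, _, _, _ = segment_phantom(default_bundle, session_config)
        g = default_bundle.induced_gaps[0]
        trunk = default_bundle.tree.vessels[g.vessel][0]
        idx, axial = tube_axial_voxels(default_bundle.ciss, trunk.points,
                                       trunk.radius * 0.8)
        sel = (axial >= g.start_mm + 0.5) & (axial <= g.end_mm - 0.5)
        assert csf[tuple(idx[sel].T)].all()

    def test_wrong_compartment_seed_warns_and_misses_csf(self, clean_bundle,
                                                         caplog):
        truth = clean_bundle.truth.values
        seed_idx = tuple(np.argwhere(truth == BRAINSTEM)[1000])
        with caplog.at_level(logging.WARNING, logger="neurofuse"):
            mask = segment_csf(clean_bundle.ciss,
                               SeedSet([seed_idx], tolerance=12.0))
        assert "wrong compartment" in caplog.text
        csf_voxels = truth == CSF
        assert (mask & csf_voxels).sum() / csf_voxels.sum() < 0.01


class TestSegmentBrainstem:
    def test_dice_against_truth(self, clean_bundle, clean_segmentation):
        bs = clean_segmentation[1]
        truth = clean_bundle.truth.values == BRAINSTEM
        dice = 2 * (bs & truth).sum() / (bs.sum() + truth.sum())
        assert dice >= 0.95

    def test_disjoint_from_csf(self, clean_segmentation):
        csf, bs = clean_segmentation[0], clean_segmentation[1]
        assert not (csf & bs).any()

    def test_bbox_excluding_brainstem_errors(self, clean_bundle):
        # the interactive bounding box misses the brainstem entirely: the
        # (brainstem) seed falls outside it and the segment comes up empty
        csf = clean_bundle.truth.values == CSF
        seed = tuple(np.argwhere(clean_bundle.truth.values == BRAINSTEM)[1000])
        with pytest.raises(ValueError, match="empty segment"):
            segment_brainstem(clean_bundle.ciss, csf,
                              ((0, 8), (0, 8), (0, 8)), seed, 12.0)


class TestMarkNerves:
    def test_dice_against_truth_nerves(self, clean_bundle):
        mask = mark_nerves(clean_bundle.ciss, clean_bundle.nerves)
        truth = clean_bundle.truth.values == NERVE
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_empty_list_gives_empty_mask(self, clean_bundle):
        assert not mark_nerves(clean_bundle.ciss, []).any()

    def test_single_voxel_radius_tube_is_thin(self):
        v = Volume(np.zeros((32, 32, 32), np.float32), 0.4)
        start, end = v.world((16, 16, 4)), v.world((16, 16, 28))
        mask = mark_nerves(v, [(np.array([start, end]), 0.4)])
        assert mask.any()
        for k in range(32):
            sl = mask[:, :, k]
            if sl.any():
                ii, jj = np.nonzero(sl)
                assert np.ptp(ii) <= 2 and np.ptp(jj) <= 2   # width <= 3 voxels

    def test_empty_polyline_rejected(self, clean_bundle):
        with pytest.raises(ValueError, match="empty nerve polyline"):
            mark_nerves(clean_bundle.ciss, [(np.empty((0, 3)), 0.5)])


class TestSegmentTofVessels:
    def test_dice_against_misaligned_truth(self, clean_bundle,
                                           clean_segmentation):
        mask = clean_segmentation[3]
        truth = clean_bundle.tof_vessel_truth
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_background_seed_rejected(self, clean_bundle):
        with pytest.raises(ValueError, match="seed violates|criterion"):
            segment_tof_vessels(
                clean_bundle.tof,
                SeedSet([(2, 2, 2), (40, 40, 40)], tolerance=30.0))


class TestApplyEdits:
    def grid(self):
        return Volume(np.zeros((24, 24, 24), np.float32), 0.4)

    def test_empty_script_is_identity(self):
        g = self.grid()
        mask = np.zeros(g.shape, bool)
        mask[4:8, 4:8, 4:8] = True
        assert np.array_equal(apply_edits(mask, MaskEditScript([]), g), mask)

    def test_add_then_remove_ball_is_empty(self):
        g = self.grid()
        mask = np.zeros(g.shape, bool)
        ball = {"center_mm": [4.0, 4.0, 4.0], "radius_mm": 1.2}
        script = MaskEditScript([{"op": "add_ball", **ball},
                                 {"op": "remove_ball", **ball}])
        out = apply_edits(mask, script, g)
        assert not out.any()

    def test_remove_component_targets_only_one_blob(self):
        g = self.grid()
        mask = np.zeros(g.shape, bool)
        mask[2:5, 2:5, 2:5] = True       # spurious blob
        mask[10:20, 10:12, 10:12] = True  # "vessel"
        script = MaskEditScript([{"op": "remove_component", "seed": [3, 3, 3]}])
        out = apply_edits(mask, script, g)
        assert not out[2:5, 2:5, 2:5].any()
        assert out[10:20, 10:12, 10:12].all()

    def test_fill_holes_is_idempotent(self):
        g = self.grid()
        mask = np.zeros(g.shape, bool)
        mask[4:12, 4:12, 4:12] = True
        mask[7:9, 7:9, 7:9] = False
        once = apply_edits(mask, MaskEditScript([{"op": "fill_holes"}]), g)
        twice = apply_edits(once, MaskEditScript([{"op": "fill_holes"}]), g)
        assert once[7:9, 7:9, 7:9].all()
        assert np.array_equal(once, twice)

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown edit op"):
            MaskEditScript([{"op": "sparkle"}])

    def test_json_round_trip(self, tmp_path):
        script = MaskEditScript([
            {"op": "add_ball", "center_mm": [1, 2, 3], "radius_mm": 0.8},
            {"op": "fill_holes"},
        ])
        script.to_json(tmp_path / "edits.json")
        back = MaskEditScript.from_json(tmp_path / "edits.json")
        assert back.ops == script.ops


class TestAssembleLabels:
    def test_disjoint_masks_map_directly(self):
        g = Volume(np.zeros((8, 8, 8), np.float32), 0.4)
        csf = np.zeros(g.shape, bool)
        csf[0:2] = True
        bs = np.zeros(g.shape, bool)
        bs[3:5] = True
        nerves = np.zeros(g.shape, bool)
        nerves[6, 6, 6] = True
        labels = assemble_labels(csf, bs, nerves, None, g)
        assert (labels.values[csf] == CSF).all()
        assert (labels.values[bs] == BRAINSTEM).all()
        assert labels.values[6, 6, 6] == NERVE
        assert labels.values[7, 7, 7] == REST

    def test_precedence_nerve_over_csf_and_vessel_over_all(self):
        g = Volume(np.zeros((8, 8, 8), np.float32), 0.4)
        every = np.ones(g.shape, bool)
        labels = assemble_labels(every, every, every, every, g)
        assert (labels.values == VESSEL).all()
        labels = assemble_labels(every, ~every, every, None, g)
        assert (labels.values == NERVE).all()

    def test_output_is_partition(self, clean_segmentation, clean_bundle):
        csf, bs, nerves, tof = clean_segmentation
        labels = assemble_labels(csf, bs, nerves, tof, clean_bundle.ciss)
        assert labels.values.size == sum(
            (labels.values == lab).sum() for lab in range(5))

    def test_geometry_mismatch_rejected(self):
        g = Volume(np.zeros((8, 8, 8), np.float32), 0.4)
        bad = np.zeros((6, 6, 6), bool)
        with pytest.raises(ValueError, match="geometry"):
            assemble_labels(bad, bad, bad, None, g)
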