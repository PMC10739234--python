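"""Phantom generator: determinism, geometry, contrast and artifact models."""

import dataclasses

import numpy as np
import pytest

from neurofuse.fusion import RigidTransform
from neurofuse.phantom import (
    PhantomSpec,
    build_tree,
    generate_phantom,
    inject_flow_artifacts,
    inject_pulsation_artifacts,
    rasterize,
    sample_polyline,
    tube_axial_voxels,
)
from neurofuse.volumes import BRAINSTEM, CSF, NERVE, VESSEL, PhantomConfig


def small_config(**kw) -> PhantomConfig:
    return dataclasses.replace(PhantomConfig(), shape=64, **kw)


@pytest.fixture(scope="module")
def small_bundle():
    return generate_phantom(PhantomSpec(small_config(), seed=3))


class TestTree:
    def test_deterministic_given_seed(self):
        a = build_tree(PhantomSpec(small_config(), seed=5))
        b = build_tree(PhantomSpec(small_config(), seed=5))
        for name in a.names:
            for ba, bb in zip(a.vessels[name], b.vessels[name]):
                assert np.array_equal(ba.points, bb.points)
        c = build_tree(PhantomSpec(small_config(), seed=6))
        assert not all(
            np.array_equal(x.points, y.points)
            for x, y in zip(a.vessels["PICA-le"], c.vessels["PICA-le"])
        )

    def test_nine_named_vessels(self):
        tree = build_tree(PhantomSpec(small_config(), seed=0))
        assert set(tree.names) == {
            "BA", "VA-le", "VA-ri", "PICA-le", "PICA-ri",
            "AICA-le", "AICA-ri", "SCA-le", "SCA-ri",
        }

    def test_radius_ordering_and_wide_lumen(self):
        tree = build_tree(PhantomSpec(small_config(), seed=0))
        assert (tree.max_radius("BA") >= tree.max_radius("VA-le")
                >= tree.max_radius("PICA-le"))
        assert set(tree.wide_lumen_names(1.25)) == {"BA", "VA-le", "VA-ri"}

    def test_every_vessel_has_distal_branches(self):
        tree = build_tree(PhantomSpec(small_config(), seed=0))
        for name in tree.names:
            assert len(tree.vessels[name]) >= 3  # trunk + at least two twigs

    def test_grid_too_small_rejected(self):
        spec = PhantomSpec(small_config(spacing=0.3), seed=0)
        with pytest.raises(ValueError, match="too small"):
            build_tree(spec)

    def test_json_round_trip(self):
        from neurofuse.phantom import VesselTree

        tree = build_tree(PhantomSpec(small_config(), seed=2))
        back = VesselTree.from_dict(tree.to_dict())
        assert back.names == tree.names
        for name in tree.names:
            for ba, bb in zip(tree.vessels[name], back.vessels[name]):
                assert np.allclose(ba.points, bb.points)
                assert ba.radius == bb.radius
        assert np.allclose(back.compression_point, tree.compression_point)


class TestRasterize:
    def test_truth_is_a_partition(self, small_bundle):
        labels = small_bundle.truth.values
        counts = [(labels == lab).sum() for lab in range(5)]
        assert sum(counts) == labels.size
        assert all((labels == lab).any() for lab in (CSF, BRAINSTEM, NERVE, VESSEL))

    def test_noise_free_intensities_are_degenerate(self):
        spec = PhantomSpec(small_config(noise_sd=0.0), seed=0)
        tree = build_tree(spec)
        truth, ciss, tof = rasterize(spec, tree)
        csf_vals = np.unique(ciss.values[truth.values == CSF])
        vessel_vals = np.unique(ciss.values[truth.values == VESSEL])
        assert len(csf_vals) == 1 and len(vessel_vals) == 1
        assert csf_vals[0] > vessel_vals[0]

    def test_contrast_contract_over_seeds(self):
        for seed in range(10):
            spec = PhantomSpec(small_config(), seed=seed)
            tree = build_tree(spec)
            truth, ciss, tof = rasterize(spec, tree)
            sd = spec.config.noise_sd
            csf_mean = ciss.values[truth.values == CSF].mean()
            vessel_mean = ciss.values[truth.values == VESSEL].mean()
            assert csf_mean - vessel_mean >= 3 * sd
            # TOF vessels are rendered in the misaligned frame: compare the
            # bright lumen against the background via the intensity histogram
            tof_vessel_mean = tof.values[tof.values > 100.0].mean()
            tof_bg_mean = tof.values[tof.values <= 100.0].mean()
            assert tof_vessel_mean - tof_bg_mean >= 3 * sd

    def test_centerlines_inside_truth_csf_area(self, small_bundle):
        truth = small_bundle.truth
        for _, _, br in small_bundle.tree.all_branches():
            _, pts = sample_polyline(br.points, 0.5)
            idx = np.round(truth.index(pts)).astype(int)
            labs = truth.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            assert np.all((labs == CSF) | (labs == VESSEL))

    def test_transformed_tof_centerlines_land_on_truth_vessels(self, small_bundle):
        # ground-truth consistency: mapping the TOF-frame centerlines through
        # the true transform lands them on truth VESSEL voxels (within 1 voxel)
        truth = small_bundle.truth
        tof_tree = small_bundle.tree.transformed(
            small_bundle.true_transform.inverse())
        for name, _, br in tof_tree.all_branches():
            back = small_bundle.true_transform.apply(br.points)
            idx = np.round(truth.index(back)).astype(int)
            labs = truth.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            assert np.all(labs == VESSEL)


class TestFlowArtifacts:
    def test_severity_zero_is_identity(self):
        spec = PhantomSpec(small_config(flow_severity=0.0), seed=0)
        tree = build_tree(spec)
        _, ciss, _ = rasterize(spec, tree)
        out, gaps = inject_flow_artifacts(ciss, tree, spec)
        assert gaps == []
        assert np.array_equal(out.values, ciss.values)

    def test_gap_lumen_is_raised_to_csf_level(self):
        spec = PhantomSpec(small_config(), seed=1)
        tree = build_tree(spec)
        truth, ciss, _ = rasterize(spec, tree)
        out, gaps = inject_flow_artifacts(ciss, tree, spec)
        assert gaps
        g = gaps[0]
        trunk = tree.vessels[g.vessel][0]
        idx, axial = tube_axial_voxels(ciss, trunk.points, trunk.radius * 0.8)
        sel = (axial >= g.start_mm + 0.3) & (axial <= g.end_mm - 0.3)
        lumen = out.values[tuple(idx[sel].T)]
        cfg = spec.config
        assert abs(lumen.mean() - cfg.ciss_csf) < 3 * cfg.noise_sd + 1.0

    def test_same_seed_reproduces_gaps(self):
        spec = PhantomSpec(small_config(), seed=2)
        tree = build_tree(spec)
        _, ciss, _ = rasterize(spec, tree)
        _, g1 = inject_flow_artifacts(ciss, tree, spec)
        _, g2 = inject_flow_artifacts(ciss, tree, spec)
        assert [(g.vessel, g.start_mm, g.end_mm) for g in g1] == [
            (g.vessel, g.start_mm, g.end_mm) for g in g2]

    def test_unknown_vessel_rejected(self):
        spec = PhantomSpec(small_config(flow_artifact_vessels=("NOPE",)), seed=0)
        tree = build_tree(spec)
        _, ciss, _ = rasterize(spec, tree)
        with pytest.raises(ValueError, match="NOPE"):
            inject_flow_artifacts(ciss, tree, spec)

    def test_distinct_gap_sets_across_25_seeds(self):
        spec = PhantomSpec(small_config(), seed=0)
        tree = build_tree(spec)
        _, ciss, _ = rasterize(spec, tree)
        seen = set()
        for seed in range(25):
            _, gaps = inject_flow_artifacts(ciss, tree, spec, seed=seed)
            seen.add(tuple((g.vessel, round(g.start_mm, 4), round(g.end_mm, 4))
                           for g in gaps))
        assert len(seen) == 25


@pytest.fixture(scope="module")
def scene():
    spec = PhantomSpec(small_config(noise_sd=0.0), seed=0)
    tree = build_tree(spec)
    truth, ciss, _ = rasterize(spec, tree)
    return spec, truth, ciss


class TestPulsationArtifacts:
    def test_amplitude_zero_is_identity(self, scene):
        spec, truth, ciss = scene
        spec0 = PhantomSpec(
            dataclasses.replace(spec.config, pulsation_amplitude=0.0), seed=0)
        out = inject_pulsation_artifacts(ciss, truth, spec0)
        assert np.array_equal(out.values, ciss.values)

    def test_support_inside_dilated_csf_region(self, scene):
        from scipy import ndimage

        spec, truth, ciss = scene
        out = inject_pulsation_artifacts(ciss, truth, spec)
        diff = out.values != ciss.values
        support = (truth.values == CSF) | (truth.values == VESSEL)
        dilated = ndimage.binary_dilation(support, iterations=2)
        assert not (diff & ~dilated).any()
        assert diff.any()

    def test_ghost_is_linear_in_amplitude(self, scene):
        spec, truth, ciss = scene
        amp = spec.config.pulsation_amplitude
        double = PhantomSpec(
            dataclasses.replace(spec.config, pulsation_amplitude=2 * amp), seed=0)
        d1 = inject_pulsation_artifacts(ciss, truth, spec).values - ciss.values
        d2 = inject_pulsation_artifacts(ciss, truth, double).values - ciss.values
        assert np.abs(d2).max() == pytest.approx(2 * np.abs(d1).max(), rel=1e-5)
        assert np.allclose(d2, 2 * d1, atol=1e-4)


class TestBundle:
    def test_bitwise_deterministic(self):
        a = generate_phantom(PhantomSpec(small_config(), seed=4))
        b = generate_phantom(PhantomSpec(small_config(), seed=4))
        assert np.array_equal(a.ciss.values, b.ciss.values)
        assert np.array_equal(a.tof.values, b.tof.values)
        assert np.array_equal(a.truth.values, b.truth.values)
        assert np.allclose(a.true_transform.translation,
                           b.true_transform.translation)

    def test_identity_alignment_makes_tof_coincide_with_truth(self):
        spec = PhantomSpec(
            small_config(noise_sd=0.0, flow_severity=0.0,
                         pulsation_amplitude=0.0),
            seed=0, true_transform=RigidTransform.identity())
        b = generate_phantom(spec)
        tof_vessels = b.tof.values > 100.0
        truth_vessels = b.truth.values == VESSEL
        dice = 2 * (tof_vessels & truth_vessels).sum() / (
            tof_vessels.sum() + truth_vessels.sum())
        assert dice >= 0.99

    def test_written_bundle_round_trips(self, tmp_path, small_bundle):
        import json

        from neurofuse.phantom import VesselTree
        from neurofuse.volumes import read_volume

        small_bundle.write(tmp_path)
        ciss = read_volume(tmp_path / "ciss.nii.gz")
        assert np.array_equal(ciss.values, small_bundle.ciss.values)
        truth = read_volume(tmp_path / "truth.nii.gz")
        assert np.array_equal(truth.values, small_bundle.truth.values)
        tree = VesselTree.from_dict(
            json.loads((tmp_path / "tree.json").read_text()))
        assert set(tree.names) == set(small_bundle.tree.names)
        t = RigidTransform.from_dict(
            json.loads((tmp_path / "transform.json").read_text()))
        assert np.allclose(t.translation, small_bundle.true_transform.translation)
        gaps = json.loads((tmp_path / "gaps.json").read_text())
        assert len(gaps) == len(small_bundle.induced_gaps)
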