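"""Phantom generator: determinism, intensity windows, corruption contracts."""

import numpy as np
import pytest

from cephalo3d.catalog import dental_names, phantom_catalog
from cephalo3d.phantom import (
    MANDIBLE_LANDMARKS,
    PhantomConfig,
    PhantomGeometryError,
    apply_malocclusion,
    apply_metal_artifact,
    apply_missing_dental,
    generate_batch,
    generate_case,
    generate_phantom,
)

BONE_WINDOW = (226.0, 2619.0)
SOFT_WINDOW = (-700.0, 225.0)


class TestGenerate:
    def test_seeded_determinism(self):
        a = generate_phantom(PhantomConfig(seed=5))
        b = generate_phantom(PhantomConfig(seed=5))
        assert np.array_equal(a.volume.data, b.volume.data)
        for n in a.truth.names():
            assert np.array_equal(a.truth[n].coord, b.truth[n].coord)

    def test_different_seeds_differ(self):
        a = generate_phantom(PhantomConfig(seed=5))
        b = generate_phantom(PhantomConfig(seed=6))
        assert not np.array_equal(a.volume.data, b.volume.data)

    def test_noise_free_intensities_in_tissue_windows(self, clean_phantom):
        vals = set(np.unique(clean_phantom.volume.data).tolist())
        cfg = clean_phantom.cfg
        assert vals == {cfg.air_hu, cfg.soft_hu, cfg.bone_hu, cfg.teeth_hu}
        assert SOFT_WINDOW[0] <= cfg.soft_hu <= SOFT_WINDOW[1]
        assert BONE_WINDOW[0] <= cfg.bone_hu <= BONE_WINDOW[1]
        assert BONE_WINDOW[0] <= cfg.teeth_hu <= BONE_WINDOW[1]

    def test_all_truths_inside_grid(self, clean_phantom):
        vol = clean_phantom.volume
        for n in clean_phantom.truth.names():
            assert vol.contains_world(clean_phantom.truth[n].coord)

    def test_truth_independent_of_noise_seed(self):
        a = generate_phantom(PhantomConfig(seed=3, noise_sd=0.0))
        b = generate_phantom(PhantomConfig(seed=3, noise_sd=40.0))
        for n in a.truth.names():
            assert np.array_equal(a.truth[n].coord, b.truth[n].coord)

    def test_unfittable_geometry_rejected(self):
        with pytest.raises(PhantomGeometryError):
            generate_phantom(PhantomConfig(shape=(96, 96, 64), cranial_radii=(0.6, 0.6, 0.6)))

    def test_landmarks_sit_on_their_features(self, clean_phantom):
        """Each truth point lies on/next to voxels of its tissue class."""
        vol, cfg = clean_phantom.volume, clean_phantom.cfg
        hu_of = {"dental": cfg.teeth_hu, "bone": cfg.bone_hu}
        for d in phantom_catalog():
            p = vol.world_to_voxel(clean_phantom.truth[d.name].coord)
            lo = np.maximum(np.round(p).astype(int) - 3, 0)
            hi = np.minimum(np.round(p).astype(int) + 4, vol.shape)
            patch = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            assert np.any(patch == hu_of[d.tissue]), d.name


class TestMissingDental:
    def test_locality_and_presence_flag(self, clean_phantom):
        out = apply_missing_dental(clean_phantom, ["L6L"])
        assert out.truth["L6L"].present is False
        diff = np.argwhere(out.volume.data != clean_phantom.volume.data)
        assert len(diff) > 0
        span = diff.max(axis=0) - diff.min(axis=0)
        assert np.all(span <= 10)  # confined to the peg's bounding box
        for n in out.truth.names():
            if n != "L6L":
                assert np.array_equal(out.truth[n].coord, clean_phantom.truth[n].coord)

    def test_empty_removal_is_identity(self, clean_phantom):
        assert apply_missing_dental(clean_phantom, []) is clean_phantom

    def test_removing_all_six_leaves_eight_present(self, clean_phantom):
        out = apply_missing_dental(clean_phantom, dental_names(phantom_catalog()))
        assert len(out.truth.present_names()) == 8

    def test_non_dental_rejected(self, clean_phantom):
        with pytest.raises(ValueError):
            apply_missing_dental(clean_phantom, ["Me"])


class TestMetalArtifact:
    def test_truth_invariant_and_exceeds_bone_window(self, clean_phantom):
        out = apply_metal_artifact(clean_phantom, "UI", n_streaks=8, seed=2)
        for n in out.truth.names():
            assert np.array_equal(out.truth[n].coord, clean_phantom.truth[n].coord)
        changed = out.volume.data != clean_phantom.volume.data
        assert out.volume.data[changed].max() > BONE_WINDOW[1]

    def test_zero_streaks_only_blob(self, clean_phantom):
        out = apply_metal_artifact(clean_phantom, "UI", n_streaks=0, seed=2)
        changed = np.argwhere(out.volume.data != clean_phantom.volume.data)
        span = (changed.max(axis=0) - changed.min(axis=0)) * np.asarray(clean_phantom.cfg.spacing)
        assert np.all(span <= 2 * 1.5 + 1.0)  # blob diameter plus voxelization slack

    def test_absent_center_rejected(self, clean_phantom):
        mdl = apply_missing_dental(clean_phantom, ["UI"])
        with pytest.raises(ValueError):
            apply_metal_artifact(mdl, "UI")


class TestMalocclusion:
    def test_exact_rigid_shift_bookkeeping(self, clean_phantom):
        shift = np.array([0.0, 2.0, 0.0])
        out = apply_malocclusion(clean_phantom, shift)
        for n in out.truth.names():
            delta = out.truth[n].coord - clean_phantom.truth[n].coord
            expected = shift if n in MANDIBLE_LANDMARKS else np.zeros(3)
            assert np.allclose(delta, expected), n

    def test_zero_shift_identity(self, clean_phantom):
        assert apply_malocclusion(clean_phantom, (0, 0, 0)) is clean_phantom

    def test_shift_composition_additivity(self, clean_phantom):
        once = apply_malocclusion(apply_malocclusion(clean_phantom, (0, 1, 0)), (0.5, 0.5, -0.5))
        combined = apply_malocclusion(clean_phantom, (0.5, 1.5, -0.5))
        for n in once.truth.names():
            assert np.allclose(once.truth[n].coord, combined.truth[n].coord)


class TestBatch:
    def test_round_robin_scenarios_and_seeds(self):
        cohort = generate_batch(PhantomConfig.tiny(), 8, base_seed=100)
        assert [p.scenario.name for p in cohort] == ["Normal", "M", "MDL", "MA"] * 2
        again = generate_case(PhantomConfig.tiny(), "M", 101)
        assert np.array_equal(again.volume.data, cohort[1].volume.data)

    def test_mdl_cases_have_absent_teeth(self):
        ph = generate_case(PhantomConfig.tiny(), "MDL", 42)
        absent = [n for n in ph.truth.names() if not ph.truth[n].present]
        assert 1 <= len(absent) <= 2
        assert set(absent) <= set(dental_names(phantom_catalog()))
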