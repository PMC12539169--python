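"""Fusion rule, presence decisions, oracle end-to-end identity."""

import numpy as np
import pytest

from cephalo3d.heatmap import PLANES, encode_targets
from cephalo3d.predictor import (
    PredictionConfig,
    coarse_localize,
    decide_presence,
    fuse_candidates,
    normalize_hu,
    predict_landmarks,
    refine_ss_p3d,
)


class TestFusion:
    def test_stated_averaging_rule(self):
        cands = {
            "axial": ((0, 1), np.array([10.0, 12.0]), 0.9),
            "sagittal": ((1, 2), np.array([14.0, 8.0]), 0.9),
            "coronal": ((0, 2), np.array([12.0, 6.0]), 0.9),
        }
        fused = fuse_candidates(np.array([0.0, 0.0, 0.0]), cands, tau=0.35)
        assert np.allclose(fused, [11.0, 13.0, 7.0])

    def test_idempotent_on_agreement(self):
        p = np.array([5.0, 6.0, 7.0])
        cands = {
            "axial": ((0, 1), p[[0, 1]], 0.9),
            "sagittal": ((1, 2), p[[1, 2]], 0.9),
            "coronal": ((0, 2), p[[0, 2]], 0.9),
        }
        assert np.allclose(fuse_candidates(p, cands, 0.35), p)

    def test_fallback_to_coarse_when_only_axial_survives(self):
        coarse = np.array([1.0, 2.0, 3.0])
        cands = {
            "axial": ((0, 1), np.array([10.0, 12.0]), 0.9),
            "sagittal": ((1, 2), np.array([99.0, 99.0]), 0.1),
            "coronal": ((0, 2), np.array([99.0, 99.0]), 0.2),
        }
        fused = fuse_candidates(coarse, cands, tau=0.35)
        assert np.allclose(fused, [10.0, 12.0, 3.0])  # x,y from axial; z from coarse

    def test_variance_reduction_property(self, rng):
        """Averaging two independent zero-mean plane observations of a
        coordinate never increases its error variance (1,000 draws)."""
        single, fused_err = [], []
        for _ in range(1000):
            truth = rng.uniform(0, 10, size=3)
            noise = rng.normal(0, 0.5, size=(3, 2))
            cands = {
                "axial": ((0, 1), truth[[0, 1]] + noise[0], 0.9),
                "sagittal": ((1, 2), truth[[1, 2]] + noise[1], 0.9),
                "coronal": ((0, 2), truth[[0, 2]] + noise[2], 0.9),
            }
            fused = fuse_candidates(truth, cands, 0.35)
            fused_err.append((fused[1] - truth[1]) ** 2)
            single.append(noise[0, 1] ** 2)
        assert np.mean(fused_err) < np.mean(single)


class TestPresence:
    def test_threshold_rule(self):
        assert decide_presence(0.9, [0.8, 0.85, 0.9], 0.35)
        assert not decide_presence(0.1, [0.05, 0.08, 0.1], 0.35)

    def test_monotone_in_tau(self, rng):
        for _ in range(50):
            peaks = rng.uniform(0, 1, size=4)
            decisions = [decide_presence(peaks[0], peaks[1:], t)
                         for t in np.linspace(0.05, 0.95, 10)]
            # once absent, never back to present as tau rises
            assert all(not (a and not b) for a, b in zip(decisions[1:], decisions[:-1]))

    def test_tau_validation(self):
        with pytest.raises(ValueError):
            PredictionConfig(tau=0.0)


class _OracleModel:
    """Stands in for a network: emits the encoded ground-truth heatmaps."""

    def __init__(self, phantom, names, sigma=2.0, stage="coarse3d", plane=None):
        self.phantom = phantom
        self.names = names
        self.sigma = sigma
        self.stage = stage
        self.plane = plane

    def __call__(self, arr):
        if self.stage == "coarse3d":
            return encode_targets(self.phantom.truth, self.phantom.volume,
                                  self.sigma, self.names).maps
        # identify the slice index by matching content
        normal, axes = PLANES[self.plane]
        vol = normalize_hu(self.phantom.volume.data)
        for idx in range(vol.shape[normal]):
            sl = [slice(None)] * 3
            sl[normal] = idx
            if np.array_equal(vol[tuple(sl)], arr):
                break
        return encode_targets(self.phantom.truth, self.phantom.volume, self.sigma,
                              self.names, stage="plane2d", plane=self.plane,
                              slice_index=idx).maps


class TestOracleEndToEnd:
    def test_coarse_oracle_recovers_truth(self, tiny_phantom, phantom_names):
        model = _OracleModel(tiny_phantom, phantom_names)
        out = coarse_localize(model, tiny_phantom.volume, phantom_names)
        for n in phantom_names:
            truth = tiny_phantom.truth[n].coord
            coord, peak = out[n]
            assert np.linalg.norm(coord - truth) <= 0.1 * 0.75 * np.sqrt(3) + 1e-6
            assert peak > 0.9

    def test_full_pipeline_oracle_identity(self, tiny_phantom, phantom_names):
        """Injecting ground-truth heatmaps yields predictions equal to truth
        within the sub-grid decode tolerance (<= 0.1 voxel per axis)."""
        models = {"coarse": _OracleModel(tiny_phantom, phantom_names)}
        for plane in PLANES:
            models[plane] = _OracleModel(tiny_phantom, phantom_names,
                                         stage="plane2d", plane=plane)
        pred = predict_landmarks(tiny_phantom.volume, models, phantom_names,
                                 PredictionConfig(tau=0.35))
        spacing = tiny_phantom.volume.spacing
        for n in phantom_names:
            assert pred[n].present
            delta = np.abs(pred[n].coord - tiny_phantom.truth[n].coord) / spacing
            assert np.all(delta <= 0.1 + 1e-9), (n, delta)

    def test_untrained_model_no_crash(self, tiny_phantom, phantom_names):
        from cephalo3d.network import NetworkSpec, build_network
        spec = NetworkSpec(landmarks=14, depth=2, base_channels=4,
                           crop=tuple(tiny_phantom.volume.shape))
        net = build_network(spec, seed=0)
        out = coarse_localize(net, tiny_phantom.volume, phantom_names)
        for n in phantom_names:
            coord, peak = out[n]
            assert peak < 0.5
            if coord is not None:  # argmax stays on-grid
                assert tiny_phantom.volume.contains_world(coord)

    def test_absent_landmark_pipeline(self, phantom_names):
        from cephalo3d.phantom import PhantomConfig, apply_missing_dental, generate_phantom
        ph = apply_missing_dental(
            generate_phantom(PhantomConfig.tiny(seed=3, noise_sd=0)), ["L6L"])
        models = {"coarse": _OracleModel(ph, phantom_names)}
        for plane in PLANES:
            models[plane] = _OracleModel(ph, phantom_names, stage="plane2d", plane=plane)
        pred = predict_landmarks(ph.volume, models, phantom_names)
        assert not pred["L6L"].present
        assert pred["L6R"].present

    def test_window_shifted_inside_at_boundary(self):
        from cephalo3d.predictor import _window_bounds
        assert _window_bounds(1.0, 16, 40) == (0, 16)
        assert _window_bounds(39.0, 16, 40) == (24, 40)
        lo, hi = _window_bounds(20.0, 16, 40)
        assert 0 <= lo and hi <= 40 and hi - lo == 16
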