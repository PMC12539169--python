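"""Coarse-to-fine landmark inference.

Stage 1 (coarse): the 3D network maps the normalized volume to one heatmap
per landmark; peaks are decoded with sub-grid refinement and mapped to world
mm.  Stage 2 (SS-P3D refinement): for each landmark, the axial, sagittal and
coronal native-resolution slices through the coarse estimate are cropped to a
window centered on it and passed to the matching 2D branch; each decoded 2D
peak is a plane candidate fixing two world coordinates (axial: x,y; sagittal:
y,z; coronal: x,z).  Fusion averages, per coordinate, the candidates from the
planes that observe it; a plane whose peak falls below the presence threshold
tau is dropped, and a coordinate observed by no surviving plane falls back to
the coarse estimate, so every landmark gets either a coordinate or an
explicit absence.  A landmark is declared present iff the maximum of its
coarse and plane peaks reaches tau.

Models are duck-typed: anything with ``forward_numpy`` (or any callable)
mapping an input array to a per-landmark heatmap stack works, which lets
tests inject oracle heatmaps in place of network outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heatmap import decode_peak, plane_axes
from .volume_io import LandmarkSet, Volume3D

__all__ = [
    "PredictionConfig",
    "normalize_hu",
    "coarse_localize",
    "refine_ss_p3d",
    "fuse_candidates",
    "decide_presence",
    "predict_landmarks",
]

PLANE_NAMES = ("axial", "sagittal", "coronal")


@dataclass
class PredictionConfig:
    """Inference knobs.

    ``tau`` is the presence threshold on decoded peak values in [0, 1]
    (calibrated on phantom validation cases, adjustable).  ``window`` is the
    side of the square crop fed to each 2D branch; None means the branch's
    native input size.  ``refine`` toggles sub-grid quadratic peak refinement
    (off = strict arg-max).  ``slab`` > 0 extracts a small stack of slices
    around the coarse estimate instead of the single central one and keeps
    the best-peak candidate per plane, compensating slice-selection error
    when branch outputs encode their through-plane distance to the landmark.
    """

    tau: float = 0.35
    window: int | None = None
    refine: bool = True
    slab: int = 0  # also try slices at +/- this offset; keep the best peak
    gate_refinement: bool = False  # refine only coarse detections >= tau
    use_planes: tuple[str, ...] = PLANE_NAMES

    def __post_init__(self):
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must be in (0,1), got {self.tau}")


def normalize_hu(data: np.ndarray) -> np.ndarray:
    """Map HU to network input units: clip to [-1000, 3000] and scale by 1/1000."""
    return (np.clip(np.asarray(data, dtype=np.float32), -1000.0, 3000.0) / 1000.0)


def _run(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "forward_numpy"):
        return model.forward_numpy(x)
    return np.asarray(model(x))


def coarse_localize(model, volume: Volume3D, names: list[str],
                    cfg: PredictionConfig | None = None) -> dict:
    """Decode each coarse 3D heatmap peak to world mm.

    Returns ``{name: (coord_mm | None, peak)}``; a flat heatmap yields
    ``(None, 0.0)`` (no-peak flag).  Decoded coordinates are always inside
    the volume bounds because the arg-max is on-grid.
    """
    cfg = cfg or PredictionConfig()
    maps = _run(model, normalize_hu(volume.data))
    if maps.shape[0] != len(names):
        raise ValueError(f"model emitted {maps.shape[0]} maps for {len(names)} landmarks")
    out = {}
    for i, name in enumerate(names):
        vox, peak = decode_peak(maps[i], refine=cfg.refine)
        peak = float(np.clip(peak, 0.0, 1.0))
        if np.any(np.isnan(vox)):
            out[name] = (None, 0.0)
        else:
            out[name] = (volume.voxel_to_world(vox), peak)
    return out


def _window_bounds(center: float, size: int, dim: int) -> tuple[int, int]:
    """Integer window [lo, lo+size) containing center, shifted inside [0, dim)."""
    size = min(size, dim)
    lo = int(round(center)) - size // 2
    lo = max(0, min(lo, dim - size))
    return lo, lo + size


def refine_ss_p3d(branches: dict, volume: Volume3D, coarse: dict,
                  cfg: PredictionConfig | None = None) -> dict:
    """Per-plane 2D candidates around each coarse estimate.

    Returns ``{name: {plane: (axes, coords_mm, peak)}}`` where ``axes`` are
    the two world axes the plane observes and ``coords_mm`` their values.
    Windows clipped at the volume boundary are shifted inward.  With
    ``cfg.gate_refinement`` landmarks whose coarse peak falls below
    ``cfg.tau`` are skipped (empty candidate dict).
    """
    cfg = cfg or PredictionConfig()
    shape = volume.shape
    norm = normalize_hu(volume.data)
    results: dict = {}
    for i, (name, (coord, cpeak)) in enumerate(coarse.items()):
        cand = {}
        if cfg.gate_refinement and cpeak < cfg.tau:
            results[name] = cand
            continue
        if coord is not None:
            vox = volume.world_to_voxel(coord)
            for plane in cfg.use_planes:
                normal, axes = plane_axes(plane)
                branch = branches[plane]
                center = int(np.clip(round(vox[normal]), 0, shape[normal] - 1))
                best = None
                for off in range(-cfg.slab, cfg.slab + 1):
                    sl_idx = int(np.clip(center + off, 0, shape[normal] - 1))
                    slicer = [slice(None)] * 3
                    slicer[normal] = sl_idx
                    img2d = norm[tuple(slicer)]
                    want = getattr(branch, "spec", None)
                    wsize = cfg.window or (want.crop if want else img2d.shape)
                    if isinstance(wsize, int):
                        wsize = (wsize, wsize)
                    b0 = _window_bounds(vox[axes[0]], wsize[0], img2d.shape[0])
                    b1 = _window_bounds(vox[axes[1]], wsize[1], img2d.shape[1])
                    crop = img2d[b0[0]:b0[1], b1[0]:b1[1]]
                    maps = _run(branch, crop)
                    ij, peak = decode_peak(maps[i], refine=cfg.refine)
                    if np.any(np.isnan(ij)):
                        continue
                    if best is None or peak > best[2]:
                        gi = np.array([ij[0] + b0[0], ij[1] + b1[0]])
                        mm = volume.origin[list(axes)] + gi * volume.spacing[list(axes)]
                        best = (axes, mm, float(np.clip(peak, 0.0, 1.0)))
                if best is not None:
                    cand[plane] = best
        results[name] = cand
    return results


def fuse_candidates(coarse_coord: np.ndarray | None, plane_cands: dict,
                    tau: float = 0.35) -> np.ndarray | None:
    """Average, per world coordinate, the plane candidates that observe it.

    Candidates with peak < tau are dropped; unobserved coordinates fall back
    to the coarse estimate.  Returns None when nothing at all is available.
    """
    if coarse_coord is None and not plane_cands:
        return None
    sums = np.zeros(3)
    counts = np.zeros(3)
    for axes, mm, peak in plane_cands.values():
        if peak < tau:
            continue
        for a, v in zip(axes, mm):
            sums[a] += v
            counts[a] += 1
    fused = np.empty(3)
    for a in range(3):
        if counts[a] > 0:
            fused[a] = sums[a] / counts[a]
        elif coarse_coord is not None:
            fused[a] = coarse_coord[a]
        else:
            return None
    return fused


def decide_presence(coarse_peak: float, plane_peaks, tau: float) -> bool:
    """Present iff the best peak across stages reaches the threshold."""
    peaks = [coarse_peak, *plane_peaks]
    return bool(max(peaks) >= tau) if peaks else False


def predict_landmarks(volume: Volume3D, models: dict, names: list[str],
                      cfg: PredictionConfig | None = None,
                      case_id: str = "case") -> LandmarkSet:
    """Full coarse-to-fine pipeline; one entry per catalog landmark.

    ``models`` maps ``"coarse"`` to the 3D model and plane names to the 2D
    branches (planes are optional: with no branches the coarse stage stands
    alone).
    """
    cfg = cfg or PredictionConfig()
    coarse = coarse_localize(models["coarse"], volume, names, cfg)
    have_planes = all(p in models for p in cfg.use_planes)
    refined = (refine_ss_p3d({p: models[p] for p in cfg.use_planes}, volume, coarse, cfg)
               if have_planes else {n: {} for n in names})
    pred = LandmarkSet(case_id=case_id, source="prediction")
    for name in names:
        coarse_coord, coarse_peak = coarse[name]
        cands = refined.get(name, {})
        present = decide_presence(coarse_peak, [c[2] for c in cands.values()], cfg.tau)
        if not present:
            pred.add(name, None, present=False)
            continue
        fused = fuse_candidates(coarse_coord, cands, cfg.tau)
        if fused is None:
            pred.add(name, None, present=False)
        else:
            pred.add(name, fused, present=True)
    return pred
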