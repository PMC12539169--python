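"""Gaussian heatmap encoding and sub-grid peak decoding.

Landmark positions are represented as peak-normalized (amplitude-1) Gaussian
confidence maps: ``map(p) = exp(-||p - c||^2 / (2 sigma^2))`` evaluated at
integer grid points, in 2D (per-plane refinement stage) or 3D (coarse stage).
Peak normalization, rather than probability normalization, keeps the presence
threshold interpretable on [0, 1].

Decoding returns the arg-max refined to sub-grid precision by a separable
three-point quadratic (log-parabola on a Gaussian) fit around the peak; plain
arg-max is available via ``refine=False`` for strict argmax behaviour.  Ties
are broken toward the lexicographically smallest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import LandmarkSet, Volume3D

__all__ = [
    "HeatmapStack",
    "encode_gaussian",
    "decode_peak",
    "encode_targets",
    "PLANES",
    "plane_axes",
]

# plane name -> (normal axis, in-plane axes); axis order x=0, y=1, z=2
PLANES = {"axial": (2, (0, 1)), "sagittal": (0, (1, 2)), "coronal": (1, (0, 2))}


def plane_axes(plane: str) -> tuple[int, tuple[int, int]]:
    """Return (normal axis, in-plane axes) for an orthogonal plane name."""
    try:
        return PLANES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {list(PLANES)}") from None


@dataclass
class HeatmapStack:
    """Per-landmark heatmaps on a common grid.

    ``maps`` has shape ``(L, *grid)``; order matches ``names``.  ``spacing``
    and ``origin`` describe the grid the maps live on so decoded peaks can be
    mapped to world mm; for 2D stacks they refer to the two in-plane axes.
    """

    maps: np.ndarray
    names: list[str]
    sigma: float
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.shape[0] != len(self.names):
            raise ValueError("one map per landmark name required")


def encode_gaussian(center, shape, sigma: float) -> np.ndarray:
    """Evaluate an amplitude-1 Gaussian centered at a continuous grid point.

    ``center`` is a continuous 0-based grid coordinate (len(shape) entries,
    may be off-grid or outside); peak value reaches 1.0 iff the center lies on
    a grid point.  ``sigma`` is in grid units.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    center = np.asarray(center, dtype=float)
    if center.shape != (len(shape),):
        raise ValueError(f"center {center} does not match grid rank {len(shape)}")
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij", sparse=True)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _quadratic_offset(m1: float, m0: float, p1: float) -> float:
    """Sub-grid offset of a 3-point parabola through (-1,m1),(0,m0),(1,p1)."""
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0:  # not a local max in this axis; keep the integer position
        return 0.0
    off = 0.5 * (m1 - p1) / denom
    return float(np.clip(off, -0.5, 0.5))


def decode_peak(hmap: np.ndarray, refine: bool = True):
    """Locate the heatmap peak, optionally refined to sub-grid precision.

    Returns ``(coordinate, peak_value)`` where ``coordinate`` is a float array
    in grid units.  For an all-zero (flat) map the peak value is 0 and the
    coordinate is all-NaN, flagging "no peak".  Ties in the arg-max are broken
    by the lowest index in lexicographic axis order (numpy argmax order).
    """
    hmap = np.asarray(hmap, dtype=float)
    if hmap.size == 0:
        raise ValueError("empty heatmap")
    flat_idx = int(np.argmax(hmap))
    peak = float(hmap.flat[flat_idx])
    if peak <= 0.0 and np.all(hmap == hmap.flat[0]):
        return np.full(hmap.ndim, np.nan), 0.0
    idx = np.array(np.unravel_index(flat_idx, hmap.shape), dtype=float)
    if refine:
        # separable 3-point quadratic fit in log-space (exact for a Gaussian);
        # falls back to linear space when a neighbour is non-positive
        for ax in range(hmap.ndim):
            i = int(idx[ax])
            if 0 < i < hmap.shape[ax] - 1:
                sl = list(np.unravel_index(flat_idx, hmap.shape))
                sl[ax] = slice(i - 1, i + 2)
                triple = hmap[tuple(sl)]
                if np.all(triple > 0):
                    m1, m0, p1 = np.log(triple)
                else:
                    m1, m0, p1 = triple
                idx[ax] += _quadratic_offset(m1, m0, p1)
    return idx, peak


def encode_targets(
    landmarks: LandmarkSet,
    volume: Volume3D,
    sigma: float,
    names: list[str],
    stage: str = "coarse3d",
    plane: str | None = None,
    slice_index: int | None = None,
    attenuate: bool = False,
    attenuate_sigma: float | None = None,
    attenuate_window: float | None = None,
) -> HeatmapStack:
    """Build target heatmaps for the coarse-3D or a per-plane 2D stage.

    Absent landmarks receive an identically-zero map ("no landmark"
    supervision).  ``plane2d`` targets place the Gaussian at the landmark's
    two in-plane grid coordinates on the given orthogonal slice, regardless of
    how far the slice is from the landmark (the slice choice is the caller's).
    With ``attenuate=True`` the plane target's amplitude depends on the
    through-plane distance between the slice and the landmark, so channels of
    landmarks far from the slice are supervised toward zero rather than left
    unconstrained.  ``attenuate_window`` gives a top-hat profile (amplitude 1
    within that many slices, 0 beyond) — appropriate when the slice content
    cannot reveal the exact through-plane offset, as for near-prismatic
    structures; otherwise a Gaussian profile of width ``attenuate_sigma``
    (default: ``sigma``) is used, the exact restriction of the 3D Gaussian.  Centers outside the grid still produce (clipped-tail)
    targets; a warning flag is recorded on the stack as ``clipped`` attribute.
    """
    shape = volume.shape
    if stage == "coarse3d":
        grid_shape = shape
        axes = (0, 1, 2)
    elif stage == "plane2d":
        normal, axes = plane_axes(plane)
        if slice_index is None:
            raise ValueError("plane2d stage requires slice_index")
        grid_shape = tuple(shape[a] for a in axes)
    else:
        raise ValueError(f"unknown stage {stage!r}")

    maps = np.zeros((len(names),) + tuple(grid_shape), dtype=np.float32)
    clipped: list[str] = []
    for i, name in enumerate(names):
        lm = landmarks[name]
        if not lm.present:
            continue
        vox = volume.world_to_voxel(lm.coord)
        center = vox[list(axes)]
        if np.any(center < 0) or np.any(center > np.array(grid_shape) - 1):
            clipped.append(name)
        amp = 1.0
        if attenuate and stage == "plane2d":
            off = abs(slice_index - vox[normal])
            if attenuate_window is not None:
                amp = 1.0 if off <= attenuate_window else 0.0
            else:
                s_n = attenuate_sigma if attenuate_sigma is not None else sigma
                amp = float(np.exp(-off ** 2 / (2.0 * s_n ** 2)))
        maps[i] = amp * encode_gaussian(center, grid_shape, sigma)
    stack = HeatmapStack(
        maps=maps,
        names=list(names),
        sigma=sigma,
        spacing=volume.spacing[list(axes)],
        origin=volume.origin[list(axes)],
    )
    stack.clipped = clipped  # type: ignore[attr-defined]
    return stack
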