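"""Deterministic synthetic skull phantoms with analytic ground-truth landmarks.

The phantom emulates a head-CT volume at desk scale: a cranial ellipsoid shell
(bone) with soft-tissue interior and envelope, an intracranial sella sphere, a
maxillary and a mandibular dental arch (bone tubes) carrying cylindrical tooth
pegs (teeth intensity), an anterior nasal spike and a chin boss.  The 14
phantom-catalog landmarks are defined on the continuous analytic geometry
*before* voxelization, so ground truth has sub-voxel precision and the
voxelization error (about half a voxel) bounds the best achievable radial
error.

Tissue intensities follow CT Hounsfield windows: air -1000 HU, soft tissue
within [-700, 225] HU, bone within [226, 2619] HU, teeth about 1800 HU and
metal about 3000 HU (outside the bone window).  Additive Gaussian HU noise is
seeded and lives on a field independent of the geometry, so corruptions that
re-render the scene leave untouched voxels bit-identical.

Three corruption scenarios are provided: malocclusion (M, rigid mandible
shift), missing dental landmarks (MDL, tooth pegs removed and flagged absent)
and metal artifacts (MA, a metal blob plus stylized axial streaks).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .catalog import dental_names, phantom_catalog
from .volume_io import LandmarkSet, Volume3D

__all__ = [
    "PhantomConfig",
    "ScenarioLabel",
    "Phantom",
    "PhantomGeometryError",
    "generate_phantom",
    "apply_missing_dental",
    "apply_metal_artifact",
    "apply_malocclusion",
    "generate_case",
    "generate_batch",
    "SCENARIOS",
]

SCENARIOS = ("Normal", "M", "MDL", "MA")

# label codes, painted in priority order (higher wins)
_AIR, _SOFT, _BONE, _TEETH, _METAL = 0, 1, 2, 3, 4

# mandible component: every lower-jaw landmark rides the rigid mandible motion
MANDIBLE_LANDMARKS = ("B", "Pog", "Me", "Gn", "LI", "L6L", "L6R")


class PhantomGeometryError(ValueError):
    """Raised when the configured geometry does not fit inside the grid."""


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise parameters of one phantom.

    Defaults give the desk-scale preset: a 96x96x64 grid at 0.5 mm isotropic
    spacing.  ``paper_scale()`` matches the 128x128x64 crop used at full
    resolution; ``tiny()`` is the preset used by the scaled-down training
    exercises.  Geometry parameters are fractions of the field of view so the
    phantom scales with the grid; ``jitter`` is the relative per-case random
    perturbation of radii and centers.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # intensity model (HU)
    air_hu: float = -1000.0
    soft_hu: float = 40.0
    bone_hu: float = 1200.0
    teeth_hu: float = 1800.0
    metal_hu: float = 3000.0
    noise_sd: float = 20.0
    # geometry (fractions of the field of view unless noted)
    cranial_center: tuple[float, float, float] = (0.50, 0.45, 0.68)
    cranial_radii: tuple[float, float, float] = (0.30, 0.33, 0.26)
    shell_mm: float = 1.5          # cranial shell thickness, mm
    sella_mm: float = 2.2          # sella sphere radius, mm
    arch_radius: float = 0.16      # dental arch radius (fraction of x extent)
    arch_tube_mm: float = 1.8      # arch tube radius, mm
    upper_z: float = 0.42          # upper arch plane (fraction of z extent)
    lower_z: float = 0.16          # lower arch plane
    arch_y: float = 0.52           # arch center, anterior-posterior
    lower_arch_factor: float = 0.90  # lower arch radius relative to upper (overjet)
    molar_deg: float = 75.0        # molar peg angle from the midline, degrees
    peg_mm: float = 1.2            # upper tooth peg radius, mm
    peg_lower_mm: float | None = None  # lower peg radius; None = same as upper
    peg_height_mm: float = 3.0     # tooth peg height, mm
    spike_mm: float = 2.5          # nasal spike length, mm
    spike_radius_mm: float = 1.2   # nasal spike half-thickness, mm
    n_boss_mm: float = 2.0         # frontonasal boss radius at N, mm
    chin_mm: float = 3.0           # chin boss radius, mm
    jitter: float = 0.06
    seed: int = 0

    @classmethod
    def paper_scale(cls, **kw) -> "PhantomConfig":
        return cls(shape=(128, 128, 64), **kw)

    @classmethod
    def tiny(cls, **kw) -> "PhantomConfig":
        """Preset for the scaled-down training exercises: a 24 x 24 x 20 mm
        field at native 0.5 mm spacing, with feature sizes chosen so every
        landmark's anchor structure spans several voxels (tooth pegs ~2.6
        voxels across, sella and frontonasal boss ~4-6)."""
        kw.setdefault("shape", (48, 48, 40))
        kw.setdefault("upper_z", 0.45)   # wider occlusal gap at this scale
        kw.setdefault("lower_arch_factor", 0.85)  # pronounced overjet: upper and
        # lower teeth stay separable at coarse voxel sizes
        kw.setdefault("shell_mm", 1.2)
        kw.setdefault("sella_mm", 3.0)
        kw.setdefault("arch_tube_mm", 0.9)  # thin alveolar ridge so crowns
        # protrude ~3 voxels: tooth presence must stay legible in the image
        kw.setdefault("peg_mm", 1.3)
        kw.setdefault("peg_lower_mm", 1.0)  # natural size asymmetry keeps the
        # arches distinguishable when the occlusal gap is a few voxels
        kw.setdefault("peg_height_mm", 2.4)
        kw.setdefault("spike_mm", 2.5)
        kw.setdefault("spike_radius_mm", 1.2)
        kw.setdefault("n_boss_mm", 2.0)
        kw.setdefault("chin_mm", 1.8)
        return cls(**kw)

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape, float) * np.asarray(self.spacing, float)

    @property
    def hu_value(self) -> dict[int, float]:
        return {_AIR: self.air_hu, _SOFT: self.soft_hu, _BONE: self.bone_hu,
                _TEETH: self.teeth_hu, _METAL: self.metal_hu}


@dataclass
class ScenarioLabel:
    """Corruption flags applied to a phantom, recorded exactly as applied."""

    flags: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return "+".join(self.flags) if self.flags else "Normal"


def _resolve_geometry(cfg: PhantomConfig) -> dict:
    """Resolve fractional geometry to world mm, with seeded per-case jitter."""
    rng = np.random.default_rng(cfg.seed)
    ext = cfg.extent
    j = cfg.jitter

    def jit(scale=1.0):
        return 1.0 + j * rng.uniform(-1, 1) * scale

    cx = 0.5 * ext[0] + 0.02 * ext[0] * rng.uniform(-1, 1) * (j > 0)
    geo = {
        "cranial_center": np.array([cx,
                                    cfg.cranial_center[1] * ext[1] * jit(0.3),
                                    cfg.cranial_center[2] * ext[2] * jit(0.3)]),
        "cranial_radii": np.array([cfg.cranial_radii[0] * ext[0] * jit(),
                                   cfg.cranial_radii[1] * ext[1] * jit(),
                                   cfg.cranial_radii[2] * ext[2] * jit()]),
        "shell": cfg.shell_mm,
        "sella_r": cfg.sella_mm,
        "arch_r_u": cfg.arch_radius * ext[0] * jit(),
        "arch_r_l": cfg.arch_radius * cfg.lower_arch_factor * ext[0] * jit(),  # overjet
        "tube": cfg.arch_tube_mm,
        "uz": cfg.upper_z * ext[2] * jit(0.3),
        "lz": cfg.lower_z * ext[2] * jit(0.3),
        "ay": cfg.arch_y * ext[1] * jit(0.3),
        "my": (cfg.arch_y - 0.02) * ext[1] * jit(0.3),
        "cx": cx,
        "molar_rad": np.deg2rad(cfg.molar_deg),
        "peg_r_u": cfg.peg_mm,
        "peg_r_l": cfg.peg_lower_mm if cfg.peg_lower_mm is not None else cfg.peg_mm,
        "peg_h": cfg.peg_height_mm,
        "spike": cfg.spike_mm,
        "spike_r": cfg.spike_radius_mm,
        "n_boss": cfg.n_boss_mm,
        "chin": cfg.chin_mm,
        "mandible_shift": np.zeros(3),
        "removed_teeth": [],
        "metal": [],  # list of dicts: center, n_streaks, angles
    }
    return geo


def _tooth_positions(geo: dict, arch: str) -> dict[str, np.ndarray]:
    """In-plane (x, y) anchor of each tooth peg on its arch; pre-shift."""
    th = geo["molar_rad"]
    if arch == "upper":
        c = np.array([geo["cx"], geo["ay"]])
        r = geo["arch_r_u"]
        names = {"UI": 0.0, "U6L": +th, "U6R": -th}
    else:
        c = np.array([geo["cx"], geo["my"]])
        r = geo["arch_r_l"]
        names = {"LI": 0.0, "L6L": +th, "L6R": -th}
    return {n: c + r * np.array([np.sin(a), np.cos(a)]) for n, a in names.items()}


def _landmark_truth(geo: dict) -> dict[str, np.ndarray]:
    """Analytic landmark positions (world mm) from the resolved geometry."""
    C, R = geo["cranial_center"], geo["cranial_radii"]
    uz, lz = geo["uz"], geo["lz"]
    tube, chin = geo["tube"], geo["chin"]
    up = _tooth_positions(geo, "upper")
    lo = _tooth_positions(geo, "lower")
    front_u = geo["ay"] + geo["arch_r_u"]   # y of the upper arch front
    front_l = geo["my"] + geo["arch_r_l"]   # y of the lower arch front
    cx = geo["cx"]
    alpha = np.deg2rad(50.0)
    s2 = 1.0 / np.sqrt(2.0)
    lm = {
        "N": np.array([cx, C[1] + R[1], C[2]]),
        "S": C.copy(),
        "ANS": np.array([cx, front_u + geo["spike"], uz + 2.0 * tube]),
        "A": np.array([cx, front_u + tube * np.cos(alpha), uz - tube * np.sin(alpha)]),
        "UI": np.array([up["UI"][0], up["UI"][1], uz - geo["peg_h"]]),
        "U6L": np.array([up["U6L"][0], up["U6L"][1], uz - geo["peg_h"]]),
        "U6R": np.array([up["U6R"][0], up["U6R"][1], uz - geo["peg_h"]]),
        "B": np.array([cx, front_l + chin * s2, lz + chin * s2]),
        "Pog": np.array([cx, front_l + chin, lz]),
        "Gn": np.array([cx, front_l + chin * s2, lz - chin * s2]),
        "Me": np.array([cx, front_l, lz - chin]),
        "LI": np.array([lo["LI"][0], lo["LI"][1], lz + geo["peg_h"]]),
        "L6L": np.array([lo["L6L"][0], lo["L6L"][1], lz + geo["peg_h"]]),
        "L6R": np.array([lo["L6R"][0], lo["L6R"][1], lz + geo["peg_h"]]),
    }
    shift = geo["mandible_shift"]
    for name in MANDIBLE_LANDMARKS:
        lm[name] = lm[name] + shift
    return lm


# ---------------------------------------------------------------------------
# voxelization


def _world_grids(cfg: PhantomConfig):
    sp, org = np.asarray(cfg.spacing), np.asarray(cfg.origin)
    ax = [org[i] + sp[i] * np.arange(cfg.shape[i], dtype=np.float64) for i in range(3)]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _paint_labels(cfg: PhantomConfig, geo: dict) -> np.ndarray:
    X, Y, Z = _world_grids(cfg)
    labels = np.zeros(cfg.shape, dtype=np.uint8)
    C, R = geo["cranial_center"], geo["cranial_radii"]
    shift = geo["mandible_shift"]

    def sphere(center, r):
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r ** 2

    def arch(cx, cy, r, z0, tube, half_angle):
        dx, dy, dz = X - cx, Y - cy, Z - z0
        rxy = np.sqrt(dx ** 2 + dy ** 2)
        ang = np.abs(np.arctan2(dx, dy + 0 * dx))
        return ((rxy - r) ** 2 + dz ** 2 <= tube ** 2) & (ang <= half_angle)

    def peg(xy, z0, z1, r):
        return ((X - xy[0]) ** 2 + (Y - xy[1]) ** 2 <= r ** 2) & (Z >= z0) & (Z <= z1)

    # soft envelope: inflated cranial ellipsoid plus a face prism over the jaws
    rho2 = (((X - C[0]) / (1.12 * R[0])) ** 2 + ((Y - C[1]) / (1.12 * R[1])) ** 2
            + ((Z - C[2]) / (1.12 * R[2])) ** 2)
    labels[rho2 <= 1.0] = _SOFT
    face = ((np.abs(X - geo["cx"]) <= geo["arch_r_l"] + 2.5)
            & (Y >= geo["my"] - geo["arch_r_l"]) & (Y <= geo["my"] + geo["arch_r_l"] + geo["chin"] + 2.0)
            & (Z >= geo["lz"] - geo["chin"] - 2.0 + shift[2]) & (Z <= geo["uz"] + 4.0))
    labels[face] = np.maximum(labels[face], _SOFT)

    # cranial shell (bone): between the inner and outer ellipsoid
    rho_out = (((X - C[0]) / R[0]) ** 2 + ((Y - C[1]) / R[1]) ** 2 + ((Z - C[2]) / R[2]) ** 2)
    Ri = R - geo["shell"]
    rho_in = (((X - C[0]) / Ri[0]) ** 2 + ((Y - C[1]) / Ri[1]) ** 2 + ((Z - C[2]) / Ri[2]) ** 2)
    labels[(rho_out <= 1.0) & (rho_in >= 1.0)] = _BONE
    labels[sphere(C, geo["sella_r"])] = _BONE
    # frontonasal boss: a marked junction at the anterior midline pole (N)
    labels[sphere((geo["cx"], C[1] + R[1], C[2]), geo["n_boss"])] = _BONE

    half = geo["molar_rad"] + 0.35  # arch tube extends slightly past the molars
    labels[arch(geo["cx"], geo["ay"], geo["arch_r_u"], geo["uz"], geo["tube"], half)] = _BONE
    # nasal spike: a thin bar protruding anteriorly from the upper arch front
    front_u = geo["ay"] + geo["arch_r_u"]
    spike = ((np.abs(X - geo["cx"]) <= geo["spike_r"]) & (np.abs(Z - (geo["uz"] + 2.0 * geo["tube"])) <= geo["spike_r"])
             & (Y >= front_u - 1.0) & (Y <= front_u + geo["spike"]))
    labels[spike] = _BONE

    # mandible component (arch + chin boss), rigidly shifted
    mcx, mcy, mlz = geo["cx"] + shift[0], geo["my"] + shift[1], geo["lz"] + shift[2]
    labels[arch(mcx, mcy, geo["arch_r_l"], mlz, geo["tube"], half)] = _BONE
    front_l = mcy + geo["arch_r_l"]
    labels[sphere((mcx, front_l, mlz), geo["chin"])] = _BONE

    # tooth pegs (skip removed teeth); lower pegs ride the mandible shift
    up = _tooth_positions(geo, "upper")
    lo = _tooth_positions(geo, "lower")
    for name, xy in up.items():
        if name not in geo["removed_teeth"]:
            labels[peg(xy, geo["uz"] - geo["peg_h"], geo["uz"], geo["peg_r_u"])] = _TEETH
    for name, xy in lo.items():
        if name not in geo["removed_teeth"]:
            labels[peg(xy + shift[:2], mlz, mlz + geo["peg_h"], geo["peg_r_l"])] = _TEETH

    # metal blobs
    for m in geo["metal"]:
        labels[sphere(m["center"], m.get("radius", 1.5))] = _METAL
    return labels


def _streak_field(cfg: PhantomConfig, geo: dict) -> np.ndarray | None:
    """Stylized alternating bright/dark rays through each metal blob, axially."""
    if not any(m.get("n_streaks", 0) for m in geo["metal"]):
        return None
    X, Y, Z = _world_grids(cfg)
    fld = np.zeros(cfg.shape, dtype=np.float32)
    for m in geo["metal"]:
        n = m.get("n_streaks", 0)
        if n == 0:
            continue
        cx, cy, cz = m["center"]
        dx, dy = X - cx, Y - cy
        ang = np.arctan2(dy, dx + 0 * dy)  # in-plane angle
        inplane = np.abs(Z - cz) <= 1.0 + 0 * X + 0 * Y
        for k, a in enumerate(m["angles"]):
            d = np.abs((ang - a + np.pi) % (2 * np.pi) - np.pi)
            ray = (d <= np.deg2rad(3.0)) & inplane
            fld[ray] += 400.0 if k % 2 == 0 else -400.0
    return fld


@dataclass
class Phantom:
    """A generated phantom: rendered volume, analytic truth, scenario record.

    Iterable as ``(volume, truth, scenario)`` to match the generation contract.
    """

    cfg: PhantomConfig
    geometry: dict
    volume: Volume3D
    truth: LandmarkSet
    scenario: ScenarioLabel

    def __iter__(self) -> Iterator:
        return iter((self.volume, self.truth, self.scenario))

    def nominal_positions(self) -> dict[str, np.ndarray]:
        """Analytic positions of all 14 landmarks, including the would-be
        sites of removed teeth (useful as supervision anchors for
        absent-landmark training examples)."""
        return _landmark_truth(self.geometry)


def _render(cfg: PhantomConfig, geo: dict, scenario: ScenarioLabel, case_id: str) -> Phantom:
    truth_pos = _landmark_truth(geo)
    shape = np.asarray(cfg.shape, float)
    sp, org = np.asarray(cfg.spacing), np.asarray(cfg.origin)
    for name, p in truth_pos.items():
        v = (p - org) / sp
        if np.any(v <= 0) or np.any(v >= shape - 1):
            raise PhantomGeometryError(
                f"landmark {name} at voxel {v} falls outside the grid {cfg.shape}")

    labels = _paint_labels(cfg, geo)
    hu = np.empty(cfg.shape, dtype=np.float32)
    for code, val in cfg.hu_value.items():
        hu[labels == code] = val
    streaks = _streak_field(cfg, geo)
    if streaks is not None:
        hu += streaks
    if cfg.noise_sd > 0:
        noise_rng = np.random.default_rng((cfg.seed, 0xC7))
        hu = hu + cfg.noise_sd * noise_rng.standard_normal(cfg.shape).astype(np.float32)

    truth = LandmarkSet(case_id=case_id, source="phantom-truth")
    removed = set(geo["removed_teeth"])
    for d in phantom_catalog():
        if d.name in removed:
            truth.add(d.name, None, present=False)
        else:
            truth.add(d.name, truth_pos[d.name], present=True)

    vol = Volume3D(data=hu, spacing=sp.copy(), origin=org.copy())
    return Phantom(cfg=cfg, geometry=geo, volume=vol, truth=truth, scenario=scenario)


def generate_phantom(cfg: PhantomConfig, case_id: str | None = None) -> Phantom:
    """Generate a clean phantom; (cfg, cfg.seed) fully determine the output."""
    geo = _resolve_geometry(cfg)
    case_id = case_id or f"phantom-{cfg.seed:05d}"
    return _render(cfg, geo, ScenarioLabel(), case_id)


def _regen(ph: Phantom, geo: dict, scenario: ScenarioLabel) -> Phantom:
    return _render(ph.cfg, geo, scenario, ph.truth.case_id)


def apply_missing_dental(ph: Phantom, names: Sequence[str]) -> Phantom:
    """Remove the named tooth pegs; their truth entries become absent.

    Voxel changes are confined to the removed pegs' regions; all other voxels
    and every other landmark are unchanged.
    """
    dental = set(dental_names(phantom_catalog()))
    bad = [n for n in names if n not in dental]
    if bad:
        raise ValueError(f"not dental landmarks: {bad}")
    if not names:
        return ph
    geo = copy.deepcopy(ph.geometry)
    geo["removed_teeth"] = sorted(set(geo["removed_teeth"]) | set(names))
    scenario = ScenarioLabel(flags=ph.scenario.flags + ["MDL"],
                             params={**ph.scenario.params, "removed": sorted(names)})
    return _regen(ph, geo, scenario)


def apply_metal_artifact(ph: Phantom, center_landmark: str, n_streaks: int = 8,
                         seed: int = 0) -> Phantom:
    """Place a metal blob at a landmark plus ``n_streaks`` axial streak rays.

    Ground-truth coordinates are unchanged; the blob exceeds the bone HU
    window (about 3000 HU).
    """
    lm = ph.truth[center_landmark] if center_landmark in ph.truth else None
    if lm is None or not lm.present:
        raise ValueError(f"no present landmark {center_landmark!r} to center the artifact on")
    rng = np.random.default_rng((seed, 0xA5))
    angles = rng.uniform(0, 2 * np.pi, size=n_streaks)
    geo = copy.deepcopy(ph.geometry)
    geo["metal"] = geo["metal"] + [{"center": lm.coord.copy(), "radius": 1.5,
                                    "n_streaks": int(n_streaks), "angles": angles}]
    scenario = ScenarioLabel(flags=ph.scenario.flags + ["MA"],
                             params={**ph.scenario.params,
                                     "metal_center": center_landmark,
                                     "n_streaks": int(n_streaks)})
    return _regen(ph, geo, scenario)


def apply_malocclusion(ph: Phantom, shift: Sequence[float]) -> Phantom:
    """Rigidly translate the mandible (arc, chin, lower pegs) by ``shift`` mm.

    Mandibular/lower-dental truths translate by exactly ``shift``; maxillary
    landmarks are unchanged.  Composed shifts sum.
    """
    shift = np.asarray(shift, float)
    if shift.shape != (3,):
        raise ValueError("shift must be a 3-vector in mm")
    if not np.any(shift):
        return ph
    geo = copy.deepcopy(ph.geometry)
    geo["mandible_shift"] = geo["mandible_shift"] + shift
    scenario = ScenarioLabel(flags=ph.scenario.flags + ["M"],
                             params={**ph.scenario.params,
                                     "shift_mm": [float(s) for s in shift]})
    return _regen(ph, geo, scenario)


# ---------------------------------------------------------------------------
# batch generation with scenario mix


def generate_case(cfg: PhantomConfig, scenario: str, seed: int,
                  mdl_remove: Sequence[str] | None = None) -> Phantom:
    """Generate one phantom under a named scenario with seeded corruption.

    M: mandible shift drawn uniformly, 1.5-3 mm anterior plus up to 1 mm
    lateral/vertical.  MDL: one or two dental landmarks removed (or exactly
    the names in ``mdl_remove``, for cohorts stratified so every tooth
    appears absent somewhere).  MA: metal blob with 8 streaks centered on a
    random dental landmark.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ph = generate_phantom(replace(cfg, seed=seed), case_id=f"case-{seed:05d}-{scenario}")
    rng = np.random.default_rng((seed, 0x5C))
    if scenario == "M":
        shift = np.array([rng.uniform(-1, 1),
                          rng.uniform(1.5, 3.0) * rng.choice([-1, 1]),
                          rng.uniform(-1, 1)])
        ph = apply_malocclusion(ph, shift)
    elif scenario == "MDL":
        if mdl_remove is None:
            k = int(rng.integers(1, 3))
            mdl_remove = [str(n) for n in
                          rng.choice(dental_names(phantom_catalog()), size=k, replace=False)]
        ph = apply_missing_dental(ph, list(mdl_remove))
    elif scenario == "MA":
        center = str(rng.choice(dental_names(phantom_catalog())))
        ph = apply_metal_artifact(ph, center, n_streaks=8, seed=seed)
    return ph


def generate_batch(cfg: PhantomConfig, n: int, base_seed: int,
                   scenarios: Sequence[str] = SCENARIOS) -> list[Phantom]:
    """Generate ``n`` phantoms, per-case seed ``base_seed + index``, scenarios
    assigned round-robin."""
    return [generate_case(cfg, scenarios[i % len(scenarios)], base_seed + i)
            for i in range(n)]
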