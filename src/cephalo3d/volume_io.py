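"""Volume and landmark-file I/O and the coordinate contract.

Every quantity downstream of this module that carries a physical unit is in
millimetres.  A :class:`Volume3D` stores a 3D scalar grid (Hounsfield units for
CT-like data) together with per-axis voxel spacing and the world position of
voxel ``(0, 0, 0)``.  Landmark coordinates are always world millimetres, so
radial errors are spacing-aware by construction.

Axis convention (fixed throughout the package):

* array axis 0 — ``x``, left–right
* array axis 1 — ``y``, anterior–posterior
* array axis 2 — ``z``, superior–inferior (the slice-stacking direction)

Continuous voxel indices are 0-based; ``world = origin + index * spacing``
componentwise, and the transform is exactly invertible on fractional indices.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

AXIS_ROLES = ("x:left-right", "y:anterior-posterior", "z:superior-inferior")

__all__ = [
    "AXIS_ROLES",
    "Volume3D",
    "Landmark",
    "LandmarkSet",
    "VolumeFormatError",
    "LandmarkParseError",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]


class VolumeFormatError(ValueError):
    """Raised when a volume file violates the format contract."""


class LandmarkParseError(ValueError):
    """Raised when a landmark file violates the format contract."""


@dataclass
class Volume3D:
    """A 3D scalar image with spacing/origin metadata.

    Parameters
    ----------
    data
        3D array of intensities (HU for CT-like volumes).
    spacing
        Per-axis voxel size in mm; strictly positive.
    origin
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_roles: tuple[str, str, str] = AXIS_ROLES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise VolumeFormatError("spacing and origin must be 3-vectors")
        if not np.all(self.spacing > 0):
            raise VolumeFormatError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map continuous 0-based voxel indices to world mm.

        Indices may be fractional and outside the grid; the transform is affine
        and total: ``world = origin + index * spacing``.
        """
        index = np.asarray(index, dtype=float)
        return self.origin + index * self.spacing

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world` (exact on fractional indices)."""
        world = np.asarray(world, dtype=float)
        return (world - self.origin) / self.spacing

    def contains_world(self, world: np.ndarray) -> bool:
        """Whether a world-mm point falls inside the voxel grid."""
        v = self.world_to_voxel(world)
        return bool(np.all(v >= 0) and np.all(v <= np.array(self.shape) - 1))


# sentinel for "no coordinate"; metric code rejects it via the present flag
_ABSENT = np.full(3, np.nan)


@dataclass
class Landmark:
    name: str
    coord: np.ndarray
    present: bool = True

    def __post_init__(self) -> None:
        if self.present:
            self.coord = np.asarray(self.coord, dtype=float)
            if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
                raise LandmarkParseError(f"malformed coordinate for {self.name!r}")
        else:
            self.coord = _ABSENT.copy()


@dataclass
class LandmarkSet:
    """Named 3D landmark coordinates (world mm) for one case.

    ``source`` records provenance: reference annotation, model prediction, or
    analytic phantom ground truth.  Entries flagged ``present=False`` carry a
    NaN sentinel coordinate that every metric operation rejects.
    """

    case_id: str
    entries: dict[str, Landmark] = field(default_factory=dict)
    source: str = "reference"

    def add(self, name: str, coord, present: bool = True) -> None:
        if name in self.entries:
            raise LandmarkParseError(f"duplicate landmark {name!r}")
        self.entries[name] = Landmark(name, coord if present else _ABSENT, present)

    def __getitem__(self, name: str) -> Landmark:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return list(self.entries)

    def present_names(self) -> list[str]:
        return [n for n, lm in self.entries.items() if lm.present]

    def validate_against(self, catalog_names: Iterable[str]) -> None:
        allowed = set(catalog_names)
        unknown = [n for n in self.entries if n not in allowed]
        if unknown:
            raise LandmarkParseError(f"landmarks not in catalog: {unknown}")


# ---------------------------------------------------------------------------
# NIfTI volumes


def _canonical_volume(img: nib.Nifti1Image) -> Volume3D:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D image, got ndim={data.ndim}")
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if not np.all(spacing > 0):
        raise VolumeFormatError(f"non-positive spacing in affine: {spacing}")
    origin = affine[:3, 3]
    return Volume3D(data=data, spacing=spacing, origin=np.asarray(origin, float))


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI volume, reorienting to the canonical axis order.

    Spacing and origin are taken from the affine; no flipping heuristics are
    applied beyond what the affine itself encodes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    return _canonical_volume(img)


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine from spacing/origin."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Landmark files: XML dialect plus JSON/CSV alternates with identical semantics


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1"):
        return True
    if t in ("false", "0"):
        return False
    raise LandmarkParseError(f"bad boolean {text!r}")


def _build_set(case_id: str, rows, source: str, catalog_names) -> LandmarkSet:
    lms = LandmarkSet(case_id=case_id, source=source)
    for name, x, y, z, present in rows:
        if present:
            try:
                coord = np.array([float(x), float(y), float(z)])
            except (TypeError, ValueError) as exc:
                raise LandmarkParseError(f"malformed coordinate for {name!r}") from exc
        else:
            coord = _ABSENT
        lms.add(name, coord, present=present)
    if catalog_names is not None:
        lms.validate_against(catalog_names)
    return lms


def read_landmarks(
    path: str | Path,
    catalog_names: Iterable[str] | None = None,
    source: str = "reference",
) -> LandmarkSet:
    """Read landmarks from XML, JSON or CSV (by extension), coordinates in mm."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".xml":
        root = ET.parse(str(path)).getroot()
        if root.tag != "landmarks":
            raise LandmarkParseError(f"unexpected root element {root.tag!r}")
        case_id = root.get("case", path.stem)
        rows = []
        for el in root.findall("landmark"):
            present = _parse_bool(el.get("present", "true"))
            rows.append((el.get("name"), el.get("x"), el.get("y"), el.get("z"), present))
    elif ext == ".json":
        payload = json.loads(path.read_text())
        case_id = payload.get("case", path.stem)
        rows = [
            (r["name"], r.get("x"), r.get("y"), r.get("z"), bool(r.get("present", True)))
            for r in payload["landmarks"]
        ]
    elif ext == ".csv":
        case_id = path.stem
        with open(path, newline="") as fh:
            rows = [
                (r["name"], r["x"], r["y"], r["z"], _parse_bool(r["present"]))
                for r in csv.DictReader(fh)
            ]
    else:
        raise LandmarkParseError(f"unsupported landmark format {ext!r}")
    return _build_set(case_id, rows, source, catalog_names)


def write_landmarks(lms: LandmarkSet, path: str | Path) -> Path:
    """Write landmarks as XML, JSON or CSV (by extension)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".xml":
        root = ET.Element("landmarks", case=lms.case_id)
        for lm in lms.entries.values():
            attrs = {"name": lm.name, "present": "true" if lm.present else "false"}
            if lm.present:
                attrs.update(x=_fmt(lm.coord[0]), y=_fmt(lm.coord[1]), z=_fmt(lm.coord[2]))
            else:
                attrs.update(x="", y="", z="")
            ET.SubElement(root, "landmark", **attrs)
        ET.indent(tree := ET.ElementTree(root))
        tree.write(str(path), xml_declaration=True, encoding="unicode")
    elif ext == ".json":
        payload = {
            "case": lms.case_id,
            "landmarks": [
                {
                    "name": lm.name,
                    "x": float(lm.coord[0]) if lm.present else None,
                    "y": float(lm.coord[1]) if lm.present else None,
                    "z": float(lm.coord[2]) if lm.present else None,
                    "present": lm.present,
                }
                for lm in lms.entries.values()
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif ext == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z", "present"])
            for lm in lms.entries.values():
                if lm.present:
                    w.writerow([lm.name, _fmt(lm.coord[0]), _fmt(lm.coord[1]), _fmt(lm.coord[2]), "true"])
                else:
                    w.writerow([lm.name, "", "", "", "false"])
    else:
        raise LandmarkParseError(f"unsupported landmark format {ext!r}")
    return path
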