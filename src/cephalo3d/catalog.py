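"""Built-in landmark catalogs for SCT, CBCT and the synthetic phantom.

The CBCT catalog is the 14-marker osteodental set: 8 skeletal midline
references (N, S, ANS, A, B, Pog, Me, Gn) and 6 dental landmarks (UI, LI,
U6L/R, L6L/R).  The SCT catalog holds 41 craniometric landmarks — 21 midline
singular landmarks plus 10 bilateral pairs (L/R suffix) — partitioned into 26
bony, 6 dental and 9 soft-tissue points.  Beyond the names printed in source
material (N, S, ANS, PNS, A, B, Pog, Me, Gn, UI, LI, U6, L6, Fz, Go, Pogs,
Mes), the roster is RECONSTRUCTED from standard craniometric nomenclature; the
counts and tissue partition are authoritative, individual reconstructed
definitions are conventional.

The phantom catalog mirrors the 14 CBCT names, each bound to an analytic
feature of the synthetic skull geometry (see :mod:`cephalo3d.phantom`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

__all__ = [
    "LandmarkDef",
    "builtin_catalog",
    "phantom_catalog",
    "catalog_names",
    "dental_names",
    "export_catalog",
    "load_catalog",
]

TISSUES = ("bone", "dental", "soft")
LATERALITIES = ("midline", "left", "right")
REGIONS = ("upper-third", "middle-third", "lower-third")


@dataclass(frozen=True)
class LandmarkDef:
    """One named landmark: tissue class, laterality, craniofacial third."""

    name: str
    tissue: str
    laterality: str
    region: str
    modality: str
    definition: str = ""

    def __post_init__(self):
        assert self.tissue in TISSUES, self.tissue
        assert self.laterality in LATERALITIES, self.laterality
        assert self.region in REGIONS, self.region


def _pair(base: str, tissue: str, region: str, modality: str, definition: str):
    return [
        LandmarkDef(f"{base}L", tissue, "left", region, modality, f"left {definition}"),
        LandmarkDef(f"{base}R", tissue, "right", region, modality, f"right {definition}"),
    ]


def _mid(name: str, tissue: str, region: str, modality: str, definition: str):
    return LandmarkDef(name, tissue, "midline", region, modality, definition)


def _sct_catalog() -> list[LandmarkDef]:
    m = "SCT"
    defs: list[LandmarkDef] = [
        # 12 midline bone
        _mid("N", "bone", "upper-third", m, "nasion: frontonasal suture midpoint"),
        _mid("S", "bone", "upper-third", m, "sella: center of sella turcica"),
        _mid("G", "bone", "upper-third", m, "glabella: most prominent frontal midline point"),
        _mid("Rhi", "bone", "middle-third", m, "rhinion: inferior tip of nasal bones"),
        _mid("ANS", "bone", "middle-third", m, "anterior nasal spine tip"),
        _mid("PNS", "bone", "middle-third", m, "posterior nasal spine tip"),
        _mid("A", "bone", "middle-third", m, "subspinale: deepest maxillary concavity"),
        _mid("Ba", "bone", "lower-third", m, "basion: anterior foramen magnum margin"),
        _mid("B", "bone", "lower-third", m, "supramentale: deepest mandibular concavity"),
        _mid("Pog", "bone", "lower-third", m, "pogonion: most anterior chin point"),
        _mid("Gn", "bone", "lower-third", m, "gnathion: midpoint between Pog and Me"),
        _mid("Me", "bone", "lower-third", m, "menton: most inferior symphysis point"),
        # 2 midline dental
        _mid("UI", "dental", "middle-third", m, "upper central incisor crown tip"),
        _mid("LI", "dental", "lower-third", m, "lower central incisor crown tip"),
        # 7 midline soft
        _mid("Ns", "soft", "upper-third", m, "soft-tissue nasion"),
        _mid("Prn", "soft", "middle-third", m, "pronasale: nasal tip"),
        _mid("Sn", "soft", "middle-third", m, "subnasale: columella-lip junction"),
        _mid("Ls", "soft", "lower-third", m, "labrale superius: upper lip vermilion"),
        _mid("Li", "soft", "lower-third", m, "labrale inferius: lower lip vermilion"),
        _mid("Pogs", "soft", "lower-third", m, "soft-tissue pogonion"),
        _mid("Mes", "soft", "lower-third", m, "soft-tissue menton"),
    ]
    # 7 bone pairs
    defs += _pair("Fz", "bone", "upper-third", m, "frontozygomatic suture at orbital rim")
    defs += _pair("Or", "bone", "upper-third", m, "orbitale: lowest infraorbital rim point")
    defs += _pair("Po", "bone", "middle-third", m, "porion: highest external auditory meatus point")
    defs += _pair("Zy", "bone", "middle-third", m, "zygion: most lateral zygomatic arch point")
    defs += _pair("J", "bone", "middle-third", m, "jugale: jugal process concavity")
    defs += _pair("Cd", "bone", "lower-third", m, "condylion: most superior condylar point")
    defs += _pair("Go", "bone", "lower-third", m, "gonion: mandibular angle vertex")
    # 2 dental pairs
    defs += _pair("U6", "dental", "middle-third", m, "upper first molar cusp")
    defs += _pair("L6", "dental", "lower-third", m, "lower first molar cusp")
    # 1 soft pair
    defs += _pair("Ch", "soft", "lower-third", m, "cheilion: labial commissure")
    return defs


_CBCT_ORDER = ("N", "S", "ANS", "A", "B", "Pog", "Me", "Gn", "UI", "LI", "U6L", "U6R", "L6L", "L6R")


def _cbct_catalog(modality: str = "CBCT") -> list[LandmarkDef]:
    region = {
        "N": "upper-third", "S": "upper-third",
        "ANS": "middle-third", "A": "middle-third", "UI": "middle-third",
        "U6L": "middle-third", "U6R": "middle-third",
        "B": "lower-third", "Pog": "lower-third", "Me": "lower-third",
        "Gn": "lower-third", "LI": "lower-third", "L6L": "lower-third", "L6R": "lower-third",
    }
    tissue = {n: ("dental" if n in ("UI", "LI", "U6L", "U6R", "L6L", "L6R") else "bone") for n in _CBCT_ORDER}
    lat = {n: ("left" if n.endswith("L") and n not in ("N", "S", "ANS", "UI", "LI") else
               "right" if n.endswith("R") else "midline") for n in _CBCT_ORDER}
    sct = {d.name: d.definition for d in _sct_catalog()}
    return [LandmarkDef(n, tissue[n], lat[n], region[n], modality, sct.get(n, "")) for n in _CBCT_ORDER]


# Analytic phantom feature each landmark is bound to (see cephalo3d.phantom).
_PHANTOM_FEATURES = {
    "N": "anterior pole of the cranial ellipsoid shell",
    "S": "center of the intracranial sella sphere",
    "ANS": "tip of the anterior nasal spike on the maxillary arch",
    "A": "anterior maxillary surface point below ANS",
    "B": "anterior mandibular surface point above Pog",
    "Pog": "most anterior midline point of the chin boss",
    "Me": "most inferior midline point of the mandibular arch",
    "Gn": "midpoint of the Pog-Me arc on the chin boss",
    "UI": "tip of the midline upper incisor peg",
    "LI": "tip of the midline lower incisor peg",
    "U6L": "tip of the left upper molar peg",
    "U6R": "tip of the right upper molar peg",
    "L6L": "tip of the left lower molar peg",
    "L6R": "tip of the right lower molar peg",
}


def builtin_catalog(modality: str) -> list[LandmarkDef]:
    """Return the ordered built-in catalog for ``modality`` (``SCT``/``CBCT``).

    SCT: 41 landmarks (21 midline + 10 L/R pairs; 26 bone, 6 dental, 9 soft).
    CBCT: 14 landmarks (8 skeletal midline + 6 dental).
    """
    if modality == "SCT":
        return _sct_catalog()
    if modality == "CBCT":
        return _cbct_catalog()
    raise ValueError(f"unknown modality {modality!r}; expected 'SCT' or 'CBCT'")


def phantom_catalog() -> list[LandmarkDef]:
    """The 14-landmark catalog of the synthetic skull phantom.

    Mirrors the CBCT set; each entry is bound to exactly one analytic feature
    of the phantom geometry, so ground truth has sub-voxel precision.
    """
    defs = _cbct_catalog(modality="phantom")
    return [
        LandmarkDef(d.name, d.tissue, d.laterality, d.region, "phantom", _PHANTOM_FEATURES[d.name])
        for d in defs
    ]


def catalog_names(catalog: list[LandmarkDef]) -> list[str]:
    return [d.name for d in catalog]


def dental_names(catalog: list[LandmarkDef]) -> list[str]:
    return [d.name for d in catalog if d.tissue == "dental"]


def export_catalog(catalog: list[LandmarkDef], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([asdict(d) for d in catalog], indent=1))
    return path


def load_catalog(path: str | Path) -> list[LandmarkDef]:
    return [LandmarkDef(**d) for d in json.loads(Path(path).read_text())]
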