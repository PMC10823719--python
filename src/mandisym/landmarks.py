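"""Named anatomical landmarks of the mandible and midline-point derivation.

The vocabulary follows standard cephalometric abbreviations: five central
(midline) landmarks — B (supramentale), Pog (pogonion), Gn (gnathion),
Me (menton), G (genial tubercle) — and bilateral landmarks with left/right
slots — F (fossa of the mandibular foramen), MF (mental foramen), Go
(gonion), Cor (coronoid superius), Consup/Conmed/Conlat (condylion
superius/medialis/lateralis), Sig (sigmoid notch), RP (ramus point), Jlat,
Jmed.

Sides are the subject's anatomical sides; in the canonical (synthetic)
frame the left side has negative x.

The seven screening points are the five central landmarks plus the
midpoints of the bilateral F and MF pairs; every combination of three of
them spans one candidate midsagittal plane, giving C(7,3) = 35 candidates.
"""

from __future__ import annotations

import csv
import json
from itertools import combinations
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "CENTRAL_NAMES",
    "BILATERAL_NAMES",
    "ALIASES",
    "LandmarkSet",
    "MidlinePointSet",
    "MissingLandmarkError",
    "bilateral_midpoint",
    "midline_points",
    "enumerate_triplets",
    "read_landmarks",
    "write_landmarks",
]

CENTRAL_NAMES = ("B", "Pog", "Gn", "Me", "G")
BILATERAL_NAMES = (
    "F", "MF", "Go", "Cor", "Consup", "Conmed", "Conlat", "Sig", "RP",
    "Jlat", "Jmed",
)

#: long-form names accepted on input and mapped to canonical abbreviations
ALIASES = {
    "supramentale": "B",
    "pogonion": "Pog",
    "gnathion": "Gn",
    "menton": "Me",
    "genial tubercle": "G",
    "genial_tubercle": "G",
    "mandibular foramen": "F",
    "mandibular_foramen": "F",
    "fossa of mandibular foramen": "F",
    "mental foramen": "MF",
    "mental_foramen": "MF",
    "gonion": "Go",
    "coronoid superius": "Cor",
    "coronoid_superius": "Cor",
    "condylion superius": "Consup",
    "condylion_superius": "Consup",
    "condylion medialis": "Conmed",
    "condylion_medialis": "Conmed",
    "condylion lateralis": "Conlat",
    "condylion_lateralis": "Conlat",
    "sigmoid notch": "Sig",
    "sigmoid_notch": "Sig",
    "ramus point": "RP",
    "ramus_point": "RP",
}

_SIDES = {"L", "R", None}


class MissingLandmarkError(KeyError):
    """Raised when required landmarks are absent; lists every missing one."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing required landmarks: " + ", ".join(self.missing))

    def __str__(self) -> str:
        return "missing required landmarks: " + ", ".join(self.missing)


def _canonical(name: str) -> str:
    name = name.strip()
    return ALIASES.get(name.lower(), name)


class LandmarkSet:
    """Mapping from ``(name, side)`` to a 3D point in mm.

    ``side`` is ``'L'``/``'R'`` for bilateral landmarks and ``None`` for
    central ones.  Unknown names are preserved (and listed by
    :attr:`unknown_names`) so user files survive round-trips.
    """

    def __init__(self, points: Mapping | None = None):
        self._points: dict[tuple[str, str | None], np.ndarray] = {}
        if points:
            for key, value in points.items():
                if isinstance(key, tuple):
                    name, side = key
                else:
                    name, side = key, None
                self.add(name, value, side=side)

    def add(self, name: str, point, side: str | None = None):
        name = _canonical(name)
        if side not in _SIDES:
            raise ValueError(f"side must be 'L', 'R' or None, got {side!r}")
        p = np.asarray(point, dtype=float).reshape(3)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite coordinates for landmark {name}")
        key = (name, side)
        if key in self._points:
            label = name if side is None else f"{name} ({side})"
            raise ValueError(f"duplicate landmark {label}")
        self._points[key] = p

    def __contains__(self, key) -> bool:
        if isinstance(key, tuple):
            return key in self._points
        return (key, None) in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self) -> Iterator[tuple[str, str | None]]:
        return iter(self._points)

    def get(self, name: str, side: str | None = None) -> np.ndarray:
        key = (_canonical(name), side)
        if key not in self._points:
            label = name if side is None else f"{name} ({'left' if side == 'L' else 'right'})"
            raise MissingLandmarkError([label])
        return self._points[key].copy()

    def pair(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) points of a bilateral landmark."""
        return self.get(name, "L"), self.get(name, "R")

    def has_pair(self, name: str) -> bool:
        name = _canonical(name)
        return (name, "L") in self._points and (name, "R") in self._points

    @property
    def names(self) -> list[str]:
        return sorted({n for n, _ in self._points})

    @property
    def unknown_names(self) -> list[str]:
        known = set(CENTRAL_NAMES) | set(BILATERAL_NAMES)
        return sorted({n for n, _ in self._points if n not in known})

    def items(self):
        return self._points.items()

    def transformed(self, rotation, translation) -> "LandmarkSet":
        """Apply the rigid map ``x -> R x + t`` to every landmark."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = LandmarkSet()
        for (name, side), p in self._points.items():
            out.add(name, R @ p + t, side=side)
        return out

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(dict(self._points))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LandmarkSet({len(self)} points: {', '.join(self.names)})"


class MidlinePointSet:
    """The 7 screening points: B, Pog, Gn, Me, G and the F/MF midpoints.

    Point order is fixed so downstream triplet enumeration is reproducible.
    The F and MF entries are bilateral *midpoints*, named after their parent
    landmarks as in the candidate-plane labels (e.g. "B-Gn-F").
    """

    ORDER = ("B", "Pog", "Gn", "Me", "G", "F", "MF")

    def __init__(self, points: Mapping[str, np.ndarray]):
        missing = [n for n in self.ORDER if n not in points]
        if missing:
            raise MissingLandmarkError(missing)
        self._points = {n: np.asarray(points[n], dtype=float).reshape(3) for n in self.ORDER}

    def __getitem__(self, name: str) -> np.ndarray:
        return self._points[name].copy()

    def __len__(self) -> int:
        return 7

    @property
    def names(self) -> tuple[str, ...]:
        return self.ORDER

    def items(self):
        return self._points.items()


def bilateral_midpoint(left, right) -> np.ndarray:
    """Arithmetic midpoint of a bilateral landmark pair."""
    return (np.asarray(left, dtype=float) + np.asarray(right, dtype=float)) / 2.0


def midline_points(landmarks: LandmarkSet) -> MidlinePointSet:
    """Derive the 7 screening points from a landmark set.

    Requires the five central landmarks and both sides of F and MF; raises
    :class:`MissingLandmarkError` naming every absent landmark at once.
    """
    missing: list[str] = []
    pts: dict[str, np.ndarray] = {}
    for name in CENTRAL_NAMES:
        if (name, None) in landmarks:
            pts[name] = landmarks.get(name)
        else:
            missing.append(name)
    for name in ("F", "MF"):
        for side, label in (("L", "left"), ("R", "right")):
            if (name, side) not in landmarks:
                missing.append(f"{name} ({label})")
        if landmarks.has_pair(name):
            pts[name] = bilateral_midpoint(*landmarks.pair(name))
    if missing:
        raise MissingLandmarkError(missing)
    return MidlinePointSet(pts)


def enumerate_triplets(midline: MidlinePointSet) -> list[tuple[str, str, str]]:
    """All unordered triplets of midline point names, lexicographically sorted.

    For the full 7-point set this is the C(7,3) = 35 candidate planes.
    """
    names = sorted(midline.names)
    return list(combinations(names, 3))


# ---------------------------------------------------------------------------
# file formats: CSV (name,side,x,y,z) and JSON (name -> side -> [x,y,z])


def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV (``name,side,x,y,z``) or JSON.

    CSV sides are ``L``, ``R`` or ``-``; JSON maps each name to
    ``{side: [x, y, z]}`` with the same side codes.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        out = LandmarkSet()
        for name, sides in data.items():
            for side, xyz in sides.items():
                out.add(name, xyz, side=None if side == "-" else side)
        return out
    out = LandmarkSet()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:5]] != ["name", "side", "x", "y", "z"]:
            raise ValueError(f"{path}: expected header 'name,side,x,y,z'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            name, side = row[0], row[1].strip()
            side_key = None if side in ("-", "") else side
            try:
                xyz = [float(c) for c in row[2:5]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            try:
                out.add(name, xyz, side=side_key)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_landmarks(landmarks: LandmarkSet, path):
    """Write landmarks; format chosen by extension (.csv or .json)."""
    path = str(path)
    if path.endswith(".json"):
        data: dict[str, dict[str, list[float]]] = {}
        for (name, side), p in landmarks.items():
            data.setdefault(name, {})[side or "-"] = [float(v) for v in p]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "side", "x", "y", "z"])
        for (name, side), p in sorted(landmarks.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
            writer.writerow([name, side or "-", repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
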