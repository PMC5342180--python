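"""Landmark-based footprint morphometry.

A footprint is digitised as 25 named landmark points (01-25) plus two scale
points with a known real-world separation.  Fifteen further "derived" points
(26-40) are constructed deterministically from the landmarks, and 128
morphometric variables (lengths in mm, angles in degrees, areas in mm**2)
are measured over the resulting 40-point configuration.

Point layout convention (left-hind print, +y toward the toes):

* points 01-04, 05-08, 09-12, 13-16 — the four toes (toe 5, 4, 3, 2), each
  digitised as base / left edge / distal tip / right edge;
* points 17-25 — the heel pad: 17/18 anterior (leading) edge left/right,
  19/25 left/right extremes, 20-24 the posterior lobe boundary with 22 the
  central posterior point.

Derived-point constructions are a versioned convention of this package (see
``DERIVED_CONSTRUCTIONS``); they are internally consistent and equivariant
under similarity transforms, which is all downstream classification needs.

Right-side prints must be mirrored (``mirror_landmarks``) before feature
extraction; all shipped conventions assume a left-hind orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "LandmarkSet",
    "FeatureVector",
    "VariableCatalog",
    "DEFAULT_CATALOG",
    "CATALOG_VERSION",
    "N_LANDMARKS",
    "N_DERIVED",
    "calibrate",
    "derive_points",
    "extract_features",
    "mirror_landmarks",
    "check_scale_anisotropy",
]

N_LANDMARKS = 25
N_DERIVED = 15
CATALOG_VERSION = "1.0"

# --- variable definition tables -------------------------------------------

# lengths: variable number -> (point, point); 1-based point ids, 1-25
# landmarks, 26-40 derived.
_LENGTHS: dict[int, tuple[int, int]] = {
    1: (1, 3), 2: (5, 7), 3: (9, 11), 4: (13, 15),
    5: (2, 4), 6: (6, 8), 7: (10, 12), 8: (14, 16),
    9: (17, 18), 10: (19, 25), 11: (22, 24), 12: (20, 22),
    13: (21, 23), 14: (1, 22), 15: (5, 22), 16: (9, 22),
    17: (13, 22), 18: (22, 31), 19: (5, 31), 20: (22, 33),
    21: (9, 33), 22: (22, 32), 23: (32, 34), 24: (34, 35),
    25: (26, 35), 26: (1, 5), 27: (5, 9), 28: (9, 13),
    29: (13, 19), 30: (19, 20), 31: (24, 25), 32: (1, 25),
    33: (3, 7), 34: (7, 11), 35: (11, 15), 36: (15, 19),
    37: (3, 25), 38: (17, 27), 39: (17, 28), 40: (17, 29),
    41: (17, 30), 42: (18, 27), 43: (18, 28), 44: (18, 29),
    45: (18, 30), 46: (5, 25), 47: (9, 25), 48: (13, 25),
    49: (1, 19), 50: (5, 19), 51: (9, 19), 52: (1, 2),
    53: (2, 3), 54: (3, 4), 55: (1, 4), 56: (5, 6),
    57: (6, 7), 58: (7, 8), 59: (5, 8), 60: (9, 10),
    61: (10, 11), 62: (11, 12), 63: (9, 12), 64: (13, 14),
    65: (14, 15), 66: (15, 16), 67: (13, 16), 68: (17, 19),
    69: (18, 25), 70: (27, 28), 71: (28, 29), 72: (29, 30),
    73: (1, 31), 74: (31, 32), 75: (32, 33), 76: (13, 33),
    77: (2, 34), 78: (16, 34), 79: (3, 35), 80: (15, 35),
    97: (2, 37), 98: (2, 36), 99: (26, 36), 100: (11, 26),
    101: (11, 39), 102: (16, 39), 103: (16, 38), 104: (24, 38),
    105: (24, 37), 106: (18, 40), 107: (13, 24), 108: (9, 24),
    109: (5, 24), 110: (1, 24), 111: (1, 13), 112: (36, 37),
    113: (2, 16), 114: (3, 15), 115: (3, 24), 116: (7, 24),
    117: (11, 24), 118: (15, 24),
}

# intersection angles: variable number -> ((a, b), (c, d)) meaning the angle
# between direction vectors a->b and c->d, reported in [0, 180] degrees.
_INTERSECTION_ANGLES: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {
    81: ((1, 5), (9, 13)),
    82: ((3, 7), (11, 15)),
    83: ((5, 1), (24, 20)),
    84: ((9, 13), (20, 24)),
    85: ((3, 1), (1, 13)),
    86: ((7, 5), (1, 13)),
    87: ((11, 9), (1, 13)),
    88: ((15, 13), (13, 1)),
}

# vertex angles: variable number -> (a, b, c), the angle at vertex b.
_VERTEX_ANGLES: dict[int, tuple[int, int, int]] = {
    89: (1, 22, 5), 90: (5, 22, 9), 91: (9, 22, 13), 92: (2, 25, 19),
    93: (16, 19, 25), 94: (1, 24, 5), 95: (5, 24, 9), 96: (9, 24, 13),
}

# areas: variable number -> polygon vertex sequence, or "hull" for the
# convex hull of the whole 25-point configuration.
_AREAS: dict[int, Sequence[int] | str] = {
    119: "hull",                                    # whole print
    120: (1, 2, 3, 4),                              # toe 5
    121: (5, 6, 7, 8),                              # toe 4
    122: (9, 10, 11, 12),                           # toe 3
    123: (13, 14, 15, 16),                          # toe 2
    124: (17, 19, 20, 21, 22, 23, 24, 25, 18),      # pad
    125: (1, 5, 9, 13, 25, 24, 23, 22, 21, 20, 19),  # toe bases + pad
    126: (1, 13, 25, 24, 23, 22, 21, 20, 19),
    127: (1, 5, 9, 13, 25, 19),
    128: (1, 3, 7, 11, 15, 13),                     # outer toes to tips
}

# the 20 variables used by the stepwise sex discriminant preset
_SEX_VARS = frozenset(
    {1, 3, 9, 13, 23, 30, 38, 52, 59, 67, 73, 85, 88, 89, 93, 95, 101, 120, 121, 122}
)

# derived points 26-40: (kind, args).  Evaluated in order, so later
# constructions may reference earlier derived points.
DERIVED_CONSTRUCTIONS: dict[int, tuple[str, tuple]] = {
    26: ("midpoint", (17, 18)),          # pad leading-edge centre
    27: ("centroid", (1, 2, 3, 4)),      # toe-5 centre
    28: ("centroid", (5, 6, 7, 8)),      # toe-4 centre
    29: ("centroid", (9, 10, 11, 12)),   # toe-3 centre
    30: ("centroid", (13, 14, 15, 16)),  # toe-2 centre
    31: ("midpoint", (1, 5)),            # toe-base gap midpoints
    32: ("midpoint", (5, 9)),
    33: ("midpoint", (9, 13)),
    34: ("midpoint", (19, 25)),          # pad mid-width
    35: ("centroid", (1, 5, 9, 13)),     # toe-base centroid
    36: ("midpoint", (22, 26)),          # pad axis centre
    37: ("intersection", ((9, 11), (19, 25))),  # toe-3 axis x pad width axis
    38: ("midpoint", (16, 24)),
    39: ("midpoint", (11, 16)),
    40: ("projection", (18, (19, 25))),  # 18 dropped onto the pad width axis
}


@dataclass(frozen=True)
class LandmarkSet:
    """One footprint's digitised points.

    ``landmarks`` holds the 25 placed points; ``derived`` the 15 constructed
    points 26-40 once :func:`derive_points` has run.  Coordinates are pixels
    until :func:`calibrate` converts them to millimetres.
    """

    footprint_id: str
    trail_id: str
    landmarks: np.ndarray
    scale_points: np.ndarray
    scale_separation_mm: float | None = None
    derived: np.ndarray | None = None
    calibrated: bool = False
    animal_id: str | None = None
    sex: str = "unknown"
    age_years: float | None = None
    side: str = "LH"

    def __post_init__(self) -> None:
        lm = np.asarray(self.landmarks, dtype=float)
        sp = np.asarray(self.scale_points, dtype=float)
        if lm.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} landmark points, got array of shape {lm.shape}"
            )
        if sp.shape != (2, 2):
            raise ValueError(f"expected 2 scale points, got shape {sp.shape}")
        # NaN marks a missing point (reported at extraction); infinities are
        # always invalid.
        if np.any(np.isinf(lm)) or not np.all(np.isfinite(sp)):
            raise ValueError("landmark/scale coordinates must be finite")
        object.__setattr__(self, "landmarks", lm)
        object.__setattr__(self, "scale_points", sp)
        if self.derived is not None:
            dv = np.asarray(self.derived, dtype=float)
            if dv.shape != (N_DERIVED, 2):
                raise ValueError(f"expected {N_DERIVED} derived points, got {dv.shape}")
            object.__setattr__(self, "derived", dv)

    def point(self, index: int) -> np.ndarray:
        """Return point ``index`` (1-based; 1-25 landmarks, 26-40 derived)."""
        if 1 <= index <= N_LANDMARKS:
            return self.landmarks[index - 1]
        if N_LANDMARKS < index <= N_LANDMARKS + N_DERIVED:
            if self.derived is None:
                raise ValueError(f"derived point {index:02d} requested before derive_points")
            return self.derived[index - N_LANDMARKS - 1]
        raise IndexError(f"point index {index} out of range 1-40")

    @property
    def all_points(self) -> np.ndarray:
        if self.derived is None:
            return self.landmarks
        return np.vstack([self.landmarks, self.derived])


@dataclass
class FeatureVector:
    """Metadata plus the 128 measured variables of one footprint."""

    footprint_id: str
    trail_id: str
    values: dict[str, float]
    animal_id: str | None = None
    sex: str = "unknown"
    age_years: float | None = None
    side: str = "LH"

    def __post_init__(self) -> None:
        if len(self.values) != 128:
            raise ValueError(f"expected 128 variables, got {len(self.values)}")

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "footprint_id": self.footprint_id,
            "trail_id": self.trail_id,
            "animal_id": self.animal_id,
            "sex": self.sex,
            "age_years": self.age_years,
            "side": self.side,
        }
        row.update(self.values)
        return row


class VariableCatalog:
    """Definitions of the measured variables V1..V128.

    Each entry records the variable kind and the point indices defining it;
    ``sex_preset`` lists the 20 variables flagged for sex discrimination.
    A catalog restricted to a subset of variables can be built with
    :meth:`subset`.
    """

    def __init__(
        self,
        lengths: Mapping[int, tuple[int, int]] | None = None,
        intersection_angles: Mapping[int, tuple[tuple[int, int], tuple[int, int]]] | None = None,
        vertex_angles: Mapping[int, tuple[int, int, int]] | None = None,
        areas: Mapping[int, Sequence[int] | str] | None = None,
        sex_flags: frozenset[int] = _SEX_VARS,
        version: str = CATALOG_VERSION,
    ) -> None:
        self.lengths = dict(_LENGTHS if lengths is None else lengths)
        self.intersection_angles = dict(
            _INTERSECTION_ANGLES if intersection_angles is None else intersection_angles
        )
        self.vertex_angles = dict(_VERTEX_ANGLES if vertex_angles is None else vertex_angles)
        self.areas = dict(_AREAS if areas is None else areas)
        self.sex_flags = frozenset(sex_flags)
        self.version = version

    @property
    def variable_numbers(self) -> list[int]:
        nums = sorted(
            list(self.lengths)
            + list(self.intersection_angles)
            + list(self.vertex_angles)
            + list(self.areas)
        )
        return nums

    @property
    def variable_names(self) -> list[str]:
        return [f"V{n}" for n in self.variable_numbers]

    @property
    def sex_preset(self) -> list[str]:
        return [f"V{n}" for n in sorted(self.sex_flags)]

    def kind(self, num: int) -> str:
        if num in self.lengths:
            return "length"
        if num in self.intersection_angles:
            return "angle-of-intersection"
        if num in self.vertex_angles:
            return "angle-at-vertex"
        if num in self.areas:
            return "area"
        raise KeyError(f"V{num} not in catalog")

    def points_used(self, num: int) -> frozenset[int]:
        """All point indices referenced by variable ``num``."""
        if num in self.lengths:
            return frozenset(self.lengths[num])
        if num in self.intersection_angles:
            (a, b), (c, d) = self.intersection_angles[num]
            return frozenset((a, b, c, d))
        if num in self.vertex_angles:
            return frozenset(self.vertex_angles[num])
        if num in self.areas:
            poly = self.areas[num]
            if poly == "hull":
                return frozenset(range(1, N_LANDMARKS + 1))
            return frozenset(poly)
        raise KeyError(f"V{num} not in catalog")

    def subset(self, numbers: Iterable[int]) -> "VariableCatalog":
        keep = set(numbers)
        return VariableCatalog(
            lengths={k: v for k, v in self.lengths.items() if k in keep},
            intersection_angles={
                k: v for k, v in self.intersection_angles.items() if k in keep
            },
            vertex_angles={k: v for k, v in self.vertex_angles.items() if k in keep},
            areas={k: v for k, v in self.areas.items() if k in keep},
            sex_flags=self.sex_flags & keep,
            version=self.version + "-subset",
        )


DEFAULT_CATALOG = VariableCatalog()


# --- geometry helpers ------------------------------------------------------

def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length vector in angle computation")
    c = float(np.dot(u, v)) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _shoelace(poly: np.ndarray) -> float:
    x = poly[:, 0]
    y = poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _line_intersection(p1, p2, p3, p4) -> np.ndarray:
    """Intersection of the infinite lines p1-p2 and p3-p4."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    scale = max(np.linalg.norm(d1) * np.linalg.norm(d2), 1e-300)
    if abs(denom) < 1e-12 * scale:
        raise ValueError("lines are parallel")
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
    return p1 + t * d1


def _project_on_line(p, a, b) -> np.ndarray:
    d = b - a
    nn = float(np.dot(d, d))
    if nn == 0.0:
        raise ValueError("degenerate projection line")
    t = float(np.dot(p - a, d)) / nn
    return a + t * d


# --- operations ------------------------------------------------------------

def check_scale_anisotropy(sep_x_mm_per_px: float, sep_y_mm_per_px: float,
                           tolerance: float = 0.02) -> None:
    """Warn if two axis calibration factors disagree by more than 2%."""
    ref = 0.5 * (sep_x_mm_per_px + sep_y_mm_per_px)
    if ref <= 0:
        raise ValueError("calibration factors must be positive")
    if abs(sep_x_mm_per_px - sep_y_mm_per_px) / ref > tolerance:
        warnings.warn(
            "X/Y scale factors disagree by more than "
            f"{tolerance:.0%}: {sep_x_mm_per_px:g} vs {sep_y_mm_per_px:g}",
            stacklevel=2,
        )


def calibrate(landmarks: LandmarkSet, known_separation_mm: float) -> LandmarkSet:
    """Convert a pixel-space landmark set to millimetres.

    The factor is ``known_separation_mm`` divided by the pixel distance
    between the two scale points; every stored point is multiplied by it.
    """
    if known_separation_mm <= 0:
        raise ValueError("known_separation_mm must be positive")
    px = float(np.linalg.norm(landmarks.scale_points[1] - landmarks.scale_points[0]))
    if px == 0.0:
        raise ValueError("degenerate scale: coincident scale points")
    factor = known_separation_mm / px
    return replace(
        landmarks,
        landmarks=landmarks.landmarks * factor,
        scale_points=landmarks.scale_points * factor,
        derived=None if landmarks.derived is None else landmarks.derived * factor,
        scale_separation_mm=known_separation_mm,
        calibrated=True,
    )


def derive_points(landmarks: LandmarkSet) -> LandmarkSet:
    """Construct derived points 26-40 from the 25 calibrated landmarks."""
    if not landmarks.calibrated:
        raise ValueError("derive_points requires a calibrated LandmarkSet")
    pts: dict[int, np.ndarray] = {i + 1: landmarks.landmarks[i] for i in range(N_LANDMARKS)}
    for num in sorted(DERIVED_CONSTRUCTIONS):
        kind, args = DERIVED_CONSTRUCTIONS[num]
        try:
            if kind == "midpoint":
                a, b = args
                pts[num] = 0.5 * (pts[a] + pts[b])
            elif kind == "centroid":
                pts[num] = np.mean([pts[a] for a in args], axis=0)
            elif kind == "intersection":
                (a, b), (c, d) = args
                pts[num] = _line_intersection(pts[a], pts[b], pts[c], pts[d])
            elif kind == "projection":
                p, (a, b) = args
                pts[num] = _project_on_line(pts[p], pts[a], pts[b])
            else:  # pragma: no cover
                raise ValueError(f"unknown construction kind {kind!r}")
        except ValueError as exc:
            raise ValueError(f"derived point {num:02d}: {exc}") from exc
    derived = np.array([pts[n] for n in range(N_LANDMARKS + 1, N_LANDMARKS + N_DERIVED + 1)])
    return replace(landmarks, derived=derived)


def mirror_landmarks(landmarks: LandmarkSet) -> LandmarkSet:
    """Mirror a right-side print about the y axis so it reads as left-side."""
    flip = np.array([-1.0, 1.0])
    new_side = {"RH": "LH", "RF": "LF"}.get(landmarks.side, "LH")
    return replace(
        landmarks,
        landmarks=landmarks.landmarks * flip,
        scale_points=landmarks.scale_points * flip,
        derived=None if landmarks.derived is None else landmarks.derived * flip,
        side=new_side,
    )


def extract_features(
    landmarks: LandmarkSet, catalog: VariableCatalog = DEFAULT_CATALOG
) -> FeatureVector:
    """Measure the catalog variables over a calibrated, derived landmark set."""
    if not landmarks.calibrated:
        raise ValueError("extract_features requires a calibrated LandmarkSet")
    if landmarks.derived is None:
        raise ValueError("extract_features requires derived points (run derive_points)")
    if landmarks.side.startswith("R"):
        raise ValueError(
            "right-side print: mirror with mirror_landmarks() before extraction"
        )

    pts = landmarks.all_points
    bad = ~np.all(np.isfinite(pts), axis=1)
    if np.any(bad):
        bad_ids = {int(i) + 1 for i in np.flatnonzero(bad)}
        affected = sorted(
            n for n in catalog.variable_numbers if catalog.points_used(n) & bad_ids
        )
        raise ValueError(
            "non-finite points "
            + ", ".join(f"{i:02d}" for i in sorted(bad_ids))
            + " affect variables "
            + ", ".join(f"V{n}" for n in affected)
        )

    def p(i: int) -> np.ndarray:
        return pts[i - 1]

    values: dict[str, float] = {}
    for num in catalog.variable_numbers:
        if num in catalog.lengths:
            a, b = catalog.lengths[num]
            values[f"V{num}"] = float(np.linalg.norm(p(a) - p(b)))
        elif num in catalog.intersection_angles:
            (a, b), (c, d) = catalog.intersection_angles[num]
            values[f"V{num}"] = _angle_between(p(b) - p(a), p(d) - p(c))
        elif num in catalog.vertex_angles:
            a, b, c = catalog.vertex_angles[num]
            values[f"V{num}"] = _angle_between(p(a) - p(b), p(c) - p(b))
        else:
            poly = catalog.areas[num]
            if poly == "hull":
                values[f"V{num}"] = float(ConvexHull(landmarks.landmarks).volume)
            else:
                values[f"V{num}"] = _shoelace(np.array([p(i) for i in poly]))

    if len(catalog.variable_numbers) == 128:
        fv = FeatureVector(
            footprint_id=landmarks.footprint_id,
            trail_id=landmarks.trail_id,
            values=values,
            animal_id=landmarks.animal_id,
            sex=landmarks.sex,
            age_years=landmarks.age_years,
            side=landmarks.side,
        )
        return fv
    # subset catalogs bypass the 128-variable invariant
    fv = FeatureVector.__new__(FeatureVector)
    fv.footprint_id = landmarks.footprint_id
    fv.trail_id = landmarks.trail_id
    fv.values = values
    fv.animal_id = landmarks.animal_id
    fv.sex = landmarks.sex
    fv.age_years = landmarks.age_years
    fv.side = landmarks.side
    return fv
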