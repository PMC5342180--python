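"""Synthetic footprint populations with a hierarchical variance structure.

Each individual carries a persistent landmark-level offset from a fixed
left-hind template (its "signature"); each footprint adds independent
isotropic noise on top.  Sexual dimorphism enters as a multiplicative size
factor plus a fixed shape-displacement field for males.  Per coordinate:

    x = s_sex * (T + d_i) + shape_shift * u_sex + e_f

with T the template, d_i ~ N(0, sigma_individual^2) per individual,
e_f ~ N(0, sigma_noise^2) per footprint, s_sex = male_scale for males else 1,
and u a fixed unit displacement field applied to males only.

Everything is driven by a single integer seed, so populations are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import (
    DEFAULT_CATALOG,
    LandmarkSet,
    VariableCatalog,
    derive_points,
    extract_features,
)

__all__ = [
    "PopulationSpec",
    "TEMPLATE",
    "generate_population",
    "split_trail",
    "study_metadata_table",
]

# Fixed 25-point left-hind template (mm): four toes of four points each
# (base/left/tip/right; toe 3 longest) over a nine-point trapezoidal pad.
TEMPLATE = np.array(
    [
        # toe 5 (outer): points 01-04
        (-32.0, 28.0), (-38.0, 38.0), (-33.0, 47.0), (-26.0, 37.0),
        # toe 4: points 05-08
        (-12.0, 36.0), (-18.0, 47.0), (-12.0, 57.0), (-5.0, 46.0),
        # toe 3 (longest): points 09-12
        (8.0, 38.0), (3.0, 50.0), (9.0, 62.0), (15.0, 49.0),
        # toe 2 (inner): points 13-16
        (27.0, 30.0), (22.0, 41.0), (28.0, 51.0), (34.0, 40.0),
        # pad: 17/18 leading edge, 19/25 sides, 20-24 posterior lobes
        (-15.0, 22.0), (15.0, 22.0), (-25.0, 0.0), (-18.0, -20.0),
        (-8.0, -16.0), (0.0, -22.0), (8.0, -16.0), (18.0, -20.0),
        (25.0, 0.0),
    ]
)

# Fixed male shape-displacement field (unit RMS per coordinate), spreading
# the toes and widening the pad; purely a simulation convention.
_rng_shape = np.random.default_rng(20170308)
_MALE_SHAPE = _rng_shape.standard_normal((25, 2))
_MALE_SHAPE /= np.sqrt(np.mean(_MALE_SHAPE**2))
del _rng_shape


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a simulated footprint population."""

    n_individuals: int = 10
    sex_ratio: float = 0.5          # fraction of females
    trails_per_individual: tuple[int, int] = (2, 3)
    prints_per_trail: tuple[int, int] = (4, 6)
    sigma_individual: float = 2.0   # mm, landmark s.d. of individual offsets
    sigma_noise: float = 0.5        # mm, per-footprint landmark noise
    male_scale: float = 1.08        # multiplicative size dimorphism
    shape_shift: float = 0.5        # mm, male shape displacement magnitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.sigma_individual < 0 or self.sigma_noise < 0:
            raise ValueError("sigma parameters must be non-negative")
        lo, hi = self.trails_per_individual
        if not (1 <= lo <= hi):
            raise ValueError("invalid trails_per_individual range")
        lo, hi = self.prints_per_trail
        if not (1 <= lo <= hi):
            raise ValueError("invalid prints_per_trail range")


def _randint_incl(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def generate_population(
    spec: PopulationSpec,
    catalog: VariableCatalog = DEFAULT_CATALOG,
    n_sex_counts: tuple[int, int] | None = None,
) -> tuple[list[LandmarkSet], pd.DataFrame]:
    """Simulate a population; return landmark sets and the measurement table.

    ``n_sex_counts`` optionally pins exact (n_female, n_male) counts instead
    of drawing them from ``sex_ratio``.
    """
    rng = np.random.default_rng(spec.seed)

    if n_sex_counts is not None:
        n_f, n_m = n_sex_counts
        if n_f + n_m != spec.n_individuals:
            raise ValueError("n_sex_counts must sum to n_individuals")
        sexes = ["F"] * n_f + ["M"] * n_m
    else:
        sexes = ["F" if rng.random() < spec.sex_ratio else "M"
                 for _ in range(spec.n_individuals)]

    landmark_sets: list[LandmarkSet] = []
    rows: list[dict] = []
    for i in range(spec.n_individuals):
        animal_id = f"A{i + 1:02d}"
        sex = sexes[i]
        offset = rng.standard_normal((25, 2)) * spec.sigma_individual
        base = TEMPLATE + offset
        if sex == "M":
            base = spec.male_scale * base + spec.shape_shift * _MALE_SHAPE
        age = float(np.round(rng.uniform(1.0, 20.0), 1))
        n_trails = _randint_incl(rng, *spec.trails_per_individual)
        fp_counter = 0
        for t in range(n_trails):
            trail_id = f"{animal_id}-T{t + 1}"
            n_prints = _randint_incl(rng, *spec.prints_per_trail)
            for _ in range(n_prints):
                fp_counter += 1
                coords = base + rng.standard_normal((25, 2)) * spec.sigma_noise
                ls = LandmarkSet(
                    footprint_id=f"{trail_id}-F{fp_counter:03d}",
                    trail_id=trail_id,
                    landmarks=coords,
                    scale_points=np.array([(0.0, 0.0), (10.0, 0.0)]),
                    scale_separation_mm=10.0,
                    calibrated=True,
                    animal_id=animal_id,
                    sex=sex,
                    age_years=age,
                )
                ls = derive_points(ls)
                landmark_sets.append(ls)
                fv = extract_features(ls, catalog)
                row = fv.as_row()
                row["site"] = "synthetic"
                rows.append(row)

    table = pd.DataFrame(rows)
    meta = ["footprint_id", "trail_id", "animal_id", "sex", "age_years", "site", "side"]
    vcols = [c for c in table.columns if c.startswith("V")]
    return landmark_sets, table[meta + vcols]


def study_metadata_table() -> pd.DataFrame:
    """A metadata-only footprint table with the reference study's totals.

    35 individuals (19 F, 16 M), 535 footprints (300 F, 235 M) and 79
    trails (45 F, 34 M), distributed as evenly as the totals allow.  Used
    to recompute the published per-individual summary means from the
    printed counts alone.
    """
    rows: list[dict] = []

    def build(n_animals: int, n_prints: int, n_trails: int, sex: str) -> None:
        prints = np.full(n_animals, n_prints // n_animals)
        prints[: n_prints % n_animals] += 1
        trails = np.full(n_animals, n_trails // n_animals)
        trails[: n_trails % n_animals] += 1
        for a in range(n_animals):
            animal = f"{sex}{a + 1:02d}"
            per_trail = np.full(trails[a], prints[a] // trails[a])
            per_trail[: prints[a] % trails[a]] += 1
            fp = 0
            for t, k in enumerate(per_trail):
                for _ in range(int(k)):
                    fp += 1
                    rows.append(
                        {
                            "footprint_id": f"{animal}-T{t + 1}-F{fp:03d}",
                            "trail_id": f"{animal}-T{t + 1}",
                            "animal_id": animal,
                            "sex": sex,
                        }
                    )

    build(19, 300, 45, "F")
    build(16, 235, 34, "M")
    return pd.DataFrame(rows)


def split_trail(
    table: pd.DataFrame, trail_id: str, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly split one trail's footprints into two disjoint pseudo-trails.

    Each half receives a suffixed trail id and has at least two footprints.
    """
    rows = table[table["trail_id"] == trail_id]
    n = len(rows)
    if n < 4:
        raise ValueError(f"trail {trail_id!r} has {n} footprints; need >= 4 to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    half = n // 2
    a = rows.iloc[np.sort(order[:half])].copy()
    b = rows.iloc[np.sort(order[half:])].copy()
    a["trail_id"] = f"{trail_id}#a"
    b["trail_id"] = f"{trail_id}#b"
    return a, b
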