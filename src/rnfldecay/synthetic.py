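"""Seeded synthetic cohorts of normal and glaucomatous RNFL profiles.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without clinical data:

* a TSNIT *double-hump* mean curve — thickness peaks in the superior
  (~80 deg) and inferior (~280 deg) sectors where the arcuate nerve
  fiber bundles cross the calculation circle, and troughs temporally
  and nasally;
* additive group effects for the 3 age bands (thinning with age) and
  3 disc-size classes;
* a per-eye random offset (between-eye variability) plus smooth
  angular noise (circular moving average of white noise), truncated at
  the 30 μm measurement floor;
* for glaucomatous eyes, focal wedge defects: the profile is
  multiplied by ``1 - depth * wedge(theta)`` where the wedge is a von
  Mises-shaped bump whose ``width`` parameter is its full width at
  half maximum.  Defect directions cluster superiorly/inferiorly,
  mirroring where glaucomatous decay concentrates.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .grid import DEFAULT_N_POINTS, AngularGrid
from .profiles import RNFLProfile

FLOOR_UM = 30.0

#: Additive thickness offsets (μm) per age band: mild diffuse thinning
#: of a few microns per decade, as seen in normative OCT cohorts.
AGE_EFFECTS = {"Age1": 0.0, "Age2": -2.5, "Age3": -5.0}
#: Larger discs carry slightly thicker peripapillary RNFL.
DISC_EFFECTS = {"Small": -2.0, "Average": 0.0, "Large": 2.0}


@dataclass(frozen=True)
class DefectSpec:
    """A focal wedge defect cluster.

    ``direction`` is the cluster's central defect direction (degrees);
    each eye's realized defect direction is drawn from a von Mises
    distribution around it with concentration ``direction_kappa``
    (kappa ~ 12 gives the ~15-17 degree between-eye scatter that the
    concentrated mixture components of clinical cohorts show).
    ``width`` is the wedge full width at half maximum; ``depth`` the
    fraction of local thickness removed at the wedge center.
    """

    direction: float
    width: float = 40.0
    depth: float = 0.5
    direction_kappa: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.direction_kappa < 0:
            raise ValueError("direction_kappa must be non-negative")

    def wedge(self, theta_deg: np.ndarray, direction: float | None = None) -> np.ndarray:
        """von Mises-shaped bump in [0, 1], value 1 at the defect center."""
        center = self.direction if direction is None else direction
        half = np.deg2rad(self.width / 2.0)
        kappa = np.log(2.0) / (1.0 - np.cos(half))  # FWHM = width
        d = np.deg2rad(theta_deg - center)
        return np.exp(kappa * (np.cos(d) - 1.0))

    def sample_direction(self, rng: np.random.Generator) -> float:
        """Draw one eye's realized defect direction (degrees)."""
        if np.isinf(self.direction_kappa):
            return float(self.direction % 360.0)
        if self.direction_kappa == 0:
            return float(rng.uniform(0.0, 360.0))
        draw = rng.vonmises(np.deg2rad(self.direction), self.direction_kappa)
        return float(np.rad2deg(draw) % 360.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator (all μm / degrees)."""

    n_points: int = DEFAULT_N_POINTS
    baseline: float = 60.0
    hump_amplitudes: tuple[float, float] = (55.0, 62.0)  # superior, inferior
    hump_centers: tuple[float, float] = (80.0, 280.0)
    hump_concentration: float = 2.2
    age_effects: dict = field(default_factory=lambda: dict(AGE_EFFECTS))
    disc_effects: dict = field(default_factory=lambda: dict(DISC_EFFECTS))
    eye_sd: float = 8.0
    point_sd: float = 6.0
    noise_correlation_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eye_sd < 0 or self.point_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not all(0 <= c < 360 for c in self.hump_centers):
            raise ValueError("hump centers must lie in [0, 360)")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


#: Defect clusters used for glaucomatous eyes when none are supplied:
#: superior (~100 deg) and inferior (~290 deg) focal loss.
DEFAULT_DEFECTS = (DefectSpec(direction=100.0), DefectSpec(direction=290.0))


def mean_curve(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free double-hump TSNIT mean thickness curve (μm)."""
    grid = AngularGrid(spec.n_points)
    theta = np.deg2rad(grid.theta)
    curve = np.full(spec.n_points, spec.baseline, dtype=float)
    for amp, center in zip(spec.hump_amplitudes, spec.hump_centers):
        curve += amp * np.exp(
            spec.hump_concentration * (np.cos(theta - np.deg2rad(center)) - 1.0)
        )
    if np.any(curve <= 0):
        raise ValueError("spec yields non-positive mean thickness")
    return curve


def _smooth_circular_noise(rng: np.random.Generator, shape, corr_len: int) -> np.ndarray:
    """Unit-variance noise, smoothed by a circular moving average."""
    white = rng.standard_normal(shape)
    if corr_len <= 1:
        return white
    window = 2 * (corr_len // 2) + 1  # odd window centered on the point
    kernel = np.ones(window) / np.sqrt(window)  # preserves the variance
    out = np.empty_like(white)
    for i in range(white.shape[0]):
        padded = np.concatenate([white[i, -window:], white[i], white[i, :window]])
        smoothed = np.convolve(padded, kernel, mode="same")
        out[i] = smoothed[window:-window]
    return out


def _sample_metadata(
    rng: np.random.Generator, n_eyes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ages uniform over 40-75; disc areas log-normal around 2.1 mm²."""
    ages = rng.integers(40, 76, size=n_eyes)
    disc = np.exp(rng.normal(np.log(2.1), 0.22, size=n_eyes))
    return ages, np.clip(disc, 0.8, 4.8)


def _group_offset(spec: SyntheticSpec, age: int, disc_area: float) -> float:
    from .profiles import assign_group

    g = assign_group(age, disc_area)
    return spec.age_effects[g.age_band] + spec.disc_effects[g.disc_class]


def generate_normal(
    spec: SyntheticSpec,
    n_eyes: int,
    rng: np.random.Generator | None = None,
    id_prefix: str = "N",
) -> list[RNFLProfile]:
    """Generate normal eyes: mean curve + group effect + noise."""
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    base = mean_curve(spec)
    ages, discs = _sample_metadata(rng, n_eyes)
    eye_offsets = rng.normal(0.0, spec.eye_sd, size=n_eyes)
    noise = spec.point_sd * _smooth_circular_noise(
        rng, (n_eyes, spec.n_points), spec.noise_correlation_length
    )
    profiles = []
    for i in range(n_eyes):
        values = base + _group_offset(spec, int(ages[i]), float(discs[i]))
        values = np.maximum(values + eye_offsets[i] + noise[i], FLOOR_UM)
        profiles.append(
            RNFLProfile(
                eye_id=f"{id_prefix}{i + 1:05d}",
                values=values,
                age=int(ages[i]),
                disc_area=float(discs[i]),
                status="normal",
            )
        )
    return profiles


def generate_glaucoma(
    spec: SyntheticSpec,
    defects: Sequence[DefectSpec] = DEFAULT_DEFECTS,
    cluster_proportions: Sequence[float] | None = None,
    n_eyes: int = 100,
    rng: np.random.Generator | None = None,
    id_prefix: str = "G",
) -> tuple[list[RNFLProfile], pd.DataFrame]:
    """Generate glaucomatous eyes with cluster-specific wedge defects.

    Each eye starts as a normal profile and is multiplied by
    ``1 - depth * wedge`` for the defect of its assigned cluster.
    Returns the profiles and a ground-truth frame (eye_id, cluster,
    defect_direction).
    """
    defects = list(defects)
    if cluster_proportions is None:
        cluster_proportions = [1.0 / len(defects)] * len(defects)
    props = np.asarray(cluster_proportions, dtype=float)
    if props.size != len(defects) or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
        raise ValueError("cluster proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    healthy = generate_normal(spec, n_eyes, rng=rng, id_prefix=id_prefix)
    grid = AngularGrid(spec.n_points)
    clusters = rng.choice(len(defects), size=n_eyes, p=props)
    truth = []
    out = []
    for i, p in enumerate(healthy):
        defect = defects[clusters[i]]
        direction = defect.sample_direction(rng)
        values = np.maximum(
            p.values * (1.0 - defect.depth * defect.wedge(grid.theta, direction)), 0.0
        )
        out.append(
            RNFLProfile(
                eye_id=p.eye_id, values=values, age=p.age,
                disc_area=p.disc_area, status="glaucoma",
            )
        )
        truth.append(
            {
                "eye_id": p.eye_id,
                "cluster": int(clusters[i]),
                "defect_direction": defect.direction,
                "realized_direction": round(direction, 2),
            }
        )
    return out, pd.DataFrame(truth).set_index("eye_id")


def generate_cohort(
    n_normal: int,
    n_glaucoma: int,
    spec: SyntheticSpec | None = None,
    defects: Sequence[DefectSpec] = DEFAULT_DEFECTS,
    cluster_proportions: Sequence[float] | None = None,
    seed: int | None = None,
) -> tuple[list[RNFLProfile], pd.DataFrame]:
    """Full seeded cohort: normal + glaucomatous profiles, plus truth."""
    spec = SyntheticSpec() if spec is None else spec
    if seed is not None:
        spec = spec.with_seed(seed)
    rng = np.random.default_rng(spec.seed)
    normals = generate_normal(spec, n_normal, rng=rng)
    glaucoma, truth = generate_glaucoma(
        spec, defects, cluster_proportions, n_glaucoma, rng=rng
    )
    return normals + glaucoma, truth


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load generator parameters from a YAML/flat key-value file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("hump_amplitudes", "hump_centers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticSpec(**raw)
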