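"""Reading, validating and stratifying circumpapillary RNFL profiles.

A profile is one eye's circular sequence of RNFL thickness values (μm)
sampled at equally spaced angular points in TSNIT order, together with
the metadata used for normative stratification: age (years), optic disc
area (mm²) and disease status.

The cohort is stratified into 3 age bands x 3 disc-size classes:

===========  =======================
Age1         40-49 years
Age2         50-59 years
Age3         >= 60 years
Small        disc area < 1.6 mm²
Average      1.6-2.6 mm² (inclusive)
Large        > 2.6 mm²
===========  =======================

Profiles with any thickness below the 30 μm segmentation floor are kept
but flagged ``excluded`` so callers can report exclusion counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import DEFAULT_N_POINTS

MIN_VALID_THICKNESS_UM = 30.0
MIN_COHORT_AGE = 40

AGE_BANDS = ("Age1", "Age2", "Age3")
DISC_CLASSES = ("Small", "Average", "Large")
STATUSES = ("normal", "glaucoma")


class MalformedProfileError(ValueError):
    """A data row does not match the expected circular layout."""


class OutOfCohortError(ValueError):
    """Metadata violates the cohort inclusion criteria (age >= 40)."""


@dataclass(frozen=True)
class GroupLabel:
    """One of the 9 age-band x disc-size normative strata."""

    age_band: str
    disc_class: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.disc_class not in DISC_CLASSES:
            raise ValueError(f"unknown disc class {self.disc_class!r}")

    def __str__(self) -> str:  # used as a CSV key
        return f"{self.age_band}-{self.disc_class}"

    @classmethod
    def parse(cls, text: str) -> "GroupLabel":
        age_band, _, disc_class = text.partition("-")
        return cls(age_band, disc_class)


def all_groups() -> list[GroupLabel]:
    """The 9 possible strata, in (age band, disc class) order."""
    return [GroupLabel(a, d) for a in AGE_BANDS for d in DISC_CLASSES]


def assign_group(age: float, disc_area: float) -> GroupLabel:
    """Assign the normative stratum for an eye.

    Boundary conventions: disc areas of exactly 1.6 or 2.6 mm² are
    Average; ages 50 and 60 fall in the older band.

    Raises
    ------
    OutOfCohortError
        If ``age`` is below the cohort inclusion minimum of 40 years.
    """
    if age < MIN_COHORT_AGE:
        raise OutOfCohortError(f"age {age} is below the cohort minimum of 40 years")
    if disc_area <= 0:
        raise ValueError("disc_area must be positive")
    if age >= 60:
        band = "Age3"
    elif age >= 50:
        band = "Age2"
    else:
        band = "Age1"
    if disc_area < 1.6:
        disc = "Small"
    elif disc_area <= 2.6:
        disc = "Average"
    else:
        disc = "Large"
    return GroupLabel(band, disc)


@dataclass
class RNFLProfile:
    """One eye's circular RNFL thickness sequence plus metadata."""

    eye_id: str
    values: np.ndarray
    age: int | None = None
    disc_area: float | None = None
    status: str | None = None
    excluded: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise MalformedProfileError("values must be a non-empty 1-D sequence")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise MalformedProfileError(
                f"profile {self.eye_id!r} has negative or non-finite thickness"
            )
        if self.status is not None and self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        # 30 μm is the structural measurement floor of circumpapillary
        # SD-OCT; anything thinner is a segmentation failure.
        self.excluded = bool(np.any(self.values < MIN_VALID_THICKNESS_UM))

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def group(self) -> GroupLabel:
        if self.age is None or self.disc_area is None:
            raise ValueError(f"profile {self.eye_id!r} has no age/disc metadata")
        return assign_group(self.age, self.disc_area)


def _looks_like_header(cells: Sequence[str]) -> bool:
    non_numeric = 0
    for c in cells:
        try:
            float(c)
        except ValueError:
            non_numeric += 1
    return non_numeric > 1 or (non_numeric == 1 and len(cells) > 1 and not _is_number(cells[1]))


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_profiles(
    path: str | Path,
    metadata: str | Path | None = None,
    n_points: int = DEFAULT_N_POINTS,
) -> list[RNFLProfile]:
    """Read profiles from a CSV of one eye per row.

    The layout matches the deposited high-resolution tables: each row is
    an anonymized eye, each column an angular point in TSNIT order.  An
    optional header row and an optional leading eye-id column are
    auto-detected.  When ``metadata`` is given (CSV with columns
    ``eye_id, age, disc_area, status``) it is joined on eye id.

    Raises
    ------
    MalformedProfileError
        If a row does not have exactly ``n_points`` numeric fields
        (plus the optional id), with the offending row named.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise MalformedProfileError(f"{path} is empty")
    if _looks_like_header(rows[0]):
        rows = rows[1:]
    if not rows:
        raise MalformedProfileError(f"{path} has a header but no data rows")

    has_id = len(rows[0]) == n_points + 1
    profiles: list[RNFLProfile] = []
    for i, row in enumerate(rows):
        eye_id = row[0] if has_id else f"eye{i + 1:05d}"
        cells = row[1:] if has_id else row
        if len(cells) != n_points:
            raise MalformedProfileError(
                f"row {i + 1} of {path.name} has {len(cells)} value columns, "
                f"expected {n_points}"
            )
        try:
            values = np.array([float(c) for c in cells])
        except ValueError as exc:
            raise MalformedProfileError(
                f"row {i + 1} of {path.name}: non-numeric cell ({exc})"
            ) from None
        profiles.append(RNFLProfile(eye_id=eye_id, values=values))

    if metadata is not None:
        meta = read_metadata(metadata)
        for p in profiles:
            if p.eye_id in meta.index:
                rec = meta.loc[p.eye_id]
                p.age = int(rec["age"])
                p.disc_area = float(rec["disc_area"])
                p.status = str(rec["status"])
    return profiles


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"eye_id": str})
    required = {"eye_id", "age", "disc_area", "status"}
    missing = required - set(meta.columns)
    if missing:
        raise MalformedProfileError(f"metadata missing columns: {sorted(missing)}")
    return meta.set_index("eye_id")


def write_profiles(profiles: Iterable[RNFLProfile], path: str | Path) -> None:
    """Write profiles in the rows-of-eyes layout (id column + header)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    n = profiles[0].n_points
    header = ["eye_id"] + [f"p{j}" for j in range(1, n + 1)]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for p in profiles:
            writer.writerow([p.eye_id] + [format(v, ".6g") for v in p.values])


def write_metadata(profiles: Iterable[RNFLProfile], path: str | Path) -> None:
    rows = [
        {
            "eye_id": p.eye_id,
            "age": p.age,
            "disc_area": p.disc_area,
            "status": p.status,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_to_frame(profiles: Iterable[RNFLProfile]) -> pd.DataFrame:
    """Stack profile values into an (n_eyes, n_points) DataFrame."""
    profiles = list(profiles)
    return pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        index=[p.eye_id for p in profiles],
        columns=[f"p{j}" for j in range(1, profiles[0].n_points + 1)],
    )
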