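"""Direction-specific normative reference for RNFL thickness.

For each of the 9 age x disc-size strata and each angular point ``j``
the catalog stores the empirical distribution of RNFL thickness over
the normal eyes of that stratum,

    eCDF_{G,j}(x) = |{r <= x : r in R_{G,j}}| / |R_{G,j}|,

where ``R_{G,j}`` collects the thickness of every normal eye of group
``G`` at point ``j``.  A fully populated catalog at 256 points holds
9 x 256 = 2304 such distributions.  The catalog turns any eye's profile
into its Angular Quantile sequence (the pointwise normative quantile)
and its complement, the Angular Decay sequence: a decay near 1 at some
angle means the eye ranks near the very bottom of the normal population
in that direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import DEFAULT_N_POINTS, AngularGrid
from .profiles import GroupLabel, RNFLProfile

logger = logging.getLogger(__name__)

SMALL_GROUP_WARN = 20


class CatalogError(ValueError):
    """Catalog construction or lookup contract violation."""


@dataclass(frozen=True)
class ECDF:
    """Empirical CDF of a normative thickness sample at one angular point.

    Ties count with multiplicity: evaluation is the right-continuous
    step function (number of sample values <= x) / size.
    """

    sample: np.ndarray  # sorted ascending

    def __post_init__(self) -> None:
        sample = np.sort(np.asarray(self.sample, dtype=float))
        if sample.size == 0:
            raise CatalogError("ECDF sample must be non-empty")
        object.__setattr__(self, "sample", sample)

    @property
    def size(self) -> int:
        return self.sample.size

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        out = np.searchsorted(self.sample, x, side="right") / self.size
        return float(out) if np.ndim(x) == 0 else out

    def quantile(self, p: float | np.ndarray) -> float | np.ndarray:
        """Type-1 (left-continuous inverse) empirical quantile.

        Returns the lower order statistic at ties so that
        ``quantile(ecdf(x)) == x`` for any sample point ``x``.
        """
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("probabilities must lie in (0, 1]")
        idx = np.maximum(np.ceil(p * self.size).astype(int) - 1, 0)
        out = self.sample[idx]
        return float(out) if p.ndim == 0 else out


def ecdf_eval(e: ECDF, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate an empirical CDF (thin wrapper over ``ECDF.__call__``)."""
    return e(x)


class NormativeCatalog:
    """Map from (group, angular point) to the empirical thickness CDF.

    Samples are stored per group as a column-sorted (n_eyes, n_points)
    matrix; ``ecdf(group, j)`` materializes the single-point view.
    """

    def __init__(self, n_points: int = DEFAULT_N_POINTS) -> None:
        self.n_points = n_points
        self._sorted: dict[GroupLabel, np.ndarray] = {}

    # -- construction -------------------------------------------------
    def add_group(self, group: GroupLabel, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.n_points:
            raise CatalogError(
                f"group sample must be (n_eyes, {self.n_points}), got {values.shape}"
            )
        if values.shape[0] == 0:
            raise CatalogError("group sample must contain at least one eye")
        if values.shape[0] < SMALL_GROUP_WARN:
            logger.warning(
                "group %s has only %d eyes; quantile resolution is coarse",
                group, values.shape[0],
            )
        self._sorted[group] = np.sort(values, axis=0)

    # -- queries ------------------------------------------------------
    @property
    def groups(self) -> list[GroupLabel]:
        return list(self._sorted)

    @property
    def n_entries(self) -> int:
        """Number of stored direction-specific distributions."""
        return len(self._sorted) * self.n_points

    def group_size(self, group: GroupLabel) -> int:
        return self._require(group).shape[0]

    def _require(self, group: GroupLabel) -> np.ndarray:
        try:
            return self._sorted[group]
        except KeyError:
            raise CatalogError(f"group {group} is not populated in the catalog") from None

    def ecdf(self, group: GroupLabel, j: int) -> ECDF:
        """Empirical CDF at 1-based angular point ``j``."""
        if not 1 <= j <= self.n_points:
            raise CatalogError(f"angular point {j} out of range 1..{self.n_points}")
        return ECDF(self._require(group)[:, j - 1])

    def quantile_at(self, group: GroupLabel, values: np.ndarray) -> np.ndarray:
        """Angular Quantile of one profile: eCDF_{G,j}(values[j]) for every j."""
        sample = self._require(group)
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_points,):
            raise CatalogError(f"profile must have {self.n_points} points")
        n = sample.shape[0]
        out = np.empty(self.n_points)
        for c in range(self.n_points):
            out[c] = np.searchsorted(sample[:, c], values[c], side="right") / n
        return out

    def quantile_contours(
        self, group: GroupLabel, probs: Sequence[float]
    ) -> pd.DataFrame:
        """Per-angle normative thickness quantiles (rows = probs).

        Type-1 empirical quantiles, monotone in ``probs`` at every
        angular point; used for the concentric percentile contours and
        the decile export.
        """
        sample = self._require(group)
        probs_arr = np.asarray(probs, dtype=float)
        if np.any((probs_arr <= 0) | (probs_arr > 1)):
            raise ValueError("probabilities must lie in (0, 1]")
        n = sample.shape[0]
        idx = np.maximum(np.ceil(probs_arr * n).astype(int) - 1, 0)
        return pd.DataFrame(
            sample[idx, :],
            index=[f"q{p:g}" for p in probs_arr],
            columns=[f"p{j}" for j in range(1, self.n_points + 1)],
        )

    # -- serialization ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format raw samples: columns group, j, value."""
        parts = []
        for group, sample in self._sorted.items():
            n, m = sample.shape
            parts.append(
                pd.DataFrame(
                    {
                        "group": str(group),
                        "j": np.repeat(np.arange(1, m + 1), n),
                        "value": sample.ravel(order="F"),
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["group", "j", "value"])
        return pd.concat(parts, ignore_index=True)

    def save(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.insert(0, "n_points", self.n_points)
        frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "NormativeCatalog":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surface as a load error
            raise CatalogError(f"cannot read catalog file {path}: {exc}") from exc
        required = {"n_points", "group", "j", "value"}
        if not required.issubset(frame.columns):
            raise CatalogError(f"catalog file {path} is missing columns")
        if frame.empty:
            return cls()
        n_points = int(frame["n_points"].iloc[0])
        catalog = cls(n_points=n_points)
        for name, part in frame.groupby("group", sort=False):
            counts = part["j"].value_counts()
            if set(counts.index) != set(range(1, n_points + 1)) or counts.nunique() != 1:
                raise CatalogError(f"catalog file {path} is truncated or corrupt")
            n_eyes = int(counts.iloc[0])
            values = np.empty((n_eyes, n_points))
            for j, sub in part.groupby("j"):
                values[:, int(j) - 1] = sub["value"].to_numpy()
            catalog.add_group(GroupLabel.parse(str(name)), values)
        return catalog


def build_catalog(
    normals: Iterable[RNFLProfile], n_points: int = DEFAULT_N_POINTS
) -> NormativeCatalog:
    """Build the direction-specific catalog from normal eyes.

    Every profile must be a non-excluded normal eye carrying age and
    disc-area metadata; groups with no eyes are simply absent.
    """
    normals = list(normals)
    if not normals:
        raise CatalogError("cannot build a catalog from zero eyes")
    by_group: dict[GroupLabel, list[np.ndarray]] = {}
    for p in normals:
        if p.status != "normal":
            raise CatalogError(
                f"profile {p.eye_id!r} has status {p.status!r}; the normative "
                "catalog is built from normal eyes only"
            )
        if p.excluded:
            raise CatalogError(
                f"profile {p.eye_id!r} is flagged excluded (below the 30 μm floor)"
            )
        if p.n_points != n_points:
            raise CatalogError(
                f"profile {p.eye_id!r} has {p.n_points} points, expected {n_points}"
            )
        by_group.setdefault(p.group, []).append(p.values)
    catalog = NormativeCatalog(n_points=n_points)
    for group, values in by_group.items():
        catalog.add_group(group, np.vstack(values))
    return catalog


def quantile_contours(
    catalog: NormativeCatalog, group: GroupLabel, probs: Sequence[float]
) -> pd.DataFrame:
    """Thin wrapper over :meth:`NormativeCatalog.quantile_contours`."""
    return catalog.quantile_contours(group, probs)


def save_catalog(catalog: NormativeCatalog, path: str | Path) -> None:
    catalog.save(path)


def load_catalog(path: str | Path) -> NormativeCatalog:
    return NormativeCatalog.load(path)


def export_deciles(catalog: NormativeCatalog, path: str | Path) -> None:
    """Write the 9-decile normative table (one block per group)."""
    deciles = np.arange(0.1, 1.0, 0.1)
    blocks = []
    for group in catalog.groups:
        block = catalog.quantile_contours(group, deciles)
        block.insert(0, "group", str(group))
        block.insert(1, "decile", [f"{int(round(p * 100))}%" for p in deciles])
        blocks.append(block)
    pd.concat(blocks, ignore_index=True).to_csv(path, index=False)


class NormativeReference(BaseEstimator, TransformerMixin):
    """Estimator wrapping the catalog: fit on normal eyes, transform to decay.

    ``fit`` builds the direction-specific eCDF catalog from normal
    profiles; ``transform`` maps any profiles (normal or glaucomatous)
    of a populated stratum to their Angular Decay sequences.

    Parameters
    ----------
    n_points : int
        Angular resolution of the profiles (default 256).

    Attributes
    ----------
    catalog_ : NormativeCatalog
        The fitted 9 x n_points empirical-distribution catalog.
    grid_ : AngularGrid
        The shared angular coordinate grid.
    """

    def __init__(self, n_points: int = DEFAULT_N_POINTS) -> None:
        self.n_points = n_points

    def fit(self, X: Iterable[RNFLProfile], y=None) -> "NormativeReference":
        self.catalog_ = build_catalog(X, n_points=self.n_points)
        self.grid_ = AngularGrid(self.n_points)
        return self

    def transform(self, X: Iterable[RNFLProfile]) -> pd.DataFrame:
        """Angular Decay sequences, one row per eye."""
        from .decay import angular_decay  # circular import guard

        X = list(X)
        rows = [angular_decay(p, self.catalog_).decay for p in X]
        return pd.DataFrame(
            np.vstack(rows),
            index=[p.eye_id for p in X],
            columns=[f"p{j}" for j in range(1, self.n_points + 1)],
        )
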