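"""Petal tracing and the directional summaries of RNFL decay.

A *petal* is a maximal circular run of angular points whose Angular
Decay exceeds a quantile threshold tau (strictly; points equal to tau
are outside).  Runs that straddle the temporal origin are merged, so a
defect crossing 0 degrees is a single petal.  From the petal set of an
eye we compute:

nu           number of petals,
pi*          the widest petal (largest angular range),
mu*          decay-weighted circular mean angle of pi* -- the eye's
             directional signature of focal loss,
lambda*      local loss, width(pi*)/N,
Lambda       global loss, total petal width / N,

with 0 <= lambda* <= Lambda <= 1.  When no decay value exceeds tau the
eye has no petals and mu*, pi*, lambda* are NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .circular import UndefinedDirectionError, circular_mean
from .decay import DecaySequence
from .grid import AngularGrid

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.75


@dataclass(frozen=True)
class Petal:
    """A maximal supra-threshold circular run [theta_s, theta_t].

    Indices are 1-based angular points; ``end`` may be smaller than
    ``start`` for a petal wrapping the temporal origin.
    """

    start: int
    end: int
    member_indices: np.ndarray  # 1-based, counterclockwise order
    decay_sum: float

    @property
    def width(self) -> int:
        return self.member_indices.size


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")


def trace_petals(d: DecaySequence | np.ndarray, tau: float = DEFAULT_TAU) -> list[Petal]:
    """Trace all petals of a decay sequence at threshold ``tau``.

    Returns petals ordered by their starting point counterclockwise
    from the origin.  Exceedance is strict (decay > tau).
    """
    _check_tau(tau)
    decay = d.decay if isinstance(d, DecaySequence) else np.asarray(d, dtype=float)
    n = decay.size
    mask = decay > tau
    if not mask.any():
        return []
    if mask.all():
        idx = np.arange(1, n + 1)
        return [Petal(start=1, end=n, member_indices=idx, decay_sum=float(decay.sum()))]

    # run-finding on the doubled sequence so origin-straddling runs merge
    mask2 = np.concatenate([mask, mask])
    starts = np.flatnonzero(mask & ~np.roll(mask, 1))  # 0-based circular run starts
    falses = np.flatnonzero(~mask2)
    petals = []
    for s in np.sort(starts):
        length = int(falses[np.searchsorted(falses, s)] - s)
        members0 = (s + np.arange(length)) % n  # 0-based
        petals.append(
            Petal(
                start=int(s + 1),
                end=int(members0[-1] + 1),
                member_indices=members0 + 1,
                decay_sum=float(decay[members0].sum()),
            )
        )
    return petals


def widest_petal(petals: Sequence[Petal]) -> Petal | None:
    """The petal of maximal width, or None for an empty petal set.

    Ties are broken by larger summed decay, then by smaller starting
    point, so the result is deterministic.
    """
    if not petals:
        return None
    return max(petals, key=lambda p: (p.width, p.decay_sum, -p.start))


def weighted_circular_mean(angles_deg, weights) -> float:
    """Decay-weighted circular mean angle in [0, 360) degrees.

    The two-argument (quadrant-specific) inverse tangent of the
    weighted resultant; raises :class:`UndefinedDirectionError` on
    antipodal cancellation.
    """
    return circular_mean(angles_deg, weights)


@dataclass
class DecaySummary:
    """Directional summary of one eye's decay at a fixed threshold."""

    tau: float
    nu: int
    pi_star: Petal | None
    mu_star: float  # degrees, NaN when no petal or direction undefined
    lambda_star: float  # NaN when no petal
    Lambda: float
    eye_id: str | None = None

    def to_row(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "tau": self.tau,
            "nu": self.nu,
            "theta_s": self.pi_star.start if self.pi_star else np.nan,
            "theta_t": self.pi_star.end if self.pi_star else np.nan,
            "width": self.pi_star.width if self.pi_star else 0,
            "mu_star": self.mu_star,
            "lambda_star": self.lambda_star,
            "Lambda": self.Lambda,
        }


def summarize_decay(
    d: DecaySequence | np.ndarray,
    tau: float = DEFAULT_TAU,
    grid: AngularGrid | None = None,
    eye_id: str | None = None,
) -> DecaySummary:
    """Compute nu, pi*, mu*, lambda* and Lambda for one decay sequence."""
    _check_tau(tau)
    if isinstance(d, DecaySequence):
        decay = d.decay
        eye_id = eye_id if eye_id is not None else d.eye_id
    else:
        decay = np.asarray(d, dtype=float)
    n = decay.size
    if grid is None:
        grid = AngularGrid(n)
    elif grid.n_points != n:
        raise ValueError("grid size does not match the decay sequence")

    petals = trace_petals(decay, tau)
    nu = len(petals)
    total_width = sum(p.width for p in petals)
    Lambda = total_width / n
    star = widest_petal(petals)
    if star is None:
        return DecaySummary(tau, 0, None, np.nan, np.nan, 0.0, eye_id)
    lambda_star = star.width / n
    try:
        mu_star = weighted_circular_mean(
            grid.angle_of(star.member_indices), decay[star.member_indices - 1]
        )
    except UndefinedDirectionError:
        logger.warning(
            "eye %s: widest petal has an undefined mean direction "
            "(antipodal cancellation); mu* reported as NA", eye_id,
        )
        mu_star = np.nan
    return DecaySummary(tau, nu, star, mu_star, lambda_star, Lambda, eye_id)


def summarize_table(
    decay: pd.DataFrame | np.ndarray, tau: float = DEFAULT_TAU
) -> pd.DataFrame:
    """Summaries for a matrix of decay sequences (rows = eyes)."""
    if isinstance(decay, pd.DataFrame):
        ids = decay.index.astype(str)
        values = decay.to_numpy()
    else:
        values = np.asarray(decay, dtype=float)
        ids = [f"eye{i + 1:05d}" for i in range(values.shape[0])]
    grid = AngularGrid(values.shape[1])
    rows = [
        summarize_decay(values[i], tau, grid, eye_id=str(ids[i])).to_row()
        for i in range(values.shape[0])
    ]
    return pd.DataFrame(rows).set_index("eye_id")


class PetalSummarizer(BaseEstimator, TransformerMixin):
    """Transformer from decay matrices to directional loss features.

    Stateless apart from the threshold: ``transform`` maps an
    (n_eyes, n_points) decay matrix to a feature frame with columns
    ``nu``, ``theta_s``, ``theta_t``, ``width``, ``mu_star``,
    ``lambda_star`` and ``Lambda``.

    Parameters
    ----------
    tau : float
        Decay quantile threshold in (0, 1); 0.75 focuses on the last
        quartile of normative decay.
    """

    def __init__(self, tau: float = DEFAULT_TAU) -> None:
        self.tau = tau

    def fit(self, X, y=None) -> "PetalSummarizer":
        _check_tau(self.tau)
        X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        self.n_points_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        _check_tau(self.tau)
        return summarize_table(X, tau=self.tau)
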