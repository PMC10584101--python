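"""Angular Quantile and Angular Decay transforms.

Given an eye of stratum G, the Angular Quantile at point j is the
normative quantile of its thickness there,

    AngularQuantile(i, j) = eCDF_{G,j}(RNFL(i, j)),

and Angular Decay is the elementwise complement 1 - AngularQuantile.
Both are circular sequences with values in [0, 1]; high decay marks a
direction where the eye ranks low among the normal eyes of its group.
Glaucomatous eyes are evaluated against the normal-only catalog of
their own stratum; normal eyes may be evaluated against a catalog that
includes themselves.  No smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .normative import NormativeCatalog
from .profiles import GroupLabel, RNFLProfile


@dataclass
class DecaySequence:
    """Per-eye Angular Quantile and Angular Decay circular sequences."""

    eye_id: str
    group: GroupLabel
    quantile: np.ndarray
    decay: np.ndarray

    def __post_init__(self) -> None:
        self.quantile = np.asarray(self.quantile, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        if self.quantile.shape != self.decay.shape:
            raise ValueError("quantile and decay must have equal length")
        for name, seq in (("quantile", self.quantile), ("decay", self.decay)):
            if np.any((seq < 0) | (seq > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if not np.allclose(self.quantile + self.decay, 1.0, rtol=0, atol=1e-12):
            raise ValueError("decay must equal 1 - quantile elementwise")

    @property
    def n_points(self) -> int:
        return self.decay.size


def angular_quantile(p: RNFLProfile, c: NormativeCatalog) -> np.ndarray:
    """Pointwise normative quantile sequence of a profile."""
    return c.quantile_at(p.group, p.values)


def angular_decay(p: RNFLProfile, c: NormativeCatalog) -> DecaySequence:
    """Angular Decay sequence of a profile (1 - Angular Quantile)."""
    q = angular_quantile(p, c)
    return DecaySequence(eye_id=p.eye_id, group=p.group, quantile=q, decay=1.0 - q)


def decay_table(
    profiles: Iterable[RNFLProfile], c: NormativeCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decay and quantile matrices (rows = eyes) for a profile collection."""
    seqs = [angular_decay(p, c) for p in profiles]
    cols = [f"p{j}" for j in range(1, c.n_points + 1)]
    index = [s.eye_id for s in seqs]
    decay = pd.DataFrame(np.vstack([s.decay for s in seqs]), index=index, columns=cols)
    quant = pd.DataFrame(np.vstack([s.quantile for s in seqs]), index=index, columns=cols)
    decay.index.name = quant.index.name = "eye_id"
    return decay, quant


def write_decay(decay: pd.DataFrame, path: str | Path) -> None:
    decay.to_csv(path)


def read_decay(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
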