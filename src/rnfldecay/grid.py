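"""Angular coordinate convention shared by every module.

The circumpapillary calculation circle is sampled at ``n_points`` equally
spaced angular points in counterclockwise TSNIT order
(Temporal-Superior-Nasal-Inferior-Temporal).  Point ``j`` (1-based, as in
clinical reports) sits at ``theta_j = (j - 1) * 360 / n_points`` degrees,
so point 1 is the temporal origin at 0 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_POINTS = 256


@dataclass(frozen=True)
class AngularGrid:
    """Equally spaced angular points on the TSNIT circle.

    Parameters
    ----------
    n_points : int
        Number of angular points (256 for the high-resolution scan,
        i.e. one sample every 1.41 degrees).
    """

    n_points: int = DEFAULT_N_POINTS
    theta: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be a positive integer")
        object.__setattr__(
            self, "theta", np.arange(self.n_points) * (360.0 / self.n_points)
        )

    @property
    def spacing(self) -> float:
        """Angular spacing between consecutive points, in degrees."""
        return 360.0 / self.n_points

    def angle_of(self, j: int | np.ndarray) -> float | np.ndarray:
        """Angle (degrees) of 1-based angular point(s) ``j``."""
        j = np.asarray(j)
        if np.any((j < 1) | (j > self.n_points)):
            raise ValueError(f"angular point out of range 1..{self.n_points}")
        out = (j - 1) * self.spacing
        return float(out) if out.ndim == 0 else out

    def nearest_point(self, angle_deg: float) -> int:
        """1-based index of the grid point closest to ``angle_deg``."""
        j = int(np.rint((angle_deg % 360.0) / self.spacing)) % self.n_points
        return j + 1
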