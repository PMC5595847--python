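"""Discretization of the ring of motion directions.

The model lives on the periodic interval [-pi, pi) of motion directions.
All operators (connectivity convolution, quadrature) are defined relative to
a uniform grid of ``n`` samples; with uniform spacing the rectangle rule is
the trapezoid rule for periodic functions and converges spectrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) in radians to the interval [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, TWO_PI) - np.pi


def deg2rad(x):
    return np.deg2rad(x)


def rad2deg(x):
    return np.rad2deg(x)


@dataclass(frozen=True)
class RingGrid:
    """Uniform periodic grid on [-pi, pi).

    Parameters
    ----------
    n : int
        Number of samples (default 404). Must be >= 8 and even so that both
        0 and the seam are representable exactly.
    """

    n: int = 404
    theta: np.ndarray = field(init=False, repr=False, compare=False)
    dtheta: float = field(init=False, compare=False)

    def __post_init__(self):
        if self.n < 8:
            raise ValueError(f"grid needs n >= 8 samples, got {self.n}")
        dtheta = TWO_PI / self.n
        theta = -np.pi + dtheta * np.arange(self.n)
        object.__setattr__(self, "dtheta", dtheta)
        object.__setattr__(self, "theta", theta)
        theta.setflags(write=False)

    @property
    def theta_deg(self) -> np.ndarray:
        return np.rad2deg(self.theta)

    def index_of(self, angle: float) -> int:
        """Index of the grid point nearest to ``angle`` (radians)."""
        return int(np.argmin(np.abs(wrap_angle(self.theta - angle))))

    def shift_steps(self, delta: float) -> int:
        """Nearest integer number of grid steps corresponding to ``delta`` rad."""
        return int(np.rint(delta / self.dtheta))

    def quadrature(self, values: np.ndarray) -> float:
        """Periodic quadrature of samples over one period."""
        return float(np.sum(values) * self.dtheta)

    def same_grid(self, other: "RingGrid") -> bool:
        return self.n == other.n
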