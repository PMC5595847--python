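"""External drive profiles for uni- and bi-directional motion stimuli.

A motion stimulus is encoded as a sum of Gaussian bumps in direction space,
one bump per component direction.  The bump standard deviation (peak width,
PW) renders the direction uncertainty of the upstream motion estimate —
broader for gratings/plaids than for random-dot patterns — and the angular
distance between the two bumps (peak separation, PS) encodes the component
direction difference.  Bumps are peak-normalized (height 1 for the stronger
component) so that ``rel_strength`` scales the amplitude of the weaker one;
an area-normalized variant is available as a switch.  The overall input gain
``kappa_i`` is applied in the dynamics, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import RingGrid, TWO_PI, wrap_angle
from .kernel import wrapped_gaussian_density


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a motion stimulus.

    Angles are user-facing degrees.  ``va_direction`` is the mean (vector
    average) direction of the components; for a bidirectional stimulus the
    components lie at ``va_direction +- ps/2``.  ``rel_strength`` is the
    amplitude of the weaker component relative to the stronger (1 =
    symmetric).
    """

    va_direction: float = 0.0
    ps: float = 120.0
    pw: float = 10.0
    rel_strength: float = 1.0
    n_components: int = 2
    area_normalized: bool = False

    def __post_init__(self):
        if self.pw <= 0:
            raise ValueError(f"peak width must be positive, got {self.pw}")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if self.n_components == 2 and not 0.0 < self.ps <= 180.0:
            raise ValueError(f"peak separation must lie in (0, 180], got {self.ps}")
        if not 0.0 <= self.rel_strength <= 1.0:
            raise ValueError("rel_strength must lie in [0, 1]")

    @property
    def component_directions_rad(self) -> np.ndarray:
        """Component directions in radians, stronger component first."""
        va = np.deg2rad(self.va_direction)
        if self.n_components == 1:
            return np.array([wrap_angle(va)])
        half = 0.5 * np.deg2rad(self.ps)
        return wrap_angle(np.array([va + half, va - half]))

    def with_direction(self, va_direction_deg: float) -> "StimulusSpec":
        return replace(self, va_direction=va_direction_deg)


@dataclass(frozen=True)
class InputProfile:
    """Discretized external drive I_ext(theta) on a ring grid."""

    spec: StimulusSpec
    grid: RingGrid
    values: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n,):
            raise ValueError("input values must match the grid size")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("input profile must be finite and non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


def _bump(theta, center, sigma, area_normalized):
    if area_normalized:
        return wrapped_gaussian_density(theta - center, sigma, n_replicas=1)
    # peak-normalized with three-replica wrapping so bumps near +-pi are
    # continuous across the seam
    d = wrap_angle(theta - center)
    out = np.exp(-0.5 * (d / sigma) ** 2)
    for k in (1, 2):  # replicas; k=2 negligible for pw <= 30 deg but cheap
        out = out + np.exp(-0.5 * ((d - TWO_PI * k) / sigma) ** 2)
        out = out + np.exp(-0.5 * ((d + TWO_PI * k) / sigma) ** 2)
    return out


def make_input(spec: StimulusSpec, grid: RingGrid) -> InputProfile:
    """Build the external drive for ``spec`` on ``grid``."""
    sigma = np.deg2rad(spec.pw)
    weights = [1.0] if spec.n_components == 1 else [1.0, spec.rel_strength]
    values = np.zeros(grid.n)
    for w, center in zip(weights, spec.component_directions_rad):
        values = values + w * _bump(grid.theta, center, sigma, spec.area_normalized)
    return InputProfile(spec=spec, grid=grid, values=values)


def rotate_input(profile: InputProfile, delta: float) -> InputProfile:
    """Circularly shift a profile by ``delta`` radians (nearest grid step).

    Exact when ``delta`` is an integer multiple of the grid spacing.
    """
    steps = profile.grid.shift_steps(delta)
    new_dir = profile.spec.va_direction + np.rad2deg(steps * profile.grid.dtheta)
    spec = profile.spec.with_direction(
        float(np.rad2deg(wrap_angle(np.deg2rad(new_dir)))))
    return InputProfile(spec=spec, grid=profile.grid,
                        values=np.roll(profile.values, steps))
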