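"""Center-surround connectivity kernels on the direction ring.

The recurrent connectivity is a weighted difference of Gaussians (DoG) in
direction-difference space: narrow local excitation minus very broad
("global") lateral inhibition,

    J(theta) = g_e * G(theta, sigma_e) - g_i * G(theta, sigma_i),

with G a unit-integral Gaussian density evaluated in radians.  A
two-parameter family is used to explore connectivity regimes: ``alpha`` in
[0, 1] interpolates the excitation width between a narrow (11.5 deg) and a
broad (60 deg) profile, and ``beta`` offsets the inhibition strength
additively.  The gains are tied to the width by a normalization constraint:
the zeroth Fourier coefficient (ring integral) of the ``beta = 0`` kernel is
-1 for every ``alpha``.

Normalization conventions
-------------------------
The inhibitory width is fixed at ``sigma_i = 10*pi`` rad (1800 deg), so the
inhibitory Gaussian is effectively constant over the ring; its mass on one
period is ``erf(pi / (sigma_i * sqrt(2))) = 0.0796557...`` (0.0797 to three
significant figures).  ``g_i = (1 + g_e) / mass`` then enforces the
integral constraint exactly.  The excitatory Gaussian is periodized over
three replicas so that the kernel is genuinely 2*pi-periodic; for widths up
to 60 deg the replica mass is what keeps the excitatory ring integral equal
to ``g_e`` and the constraint width-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .grid import RingGrid, TWO_PI, wrap_angle

#: Default narrow / broad excitation widths (degrees) and inhibition width (radians).
SIGMA_E_NARROW_DEG = 11.5
SIGMA_E_BROAD_DEG = 60.0
SIGMA_I_RAD = 10.0 * np.pi


def gaussian_density(theta, sigma):
    """Unit-integral Gaussian density on the line, angles in radians."""
    theta = np.asarray(theta, dtype=float)
    return np.exp(-0.5 * (theta / sigma) ** 2) / (sigma * np.sqrt(TWO_PI))


def wrapped_gaussian_density(theta, sigma, n_replicas: int = 1):
    """Gaussian density periodized by summing +-``n_replicas`` shifted copies.

    One replica on each side is exact to machine precision for
    ``sigma <= 60 deg`` on [-pi, pi).
    """
    theta = wrap_angle(theta)
    out = gaussian_density(theta, sigma)
    for k in range(1, n_replicas + 1):
        out = out + gaussian_density(theta - TWO_PI * k, sigma)
        out = out + gaussian_density(theta + TWO_PI * k, sigma)
    return out


def ring_gaussian_mass(sigma: float) -> float:
    """Integral of the (un-periodized) Gaussian density over one ring period.

    For the default inhibitory width 10*pi this evaluates to 0.0796557...,
    the constant printed as 0.0797 in the gain formula.
    """
    return float(erf(np.pi / (sigma * np.sqrt(2.0))))


def excitation_width(alpha: float,
                     sigma_e_a: float = SIGMA_E_NARROW_DEG,
                     sigma_e_b: float = SIGMA_E_BROAD_DEG) -> float:
    """Excitation width (degrees) interpolated by the homotopy parameter alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return sigma_e_a + alpha * (sigma_e_b - sigma_e_a)


def excitation_gain(sigma_e_deg: float) -> float:
    """Excitatory gain g_e = exp(-sigma_e^2 / 2) with sigma_e in radians."""
    if sigma_e_deg <= 0:
        raise ValueError(f"excitation width must be positive, got {sigma_e_deg}")
    s = np.deg2rad(sigma_e_deg)
    return float(np.exp(-0.5 * s * s))


def inhibition_gain(g_e: float, sigma_i: float = SIGMA_I_RAD) -> float:
    """Inhibitory gain g_i = (1 + g_e) / mass(sigma_i).

    ``mass`` is the inhibitory Gaussian's integral over one period
    (0.0797 to printed precision for sigma_i = 10*pi); this choice makes the
    ring integral of the beta = 0 kernel equal to -1.
    """
    if not 0.0 < g_e <= 1.0:
        raise ValueError(f"g_e must lie in (0, 1], got {g_e}")
    return (1.0 + g_e) / ring_gaussian_mass(sigma_i)


@dataclass(frozen=True)
class KernelParams:
    """Parameters of the DoG connectivity family.

    ``alpha`` interpolates the excitation width, ``beta`` is added to the
    inhibition strength.  Widths are user-facing degrees except ``sigma_i``
    which is radians (default 10*pi, i.e. 1800 deg).
    """

    alpha: float = 0.0
    beta: float = 0.0
    sigma_e_a: float = SIGMA_E_NARROW_DEG
    sigma_e_b: float = SIGMA_E_BROAD_DEG
    sigma_i: float = SIGMA_I_RAD

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not -10.0 <= self.beta <= 15.0:
            raise ValueError(f"beta must lie in [-10, 15], got {self.beta}")
        if not self.sigma_e_a < self.sigma_e_b:
            raise ValueError("need sigma_e_a < sigma_e_b")
        if self.sigma_i <= TWO_PI:
            raise ValueError("sigma_i must be much larger than 2*pi")

    @property
    def sigma_e(self) -> float:
        """Effective excitation width in degrees."""
        return excitation_width(self.alpha, self.sigma_e_a, self.sigma_e_b)

    @property
    def g_e(self) -> float:
        return excitation_gain(self.sigma_e)

    @property
    def g_i(self) -> float:
        """Base inhibition strength (before the beta offset)."""
        return inhibition_gain(self.g_e, self.sigma_i)


@dataclass(frozen=True)
class Kernel:
    """Discretized connectivity profile J(theta) with FFT convolution support."""

    params: KernelParams
    grid: RingGrid
    values: np.ndarray = field(repr=False, compare=False)
    _chat: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n,):
            raise ValueError("kernel values must match the grid size")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        # circulant first column: c[m] = J(wrap(m * dtheta))
        col = np.roll(values, -(self.grid.n // 2))
        object.__setattr__(self, "_chat", np.fft.rfft(col) * self.grid.dtheta)

    def convolve(self, s: np.ndarray) -> np.ndarray:
        """Circular convolution (J * s)(theta_j) = sum_k J(theta_j - theta_k) s_k dtheta."""
        s = np.asarray(s, dtype=float)
        if s.shape[-1] != self.grid.n:
            raise ValueError("state vector does not match the kernel grid")
        return np.fft.irfft(self._chat * np.fft.rfft(s), n=self.grid.n)

    def operator_matrix(self) -> np.ndarray:
        """Dense convolution operator C with C[i, j] = J(theta_i - theta_j) * dtheta."""
        from scipy.linalg import circulant

        col = np.roll(self.values, -(self.grid.n // 2))
        return circulant(col) * self.grid.dtheta


def build_kernel(params: KernelParams, grid: RingGrid) -> Kernel:
    """Evaluate the DoG kernel of ``params`` on ``grid``.

    The excitatory Gaussian is periodized (three replicas); the inhibitory
    one is evaluated directly since it is effectively constant on the ring.
    """
    sigma_e = np.deg2rad(params.sigma_e)
    exc = params.g_e * wrapped_gaussian_density(grid.theta, sigma_e, n_replicas=1)
    inh = (params.g_i + params.beta) * gaussian_density(grid.theta, params.sigma_i)
    return Kernel(params=params, grid=grid, values=exc - inh)


def kernel_with_inhibition(params: KernelParams, grid: RingGrid,
                           g_i_total: float) -> Kernel:
    """Kernel with an explicit total inhibition strength (for time-varying g_i)."""
    sigma_e = np.deg2rad(params.sigma_e)
    exc = params.g_e * wrapped_gaussian_density(grid.theta, sigma_e, n_replicas=1)
    inh = g_i_total * gaussian_density(grid.theta, params.sigma_i)
    return Kernel(params=params, grid=grid, values=exc - inh)


def kernel_fourier(kernel: Kernel, mode: int) -> float:
    """Cosine Fourier coefficient int J(theta) cos(mode*theta) dtheta by quadrature."""
    if mode < 0:
        raise ValueError("mode must be non-negative")
    g = kernel.grid
    return g.quadrature(kernel.values * np.cos(mode * g.theta))


@dataclass(frozen=True)
class InhibitionSchedule:
    """Exponential ramp of the total inhibition strength g_i(t).

    g_i(t) = g_i_low + (g_i_final - g_i_low) * (1 - exp(-(t - onset)/tau_l))
    for t >= onset, constant at g_i_low before.  ``tau_l`` is the slow
    inhibition time constant in ms (30-100 ms range), ``onset`` an optional
    delay in ms before the ramp starts.
    """

    g_i_low: float = 0.0
    g_i_final: float = 0.0
    tau_l: float = 100.0
    onset: float = 0.0

    def __post_init__(self):
        if self.tau_l <= 0:
            raise ValueError("tau_l must be positive")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")


def inhibition_at_time(t, schedule: InhibitionSchedule):
    """Inhibition strength at time(s) ``t`` (ms) under ``schedule``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    ramp = 1.0 - np.exp(-np.maximum(t - schedule.onset, 0.0) / schedule.tau_l)
    out = schedule.g_i_low + (schedule.g_i_final - schedule.g_i_low) * ramp
    return out if out.ndim else float(out)
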