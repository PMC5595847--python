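"""Neural field dynamics on the direction ring.

The population activity u(theta, t) follows the Amari-type rate equation

    tau_p * du/dt = -u(theta)
                    + int_{-pi}^{pi} J(theta - phi) S(mu u(phi), th) dphi
                    + kappa_i * I_ext(theta),

i.e. leak plus recurrent drive plus feed-forward input, where S is a
threshold-shifted logistic nonlinearity with S(0) = 0 so the rest state
u = 0 is an equilibrium of the undriven network.  The recurrent integral is
a circular convolution evaluated by FFT with periodic quadrature weights.

Deterministic trajectories use an adaptive implicit solver (absolute
tolerance 1e-12) with the analytic Jacobian; stochastic trajectories use
fixed-step Euler-Maruyama with additive white noise, independent per node.
Activity is a lumped excitation/inhibition potential and may be negative
(net inhibition); it is never rectified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .grid import RingGrid
from .kernel import Kernel
from .stimulus import InputProfile


class DivergenceError(RuntimeError):
    """Raised when the state blows up during integration."""


@dataclass(frozen=True)
class NetworkParams:
    """Global network parameters.

    mu : sigmoid gain (16.0), th : sigmoid threshold (3.0),
    kappa_i : input gain (0.1), tau_p : population time constant in ms (1.0),
    noise_eps : additive noise amplitude (0 = deterministic path),
    dt : Euler-Maruyama step in ms, ic_amp : amplitude of the uniform random
    initial condition.
    """

    mu: float = 16.0
    th: float = 3.0
    kappa_i: float = 0.1
    tau_p: float = 1.0
    noise_eps: float = 0.0
    dt: float = 0.1
    ic_amp: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.mu <= 0 or self.th <= 0:
            raise ValueError("mu and th must be positive")
        if self.tau_p <= 0 or self.dt <= 0:
            raise ValueError("tau_p and dt must be positive")
        if self.noise_eps < 0:
            raise ValueError("noise_eps must be non-negative")


def sigmoid(u, mu: float = 16.0, th: float = 3.0):
    """Threshold-shifted logistic rate function; zero at u = 0, bounded."""
    return expit(mu * np.asarray(u, dtype=float) - th) - expit(-th)


def sigmoid_prime(u, mu: float = 16.0, th: float = 3.0):
    """Derivative of :func:`sigmoid` with respect to u."""
    s = expit(mu * np.asarray(u, dtype=float) - th)
    return mu * s * (1.0 - s)


def random_initial_condition(grid: RingGrid, params: NetworkParams,
                             rng: np.random.Generator) -> np.ndarray:
    """Low level of random activity: iid uniform on [0, ic_amp] per node."""
    return rng.uniform(0.0, params.ic_amp, size=grid.n)


def rhs(u: np.ndarray, kernel: Kernel, inp: InputProfile,
        params: NetworkParams) -> np.ndarray:
    """Right-hand side of the field equation (du/dt)."""
    if u.shape[-1] != kernel.grid.n or not kernel.grid.same_grid(inp.grid):
        raise ValueError("state, kernel and input must share one grid")
    rec = kernel.convolve(sigmoid(u, params.mu, params.th))
    return (-u + rec + params.kappa_i * inp.values) / params.tau_p


def jacobian(u: np.ndarray, kernel: Kernel, params: NetworkParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`: (-I + C diag(S'(u))) / tau_p."""
    C = kernel.operator_matrix()
    J = C * sigmoid_prime(u, params.mu, params.th)[np.newaxis, :]
    J[np.diag_indices_from(J)] -= 1.0
    return J / params.tau_p


def energy(u: np.ndarray, grid: RingGrid) -> float:
    """Grid-weighted l2-norm sqrt(sum u_k^2 dtheta) of an activity profile."""
    return float(np.sqrt(np.sum(np.square(u)) * grid.dtheta))


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_times, n)
    params: NetworkParams
    stimulus: InputProfile
    converged: bool = False
    final_residual: float = np.nan

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class SteadyState:
    u_star: np.ndarray
    residual: float
    energy: float
    provenance: str = "integration"
    converged: bool = True


def _check_finite(u, t):
    if not np.all(np.isfinite(u)):
        raise DivergenceError(
            f"non-finite state at t={t:.3f} ms (max |u| = {np.nanmax(np.abs(u)):.3g})")


def euler_maruyama(u0: np.ndarray, kernel: Kernel, inp: InputProfile,
                   params: NetworkParams, t_end: float,
                   rng: Optional[np.random.Generator] = None,
                   record_every: float = 1.0,
                   t0: float = 0.0,
                   kernel_at_time: Optional[Callable[[float], Kernel]] = None,
                   ) -> Trajectory:
    """Fixed-step Euler-Maruyama integration with additive white noise.

    With ``noise_eps = 0`` this reduces to the forward Euler scheme.  An
    optional ``kernel_at_time`` callback supplies a time-dependent kernel
    (used for the slow-inhibition ramp).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = params.dt
    n_steps = int(np.ceil((t_end - t0) / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    u = np.array(u0, dtype=float)
    times = [t0]
    states = [u.copy()]
    sqrt_dt = np.sqrt(dt)
    t = t0
    for step in range(1, n_steps + 1):
        ker = kernel if kernel_at_time is None else kernel_at_time(t)
        du = rhs(u, ker, inp, params)
        u = u + dt * du
        if params.noise_eps > 0:
            u = u + params.noise_eps * sqrt_dt * rng.standard_normal(u.shape)
        t = t0 + step * dt
        if np.max(np.abs(u)) > 1e6:
            _check_finite(u, t)
            raise DivergenceError(
                f"state blew up at t={t:.3f} ms (max |u| = {np.max(np.abs(u)):.3g})")
        _check_finite(u, t)
        if step % rec_stride == 0 or step == n_steps:
            times.append(t)
            states.append(u.copy())
    ker = kernel if kernel_at_time is None else kernel_at_time(t)
    res = float(np.max(np.abs(rhs(u, ker, inp, params))))
    return Trajectory(times=np.asarray(times), states=np.asarray(states),
                      params=params, stimulus=inp, final_residual=res)


def integrate(u0: np.ndarray, kernel: Kernel, inp: InputProfile,
              params: NetworkParams, t_end: float,
              record_every: float = 1.0,
              rng: Optional[np.random.Generator] = None,
              rtol: float = 1e-8, atol: float = 1e-12) -> Trajectory:
    """Integrate the field equation from ``u0`` to ``t_end`` (ms).

    The deterministic path (``noise_eps == 0``) uses an adaptive implicit
    solver (Radau) with the analytic Jacobian and absolute tolerance 1e-12;
    with noise the fixed-step Euler-Maruyama scheme is used.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if params.noise_eps > 0:
        return euler_maruyama(u0, kernel, inp, params, t_end, rng=rng,
                              record_every=record_every)
    t_eval = np.arange(0.0, t_end + 0.5 * record_every, record_every)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(
        lambda t, u: rhs(u, kernel, inp, params),
        (0.0, t_end), np.asarray(u0, dtype=float),
        method="Radau", t_eval=t_eval, rtol=rtol, atol=atol,
        jac=lambda t, u: jacobian(u, kernel, params))
    if not sol.success:
        raise DivergenceError(f"integration failed: {sol.message}")
    _check_finite(sol.y[:, -1], sol.t[-1])
    res = float(np.max(np.abs(rhs(sol.y[:, -1], kernel, inp, params))))
    return Trajectory(times=sol.t, states=sol.y.T, params=params, stimulus=inp,
                      final_residual=res)


def newton_polish(u0: np.ndarray, kernel: Kernel, inp: InputProfile,
                  params: NetworkParams, tol: float = 1e-10,
                  max_iter: int = 50) -> tuple[np.ndarray, float, bool]:
    """Damped Newton iteration on the equilibrium condition rhs(u) = 0.

    Returns ``(u, residual, success)``; ``success`` is False when the
    iteration stalls or exceeds ``max_iter``.
    """
    u = np.array(u0, dtype=float)
    # solve F(u) = -u + C S(u) + kappa_i I = 0 (tau_p cancels at equilibrium)
    scaled = replace(params, tau_p=1.0)
    stalls = 0
    for _ in range(max_iter):
        f = rhs(u, kernel, inp, scaled)
        res = float(np.max(np.abs(f)))
        if not np.isfinite(res):
            return u, np.inf, False
        if res < tol:
            return u, res, True
        J = jacobian(u, kernel, scaled)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return u, res, False
        if res > 1e-3:
            # far field: backtrack toward residual decrease
            lam = 1.0
            for _ in range(8):
                trial = u + lam * step
                if np.max(np.abs(rhs(trial, kernel, inp, scaled))) < res:
                    break
                lam *= 0.5
            else:
                stalls += 1
                if stalls > 5:
                    return u, res, False
            u = u + lam * step
        else:
            # near field: full steps; the residual may rise transiently when
            # a near-marginal (e.g. rotational) mode is corrected, so no
            # monotonicity is enforced here
            u = u + step
    res = float(np.max(np.abs(rhs(u, kernel, inp, scaled))))
    return u, res, res < tol


def find_steady_state(u0: np.ndarray, kernel: Kernel, inp: InputProfile,
                      params: NetworkParams, tol_ss: float = 1e-9,
                      t_max: float = 2000.0,
                      rng: Optional[np.random.Generator] = None,
                      stability_check: bool = True) -> SteadyState:
    """Integrate toward an attractor, then polish it with a damped Newton solve.

    Stochastic parameters are honored during the transient (the noisy phase
    selects the basin); the polish itself is always deterministic.  A
    polished state with a clearly positive leading eigenvalue is rejected —
    a trajectory lingering near a saddle (common close to symmetry-breaking
    bifurcations) must be allowed to escape rather than be pinned onto the
    unstable state.  On failure a non-converged :class:`SteadyState` is
    returned rather than an exception, so attractor statistics can tally it.
    """
    u = np.asarray(u0, dtype=float)
    det = replace(params, noise_eps=0.0)
    t_chunk = 100.0
    t_done = 0.0
    if params.noise_eps > 0:
        # noisy transient selects the basin, then deterministic settling
        traj = euler_maruyama(u, kernel, inp, params, t_end=min(300.0, t_max),
                              rng=rng, record_every=min(300.0, t_max))
        u = traj.final_state
        t_done = traj.times[-1]
    while True:
        # cheap fixed-step settling; precision comes from the Newton polish
        traj = euler_maruyama(u, kernel, inp, det, t_end=t_chunk,
                              record_every=t_chunk)
        u = traj.final_state
        t_done += t_chunk
        if traj.final_residual < 1e-4 or t_done >= t_max:
            u_pol, res, ok = newton_polish(u, kernel, inp, det)
            if ok and res < tol_ss:
                unstable = False
                if stability_check:
                    lam = np.linalg.eigvals(jacobian(u_pol, kernel, det))
                    unstable = float(np.max(lam.real)) > 1e-6
                if not unstable:
                    return SteadyState(u_star=u_pol, residual=res,
                                       energy=energy(u_pol, kernel.grid),
                                       provenance="newton", converged=True)
            if t_done >= t_max:
                return SteadyState(u_star=u, residual=traj.final_residual,
                                   energy=energy(u, kernel.grid),
                                   provenance="integration", converged=False)
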