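"""Numerical continuation of steady states with stability analysis.

Steady states of the field equation solve F(u, p) = -u + C S(u) + kappa_i I(p)
= 0, where the continuation parameter p typically deforms the stimulus
(e.g. the peak separation PS).  Branches are traced by pseudo-arclength
predictor-corrector stepping: a secant predictor followed by a Newton
corrector on the bordered system, with adaptive step length so folds are
rounded instead of terminating the branch.  Stability comes from the
eigenvalues of the analytic Jacobian (-I + C diag(S'(u))) / tau_p.

Special points are classified from the branch data: folds where the
parameter reverses direction along arclength, and symmetry-breaking branch
points (pitchforks) where an eigenvalue with an *odd* eigenvector (odd
about the stimulus axis) crosses zero along a mirror-symmetric branch.  The
mirror WTA pair of the ring model emerges from such a pitchfork on the
vector-average branch and can be reached with :func:`switch_branch`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np

from .dynamics import (NetworkParams, SteadyState, energy, jacobian,
                       newton_polish, rhs)
from .grid import RingGrid, wrap_angle
from .kernel import Kernel
from .stimulus import InputProfile

#: A continuation problem maps a parameter value to (kernel, input).
Problem = Callable[[float], Tuple[Kernel, InputProfile]]


class NewtonError(RuntimeError):
    """Newton corrector failed to converge."""


def newton_steady_state(u_guess: np.ndarray, kernel: Kernel,
                        inp: InputProfile, params: NetworkParams,
                        tol: float = 1e-10, max_iter: int = 50) -> SteadyState:
    """Damped Newton solve of the equilibrium condition from ``u_guess``."""
    u, res, ok = newton_polish(u_guess, kernel, inp, params,
                               tol=tol, max_iter=max_iter)
    if not ok:
        raise NewtonError(f"Newton failed to converge (residual {res:.3g})")
    return SteadyState(u_star=u, residual=res, energy=energy(u, kernel.grid),
                       provenance="newton", converged=True)


@dataclass(frozen=True)
class BranchPoint:
    param: float
    u: np.ndarray = field(repr=False)
    energy: float = 0.0
    eig_max: float = np.nan
    stable: bool = False


@dataclass(frozen=True)
class SpecialPoint:
    kind: str  # "fold" | "branch_point"
    param: float
    u: np.ndarray = field(repr=False)


@dataclass
class Branch:
    parameter: str
    points: List[BranchPoint] = field(default_factory=list)
    special_points: List[SpecialPoint] = field(default_factory=list)
    truncated: bool = False
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    @property
    def energies(self) -> np.ndarray:
        return np.array([pt.energy for pt in self.points])

    @property
    def stability(self) -> np.ndarray:
        return np.array([pt.stable for pt in self.points])

    def stable_interval(self) -> Tuple[float, float]:
        """(min, max) parameter over the stable points of the branch."""
        ps = self.params[self.stability]
        if ps.size == 0:
            return (np.nan, np.nan)
        return float(ps.min()), float(ps.max())


def _residual(u, p, problem, params):
    kernel, inp = problem(p)
    return rhs(u, kernel, inp, replace(params, tau_p=1.0))


def _dF_dp(u, p, problem, params, h=1e-5):
    return (_residual(u, p + h, problem, params)
            - _residual(u, p - h, problem, params)) / (2.0 * h)


def _eig_max(u, p, problem, params) -> float:
    kernel, _ = problem(p)
    lam = np.linalg.eigvals(jacobian(u, kernel, params))
    return float(np.max(lam.real))


def _corrector(u, p, problem, params, tangent, x_pred, tol=1e-10, max_iter=12):
    """Newton on the bordered system (F(u, p) = 0, tangent . (x - x_pred) = 0)."""
    tu, tp = tangent
    n = u.size
    for _ in range(max_iter):
        kernel, inp = problem(p)
        f = rhs(u, kernel, inp, replace(params, tau_p=1.0))
        g = float(tu @ (u - x_pred[0]) + tp * (p - x_pred[1]))
        if max(np.max(np.abs(f)), abs(g)) < tol:
            return u, p, True
        J = jacobian(u, kernel, replace(params, tau_p=1.0))
        Fp = _dF_dp(u, p, problem, params)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = Fp
        A[n, :n] = tu
        A[n, n] = tp
        try:
            dx = np.linalg.solve(A, -np.concatenate([f, [g]]))
        except np.linalg.LinAlgError:
            return u, p, False
        u = u + dx[:n]
        p = p + dx[n]
    return u, p, False


def continue_branch(problem: Problem, start: SteadyState, p_start: float,
                    p_range: Tuple[float, float], params: NetworkParams,
                    parameter: str = "ps",
                    ds: float = 2.0, ds_min: float = 1e-3, ds_max: float = 8.0,
                    max_steps: int = 400, initial_direction: float = 1.0,
                    stability_margin: float = 1e-8) -> Branch:
    """Pseudo-arclength continuation of a steady-state branch.

    ``p_range`` bounds the parameter window; the branch is traced from
    ``p_start`` in ``initial_direction`` until it leaves the window, the
    step budget is exhausted, or the corrector fails at the minimum step
    (then ``truncated`` is set).  Arclength uses the grid-weighted state
    norm so steps are resolution-independent.
    """
    grid = problem(p_start)[0].grid
    w = grid.dtheta  # state-space metric weight
    branch = Branch(parameter=parameter)

    def record(u, p):
        lam = _eig_max(u, p, problem, params)
        branch.points.append(BranchPoint(
            param=float(p), u=u.copy(), energy=energy(u, grid),
            eig_max=lam, stable=lam < -stability_margin))

    # first point
    kernel, inp = problem(p_start)
    u0, res, ok = newton_polish(start.u_star, kernel, inp, params)
    if not ok:
        branch.truncated = True
        branch.message = f"initial Newton solve failed (residual {res:.3g})"
        return branch
    record(u0, p_start)

    # second point by natural continuation
    dp = initial_direction * min(ds, 1.0)
    p1 = p_start + dp
    kernel, inp = problem(p1)
    u1, res, ok = newton_polish(u0, kernel, inp, params)
    if not ok:
        branch.truncated = True
        branch.message = "natural continuation for second point failed"
        return branch
    record(u1, p1)

    u_prev, p_prev = u0, p_start
    u_cur, p_cur = u1, p1
    lo, hi = min(p_range), max(p_range)
    for _ in range(max_steps):
        du = u_cur - u_prev
        dpar = p_cur - p_prev
        norm = np.sqrt(w * du @ du + dpar * dpar)
        if norm == 0:
            branch.truncated = True
            branch.message = "zero secant"
            break
        tu, tp = w * du / norm, dpar / norm
        step = ds
        while True:
            scale = step / norm
            x_pred = (u_cur + du * scale, p_cur + dpar * scale)
            u_new, p_new, ok = _corrector(
                x_pred[0].copy(), x_pred[1], problem, params, (tu, tp), x_pred)
            if ok:
                break
            step *= 0.5
            if step < ds_min:
                branch.truncated = True
                branch.message = f"corrector failed near p={p_cur:.4g}"
                break
        if step < ds_min:
            break
        record(u_new, p_new)
        u_prev, p_prev = u_cur, p_cur
        u_cur, p_cur = u_new, p_new
        ds = min(ds_max, step * 1.3)
        if not (lo - 1e-9 <= p_cur <= hi + 1e-9):
            break
    return branch


def odd_projection_basis(grid: RingGrid, axis: float) -> np.ndarray:
    """Orthonormal basis (columns) of profiles odd under reflection about ``axis``."""
    n = grid.n
    # reflection theta -> 2*axis - theta as an index permutation
    refl = np.rint((2.0 * axis - grid.theta + np.pi) / grid.dtheta).astype(int) % n
    cols = []
    for i in range(n):
        j = refl[i]
        if i < j:
            v = np.zeros(n)
            v[i], v[j] = 1.0, -1.0
            cols.append(v / np.sqrt(2.0))
    return np.array(cols).T


def _odd_leading_eig(u, p, problem, params, basis):
    kernel, _ = problem(p)
    J = jacobian(u, kernel, params)
    Jodd = basis.T @ J @ basis
    lam, vec = np.linalg.eig(Jodd)
    k = int(np.argmax(lam.real))
    return float(lam[k].real), basis @ vec[:, k].real


def detect_special_points(branch: Branch, problem: Problem,
                          params: NetworkParams,
                          symmetry_axis: Optional[float] = None,
                          param_tol: float = 0.5) -> Branch:
    """Annotate a branch with folds and symmetry-breaking branch points.

    Folds are flagged where the parameter reverses direction along
    arclength and refined by a quadratic fit of p(s).  On a branch of
    mirror-symmetric states (``symmetry_axis`` in radians), pitchforks are
    flagged where the leading eigenvalue restricted to the odd subspace
    crosses zero, refined by bisection in the parameter to ``param_tol``
    (degrees for stimulus parameters).
    """
    if len(branch.points) < 3:
        return branch
    pts = branch.points
    p = branch.params
    specials = list(branch.special_points)

    # folds: parameter direction reversal
    dp = np.diff(p)
    for k in range(1, len(dp)):
        if dp[k - 1] * dp[k] < 0:
            # quadratic fit of p against arclength index around the reversal
            idx = [k - 1, k, k + 1]
            s = np.array([0.0, 1.0, 2.0])
            coef = np.polyfit(s, p[idx], 2)
            s_star = np.clip(-coef[1] / (2.0 * coef[0]), 0.0, 2.0)
            p_star = float(np.polyval(coef, s_star))
            u_star = pts[k].u
            specials.append(SpecialPoint("fold", p_star, u_star))

    # symmetry-breaking branch points
    if symmetry_axis is not None:
        grid = problem(p[0])[0].grid
        basis = odd_projection_basis(grid, symmetry_axis)
        lam_odd = []
        for pt in pts:
            lam, _ = _odd_leading_eig(pt.u, pt.param, problem, params, basis)
            lam_odd.append(lam)
        for k in range(len(pts) - 1):
            if lam_odd[k] * lam_odd[k + 1] < 0:
                pa, ua, la = pts[k].param, pts[k].u, lam_odd[k]
                pb, ub = pts[k + 1].param, pts[k + 1].u
                while abs(pb - pa) > param_tol:
                    pm = 0.5 * (pa + pb)
                    kernel, inp = problem(pm)
                    um, _, ok = newton_polish(0.5 * (ua + ub), kernel, inp, params)
                    if not ok:
                        break
                    lm, _ = _odd_leading_eig(um, pm, problem, params, basis)
                    if la * lm <= 0:
                        pb, ub = pm, um
                    else:
                        pa, ua, la = pm, um, lm
                specials.append(SpecialPoint(
                    "branch_point", 0.5 * (pa + pb), 0.5 * (ua + ub)))

    specials.sort(key=lambda sp: sp.param)
    branch.special_points = specials
    return branch


def switch_branch(problem: Problem, special: SpecialPoint,
                  params: NetworkParams, symmetry_axis: float,
                  direction: float = 1.0, amplitude: float = 0.05,
                  dparam: float = 1.0) -> Tuple[SteadyState, float]:
    """Land on the asymmetric branch emanating from a pitchfork.

    The branch-point solution is perturbed along the critical odd
    eigenvector (sign ``direction``) and Newton-corrected at nearby
    parameter values on either side; returns the first corrected state that
    is distinct from the symmetric branch, with its parameter value.
    """
    if special.kind != "branch_point":
        raise ValueError("switch_branch needs a branch_point special point")
    grid = problem(special.param)[0].grid
    basis = odd_projection_basis(grid, symmetry_axis)
    _, vec = _odd_leading_eig(special.u, special.param, problem, params, basis)
    vec = vec / np.max(np.abs(vec))
    if amplitude == 0.0:
        kernel, inp = problem(special.param)
        return (newton_steady_state(special.u, kernel, inp, params),
                special.param)
    for dp in (dparam, -dparam, 2 * dparam, -2 * dparam):
        p_try = special.param + dp
        kernel, inp = problem(p_try)
        u_guess = special.u + direction * amplitude * vec
        u, res, ok = newton_polish(u_guess, kernel, inp, params)
        if not ok:
            continue
        # reject falling back onto the symmetric branch
        odd_part = basis @ (basis.T @ u)
        if np.max(np.abs(odd_part)) > 0.5 * amplitude:
            ss = SteadyState(u_star=u, residual=res, energy=energy(u, grid),
                             provenance="newton", converged=True)
            return ss, p_try
    raise NewtonError("could not land on the bifurcating branch; "
                      "retry with smaller amplitude")


# ---------------------------------------------------------------------------
# High-level assembly of the peak-separation bifurcation diagram
# ---------------------------------------------------------------------------

def ps_problem(spec_template, kernel_params, grid: RingGrid,
               params: NetworkParams) -> Problem:
    """Continuation problem in the peak separation PS (degrees).

    The kernel is fixed; the stimulus is rebuilt at each parameter value
    with the template's width, direction and relative strength.
    """
    from .kernel import build_kernel
    from .stimulus import make_input

    kernel = build_kernel(kernel_params, grid)

    def problem(ps: float):
        spec = replace(spec_template, ps=float(np.clip(ps, 1e-6, 180.0)))
        return kernel, make_input(spec, grid)

    return problem


@dataclass
class PSDiagram:
    """Branches of the symmetric-stimulus diagram in peak separation."""

    va: Branch
    wta: Branch
    tp: Branch

    def tristable_window(self) -> Tuple[float, float]:
        """PS interval over which VA, WTA and TP are simultaneously stable."""
        lo = max(b.stable_interval()[0] for b in (self.va, self.wta, self.tp))
        hi = min(b.stable_interval()[1] for b in (self.va, self.wta, self.tp))
        return lo, hi

    def unstable_energy_crossing(self) -> float:
        """PS at which the two unstable branch segments cross in energy.

        The post-fold (unstable) segments of the WTA and TP continuations
        are interpolated in energy against PS and the intersection located
        by bisection of the energy difference.
        """
        curves = []
        for br in (self.wta, self.tp):
            p, e, st = br.params, br.energies, br.stability
            seg = ~st
            if not seg.any():
                raise ValueError("branch has no unstable segment")
            curves.append((p[seg], e[seg]))
        (p1, e1), (p2, e2) = curves
        lo = max(p1.min(), p2.min())
        hi = min(p1.max(), p2.max())
        if not lo < hi:
            raise ValueError("unstable segments do not overlap in PS")
        ps_grid = np.linspace(lo, hi, 2001)

        def interp(p, e):
            order = np.argsort(p)
            return np.interp(ps_grid, p[order], e[order])

        diff = interp(p1, e1) - interp(p2, e2)
        sign = np.sign(diff)
        idx = np.flatnonzero(np.diff(sign) != 0)
        if idx.size == 0:
            raise ValueError("unstable branches do not cross in energy")
        k = idx[0]
        # linear root of the difference between neighboring grid points
        f0, f1 = diff[k], diff[k + 1]
        return float(ps_grid[k] + (ps_grid[k + 1] - ps_grid[k]) * f0 / (f0 - f1))


def _template_state(problem: Problem, ps: float, params: NetworkParams,
                    centers, width_rad: float, amp: float = 0.6):
    """Deterministic relaxation from a bump-template initial condition."""
    from .dynamics import find_steady_state

    kernel, inp = problem(ps)
    grid = kernel.grid
    u0 = np.zeros(grid.n)
    for c in centers:
        u0 += amp * np.exp(-0.5 * (wrap_angle(grid.theta - c) / width_rad) ** 2)
    det = replace(params, noise_eps=0.0)
    return find_steady_state(u0, kernel, inp, det, t_max=800.0)


def ps_diagram(spec_template, kernel_params, grid: RingGrid,
               params: NetworkParams, ps_low: float = 40.0,
               ps_high: float = 175.0, ds: float = 2.0,
               max_steps: int = 400) -> PSDiagram:
    """Trace the VA, WTA and TP branches of the symmetric-input diagram.

    The VA branch is continued upward from small PS (where integration is
    the only attractor).  The WTA and TP branches are found at large PS
    from biased initial conditions and continued downward through their
    folds, which yields their unstable continuations as well.
    """
    problem = ps_problem(spec_template, kernel_params, grid, params)
    va_dir = np.deg2rad(spec_template.va_direction)

    ss_va = _template_state(problem, ps_low, params, [va_dir],
                            np.deg2rad(max(spec_template.pw, 10.0)))
    va = continue_branch(problem, ss_va, ps_low, (ps_low, ps_high), params,
                         ds=ds, max_steps=max_steps, initial_direction=1.0)
    va = detect_special_points(va, problem, params, symmetry_axis=va_dir)

    half = 0.5 * np.deg2rad(ps_high)
    ss_wta = _template_state(problem, ps_high, params, [va_dir + half],
                             np.deg2rad(max(spec_template.pw, 10.0)))
    wta = continue_branch(problem, ss_wta, ps_high, (ps_low, ps_high), params,
                          ds=ds, max_steps=max_steps, initial_direction=-1.0)
    wta = detect_special_points(wta, problem, params)

    ss_tp = _template_state(problem, ps_high, params,
                            [va_dir - half, va_dir + half],
                            np.deg2rad(max(spec_template.pw, 10.0)))
    tp = continue_branch(problem, ss_tp, ps_high, (ps_low, ps_high), params,
                         ds=ds, max_steps=max_steps, initial_direction=-1.0)
    tp = detect_special_points(tp, problem, params, symmetry_axis=va_dir)

    return PSDiagram(va=va, wta=wta, tp=tp)
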