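"""Continuation, stability flags, special points and branch switching."""

import numpy as np
import pytest

from ringmt import (KernelParams, NetworkParams, RingGrid, StimulusSpec,
                    build_kernel, energy, make_input, newton_steady_state)
from ringmt.bifurcation import (continue_branch, ps_diagram, ps_problem,
                                switch_branch)
from ringmt.dynamics import euler_maruyama
from ringmt.stimulus import InputProfile


@pytest.fixture(scope="module")
def diagram202():
    """Peak-separation diagram in the low-inhibition regime (scaled grid)."""
    grid = RingGrid(202)
    return grid, ps_diagram(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                            KernelParams(alpha=0.0, beta=-10.0), grid,
                            NetworkParams(), ps_low=40.0, ps_high=175.0)


class TestNewtonSteadyState:
    def test_zero_input_zero_guess_returns_rest(self, grid202, kernel202):
        inp = InputProfile(spec=StimulusSpec(), grid=grid202,
                           values=np.zeros(grid202.n))
        ss = newton_steady_state(np.zeros(grid202.n), kernel202, inp,
                                 NetworkParams())
        assert np.allclose(ss.u_star, 0.0, atol=1e-12)
        assert ss.residual < 1e-10

    def test_succeeds_from_integration_endpoint(self, grid202, kernel202):
        inp = make_input(StimulusSpec(ps=120.0, pw=10.0), grid202)
        traj = euler_maruyama(np.full(grid202.n, 0.05), kernel202, inp,
                              NetworkParams(), t_end=150.0)
        ss = newton_steady_state(traj.final_state, kernel202, inp,
                                 NetworkParams())
        assert ss.residual < 1e-10


class TestContinuation:
    def test_branch_from_zero_input_gain_deforms_smoothly(self, grid202,
                                                          kernel202):
        # continuation in the input gain kappa_i starting from the trivial
        # rest state at kappa_i = 0
        base = make_input(StimulusSpec(va_direction=0.0, pw=10.0,
                                       n_components=1), grid202)
        params = NetworkParams()

        def problem(kappa):
            # clip: finite-difference probes may step slightly below zero
            k = max(float(kappa), 0.0)
            return kernel202, InputProfile(spec=base.spec, grid=grid202,
                                           values=base.values * k / 0.1)

        ss0 = newton_steady_state(np.zeros(grid202.n), kernel202,
                                  InputProfile(spec=base.spec, grid=grid202,
                                               values=np.zeros(grid202.n)),
                                  params)
        br = continue_branch(problem, ss0, 0.0, (0.0, 0.05), params,
                             parameter="kappa_i", ds=0.01, ds_max=0.02)
        assert len(br.points) >= 4
        assert br.points[0].energy == pytest.approx(0.0, abs=1e-10)
        # energy grows continuously with the drive
        de = np.abs(np.diff(br.energies))
        assert np.all(de < 0.5)

    def test_three_branch_diagram_topology(self, diagram202):
        _, diag = diagram202
        lo, hi = diag.tristable_window()
        # one stable branch at small separation, three in the window,
        # two (winner-take-all and transparency) at large separation
        assert lo < hi
        assert diag.va.stable_interval()[0] <= 45.0
        assert diag.wta.stable_interval()[1] >= 170.0
        assert diag.tp.stable_interval()[1] >= 170.0
        # energy ordering in the coexistence window: VA > WTA > TP
        mid = 0.5 * (lo + hi)

        def energy_at(branch, stable):
            p, e, st = branch.params, branch.energies, branch.stability
            sel = st == stable
            return float(np.interp(mid, p[sel][np.argsort(p[sel])],
                                   e[sel][np.argsort(p[sel])]))

        assert (energy_at(diag.va, True) > energy_at(diag.wta, True)
                > energy_at(diag.tp, True))

    def test_special_points_found(self, diagram202):
        _, diag = diagram202
        kinds_va = [sp.kind for sp in diag.va.special_points]
        assert "branch_point" in kinds_va
        assert any(sp.kind == "fold" for sp in diag.wta.special_points)
        assert any(sp.kind == "fold" for sp in diag.tp.special_points)

    def test_residual_contract_along_branches(self, diagram202):
        grid, diag = diagram202
        problem = ps_problem(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                             KernelParams(alpha=0.0, beta=-10.0), grid,
                             NetworkParams())
        from ringmt.dynamics import rhs
        for br in (diag.va, diag.wta, diag.tp):
            for pt in br.points[:: max(1, len(br.points) // 5)]:
                kernel, inp = problem(pt.param)
                res = np.max(np.abs(rhs(pt.u, kernel, inp, NetworkParams())))
                assert res < 1e-8

    def test_stability_flags_agree_with_integration(self, diagram202):
        grid, diag = diagram202
        problem = ps_problem(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                             KernelParams(alpha=0.0, beta=-10.0), grid,
                             NetworkParams())
        rng = np.random.default_rng(0)

        def drift_after_perturbation(pt):
            kernel, inp = problem(pt.param)
            u0 = pt.u + rng.normal(0.0, 1e-4, grid.n)
            traj = euler_maruyama(u0, kernel, inp, NetworkParams(),
                                  t_end=400.0, record_every=400.0)
            return np.max(np.abs(traj.final_state - pt.u))

        stable_pt = next(pt for pt in diag.wta.points if pt.stable)
        unstable_pt = max((pt for pt in diag.wta.points if not pt.stable),
                          key=lambda pt: pt.eig_max)
        assert drift_after_perturbation(stable_pt) < 1e-3
        assert drift_after_perturbation(unstable_pt) > 1e-2

    def test_pitchfork_switch_yields_mirror_pair(self, diagram202):
        grid, diag = diagram202
        problem = ps_problem(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                             KernelParams(alpha=0.0, beta=-10.0), grid,
                             NetworkParams())
        bp = next(sp for sp in diag.va.special_points
                  if sp.kind == "branch_point")
        plus, p_plus = switch_branch(problem, bp, NetworkParams(),
                                     symmetry_axis=0.0, direction=+1.0)
        minus, p_minus = switch_branch(problem, bp, NetworkParams(),
                                      symmetry_axis=0.0, direction=-1.0)
        assert p_plus == p_minus
        refl = np.array([grid.index_of(-t) for t in grid.theta])
        assert np.max(np.abs(plus.u_star - minus.u_star[refl])) < 1e-6
        # genuinely asymmetric states
        assert np.max(np.abs(plus.u_star - plus.u_star[refl])) > 1e-3

    def test_zero_perturbation_returns_branch_point(self, diagram202):
        grid, diag = diagram202
        problem = ps_problem(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                             KernelParams(alpha=0.0, beta=-10.0), grid,
                             NetworkParams())
        bp = next(sp for sp in diag.va.special_points
                  if sp.kind == "branch_point")
        ss, p = switch_branch(problem, bp, NetworkParams(), symmetry_axis=0.0,
                              amplitude=0.0)
        assert p == bp.param
        # the stored branch-point profile is a bisection midpoint; the
        # Newton-corrected state stays within that approximation error
        assert np.max(np.abs(ss.u_star - bp.u)) < 5e-3
        assert ss.residual < 1e-10

    def test_switch_requires_branch_point(self, diagram202):
        grid, diag = diagram202
        problem = ps_problem(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                             KernelParams(alpha=0.0, beta=-10.0), grid,
                             NetworkParams())
        fold = next(sp for sp in diag.wta.special_points if sp.kind == "fold")
        with pytest.raises(ValueError):
            switch_branch(problem, fold, NetworkParams(), symmetry_axis=0.0)
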