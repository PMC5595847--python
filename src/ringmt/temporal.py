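"""Tuning dynamics: direction sweeps and the slow inhibition ramp.

Two analyses connect the model to physiological tuning measurements.

*Direction sweeps* emulate the experimental protocol of presenting the same
stimulus at many pattern directions: one steady state per direction yields
a joint matrix whose columns are population tuning curves (response of all
units to one stimulus) and whose rows are single-unit tuning curves
(response of one unit across stimulus directions).  For deterministic,
rotation-equivariant dynamics the matrix is circulant; multistability and
noise break this and make single-unit tuning fluctuate across directions.

*Inhibition ramps* let the total inhibition strength grow with a slow time
constant (tens of ms) during a single trial, so the early network is
excitation-dominated (favoring the integrated, vector-average state) and
the late network is inhibition-dominated (favoring segmentation: WTA or
two-peak states).  The trajectory is classified at regular sample times to
produce a label track.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import SolutionLabel, classify
from .dynamics import (NetworkParams, Trajectory, euler_maruyama,
                       find_steady_state, random_initial_condition)
from .grid import RingGrid
from .kernel import (InhibitionSchedule, Kernel, KernelParams,
                     inhibition_at_time, kernel_with_inhibition)
from .stimulus import StimulusSpec, make_input


@dataclass(frozen=True)
class TuningMatrix:
    """Joint population-vs-single-unit tuning over a direction sweep."""

    stim_directions: np.ndarray  # degrees
    response: np.ndarray = field(repr=False)  # (n_units, n_directions)
    labels: List[SolutionLabel] = field(repr=False, default_factory=list)
    converged: np.ndarray = field(repr=False, default=None)
    grid: Optional[RingGrid] = None
    spec_template: Optional[StimulusSpec] = None
    kernel_params: Optional[KernelParams] = None

    def population_tuning(self, direction_index: int) -> np.ndarray:
        """Column: response of every unit to one stimulus direction."""
        return self.response[:, direction_index]

    def single_unit_tuning(self, unit_index: int) -> np.ndarray:
        """Row: response of one unit across stimulus directions."""
        return self.response[unit_index, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.response,
                            index=np.rad2deg(self.grid.theta) if self.grid
                            else None,
                            columns=self.stim_directions)


def tuning_sweep(spec_template: StimulusSpec, n_directions: int,
                 kernel: Kernel, params: NetworkParams, grid: RingGrid,
                 mode: str = "deterministic", seed: int = 0,
                 t_max: float = 600.0, **classify_kwargs) -> TuningMatrix:
    """One steady state per stimulus direction on an even sweep of the ring.

    Directions are snapped to grid multiples so that, for deterministic
    dynamics, rotation equivariance makes the response matrix circulant.
    In ``stochastic`` mode each direction gets an independent seeded noise
    path and random initial condition.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    step = grid.n // n_directions if grid.n % n_directions == 0 else None
    if step is not None:
        dirs_rad = grid.theta[::step][:n_directions]
    else:
        raw = -np.pi + 2 * np.pi * np.arange(n_directions) / n_directions
        dirs_rad = grid.theta[[grid.index_of(d) for d in raw]]
    dirs_deg = np.rad2deg(dirs_rad)

    det = mode == "deterministic"
    run_params = replace(params, noise_eps=0.0) if det else params
    response = np.zeros((grid.n, n_directions))
    labels: List[SolutionLabel] = []
    conv = np.zeros(n_directions, dtype=bool)
    for j, d in enumerate(dirs_deg):
        spec = spec_template.with_direction(float(d))
        inp = make_input(spec, grid)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
        if det:
            u0 = np.full(grid.n, 0.5 * params.ic_amp)
        else:
            u0 = random_initial_condition(grid, params, rng)
        ss = find_steady_state(u0, kernel, inp, run_params, t_max=t_max, rng=rng)
        response[:, j] = ss.u_star
        conv[j] = ss.converged
        labels.append(classify(ss.u_star, spec, grid, converged=ss.converged,
                               **classify_kwargs))
    return TuningMatrix(stim_directions=dirs_deg, response=response,
                        labels=labels, converged=conv, grid=grid,
                        spec_template=spec_template,
                        kernel_params=kernel.params)


@dataclass(frozen=True)
class RampTrajectory:
    """Trajectory under a slow inhibition ramp with label track."""

    trajectory: Trajectory
    schedule: InhibitionSchedule
    sample_times: np.ndarray
    g_i_series: np.ndarray
    labels: List[SolutionLabel] = field(repr=False, default_factory=list)

    @property
    def label_track(self) -> List[str]:
        return [lab.label for lab in self.labels]


def simulate_ramp(stimulus: StimulusSpec, kernel_params: KernelParams,
                  schedule: InhibitionSchedule, params: NetworkParams,
                  grid: RingGrid, t_end: float = 600.0,
                  sample_every: float = 10.0, seed: int = 0,
                  u0: Optional[np.ndarray] = None,
                  **classify_kwargs) -> RampTrajectory:
    """Integrate with time-varying inhibition g_i(t) and classify over time.

    Only the inhibitory part of the kernel follows the schedule; excitation
    is fixed.  Integration is fixed-step (Euler, or Euler-Maruyama when
    ``noise_eps > 0``) with the kernel's inhibition level updated every
    step.
    """
    inp = make_input(stimulus, grid)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if u0 is None:
        u0 = random_initial_condition(grid, params, rng)

    # split the kernel into fixed excitatory and unit-strength inhibitory
    # parts so the per-step kernel is a cheap linear combination
    exc = kernel_with_inhibition(kernel_params, grid, 0.0).values
    inh = -(kernel_with_inhibition(kernel_params, grid, 1.0).values - exc)

    def kernel_at(t: float) -> Kernel:
        g_i = float(inhibition_at_time(t, schedule))
        return Kernel(params=kernel_params, grid=grid, values=exc - g_i * inh)

    traj = euler_maruyama(u0, kernel_at(0.0), inp, params, t_end=t_end,
                          rng=rng, record_every=sample_every,
                          kernel_at_time=kernel_at)
    times = traj.times
    g_series = inhibition_at_time(times, schedule)
    labels = [classify(traj.states[k], stimulus, grid, **classify_kwargs)
              for k in range(len(times))]
    return RampTrajectory(trajectory=traj, schedule=schedule,
                          sample_times=times, g_i_series=np.asarray(g_series),
                          labels=labels)


def _sustained_labels(track: List[str], min_run: int = 3) -> List[Tuple[str, int]]:
    """(label, start_index) of runs lasting at least ``min_run`` samples."""
    out: List[Tuple[str, int]] = []
    k = 0
    while k < len(track):
        j = k
        while j < len(track) and track[j] == track[k]:
            j += 1
        if j - k >= min_run and (not out or out[-1][0] != track[k]):
            out.append((track[k], k))
        k = j
    return out


def ramp_summary(ramp: RampTrajectory, min_run: int = 3,
                 ignore: Tuple[str, ...] = ("UNTUNED", "NONCONVERGED"),
                 ) -> Dict[str, object]:
    """Early label, late label and first sustained transition time of a ramp."""
    track = ramp.label_track
    runs = [(lab, k) for lab, k in _sustained_labels(track, min_run)
            if lab not in ignore]
    early = runs[0][0] if runs else None
    late = runs[-1][0] if runs else None
    transition = np.nan
    if len(runs) >= 2:
        transition = float(ramp.sample_times[runs[1][1]])
    return {"early_label": early, "late_label": late,
            "transition_time_ms": transition}


def ramp_sensitivity(stimulus: StimulusSpec, kernel_params: KernelParams,
                     params: NetworkParams, grid: RingGrid,
                     onsets: np.ndarray, tau_ls: np.ndarray,
                     g_i_finals: np.ndarray, g_i_low: float = 0.0,
                     t_end: float = 600.0, sample_every: float = 10.0,
                     seed: int = 0, min_run: int = 3) -> pd.DataFrame:
    """Sweep (onset, tau_l, final strength) and tabulate the label dynamics.

    Returns a DataFrame with one row per setting: early label, late label
    and the first sustained transition time (NaN when no transition occurs
    within ``t_end``).
    """
    rows = []
    for onset, tau_l, g_fin in product(onsets, tau_ls, g_i_finals):
        sched = InhibitionSchedule(g_i_low=g_i_low, g_i_final=float(g_fin),
                                   tau_l=float(tau_l), onset=float(onset))
        ramp = simulate_ramp(stimulus, kernel_params, sched, params, grid,
                             t_end=t_end, sample_every=sample_every, seed=seed)
        row = {"onset": float(onset), "tau_l": float(tau_l),
               "g_i_final": float(g_fin)}
        row.update(ramp_summary(ramp, min_run=min_run))
        rows.append(row)
    return pd.DataFrame(rows)
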