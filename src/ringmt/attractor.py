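"""Attractor-strength maps and migration (transition) percentages.

Where several tuning states coexist, the *attractor strength* of each state
is estimated empirically as the probability of converging to it from random
initial conditions — repeated seeded simulations per parameter cell, each
classified at its steady state.  Maps are computed on stimulus (PS x PW) or
connectivity (alpha x beta) grids; the WTA and SB labels are pooled, as are
T and TP.

A *migration* between two stimulus conditions is quantified by binarizing
the two maps at a support threshold and measuring the overlap of the
supporting connectivity regions relative to the whole parameter plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from .classify import classify
from .dynamics import NetworkParams, find_steady_state, random_initial_condition
from .grid import RingGrid
from .kernel import KernelParams, build_kernel
from .stimulus import StimulusSpec, make_input

#: Labels used in probability maps (WTA/SB and T/TP pooled).
MAP_LABELS = ("VA", "WTA_SB", "TP", "UNTUNED", "NONCONVERGED")

_POOL = {"VA": "VA", "WTA": "WTA_SB", "SB": "WTA_SB", "TP": "TP",
         "UNTUNED": "UNTUNED", "NONCONVERGED": "NONCONVERGED"}


def _cell_rng(seed: int, *indices: int) -> np.random.Generator:
    """Independent generator derived from a master seed and cell indices."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=indices))


def attractor_strength(stimulus: StimulusSpec, kernel_params: KernelParams,
                       network_params: NetworkParams, grid: RingGrid,
                       n_trials: int = 100, seed: int = 0,
                       t_max: float = 600.0,
                       tol_dir: float = 20.0, sb_frac: float = 0.1,
                       count_nonconverged: bool = True,
                       ) -> Dict[str, float]:
    """Empirical probability of each pooled label over repeated trials.

    Each trial draws a fresh low-amplitude random initial condition (and an
    independent noise path when ``noise_eps > 0``), relaxes to a steady
    state and classifies it.  Deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    kernel = build_kernel(kernel_params, grid)
    inp = make_input(stimulus, grid)
    counts = {lab: 0 for lab in MAP_LABELS}
    for trial in range(n_trials):
        rng = _cell_rng(seed, trial)
        u0 = random_initial_condition(grid, network_params, rng)
        ss = find_steady_state(u0, kernel, inp, network_params,
                               t_max=t_max, rng=rng)
        lab = classify(ss.u_star, stimulus, grid, tol_dir=tol_dir,
                       sb_frac=sb_frac, converged=ss.converged)
        counts[_POOL[lab.label]] += 1
    denom = n_trials if count_nonconverged else max(
        1, n_trials - counts["NONCONVERGED"])
    return {lab: counts[lab] / denom for lab in MAP_LABELS}


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-label convergence probabilities over a 2-D parameter grid."""

    axis_names: Tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    probs: Dict[str, np.ndarray] = field(repr=False)
    n_trials: int = 0
    seed: int = 0

    def __post_init__(self):
        shape = (len(self.axis1), len(self.axis2))
        for lab, arr in self.probs.items():
            if arr.shape != shape:
                raise ValueError(f"probability array for {lab} has wrong shape")
        total = sum(self.probs[lab] for lab in MAP_LABELS)
        if not np.allclose(total, 1.0, atol=1e-12):
            raise ValueError("label probabilities must sum to 1 in every cell")

    def same_axes(self, other: "ProbabilityMap") -> bool:
        return (self.axis_names == other.axis_names
                and np.array_equal(self.axis1, other.axis1)
                and np.array_equal(self.axis2, other.axis2))


_AXIS_SETTERS = {
    "ps": lambda stim, ker, v: (replace(stim, ps=v), ker),
    "pw": lambda stim, ker, v: (replace(stim, pw=v), ker),
    "alpha": lambda stim, ker, v: (stim, replace(ker, alpha=v)),
    "beta": lambda stim, ker, v: (stim, replace(ker, beta=v)),
}


def probability_map(axis1: Tuple[str, np.ndarray], axis2: Tuple[str, np.ndarray],
                    stimulus: StimulusSpec, kernel_params: KernelParams,
                    network_params: NetworkParams, grid: RingGrid,
                    n_trials: int = 100, seed: int = 0,
                    **strength_kwargs) -> ProbabilityMap:
    """Attractor strength on the product grid ``axis1 x axis2``.

    Axis names are any of ``ps``, ``pw`` (stimulus) or ``alpha``, ``beta``
    (connectivity).  Per-cell seeds are derived from the master seed and the
    cell indices, so the result is independent of evaluation order.
    """
    (name1, vals1), (name2, vals2) = axis1, axis2
    for name in (name1, name2):
        if name not in _AXIS_SETTERS:
            raise ValueError(f"unknown axis {name!r}")
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("axis grids must be nonempty")
    probs = {lab: np.zeros((vals1.size, vals2.size)) for lab in MAP_LABELS}
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            stim, ker = _AXIS_SETTERS[name1](stimulus, kernel_params, v1)
            stim, ker = _AXIS_SETTERS[name2](stim, ker, v2)
            cell_seed = np.random.SeedSequence(seed, spawn_key=(i, j))
            freqs = attractor_strength(
                stim, ker, network_params, grid, n_trials=n_trials,
                seed=int(cell_seed.generate_state(1)[0] % (2 ** 31)),
                **strength_kwargs)
            for lab in MAP_LABELS:
                probs[lab][i, j] = freqs[lab]
    return ProbabilityMap(axis_names=(name1, name2), axis1=vals1, axis2=vals2,
                          probs=probs, n_trials=n_trials, seed=seed)


@dataclass(frozen=True)
class MigrationResult:
    """Overlap percentages of thresholded support regions between conditions."""

    condition_pair: Tuple[StimulusSpec, StimulusSpec]
    threshold: float
    percentages: Dict[Tuple[str, str], float]

    def get(self, label_a: str, label_b: str) -> float:
        return self.percentages[(label_a, label_b)]


def migration(map_a: ProbabilityMap, map_b: ProbabilityMap,
              condition_pair: Tuple[StimulusSpec, StimulusSpec],
              threshold: float = 0.5,
              labels: Tuple[str, ...] = ("VA", "WTA_SB", "TP"),
              ) -> MigrationResult:
    """Transition percentages between two stimulus conditions.

    For each ordered label pair (x under A, y under B) the two probability
    maps are binarized at ``threshold`` and the intersection area is
    reported as a percentage of the full parameter plane.
    """
    if not map_a.same_axes(map_b):
        raise ValueError("maps must share the same parameter axes")
    total = map_a.axis1.size * map_a.axis2.size
    pct = {}
    for la in labels:
        sup_a = map_a.probs[la] >= threshold
        for lb in labels:
            sup_b = map_b.probs[lb] >= threshold
            pct[(la, lb)] = 100.0 * np.count_nonzero(sup_a & sup_b) / total
    return MigrationResult(condition_pair=condition_pair, threshold=threshold,
                           percentages=pct)
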