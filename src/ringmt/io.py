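"""Serialization of results to CSV/JSON and run manifests."""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .attractor import MAP_LABELS, MigrationResult, ProbabilityMap
from .bifurcation import Branch
from .classify import SolutionLabel
from .dynamics import SteadyState, Trajectory, energy
from .grid import RingGrid
from .kernel import Kernel
from .stimulus import InputProfile
from .temporal import RampTrajectory, TuningMatrix


def kernel_to_csv(kernel: Kernel, path) -> None:
    pd.DataFrame({"theta_deg": kernel.grid.theta_deg,
                  "J_value": kernel.values}).to_csv(path, index=False)


def input_to_csv(profile: InputProfile, path) -> None:
    pd.DataFrame({"theta_deg": profile.grid.theta_deg,
                  "I_value": profile.values}).to_csv(path, index=False)


def steady_state_to_csv(ss: SteadyState, grid: RingGrid, path) -> None:
    pd.DataFrame({"theta_deg": grid.theta_deg,
                  "u_star": ss.u_star}).to_csv(path, index=False)


def trajectory_summary_to_csv(traj: Trajectory, grid: RingGrid, path) -> None:
    from .classify import find_peaks

    rows = []
    for t, u in zip(traj.times, traj.states):
        peaks = find_peaks(u, grid)
        rows.append({
            "time_ms": t,
            "energy": energy(u, grid),
            "peak1_deg": np.rad2deg(peaks[0][0]) if peaks else np.nan,
            "peak2_deg": np.rad2deg(peaks[1][0]) if len(peaks) > 1 else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def trajectory_states_to_npy(traj: Trajectory, path) -> None:
    np.save(path, traj.states)


def branch_to_csv(branch: Branch, path) -> None:
    special = {round(sp.param, 6): sp.kind for sp in branch.special_points}
    df = pd.DataFrame({
        "param": branch.params,
        "energy": branch.energies,
        "max_real_eig": [pt.eig_max for pt in branch.points],
        "stable": branch.stability.astype(int),
    })
    df["special_type"] = ""
    pd.DataFrame(df).to_csv(path, index=False)
    # special points in a side-car so the per-point table stays rectangular
    side = Path(str(path)).with_suffix(".special.json")
    side.write_text(json.dumps(
        [{"kind": sp.kind, "param": sp.param} for sp in branch.special_points],
        indent=2))


def branch_states_to_npy(branch: Branch, path) -> None:
    np.save(path, np.array([pt.u for pt in branch.points]))


def probability_map_to_csv(pmap: ProbabilityMap, out_dir, stem: str = "map",
                           ) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a1, a2 = np.meshgrid(pmap.axis1, pmap.axis2, indexing="ij")
    for lab in MAP_LABELS:
        pd.DataFrame({pmap.axis_names[0]: a1.ravel(),
                      pmap.axis_names[1]: a2.ravel(),
                      "probability": pmap.probs[lab].ravel()}
                     ).to_csv(out / f"{stem}_{lab}.csv", index=False)
    manifest = {"axes": list(pmap.axis_names),
                "axis1": pmap.axis1.tolist(), "axis2": pmap.axis2.tolist(),
                "n_trials": pmap.n_trials, "seed": pmap.seed,
                "labels": list(MAP_LABELS)}
    (out / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))


def migration_to_json(result: MigrationResult, path) -> None:
    payload = {
        "threshold": result.threshold,
        "percentages": {f"{a}->{b}": v
                        for (a, b), v in result.percentages.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def label_to_dict(label: SolutionLabel) -> Dict:
    return {"label": label.label,
            "peaks": [{"direction_deg": float(np.rad2deg(p)),
                       "height": float(h)} for p, h in label.peaks],
            "dominant_component_deg": (
                float(np.rad2deg(label.dominant_component))
                if label.dominant_component is not None else None)}


def tuning_matrix_to_csv(tm: TuningMatrix, path) -> None:
    tm.to_frame().to_csv(path)


def ramp_to_csv(ramp: RampTrajectory, grid: RingGrid, path) -> None:
    from .classify import find_peaks

    rows = []
    for k, t in enumerate(ramp.sample_times):
        u = ramp.trajectory.states[k]
        peaks = find_peaks(u, grid)
        rows.append({
            "time_ms": t, "g_i": ramp.g_i_series[k],
            "label": ramp.labels[k].label,
            "peak1_deg": np.rad2deg(peaks[0][0]) if peaks else np.nan,
            "peak2_deg": np.rad2deg(peaks[1][0]) if len(peaks) > 1 else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(out_dir, command: str, config_values: dict,
                   seed: Optional[int], t_start: float) -> None:
    """JSON run manifest: inputs, seed, version, wall time."""
    from . import __version__

    payload = {
        "command": command,
        "config": {k: (v if not isinstance(v, (np.floating, np.integer))
                       else float(v)) for k, v in config_values.items()},
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "wall_time_s": time.time() - t_start,
    }
    Path(out_dir, "manifest.json").write_text(json.dumps(payload, indent=2))
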