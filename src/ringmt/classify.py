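"""Labeling of converged population tuning curves.

Relative to a two-component stimulus, a steady-state profile is labeled

- ``VA``   one peak at the vector-average (mean) direction — integration;
- ``WTA``  one peak at a component direction, other component suppressed;
- ``SB``   WTA with a residual positive bump at the suppressed component;
- ``TP``   two peaks, one near each component — transparency;
- ``UNTUNED``      no qualifying peak, or peaks matching neither rule;
- ``NONCONVERGED`` the dynamics did not settle.

Peak directions may be repulsed a few degrees outward from the component
directions, so the direction tolerance (default 20 deg) is chosen to absorb
motion repulsion while still separating the vector average from the
components down to PS = 60 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .grid import RingGrid, wrap_angle
from .stimulus import StimulusSpec

#: Canonical label strings.
LABELS = ("VA", "WTA", "SB", "TP", "UNTUNED", "NONCONVERGED")


@dataclass(frozen=True)
class SolutionLabel:
    label: str
    peaks: List[Tuple[float, float]] = field(default_factory=list)
    dominant_component: Optional[float] = None  # radians, for WTA/SB

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _raw_peaks(u: np.ndarray) -> np.ndarray:
    """Indices of periodic local maxima (strict on the left, >= on the right)."""
    left = np.roll(u, 1)
    right = np.roll(u, -1)
    return np.flatnonzero((u > left) & (u >= right))


def _prominence(u: np.ndarray, idx: int) -> float:
    """Topographic prominence of the local maximum at ``idx`` on the ring."""
    n = u.size
    h = u[idx]
    mins = []
    for step in (1, -1):
        lowest = h
        j = idx
        for _ in range(n - 1):
            j = (j + step) % n
            if u[j] > h:
                break
            lowest = min(lowest, u[j])
        mins.append(lowest)
    return h - max(mins)


def _refine(u: np.ndarray, grid: RingGrid, idx: int) -> Tuple[float, float]:
    """Sub-grid peak position/height by quadratic fit through three points."""
    n = u.size
    y0, y1, y2 = u[(idx - 1) % n], u[idx], u[(idx + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(grid.theta[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    pos = wrap_angle(grid.theta[idx] + delta * grid.dtheta)
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(pos), float(height)


def _ring_saddle(u: np.ndarray, i: int, j: int) -> float:
    """Minimum of ``u`` on the arc from index i to index j (forward)."""
    n = u.size
    if i <= j:
        return float(np.min(u[i:j + 1]))
    return float(min(np.min(u[i:]), np.min(u[:j + 1])))


def _merge_clusters(u: np.ndarray, maxima: np.ndarray,
                    merge_level: float) -> List[List[int]]:
    """Group ring-adjacent maxima whose separating saddle is shallow.

    Two neighboring maxima belong to the same broad peak when the lower one
    rises less than ``merge_level`` above the saddle between them —
    a bimodality criterion: a slightly dimpled plateau is one peak, two
    well-separated bumps are two.
    """
    m = len(maxima)
    if m == 1:
        return [[int(maxima[0])]]
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in range(m):
        i, j = int(maxima[k]), int(maxima[(k + 1) % m])
        saddle = _ring_saddle(u, i, j)
        if min(u[i], u[j]) - saddle < merge_level:
            parent[find(k)] = find((k + 1) % m)
    groups: dict = {}
    for k in range(m):
        groups.setdefault(find(k), []).append(int(maxima[k]))
    return list(groups.values())


def _cluster_position(u: np.ndarray, grid: RingGrid, members: List[int],
                      level: float) -> Tuple[float, float]:
    """Peak position of a merged cluster: circular centroid of the activity
    above ``level`` in the connected region containing the cluster top."""
    top = members[int(np.argmax(u[members]))]
    if len(members) == 1:
        return _refine(u, grid, top)
    n = u.size
    mask = np.zeros(n, dtype=bool)
    mask[top] = True
    for step in (1, -1):
        j = top
        for _ in range(n - 1):
            j = (j + step) % n
            if u[j] <= level:
                break
            mask[j] = True
    w = np.where(mask, np.maximum(u - level, 0.0), 0.0)
    z = np.sum(w * np.exp(1j * grid.theta))
    if np.abs(z) < 1e-30:
        return _refine(u, grid, top)
    _, height = _refine(u, grid, top)
    return float(np.angle(z)), height


def find_peaks(u_star: np.ndarray, grid: RingGrid,
               min_height_frac: float = 0.1,
               min_prominence_frac: float = 0.05,
               merge_frac: float = 0.25) -> List[Tuple[float, float]]:
    """Qualifying peaks of a profile: list of (direction_rad, height).

    Local maxima separated by saddles shallower than ``merge_frac`` of the
    profile maximum are merged into a single broad peak at their circular
    centroid (a slightly dimpled integrated profile is one peak, not two).
    A merged peak qualifies if its height exceeds ``min_height_frac`` and
    its prominence exceeds ``min_prominence_frac``, both relative to the
    profile maximum.  Peaks are sorted by height, descending.  An
    all-nonpositive profile has no peaks.
    """
    u = np.asarray(u_star, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("profile must be finite")
    umax = float(np.max(u))
    if umax <= 0:
        return []
    maxima = _raw_peaks(u)
    if maxima.size == 0:  # constant profile
        return []
    out = []
    for members in _merge_clusters(u, maxima, merge_frac * umax):
        top = members[int(np.argmax(u[members]))]
        height = float(u[top])
        if height < min_height_frac * umax:
            continue
        if _prominence(u, top) < min_prominence_frac * umax:
            continue
        out.append(_cluster_position(u, grid, members,
                                     height - merge_frac * umax))
    out.sort(key=lambda ph: -ph[1])
    return out


def _near(angle: float, target: float, tol_rad: float) -> bool:
    return abs(wrap_angle(angle - target)) <= tol_rad


def classify(u_star: np.ndarray, stimulus: StimulusSpec, grid: RingGrid,
             tol_dir: float = 20.0, sb_frac: float = 0.1,
             min_height_frac: float = 0.1,
             min_prominence_frac: float = 0.05,
             merge_frac: float = 0.25,
             tp_ratio: float = 0.5,
             converged: bool = True) -> SolutionLabel:
    """Label a steady-state profile relative to its driving stimulus.

    ``tol_dir`` is the direction tolerance in degrees; ``sb_frac`` the
    relative height of a residual bump at the suppressed component above
    which a WTA state is downgraded to side-biased (SB); ``tp_ratio`` the
    secondary/primary height ratio above which two component-aligned peaks
    count as transparency rather than a side-biased residual.
    """
    if not converged:
        return SolutionLabel("NONCONVERGED")
    peaks = find_peaks(u_star, grid, min_height_frac, min_prominence_frac,
                       merge_frac)
    if not peaks:
        return SolutionLabel("UNTUNED")
    tol = np.deg2rad(tol_dir)
    va = np.deg2rad(stimulus.va_direction)
    comps = stimulus.component_directions_rad

    if stimulus.n_components == 1:
        pos, _ = peaks[0]
        lab = "VA" if len(peaks) == 1 and _near(pos, va, tol) else "UNTUNED"
        return SolutionLabel(lab, peaks=peaks)

    c1, c2 = comps  # stronger first
    if len(peaks) >= 2:
        (p1, h1), (p2, h2) = peaks[0], peaks[1]
        hit11 = _near(p1, c1, tol) and _near(p2, c2, tol)
        hit12 = _near(p1, c2, tol) and _near(p2, c1, tol)
        # transparency peaks repulse outward; tol_dir absorbs the shift
        if (hit11 or hit12) and h2 >= tp_ratio * h1:
            return SolutionLabel("TP", peaks=peaks)
        # fall through with the dominant peak: a low secondary bump is a
        # side-biased residual, not a transparency peak
        peaks = peaks[:1]

    pos, height = peaks[0]
    if _near(pos, va, tol):
        return SolutionLabel("VA", peaks=peaks)
    for comp, other in ((c1, c2), (c2, c1)):
        if _near(pos, comp, tol):
            # residual positive bump at the suppressed component? inspect raw
            # local maxima without the qualifying-height filter
            u = np.asarray(u_star, dtype=float)
            residual = 0.0
            for idx in _raw_peaks(u):
                if u[idx] > 0 and _near(grid.theta[idx], other, tol):
                    residual = max(residual, float(u[idx]))
            label = "SB" if residual >= sb_frac * height else "WTA"
            return SolutionLabel(label, peaks=peaks,
                                 dominant_component=float(comp))
    return SolutionLabel("UNTUNED", peaks=peaks)
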