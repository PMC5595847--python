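# ringmt

A recurrent ring-network (neural field) model of how visual motion area MT
integrates or segments two superimposed motion directions.

When a stimulus contains two motion components (a bidirectional random-dot
field, or a plaid made of two gratings), direction-selective MT populations
are observed to do one of three things: encode the mean direction (vector
average, **VA** — motion integration), encode a single component while
suppressing the other (winner-take-all, **WTA**, or its side-biased variant
**SB**), or encode both components at once (transparency / two-peaked,
**T/TP**). `ringmt` implements a rate-based ring attractor network in which
all three behaviors arise as coexisting steady states of a single circuit,
with their relative strength controlled by the stimulus (peak separation PS
and peak width PW of the two input bumps) and by the excitation/inhibition
balance of the recurrent connectivity.

The package is aimed at computational neuroscientists who want to simulate
the model, map its attractor structure, and reproduce its bifurcation
analysis from Python.

## Model

Population activity `u(θ, t)` on the ring of motion directions
`θ ∈ [−π, π)` follows the Amari-type field equation

    τ_p ∂u(θ,t)/∂t = −u(θ) + ∫ J(θ−φ) S(μ u(φ), th) dφ + κ_i I_ext(θ),

with a logistic rate function shifted so that `S(0) = 0`,

    S(μu, th) = 1/(1 + e^{−μu+th}) − 1/(1 + e^{th}),   μ = 16, th = 3,

and a difference-of-Gaussians connectivity with global inhibition,

    J(θ) = g_e G(θ, σ_e) − g_i G(θ, σ_i),   σ_i = 10π (effectively flat).

A two-parameter family explores the connectivity: `α ∈ [0, 1]` interpolates
the excitation width `σ_e` from 11.5° to 60°, and `β ∈ [−10, 15]` offsets
the inhibition strength. The gains follow `g_e = exp(−σ_e²/2)` (radians)
and `g_i = (1 + g_e)/0.0797…`, which pins the ring integral of the `β = 0`
kernel to −1. Stimuli are sums of peak-normalized Gaussian bumps, one per
motion component, parameterized by PS, PW and the relative strength of the
weaker component.

On top of the dynamics the package provides:

- steady-state classification into VA / WTA / SB / TP / untuned
  (`ringmt.classify`),
- attractor-strength maps: convergence probability per class from repeated
  seeded stochastic trials over stimulus or connectivity grids, and
  migration overlap between stimulus conditions (`ringmt.attractor`),
- pseudo-arclength continuation with Jacobian-eigenvalue stability, fold
  and pitchfork detection, and branch switching (`ringmt.bifurcation`),
- direction-sweep tuning matrices (population vs single-unit tuning) and
  slow-inhibition ramps with label tracks (`ringmt.temporal`).

## Worked example

`examples/02_steady_state_classes.py` relaxes the network to the three
attractors that coexist at PS = 120°, PW = 10°, α = 0, β = −10:

```
seeded near          label  energy  peaks (deg: height)
the mean direction   VA      1.085  +0.0: 0.58
one component        WTA     0.995  +60.0: 0.78
both components      TP      0.921  +60.1: 0.73, -60.1: 0.73
```

The same stimulus supports integration (one peak at the 0° mean), selection
(one peak at the +60° component) and transparency (a peak at each
component); the l2-norm "energy" orders the branches as in the bifurcation
diagram. `examples/03_bifurcation_diagram.py` traces those branches in PS:

```
All three classes stable for PS in [95.2, 122.5] deg
Unstable branches cross in energy at PS = 126.6 deg
```

Below the window, integration is the only attractor; above it the VA branch
has lost stability at a symmetry-breaking pitchfork and only the two
segmentation states remain. The other examples map attractor strength over
stimulus and connectivity planes, simulate the slow-inhibition ramp that
switches the network from integration to selection over a few hundred
milliseconds, and compute migration percentages between random-dot-like and
plaid-like inputs.

A thin CLI mirrors these capabilities
(`ringmt simulate|sweep|bifurcate|maps|migrate|ramp`); every subcommand
writes CSV/JSON outputs plus a run manifest and an echo of the effective
YAML configuration.

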