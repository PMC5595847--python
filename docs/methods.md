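# Methods

## Model

`ringmt` simulates a rate-based neural field on the ring of motion
directions θ ∈ [−π, π), representing a population of direction-selective MT
cells driven by two superimposed motion components. The state u(θ, t) is a
lumped excitation/inhibition potential (negative values mean net
inhibition; activity is never rectified) evolving as

    τ_p du/dt = −u(θ) + ∫ J(θ−φ) S(μ u(φ), th) dφ + κ_i I_ext(θ).

The equation combines leak, recurrent drive through a distance-dependent
kernel, and feed-forward input. The rate function is a threshold-shifted
logistic, S(μu, th) = σ(μu − th) − σ(−th) with σ the standard logistic, so
S(0) = 0 and the rest state of the undriven network is an equilibrium.

**Connectivity.** J is a difference of Gaussians in direction-difference
space with *global* inhibition: J(θ) = g_e G(θ, σ_e) − g_i G(θ, σ_i), where
G is the unit-integral Gaussian density evaluated in radians and
σ_i = 10π rad (1800°), i.e. the inhibitory Gaussian is effectively constant
on the ring. A two-parameter family spans the regimes of interest: α ∈
[0, 1] interpolates σ_e linearly between 11.5° and 60°, and β ∈ [−10, 15]
adds to the inhibition strength. The gains are tied to the width by
g_e = exp(−σ_e²/2) and g_i = (1 + g_e)/m(σ_i), with m(σ_i) =
erf(π/(σ_i√2)) = 0.0796557… the inhibitory mass on one ring period (0.0797
to three significant figures). This normalization makes the ring integral
(zeroth Fourier coefficient) of every β = 0 kernel equal to −1: the family
is always net-inhibitory, and β tilts the balance without reshaping
excitation. Two implementation choices keep the constraint exact rather
than approximate:

- the excitatory Gaussian is periodized with one replica pair on each side
  (exact to machine precision for σ_e ≤ 60°), so its ring mass is exactly
  g_e for every α — evaluating the bare Gaussian at the wrapped difference
  would lose ≈0.3% of the mass at σ_e = 60°;
- the divisor in g_i is the closed-form mass m(σ_i), not its 3-digit
  rounding; with the rounded constant the integral misses −1 by ≈1.1×10⁻³
  at α = 0.

The first cosine coefficient of the β = 0 family is *not* 1 under these
gain formulas (it ranges from 0.96 at α = 0 to 0.33 at α = 1); no rescaling
is applied, and only the zeroth-coefficient constraint is asserted.

**Stimuli.** I_ext is a sum of Gaussian bumps, one per motion component,
with standard deviation PW (direction uncertainty; larger for gratings and
plaids than for random dots) and centers va_direction ± PS/2. Bumps are
peak-normalized (height 1 for the stronger component) so the relative
strength r ∈ [0, 1] of the weaker component scales amplitude, matching the
reading of r as signal strength; an area-normalized variant is available as
a config switch (`area_normalized_input`). Bumps are built with
three-replica wrapping so profiles are continuous across ±π. The overall
gain κ_i is applied in the dynamics, not in the profile.

## Parameters

| parameter | meaning | default |
|---|---|---|
| N | ring samples on [−π, π) | 404 |
| μ, th | sigmoid gain, threshold | 16.0, 3.0 |
| κ_i | input gain | 0.1 |
| τ_p | population time constant (ms) | 1.0 |
| σ_e | excitation width (deg), α-interpolated | 11.5 … 60 |
| σ_i | inhibition width (rad) | 10π |
| β | inhibition offset | [−10, 15] |
| PS, PW | input peak separation / width (deg) | (0, 180], 5–30 |
| τ_l | inhibition ramp time constant (ms) | 30–100 |
| noise_eps | additive noise amplitude | 0.01 |
| ic_amp | initial-condition amplitude | 0.1 |
| dt | Euler–Maruyama step (ms) | 0.1 |

Initial conditions are iid uniform on [0, ic_amp] per node ("a low level of
random activity"); the noise amplitude is not fixed by the source material,
so it is a configuration parameter, and analyses that depend on it state
their value explicitly.

## Numerics

**Convolution.** The recurrent integral is a circular convolution computed
by FFT with periodic-quadrature weights (step dθ = 2π/N); with a uniform
grid this equals the trapezoid rule and is spectrally accurate. An O(N²)
direct-quadrature oracle verifies the FFT path to 1e−10 in the tests.

**Integration.** Deterministic trajectories use scipy's implicit Radau
solver with the analytic Jacobian (−I + C·diag(S′(u)))/τ_p (C the dense
circulant operator) at absolute tolerance 1e−12. Stochastic trajectories
use fixed-step Euler–Maruyama, adding noise_eps·√dt·ξ per node and step
with independent standard normal ξ, seeded through
`numpy.random.Generator`. With noise_eps = 0 the Euler path reproduces the
adaptive solver's endpoint to 1e−6 (verified after the ignition transient,
where the contracting flow has damped the accumulated first-order error).

**Steady states.** `find_steady_state` settles with cheap fixed-step
integration (a noisy transient of up to 300 ms selects the basin when
noise is on, then noise-free settling in 100 ms chunks up to t_max =
2000 ms) and polishes with Newton. The Newton iteration backtracks while
the residual exceeds 1e−3 and then takes full steps: near the solution the
residual is allowed to rise transiently, because correcting the
near-marginal rotational soft mode of a pinned bump (leading eigenvalue
≈ −1e−4) overshoots in residual norm before converging quadratically — a
monotone line search stalls there. A polished state whose leading Jacobian
eigenvalue is clearly positive (> 1e−6) is rejected and settling continues:
near symmetry-breaking bifurcations trajectories linger close to the
symmetric saddle, and accepting the polish would silently count an unstable
state as an attractor. Failure to converge by t_max is returned as a
flagged (non-exceptional) result and tallied separately in attractor
statistics.

**Classification.** Peaks are local maxima on the periodic grid with
sub-grid position by quadratic interpolation, filtered by height (≥ 0.1 of
the profile maximum) and topographic prominence (≥ 0.05). Maxima separated
by a saddle shallower than 0.25 of the profile maximum are merged into one
broad peak at the circular centroid of the activity above the saddle level.
This bimodality threshold is the operative VA/TP distinction: along the
integrated (VA) branch the central dimple between the two input sites never
exceeds ≈0.12 of the maximum, while genuine transparency profiles dip below
zero between peaks (saddle depth > 1.0 of the maximum), so any threshold in
(0.15, 0.45) separates the classes; 0.25 sits centrally in that gap. A
single peak within tol_dir = 20° of the mean direction is VA; within
tol_dir of a component it is WTA, downgraded to SB when a residual positive
bump at the suppressed component exceeds sb_frac = 0.1 of the main height;
two peaks within tol_dir of the two components with height ratio ≥ 0.5
(`tp_ratio`) are TP. tol_dir both separates the mean from the components
down to PS = 60° and absorbs the few degrees of outward motion repulsion of
transparency peaks. All thresholds are configuration-exposed; none is given
numerically by the source material.

**Attractor strength and migration.** The probability of each class is the
empirical frequency over n_trials independent trials (fresh initial
condition and noise path each), with per-cell generators derived from
(master seed, cell indices) via `SeedSequence` spawn keys, so maps are
reproducible and evaluation-order independent. WTA and SB are pooled, as
are T and TP; non-converged runs are counted in the denominator by default
(switchable). Migration between two stimulus conditions binarizes the two
maps at a support threshold (default 0.5, i.e. "majority outcome") and
reports the intersection area as a percentage of the whole parameter plane;
raising the threshold is monotone non-increasing in every overlap.

**Continuation.** Branches of the equilibrium equation are traced by
pseudo-arclength predictor–corrector stepping: secant predictor, Newton
corrector on the bordered system with the parameter derivative obtained by
central finite differences on the stimulus, adaptive step length (halving
on corrector failure, 1.3× growth on success, floor 1e−3), and the
grid-weighted state norm in the arclength metric so steps are
resolution-independent. Stability is flagged from the full dense Jacobian
spectrum at each accepted point (margin 1e−8); continuation always runs
noise-free. Folds are detected as parameter-direction reversals along
arclength and refined by a quadratic fit of p(s); symmetry-breaking branch
points are detected as zero crossings of the leading eigenvalue restricted
to the subspace of profiles odd about the stimulus axis, refined by
bisection to 0.5°, and `switch_branch` lands on the bifurcating (mirror
WTA) pair by perturbing along the critical odd eigenvector. The
peak-separation diagram (PW = 10°, β = −10) is assembled by continuing the
vector-average branch upward from PS = 40° and the winner-take-all and
transparency branches downward from PS = 175° through their folds, which
yields their unstable continuations; the tri-stable window is the overlap
of the three stable intervals, and the unstable-branch crossing is located
by interpolating the two unstable energy curves in PS.

The diagram is evaluated at α = 0: the published caption's homotopy setting
is ambiguous (a value outside the allowed range), and of the two plausible
readings only α = 0 produces three coexisting classes — at α = 1 the peak
feed-forward drive (κ_i = 0.1) stays below the effective threshold
th/μ = 0.1875 and the broad, weak excitation (g_e = 0.58) cannot ignite a
self-sustained bump, so all initial conditions relax to one weak
input-following state. The test suite demonstrates both readings.

## Problem sizes

All quantitative analyses run at the standard N = 404; the continuation
diagram takes ~10 s and the 100-trial convergence-probability estimate
~30 s on one core. The test suite uses N = 202 for auxiliary invariants
(branch topology regressions, ramp sweeps) after verifying that steady
states at N = 404 and N = 808 agree to 1e−4 and that the window edges at
N = 202 match N = 404 to better than 0.1°.

## What the simulations do and do not show

The model reproduces, with the default parameters: integration (VA) as the
dominant outcome for small peak separations regardless of width; the
tri-stable window ≈ [95°, 123°] in PS with energies ordered VA > WTA > TP;
winner selection in ≈60% of random initializations for narrow, widely
separated inputs; locking of the winner to the stronger component for
asymmetric inputs (r = 0.7) across a full direction sweep; the slow
switch from integration to selection under a rising inhibition ramp, with
transition time increasing under delayed onset or weaker final strength;
and migration orderings under fixed connectivity (integration regimes
migrate to segmentation when the input broadens and separates; no regime
migrates back to VA, and TP→VA is absent).

Known limitations, kept as documented behavior rather than patched:

- The VA→TP temporal transition is not produced by the inhibition ramp (the
  two-peak basin is tiny for narrow close inputs); the ramp instead yields
  VA→WTA at PS = 60° and SB→WTA at PS = 135°.
- At α = 1 (broad excitation) with peak-normalized drive the network is
  subthreshold, so the broad-excitation/low-inhibition corner of the
  connectivity plane is classified by its weak input-following two-peak
  profile rather than by an ignited integration state. The
  `area_normalized_input` switch provides stronger narrow-input drive for
  exploring that corner.
- At the default noise (0.01) the transparency basin captures essentially
  all random initializations at PS = 120°; occasional winner selection
  under symmetric inputs — the trial-to-trial variability regime — appears
  at noise comparable to the initial-activity amplitude (0.1), which is the
  value the corresponding test states.
- Biological firing-rate scales, the feed-forward latency (~50 ms), and
  spiking/mean-field-variance extensions are out of scope; single-cell
  taxonomies based on pattern/component correlations are not modeled.
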