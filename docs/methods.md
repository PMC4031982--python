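# Methods

## The model

A sperm cell swimming close to a channel wall is described in the effective
2-D plane of the wall by its position **R** = (X, Y) and a unit orientation
**N** = (N_x, N_y):

    dR/dt = V N + σ Ū e_y
    dN/dt = σγ̇α (N_x N_y, N_y² − 1) + σγ̇χβ (N_x² − 1, N_x N_y)
            + √(2D) (I − N Nᵀ)·ξ(t)        (Stratonovich)

The flow points along σ e_y (σ = ±1) with near-wall shear rate γ̇ and mean
advection speed Ū experienced by the cell body. The α term rotates the cell
against the flow (the beat envelope acts like a weather vane under shear);
the χβ term couples shear to the handedness χ ∈ {−1, 0, +1} of the
three-dimensional flagellar beat and tilts the stable heading sideways, with
transverse drift of sign −χ; the projected Gaussian white noise of amplitude
D lumps the biological variability of the swimming direction.

Internally the orientation is a single angle ψ with N = (sin ψ, cos ψ)
(ψ = 0 along +y). On the circle the model reduces exactly to

    dψ/dt = σγ̇ (α sin ψ − χβ cos ψ) + √(2D) η(t),

which conserves |N| = 1 by construction; the noise is additive in ψ, so the
Itô and Stratonovich readings coincide and a plain Euler–Maruyama step is
used. A test verifies one deterministic step agrees with a Stratonovich
Euler–Heun step of the constrained 2-vector form to O(dt²).

The drift derives from the tilted-cosine potential
Φ(ψ) = σγ̇(α cos ψ + χβ sin ψ), giving

* fixed points at tan ψ = χβ/α; the stable heading (for σ = +1) is
  N* = (−χβ, −α)/√(α² + β²) — upstream with a transverse tilt;
* the closed-form stationary angle density p(ψ) ∝ exp(−Φ(ψ)/D), which the
  package integrates on a uniform 2048-point grid (spectrally accurate for
  periodic smooth integrands) to predict ensemble-mean velocities
  (V⟨N_x⟩, V⟨N_y⟩ + σŪ) without simulation. Quadrature and Monte-Carlo are
  kept as independent routes and cross-checked in the tests.

## Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| V | swimming speed | 50 | μm/s |
| α | shear-alignment shape factor | 0.3 | — |
| β | chirality shape factor | 0.075 | — |
| χ | beat handedness (+1 human at low viscosity, 0 bull) | +1 | — |
| D | orientational noise amplitude | 0.25 | rad²/s |
| A | flagellar beat amplitude (2A = envelope height) | 10 | μm |
| ℓ | sperm length (metadata) | 60 | μm |
| h_adv | effective advection height | 10 | μm |

Defaults for (α, β, D) are the centres of the ranges that reproduce the
experimental velocity statistics for human sperm at low viscosity; V, A, ℓ
are the values used in the reference simulations. D is treated as an angular
diffusivity (rad²/s) although it is conventionally quoted in rad/s; configs
accept the quoted numbers unchanged.

Ū is not fixed by γ̇ alone — it depends on how high above the wall the cell
body rides, which is not measured. We take Ū = γ̇·h_adv with h_adv = A =
10 μm by default (the midpoint of the beat envelope), overridable via
`FlowProtocol.U_bar`. The location of the upstream-velocity optimum in the
rescaled flow speed u20 = γ̇·2A/v₀ shifts with this choice; with h_adv = A
the simulated optimum sits at u20 ≈ 0.6–0.8, consistent with the observed
"optimal rectification near u20 ~ 1" at the reported precision.

Integration uses dt = 0.01 s with a stability guard
dt ≤ 0.1/max(1, γ̇·max(α, β)), output decimated to 25 frames/s to mirror
the acquisition. All stochastic operations take an explicit seed; ensembles
spawn per-track substreams from the master seed (`numpy SeedSequence`), so a
single track can be reproduced bit-for-bit independently of ensemble size.

## Channel flow and shear calibration

The channel is a rectangular duct (height H = 340 μm between the observed
walls, width W = 3000 μm). The Stokes solution is the classical double-cosh
Fourier series; the x-independent part is summed in closed form (it is the
plane-Poiseuille parabola), so the truncated remainder decays like
exp(−nπ·d/H) with d the distance to the nearer side wall — at the default
51 odd modes, point values away from the side walls are converged to machine
precision, the cross-section flux closes within 0.1%, and wall values are
returned as exact zeros. At this aspect ratio (W/H ≈ 8.8) the mid-width
profile is the plane parabola boosted by the side-wall flux correction
1/(1 − 0.63 H/W) ≈ 1.077.

The shear rate that drives the swimmer model is calibrated the way the
experiment does it: the secant slope u(0, δ)/δ of the flow speed measured at
δ = 20 μm above the wall (the analytic wall derivative is also exposed; it
is slightly larger because the profile is concave). Reversal time series use
the flow speed at 5 μm as their display reference. Flow rates are accepted
in μl/min, μl/s or μm³/s.

## Synthetic tracks: what they emulate, and what not

`generate_dataset` emulates tracked coordinates as a PTV pipeline would
deliver them: sampling at the camera frame rate (25 fps), i.i.d. Gaussian
localization noise per coordinate (default 0.5 μm ≈ sub-pixel accuracy at
10–20×), loss of cells whose observed position leaves the 800 × 800 μm
field of view (truncation, no re-entry), per-frame detection dropout that
fragments tracks, and discarding of fragments shorter than 1 s. An optional
constant intrinsic turning rate ω₀ (rad/s, default 0) exists only inside the
generator, to emulate the small nonzero mean trajectory curvature real cells
show at zero shear; the model and inference layers never include it.

Not emulated: raw image formation, cell–cell interactions and collisions,
immotile subpopulations, speed heterogeneity across cells (every synthetic
cell shares one V), track-linking errors (identity swaps), and
depth-of-field effects. Passing tests therefore demonstrate correctness of
the analysis pipeline and self-consistency of the model — not that the
model describes any particular experimental dataset.

## Statistics pipeline

Velocities are central differences of the raw positions on the sample times
(one-sided at track ends). Two discretization effects are inherent and
quantified in the tests: on a circle sampled m times per revolution the
speed is attenuated by exactly sinc(2π/m) (1.6% at m = 20), and under
heading diffusion the mean speed is attenuated by O(D/frame rate) (~0.06%
at 100 fps). Velocity statistics are normalized by the zero-shear sample
mean speed v₀; "upstream" means −σ·v_y. Standard errors cluster by track
(samples within a track are strongly autocorrelated): SE = sd(track
means)/√n_tracks; the raw spread of track means is also reported for
experiment-level error bars.

Signed curvature κ = (ẋÿ − ẏẍ)/(ẋ² + ẏ²)^{3/2} uses Savitzky–Golay
(local quadratic) derivatives over a sliding window (default 7 samples);
samples slower than 5 μm/s, where curvature is ill-defined, are masked
rather than raising per-sample. The estimator bias on circles is
O((ωΔt)²·window²): below 0.5% at R = 50 μm, 25 fps, 50 μm/s with window 7;
the 2%-across-radii check uses window 5, which stays unbiased down to
R = 20 μm.

The reversal response time τ has no standard operational definition; we use
the first post-reversal time (linear interpolation between 0.5-s bins) at
which the ensemble-mean velocity along the *new* upstream direction reaches
90% of its post-reversal long-time mean (window configurable, default the
second half of the post-reversal span). This is robust to the transient
"peak" (cells momentarily carried with the new flow) and to noise. τ is
undefined when the long-time net upstream motion is not positive (advection
faster than swimming, Ū > V·alignment); `response_curve` raises in that
regime, and also when the post-reversal span is shorter than 3τ.

## Inference, and an identifiability caveat

Fitting minimizes the inverse-variance-weighted squared error between
quadrature-predicted and observed normalized mean upstream/transverse
velocities across shear conditions, with a systematic grid scan and a
bounded L-BFGS-B refinement from an initial guess (default: the centre of
the plausible box, (0.3, 0.075, 0.25)).

The stationary density depends on the parameters only through γ̇α/D and
γ̇χβ/D, so *any* single-time statistic — means, histograms — constrains
only the ratios α/D and β/D: the objective is exactly flat along
(α, β, D) → (cα, cβ, cD) (a test asserts this). The overall time scale is
therefore set by the initial guess: the optimizer lands at the point of the
degenerate ridge its path reaches from the anchor, which is why the grid
pre-scan is off by default (it would pick an arbitrary ridge node). Pinning
the scale from data requires dynamical observables, e.g. the reversal
response time. Consequences: the recovery experiments are exact for the
ratios and anchor-dependent for the scale; the fitted D still responds in
the right direction to injected noise (the ridge tilts relative to the
anchor), which is verified by a 2-point test.

Confidence intervals use a parametric bootstrap that resamples the observed
condition means from Gaussian(mean, SE) and refits. This replaces
re-simulating full synthetic ensembles per replicate; at the sample sizes
involved the condition means are Gaussian to high accuracy, and the
replacement is orders of magnitude cheaper.

χ is not fitted: it is fixed by species/viscosity convention (+1 human at
low viscosity, 0 bull). V, A and h_adv are inputs, measured directly.

## Problem sizes

Reference runs use 1000 trajectories per condition, 120 s at dt = 0.01 s
(stationary scans and reversals), 13-point u20 grids, and 8-condition ×
1000-track datasets for recovery experiments; cross-validation tests use
300–600 trajectories. These sizes put Monte-Carlo standard errors well
below the effect sizes being checked (3-SE criteria throughout).

## Known limitations

* No flagellar beat resolution, no hydrodynamic wall coupling beyond the
  effective 2-D confinement, no 3-D channel geometry.
* Zero-shear single-cell dynamics are not faithful: real trajectories have
  intrinsic curvature, absorbed here into the noise term (generator-only ω₀
  aside).
* The medium is treated as Newtonian with a modified viscosity.
* The α, β reduction assumes a rigid conical beat envelope; viscosity
  dependence of the beat shape enters only through the parameter values.
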