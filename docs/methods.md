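# Methods

## Model overview

Two continuous attractor networks share one principle: units conjunctively
encode a spatial variable and its rate of change, and the recurrent
weights are shifted by the presynaptic velocity coordinate so that the
activity packet moves at the speed the velocity coordinate encodes.

**Ring network (head direction × rotation).** Units on a lattice of
n_θ × n_ν = 51 × 25 coordinates, θ periodic on [0, 2π), ν non-periodic on
[−L_r, L_r]. Rate dynamics

    τ dm/dt = −m + [ ∬ J(θ,ν|θ′,ν′) m(θ′,ν′) Dθ′Dν′ + I_ν + I_view ]₊,

with threshold-linear transfer and the normalized measures
Dθ = dθ/2π, Dν = dν/2L_r. The angular-velocity input is Gaussian in ν,
centred at u(V) = arctan(τV), with amplitude I_r(1 − ε + ε·exp(·)).
Heading and rotation phase are the angles of the Fourier integrals
∬ m e^{iθ} and ∬ m e^{iλν} (the latter divided by λ), and V = tan(φ)/τ
inverts the placement rule.

**Torus network (position × translation).** The four-dimensional analogue
with 15² × 7² units, k = 2 bumps per spatial axis, velocity placement
u(V) = (1/k)·arctan(2πτV/S) per component, and position read-out
x = S/(2π/k)·θ̂ with S the grid spacing in metres.

### Parameters (shipped defaults)

| symbol | meaning | default |
|---|---|---|
| J0, J1/J_k | uniform inhibition, interaction strength | −60, 50 |
| λ | velocity-tuning spread in the weights | 0.8 |
| L_r, L_t | half-range of the rotation / translation axes | 0.0095, 0.3 |
| τ | membrane time constant | 10 ms |
| I_r, I_t | velocity input amplitudes | 50, 60 |
| ε | velocity-tuning strength | 0.8 |
| σ_r, σ_t | velocity-tuning widths | 0.012, 0.1 |
| I_d, σ_d | ring view-current amplitude, width | 60, 2.19 rad |
| I_p, C | torus view-current amplitude, baseline | 200, 0.5 |
| S | metres per torus period (grid spacing) | 30 m |
| k | bumps per spatial axis | 2 |
| dt | integration step | 1 ms |

## Numerical choices

**Integrator.** Explicit Euler with dt = 1 ms (dt/τ = 0.1); the rate model
is smooth and the threshold-linear clipping bounds transients. Rates below
1e-12 are flushed to zero: the exponential decay of silent units otherwise
reaches subnormal floats, which slows the BLAS/FFT kernels by an order of
magnitude without affecting any decoded quantity.

**Quadrature.** The θ axes use the plain lattice mean (exact for periodic
grids). The non-periodic ν axes use trapezoid weights c_i/(n−1) with
c = [½, 1, …, 1, ½], which sum exactly to one and match the continuum
normalization 1/(2L)∫dν. This matters: with plain means (weight 1/n per
point) the ν integral is underweighted by (n/(n−1))² ≈ 1.36 on the 7-point
velocity axes, and the torus kernel's best spatial mode then has recurrent
gain ≈ 0.9 — no grid pattern can form at all.

**Recurrent drive.** The ring uses the explicit (1275)² weight matrix. The
torus drive is evaluated as a circular FFT convolution over the spatial
axes contracted with a dense 49 × 49 velocity-coupling matrix; this is
algebraically exact for the difference-only weight structure and is
verified in the tests against an explicit dense matrix on small and
medium lattices (agreement to 1e-12).

## Pattern formation, bootstrap, and the maintenance current

The hexagonal triad the projection axes decode — lattice modes (0,2),
(2,−1), (−2,−1), hence α = arctan 2 and oblique wavelengths sin α — is
the most excitable spatial structure of the torus kernel. At the shipped
parameters, however, the uniform inhibition (|J0| times the equilibrium
activity integral ≈ 0.74) exceeds the velocity-input pedestal
I_t(1 − ε) = 12 everywhere except the central few velocity cells, so only
~7 % of the velocity lattice is active and the triad's recurrent gain
lands at ≈ 0.98: the pattern decays with a time constant of a few hundred
milliseconds rather than self-sustaining. (A broad-velocity state that
would raise the gain is arithmetically impossible at these constants: it
would require an activity integral below 0.2 while the central cell alone
contributes more than 0.3.)

The package therefore operates the torus network the way the closed-loop
system does — supported by its own calibration input:

- **Bootstrap.** `grid.settle` breaks the symmetry with the view-current
  profile anchored at the origin (amplitude I_p, baseline C) for the
  settle steps, followed by a release phase under the maintenance current
  so the withdrawal transient finishes before the phase anchors
  position (0, 0).
- **Maintenance.** Between calibrations a weak current (I_maint = 5,
  ~2.5 % of I_p) re-imprints the triad at the phase the network itself
  predicts one frame ahead (current decoded phase advanced by the decoded
  phase velocity tan(kφ)/(kτ)). It uses only information already in the
  network state, holds the pattern resultant near 0.3 (two orders above
  the decode floor, one below the bootstrap level), and leaves the phase
  free to move. Strong anchored currents would pin the phase outright;
  with no support the mode amplitude reaches the floating-point floor
  within seconds.

## Decoding and unwrapping

ψ_j is the angle of the projection integral divided by k, wrapped to
[0, 2π/k). The k²-bump pattern is invariant not only under per-axis
period translations but also under the staggered vector (π/k, 2π/k); a
single frame therefore pins the centre only modulo that joint lattice,
and combining wrapped ψ₁, ψ₂ into per-axis phases can jump by a quarter
period when θ̂_y crosses its wrap boundary. The position tracker instead
unwraps ψ₁ and ψ₂ themselves over time (nearest-branch rule, valid while
per-frame phase changes stay below half a period) and combines the
cumulative values, which is continuous by construction. The third
projection axis is a redundancy diagnostic: a reconstruction disagreement
beyond two lattice spacings raises a warning, and it never enters the
estimate.

## Velocity transfer at the shipped parameters

The decoded phase velocity always reports the packet's *actual* motion
(the Fourier read-outs are self-consistent), but the open-loop transfer
from commanded velocity to packet velocity is not unity:

- **Ring:** σ_r = 0.012 exceeds L_r = 0.0095, so the Gaussian tuning
  barely decays across the rotation axis and rides on the
  I_r(1 − ε) pedestal plus the recurrent input. The activity centroid on
  ν — which sets the drift speed — reaches only ≈ 0.45·u(V): measured
  gain 0.44 at 0.5 rad/s, with lattice pinning near zero commanded
  rotation. With tuning much sharper than the axis (σ_r ≈ 0.002) the
  active profile is clipped symmetric around u(V) and the measured gain
  is within 2 % of unity (tested).
- **Torus:** the conjunctive recurrent feedback is under-damped at
  σ_t = 0.1, and the packet overshoots: gain ≈ 2.4 bare, ≈ 1.2–1.8 under
  the maintenance current.

Consequently the end-to-end path-integration accuracy checks against
ground truth (2 % endpoint error, 5 % heading tracking) fail at the
shipped parameter set; the corresponding acceptance tests measure and
report the real gains rather than being weakened. Maps produced by the
pipeline are topologically correct and internally consistent but globally
warped in scale and rotation.

## Local views and the experience map

Scene descriptors are abstract non-negative vectors (the image front-end
of a real system is a pluggable adapter). Similarity is 1 minus the mean
absolute difference over the descriptor range; the default threshold is
0.85, far above the ≈ 2/3 baseline of unrelated uniform descriptors and
below the ≈ 0.98 similarity of noisy revisits. Exactly one cell — the
best match — is active per frame; a reactivation after an absence of more
than `refractory_frames` (50) starts a calibration run, during which the
cell's currents are injected every frame it stays matched. The ring
current (σ_d = 2.19 rad) spans a third of the ring, so capture is a
smooth drag taking ~1 s of injection; the torus current imposes the triad
directly and captures within 50 steps.

Experience vertices are created whenever the decoded position moves
`creation_threshold` (5 m) from the current vertex; a loop closure links
the current vertex to the one associated with the re-recognised view,
carrying the decoded displacement measured before the calibration snap.
Relaxation minimises Σ_links |p_to − p_from − rel|² by Gauss–Seidel
sweeps in which vertex i moves a fraction min(α, 1/deg_i) toward the
average position its links suggest (α = 0.25, 20 sweeps per closure, root
fixed). Each single-vertex move is an under-relaxed minimisation of a
convex local energy, so the total energy is non-increasing sweep by sweep
on any graph — a guarantee a synchronous (Jacobi) update with fixed α
does not give once vertex degrees exceed two.

## Synthetic world

The generator emulates a vehicle with a forward camera sampled at
10 frames/s: piecewise-constant (speed, ω) control segments integrated
with exact arc formulas (pose is the exact integral of the true
velocities; segment controls are rescaled by < 0.5 % so that laps close
exactly after frame quantization), multiplicative Gaussian speed noise
and additive Gaussian ω noise, and scene descriptors keyed
deterministically by 5 m spatial cell and heading octant. It does not
emulate lighting or terrain variability, perceptual aliasing between
distinct places, or image-derived odometry error structure — so passing
tests show the model's mechanics work, not that it is robust to real
visual input.

Problem sizes used by the test-suite demonstrations: a 200 m L-shaped
path at 15 m/s for path integration, 10 s constant-rotation runs for
heading tracking, and three 150 m laps around a 40 m block with 3 %
velocity noise (≈ 850 frames, ≈ 100 experience vertices, ≈ 60 loop
closures) for the mapping demonstration.

## Known limitations

- The shipped parameter set does not path-integrate accurately open-loop
  (gains above); the package reproduces the mechanism, and accurate
  regimes exist (sharper velocity tuning) but are not the defaults.
- The torus pattern is input-supported, not self-sustaining, at the
  shipped parameters; long view-free runs rely on the maintenance
  current.
- Vertices store positions only; heading lives in the ring network, and
  relaxation treats links as pure translations.
- Single grid module: one spacing and orientation, no place-cell layer.
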