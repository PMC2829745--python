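# Methods

## Model

Tissue motion over a short-axis slice is described in the Lagrange picture
by the map x(X, t) taking reference (end-diastolic, t₀) positions X to
current positions x. Its Jacobian F(t, t₀) = ∂x/∂X — the deformation
gradient — obeys the non-autonomous linear matrix ODE

    Ḟ = L F,   F(t₀, t₀) = I,

with L(x, t) = ∂v/∂x the Eulerian velocity-gradient tensor. The solution is
the matricant, with an ordered multiplicative-integral representation: the
limit over partition refinements of products (newest factor leftmost) of
either (I + L(t_k*) Δt_k) or exp(L(t_k*) Δt_k). Used at the finite frame
interval Δt of a cine sequence these give two one-step integrators:

* **linear product** (default): cheap, first-order accurate;
  det(I + LΔt) = 1 + Δt tr L + Δt² det L, so volume is preserved only up to
  O(Δt) for divergence-free flows.
* **exponential product**: the closed-form 2×2 exponential (Cayley–Hamilton
  form with a series branch near a degenerate discriminant) preserves
  det exp A = exp tr A exactly, hence det F = 1 to machine precision for
  trace-free L at any step size.

Both satisfy the composition rule F(t, t₀) = F(t, t₁) F(t₁, t₀) exactly
when the second run continues the ordered product from F(t₁, t₀). The
sampling point is t_k* = kΔt (the right endpoint of each interval), and L is
treated as piecewise constant per interval. A truncated matricant series
(I + ∫L + ∫L∫L + …, trapezoid rule on the frame grid, order ≤ 3) serves as
an independent discretization for cross-checks, not as the default solver.

The Lagrangian strain tensor is E = ½(f∗ᵀ∘f∗ − id); in mixed components
under a reference metric g and deformed-chart metric h,

    E_i^j = ½ (g^{ℓj} F_ℓ^α h_αβ F_i^β − δ_i^j),

reducing to E = ½(FᵀF − I) for a single Cartesian chart. E vanishes for
isometries, and vanishes identically when h is induced from g by the
deformation itself (carry-along); both nullifications are enforced by tests
to 1e−12 / 1e−10. Scalar strains are projections (u, E(w)) = g_jk u^k E_i^j w^i
onto the radial/circumferential unit frame of the polar system at the ROI
centroid, and onto the principal eigensystem.

## Velocity-gradient estimation

Harmonic phase is extracted per tag direction by multiplying the frame's
DFT with an isotropic Gaussian window centred at the detected carrier
(single side-band) and inverse transforming. The carrier is the largest
non-DC spectral peak of frame 0, refined sub-bin by a local quadratic fit
of the log magnitude. Since harmonic phase is a material invariant, the
optic-flow constraint φ_t + v·∇φ = 0 holds per phase image; inserting the
local model v(x) = v₀ + L(x − x₀) into the constraint and its two first
spatial derivatives yields, for two phases, six equations in the six
unknowns (v₀, L) per pixel. All derivatives are Gaussian scale-space
derivatives; the scale is chosen per pixel, independently, by minimizing
the 2-norm condition number of the 6×6 matrix over a log-spaced sweep.

Numerical choices that materially affect accuracy:

* **Demodulation before smoothing.** Phase gradients are computed as
  ∇φ = c + Im(z̄_d ∇z_d)/|z_d|² with z_d = z·exp(−i c·x) the
  carrier-demodulated complex image. Without demodulation, Gaussian
  smoothing at scales near or above a tag spacing attenuates the harmonic
  by factors of 1e−2…1e−70 while leaked DC energy passes unattenuated and
  dominates the phase. Temporal derivatives come from the inter-frame
  complex product z_{k+1} z̄_k (carrier-free by construction, wrap-free for
  sub-half-wavelength inter-frame motion). No phase unwrapping exists
  anywhere in the pipeline.
* **Condition-number ties.** Condition numbers within 10 % (relative) of
  the per-pixel minimum are treated as tied, and ties resolve to the
  smallest scale. The conditioning functional discriminates genuinely
  ill-posed configurations (noise, phase nulls); where it is flat — on
  clean data it varies by a few percent across the sweep — locality must
  win, because the first-order local flow model is increasingly biased at
  coarse scales wherever the velocity field is spatially nonlinear.
  Without the tie band, isolated pixels pick coarse scales for ~1 %
  conditioning gains and incur order-of-magnitude L errors.
* **Kernel support.** All Gaussian (derivative) kernels are truncated at
  6σ with mirror-reflect boundaries. At carrier-scale frequencies the ideal
  transfer can be O(1e−3); the spectral ripple of a 4σ-truncated kernel is
  of the same order and would bias phase gradients by several percent.
* **Carrier significance.** A carrier is accepted only if the peak exceeds
  3× the median spectral magnitude scaled by √(log₂ N) — the growth rate of
  the maximum of N flat-spectrum bins — and carries at least 1e−6 of the DC
  magnitude; a fixed 3× rule would pass white noise at realistic image
  sizes.
* Pixels whose selected condition number exceeds 1e6, or whose band-passed
  magnitude falls below 5 % of the frame mean (phase undefined), are
  invalidated, never clipped or extrapolated. A guard band of 3·scale
  pixels at the image border is excluded from statistics.

L is reported at the mid-time of each frame pair and attributed to that
interval. Material trajectories are advanced by explicit Euler with one
bilinearly interpolated velocity sample per interval, mirroring the
piecewise-constant-L assumption (higher-order advection is intentionally
not the default); L for interval k is sampled at the tracked position at
the interval's right endpoint. An `eulerian_sampling` flag samples L at
fixed reference pixels instead, for comparison.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| tag spacing (phantom) | 7 | mm | typical SPAMM stripe pitch; carrier ≈ 0.90 rad/mm |
| band-pass filter_sd | ‖carrier‖/4 | rad/mm | separates side-bands, tolerates deformation-induced broadening |
| scale sweep | 8 log-spaced in [0.5, 3]×tag spacing | mm | below: filter sees < 1 stripe; above: local model bias dominates |
| condition-number tie band | 10 % | — | see above |
| condition limit | 1e6 | — | fail loudly rather than clip |
| integration method | linear product | — | cheapest; exponential product available for volume exactness |
| σ (strain-map regularization) | 1.0 | px | applied to derived scalar strain fields only (not L or F); masked, normalized convolution |
| ROI std | sample (n−1) | — | spatial variability, not uncertainty of the mean |

## Synthetic phantom

The default dataset emulates a contracting, twisting left-ventricular
annulus: r(R) = √(R² + λ(t)), θ = Θ + φ(t), with λ and φ half-cosine ramps
from 0 to −150 mm² and 0.15 rad over a 0.4 s systole, annulus radii
25/45 mm on a 128×128 grid at 1 mm, 21 frames (Δt = 20 ms). The map is
exactly area-preserving (det F ≡ 1) and its Eulerian velocity field is
divergence-free; analytic F, L and E provide oracles at every point and
time. Mid-wall end-systolic strains are E_cc ≈ −0.06, E_rr ≈ +0.07 —
physiological in sign and modest in magnitude, with steep 1/r velocity
variation near the inner radius exercising the estimator's bias behaviour.
Simpler models (translation, rigid rotation, uniform scaling, simple
shear) have spatially constant L for unit-level recovery tests.

Rendering paints a single-harmonic cosine of the *reference* coordinate
(inverse motion map, closed form for every model) and advects it
passively, with optional exponential tag fading and additive white
Gaussian pixel noise. Deliberately not modelled: MR k-space acquisition,
T1 relaxation dynamics, true 1-1 SPAMM product patterns, through-plane
motion, intensity inhomogeneity, and receive-coil noise correlation.
Passing tests therefore demonstrate correctness of the phase→motion→
deformation→strain chain under ideal single-harmonic tagging; they do not
certify robustness to the full physics of clinical acquisitions.

## Verification summary

* Phantom oracles: F vs central-difference Jacobians (1e−6), det F ≡ 1
  (1e−10), Ḟ = L F compatibility, divergence-free velocity.
* HARP: analytic phase recovery, shift theorem, phase-offset invariance
  (≈ machine precision; exact only in exact arithmetic), no wrap-line
  ridges, error monotone in noise down to the deterministic band-pass
  floor.
* Motion: translation v within 5 %, rotation L within 10 %, 90°-rotation
  equivariance, near-trace-free recovery on the incompressible phantom.
* Deformation: stationary-flow closed form exp((t−t₀)L₀) (1e−10), exact
  volume preservation (exponential product), first-order det convergence
  (linear product), bit-exact interval splitting, matricant cross-check.
* End-to-end: on the noise-free default phantom the full pipeline recovers
  the end-systolic strain tensor with ROI-median absolute error ≈ 0.002
  (tolerance 0.05), correct mid-wall sign pattern, in ≈ 20 s on one CPU.

The expensive end-to-end fit runs once per test session; unit-level motion
tests use 96×96 grids with 2–5 frames to keep the suite under a minute.

## Known limitations

* 2D only: contracts are dimension-agnostic, but only n = 2 is implemented
  and tested; through-plane motion is invisible.
* The scale-selection functional is a conditioning stand-in; no
  spatiotemporal regularization of the selected-scale map is attempted.
* Strain error concentrates near the inner radius, where the 1/r velocity
  profile defeats the first-order local flow model at any admissible scale
  (95th-percentile tensor errors ~0.05 on the default phantom).
* Euler tracking drifts quadratically in Δt; at the default 21 frames the
  drift is far below the strain error floor, but very coarse temporal
  sampling would require the (provided, non-default) higher-order options.
* The ROI mask is an input; no segmentation is performed. DICOM ingestion
  of clinical tagged series is not implemented.
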