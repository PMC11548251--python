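# Methods

This note records the models, conventions and numerical choices behind
`picdl`, and what the bundled synthetic experiments do and do not
demonstrate.

## Geometry and projectors

Images are square-pixel grids of linear attenuation (mm⁻¹), pixel centres,
physical origin at the grid centre, +y up; angles are degrees,
counterclockwise, 0° along +x.  The forward operator is a ray-driven Joseph
projector: for each ray the major axis is stepped one grid line at a time,
the two adjacent pixels are weighted by linear interpolation, and each
crossing contributes the intersection length (pixel size over the major
direction cosine).  The operator is materialised once per geometry as a
sparse CSR matrix, so the backprojector is its literal transpose: the
adjoint identity ⟨Fu, y⟩ = ⟨u, Fᵀy⟩ holds to rounding error by
construction, which the normal operator FᵀF inside the iterative solver
requires.  Parallel beam is the default for tests; a flat-equidistant-
detector fan beam (the central slice of a circular cone-beam flat-panel
system) is available, including a preset with the 370.95 mm
source-to-detector distance of a small-animal scanner.

A cautionary degeneracy worth knowing: with parallel rays, view sets
`i·8°` and `i·4°` over a full circle cover the *same* 45 directions modulo
180°, so doubling 45 → 90 uniformly spaced views adds no information; the
fan-beam geometry has no such coincidences and is used where view-count
scaling is studied.

### FBP

Projections are filtered with the discretised Ram-Lak kernel (spatial-domain
band-limited kernel, FFT'd after zero-padding to the next power of two;
optional Hann apodisation).  Sampling |ν| directly instead biases the DC
response and leaves a background offset.  Views are weighted by their actual
angular spacing (mean of adjacent gaps, end gaps replicated, no circular
wrap), so random subsets and contiguous arcs are reconstructed *plainly* —
a missing arc contributes nothing and produces the classic limited-angle
deformation on purpose, since those artifacted images are exactly what the
prior-generation stage consumes.  The global scale assumes the
doubly-covered 360° parallel case.  Fan-beam FBP cosine-weights the
projections and filters at the isocenter-referred detector pitch but
backprojects through the matched adjoint without the exact fan distance
weighting — adequate at the bundled fan angles, and irrelevant to the
iterative solver, which never uses FBP beyond initialisation.

## Simulator

Phantoms are material label maps (air / soft tissue / bone) with relative
density: a homogeneous disk (cupping object), a soft-tissue ellipse enclosed
by a dense bone shell with seeded internal blobs (dark-band object,
skull-like), and random blobs.  The bundled 4-bin spectrum (30/45/60/80 keV,
weights 0.45/0.25/0.18/0.12) uses hand-set attenuation tables — water-like
soft tissue, bone with a strong low-energy excess — chosen so that the
beam-hardening signature is clearly visible at 128×128: ≈6% cupping on the
disk and a distinct inter-shell dark band, while the one-bin reference
(weighted-mean attenuation at the mean energy) reconstructs flat to <0.1%.
They are plausible magnitudes, not tabulated physics data; no spectrum
download is needed.

Polychromatic data follows p = −ln Σ_E w(E)·exp(−Σ_m μ_m(E)·L_m) with
per-material path lengths from the same discrete projector, so a one-bin
spectrum reduces *exactly* to monochromatic projection, and Jensen's
inequality guarantees p_poly ≤ Σ w·μ·L ray by ray.  Counting noise is
Poisson in the count domain (counts ~ Poisson(i0·e^{−p}), clamped at one
count before the log) and is an orthogonal, optional switch — the LD
scenario itself is pure angular subsampling.

The four acquisition scenarios are pure view selection (retained rows are
bit-exact): SD keeps all 360 views, LD every second view, LSA a contiguous
arc with span uniform in [90°, 160°] and uniform start, LNP a uniform
random subset of 30–60 views.  All draws are seeded and recorded.

**Fabricated priors** stand in for the output of a learned correction
model: a half-size round-trip (2×2-mean downsample, bilinear upsample —
the train-at-half-size protocol), Gaussian blur, and compactly-supported
cosine-tapered radial bumps, additive for invented structures and
subtractive for erased ones.  The fabrication is deterministic per seed,
the identity under an empty recipe, and commutes with constant offsets.

## Solver

Discrete gradients are forward differences with replicate (Neumann)
boundaries, so DᵀD is the standard 5-point Neumann Laplacian.  The
u-subproblem is solved matrix-free by conjugate gradient (K is symmetric
positive definite whenever 2α + γ > 0), warm-started from the previous
iterate, relative tolerance 1e−4, at most 30 inner iterations; the
dense-oracle tests tighten this to 1e−12 to compare against a direct solve.
The outer loop runs up to 50 cycles with early stop when the relative
change in u drops below 1e−4; u⁰ is the FBP of the limited data, all
auxiliary variables start at zero (v⁰ = max(u⁰, 0), f⁰ = f).

Edge conventions: the shrinkage factor is defined as 0 where the joint
gradient magnitude is exactly 0; the prior-attachment term is *squared* L2
(the 2α coefficient in r^k arises from differentiating a square); the noise
bound σ of the constrained formulation is never used explicitly — fidelity
is governed by μ, the add-back update and the stopping rule.  A prior
weight α > 1 (as in the published limited-span presets) makes the shrinkage
threshold negative and amplifies gradients; the formula is applied
literally and a warning is logged, since the published parameterisation
does not discuss α outside [0, 1).

### Hyperparameters

| name  | role                            | default (`synthetic`) |
|-------|---------------------------------|-----------------------|
| μ     | data-fidelity weight            | 1.0 |
| λ     | gradient-splitting weight       | 20.0 |
| α     | prior attachment (0 disables)   | 0.5 |
| γ     | positivity penalty / speed      | 2.0 |

Only the ratios matter (Ku = r is scale invariant).  The published presets
(`lnp_r1`: μ=1.6, λ=0.12, α=0.5; `lnp_r2`: μ=1.4, λ=0.1, α=0.9; `lsa`:
μ=1.4, λ=0.12, α=3) are tuned to a physical scanner whose operator scaling
— hundreds of detector bins, 0.2 mm pitch — differs from the simulator's,
so the `synthetic` default was selected once by the coarse grid search in
`scripts/tune_defaults.py` (shell phantom, 45-view sparse acquisition,
fabricated prior, tuning seed disjoint from the test seeds) and frozen; γ
is not part of the published presets and defaults to the grid-search value.

SART is implemented with per-view sweeps: for each view's ray subset the
residual is row-sum-normalised, the correction column-sum-normalised,
relaxation in (0, 2), nonnegativity clamped after every sweep.  The
simultaneous-over-all-views variant converges far too slowly to serve as a
40-iteration baseline.

## Prior model

The training loss is Smooth L1 (quadratic for |r| ≤ 1, |r| − 0.5 beyond,
continuous at the transition), averaged over elements.  `NetworkSpec`
records the scanner-scale architecture — U-Net-style with a
residual-network-34 encoder (7×7 stem, 3/4/6/3 residual blocks), a decoder
of sub-pixel (pixel-shuffle) upsampling blocks with resize-consistent ICNR
initialisation followed by two conv+ReLU blocks each, stage-wise skip
connections, single channel in/out, operating at half the reconstruction
grid.  The bundled *trainable* model is deliberately compact: a three-layer
residual CNN (16 hidden channels, 3×3 kernels) in pure numpy with manual
backpropagation, AdamW (decoupled weight decay 1e−2, biases undecayed) and
Kaiming-uniform initialisation from an explicit seed.  Inputs are
standardised by the training inputs' mean and deviation.  Training is
full-batch and two-phase — encoder-only first (read literally; a config
switch selects the conventional decoder-first reading), then end-to-end at
a smaller rate.  The published rates (1e−4, then 1e−7) are defaults;
the desk-scale smoke tests use larger rates and a few hundred epochs, which
overfits five 32×32 slice pairs to below 10% of the initial loss in
seconds.  Everything downstream treats the prior as an opaque image, so the
fabricated-prior path and the model path are interchangeable.

## What the synthetic experiments show — and what they do not

The phantoms are piecewise-constant with sharp edges, which is *favourable*
to TV regularisation: with noiseless monochromatic 45-view data the solver
recovers the phantom nearly exactly (60+ dB), and the hallucination bump in
the prior is suppressed to a few percent of its amplitude.  Real anatomy
has texture; gains there are necessarily smaller.  Conversely, with
polychromatic data the linear data term *faithfully reproduces* the
beam-hardened solution on the measured subspace — at full sampling the
result matches FBP to within a fraction of a dB (the intended degeneracy),
and the clean prior mainly shapes the null space.  Correction of
beam-hardening through the prior is therefore visible in structural terms
(streak suppression, SSIM) rather than as a wholesale intensity fix in
these experiments.  The simulator also omits scatter, detector blur, ring
artifacts and 3D cone-beam effects; the solver is strictly 2D
(central-slice), as is the acquisition model.

## Problem sizes

All end-to-end experiments run at 128×128 with 0.5 mm pixels, 360 base
views, 45-view sparse subsets, and 50 outer × ≤30 inner iterations —
seconds per reconstruction on one CPU, chosen so the whole protocol
(`scripts/acceptance.py`) completes in well under a minute while the
beam-hardening and limited-view signatures remain unambiguous.  Oracle
comparisons use a 6×6 grid with 8 views, where dense matrices are exact.
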