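# Methods

## Forward model and projector

Images are square grids of unit pixels centred at the origin; a parallel-beam
ray for angle `theta` and signed detector offset `t` is the line
`p . (cos theta, sin theta) = t`. The system matrix stores exact ray–pixel
intersection lengths computed by Siddon-style traversal (crossing parameters
with the two families of grid lines, sorted, segment midpoints mapped to
pixels). This discretisation was chosen over pixel-area or Joseph kernels
because the adjoint is exact by construction, which the level-set gradient
relies on. Rays that miss the image keep their (empty) rows so the row index
remains a pure function of (angle, detector).

Detector defaults: `ceil(sqrt(2) * grid_size)` bins at unit spacing, which
covers the image diagonal at every angle; narrower arrays trigger a warning.
Angles are equally spaced on the half-open interval `[theta_min, theta_max)`
to avoid duplicating the redundant 0 and pi views of a parallel beam.

## Dictionary

One Gaussian atom per pixel, `m_i(x) = exp(-||x - x_i||^2 / (2 gamma^2))`,
sampled at pixel centres; a multiscale dictionary repeats the lattice at ten
widths equally spaced on `[0.1, 0.5]`. Widths are expressed in the
normalised unit image domain (pixel spacing `1/grid_size`): sub-pixel widths
cannot represent contiguous shapes, whereas unit-domain widths of 0.1–0.5
span roughly 6–32 pixels at 64², wide enough that a sparse set of atoms
carries a smooth boundary. The default single-scale width `gamma = 0.1` was
fixed empirically on the 64² benchmarks (the width is a tunable of the
method; smaller widths resolve concavities, larger widths converge faster
but blur detail). Basis-matrix entries below a truncation threshold
(default `1e-4`) are dropped; the matrix is stored sparse with a cached
dense copy used for BLAS products when mostly full.

## Level-set image model

The smoothed Heaviside ramps over `[-eps, eps]` as
`1/2 + t/(2 eps) + sin(pi t / eps)/(2 pi)`; its exact derivative
`(1 + cos(pi t / eps))/(2 eps)` serves as the smoothed delta, so the
analytic gradient of the data misfit is exactly consistent with the
objective (verified by finite differences to 1e-5 relative). Defaults
`eps = 0.1`, `c = 0.05` in level-set-field units: `c` must be a small
positive offset so the background field (phi = 0) lies below the boundary
level, and `eps > c` keeps a near-zero field inside the smoothing band.
Both are configurable and logged in result metadata.

Three-level images use two fields with one shared dictionary:
`u = u0 + (u1-u0) H(phi1-c) + (u2-u1) H(phi1-c) H(phi2-c)`. Gray levels are
assumed known and strictly increasing (the discrete-tomography prior). More
than three regions are out of scope.

## Optimisation

OWL-QN is implemented from scratch as a generic smooth-plus-l1 solver:
pseudo-gradient with the subgradient interval clipped toward zero at zeros;
reference orthant from current signs (falling back to the descent
direction's signs at zeros); L-BFGS two-loop recursion (default memory 10,
initial scaling `s.y / y.y`, pairs with `s.y <= 1e-12` discarded) with the
direction and every line-search trial projected into the reference orthant;
Armijo backtracking (`sigma = 1e-4`, halving) on the pseudo-gradient
decrease. The first step of a fresh history is scaled to unit length so
badly scaled problems do not spend dozens of backtracks. Stopping: sup-norm
of the pseudo-gradient, relative objective change, or an iteration cap. The
solver is validated against closed forms (soft threshold) and an
independent FISTA oracle on random lasso problems.

The reconstruction initialises all coefficients to the uniform value that
places the mean of each field at `c`: the whole domain then starts inside
the smoothing band, where the delta factor — and hence the first gradient —
is non-zero. A zero start is a critical point of the smooth loss and goes
nowhere. For the benchmark runs the iteration cap is 800; the stopping
tolerances rarely trigger earlier, and quality plateaus well before the cap
on easy instances. With two fields the stacked coefficient vector is
optimised jointly (a single OWL-QN run), not alternated.

`lambda` defaults to a scan over {1e-4, 3e-4, 1e-3, 3e-3, 1e-2} — "several
small values" — keeping the reconstruction with the best mean Dice when
ground truth is available (the quality-based selection used on synthetic
benchmarks) and otherwise a data-fit-plus-sparsity heuristic. Note the
coefficient scale is set by the dictionary row sums, so useful `lambda`
values are small relative to the data misfit; at the defaults the l1 term
acts as a mild pruning pressure rather than a hard sparsifier.

Quantization hard-thresholds at `phi > c`, ties assigned to the lower
region (the object is the strict super-level set). Output values are
exactly the configured gray levels.

## Phantoms and noise

Phantoms are rasterised at pixel centres from parametric shapes in the unit
domain: disc, annulus, two disjoint blobs, a non-convex "bean" (union of
two discs minus a circular bite, giving boundary concavities), a block
letter E, and a nested three-level object (body at `u1`, core at `u2`,
walnut-like topology). The published benchmark images exist only as
figures, so these are parametric stand-ins matching their character
(convexity defects, disconnection, holes, three-level nesting) rather than
copies. Ground truths contain exactly the declared gray values.

Projection noise is additive i.i.d. Gaussian with `sigma = n * max(y)`;
relative-to-peak scaling keeps the level `n` scale-free and monotone. The
generator does not emulate photon statistics, scatter, detector blur or
beam hardening, so passing benchmarks demonstrates robustness to broadband
measurement noise, not to physics-correlated artifacts of real scanners.

## Metrics

PSNR uses `MAX = 1` for the binary experiments (the model's maximum level).
SSIM defaults to the single-window global-statistics form with
`c1 = (0.01 L)^2`, `c2 = (0.03 L)^2` and population moments; the common
sliding-window variant is available behind a flag (scikit-image) and is
clearly distinguished. Dice is per gray level; two empty masks score 1.

## Baselines

FBP: Ram–Lak filter in the Fourier domain (zero-padded), linear-interpolated
backprojection matching the package's detector conventions, angular weight
`range / (2 n_views)`. TV: Chambolle–Pock on the stacked operator
`[A; grad]` with isotropic TV, nonnegativity via projection, and block-wise
dual step sizes (`tau sigma_A ||A||^2 + tau sigma_g ||grad||^2 < 1`, half
the budget per dual block) — a single scalar step starves the TV dual when
`||A|| >> ||grad||` and large penalties then take unreasonably many
iterations to flatten the image. `||A||` is estimated by power iteration;
the TV discretisation is isotropic forward differences with Neumann
boundaries. Defaults `lambda = 8e-3`, tolerance `1e-6`.

## Problem sizes and determinism

Benchmarks run at 64² with 4–10 views; unit and property tests use 16–48²
so the full suite completes in a few minutes. Everything is deterministic
given the configuration: the only randomness is projection noise, which is
seeded, so identical configs and seeds reproduce bitwise-identical
quantized images.

## Known limitations

Parallel beam only (the geometry type reserves a fan-beam extension for the
real scanner datasets); at most three gray levels / two fields; the l1
weight needs the grid scan rather than an a-priori rule; very wide atoms
cannot represent sharp concavities, so `gamma` trades boundary fidelity
against conditioning; the MAT-file reader returns raw arrays and leaves
scanner-geometry interpretation to the caller.
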