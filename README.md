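# plstomo

Discrete tomography reconstruction from sparse-view and limited-angle
parallel-beam data, for images known a priori to contain a small set of
discrete gray levels (industrial CT of machined parts, micro-CT of bone,
electron tomography of nanoparticles, carved-cheese / walnut benchmark
scans). Conventional reconstructions (FBP, algebraic methods, TV) degrade
badly when only a handful of projection angles are available or the angular
arc is truncated; `plstomo` exploits the discrete-level prior through a
parametric level-set model and recovers sharp boundaries from as few as
four projections.

## Method

The scan is modelled as `y = A u`, where `A` holds exact ray–pixel
intersection lengths (Siddon traversal) and `u` is piecewise constant with
known levels `u0 < u1 (< u2)`. The object boundary is the `c`-level curve of
a level-set field expanded in a dictionary of Gaussian radial basis
functions, one per pixel (optionally ten widths per pixel):

    phi(x, alpha) = sum_i alpha_i exp(-||x - x_i||^2 / (2 gamma^2))

    u(x, alpha) = u0 (1 - H(phi - c)) + u1 H(phi - c)          (two levels)
    u = u0 + (u1-u0) H(phi1-c) + (u2-u1) H(phi1-c) H(phi2-c)   (three levels)

with `H` a Heaviside step smoothed over a band `[-eps, eps]` so `u` is
differentiable in `alpha`. Reconstruction is the sparsity-regularised fit

    min_alpha  1/2 ||y - A u(x, alpha)||^2  +  lambda sum_j ||alpha_j||_1

solved with an Orthant-Wise Limited-memory Quasi-Newton (OWL-QN) solver
written for this package: an L-BFGS direction from the smooth curvature,
restricted and projected orthant-wise so the l1 term stays differentiable
along the path and coefficients are zeroed exactly. The smooth gradient is
the chain rule through the model,
`grad f = M^T [ (u1-u0) delta(phi-c) * A^T (A u - y) ]`, with the analogous
blockwise form for two fields sharing one dictionary. `lambda` is chosen by
scanning a small grid and keeping the best reconstruction. The final image
hard-thresholds the fields at `phi > c`, so the output takes exactly the
known gray values.

Baselines (`fbp`, `tv_chambolle_pock`) and quality metrics (PSNR, SSIM,
Dice) are included, plus a phantom factory generating binary and
three-level test images and relative Gaussian projection noise
(`sigma = n * max(y)`).

## Worked example

```python
import numpy as np
import plstomo as pt

truth = pt.make_phantom(pt.PhantomSpec(kind="nonconvex_blob", grid_size=64))
geom = pt.make_geometry(6, (0.0, np.pi), grid_size=64)
A = pt.build_system_matrix(geom, 64)
sino = pt.add_projection_noise(pt.forward_project(A, truth), 0.01, seed=7)

cfg = pt.ReconstructionConfig(gammas=(0.1,), lam=1e-3)
res = pt.reconstruct(sino, A, cfg, truth=truth)

print(f"Dice : {res.metrics.dice[1.0]:.4f}")
print(f"PSNR : {res.metrics.psnr:.2f} dB")
print(f"SSIM : {res.metrics.ssim:.4f}")
```

Output:

```
Dice : 0.9944
PSNR : 27.09 dB
SSIM : 0.9932
```

Six projections with 1% noise recover the non-convex binary phantom with
99.4% region overlap; PSNR/SSIM are computed between the quantized
reconstruction and the ground truth. The same pipeline is available from
the shell:

```
plstomo simulate --phantom nonconvex_blob --size 64 --projections 6 \
    --noise 0.01 --seed 7 --out run/
plstomo reconstruct --sinogram run/sinogram --size 64 --gamma 0.1 \
    --lambda 1e-3 --out run/recon/
plstomo evaluate --truth run/phantom.csv \
    --recon run/recon/recon_quantized.csv --levels 0,1
```

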