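"""Comparison baselines: filtered backprojection and TV via Chambolle-Pock.

Neither baseline uses the discrete gray-level prior; they serve as reference
points for the level-set reconstructions under the same scan geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection_geometry import ScanGeometry, Sinogram, SystemMatrix

__all__ = ["TvConfig", "fbp", "tv_chambolle_pock"]


@dataclass(frozen=True)
class TvConfig:
    """Chambolle-Pock TV settings; lambda weights the isotropic TV term."""

    lam: float = 8e-3
    tolerance: float = 1e-6
    max_iterations: int = 2000
    power_iterations: int = 30

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def fbp(y: Sinogram, geom: ScanGeometry, grid_size: int) -> np.ndarray:
    """Ram-Lak filtered backprojection on the given (possibly sparse) angles.

    Matches the projector conventions of this package: detector bins with
    unit spacing centred on the rotation axis, angle-major sinogram rows.
    """
    if geom.n_projections == 0:
        raise ValueError("empty angle set")
    vals = y.values
    n_det = geom.n_detectors

    # Ram-Lak filter applied per projection in the Fourier domain, using the
    # standard band-limited ramp (zero-padded to the next power of two).
    pad = 1 << max(6, int(np.ceil(np.log2(2 * n_det))))
    freqs = np.fft.rfftfreq(pad)
    ramp = 2.0 * np.abs(freqs)
    f = np.fft.rfft(vals, n=pad, axis=1)
    filtered = np.fft.irfft(f * ramp[None, :], n=pad, axis=1)[:, :n_det]

    # Backproject: pixel (i, j) at (x, y) reads detector coordinate
    # t = x cos(theta) + y sin(theta).
    n = grid_size
    c = np.arange(n) + 0.5 - n / 2.0
    yy, xx = np.meshgrid(c, c, indexing="ij")
    out = np.zeros((n, n))
    offs0 = -(n_det - 1) / 2.0 * geom.detector_spacing
    for a, theta in enumerate(geom.angles):
        t = xx * np.cos(theta) + yy * np.sin(theta)
        idx = (t - offs0) / geom.detector_spacing
        i0 = np.clip(np.floor(idx).astype(int), 0, n_det - 2)
        w = np.clip(idx - i0, 0.0, 1.0)
        prof = filtered[a]
        out += (1 - w) * prof[i0] + w * prof[i0 + 1]
    # Angular quadrature weight: interval width / number of views.
    lo, hi = geom.angular_range
    out *= (hi - lo) / (2.0 * geom.n_projections)
    return out


def _grad2d(x: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary; shape (2, n, n)."""
    g = np.zeros((2,) + x.shape)
    g[0, :-1, :] = x[1:, :] - x[:-1, :]
    g[1, :, :-1] = x[:, 1:] - x[:, :-1]
    return g


def _div2d(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_grad2d` (discrete divergence)."""
    d = np.zeros(p.shape[1:])
    d[:-1, :] += p[0, :-1, :]
    d[1:, :] -= p[0, :-1, :]
    d[:, :-1] += p[1, :, :-1]
    d[:, 1:] -= p[1, :, :-1]
    return d


def tv_chambolle_pock(
    y: Sinogram | np.ndarray, A: SystemMatrix, cfg: TvConfig = TvConfig()
) -> np.ndarray:
    """min_x 1/2 ||A x - y||^2 + lam * TV(x)  s.t.  x >= 0.

    Primal-dual iteration on the stacked operator K = [A; grad] with
    isotropic TV; step sizes from a power estimate of ||K||.
    """
    y_vec = y.ravel() if isinstance(y, Sinogram) else np.asarray(y).ravel()
    n = A.grid_size
    rng = np.random.default_rng(0)

    # Power iteration for ||A||^2; the gradient operator norm is sqrt(8).
    x = rng.standard_normal(n * n)
    lam_max = 1.0
    for _ in range(cfg.power_iterations):
        v = A.rmatvec(A.dot(x))
        nv = float(np.linalg.norm(v))
        if nv == 0:
            break
        lam_max = nv
        x = v / nv
    norm_a2 = max(lam_max, 1e-12)
    # Block-wise dual steps (preconditioned primal-dual): convergence needs
    # tau * (sigma_a ||A||^2 + sigma_g ||grad||^2) < 1.  Giving each dual
    # block half of the budget keeps the TV dual fast even when ||A|| is
    # much larger than ||grad||.
    tau = 0.95 / np.sqrt(norm_a2)
    sigma_a = 0.95 / (2.0 * tau * norm_a2)
    sigma_g = 0.95 / (2.0 * tau * 8.0)

    x = np.zeros(n * n)
    x_bar = x.copy()
    p = np.zeros(y_vec.size)  # dual for the data term
    q = np.zeros((2, n, n))  # dual for TV

    for _ in range(cfg.max_iterations):
        # Dual ascent.
        p = (p + sigma_a * (A.dot(x_bar) - y_vec)) / (1.0 + sigma_a)
        q += sigma_g * _grad2d(x_bar.reshape(n, n))
        norm = np.sqrt(np.sum(q**2, axis=0))
        q /= np.maximum(1.0, norm / cfg.lam)[None, :, :]
        # Primal descent with nonnegativity.
        x_old = x
        x = x - tau * (A.rmatvec(p) - _div2d(q).ravel())
        x = np.maximum(x, 0.0)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("Chambolle-Pock diverged; reduce steps")
        x_bar = 2.0 * x - x_old
        rel = np.linalg.norm(x - x_old) / max(np.linalg.norm(x), 1e-12)
        if rel < cfg.tolerance:
            break
    return x.reshape(n, n)
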