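"""Gaussian radial-basis dictionaries for the parametric level set.

The level-set field is parameterised as phi(x, alpha) = sum_i alpha_i m_i(x)
with Gaussian atoms m_i(x) = exp(-||x - x_i||^2 / (2 gamma^2)).  One atom is
centred at every pixel; a multiscale dictionary repeats the grid of centres
at several widths.  Atom widths gamma are expressed in the normalised unit
image domain [0, 1] x [0, 1] (pixel spacing 1/grid_size), so gamma in
[0.1, 0.5] spans from a few pixels to roughly half the image.

Atom ordering is pixel-major, scale-minor: atom ``p * n_scales + s`` is
centred at (row-major) pixel ``p`` with width ``gammas[s]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GaussianAtom",
    "Dictionary",
    "gaussian_value",
    "build_dictionary",
    "evaluate_pls",
    "MULTISCALE_GAMMAS",
]

#: Ten widths equally spaced on [0.1, 0.5] for the multiscale dictionary.
MULTISCALE_GAMMAS: tuple[float, ...] = tuple(np.linspace(0.1, 0.5, 10))


@dataclass(frozen=True)
class GaussianAtom:
    """One Gaussian basis function: centre in unit-domain coordinates."""

    center: tuple[float, float]
    gamma: float
    scale_index: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        cx, cy = self.center
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError("atom center must lie inside the unit domain")

    @property
    def beta(self) -> float:
        """Equivalent exponential rate, beta = 1 / (2 gamma^2)."""
        return 1.0 / (2.0 * self.gamma**2)


def gaussian_value(
    x: Sequence[float] | np.ndarray,
    center: Sequence[float] | np.ndarray,
    gamma: float,
) -> float | np.ndarray:
    """exp(-||x - center||^2 / (2 gamma^2)); value in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    sq = np.sum((x - center) ** 2, axis=-1)
    return np.exp(-sq / (2.0 * gamma**2))


@dataclass
class Dictionary:
    """Sampled basis matrix (n_pixels x n_atoms) plus atom metadata.

    ``basis_matrix`` is a CSR array with entries below the truncation
    threshold dropped; every stored entry lies in (threshold, 1].  A dense
    copy is cached lazily for fast BLAS products when the matrix is mostly
    full, which is the usual case for unit-domain widths >= 0.1.
    """

    atoms: list[GaussianAtom]
    basis_matrix: sp.csr_array
    truncation_threshold: float
    grid_size: int
    gammas: tuple[float, ...]
    _dense: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_pixels(self) -> int:
        return self.grid_size * self.grid_size

    def _dense_matrix(self) -> np.ndarray:
        if self._dense is None:
            self._dense = self.basis_matrix.toarray()
        return self._dense

    @property
    def density(self) -> float:
        m = self.basis_matrix
        return m.nnz / (m.shape[0] * m.shape[1])

    def matvec(self, alpha: np.ndarray) -> np.ndarray:
        """``M @ alpha`` using the dense cache when the matrix is full-ish."""
        if self.density > 0.25:
            return self._dense_matrix() @ alpha
        return self.basis_matrix @ alpha

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        """``M.T @ v`` with the same dense fast path."""
        if self.density > 0.25:
            return self._dense_matrix().T @ v
        return self.basis_matrix.T @ v


def _pixel_centers(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-domain coordinates of pixel centres, row-major order."""
    coords = (np.arange(grid_size) + 0.5) / grid_size
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    return xx.ravel(), yy.ravel()


def build_dictionary(
    grid_size: int,
    gammas: Sequence[float] = (0.15,),
    truncation_threshold: float = 1e-4,
) -> Dictionary:
    """One Gaussian atom per (pixel, width) pair, sampled at pixel centres.

    With a single width the dictionary has exactly one atom per pixel; with
    ``k`` widths it has ``k`` atoms per pixel.  Entries of the sampled basis
    matrix strictly below ``truncation_threshold`` are dropped.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be positive")
    gammas = tuple(float(g) for g in gammas)
    if len(gammas) == 0:
        raise ValueError("gammas must be non-empty")
    if any(g <= 0 for g in gammas):
        raise ValueError("all gammas must be positive")
    if not (0.0 <= truncation_threshold < 1.0):
        raise ValueError("truncation_threshold must be in [0, 1)")

    xs, ys = _pixel_centers(grid_size)
    n_pix = grid_size * grid_size
    n_scales = len(gammas)

    # Pairwise squared distances between all pixel centres (atoms sit on the
    # same lattice as the sampling points).
    dx = xs[:, None] - xs[None, :]
    dy = ys[:, None] - ys[None, :]
    dist2 = dx * dx + dy * dy

    blocks = []
    for g in gammas:
        blocks.append(np.exp(-dist2 / (2.0 * g * g)))
    # Interleave scale-minor: column p * n_scales + s.
    dense = np.empty((n_pix, n_pix * n_scales))
    for s, block in enumerate(blocks):
        dense[:, s::n_scales] = block
    dense[dense < truncation_threshold] = 0.0
    mat = sp.csr_array(dense)

    atoms = [
        GaussianAtom(center=(float(xs[p]), float(ys[p])), gamma=gammas[s],
                     scale_index=s)
        for p in range(n_pix)
        for s in range(n_scales)
    ]
    return Dictionary(
        atoms=atoms,
        basis_matrix=mat,
        truncation_threshold=truncation_threshold,
        grid_size=grid_size,
        gammas=gammas,
    )


def evaluate_pls(dictionary: Dictionary, alpha: np.ndarray) -> np.ndarray:
    """Level-set field phi = M @ alpha on the pixel grid (2-D array)."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != dictionary.n_atoms:
        raise ValueError(
            f"alpha has length {alpha.size}, dictionary has "
            f"{dictionary.n_atoms} atoms"
        )
    phi = dictionary.matvec(alpha)
    n = dictionary.grid_size
    return phi.reshape(n, n)
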