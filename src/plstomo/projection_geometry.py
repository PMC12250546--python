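"""Parallel-beam scan geometries and the sparse tomographic system matrix.

The discrete forward model is ``y = A x`` where ``x`` is a pixelized image
flattened row-major and ``A`` holds exact ray--pixel intersection lengths
(Siddon-style traversal).  Rows of ``A`` are ordered angle-major: row
``a * n_detectors + d`` belongs to projection angle ``a`` and detector bin
``d``.

Coordinate conventions
----------------------
The image is an ``n x n`` square of unit pixels centred at the origin, so the
domain is ``[-n/2, n/2]^2``.  Pixel ``(i, j)`` (row, column; 0-based,
row-major) occupies ``x in [j - n/2, j + 1 - n/2]`` and
``y in [i - n/2, i + 1 - n/2]``.  A ray for angle ``theta`` and signed
detector offset ``t`` is the line ``{p : p . (cos t, sin t) = t}``; detector
offsets are centred on zero, ``t_d = (d - (n_det - 1)/2) * spacing``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BeamType",
    "ScanGeometry",
    "SystemMatrix",
    "Sinogram",
    "make_geometry",
    "build_system_matrix",
    "forward_project",
]


class BeamType(enum.Enum):
    """Beam shape; only parallel-beam is implemented (fan is reserved)."""

    PARALLEL = "parallel"


@dataclass(frozen=True)
class ScanGeometry:
    """A set of projection angles plus a linear detector array.

    Parameters
    ----------
    angles : ndarray
        Strictly increasing projection angles in radians, all in ``[0, 2*pi)``.
    n_detectors : int
        Number of detector bins per projection.
    detector_spacing : float
        Detector pitch in pixel units.
    angular_range : tuple of float
        The nominal ``(theta_min, theta_max)`` interval the angles sample.
    """

    angles: np.ndarray
    n_detectors: int
    detector_spacing: float = 1.0
    angular_range: tuple[float, float] = (0.0, math.pi)
    beam_type: BeamType = BeamType.PARALLEL

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D array")
        if np.any(angles < 0.0) or np.any(angles >= 2.0 * math.pi):
            raise ValueError("angles must lie in [0, 2*pi)")
        if angles.size > 1 and np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.n_detectors < 1:
            raise ValueError("n_detectors must be positive")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    @property
    def n_projections(self) -> int:
        return int(self.angles.size)

    @property
    def n_rays(self) -> int:
        return self.n_projections * self.n_detectors

    def detector_offsets(self) -> np.ndarray:
        """Signed detector-centre offsets from the rotation axis."""
        d = np.arange(self.n_detectors, dtype=float)
        return (d - (self.n_detectors - 1) / 2.0) * self.detector_spacing

    def check_coverage(self, grid_size: int) -> bool:
        """Warn unless the detector array spans the image diagonal."""
        diagonal = math.sqrt(2.0) * grid_size
        covered = self.n_detectors * self.detector_spacing >= diagonal
        if not covered:
            warnings.warn(
                "detector array narrower than the image diagonal; "
                "lateral truncation will occur",
                stacklevel=2,
            )
        return covered


@dataclass(frozen=True)
class SystemMatrix:
    """Sparse projection operator with back-references to its geometry."""

    matrix: sp.csr_array
    geometry: ScanGeometry
    grid_size: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dot(self, image: np.ndarray) -> np.ndarray:
        """Forward projection ``A @ x`` (accepts flat or 2-D image)."""
        x = np.asarray(image, dtype=float).ravel()
        if x.size != self.matrix.shape[1]:
            raise ValueError(
                f"image has {x.size} pixels, system matrix expects "
                f"{self.matrix.shape[1]}"
            )
        return self.matrix @ x

    def rmatvec(self, sino: np.ndarray) -> np.ndarray:
        """Backprojection ``A.T @ s`` returned as a flat pixel vector."""
        s = np.asarray(sino, dtype=float).ravel()
        if s.size != self.matrix.shape[0]:
            raise ValueError("sinogram size does not match system matrix rows")
        return self.matrix.T @ s


@dataclass
class Sinogram:
    """Projection data indexed ``(angle, detector)`` plus noise metadata."""

    values: np.ndarray
    geometry: ScanGeometry
    noise_level: float = 0.0
    noise_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_projections, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


def make_geometry(
    n_projections: int,
    angular_range: tuple[float, float] = (0.0, math.pi),
    n_detectors: Optional[int] = None,
    *,
    grid_size: Optional[int] = None,
    detector_spacing: float = 1.0,
) -> ScanGeometry:
    """Equally spaced angles on the half-open interval ``[t_min, t_max)``.

    The half-open convention avoids duplicating the redundant 0 and pi views
    of a parallel beam.  If ``n_detectors`` is omitted, ``grid_size`` must be
    given and the default ``ceil(sqrt(2) * grid_size)`` covers the diagonal.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    lo, hi = float(angular_range[0]), float(angular_range[1])
    if hi <= lo:
        raise ValueError("angular_range must have positive width")
    if n_detectors is None:
        if grid_size is None:
            raise ValueError("provide n_detectors or grid_size")
        n_detectors = math.ceil(math.sqrt(2.0) * grid_size)
    if n_detectors < 1:
        raise ValueError("n_detectors must be >= 1")
    angles = lo + (hi - lo) * np.arange(n_projections) / n_projections
    return ScanGeometry(
        angles=angles,
        n_detectors=int(n_detectors),
        detector_spacing=detector_spacing,
        angular_range=(lo, hi),
    )


def _ray_pixel_weights(
    theta: float, t: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Siddon traversal of one ray through the ``n x n`` unit-pixel grid.

    Returns (flat pixel indices, intersection lengths).  The ray is
    ``P(s) = t*(cos,sin) + s*(-sin,cos)``.
    """
    c, s_ = math.cos(theta), math.sin(theta)
    half = n / 2.0
    # Entry/exit parameters against the bounding square via slab clipping.
    p0 = np.array([t * c, t * s_])
    d = np.array([-s_, c])
    s_lo, s_hi = -np.inf, np.inf
    for axis in range(2):
        if abs(d[axis]) < 1e-14:
            if not (-half <= p0[axis] <= half):
                return np.empty(0, dtype=np.int64), np.empty(0)
        else:
            sa = (-half - p0[axis]) / d[axis]
            sb = (half - p0[axis]) / d[axis]
            if sa > sb:
                sa, sb = sb, sa
            s_lo = max(s_lo, sa)
            s_hi = min(s_hi, sb)
    if not (s_hi > s_lo):
        return np.empty(0, dtype=np.int64), np.empty(0)

    # Crossing parameters with the x = const and y = const grid lines.
    planes = np.arange(n + 1) - half
    crossings = [np.array([s_lo, s_hi])]
    for axis in range(2):
        if abs(d[axis]) > 1e-14:
            sc = (planes - p0[axis]) / d[axis]
            crossings.append(sc[(sc > s_lo) & (sc < s_hi)])
    svals = np.unique(np.concatenate(crossings))
    if svals.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    lengths = np.diff(svals)
    mids = 0.5 * (svals[:-1] + svals[1:])
    px = p0[0] + mids * d[0]
    py = p0[1] + mids * d[1]
    cols = np.floor(px + half).astype(np.int64)
    rows = np.floor(py + half).astype(np.int64)
    ok = (cols >= 0) & (cols < n) & (rows >= 0) & (rows < n) & (lengths > 1e-12)
    return rows[ok] * n + cols[ok], lengths[ok]


def build_system_matrix(geom: ScanGeometry, grid_size: int) -> SystemMatrix:
    """Assemble the sparse projector for a square ``grid_size ** 2`` image.

    Row ``a * n_det + d`` holds the exact intersection lengths of the
    ``(angle a, detector d)`` ray with every pixel; rays that miss the image
    yield empty rows but are retained so the row index stays a pure function
    of ``(angle, detector)``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    geom.check_coverage(grid_size)
    offsets = geom.detector_offsets()
    n_rows = geom.n_rays
    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    vals_acc: list[np.ndarray] = []
    for a, theta in enumerate(geom.angles):
        for d, t in enumerate(offsets):
            idx, w = _ray_pixel_weights(float(theta), float(t), grid_size)
            if idx.size:
                r = a * geom.n_detectors + d
                rows_acc.append(np.full(idx.size, r, dtype=np.int64))
                cols_acc.append(idx)
                vals_acc.append(w)
    if rows_acc:
        rows = np.concatenate(rows_acc)
        cols = np.concatenate(cols_acc)
        vals = np.concatenate(vals_acc)
    else:  # pragma: no cover - degenerate geometry
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    mat = sp.csr_array(
        (vals, (rows, cols)), shape=(n_rows, grid_size * grid_size)
    )
    return SystemMatrix(matrix=mat, geometry=geom, grid_size=grid_size)


def forward_project(A: SystemMatrix, image: np.ndarray) -> Sinogram:
    """Exact sparse product ``A @ image`` reshaped into a sinogram."""
    y = A.dot(image)
    geom = A.geometry
    return Sinogram(
        values=y.reshape(geom.n_projections, geom.n_detectors),
        geometry=geom,
    )
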