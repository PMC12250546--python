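"""Synthetic piecewise-constant phantoms and projection noise.

Ground-truth images are rasterised at pixel centres from parametric shape
descriptions, so they take exactly the declared gray values (no anti-aliased
edges).  Shape parameters live in the normalised unit domain [0, 1]^2 with
(x, y) = ((col + 0.5)/n, (row + 0.5)/n).

The binary kinds mirror the usual discrete-tomography test classes: a convex
disc, an annulus (hole), two disjoint blobs (disconnection), a non-convex
blob with concavities, and a block letter.  The three-level kind nests a
high-density core inside a medium-density body, the shell/kernel/air
topology of a walnut slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .projection_geometry import Sinogram

__all__ = [
    "PhantomSpec",
    "make_binary_phantom",
    "make_three_level_phantom",
    "make_phantom",
    "add_projection_noise",
    "BINARY_KINDS",
]

BINARY_KINDS = ("disc", "annulus", "two_blobs", "nonconvex_blob", "letter")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic ground-truth image."""

    kind: str = "disc"
    grid_size: int = 64
    gray_levels: tuple[float, ...] = (0.0, 1.0)
    #: kind-specific geometry; empty means the built-in defaults below.
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BINARY_KINDS + ("nested_three_level",):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        n_expected = 3 if self.kind == "nested_three_level" else 2
        if len(self.gray_levels) != n_expected:
            raise ValueError(
                f"kind {self.kind!r} requires {n_expected} gray levels"
            )


def _unit_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(n) + 0.5) / n
    yy, xx = np.meshgrid(c, c, indexing="ij")
    return xx, yy


def _disc(xx, yy, cx, cy, r) -> np.ndarray:
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _check_inside(cx: float, cy: float, r: float) -> None:
    if cx - r < 0 or cx + r > 1 or cy - r < 0 or cy + r > 1:
        raise ValueError("shape exceeds the unit image domain")


def _binary_mask(spec: PhantomSpec) -> np.ndarray:
    n = spec.grid_size
    xx, yy = _unit_grid(n)
    p = spec.params
    if spec.kind == "disc":
        cx, cy, r = p.get("cx", 0.5), p.get("cy", 0.5), p.get("r", 0.3)
        _check_inside(cx, cy, r)
        return _disc(xx, yy, cx, cy, r)
    if spec.kind == "annulus":
        cx, cy = p.get("cx", 0.5), p.get("cy", 0.5)
        r_out, r_in = p.get("r_out", 0.32), p.get("r_in", 0.18)
        if r_in >= r_out:
            raise ValueError("annulus needs r_in < r_out")
        _check_inside(cx, cy, r_out)
        return _disc(xx, yy, cx, cy, r_out) & ~_disc(xx, yy, cx, cy, r_in)
    if spec.kind == "two_blobs":
        c1 = p.get("c1", (0.3, 0.34))
        c2 = p.get("c2", (0.68, 0.66))
        r1, r2 = p.get("r1", 0.14), p.get("r2", 0.17)
        _check_inside(*c1, r1)
        _check_inside(*c2, r2)
        m1 = _disc(xx, yy, *c1, r1)
        m2 = _disc(xx, yy, *c2, r2)
        if np.any(m1 & m2):
            raise ValueError("two_blobs components overlap")
        return m1 | m2
    if spec.kind == "nonconvex_blob":
        # Bean shape: union of two overlapping discs with a circular bite
        # taken between them - convexity defects on the lower boundary.
        body1 = p.get("body1", (0.40, 0.52, 0.21))
        body2 = p.get("body2", (0.62, 0.56, 0.17))
        bite = p.get("bite", (0.52, 0.34, 0.13))
        for cx, cy, r in (body1, body2):
            _check_inside(cx, cy, r)
        return (_disc(xx, yy, *body1) | _disc(xx, yy, *body2)) & ~_disc(
            xx, yy, *bite
        )
    if spec.kind == "letter":
        # Block capital "E" from axis-aligned bars.
        x0, x1 = p.get("x0", 0.28), p.get("x1", 0.72)
        y0, y1 = p.get("y0", 0.22), p.get("y1", 0.78)
        bar = p.get("bar", 0.12)
        stem = (xx >= x0) & (xx <= x0 + bar) & (yy >= y0) & (yy <= y1)
        bars = np.zeros_like(stem)
        for yc in (y0, 0.5 * (y0 + y1 - bar), y1 - bar):
            bars |= (xx >= x0) & (xx <= x1) & (yy >= yc) & (yy <= yc + bar)
        return stem | bars
    raise ValueError(f"not a binary kind: {spec.kind!r}")


def make_binary_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterise a two-level phantom; values are exactly {u0, u1}."""
    if spec.kind not in BINARY_KINDS:
        raise ValueError(f"kind {spec.kind!r} is not a binary phantom kind")
    u0, u1 = spec.gray_levels
    mask = _binary_mask(spec)
    return np.where(mask, u1, u0).astype(float)


def make_three_level_phantom(spec: PhantomSpec) -> np.ndarray:
    """Nested three-level phantom: body at u1 with a core at u2 inside it."""
    if spec.kind != "nested_three_level":
        raise ValueError("spec.kind must be 'nested_three_level'")
    u0, u1, u2 = spec.gray_levels
    n = spec.grid_size
    xx, yy = _unit_grid(n)
    p = spec.params
    cx, cy = p.get("cx", 0.5), p.get("cy", 0.5)
    r_body = p.get("r_body", 0.34)
    core = p.get("core", (0.54, 0.46, 0.15))
    _check_inside(cx, cy, r_body)
    body = _disc(xx, yy, cx, cy, r_body)
    core_mask = _disc(xx, yy, *core)
    if np.any(core_mask & ~body):
        raise ValueError("core must be nested strictly inside the body")
    img = np.full((n, n), u0, dtype=float)
    img[body] = u1
    img[core_mask] = u2
    return img


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "nested_three_level":
        return make_three_level_phantom(spec)
    return make_binary_phantom(spec)


def add_projection_noise(
    y: Sinogram, n: float, seed: Optional[int] = None
) -> Sinogram:
    """Additive i.i.d. Gaussian noise with sigma = n * max(y).

    The noise level ``n`` is relative to the peak sinogram value, so it is
    invariant to rescaling of the data.  ``n = 0`` returns the input
    unchanged.
    """
    if n < 0:
        raise ValueError("noise level must be >= 0")
    if n == 0:
        return y
    rng = np.random.default_rng(seed)
    sigma = n * float(np.max(y.values))
    noisy = y.values + rng.normal(0.0, sigma, size=y.values.shape)
    return Sinogram(
        values=noisy, geometry=y.geometry, noise_level=n, noise_seed=seed
    )
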