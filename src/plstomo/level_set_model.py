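"""Smoothed-Heaviside level-set image model for discrete tomography.

A level-set field phi partitions the domain through its c-super-level set:
the object is {phi > c} for a small positive offset c.  The indicator is
smoothed over a band [-epsilon, epsilon] so the piecewise-constant image
u(x, alpha) is differentiable in the level-set coefficients.  Two-region
images use one field; three-region images use two fields whose sign
combinations select the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LevelSetConfig",
    "smooth_heaviside",
    "smooth_delta",
    "compose_two_region",
    "compose_three_region",
    "jacobian_two_region",
    "jacobian_three_region",
]


@dataclass(frozen=True)
class LevelSetConfig:
    """Smoothing band half-width, level offset, and the known gray levels.

    ``epsilon`` and ``c`` are in level-set-field units.  ``epsilon > c`` is
    recommended so an initial near-zero field sits inside the smoothing band
    and produces informative gradients.
    """

    epsilon: float = 0.1
    c: float = 0.05
    gray_levels: tuple[float, ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.c <= 0:
            raise ValueError("c must be a small positive value")
        levels = tuple(float(u) for u in self.gray_levels)
        object.__setattr__(self, "gray_levels", levels)
        if len(levels) not in (2, 3):
            raise ValueError("gray_levels must list 2 or 3 values")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("gray levels must be strictly increasing")

    @property
    def n_level_sets(self) -> int:
        return len(self.gray_levels) - 1


def smooth_heaviside(t: np.ndarray | float, epsilon: float) -> np.ndarray:
    """Continuous ramp approximation of the unit step over [-eps, eps].

    1 for t > eps, 0 for t < -eps, and
    1/2 + t/(2 eps) + sin(pi t / eps) / (2 pi) inside the band.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    t = np.asarray(t, dtype=float)
    inner = 0.5 + t / (2.0 * epsilon) + np.sin(np.pi * t / epsilon) / (2.0 * np.pi)
    return np.where(t > epsilon, 1.0, np.where(t < -epsilon, 0.0, inner))


def smooth_delta(t: np.ndarray | float, epsilon: float) -> np.ndarray:
    """Exact derivative of :func:`smooth_heaviside`.

    (1 + cos(pi t / eps)) / (2 eps) on [-eps, eps], zero outside; integrates
    to one over the band.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    t = np.asarray(t, dtype=float)
    inner = (1.0 + np.cos(np.pi * t / epsilon)) / (2.0 * epsilon)
    return np.where(np.abs(t) <= epsilon, inner, 0.0)


def _require_levels(cfg: LevelSetConfig, n: int) -> None:
    if len(cfg.gray_levels) != n:
        raise ValueError(
            f"expected {n} gray levels, config has {len(cfg.gray_levels)}"
        )


def compose_two_region(phi: np.ndarray, cfg: LevelSetConfig) -> np.ndarray:
    """u = u0 (1 - H(phi - c)) + u1 H(phi - c)."""
    _require_levels(cfg, 2)
    u0, u1 = cfg.gray_levels
    h = smooth_heaviside(np.asarray(phi, dtype=float) - cfg.c, cfg.epsilon)
    return u0 * (1.0 - h) + u1 * h


def compose_three_region(
    phi1: np.ndarray, phi2: np.ndarray, cfg: LevelSetConfig
) -> np.ndarray:
    """u = u0 + (u1 - u0) H(phi1 - c) + (u2 - u1) H(phi1 - c) H(phi2 - c).

    Region map: phi1 < c -> u0; phi1 > c, phi2 < c -> u1; both above -> u2.
    """
    _require_levels(cfg, 3)
    u0, u1, u2 = cfg.gray_levels
    h1 = smooth_heaviside(np.asarray(phi1, dtype=float) - cfg.c, cfg.epsilon)
    h2 = smooth_heaviside(np.asarray(phi2, dtype=float) - cfg.c, cfg.epsilon)
    return u0 + (u1 - u0) * h1 + (u2 - u1) * h1 * h2


def jacobian_two_region(phi: np.ndarray, cfg: LevelSetConfig) -> np.ndarray:
    """Pixelwise sensitivity du/dphi = (u1 - u0) delta(phi - c).

    The caller contracts this diagonal field with the dictionary matrix to
    obtain du/dalpha.
    """
    _require_levels(cfg, 2)
    u0, u1 = cfg.gray_levels
    return (u1 - u0) * smooth_delta(
        np.asarray(phi, dtype=float) - cfg.c, cfg.epsilon
    )


def jacobian_three_region(
    phi1: np.ndarray, phi2: np.ndarray, cfg: LevelSetConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise sensitivities (du/dphi1, du/dphi2) of the three-region model."""
    _require_levels(cfg, 3)
    u0, u1, u2 = cfg.gray_levels
    t1 = np.asarray(phi1, dtype=float) - cfg.c
    t2 = np.asarray(phi2, dtype=float) - cfg.c
    d1 = smooth_delta(t1, cfg.epsilon)
    d2 = smooth_delta(t2, cfg.epsilon)
    h1 = smooth_heaviside(t1, cfg.epsilon)
    h2 = smooth_heaviside(t2, cfg.epsilon)
    field1 = (u1 - u0) * d1 + (u2 - u1) * d1 * h2
    field2 = (u2 - u1) * h1 * d2
    return field1, field2
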