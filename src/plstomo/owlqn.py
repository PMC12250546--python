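"""Orthant-Wise Limited-memory Quasi-Newton (OWL-QN) solver.

Minimises f(x) = l(x) + C * ||x||_1 for a smooth loss l.  The l1 term is
linear inside any orthant, so the solver picks a reference orthant from the
pseudo-gradient, computes an L-BFGS direction from the smooth curvature,
projects the direction and every trial point back into that orthant, and
backtracks on an Armijo condition expressed through the pseudo-gradient.
The projection produces exact zeros, so iterates stay genuinely sparse.

The solver is generic: it knows nothing about tomography and can be used on
any smooth-plus-l1 problem.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "OwlqnOptions",
    "OwlqnResult",
    "pseudo_gradient",
    "orthant_project",
    "choose_orthant",
    "two_loop_direction",
    "minimize",
]


@dataclass(frozen=True)
class OwlqnOptions:
    """Solver settings.

    ``C`` is the l1 weight (0 reduces the solver to projected L-BFGS, and
    the projection is inert away from the axes).  ``memory`` is the number
    of stored curvature pairs.  Convergence: sup-norm of the pseudo-gradient
    below ``gradient_tolerance``, or relative objective change below
    ``f_relative_tolerance``, or ``max_iterations``.
    """

    C: float = 0.0
    memory: int = 10
    max_iterations: int = 1000
    gradient_tolerance: float = 1e-6
    f_relative_tolerance: float = 1e-10
    armijo_sigma: float = 1e-4
    backtrack_factor: float = 0.5
    min_step: float = 1e-12

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if min(self.gradient_tolerance, self.f_relative_tolerance) <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.backtrack_factor < 1):
            raise ValueError("backtrack_factor must be in (0, 1)")


@dataclass
class OwlqnResult:
    x: np.ndarray
    f: float
    trace: list[float]
    n_iterations: int
    converged: bool
    status: str


def pseudo_gradient(grad_l: np.ndarray, x: np.ndarray, C: float) -> np.ndarray:
    """Steepest one-sided descent direction of l(x) + C ||x||_1.

    Componentwise: g + C sign(x) where x != 0; at x = 0 the subgradient
    interval [g - C, g + C] is clipped toward zero (g + C if g < -C,
    g - C if g > C, else 0).
    """
    grad_l = np.asarray(grad_l, dtype=float)
    x = np.asarray(x, dtype=float)
    if grad_l.shape != x.shape:
        raise ValueError("grad_l and x must have the same shape")
    pg = grad_l + C * np.sign(x)
    at_zero = x == 0
    g0 = grad_l[at_zero]
    pz = np.zeros_like(g0)
    pz[g0 < -C] = g0[g0 < -C] + C
    pz[g0 > C] = g0[g0 > C] - C
    pg[at_zero] = pz
    return pg


def orthant_project(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Zero every component of ``x`` whose sign differs from ``ref``.

    ``sign(0) = 0``, so components with a zero reference are zeroed too.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("x and ref must have the same shape")
    out = np.where(np.sign(x) == np.sign(ref), x, 0.0)
    return out


def choose_orthant(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Reference orthant: sign(x) where x != 0, else sign(v)."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.where(x != 0, np.sign(x), np.sign(v))


def two_loop_direction(
    history: deque[tuple[np.ndarray, np.ndarray]], v: np.ndarray
) -> np.ndarray:
    """L-BFGS two-loop recursion: approximate inverse-Hessian product H v.

    Initial scaling (s.y)/(y.y) from the most recent pair; the identity is
    used with an empty history.
    """
    if not history:
        return v.copy()
    q = v.copy()
    alphas = []
    rhos = []
    for s, y in reversed(history):
        rho = 1.0 / (y @ s)
        a = rho * (s @ q)
        q -= a * y
        alphas.append(a)
        rhos.append(rho)
    s_last, y_last = history[-1]
    q *= (s_last @ y_last) / (y_last @ y_last)
    for (s, y), a, rho in zip(history, reversed(alphas), reversed(rhos)):
        b = rho * (y @ q)
        q += (a - b) * s
    return q


def minimize(
    smooth_loss: Callable[[np.ndarray], float],
    smooth_grad: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    options: Optional[OwlqnOptions] = None,
    callback: Optional[Callable[[int, np.ndarray, float], None]] = None,
) -> OwlqnResult:
    """Run OWL-QN from ``x0``; returns the best iterate and objective trace."""
    opts = options or OwlqnOptions()
    C = opts.C
    x = np.asarray(x0, dtype=float).copy()

    def f_total(z: np.ndarray) -> float:
        return smooth_loss(z) + C * np.abs(z).sum()

    g = np.asarray(smooth_grad(x), dtype=float)
    fx = f_total(x)
    if not np.isfinite(fx) or not np.all(np.isfinite(g)):
        raise ValueError("loss or gradient non-finite at the initial point")

    history: deque[tuple[np.ndarray, np.ndarray]] = deque(maxlen=opts.memory)
    trace = [fx]
    status = "max_iterations"
    converged = False

    for k in range(opts.max_iterations):
        pg = pseudo_gradient(g, x, C)
        if np.max(np.abs(pg)) <= opts.gradient_tolerance:
            status, converged = "gradient_tolerance", True
            break
        v = -pg
        xi = choose_orthant(x, v)

        p = orthant_project(two_loop_direction(history, v), v)
        if p @ v <= 0:
            # Not a descent direction for the pseudo-gradient: fall back to
            # projected steepest descent and drop the stale history.
            history.clear()
            p = orthant_project(v, v)
            if p @ v <= 0:
                status, converged = "stationary", True
                break

        # First iteration: scale the steepest-descent step to unit length so
        # badly scaled problems do not need dozens of backtracks.
        step = 1.0 if history else min(1.0, 1.0 / np.linalg.norm(p))
        accepted = False
        while step >= opts.min_step:
            x_new = orthant_project(x + step * p, xi)
            f_new = f_total(x_new)
            decrease = pg @ (x - x_new)
            if np.isfinite(f_new) and f_new <= fx - opts.armijo_sigma * decrease:
                accepted = True
                break
            step *= opts.backtrack_factor
        if not accepted:
            status, converged = "line_search_stagnation", True
            break

        g_new = np.asarray(smooth_grad(x_new), dtype=float)
        s = x_new - x
        yv = g_new - g
        if s @ yv > 1e-12:
            history.append((s, yv))

        f_prev, x, g, fx = fx, x_new, g_new, f_new
        trace.append(fx)
        if callback is not None:
            callback(k, x, fx)
        denom = max(abs(f_prev), abs(fx), 1.0)
        if abs(f_prev - fx) / denom <= opts.f_relative_tolerance:
            status, converged = "f_relative_tolerance", True
            break

    return OwlqnResult(
        x=x,
        f=fx,
        trace=trace,
        n_iterations=len(trace) - 1,
        converged=converged,
        status=status,
    )
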