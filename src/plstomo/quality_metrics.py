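"""Image-quality metrics: MSE, PSNR, SSIM and the Dice coefficient.

SSIM defaults to the single-window ("global statistics") form computed from
the means, variances and covariance of the whole images with stabilisers
c1 = (k1 L)^2, c2 = (k2 L)^2.  A sliding-window mean variant (the common
practice behind most SSIM implementations) is available behind a flag and
delegates to scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["MetricReport", "mse", "psnr", "ssim", "dice", "evaluate_images"]


def _as_pair(x: np.ndarray, x_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(x, dtype=float)
    b = np.asarray(x_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(x: np.ndarray, x_ref: np.ndarray) -> float:
    """Mean squared error over all pixels."""
    a, b = _as_pair(x, x_ref)
    return float(np.mean((a - b) ** 2))


def psnr(x: np.ndarray, x_ref: np.ndarray, max_value: float = 1.0) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images give +inf."""
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    err = mse(x, x_ref)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / err))


def ssim(
    x: np.ndarray,
    x_ref: np.ndarray,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
    windowed: bool = False,
) -> float:
    """Structural similarity between two images.

    Default is the global-statistics form
    ((2 mu_x mu_y + c1)(2 cov + c2)) / ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2))
    with population (1/N) moments.  ``windowed=True`` instead averages local
    SSIM over sliding windows via scikit-image.
    """
    a, b = _as_pair(x, x_ref)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=data_range))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a = a.var()
    var_b = b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def dice(
    truth: np.ndarray,
    recon: np.ndarray,
    level: float,
    gray_levels: Optional[Sequence[float]] = None,
) -> float:
    """Overlap 2|A n B| / (|A| + |B|) of the masks at ``level``.

    Both masks empty is scored 1 (perfect agreement on absence).  If
    ``gray_levels`` is given, ``level`` must be one of them.
    """
    a, b = _as_pair(truth, recon)
    if gray_levels is not None and level not in [float(g) for g in gray_levels]:
        raise ValueError(f"level {level} not in gray-level set {gray_levels}")
    mask_a = a == level
    mask_b = b == level
    denom = int(mask_a.sum()) + int(mask_b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(mask_a & mask_b) / denom)


@dataclass
class MetricReport:
    """Bundle of all metrics for one truth/reconstruction pair."""

    mse: float
    psnr: float
    ssim: float
    dice: dict[float, float]

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "dice": {str(k): v for k, v in self.dice.items()},
        }


def evaluate_images(
    truth: np.ndarray,
    recon: np.ndarray,
    gray_levels: Sequence[float],
    max_value: Optional[float] = None,
) -> MetricReport:
    """All metrics at once; Dice is computed per non-background level."""
    levels = [float(g) for g in gray_levels]
    if max_value is None:
        max_value = max(levels) if max(levels) > 0 else 1.0
    return MetricReport(
        mse=mse(recon, truth),
        psnr=psnr(recon, truth, max_value=max_value),
        ssim=ssim(recon, truth, data_range=max_value),
        dice={lv: dice(truth, recon, lv) for lv in levels[1:]},
    )
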