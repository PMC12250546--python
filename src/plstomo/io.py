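"""Plain-text I/O for sinograms, images and run manifests.

Sinograms are stored as a CSV matrix (one row per projection angle) with a
JSON sidecar describing the geometry and any noise metadata.  Images go to
CSV and, optionally, 8-bit grayscale PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .projection_geometry import ScanGeometry, Sinogram

__all__ = [
    "save_sinogram",
    "load_sinogram",
    "save_image_csv",
    "load_image_csv",
    "save_image_png",
    "load_mat_sinogram",
]


def save_sinogram(path: str | Path, sino: Sinogram) -> None:
    """Write ``path``.csv (values) and ``path``.json (geometry sidecar)."""
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), sino.values, delimiter=",")
    geom = sino.geometry
    sidecar = {
        "angles": list(map(float, geom.angles)),
        "n_detectors": geom.n_detectors,
        "detector_spacing": geom.detector_spacing,
        "angular_range": list(geom.angular_range),
        "noise_level": sino.noise_level,
        "noise_seed": sino.noise_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    values = np.loadtxt(path.with_suffix(".csv"), delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = ScanGeometry(
        angles=np.asarray(meta["angles"], dtype=float),
        n_detectors=int(meta["n_detectors"]),
        detector_spacing=float(meta["detector_spacing"]),
        angular_range=tuple(meta["angular_range"]),
    )
    return Sinogram(
        values=values,
        geometry=geom,
        noise_level=float(meta.get("noise_level", 0.0)),
        noise_seed=meta.get("noise_seed"),
    )


def save_image_csv(path: str | Path, image: np.ndarray) -> None:
    np.savetxt(Path(path), np.asarray(image, dtype=float), delimiter=",")


def load_image_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)


def save_image_png(path: str | Path, image: np.ndarray) -> None:
    """8-bit grayscale PNG, linearly rescaled to the image's value range."""
    from PIL import Image

    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    arr = ((img - lo) * scale).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_mat_sinogram(
    path: str | Path, key: Optional[str] = None
) -> np.ndarray:
    """Optional reader for MATLAB ``.mat`` sinogram files.

    Returns the raw array under ``key`` (or the single non-metadata array).
    Interpreting the scanner geometry of a specific dataset is left to the
    caller.
    """
    from scipy.io import loadmat

    data = loadmat(str(path))
    arrays = {k: v for k, v in data.items() if not k.startswith("__")}
    if key is not None:
        return np.asarray(arrays[key])
    if len(arrays) != 1:
        raise ValueError(
            f"ambiguous .mat contents {sorted(arrays)}; pass key explicitly"
        )
    return np.asarray(next(iter(arrays.values())))
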