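"""Flat QC projections of caliber-classified vessels.

Interactive 3D rendering is out of scope; for quick visual QC the caliber
map is collapsed to a color-coded maximum-intensity projection along z,
with classes grouped as small (cyan), medium (yellow) and large (red)
calibers — for the default bin set that is 1–5, 5–19 and 19–75 µm².
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .caliber import CaliberResult

__all__ = ["caliber_projection", "save_projection"]

_GROUP_COLORS = (
    (0.0, 1.0, 1.0),  # cyan: smallest third of the classes
    (1.0, 1.0, 0.0),  # yellow: middle third
    (1.0, 0.0, 0.0),  # red: largest third
)


def caliber_projection(result: CaliberResult) -> np.ndarray:
    """RGB max-intensity z-projection of the per-class wall masks."""
    k = result.volumes.bin_set.n_classes
    shape = result.caliber_map.shape
    rgb = np.zeros((shape[1], shape[2], 3), dtype=float)
    bounds = np.array_split(np.arange(k), 3)
    for group, color in zip(bounds, _GROUP_COLORS):
        mask = np.zeros(shape, dtype=bool)
        for c in group:
            mask |= result.wall_masks[c].voxels
        proj = mask.any(axis=0)
        for ch in range(3):
            rgb[..., ch] = np.maximum(rgb[..., ch], proj * color[ch])
    return rgb


def save_projection(result: CaliberResult, path: str | Path) -> None:
    """Write the color-coded projection as a PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(Path(path), caliber_projection(result))
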