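"""Vessel caliber classification by minimal Cartesian cross-section.

A voxel's caliber proxy is the smallest area, in pixels, of the 2D
connected vessel component containing it among its three Cartesian slices
(xy, xz, yz). Computed on *filled* vessels (hollow walls inherit the
section of the whole tube, not of their own 1-px wall), the proxy bins
voxels into pixel-area classes whose µm² labels follow from the isotropic
pitch: with 0.54 µm pixels the default bin set spans 4–256 px ≈ 1–75 µm²,
i.e. microvessels below roughly 10 µm diameter. Voxels whose minimal
section falls outside the bin range (large vessels, sub-resolution debris)
are excluded with label 0.

Processing order: remove sub-resolution particles, fill hollow vessels,
compute per-voxel minimal sections, bin, then intersect each class mask
with the unfilled input to recover wall voxels; filled − wall = lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .stacks import BinaryVolume

__all__ = [
    "CaliberBinSet",
    "BIN_SETS",
    "CaliberMap",
    "ClassVolumes",
    "CaliberResult",
    "CaliberClassifier",
    "remove_small_particles",
    "fill_vessels",
    "min_cartesian_cross_section",
    "classify_voxels",
    "px_to_um2",
]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
_SQUARE = np.ones((3, 3), dtype=bool)  # 8-connectivity


def px_to_um2(area_px: float, pitch: float = 0.54) -> int:
    """Convert a pixel area to the rounded µm² label used for bin names.

    With the default 0.54 µm pitch this reproduces the published bin
    labels, e.g. 128 px → 37 µm² and 256 px → 75 µm². The unrounded
    product is ``area_px * pitch**2``.
    """
    if area_px < 0:
        raise ValueError("pixel area must be non-negative")
    if pitch <= 0:
        raise ValueError("pitch must be strictly positive")
    return int(round(area_px * pitch * pitch))


@dataclass(frozen=True)
class CaliberBinSet:
    """An ordered, contiguous set of half-open pixel-area bins.

    ``bounds_px`` lists K+1 strictly increasing integers defining K bins
    ``[bounds[k], bounds[k+1])``. Areas below the first bound or at/above
    the last are excluded (class label 0). µm² labels are derived from the
    pitch by :func:`px_to_um2`.
    """

    name: str
    bounds_px: tuple[int, ...]
    pitch: float = 0.54

    def __post_init__(self) -> None:
        b = self.bounds_px
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bin bounds must be strictly increasing with >= 2 entries")

    @property
    def n_classes(self) -> int:
        return len(self.bounds_px) - 1

    @property
    def bins_px(self) -> list[tuple[int, int]]:
        b = self.bounds_px
        return [(b[k], b[k + 1]) for k in range(self.n_classes)]

    @property
    def bins_um2(self) -> list[tuple[int, int]]:
        return [(px_to_um2(lo, self.pitch), px_to_um2(hi, self.pitch)) for lo, hi in self.bins_px]

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}um2" for lo, hi in self.bins_um2]

    def class_of(self, area_px: float) -> int:
        """Class index (1..K) of a pixel area; 0 if outside the bin range."""
        if area_px < self.bounds_px[0] or area_px >= self.bounds_px[-1]:
            return 0
        return int(np.searchsorted(self.bounds_px, area_px, side="right"))

    def classify_areas(self, areas: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`class_of`; 0 stays 0 (background)."""
        areas = np.asarray(areas)
        labels = np.searchsorted(self.bounds_px, areas, side="right").astype(np.int32)
        labels[(areas < self.bounds_px[0]) | (areas >= self.bounds_px[-1])] = 0
        return labels


#: The four redundant presets, in geometric progression of pixel area.
#: set1 is the default (its µm² labels read 1-2, 2-5, 5-9, 9-19, 19-37,
#: 37-75 at 0.54 µm pitch); the other three interleave it so that the 21
#: classes together tile the 1-75 µm² range redundantly.
BIN_SETS: dict[str, CaliberBinSet] = {
    "set1": CaliberBinSet("set1", (4, 8, 16, 32, 64, 128, 256)),
    "set2": CaliberBinSet("set2", (5, 10, 20, 40, 80, 160)),
    "set3": CaliberBinSet("set3", (6, 12, 24, 48, 96, 192)),
    "set4": CaliberBinSet("set4", (7, 14, 28, 56, 112, 224)),
}


@dataclass
class CaliberMap:
    """Per-voxel caliber class labels plus the underlying minimal sections."""

    labels: np.ndarray  # int32, 0 = background/excluded, 1..K = class
    min_cross_section_px: np.ndarray  # int64, 0 on background
    bin_set: CaliberBinSet

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class ClassVolumes:
    """Voxel counts per caliber class: filled, wall (∩ input) and lumen."""

    bin_set: CaliberBinSet
    filled_counts: np.ndarray  # (K,)
    wall_counts: np.ndarray  # (K,)

    @property
    def lumen_counts(self) -> np.ndarray:
        return self.filled_counts - self.wall_counts

    def to_frame(self, sample: str = "") -> pd.DataFrame:
        rows = []
        for k, (lo, hi) in enumerate(self.bin_set.bins_px):
            rows.append(
                {
                    "sample": sample,
                    "class": k + 1,
                    "lower_px": lo,
                    "upper_px": hi,
                    "filled": int(self.filled_counts[k]),
                    "wall": int(self.wall_counts[k]),
                    "lumen": int(self.lumen_counts[k]),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CaliberResult:
    """Full output of caliber classification for one sample."""

    caliber_map: CaliberMap
    volumes: ClassVolumes
    wall_masks: list[BinaryVolume] = field(repr=False)
    filled: BinaryVolume = field(repr=False)
    input_vol: BinaryVolume = field(repr=False)


def _slices_along(vol: np.ndarray, axis: int):
    for i in range(vol.shape[axis]):
        yield i, np.take(vol, i, axis=axis)


def remove_small_particles(vol: BinaryVolume, min_area_px: int = 4) -> BinaryVolume:
    """Delete 3D components whose largest 2D cross-section is below a floor.

    A 26-connected component survives iff the maximum area over all of its
    2D 8-connected in-slice components, across the three Cartesian slice
    orientations, is at least ``min_area_px`` (default 4 px ≈ 1 µm² at
    0.54 µm pitch). Long 1-voxel filaments therefore survive (their
    lengthwise sections are large) while isolated speckles do not.
    """
    v = vol.voxels
    lab3, n = ndimage.label(v, structure=_CUBE)
    if n == 0:
        return BinaryVolume(v.copy(), pitch=vol.pitch)
    max_area = np.zeros(n + 1, dtype=np.int64)
    for axis in range(3):
        for i, sl in _slices_along(v, axis):
            lab2, m = ndimage.label(sl, structure=_SQUARE)
            if m == 0:
                continue
            areas2 = np.bincount(lab2.ravel())
            lab3_sl = np.take(lab3, i, axis=axis)
            fg = lab2 > 0
            np.maximum.at(max_area, lab3_sl[fg], areas2[lab2[fg]])
    keep = max_area >= min_area_px
    keep[0] = False
    return BinaryVolume(keep[lab3], pitch=vol.pitch)


def fill_vessels(vol: BinaryVolume) -> BinaryVolume:
    """Fill hollow vessels by slice-wise 2D hole filling in all 3 orientations.

    Holes are filled independently in every xy, xz and yz slice and the
    three filled volumes are unioned with the input. Slice-wise filling
    (rather than one 3D fill) is what closes tubes that are open at the
    stack faces; tubes oblique to one orientation are caught by another.
    Output is a superset of the input.
    """
    v = vol.voxels
    out = v.copy()
    for axis in range(3):
        filled = np.zeros_like(v)
        idx = [slice(None)] * 3
        for i, sl in _slices_along(v, axis):
            idx[axis] = i
            filled[tuple(idx)] = ndimage.binary_fill_holes(sl)
        out |= filled
    return BinaryVolume(out, pitch=vol.pitch)


def min_cartesian_cross_section(filled: BinaryVolume) -> np.ndarray:
    """Per-voxel minimal Cartesian cross-section area, in pixels.

    For each foreground voxel, the area of the 2D 8-connected component
    containing it is measured in its xy, xz and yz slices; the minimum of
    the three is returned. Background voxels get 0.
    """
    v = filled.voxels
    out = np.where(v, np.iinfo(np.int64).max, 0).astype(np.int64)
    for axis in range(3):
        idx = [slice(None)] * 3
        for i, sl in _slices_along(v, axis):
            lab2, m = ndimage.label(sl, structure=_SQUARE)
            if m == 0:
                continue
            areas2 = np.bincount(lab2.ravel())
            area_sl = np.where(sl, areas2[lab2], 0)
            idx[axis] = i
            out[tuple(idx)] = np.minimum(out[tuple(idx)], np.where(sl, area_sl, out[tuple(idx)]))
    return out


def classify_voxels(
    input_vol: BinaryVolume,
    filled: BinaryVolume,
    bins: CaliberBinSet | str = "set1",
) -> CaliberResult:
    """Label filled voxels by caliber bin and intersect with the input walls.

    ``input_vol`` is the particle-filtered, *unfilled* binary volume;
    ``filled`` its hole-filled counterpart. Each filled voxel is binned by
    its minimal Cartesian cross-section; sections at or above the top
    bound (256 px for the default set — overly large vessels) or below the
    bottom bound are excluded as label 0. Per-class wall masks are the
    class masks intersected with ``input_vol``; lumen = filled − wall.
    """
    if isinstance(bins, str):
        bins = BIN_SETS[bins]
    if input_vol.shape != filled.shape:
        raise ValueError(
            f"input volume {input_vol.shape} and filled volume {filled.shape} differ in shape"
        )
    if not np.all(filled.voxels[input_vol.voxels]):
        raise ValueError("filled volume must be a superset of the input volume")
    mcs = min_cartesian_cross_section(filled)
    labels = bins.classify_areas(mcs)
    labels[~filled.voxels] = 0

    k = bins.n_classes
    filled_counts = np.bincount(labels.ravel(), minlength=k + 1)[1:].astype(np.int64)
    wall_labels = np.where(input_vol.voxels, labels, 0)
    wall_counts = np.bincount(wall_labels.ravel(), minlength=k + 1)[1:].astype(np.int64)
    wall_masks = [
        BinaryVolume(wall_labels == c, pitch=input_vol.pitch) for c in range(1, k + 1)
    ]
    cmap = CaliberMap(labels=labels, min_cross_section_px=mcs, bin_set=bins)
    volumes = ClassVolumes(bin_set=bins, filled_counts=filled_counts, wall_counts=wall_counts)
    return CaliberResult(
        caliber_map=cmap,
        volumes=volumes,
        wall_masks=wall_masks,
        filled=filled,
        input_vol=input_vol,
    )


class CaliberClassifier(BaseEstimator, TransformerMixin):
    """Particle filter → vessel fill → minimal-section binning, as one transformer.

    Parameters
    ----------
    bin_set : str or CaliberBinSet, default "set1"
        Caliber bins; the named presets are in :data:`BIN_SETS`.
    min_particle_px : int, default 4
        Particle-filter floor on the maximal 2D cross-section (px);
        4 px ≈ 1 µm² at the default 0.54 µm pitch.
    """

    def __init__(self, bin_set: str | CaliberBinSet = "set1", min_particle_px: int = 4):
        self.bin_set = bin_set
        self.min_particle_px = min_particle_px

    def _bins(self) -> CaliberBinSet:
        return BIN_SETS[self.bin_set] if isinstance(self.bin_set, str) else self.bin_set

    def fit(self, X: BinaryVolume, y=None):
        return self

    def transform(self, X: BinaryVolume) -> CaliberResult:
        cleaned = remove_small_particles(X, min_area_px=self.min_particle_px)
        filled = fill_vessels(cleaned)
        return classify_voxels(cleaned, filled, self._bins())
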