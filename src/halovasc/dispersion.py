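"""Volumetric spatial dispersion: the Halo index (Hv) and its normalized form (nHv).

The dispersion of vessel voxels in a stack is measured by growing them
with a *rhombicuboctahedral* dilation — alternating the 6-neighbor 3D
cross and the 3×3×3 cube structuring elements, which approximates
spherical expansion on the voxel grid — and counting how many cycles it
takes for the foreground to occupy a target fraction (default 90%) of the
stack. Few cycles = space-filling, homogeneous layout; many cycles =
clustered layout. The fractional cycle count at which the fill curve
crosses the target, by linear interpolation between the bracketing
cycles, is the volumetric Halo index Hv.

Because a sample with more initial voxels fills the stack sooner whatever
its layout, cohorts are compared with a normalized index: every sample is
first notionally grown to the cohort's largest initial foreground count
(the cycles needed, again fractional, are ``norm_cycles``), and
nHv = Hv − norm_cycles. nHv is comparable only within a cohort sharing
one normalization count and one stack geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .stacks import BinaryVolume

__all__ = [
    "FillCurve",
    "DispersionResult",
    "HaloDispersion",
    "rhombicuboctahedral_step",
    "fill_curve",
    "halo_index",
    "cohort_normalization_count",
    "normalized_halo",
]

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-neighbor 3D cross
_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-neighbor cube


@dataclass
class FillCurve:
    """Foreground counts per dilation cycle, starting at cycle 0."""

    counts: np.ndarray  # (n_cycles+1,) absolute foreground voxels
    total_voxels: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total_voxels

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(len(self.counts))

    def to_frame(self, sample: str = "", label: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": sample,
                "class": label,
                "cycle": self.cycles,
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


@dataclass
class DispersionResult:
    """Hv, the normalization cycles and nHv for one volume."""

    hv: float
    norm_cycles: float
    nhv: float
    target_fraction: float
    normalization_count: int
    initial_count: int
    curve: FillCurve = field(repr=False)


def rhombicuboctahedral_step(vol: BinaryVolume, cycle_index: int) -> BinaryVolume:
    """One alternating-dilation cycle: cross on odd cycles, cube on even.

    ``cycle_index`` is 1-based. Growth is clipped at the stack faces (no
    wraparound, no padding beyond the grid).
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based; got < 1")
    selem = _CROSS if cycle_index % 2 == 1 else _CUBE
    grown = ndimage.binary_dilation(vol.voxels, structure=selem)
    return BinaryVolume(grown, pitch=vol.pitch)


def _fill_counts(
    voxels: np.ndarray, stop_count: float, cross_first: bool = True
) -> np.ndarray:
    """Dilate until the foreground count reaches ``stop_count`` (or saturation)."""
    counts = [int(voxels.sum())]
    current = voxels
    cycle = 0
    total = voxels.size
    while counts[-1] < stop_count and counts[-1] < total:
        cycle += 1
        odd = cycle % 2 == 1
        selem = _CROSS if odd == cross_first else _CUBE
        current = ndimage.binary_dilation(current, structure=selem)
        counts.append(int(current.sum()))
    return np.asarray(counts, dtype=np.int64)


def fill_curve(
    vol: BinaryVolume, target_fraction: float = 0.90, cross_first: bool = True
) -> FillCurve:
    """Grow ``vol`` by alternating dilation until it covers ``target_fraction``.

    The curve starts at cycle 0 with the initial count and stops at the
    first cycle whose foreground fraction reaches the target (any nonempty
    set eventually saturates the grid, so termination is guaranteed).
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if vol.foreground_count == 0:
        raise ValueError("no foreground to expand: empty volume has no fill curve")
    stop = target_fraction * vol.voxels.size
    counts = _fill_counts(vol.voxels, stop, cross_first=cross_first)
    return FillCurve(counts=counts, total_voxels=vol.voxels.size)


def _interp_cycles(counts: np.ndarray, target_count: float) -> float:
    """Fractional cycles at which the monotone count curve reaches a value."""
    if np.any(np.diff(counts) < 0):
        raise ValueError("fill curve is not monotone; upstream dilation is broken")
    if counts[0] >= target_count:
        return 0.0
    idx = np.nonzero(counts >= target_count)[0]
    if idx.size == 0:
        raise ValueError("fill curve never reaches the requested count")
    c = int(idx[0])
    prev, curr = counts[c - 1], counts[c]
    return (c - 1) + (target_count - prev) / (curr - prev)


def halo_index(curve: FillCurve, target_fraction: float = 0.90) -> float:
    """Hv: fractional dilation cycles to reach the target fill fraction.

    With c the first cycle at/above target: Hv = (c−1) +
    (target − f_{c−1}) / (f_c − f_{c−1}); 0 if the initial fraction
    already meets the target.
    """
    return _interp_cycles(curve.counts, target_fraction * curve.total_voxels)


def cohort_normalization_count(samples: list[BinaryVolume]) -> int:
    """Largest initial foreground count across the cohort (the nHv reference).

    All samples must share one stack shape — nHv values compared across
    different geometries would be meaningless.
    """
    if not samples:
        raise ValueError("need at least one sample")
    shapes = {s.shape for s in samples}
    if len(shapes) > 1:
        raise ValueError(f"samples differ in stack dimensions: {sorted(shapes)}")
    return max(s.foreground_count for s in samples)


def normalized_halo(
    vol: BinaryVolume,
    normalization_count: int,
    target_fraction: float = 0.90,
    cross_first: bool = True,
    integer_norm: bool = False,
) -> DispersionResult:
    """Hv, norm_cycles and nHv = Hv − norm_cycles for one volume.

    ``norm_cycles`` is the (by default fractional, interpolated like Hv)
    number of cycles the sample needs to grow to ``normalization_count``
    voxels — 0 for the cohort's largest sample. ``integer_norm=True``
    uses instead the first whole cycle at/above the normalization count.
    """
    n0 = vol.foreground_count
    if normalization_count < n0:
        raise ValueError(
            f"normalization count {normalization_count} below the sample's "
            f"initial count {n0}; normalize to the cohort maximum"
        )
    if normalization_count > target_fraction * vol.voxels.size:
        raise ValueError("normalization count exceeds the target fill volume")
    curve = fill_curve(vol, target_fraction=target_fraction, cross_first=cross_first)
    hv = halo_index(curve, target_fraction)
    norm = _interp_cycles(curve.counts, normalization_count)
    if integer_norm:
        norm = float(np.ceil(norm))
    return DispersionResult(
        hv=hv,
        norm_cycles=norm,
        nhv=hv - norm,
        target_fraction=target_fraction,
        normalization_count=int(normalization_count),
        initial_count=n0,
        curve=curve,
    )


class HaloDispersion(BaseEstimator, TransformerMixin):
    """Cohort-wise nHv computation as a fit/transform estimator.

    ``fit`` records the cohort normalization count (the maximum initial
    foreground count over the fitted volumes, unless ``normalization_count``
    is given); ``transform`` returns a :class:`DispersionResult` per
    volume. Empty volumes yield NaN results (dispersion of an absent
    vessel class is missing by design, not zero).

    Parameters
    ----------
    target_fraction : float, default 0.90
        Fill fraction defining Hv.
    cross_first : bool, default True
        Dilation parity: cross on odd cycles, cube on even. Hv depends on
        this, so it is part of a run's recorded provenance.
    integer_norm : bool, default False
        Use whole cycles instead of interpolated cycles for norm_cycles.
    normalization_count : int, optional
        Fixed normalization count overriding the fitted cohort maximum.
    """

    def __init__(
        self,
        target_fraction: float = 0.90,
        cross_first: bool = True,
        integer_norm: bool = False,
        normalization_count: int | None = None,
    ):
        self.target_fraction = target_fraction
        self.cross_first = cross_first
        self.integer_norm = integer_norm
        self.normalization_count = normalization_count

    def fit(self, X: list[BinaryVolume], y=None):
        if self.normalization_count is not None:
            self.normalization_count_ = int(self.normalization_count)
        else:
            nonempty = [v for v in X if v.foreground_count > 0]
            if not nonempty:
                raise ValueError("cohort contains no nonempty volume")
            shapes = {v.shape for v in X}
            if len(shapes) > 1:
                raise ValueError(f"samples differ in stack dimensions: {sorted(shapes)}")
            self.normalization_count_ = cohort_normalization_count(nonempty)
        return self

    def transform(self, X: list[BinaryVolume]) -> list[DispersionResult]:
        results = []
        for vol in X:
            if vol.foreground_count == 0:
                results.append(
                    DispersionResult(
                        hv=float("nan"),
                        norm_cycles=float("nan"),
                        nhv=float("nan"),
                        target_fraction=self.target_fraction,
                        normalization_count=self.normalization_count_,
                        initial_count=0,
                        curve=FillCurve(
                            counts=np.array([0], dtype=np.int64),
                            total_voxels=vol.voxels.size,
                        ),
                    )
                )
            else:
                results.append(
                    normalized_halo(
                        vol,
                        self.normalization_count_,
                        target_fraction=self.target_fraction,
                        cross_first=self.cross_first,
                        integer_norm=self.integer_norm,
                    )
                )
        return results
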