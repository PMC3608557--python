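"""Voxel-grid containers and TIFF stack I/O.

The package works on two kinds of 3D grids: :class:`GreyStack` (8-bit
fluorescence intensities with possibly anisotropic voxel pitch, as acquired
by a confocal microscope) and :class:`BinaryVolume` (vessel masks on an
isotropic grid). Stacks are stored axis order ``(z, y, x)``: page, row,
column of the multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GreyStack",
    "BinaryVolume",
    "UnsupportedFormatError",
    "read_stack",
    "write_stack",
    "read_binary",
    "write_binary",
]


class UnsupportedFormatError(ValueError):
    """Raised for stacks that are not single-channel 8-bit greyscale."""


@dataclass
class GreyStack:
    """An 8-bit greyscale confocal z-stack with voxel pitch metadata.

    Parameters
    ----------
    voxels
        ``(z, y, x)`` array of uint8 intensities.
    lateral_pitch
        In-plane pixel edge length in µm (e.g. 0.54 for a 40× NA 1.0
        oil objective on the acquisition system the defaults emulate).
    axial_pitch
        Distance between consecutive z-slices in µm (e.g. 1.0).
    """

    voxels: np.ndarray
    lateral_pitch: float = 0.54
    axial_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.voxels.ndim}")
        if self.voxels.dtype != np.uint8:
            if np.issubdtype(self.voxels.dtype, np.integer) and (
                self.voxels.min(initial=0) >= 0 and self.voxels.max(initial=0) <= 255
            ):
                self.voxels = self.voxels.astype(np.uint8)
            else:
                raise UnsupportedFormatError(
                    f"intensities must be 8-bit (0..255); got dtype {self.voxels.dtype}"
                )
        if not (self.lateral_pitch > 0 and self.axial_pitch > 0):
            raise ValueError("voxel pitches must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.lateral_pitch, self.axial_pitch)


@dataclass
class BinaryVolume:
    """A boolean vessel mask on an isotropic voxel grid.

    ``voxels`` is a ``(z, y, x)`` boolean array; ``pitch`` is the common
    edge length of a voxel in µm.
    """

    voxels: np.ndarray
    pitch: float = 0.54

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels > 0
        if not self.pitch > 0:
            raise ValueError("pitch must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_count / self.voxels.size


def read_stack(
    path: str | Path,
    lateral_pitch: float | None = None,
    axial_pitch: float | None = None,
) -> GreyStack:
    """Read a single- or multi-page 8-bit greyscale TIFF as a :class:`GreyStack`.

    Pitch is taken from the arguments when given; otherwise from TIFF
    resolution metadata (XResolution in pixels/µm and the ImageJ
    ``spacing`` tag); an error is raised if neither source provides it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise UnsupportedFormatError(
                f"{path.name}: expected greyscale pages, got array of shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            raise UnsupportedFormatError(
                f"{path.name}: only 8-bit greyscale TIFF is supported, got {arr.dtype}"
            )
        meta_lateral = meta_axial = None
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:  # pixels per unit -> µm per pixel
                meta_lateral = den / num
        ij = tif.imagej_metadata
        if ij and "spacing" in ij:
            meta_axial = float(ij["spacing"])
    lateral = lateral_pitch if lateral_pitch is not None else meta_lateral
    axial = axial_pitch if axial_pitch is not None else meta_axial
    if lateral is None or axial is None:
        raise ValueError(
            f"{path.name}: voxel pitch not found in TIFF metadata; "
            "pass lateral_pitch/axial_pitch explicitly"
        )
    return GreyStack(arr, lateral_pitch=float(lateral), axial_pitch=float(axial))


def write_stack(stack: GreyStack, path: str | Path) -> None:
    """Write a :class:`GreyStack` as an ImageJ-compatible 8-bit TIFF."""
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        imagej=True,
        resolution=(1.0 / stack.lateral_pitch, 1.0 / stack.lateral_pitch),
        metadata={"spacing": stack.axial_pitch, "unit": "um", "axes": "ZYX"},
    )


def read_binary(path: str | Path, pitch: float | None = None) -> BinaryVolume:
    """Read a binary mask stored as an 8-bit TIFF (0 = background, >0 = vessel)."""
    stack = read_stack(path, lateral_pitch=pitch, axial_pitch=pitch)
    return BinaryVolume(stack.voxels > 0, pitch=stack.lateral_pitch)


def write_binary(vol: BinaryVolume, path: str | Path) -> None:
    """Write a :class:`BinaryVolume` as an 8-bit TIFF encoding 0/255."""
    write_stack(
        GreyStack(
            vol.voxels.astype(np.uint8) * 255,
            lateral_pitch=vol.pitch,
            axial_pitch=vol.pitch,
        ),
        path,
    )
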