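"""Whole-tumor VOI handling: loading, gray-level normalization, quantization.

The volume of interest (VOI) is the manually delineated whole-lesion 3D mask
drawn on contrast-enhanced MR volumes.  Before any texture computation the
VOI intensities are normalized by clipping to the window ``mu +/- 3*sigma``
(``mu`` and ``sigma`` computed over the VOI voxels only) and mapping linearly
onto ``Ng`` discrete gray levels ``1..Ng``.  This per-lesion windowing makes
every downstream texture feature invariant to global brightness/contrast
changes of the scanner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeWithMask",
    "NormalizationParams",
    "QuantizedVOI",
    "DimensionMismatchError",
    "EmptyVOIError",
    "DataError",
    "load_volume_mask",
    "normalize_voi",
]


class DimensionMismatchError(ValueError):
    """Volume and mask shapes disagree."""


class EmptyVOIError(ValueError):
    """Mask selects no voxels."""


class DataError(ValueError):
    """Non-finite or otherwise unusable intensity data."""


@dataclass
class VolumeWithMask:
    """A 3D scalar intensity volume with an aligned binary lesion mask.

    Parameters
    ----------
    voxels
        3D array of scalar intensities (arbitrary units).
    mask
        3D boolean array of the same shape; True marks VOI voxels.
    spacing
        Voxel spacing in mm, informational only.
    """

    voxels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.mask = np.asarray(self.mask) > 0
        if self.voxels.ndim != 3:
            raise DimensionMismatchError(
                f"expected a 3D volume, got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape != self.mask.shape:
            raise DimensionMismatchError(
                f"volume shape {self.voxels.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise EmptyVOIError("mask selects no voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def voi_values(self) -> np.ndarray:
        """Intensities of the VOI voxels, in C order of their coordinates."""
        return self.voxels[self.mask]


@dataclass
class NormalizationParams:
    """Gray-level normalization parameters for one VOI.

    ``window`` is ``(mu - 3*sigma, mu + 3*sigma)``; ``sigma`` uses the
    population convention (divide by the voxel count Np).
    """

    mu: float
    sigma: float
    n_levels: int

    @property
    def window(self) -> tuple[float, float]:
        return (self.mu - 3.0 * self.sigma, self.mu + 3.0 * self.sigma)


@dataclass
class QuantizedVOI:
    """A VOI after clipping and quantization to integer gray levels 1..Ng.

    ``coords`` is an (Np, 3) integer array of 0-based voxel indices and
    ``levels`` the matching (Np,) array of gray levels.
    """

    coords: np.ndarray
    levels: np.ndarray
    shape: tuple[int, int, int]
    n_levels: int
    _dense: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.intp).reshape(-1, 3)
        self.levels = np.asarray(self.levels, dtype=np.int64).reshape(-1)
        if len(self.coords) != len(self.levels):
            raise ValueError("coords and levels length mismatch")
        if len(self.levels) == 0:
            raise EmptyVOIError("quantized VOI is empty")
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("levels outside 1..Ng")

    @property
    def n_voxels(self) -> int:
        return len(self.levels)

    def to_dense(self) -> np.ndarray:
        """Dense int array of the volume shape; 0 outside the VOI."""
        if self._dense is None:
            dense = np.zeros(self.shape, dtype=np.int64)
            dense[tuple(self.coords.T)] = self.levels
            self._dense = dense
        return self._dense

    @property
    def mask(self) -> np.ndarray:
        return self.to_dense() > 0

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            coords=self.coords,
            levels=self.levels,
            shape=np.asarray(self.shape),
            n_levels=np.asarray(self.n_levels),
        )

    @classmethod
    def load(cls, path) -> "QuantizedVOI":
        with np.load(path) as z:
            return cls(
                coords=z["coords"],
                levels=z["levels"],
                shape=tuple(int(s) for s in z["shape"]),
                n_levels=int(z["n_levels"]),
            )


def load_volume_mask(volume_path, mask_path) -> VolumeWithMask:
    """Load a NIfTI volume and its aligned binary mask.

    The mask is binarized at ``> 0``.  Arrays are taken in the on-disk
    layout; no reorientation is performed.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    voxels = np.asarray(vol_img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if voxels.shape != mask.shape:
        raise DimensionMismatchError(
            f"volume shape {voxels.shape} != mask shape {mask.shape}"
        )
    zooms = vol_img.header.get_zooms()[:3]
    spacing = tuple(float(z) if z > 0 else 1.0 for z in zooms)
    return VolumeWithMask(voxels=voxels, mask=mask, spacing=spacing)


def normalize_voi(
    vm: VolumeWithMask, n_levels: int = 64
) -> tuple[QuantizedVOI, NormalizationParams]:
    """Clip VOI intensities to ``mu +/- 3*sigma`` and quantize to 1..Ng.

    ``mu`` and ``sigma`` are computed over mask voxels only, with the
    population (divide-by-Np) convention for ``sigma``.  Each intensity x is
    clipped to the window and mapped to
    ``level = 1 + floor((x_clipped - (mu - 3*sigma)) / (6*sigma) * Ng)``,
    with the exact upper endpoint mapped to ``Ng``.  A zero-variance VOI maps
    every voxel to level 1 (logged as a warning) so constant phantoms remain
    usable.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    values = vm.voi_values()
    if not np.all(np.isfinite(values)):
        raise DataError("VOI contains non-finite intensities")
    mu = float(values.mean())
    sigma = float(values.std())  # population: ddof=0
    coords = np.argwhere(vm.mask)
    if sigma == 0.0:
        logger.warning("zero-variance VOI: all voxels mapped to level 1")
        levels = np.ones(len(values), dtype=np.int64)
    else:
        lo = mu - 3.0 * sigma
        hi = mu + 3.0 * sigma
        clipped = np.clip(values, lo, hi)
        levels = 1 + np.floor((clipped - lo) / (6.0 * sigma) * n_levels).astype(
            np.int64
        )
        np.clip(levels, 1, n_levels, out=levels)  # exact upper endpoint -> Ng
    q = QuantizedVOI(
        coords=coords, levels=levels, shape=vm.voxels.shape, n_levels=n_levels
    )
    return q, NormalizationParams(mu=mu, sigma=sigma, n_levels=n_levels)
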