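"""Density-calibrated 3-D image handling: filtering, binning, masking, volumes.

Registered longitudinal micro-CT volumes are represented as `DensityImage`
objects holding mineral density in mg HA/cm^3 on a regular voxel grid
(nominally 10.5 um).  The multi-density analysis stratifies every
measurement into bands of mineral density from 395 to 720 mg HA/cm^3 in
steps of 25; band 0 is soft tissue / background below the lowest edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DensityImage",
    "DensityBands",
    "BandedImage",
    "RegionMasks",
    "gaussian_prefilter",
    "bin_to_bands",
    "make_region_masks",
    "bone_volume_by_threshold",
    "load_density_image",
    "save_density_image",
]

#: Default cortical-bone segmentation threshold, mg HA/cm^3.
CORTEX_THRESHOLD = 645.0


@dataclass
class DensityImage:
    """A registered 3-D mineral-density image.

    Axes are (x, y, z) with z the anatomical / loading axis; ``spacing_um``
    gives the voxel edge lengths in micrometres.
    """

    values: np.ndarray  # mg HA/cm^3
    spacing_um: tuple[float, float, float] = (10.5, 10.5, 10.5)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("DensityImage requires a 3-D array")
        if np.any(np.asarray(self.spacing_um) <= 0):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(np.asarray(self.spacing_um) / 1000.0))

    def crop(self, slices: tuple[slice, slice, slice]) -> "DensityImage":
        """Extract an analysis subvolume (configurable crop)."""
        return DensityImage(
            values=self.values[slices],
            spacing_um=self.spacing_um,
            origin_um=self.origin_um,
        )


@dataclass
class DensityBands:
    """Ordered density band edges (mg HA/cm^3), default 395..720 step 25.

    The first edge is the bone / soft-tissue boundary.  Band intervals are
    half-open ``[edge_k, edge_{k+1})``; the top band is closed at its upper
    edge, so a voxel at exactly the highest edge belongs to the top band.
    """

    edges: tuple[float, ...] = tuple(float(v) for v in range(395, 721, 25))

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        self.edges = edges

    @property
    def n_bands(self) -> int:
        """Number of bone bands (band indices 1..n_bands)."""
        return len(self.edges)

    def assign(self, density: np.ndarray) -> np.ndarray:
        """Band index per value: 0 below the first edge, else highest edge <= value."""
        idx = np.searchsorted(self.edges, np.asarray(density, dtype=float), side="right")
        return idx.astype(np.int16)


@dataclass
class BandedImage:
    """Per-voxel density band indices (0 = soft tissue / background)."""

    band_index: np.ndarray
    bands: DensityBands
    spacing_um: tuple[float, float, float] = (10.5, 10.5, 10.5)

    def __post_init__(self) -> None:
        self.band_index = np.asarray(self.band_index)
        if self.band_index.min(initial=0) < 0 or self.band_index.max(initial=0) > self.bands.n_bands:
            raise ValueError("band indices out of range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.band_index.shape

    def bone_mask(self, bone_band_min: int = 1) -> np.ndarray:
        return self.band_index >= bone_band_min


class RegionMasks:
    """Anatomical region labels derived from the baseline (week-0) image.

    Labels: 0 outside, 1 cortical, 2 medullary (marrow cavity enclosed by
    the cortex), 3 peripheral (everything else in the analysis subvolume).
    Masks are static over the time series, as they derive from baseline.
    """

    OUTSIDE, CORTICAL, MEDULLARY, PERIPHERAL = 0, 1, 2, 3
    REGION_NAMES = {"cortical": 1, "medullary": 2, "peripheral": 3}

    def __init__(self, label: np.ndarray, spacing_um=(10.5, 10.5, 10.5)):
        self.label = np.asarray(label, dtype=np.int8)
        self.spacing_um = tuple(spacing_um)

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask for a named region, or the whole subvolume for 'all'."""
        if region == "all":
            return self.label != self.OUTSIDE
        if region not in self.REGION_NAMES:
            raise ValueError(
                f"unknown region {region!r}; expected one of "
                f"{sorted(self.REGION_NAMES)} or 'all'"
            )
        return self.label == self.REGION_NAMES[region]


def gaussian_prefilter(
    img: DensityImage, sigma: float = 1.2, support: int = 1
) -> DensityImage:
    """Gaussian noise filtration with a truncated kernel (default sigma 1.2,
    support 1 voxel), as conventional for micro-CT grayscale preprocessing.

    ``support`` is the truncation half-width in voxels, so the default is a
    3x3x3 kernel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if support < 1:
        raise ValueError("support must be >= 1 voxel")
    smoothed = ndimage.gaussian_filter(
        img.values, sigma=sigma, truncate=support / sigma, mode="nearest"
    )
    return DensityImage(values=smoothed, spacing_um=img.spacing_um, origin_um=img.origin_um)


def bin_to_bands(img: DensityImage, bands: Optional[DensityBands] = None) -> BandedImage:
    """Multi-density binning of a grayscale image into density bands."""
    bands = bands or DensityBands()
    return BandedImage(
        band_index=bands.assign(img.values), bands=bands, spacing_um=img.spacing_um
    )


def _ray_enclosed_slice(
    cortex: np.ndarray,
    center: tuple[float, float],
    n_dirs: int,
    step: float = 0.5,
) -> np.ndarray:
    """Voxels of a 2-D slice from which rays in every sampled transverse
    direction hit cortex (nearest-neighbour ray marching)."""
    nx, ny = cortex.shape
    if not cortex.any():
        return np.zeros_like(cortex, dtype=bool)
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    max_r = float(np.hypot(nx, ny))
    steps = np.arange(step, max_r + step, step)
    enclosed = np.ones((nx, ny), dtype=bool)
    for k in range(n_dirs):
        theta = 2.0 * np.pi * k / n_dirs
        dx, dy = np.cos(theta), np.sin(theta)
        hit = np.zeros((nx, ny), dtype=bool)
        for s in steps:
            px = np.rint(xs + s * dx).astype(int)
            py = np.rint(ys + s * dy).astype(int)
            inside = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
            newly = np.zeros((nx, ny), dtype=bool)
            newly[inside] = cortex[px[inside], py[inside]]
            hit |= newly
            if hit.all():
                break
        enclosed &= hit
        if not enclosed.any():
            break
    return enclosed


def make_region_masks(
    baseline: DensityImage,
    cortex_threshold: float = CORTEX_THRESHOLD,
    *,
    n_dirs: int = 16,
    closing_radius: int = 2,
) -> RegionMasks:
    """Segment cortical / medullary / peripheral regions from baseline.

    The cortex is thresholded at ``cortex_threshold`` (default 645 mg
    HA/cm^3).  The medullary cavity is recovered per transverse slice by
    radial ray casting: after morphological closing of the cortex, a voxel
    is medullary when rays in all ``n_dirs`` sampled transverse directions
    hit cortex.  Everything else inside the subvolume is peripheral.
    """
    cortex = baseline.values > cortex_threshold
    label = np.full(baseline.shape, RegionMasks.PERIPHERAL, dtype=np.int8)
    if not cortex.any():
        warnings.warn(
            "no voxel above the cortical threshold; all-peripheral masks returned",
            stacklevel=2,
        )
        return RegionMasks(label, baseline.spacing_um)
    if closing_radius > 0:
        r = closing_radius
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        selem = (xx**2 + yy**2 <= r**2)[:, :, None]  # transverse disk
        closed = ndimage.binary_closing(cortex, structure=selem)
    else:
        closed = cortex
    # in-plane centre of cortical mass (shared across slices; robust to the
    # defect slices, which contain no cortex at all)
    idx = np.nonzero(closed)
    center = (float(idx[0].mean()), float(idx[1].mean()))
    for z in range(baseline.shape[2]):
        sl = closed[:, :, z]
        enclosed = _ray_enclosed_slice(sl, center, n_dirs=n_dirs)
        med = enclosed & ~sl
        label[:, :, z][med] = RegionMasks.MEDULLARY
    label[cortex] = RegionMasks.CORTICAL
    return RegionMasks(label, baseline.spacing_um)


def bone_volume_by_threshold(
    img: DensityImage,
    bands: Optional[DensityBands] = None,
    masks: Optional[RegionMasks] = None,
    region: str = "all",
) -> pd.DataFrame:
    """Bone volume (mm^3) above each density threshold of the band sweep.

    Volume is voxel count above threshold times voxel volume, restricted to
    the requested region ('cortical', 'medullary', 'peripheral' or 'all').
    """
    bands = bands or DensityBands()
    if masks is not None:
        if masks.label.shape != img.shape:
            raise ValueError("image and masks are not aligned")
        sel = masks.region_mask(region)
    else:
        if region != "all":
            raise ValueError("region selection requires masks")
        sel = np.ones(img.shape, dtype=bool)
    vals = img.values[sel]
    rows = [
        {
            "region": region,
            "threshold_mgHA": edge,
            "volume_mm3": float(np.count_nonzero(vals >= edge) * img.voxel_volume_mm3),
        }
        for edge in bands.edges
    ]
    return pd.DataFrame(rows)


def load_density_image(path: str | Path) -> DensityImage:
    """Read a density image from NIfTI; spacing converted from mm to um."""
    nii = nib.load(str(path))
    values = np.asarray(nii.get_fdata(), dtype=float)
    spacing_mm = nii.header.get_zooms()[:3]
    return DensityImage(
        values=values, spacing_um=tuple(1000.0 * s for s in spacing_mm)
    )


def save_density_image(img: DensityImage, path: str | Path) -> None:
    """Write a density image to NIfTI with spacing recorded in mm."""
    affine = np.diag(list(np.asarray(img.spacing_um) / 1000.0) + [1.0])
    nii = nib.Nifti1Image(np.asarray(img.values, dtype=np.float32), affine)
    nii.header.set_zooms(tuple(np.asarray(img.spacing_um) / 1000.0))
    nib.save(nii, str(path))
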