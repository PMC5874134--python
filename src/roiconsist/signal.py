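"""Signal transformations: linear detrending, Gaussian spatial smoothing,
and ROI averaging (the voxel-mean ROI time series X_I)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .exceptions import DegenerateInputError, ValidationError
from .io import Parcellation, VoxelTimeSeriesSet

__all__ = [
    "SmoothingKernel",
    "ROITimeSeriesSet",
    "detrend_linear",
    "smooth_spatial",
    "roi_average",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SmoothingKernel:
    """Isotropic Gaussian kernel specified by its FWHM in millimetres.

    sigma = FWHM / (2 * sqrt(2 * ln 2)); the kernel is truncated at
    ``truncate_sigmas`` standard deviations.
    """

    fwhm_mm: float
    truncate_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValidationError("FWHM must be nonnegative")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm * _FWHM_TO_SIGMA


@dataclass
class ROITimeSeriesSet:
    """ROI-by-time matrix of averaged voxel signals, rows ordered by roi_id."""

    data: np.ndarray
    roi_ids: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.roi_ids = np.asarray(self.roi_ids, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.roi_ids):
            raise ValidationError("ROI matrix rows must match roi_ids")
        if len(self.sizes) != len(self.roi_ids):
            raise ValidationError("sizes must match roi_ids")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def row(self, roi_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if len(idx) != 1:
            raise ValidationError(f"unknown ROI id {roi_id}")
        return self.data[idx[0]]

    def to_tsv(self, path: str | Path, roi_names: list[str] | None = None) -> None:
        """Rows = ROIs, columns = time points, with an id/name header."""
        df = pd.DataFrame(self.data)
        df.insert(0, "roi_id", self.roi_ids)
        if roi_names is not None:
            df.insert(1, "roi_name", roi_names)
        df.to_csv(path, sep="\t", index=False)


def detrend_linear(vts: VoxelTimeSeriesSet) -> VoxelTimeSeriesSet:
    """Subtract each voxel's least-squares straight-line fit.

    Output series have exactly zero mean and zero linear trend.
    """
    if vts.n_timepoints < 3:
        raise ValidationError("detrending needs at least 3 time points")
    return vts.with_data(scipy.signal.detrend(vts.data, axis=1, type="linear"))


def smooth_spatial(
    vts: VoxelTimeSeriesSet,
    kernel: SmoothingKernel,
    mask: np.ndarray | None = None,
) -> VoxelTimeSeriesSet:
    """Convolve every time frame with an isotropic Gaussian, renormalized
    over in-mask voxels.

    Kernel weight falling outside the mask is dropped and the remaining
    weights rescaled to sum to one, so a spatially constant field is
    preserved exactly and no power leaks out at the brain boundary.
    ``fwhm_mm = 0`` is the identity.
    """
    if kernel.fwhm_mm == 0:
        return vts.with_data(vts.data.copy())
    if any(s <= 0 for s in vts.voxel_size_mm):
        raise ValidationError("voxel size must be known and positive")
    if mask is None:
        mask = vts.mask_volume()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(vts.grid_shape):
            raise ValidationError("mask shape does not match the grid")
    sigma_vox = tuple(
        kernel.sigma_mm / s for s in vts.voxel_size_mm
    )
    vol = vts.to_volume()
    vol[~mask] = 0.0
    num = scipy.ndimage.gaussian_filter(
        vol, sigma=sigma_vox + (0.0,), truncate=kernel.truncate_sigmas
    )
    den = scipy.ndimage.gaussian_filter(
        mask.astype(np.float64), sigma=sigma_vox, truncate=kernel.truncate_sigmas
    )
    rows = tuple(vts.coords.T)
    smoothed = num[rows] / den[rows][:, None]
    return vts.with_data(smoothed)


def roi_average(vts: VoxelTimeSeriesSet, parc: Parcellation) -> ROITimeSeriesSet:
    """Average member-voxel series into one time series per ROI.

    X_I is the unweighted time-point-wise mean over the N_I voxels of ROI I
    that are present in ``vts``; an ROI with no surviving voxels is an error.
    """
    members = parc.member_rows(vts)
    empty = [i for i in parc.roi_ids if len(members[int(i)]) == 0]
    if empty:
        raise DegenerateInputError(
            f"ROI(s) with zero surviving voxels: {[int(i) for i in empty]}"
        )
    data = np.stack(
        [vts.data[members[int(i)]].mean(axis=0) for i in parc.roi_ids]
    )
    sizes = np.array([len(members[int(i)]) for i in parc.roi_ids])
    return ROITimeSeriesSet(data=data, roi_ids=parc.roi_ids, sizes=sizes)
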