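"""Reading and writing voxel time series and ROI label volumes.

The in-memory containers used throughout the package live here:
:class:`VoxelTimeSeriesSet` (one row per in-mask voxel) and
:class:`Parcellation` (a 3-D integer label grid, 0 = background).
All coordinates are 0-based voxel grid indices ordered lexicographically
by (x, y, z); affines are consumed only at the NIfTI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "VoxelTimeSeriesSet",
    "Parcellation",
    "read_4d_image",
    "read_label_volume",
    "filter_low_power_voxels",
    "write_4d_image",
    "write_label_volume",
]


@dataclass
class VoxelTimeSeriesSet:
    """Voxel-by-time BOLD matrix with the grid coordinates of each row.

    Parameters
    ----------
    data : ndarray, shape (n_voxels, n_timepoints)
        One time series per voxel; all values finite.
    coords : ndarray of int, shape (n_voxels, 3)
        0-based (x, y, z) grid index of each row; unique, lexicographically
        ordered.
    grid_shape : tuple of int
        Spatial shape of the originating volume.
    voxel_size_mm : tuple of float
        Edge lengths of a voxel in millimetres.
    tr_seconds : float, optional
        Repetition time, if known.
    """

    data: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.intp)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValidationError(
                "time-series matrix must be (n_voxels, n_timepoints>=2); "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = int(np.sum(~np.isfinite(self.data).all(axis=1)))
            raise ValidationError(f"non-finite values in {bad} voxel series")
        if self.coords.shape != (self.data.shape[0], 3):
            raise ValidationError("coords must be (n_voxels, 3)")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise ValidationError("duplicate voxel coordinates")
        if np.any(self.coords < 0) or np.any(
            self.coords >= np.asarray(self.grid_shape)
        ):
            raise ValidationError("coordinates outside the grid")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def mask_volume(self) -> np.ndarray:
        """Boolean 3-D volume, True where a voxel row exists."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.coords.T)] = True
        return mask

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter rows back into a 4-D (x, y, z, t) array."""
        vol = np.full(self.grid_shape + (self.n_timepoints,), fill)
        vol[tuple(self.coords.T)] = self.data
        return vol

    def with_data(self, data: np.ndarray) -> "VoxelTimeSeriesSet":
        """Copy of this set with the time-series matrix replaced."""
        return replace(self, data=data)


@dataclass
class Parcellation:
    """3-D ROI label grid; label 0 is background, each voxel has one ROI."""

    labels: np.ndarray
    roi_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValidationError("non-integer labels in label grid")
            self.labels = self.labels.astype(np.int64)
        if np.any(self.labels < 0):
            raise ValidationError("negative labels in label grid")
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        if self.roi_ids is None:
            self.roi_ids = ids
        self.roi_ids = np.asarray(self.roi_ids, dtype=np.int64)
        if self.sizes is None:
            lookup = dict(zip(ids.tolist(), counts.tolist()))
            self.sizes = np.array([lookup.get(i, 0) for i in self.roi_ids])
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.roi_names is not None and len(self.roi_names) != len(self.roi_ids):
            raise ValidationError("roi_names length mismatch")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def member_rows(self, vts: VoxelTimeSeriesSet) -> dict[int, np.ndarray]:
        """Map each ROI id to the row indices of its voxels in ``vts``.

        Only voxels present in the time-series set count as members, so
        sizes derived from this mapping reflect masking and filtering.
        """
        voxel_labels = self.labels[tuple(vts.coords.T)]
        return {
            int(i): np.flatnonzero(voxel_labels == i) for i in self.roi_ids
        }

    def sizes_in(self, vts: VoxelTimeSeriesSet) -> np.ndarray:
        """Per-ROI voxel counts restricted to voxels present in ``vts``."""
        rows = self.member_rows(vts)
        return np.array([len(rows[int(i)]) for i in self.roi_ids])


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def read_4d_image(
    path: str | Path, mask_path: str | Path | None = None
) -> VoxelTimeSeriesSet:
    """Load a 4-D NIfTI image into a :class:`VoxelTimeSeriesSet`.

    The voxel mask is either an explicit 3-D NIfTI (nonzero = in-mask) or,
    by default, every voxel whose series is nonzero at any time point.
    Rows are ordered lexicographically by grid coordinate.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValidationError(f"expected a 4-D image, got {img.ndim}-D: {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    n_bad = int(np.sum(~np.isfinite(data).all(axis=3)))
    if n_bad:
        raise ValidationError(f"{n_bad} voxels contain NaN/Inf values")
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if mimg.shape != data.shape[:3]:
            raise ValidationError("mask shape does not match image grid")
        mask = np.asarray(mimg.get_fdata()) != 0
    else:
        mask = np.any(data != 0, axis=3)
    coords = np.argwhere(mask)  # C-order argwhere is lexicographic
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return VoxelTimeSeriesSet(
        data=data[mask],
        coords=coords,
        grid_shape=data.shape[:3],
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_seconds=tr,
    )


def read_label_volume(
    path: str | Path, image: VoxelTimeSeriesSet | None = None
) -> Parcellation:
    """Load a 3-D integer label volume as a :class:`Parcellation`.

    When ``image`` is given the grid shapes must match and ROI sizes are
    counted only over voxels present in the image (i.e. post-masking).
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValidationError(f"expected a 3-D label volume, got {img.ndim}-D")
    labels = np.asarray(img.get_fdata())
    parc = Parcellation(labels=labels)
    if image is not None:
        if parc.labels.shape != tuple(image.grid_shape):
            raise ValidationError(
                f"label grid {parc.labels.shape} does not match image grid "
                f"{tuple(image.grid_shape)}"
            )
        parc.sizes = parc.sizes_in(image)
    return parc


def filter_low_power_voxels(
    vts: VoxelTimeSeriesSet,
    fraction: float = 0.02,
    absolute_threshold: float | None = None,
) -> tuple[VoxelTimeSeriesSet, pd.DataFrame]:
    """Drop voxels whose signal power falls below a fraction of the mean.

    Signal power is the variance of the voxel time series, so the filter
    targets near-dead voxels (typically at the brain/skull edge) regardless
    of mean signal offset. A voxel is removed when its power is strictly
    below ``fraction`` times the mean power over all voxels; passing
    ``absolute_threshold`` instead reuses a previously recorded cutoff,
    which makes the filter idempotent.

    Returns the filtered set and a removal report with columns
    ``x, y, z, power, threshold``.
    """
    if absolute_threshold is None and not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    power = np.var(vts.data, axis=1)
    if absolute_threshold is not None:
        threshold = float(absolute_threshold)
    else:
        threshold = float(fraction * power.mean())
    removed = power < threshold
    if removed.all():
        raise DegenerateInputError(
            "low-power filter would remove every voxel "
            f"(threshold {threshold:.4g})"
        )
    report = pd.DataFrame(
        {
            "x": vts.coords[removed, 0],
            "y": vts.coords[removed, 1],
            "z": vts.coords[removed, 2],
            "power": power[removed],
            "threshold": threshold,
        }
    )
    kept = VoxelTimeSeriesSet(
        data=vts.data[~removed],
        coords=vts.coords[~removed],
        grid_shape=vts.grid_shape,
        voxel_size_mm=vts.voxel_size_mm,
        tr_seconds=vts.tr_seconds,
    )
    return kept, report


def write_4d_image(vts: VoxelTimeSeriesSet, path: str | Path) -> None:
    """Write the set as a 4-D NIfTI-1 image (identity RAS affine scaled
    by voxel size); out-of-mask voxels are zero-filled."""
    vol = vts.to_volume()
    img = nib.Nifti1Image(vol, _affine(vts.voxel_size_mm))
    if vts.tr_seconds is not None:
        zooms = vts.voxel_size_mm + (vts.tr_seconds,)
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_label_volume(
    parc: Parcellation,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> None:
    """Write the label grid as a 3-D NIfTI-1 volume."""
    img = nib.Nifti1Image(
        parc.labels.astype(np.int32), _affine(voxel_size_mm)
    )
    nib.save(img, str(path))
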