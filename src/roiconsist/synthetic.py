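"""Synthetic BOLD generator with known population correlation structure.

Each voxel time series is a variance-weighted sum of three zero-mean,
unit-variance Gaussian sources: a latent shared by all voxels of its ROI,
an optional brain-wide (global) latent, and voxel-unique noise::

    x_i = sqrt(a_I) * g_I + sqrt(b) * h + sqrt(1 - a_I - b) * eps_i

ROI latents g_I carry a configurable cross-correlation matrix R. Under
this model every downstream quantity has a closed form (see
:func:`expected_statistics`):

* population within-ROI voxel correlation (consistency)  phi*_I = a_I + b
* population cross-ROI voxel correlation  C*_vox(I,J) = sqrt(a_I a_J) R_IJ + b
* population ROI-level correlation  C*_ROI(I,J) = C*_vox / sqrt(v_I v_J),
  where v_I = a_I + b + (1 - a_I - b) / N_I is the variance of the ROI
  average of N_I voxels.

The averaging denominator v_I < 1 is what amplifies ROI-level correlations
above voxel-level ones: pairs of low-consistency ROIs can be strongly
correlated once their voxel signals are averaged.

Randomness is organised as one master seed with per-source substreams
(one per ROI latent, one per ROI noise block, one global), so changing
one ROI's size does not reshuffle any other ROI's draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import CapacityError, ValidationError
from .io import Parcellation, VoxelTimeSeriesSet, write_4d_image, write_label_volume

__all__ = [
    "SyntheticSpec",
    "generate_parcellation",
    "generate_voxel_timeseries",
    "expected_statistics",
    "write_dataset",
    "study_spec",
]

_PSD_TOL = 1e-8
_AR_BURN_IN = 100


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Parameters
    ----------
    roi_sizes : list of int
        Voxel count N_I of each ROI.
    n_timepoints : int
        Length T of every time series.
    shared_fraction : list of float
        Variance fraction a_I of the ROI-shared latent, one per ROI,
        each in [0, 1].
    global_fraction : float
        Variance fraction b of the brain-wide latent, in [0, 1];
        a_I + b must not exceed 1 for any ROI.
    latent_correlation : ndarray, optional
        Symmetric unit-diagonal positive-semidefinite matrix R of
        correlations among the ROI latents; defaults to the identity.
        Non-PSD input is rejected, not repaired.
    seed : int
        Master seed; regeneration with the same seed is bit-identical.
    grid_shape : tuple of int
        Voxel grid into which the ROIs are embedded as contiguous
        axis-aligned blocks.
    ar_coefficient : float
        Optional AR(1) coefficient applied to every latent and noise
        sequence (stationary unit variance); 0 = serially independent.
    voxel_size_mm : tuple of float
        Voxel edge length in mm, used only when writing NIfTI output.
    """

    roi_sizes: tuple[int, ...]
    n_timepoints: int
    shared_fraction: tuple[float, ...]
    global_fraction: float = 0.0
    latent_correlation: np.ndarray | None = None
    seed: int = 0
    grid_shape: tuple[int, int, int] = (10, 10, 10)
    ar_coefficient: float = 0.0
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_sizes", tuple(int(n) for n in self.roi_sizes))
        object.__setattr__(
            self, "shared_fraction", tuple(float(a) for a in self.shared_fraction)
        )
        if self.latent_correlation is not None:
            object.__setattr__(
                self,
                "latent_correlation",
                np.asarray(self.latent_correlation, dtype=np.float64),
            )
        self.validate()

    @property
    def n_rois(self) -> int:
        return len(self.roi_sizes)

    @property
    def R(self) -> np.ndarray:
        if self.latent_correlation is None:
            return np.eye(self.n_rois)
        return self.latent_correlation

    def validate(self) -> None:
        if self.n_rois < 1:
            raise ValidationError("at least one ROI required")
        if any(n < 1 for n in self.roi_sizes):
            raise ValidationError("ROI sizes must be positive")
        if self.n_timepoints < 2:
            raise ValidationError("need at least two time points")
        if len(self.shared_fraction) != self.n_rois:
            raise ValidationError("one shared_fraction per ROI required")
        b = self.global_fraction
        if not 0.0 <= b <= 1.0:
            raise ValidationError("global_fraction must lie in [0, 1]")
        for a in self.shared_fraction:
            if not 0.0 <= a <= 1.0:
                raise ValidationError("shared fractions must lie in [0, 1]")
            if a + b > 1.0 + 1e-12:
                raise ValidationError(
                    f"shared + global variance fraction exceeds 1 ({a} + {b})"
                )
        R = self.R
        if R.shape != (self.n_rois, self.n_rois):
            raise ValidationError("latent_correlation has wrong shape")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValidationError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValidationError("latent_correlation must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValidationError("latent correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(R).min() < -_PSD_TOL:
            raise ValidationError("latent_correlation is not positive semidefinite")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValidationError("ar_coefficient must lie in [0, 1)")
        if sum(self.roi_sizes) > int(np.prod(self.grid_shape)):
            raise CapacityError(
                f"total ROI volume {sum(self.roi_sizes)} exceeds grid capacity "
                f"{int(np.prod(self.grid_shape))}"
            )

    def to_json(self) -> str:
        d = {
            "roi_sizes": list(self.roi_sizes),
            "n_timepoints": self.n_timepoints,
            "shared_fraction": list(self.shared_fraction),
            "global_fraction": self.global_fraction,
            "latent_correlation": self.R.tolist(),
            "seed": self.seed,
            "grid_shape": list(self.grid_shape),
            "ar_coefficient": self.ar_coefficient,
            "voxel_size_mm": list(self.voxel_size_mm),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        return cls(
            roi_sizes=tuple(d["roi_sizes"]),
            n_timepoints=d["n_timepoints"],
            shared_fraction=tuple(d["shared_fraction"]),
            global_fraction=d.get("global_fraction", 0.0),
            latent_correlation=np.asarray(d["latent_correlation"])
            if d.get("latent_correlation") is not None
            else None,
            seed=d.get("seed", 0),
            grid_shape=tuple(d.get("grid_shape", (10, 10, 10))),
            ar_coefficient=d.get("ar_coefficient", 0.0),
            voxel_size_mm=tuple(d.get("voxel_size_mm", (4.0, 4.0, 4.0))),
        )


def _block_dims(n: int, grid: tuple[int, int, int]) -> tuple[int, int, int]:
    """Most compact axis-aligned block of exactly n voxels fitting the grid."""
    best: tuple[int, int, int] | None = None
    best_key: tuple[int, int] | None = None
    for dx in range(1, min(n, grid[0]) + 1):
        if n % dx:
            continue
        rem = n // dx
        for dy in range(1, min(rem, grid[1]) + 1):
            if rem % dy:
                continue
            dz = rem // dy
            if dz > grid[2]:
                continue
            key = (max(dx, dy, dz), dx * dy + dy * dz + dx * dz)
            if best_key is None or key < best_key:
                best, best_key = (dx, dy, dz), key
    if best is None:
        raise CapacityError(
            f"no axis-aligned block of {n} voxels fits a grid of shape {grid}"
        )
    return best


def generate_parcellation(spec: SyntheticSpec) -> Parcellation:
    """Embed each ROI as a contiguous axis-aligned block in the grid.

    Blocks are packed shelf-wise (rows along x, shelves along y, layers
    along z); ROI k gets label k+1 and exactly ``roi_sizes[k]`` voxels.
    Raises :class:`CapacityError` when the blocks cannot be packed.
    """
    spec.validate()
    gx, gy, gz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int64)
    dims = [_block_dims(n, spec.grid_shape) for n in spec.roi_sizes]
    # place big blocks first so shelves/layers are set by the tallest
    # blocks; labels keep the spec's ROI order
    order = sorted(range(len(dims)), key=lambda k: (-dims[k][2], -dims[k][1], -dims[k][0]))
    x = y = z = 0
    row_h = layer_d = 0
    for k in order:
        dx, dy, dz = dims[k]
        if x + dx > gx:
            x, y = 0, y + row_h
            row_h = 0
        if y + dy > gy:
            x, y, z = 0, 0, z + layer_d
            layer_d = 0
        if x + dx > gx or y + dy > gy or z + dz > gz:
            raise CapacityError(
                f"cannot pack ROI {k + 1} (block {dx}x{dy}x{dz}) into grid "
                f"{spec.grid_shape}"
            )
        labels[x : x + dx, y : y + dy, z : z + dz] = k + 1
        x += dx
        row_h = max(row_h, dy)
        layer_d = max(layer_d, dz)
    return Parcellation(labels=labels)


def _draw(rng: np.random.Generator, shape: tuple[int, ...], ar: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian sequences, optionally AR(1)."""
    if ar == 0.0:
        return rng.standard_normal(shape)
    burn = _AR_BURN_IN
    w = rng.standard_normal(shape[:-1] + (shape[-1] + burn,))
    x = lfilter([np.sqrt(1.0 - ar * ar)], [1.0, -ar], w, axis=-1)
    return np.asarray(x)[..., burn:]


def generate_voxel_timeseries(
    spec: SyntheticSpec, parcellation: Parcellation
) -> VoxelTimeSeriesSet:
    """Draw the voxel-by-time matrix from the shared-component model.

    Population correlations implied by the draw: a_I + b between voxels of
    the same ROI, and sqrt(a_I a_J) R_IJ + b between voxels of different
    ROIs. Reproducible bit-for-bit from ``spec.seed``.
    """
    spec.validate()
    if parcellation.n_rois != spec.n_rois:
        raise ValidationError(
            f"parcellation has {parcellation.n_rois} ROIs, spec has {spec.n_rois}"
        )
    T = spec.n_timepoints
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(2 * spec.n_rois + 1)
    latent_rngs = [np.random.default_rng(s) for s in streams[: spec.n_rois]]
    noise_rngs = [
        np.random.default_rng(s) for s in streams[spec.n_rois : 2 * spec.n_rois]
    ]
    global_rng = np.random.default_rng(streams[-1])

    Z = np.stack([_draw(r, (T,), spec.ar_coefficient) for r in latent_rngs])
    vals, vecs = np.linalg.eigh(spec.R)
    sqrt_R = (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    G = sqrt_R @ Z  # ROI latents with cross-correlation R
    h = _draw(global_rng, (T,), spec.ar_coefficient)

    coords = np.argwhere(parcellation.labels > 0)
    voxel_labels = parcellation.labels[tuple(coords.T)]
    data = np.empty((coords.shape[0], T))
    b = spec.global_fraction
    for k, roi_id in enumerate(parcellation.roi_ids):
        rows = np.flatnonzero(voxel_labels == roi_id)
        a = spec.shared_fraction[k]
        eps = _draw(noise_rngs[k], (len(rows), T), spec.ar_coefficient)
        data[rows] = (
            np.sqrt(a) * G[k]
            + np.sqrt(b) * h
            + np.sqrt(max(1.0 - a - b, 0.0)) * eps
        )
    return VoxelTimeSeriesSet(
        data=data,
        coords=coords,
        grid_shape=tuple(parcellation.labels.shape),
        voxel_size_mm=spec.voxel_size_mm,
    )


def expected_statistics(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form population values of every downstream statistic.

    Returns
    -------
    roi_table : DataFrame
        Columns ``roi_id, size, phi`` with phi*_I = a_I + b.
    pair_table : DataFrame
        One row per unordered ROI pair with columns ``roi_i, roi_j,
        mean_consistency, c_vox, c_roi``:

        * C*_vox = sqrt(a_I a_J) R_IJ + b
        * C*_ROI = C*_vox / sqrt(v_I v_J),
          v_I = a_I + b + (1 - a_I - b) / N_I.
    """
    spec.validate()
    a = np.asarray(spec.shared_fraction)
    b = spec.global_fraction
    N = np.asarray(spec.roi_sizes, dtype=float)
    phi = a + b
    v = a + b + (1.0 - a - b) / N
    roi_table = pd.DataFrame(
        {"roi_id": np.arange(1, spec.n_rois + 1), "size": N.astype(int), "phi": phi}
    )
    rows = []
    R = spec.R
    for i in range(spec.n_rois):
        for j in range(i + 1, spec.n_rois):
            c_vox = np.sqrt(a[i] * a[j]) * R[i, j] + b
            denom = np.sqrt(v[i] * v[j])
            rows.append(
                {
                    "roi_i": i + 1,
                    "roi_j": j + 1,
                    "mean_consistency": (phi[i] + phi[j]) / 2.0,
                    "c_vox": c_vox,
                    "c_roi": c_vox / denom if denom > 0 else np.nan,
                }
            )
    pair_table = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "mean_consistency", "c_vox", "c_roi"]
    )
    return roi_table, pair_table


def write_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    parcellation: Parcellation | None = None,
    vts: VoxelTimeSeriesSet | None = None,
) -> dict[str, Path]:
    """Write the synthetic study as NIfTI files plus a JSON spec sidecar.

    Emits ``bold.nii.gz`` (4-D series), ``labels.nii.gz`` (ROI volume) and
    ``spec.json`` so the file-based pipeline can be exercised end to end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if parcellation is None:
        parcellation = generate_parcellation(spec)
    if vts is None:
        vts = generate_voxel_timeseries(spec, parcellation)
    paths = {
        "bold": out / "bold.nii.gz",
        "labels": out / "labels.nii.gz",
        "spec": out / "spec.json",
    }
    write_4d_image(vts, paths["bold"])
    write_label_volume(parcellation, paths["labels"], spec.voxel_size_mm)
    paths["spec"].write_text(spec.to_json())
    return paths


def study_spec(seed: int = 0, n_timepoints: int = 212) -> SyntheticSpec:
    """Reference synthetic study emulating a resting-state session.

    Thirty ROIs with sizes from 8 to 216 voxels (anatomical atlases show
    broad, right-skewed size distributions), 212 time points as in a
    standard ~6 min resting-state acquisition, 4 mm isotropic voxels.
    Shared-variance fractions decrease smoothly with ROI size
    (a_I = 0.08 + 0.42 / (1 + N_I / 40)), reproducing the empirical
    tendency of small ROIs to be more consistent, plus a weak global
    component b = 0.05. Latent correlations combine a common baseline
    with a distance-decaying term, R_IJ = 0.25 + 0.35 * 0.7**|I-J|.
    """
    sizes = (
        8, 10, 12, 14, 16, 20, 24, 28, 32, 36,
        40, 48, 54, 60, 64, 72, 80, 90, 96, 100,
        108, 120, 126, 132, 144, 150, 160, 180, 200, 216,
    )
    # fixed shuffle so ROI index (which orders the latent-correlation
    # decay) is not a proxy for ROI size
    order = np.random.default_rng(1234).permutation(len(sizes))
    sizes = tuple(sizes[k] for k in order)
    n = len(sizes)
    a = tuple(0.08 + 0.42 / (1.0 + s / 40.0) for s in sizes)
    idx = np.arange(n)
    R = 0.25 + 0.35 * 0.7 ** np.abs(idx[:, None] - idx[None, :])
    np.fill_diagonal(R, 1.0)
    return SyntheticSpec(
        roi_sizes=sizes,
        n_timepoints=n_timepoints,
        shared_fraction=a,
        global_fraction=0.05,
        latent_correlation=R,
        seed=seed,
        grid_shape=(24, 24, 16),
        voxel_size_mm=(4.0, 4.0, 4.0),
    )
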