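"""Inter-ROI correlation at two scales and their relation to consistency.

For an ROI pair (I, J) the voxel-level correlation C_vox is the mean
Pearson correlation over all N_I * N_J cross-ROI voxel pairs, while the
ROI-level correlation C_roi correlates the two averaged series. Averaging
suppresses voxel-unique signal, so C_roi systematically exceeds C_vox —
pairs of barely consistent ROIs can appear strongly connected at the ROI
level. Conversely C_vox is bounded by the pair's mean consistency (the
identity-line bound), which :func:`identity_bound_check` asserts.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .consistency import ConsistencyRecord, _centered_rows, _cross_corr, pearson
from .exceptions import DegenerateInputError, ValidationError, ZeroVarianceError
from .io import Parcellation, VoxelTimeSeriesSet
from .signal import ROITimeSeriesSet

__all__ = [
    "voxel_level_correlation",
    "roi_level_correlation",
    "build_pair_table",
    "identity_bound_check",
    "relation_binned",
]


def voxel_level_correlation(
    vts: VoxelTimeSeriesSet,
    parc: Parcellation,
    roi_i: int,
    roi_j: int,
    pair_budget: int | None = None,
    seed: int = 0,
) -> float:
    """Mean Pearson correlation over all cross-ROI voxel pairs (C_vox).

    Exact enumeration of the N_I * N_J pairs up to ``pair_budget``; beyond
    it, a seed-reproducible uniform subsample of pairs is averaged instead.
    Zero-variance voxels are skipped with the pair count adjusted.
    """
    if roi_i == roi_j:
        raise ValidationError("voxel-level correlation needs two distinct ROIs")
    members = parc.member_rows(vts)
    try:
        ra, rb = members[int(roi_i)], members[int(roi_j)]
    except KeyError as e:
        raise ValidationError(f"unknown ROI id {e}") from None
    if len(ra) == 0 or len(rb) == 0:
        raise DegenerateInputError("both ROIs must contain at least one voxel")
    centred, sq, valid = _centered_rows(vts.data)
    ra, rb = ra[valid[ra]], rb[valid[rb]]
    n_dead = (len(members[int(roi_i)]) - len(ra)) + (len(members[int(roi_j)]) - len(rb))
    if n_dead:
        warnings.warn(
            f"ROI pair ({roi_i},{roi_j}): {n_dead} zero-variance voxel(s) "
            "skipped",
            stacklevel=2,
        )
    if len(ra) == 0 or len(rb) == 0:
        raise ZeroVarianceError(
            f"all voxels of one ROI in pair ({roi_i},{roi_j}) are constant"
        )
    total = len(ra) * len(rb)
    if pair_budget is not None and total > pair_budget:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=pair_budget, replace=False)
        ia, jb = np.unravel_index(flat, (len(ra), len(rb)))
        vals = np.einsum("ij,ij->i", centred[ra[ia]], centred[rb[jb]]) / np.sqrt(
            sq[ra[ia]] * sq[rb[jb]]
        )
        return float(np.clip(vals, -1.0, 1.0).mean())
    C = _cross_corr(centred[ra], sq[ra], centred[rb], sq[rb])
    return float(C.mean())


def roi_level_correlation(rts: ROITimeSeriesSet, roi_i: int, roi_j: int) -> float:
    """Pearson correlation of the two averaged ROI series (C_roi).

    Raises :class:`ZeroVarianceError` when either averaged series is
    constant (e.g. an ROI of perfectly anticorrelated voxels).
    """
    return pearson(rts.row(roi_i), rts.row(roi_j))


def build_pair_table(
    vts: VoxelTimeSeriesSet,
    rts: ROITimeSeriesSet,
    parc: Parcellation,
    consistencies: list[ConsistencyRecord],
    pair_budget: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One row per unordered ROI pair: mean consistency, C_vox, C_roi.

    Pairs whose correlation is undefined (constant averaged series, ROIs
    of dead voxels) or whose consistency is undefined are flagged in the
    ``flag`` column and excluded from the cross-pair summary correlations,
    never silently dropped.

    Returns the table and a summary dict with Pearson r (and p) of
    C_vox vs mean consistency and of C_roi vs mean consistency.
    """
    phi = {r.roi_id: r.phi for r in consistencies}
    ids = [int(i) for i in parc.roi_ids]
    rows = []
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            i, j = ids[a_idx], ids[b_idx]
            flags = []
            mean_cons = (phi.get(i, math.nan) + phi.get(j, math.nan)) / 2.0
            if math.isnan(mean_cons):
                flags.append("phi_undefined")
            try:
                c_vox = voxel_level_correlation(
                    vts, parc, i, j, pair_budget=pair_budget, seed=seed
                )
            except ZeroVarianceError:
                c_vox = math.nan
                flags.append("c_vox_undefined")
            try:
                c_roi = roi_level_correlation(rts, i, j)
            except ZeroVarianceError:
                c_roi = math.nan
                flags.append("c_roi_undefined")
            rows.append(
                {
                    "roi_i": i,
                    "roi_j": j,
                    "mean_consistency": mean_cons,
                    "c_vox": c_vox,
                    "c_roi": c_roi,
                    "flag": ";".join(flags),
                }
            )
    table = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "mean_consistency", "c_vox", "c_roi", "flag"]
    )
    summary: dict = {"n_pairs": len(table), "n_flagged": int((table["flag"] != "").sum())}
    for col, key in (("c_vox", "vox"), ("c_roi", "roi")):
        ok = table[["mean_consistency", col]].dropna()
        if len(ok) > 1 and ok.nunique().min() > 1:
            r, p = scipy.stats.pearsonr(ok[col], ok["mean_consistency"])
            summary[f"r_{key}_vs_consistency"] = float(r)
            summary[f"p_{key}_vs_consistency"] = float(p)
        else:
            summary[f"r_{key}_vs_consistency"] = math.nan
            summary[f"p_{key}_vs_consistency"] = math.nan
    return table, summary


def identity_bound_check(table: pd.DataFrame, tolerance: float = 0.0) -> pd.DataFrame:
    """Pairs violating C_vox <= mean consistency + tolerance.

    The population bound sqrt(a_I a_J) R_IJ + b <= (a_I + a_J)/2 + b holds
    by AM-GM with |R| <= 1; an empty result asserts its sample analogue.
    Flagged (undefined) rows are not counted as violations.
    """
    if len(table) == 0:
        raise ValidationError("pair table is empty")
    ok = table.dropna(subset=["c_vox", "mean_consistency"])
    return ok[ok["c_vox"] > ok["mean_consistency"] + tolerance]


def relation_binned(
    table: pd.DataFrame, x_field: str, y_field: str, n_bins: int
) -> pd.DataFrame:
    """Equal-width bins over ``x_field``; per-bin mean and SD of ``y_field``.

    Rows with a NaN in either field are dropped. Columns:
    ``bin_lo, bin_hi, n, mean_x, mean_y, sd_y``.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    for f in (x_field, y_field):
        if f not in table.columns:
            raise ValidationError(f"no column {f!r} in pair table")
    ok = table.dropna(subset=[x_field, y_field])
    if len(ok) == 0:
        raise DegenerateInputError("no complete rows to bin")
    x = ok[x_field].to_numpy(dtype=float)
    y = ok[y_field].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi or n_bins == 1:
        edges = np.array([lo, hi])
        n_eff = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        n_eff = n_bins
    edges = edges.astype(float)
    edges[-1] += max(abs(edges[-1]), 1.0) * 1e-9
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_eff - 1)
    rows = []
    for k in range(n_eff):
        sel = which == k
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "n": int(sel.sum()),
                "mean_x": float(x[sel].mean()) if sel.any() else math.nan,
                "mean_y": float(y[sel].mean()) if sel.any() else math.nan,
                "sd_y": float(y[sel].std(ddof=1)) if sel.sum() > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)
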