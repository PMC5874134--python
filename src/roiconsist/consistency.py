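"""ROI consistency and related statistics.

The consistency of an ROI,

    phi(I) = mean Pearson correlation over all distinct voxel pairs in I,

quantifies how well the averaged ROI signal represents its voxels: phi = 1
exactly when all member series are positive affine images of one another,
and low phi flags a functionally inhomogeneous ROI. This module also pools
within- and between-ROI voxel correlation distributions, compares their
means with a permutation-based two-tailed t test, and bins consistency
against ROI size.

Correlations are averaged raw (no Fisher-z transform before averaging),
matching the definition of the statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DegenerateInputError, ValidationError, ZeroVarianceError
from .io import Parcellation, VoxelTimeSeriesSet

__all__ = [
    "ConsistencyRecord",
    "CorrelationDistributionSummary",
    "pearson",
    "roi_consistency",
    "roi_consistencies",
    "within_between_distributions",
    "permutation_t_test",
    "consistency_vs_size",
]

# Exhaustive enumeration of labelings is used below this count.
EXHAUSTIVE_LIMIT = 20_000
_PERM_CHUNK_VALUES = 10_000_000
# correlations this close to +/-1 are rounding-level equal to +/-1
_SNAP_TOL = 1e-14


@dataclass
class ConsistencyRecord:
    """Consistency phi of one ROI; phi is NaN when undefined (N_I < 2)."""

    roi_id: int
    phi: float
    size: int
    subject_id: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.phi)


@dataclass
class CorrelationDistributionSummary:
    """Pooled within- vs between-ROI voxel correlation distributions."""

    within_values: np.ndarray
    between_values: np.ndarray
    within_mean: float
    between_mean: float
    t_statistic: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "n_within": int(len(self.within_values)),
            "n_between": int(len(self.between_values)),
            "within_mean": self.within_mean,
            "between_mean": self.between_mean,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length series.

    Raises :class:`ZeroVarianceError` when either series is constant
    (the correlation is undefined; callers decide whether to skip).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("need two equal-length 1-D series of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(xc @ xc)
    ny = float(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    r = float(xc @ yc) / math.sqrt(nx * ny)
    if r >= 1.0 - _SNAP_TOL:  # rounding-level equal to +/-1 (cf. _cross_corr)
        return 1.0
    if r <= -1.0 + _SNAP_TOL:
        return -1.0
    return min(1.0, max(-1.0, r))


def _centered_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows centred, with their squared norms and a nonconstant-row mask.

    Correlations are formed as gram / sqrt(outer(sq, sq)) rather than from
    pre-normalized rows so that identical series correlate at exactly 1.0
    (numerator and denominator are then the same float).
    """
    centred = data - data.mean(axis=1, keepdims=True)
    sq = np.einsum("ij,ij->i", centred, centred)
    valid = sq > 0
    return centred, sq, valid


def _cross_corr(
    ca: np.ndarray, sqa: np.ndarray, cb: np.ndarray, sqb: np.ndarray
) -> np.ndarray:
    """Pearson block between two sets of centred rows, clipped to [-1, 1].

    Values within 1e-14 of +/-1 are snapped to exactly +/-1: identical
    series land there through rounding alone (matmul and norm accumulate
    differently), and at double precision such values are
    indistinguishable from the theoretical maximum phi = 1.
    """
    num = ca @ cb.T
    denom = np.sqrt(np.outer(sqa, sqb))
    r = np.clip(num / denom, -1.0, 1.0)
    r[r >= 1.0 - _SNAP_TOL] = 1.0
    r[r <= -1.0 + _SNAP_TOL] = -1.0
    return r


def _corr_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson matrix of the rows, clipped to [-1, 1]; zero-variance rows
    flagged invalid (their correlations set to NaN)."""
    centred, sq, valid = _centered_rows(data)
    C = np.full((len(sq), len(sq)), np.nan)
    idx = np.flatnonzero(valid)
    if len(idx):
        C[np.ix_(idx, idx)] = _cross_corr(
            centred[idx], sq[idx], centred[idx], sq[idx]
        )
    return C, valid


def roi_consistency(
    vts: VoxelTimeSeriesSet,
    parc: Parcellation,
    roi_id: int,
    subject_id: str | None = None,
) -> ConsistencyRecord:
    """Mean Pearson correlation over all distinct voxel pairs of one ROI.

    The double sum over ordered pairs with 1/(N(N-1)) normalization equals
    the mean over unordered pairs, which is what is computed (the strict
    upper triangle of the within-ROI correlation matrix). ROIs with fewer
    than two voxels get phi = NaN with a warning; zero-variance member
    voxels are excluded pairwise with the count adjusted.
    """
    rows = parc.member_rows(vts).get(int(roi_id))
    if rows is None:
        raise ValidationError(f"unknown ROI id {roi_id}")
    size = len(rows)
    if size < 2:
        warnings.warn(
            f"ROI {roi_id} has fewer than 2 voxels; consistency undefined",
            stacklevel=2,
        )
        return ConsistencyRecord(int(roi_id), math.nan, size, subject_id)
    C, valid = _corr_matrix(vts.data[rows])
    n_dead = int(np.sum(~valid))
    if n_dead:
        warnings.warn(
            f"ROI {roi_id}: {n_dead} zero-variance voxel(s) excluded from "
            "consistency pairs",
            stacklevel=2,
        )
    iu = np.triu_indices(size, k=1)
    vals = C[iu]
    vals = vals[~np.isnan(vals)]
    phi = float(vals.mean()) if len(vals) else math.nan
    return ConsistencyRecord(int(roi_id), phi, size, subject_id)


def roi_consistencies(
    vts: VoxelTimeSeriesSet,
    parc: Parcellation,
    subject_id: str | None = None,
) -> list[ConsistencyRecord]:
    """Consistency records for every ROI of the parcellation."""
    return [roi_consistency(vts, parc, int(i), subject_id) for i in parc.roi_ids]


def within_between_distributions(
    vts: VoxelTimeSeriesSet,
    parc: Parcellation,
    pair_cap: int | None = 10_000_000,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> CorrelationDistributionSummary:
    """Pooled same-ROI vs different-ROI voxel correlation distributions.

    Within-pairs are all distinct same-ROI pairs pooled across ROIs (each
    ROI implicitly weighted by its pair count); between-pairs are all
    cross-ROI pairs, subsampled uniformly (seed-reproducible) when their
    count exceeds ``pair_cap``. Zero-variance voxels are skipped with a
    warning. The two means are compared with
    :func:`permutation_t_test`.
    """
    members = parc.member_rows(vts)
    ids = [int(i) for i in parc.roi_ids]
    if len(ids) < 2:
        raise DegenerateInputError("need at least two ROIs for a between group")
    centred, sq, valid = _centered_rows(vts.data)
    if not valid.all():
        warnings.warn(
            f"{int(np.sum(~valid))} zero-variance voxel(s) skipped in "
            "correlation distributions",
            stacklevel=2,
        )
    within: list[np.ndarray] = []
    for i in ids:
        rows = members[i][valid[members[i]]]
        if len(rows) >= 2:
            C = _cross_corr(centred[rows], sq[rows], centred[rows], sq[rows])
            within.append(C[np.triu_indices(len(rows), k=1)])
    between: list[np.ndarray] = []
    for a_idx in range(len(ids)):
        ra = members[ids[a_idx]]
        ra = ra[valid[ra]]
        if len(ra) == 0:
            continue
        for b_idx in range(a_idx + 1, len(ids)):
            rb = members[ids[b_idx]]
            rb = rb[valid[rb]]
            if len(rb) == 0:
                continue
            between.append(
                _cross_corr(centred[ra], sq[ra], centred[rb], sq[rb]).ravel()
            )
    within_v = np.concatenate(within) if within else np.array([])
    between_v = np.concatenate(between) if between else np.array([])
    if len(within_v) == 0 or len(between_v) == 0:
        raise DegenerateInputError("no valid within- or between-ROI pairs")
    if pair_cap is not None and len(between_v) > pair_cap:
        rng = np.random.default_rng(seed)
        between_v = rng.choice(between_v, size=pair_cap, replace=False)
    t, p = permutation_t_test(
        within_v, between_v, n_permutations=n_permutations, seed=seed
    )
    return CorrelationDistributionSummary(
        within_values=within_v,
        between_values=between_v,
        within_mean=float(within_v.mean()),
        between_mean=float(between_v.mean()),
        t_statistic=t,
        p_value=p,
        n_permutations=n_permutations,
    )


def _t_from_sums(
    sa: np.ndarray, qa: np.ndarray, na: int, S: float, Q: float, n: int
) -> np.ndarray:
    """Pooled-variance two-sample t from group-A sums/squares."""
    nb = n - na
    sb = S - sa
    qb = Q - qa
    va = (qa - sa * sa / na) / (na - 1) if na > 1 else np.zeros_like(sa)
    vb = (qb - sb * sb / nb) / (nb - 1) if nb > 1 else np.zeros_like(sb)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (sa / na - sb / nb) / denom


def permutation_t_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed two-sample t test with a permutation null.

    t is the pooled-variance Student statistic on the observed labeling;
    p = (1 + #{labelings with |t| >= |t_obs|}) / (1 + n), where labels are
    permuted uniformly at random. All C(n_a+n_b, n_a) labelings are
    enumerated exhaustively when their number is at most
    ``EXHAUSTIVE_LIMIT`` (the observed labeling is then among those
    counted); otherwise ``n_permutations`` Monte-Carlo permutations are
    drawn.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)
    if n < 3 or np.var(pooled) == 0.0:
        raise DegenerateInputError(
            "pooled sample is constant or too small; t undefined"
        )
    S = float(pooled.sum())
    Q = float(pooled @ pooled)
    sq = pooled * pooled
    t_obs = float(
        _t_from_sums(
            np.array([a.sum()]), np.array([float(a @ a)]), na, S, Q, n
        )[0]
    )
    n_labelings = math.comb(n, na)
    if n_labelings <= EXHAUSTIVE_LIMIT:
        idx = np.fromiter(
            (i for comb in combinations(range(n), na) for i in comb),
            dtype=np.intp,
            count=n_labelings * na,
        ).reshape(n_labelings, na)
        sa = pooled[idx].sum(axis=1)
        qa = sq[idx].sum(axis=1)
        t_perm = _t_from_sums(sa, qa, na, S, Q, n)
        count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        p = (1.0 + count) / (1.0 + n_labelings)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        chunk = max(1, _PERM_CHUNK_VALUES // n)
        done = 0
        while done < n_permutations:
            m = min(chunk, n_permutations - done)
            # m random subsets of size na via argpartition of random keys
            keys = rng.random((m, n))
            idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
            sa = pooled[idx].sum(axis=1)
            qa = sq[idx].sum(axis=1)
            t_perm = _t_from_sums(sa, qa, na, S, Q, n)
            count += int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
            done += m
        p = (1.0 + count) / (1.0 + n_permutations)
    return t_obs, float(min(p, 1.0))


def consistency_vs_size(
    records: list[ConsistencyRecord], n_bins: int
) -> tuple[pd.DataFrame, float, float]:
    """Bin consistency by ROI size (log-spaced bins) and bin-average.

    Records with undefined phi are dropped. Returns the binned table
    (columns ``bin_lo, bin_hi, n, mean_phi, sd_phi``), plus the overall
    Pearson correlation between size and phi and its p value (NaN when
    fewer than two distinct sizes/phis are available).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    recs = [r for r in records if r.defined]
    if not recs:
        raise DegenerateInputError("no records with defined consistency")
    sizes = np.array([r.size for r in recs], dtype=float)
    phis = np.array([r.phi for r in recs])
    lo, hi = sizes.min(), sizes.max()
    if lo == hi or n_bins == 1:
        edges = np.array([lo, hi])
        n_bins_eff = 1
    else:
        edges = np.geomspace(lo, hi, n_bins + 1)
        n_bins_eff = n_bins
    edges[-1] *= 1 + 1e-9  # make the top edge inclusive
    which = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, n_bins_eff - 1)
    rows = []
    for k in range(n_bins_eff):
        in_bin = phis[which == k]
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "n": len(in_bin),
                "mean_phi": float(in_bin.mean()) if len(in_bin) else math.nan,
                "sd_phi": float(in_bin.std(ddof=1)) if len(in_bin) > 1 else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    if len(recs) > 1 and np.ptp(sizes) > 0 and np.ptp(phis) > 0:
        r, p = scipy.stats.pearsonr(sizes, phis)
        r, p = float(r), float(p)
    else:
        r, p = math.nan, math.nan
    return table, r, p
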