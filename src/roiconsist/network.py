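"""Weighted correlation networks, density thresholding, and centrality.

The ROI-level network is the full symmetric matrix of zero-lag Pearson
correlations between averaged ROI series (diagonal removed, negative
weights retained). Thresholding to density d keeps the m = round(d * M)
strongest links by signed weight out of the M = N(N-1)/2 possible ones —
at low densities this automatically excludes negative correlations — and
the surviving network is analyzed as weighted: degree k counts a node's
retained links, strength s sums their weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .consistency import ConsistencyRecord
from .exceptions import DegenerateInputError, ValidationError, ZeroVarianceError
from .signal import ROITimeSeriesSet

__all__ = [
    "DEFAULT_DENSITY_GRID",
    "AdjacencyMatrix",
    "ThresholdedNetwork",
    "build_adjacency",
    "threshold_to_density",
    "degree_and_strength",
    "consistency_centrality_relation",
]

# Density grid emphasizing the sparse regime where network structure is
# most sensitive to link-weight changes (densities in percent:
# 0.25 ... 5, 10, 15, 20).
DEFAULT_DENSITY_GRID: tuple[float, ...] = (
    0.0025, 0.005, 0.0075, 0.01, 0.015, 0.02, 0.025, 0.03,
    0.035, 0.04, 0.045, 0.05, 0.10, 0.15, 0.20,
)


@dataclass
class AdjacencyMatrix:
    """Full symmetric weighted adjacency with exactly zero diagonal."""

    weights: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValidationError("adjacency shape does not match node ids")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValidationError("adjacency must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValidationError("adjacency diagonal must be exactly zero")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_possible_links(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2


@dataclass
class ThresholdedNetwork:
    """Weighted network at a fixed link density.

    ``mask`` marks retained links (symmetric boolean), ``weights`` keeps
    their original signed correlations (zero elsewhere); ``degree`` and
    ``strength`` are the per-node link count and weight sum.
    """

    density: float
    node_ids: np.ndarray
    mask: np.ndarray
    weights: np.ndarray
    n_links: int
    degree: np.ndarray
    strength: np.ndarray


def build_adjacency(rts: ROITimeSeriesSet) -> AdjacencyMatrix:
    """Full matrix of zero-lag Pearson correlations between ROI series.

    Negative correlations are retained; a constant ROI series makes the
    matrix undefined and raises :class:`ZeroVarianceError` naming the ROI.
    """
    sd = rts.data.std(axis=1)
    dead = rts.roi_ids[sd == 0]
    if len(dead):
        raise ZeroVarianceError(
            f"constant averaged series for ROI(s) {[int(i) for i in dead]}"
        )
    C = np.clip(np.corrcoef(rts.data), -1.0, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    return AdjacencyMatrix(weights=C, node_ids=rts.roi_ids)


def threshold_to_density(A: AdjacencyMatrix, d: float) -> ThresholdedNetwork:
    """Keep the m = round(d * M) strongest links by signed weight.

    Rounding is half-up (so d*M = 1.5 keeps 2 links); ties at the cutoff
    are broken by lexicographic (i, j) node-pair order, logged as a
    warning. m = 0 is an error.
    """
    if not 0.0 < d <= 1.0:
        raise ValidationError("density must lie in (0, 1]")
    M = A.n_possible_links
    m = int(math.floor(d * M + 0.5))
    if m == 0:
        raise DegenerateInputError(
            f"density {d} retains zero links on {A.n_nodes} nodes"
        )
    iu, ju = np.triu_indices(A.n_nodes, k=1)
    w = A.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))  # strongest first, ties by (i, j)
    keep = order[:m]
    if m < M and w[order[m - 1]] == w[order[m]]:
        warnings.warn(
            f"tie at the density-{d} cutoff weight {w[order[m]]:.6g}; "
            "broken by node-pair order",
            stacklevel=2,
        )
    mask = np.zeros_like(A.weights, dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    weights = np.where(mask, A.weights, 0.0)
    return ThresholdedNetwork(
        density=d,
        node_ids=A.node_ids,
        mask=mask,
        weights=weights,
        n_links=m,
        degree=mask.sum(axis=1).astype(np.int64),
        strength=weights.sum(axis=1),
    )


def degree_and_strength(net: ThresholdedNetwork) -> pd.DataFrame:
    """Per-node table of degree k and strength s (isolated nodes: 0, 0)."""
    return pd.DataFrame(
        {
            "roi_id": net.node_ids,
            "density": net.density,
            "degree": net.degree,
            "strength": net.strength,
        }
    )


def consistency_centrality_relation(
    records: list[ConsistencyRecord],
    A: AdjacencyMatrix,
    densities: tuple[float, ...] = DEFAULT_DENSITY_GRID,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate consistency with degree and strength across densities.

    For each density the adjacency is thresholded and the Pearson
    correlation (with p) of phi vs k and phi vs s is computed; a constant
    k or s (e.g. the full network, where every k = N-1) is flagged
    undefined rather than reported. Also returns consistency-binned mean
    degree/strength curves (equal-width phi bins).

    Densities retaining zero links on this node count are skipped with a
    ``skipped`` status.
    """
    phi_map = {r.roi_id: r.phi for r in records}
    phi = np.array([phi_map.get(int(i), math.nan) for i in A.node_ids])
    ok_phi = ~np.isnan(phi)
    summaries = []
    binned_rows = []
    for d in densities:
        row: dict = {"density": d}
        try:
            net = threshold_to_density(A, d)
        except DegenerateInputError:
            row.update(
                status="skipped", n_links=0,
                r_degree=math.nan, p_degree=math.nan,
                r_strength=math.nan, p_strength=math.nan,
            )
            summaries.append(row)
            continue
        row["status"] = "ok"
        row["n_links"] = net.n_links
        for name, vals in (("degree", net.degree), ("strength", net.strength)):
            v = vals[ok_phi].astype(float)
            p_ = phi[ok_phi]
            if len(v) > 1 and np.ptp(v) > 0 and np.ptp(p_) > 0:
                r, p = scipy.stats.pearsonr(p_, v)
                row[f"r_{name}"], row[f"p_{name}"] = float(r), float(p)
            else:
                row[f"r_{name}"], row[f"p_{name}"] = math.nan, math.nan
                row["status"] = "undefined_correlation"
        summaries.append(row)
        lo, hi = phi[ok_phi].min(), phi[ok_phi].max()
        edges = (
            np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, lo])
        )
        if hi > lo:
            edges[-1] += abs(edges[-1]) * 1e-9 + 1e-12
            which = np.clip(
                np.searchsorted(edges, phi[ok_phi], side="right") - 1, 0, n_bins - 1
            )
            for k in range(n_bins):
                sel = which == k
                if not sel.any():
                    continue
                binned_rows.append(
                    {
                        "density": d,
                        "bin_lo": edges[k],
                        "bin_hi": edges[k + 1],
                        "n": int(sel.sum()),
                        "mean_phi": float(phi[ok_phi][sel].mean()),
                        "mean_degree": float(net.degree[ok_phi][sel].mean()),
                        "mean_strength": float(net.strength[ok_phi][sel].mean()),
                    }
                )
    summary = pd.DataFrame(summaries)
    binned = pd.DataFrame(
        binned_rows,
        columns=[
            "density", "bin_lo", "bin_hi", "n",
            "mean_phi", "mean_degree", "mean_strength",
        ],
    )
    return summary, binned
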