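"""Clustering and distribution analysis of conformational ensembles.

Covers the ensemble-characterization steps downstream of the collective
variables: GROMOS-style leader clustering over a pairwise RMSD matrix
with centroid extraction, kernel-density estimates of 1D CV
distributions (optionally weighted by reweighting factors so the "most
probable" value refers to the recovered equilibrium distribution), and
peak detection for uni-/bimodal distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

from .errors import InputError
from .geometry import CVSeries, kabsch_superpose
from .io import Ensemble, MotifDefinition, resolve_selection

__all__ = [
    "ClusterResult",
    "DensityCurve",
    "Peak",
    "PeakReport",
    "pairwise_rmsd_matrix",
    "cluster_leader",
    "centroid_frame",
    "density_1d",
    "find_peaks_1d",
    "state_summary",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Frame→cluster assignment with populations and centroids.

    Cluster ids are 0-based and ordered by descending population
    (id 0 = most populated); each centroid is the member frame
    minimizing mean RMSD to the rest of its cluster.
    """

    assignment: np.ndarray       # per-frame cluster id
    populations: np.ndarray      # per-cluster frame counts
    centroid_frames: np.ndarray  # per-cluster frame index
    cutoff: float                # Å

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignment == cluster_id)[0]


@dataclass
class DensityCurve:
    """A kernel-density estimate sampled on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False  # zero-variance input: a single delta


@dataclass(frozen=True)
class Peak:
    position: float    # CV units
    density: float     # probability density at the peak
    prominence: float  # density units


@dataclass
class PeakReport:
    """Density peaks ordered by descending height."""

    peaks: list[Peak]
    bandwidth: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def positions(self) -> list[float]:
        return [p.position for p in self.peaks]


# ---------------------------------------------------------------------------
# Pairwise RMSD and clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(
    ensemble: Ensemble,
    selection: MotifDefinition | Sequence[MotifDefinition],
) -> np.ndarray:
    """Symmetric frame-vs-frame superposition RMSD matrix in Å.

    ``selection`` may be one motif or a sequence of motifs whose atom
    selections are merged — e.g. both domains of a complex.
    """
    if ensemble.n_frames < 2:
        raise InputError("pairwise RMSD needs at least 2 frames")
    if isinstance(selection, MotifDefinition):
        idx = resolve_selection(ensemble, selection)
    else:
        idx = np.unique(np.concatenate(
            [resolve_selection(ensemble, m) for m in selection]
        ))
    coords = ensemble.coordinates[:, idx, :]
    n = ensemble.n_frames
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(coords[j], coords[i])
            matrix[i, j] = matrix[j, i] = rmsd
    return matrix


def cluster_leader(matrix: np.ndarray, cutoff: float = 2.0) -> ClusterResult:
    """GROMOS leader clustering of a pairwise RMSD matrix.

    Iteratively, the frame with the most neighbors within ``cutoff``
    becomes a cluster center; it and its neighbors are removed and the
    procedure repeats on the remainder. Ties break to the lowest frame
    index. Clusters are then renumbered by descending population and
    each cluster's centroid (member minimizing mean RMSD to the others)
    is recorded.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("RMSD matrix must be square")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    n = m.shape[0]
    within = m <= cutoff
    remaining = np.ones(n, dtype=bool)
    raw_clusters: list[np.ndarray] = []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(within[center] & remaining)[0]
        raw_clusters.append(members)
        remaining[members] = False
    order = sorted(
        range(len(raw_clusters)),
        key=lambda c: (-len(raw_clusters[c]), int(raw_clusters[c][0])),
    )
    assignment = np.empty(n, dtype=int)
    populations = np.empty(len(raw_clusters), dtype=int)
    centroids = np.empty(len(raw_clusters), dtype=int)
    for new_id, old_id in enumerate(order):
        members = raw_clusters[old_id]
        assignment[members] = new_id
        populations[new_id] = len(members)
        centroids[new_id] = centroid_frame(m, members)
    return ClusterResult(
        assignment=assignment,
        populations=populations,
        centroid_frames=centroids,
        cutoff=float(cutoff),
    )


def centroid_frame(matrix: np.ndarray, member_indices: Sequence[int]) -> int:
    """Cluster member minimizing mean RMSD to the other members.

    Ties break to the lowest frame index; a singleton cluster's
    centroid is its only member.
    """
    members = np.asarray(member_indices, dtype=int)
    if len(members) == 0:
        raise InputError("empty member list has no centroid")
    if len(members) == 1:
        return int(members[0])
    sub = np.asarray(matrix)[np.ix_(members, members)]
    mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
    return int(members[int(np.argmin(mean_rmsd))])


# ---------------------------------------------------------------------------
# Densities and peaks
# ---------------------------------------------------------------------------

def density_1d(
    cv,
    weights: np.ndarray | None = None,
    bandwidth: float | str = "auto",
    grid_points: int = 512,
) -> DensityCurve:
    """Gaussian-kernel density of a CV series on a regular grid.

    The grid spans the data range padded by three bandwidths.
    ``bandwidth="auto"`` applies Silverman's rule (on the effective
    sample size when weights are given); a float fixes the kernel SD in
    CV units. Zero-variance input yields a degenerate single-delta
    curve rather than an error.
    """
    values = cv.values if isinstance(cv, CVSeries) else np.asarray(cv, float)
    if len(values) < 10:
        raise InputError(f"density estimate needs ≥10 frames, got {len(values)}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(values):
            raise InputError("weights length must match CV length")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise InputError("weights must be nonnegative with positive sum")
        weights = weights / weights.sum()

    if np.ptp(values) == 0.0:
        grid = np.full(grid_points, values[0])
        density = np.zeros(grid_points)
        density[grid_points // 2] = np.inf
        return DensityCurve(grid=grid, density=density, bandwidth=0.0,
                            degenerate=True)

    kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    if bandwidth == "auto":
        bw = float(np.sqrt(kde.covariance[0, 0]))
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise InputError("bandwidth must be positive")
        sigma = np.sqrt(np.cov(values, aweights=weights))
        kde.set_bandwidth(bw / float(sigma))
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw,
                       grid_points)
    density = kde(grid)
    return DensityCurve(grid=grid, density=density, bandwidth=bw)


def find_peaks_1d(
    curve: DensityCurve, prominence_fraction: float = 0.05
) -> PeakReport:
    """Local density maxima with prominence above a fraction of the mode.

    Peaks are returned ordered by descending density. A degenerate
    (delta) curve reports its single location. An empty report — no
    peak qualifying — is a valid outcome, not an error.
    """
    if not 0 < prominence_fraction <= 1:
        raise InputError("prominence_fraction must be in (0, 1]")
    if curve.degenerate:
        pos = float(curve.grid[0])
        return PeakReport(
            peaks=[Peak(position=pos, density=float("inf"),
                        prominence=float("inf"))],
            bandwidth=curve.bandwidth,
        )
    threshold = prominence_fraction * curve.density.max()
    idx, props = signal.find_peaks(curve.density, prominence=threshold)
    # An interior global maximum at the grid edge has no left/right base;
    # pad so monotone-edge modes are still seen.
    padded = np.concatenate([[0.0], curve.density, [0.0]])
    idx_p, props_p = signal.find_peaks(padded, prominence=threshold)
    idx = idx_p - 1
    keep = (idx >= 0) & (idx < len(curve.density))
    idx = idx[keep]
    prominences = props_p["prominences"][keep]
    order = np.argsort(-curve.density[idx], kind="stable")
    peaks = [
        Peak(
            position=float(curve.grid[i]),
            density=float(curve.density[i]),
            prominence=float(p),
        )
        for i, p in zip(idx[order], prominences[order])
    ]
    return PeakReport(peaks=peaks, bandwidth=curve.bandwidth)


def state_summary(
    cv,
    weights: np.ndarray | None = None,
    bandwidth: float | str = "auto",
) -> tuple[float, float, float]:
    """(most probable value, mean, sd) of a CV distribution.

    The most probable value is the highest-density peak position — for
    a bimodal distance distribution this is the dominant mode, not the
    mean. Weights, when given, are equilibrium reweighting factors.
    """
    values = cv.values if isinstance(cv, CVSeries) else np.asarray(cv, float)
    if np.ptp(values) == 0.0:
        return float(values[0]), float(values[0]), 0.0
    curve = density_1d(values, weights=weights, bandwidth=bandwidth)
    report = find_peaks_1d(curve, prominence_fraction=0.01)
    if report.peaks:
        most_probable = report.peaks[0].position
    else:
        most_probable = float(curve.grid[int(np.argmax(curve.density))])
    if weights is None:
        w = np.full(len(values), 1.0 / len(values))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mean = float(w @ values)
    sd = float(np.sqrt(w @ (values - mean) ** 2))
    return most_probable, mean, sd
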