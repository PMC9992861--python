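"""Cumulant-expansion reweighting of boosted ensembles into free-energy profiles.

Gaussian accelerated MD adds a nonnegative boost ΔV(x) = ½k(E − V(x))²
wherever the potential lies below a threshold E, flattening barriers.
The equilibrium density along a collective variable ξ is recovered from
the biased samples by

    p(ξ) ∝ p*(ξ) · ⟨exp(βΔV)⟩_ξ ,    β = 1/(k_B T)

and the exponential average is evaluated per bin through its cumulant
(Maclaurin) expansion

    ln ⟨exp(βΔV)⟩ ≈ β C₁ + β² C₂/2! + β³ C₃/3!

with C₁ the bin mean of ΔV, C₂ the bin variance, C₃ the third central
moment. Second order is exact when ΔV is Gaussian within the bin —
the working regime of GaMD — and is the default; orders 1–3 are
implemented. The potential of mean force is F(ξ) = −k_B T ln p(ξ),
anchored so its minimum over adequately sampled bins is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import BoostLogError, EmptyProfileError, InputError, TopologyError
from .geometry import CVSeries
from .io import Ensemble

__all__ = [
    "KB_KCAL",
    "FreeEnergyProfile",
    "Basin",
    "BasinSet",
    "combine_replicas",
    "pmf_1d",
    "pmf_2d",
    "find_basins",
    "anharmonicity_check",
    "reweight_factors",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 0.0019872041


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """A 1D or 2D binned potential of mean force.

    ``pmf`` is NaN wherever ``mask`` is true (bin under-sampled, free
    energy undefined there); over unmasked bins the minimum is exactly
    zero. ``counts`` are the raw (biased) frame counts per bin.
    """

    dims: int
    bin_edges: list[np.ndarray]
    pmf: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    temperature: float
    cumulant_order: int
    cv_names: tuple[str, ...] = ()

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]

    def n_frames(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Basin:
    """One labeled local free-energy minimum."""

    label: str
    bin_index: tuple[int, ...]
    pmf_value: float
    cv_coordinates: tuple[float, ...]


@dataclass
class BasinSet:
    """Local minima of a profile, labeled m1, m2, … by ascending depth."""

    basins: list[Basin]

    def __len__(self) -> int:
        return len(self.basins)

    def __iter__(self):
        return iter(self.basins)

    def __getitem__(self, i):
        return self.basins[i]


# ---------------------------------------------------------------------------
# Replica combination
# ---------------------------------------------------------------------------

def combine_replicas(ensembles: list[Ensemble]) -> Ensemble:
    """Concatenate boosted replicas into one ensemble.

    All replicas must share the topology and carry per-frame boost
    potentials. Frames keep input-list order; ``replica_id`` records
    each frame's source (position in the input list).
    """
    if not ensembles:
        raise InputError("no replicas given")
    ref_keys = ensembles[0].topology.atom_keys()
    for r, ens in enumerate(ensembles):
        if ens.boost_dV is None:
            raise BoostLogError(f"replica {r} carries no boost potential")
        if ens.topology.atom_keys() != ref_keys:
            raise TopologyError(f"replica {r} topology differs from replica 0")
    coords = np.concatenate([e.coordinates for e in ensembles], axis=0)
    dv = np.concatenate([e.boost_dV for e in ensembles])
    replica_id = np.concatenate(
        [np.full(e.n_frames, r, dtype=int) for r, e in enumerate(ensembles)]
    )
    return Ensemble(
        topology=ensembles[0].topology,
        coordinates=coords,
        replica_id=replica_id,
        state_label=ensembles[0].state_label,
        boost_dV=dv,
    )


# ---------------------------------------------------------------------------
# PMF estimation
# ---------------------------------------------------------------------------

def _as_values(cv) -> np.ndarray:
    if isinstance(cv, CVSeries):
        return cv.values
    return np.asarray(cv, dtype=float)


def _cumulant_correction(dv: np.ndarray, beta: float, order: int) -> float:
    """ln⟨exp(βΔV)⟩ truncated at the given cumulant order."""
    c1 = dv.mean()
    corr = beta * c1
    if order >= 2:
        corr += beta**2 * dv.var() / 2.0
    if order >= 3:
        corr += beta**3 * np.mean((dv - c1) ** 3) / 6.0
    return corr


def _pmf_nd(
    values: list[np.ndarray],
    dv: np.ndarray,
    temperature: float,
    bins,
    cumulant_order: int,
    min_count: int,
    cv_names: tuple[str, ...],
) -> FreeEnergyProfile:
    dims = len(values)
    n = len(values[0])
    for v in values:
        if len(v) != n:
            raise InputError("collective-variable series lengths differ")
    if len(dv) != n:
        raise InputError(
            f"boost series length {len(dv)} does not match CV length {n}"
        )
    if temperature <= 0:
        raise InputError("temperature must be positive")
    if cumulant_order not in (1, 2, 3):
        raise InputError("cumulant_order must be 1, 2 or 3")
    if n == 0:
        raise InputError("empty series")

    if isinstance(bins, (int, np.integer)):
        bins = [int(bins)] * dims
    elif dims == 1 and not isinstance(bins, (list, tuple)):
        bins = [bins]
    edges = [
        np.histogram_bin_edges(v, bins=b) for v, b in zip(values, bins)
    ]
    counts, _ = np.histogramdd(np.column_stack(values), bins=edges)
    counts = counts.astype(int)
    mask = counts < min_count
    if mask.all():
        raise EmptyProfileError(
            f"no bin reaches min_count={min_count}; profile is empty"
        )

    beta = 1.0 / (KB_KCAL * temperature)
    # flat bin id per frame
    flat = np.zeros(n, dtype=np.int64)
    shape = counts.shape
    for d in range(dims):
        ix = np.clip(np.searchsorted(edges[d], values[d], side="right") - 1,
                     0, shape[d] - 1)
        flat = flat * shape[d] + ix

    logp = np.full(counts.size, np.nan)
    flat_counts = counts.ravel()
    order_idx = np.argsort(flat, kind="stable")
    sorted_flat = flat[order_idx]
    boundaries = np.searchsorted(sorted_flat, np.arange(counts.size + 1))
    for b in range(counts.size):
        if flat_counts[b] < min_count:
            continue
        members = order_idx[boundaries[b]:boundaries[b + 1]]
        corr = _cumulant_correction(dv[members], beta, cumulant_order)
        logp[b] = np.log(flat_counts[b] / n) + corr

    pmf = -logp / beta
    pmf = pmf.reshape(shape)
    pmf[mask.reshape(shape)] = np.nan
    pmf -= np.nanmin(pmf)
    return FreeEnergyProfile(
        dims=dims,
        bin_edges=edges,
        pmf=pmf,
        counts=counts,
        mask=mask.reshape(shape),
        temperature=temperature,
        cumulant_order=cumulant_order,
        cv_names=cv_names,
    )


def pmf_1d(
    cv,
    dV,
    temperature: float = 300.0,
    bins=50,
    cumulant_order: int = 2,
    min_count: int = 20,
) -> FreeEnergyProfile:
    """1D potential of mean force from boosted samples.

    With ΔV ≡ 0 this reduces exactly to the histogram estimate
    −k_B T ln p̂(ξ), anchored at zero; adding a constant to all ΔV
    leaves the profile unchanged. Bins with fewer than ``min_count``
    frames are masked rather than reported.
    """
    values = _as_values(cv)
    name = (cv.name,) if isinstance(cv, CVSeries) else ("cv",)
    return _pmf_nd(
        [values], np.asarray(dV, dtype=float), temperature, bins,
        cumulant_order, min_count, name,
    )


def pmf_2d(
    cv1,
    cv2,
    dV,
    temperature: float = 300.0,
    bins=40,
    cumulant_order: int = 2,
    min_count: int = 20,
) -> FreeEnergyProfile:
    """2D potential of mean force over two collective variables."""
    v1, v2 = _as_values(cv1), _as_values(cv2)
    names = (
        cv1.name if isinstance(cv1, CVSeries) else "cv1",
        cv2.name if isinstance(cv2, CVSeries) else "cv2",
    )
    return _pmf_nd(
        [v1, v2], np.asarray(dV, dtype=float), temperature, bins,
        cumulant_order, min_count, names,
    )


def reweight_factors(
    cv,
    dV,
    temperature: float = 300.0,
    bins=50,
    cumulant_order: int = 2,
    min_count: int = 1,
) -> np.ndarray:
    """Per-frame equilibrium weights from binned cumulant reweighting.

    Each frame inherits its bin's reweighting factor exp(ln⟨e^{βΔV}⟩);
    weights are normalized to sum to one. Useful for weighted density
    and summary statistics on the recovered equilibrium distribution.
    """
    values = _as_values(cv)
    dv = np.asarray(dV, dtype=float)
    if len(values) != len(dv):
        raise InputError("cv and dV lengths differ")
    beta = 1.0 / (KB_KCAL * temperature)
    edges = np.histogram_bin_edges(values, bins=bins)
    ix = np.clip(
        np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2
    )
    weights = np.zeros(len(values))
    for b in np.unique(ix):
        members = np.nonzero(ix == b)[0]
        if len(members) < min_count:
            continue
        corr = _cumulant_correction(dv[members], beta, cumulant_order)
        weights[members] = np.exp(corr)
    total = weights.sum()
    if total <= 0:
        raise EmptyProfileError("all frames fell in under-sampled bins")
    return weights / total


# ---------------------------------------------------------------------------
# Basin detection
# ---------------------------------------------------------------------------

def _neighbors(index: tuple[int, ...], shape: tuple[int, ...]):
    for d in range(len(shape)):
        for step in (-1, 1):
            n = list(index)
            n[d] += step
            if 0 <= n[d] < shape[d]:
                yield tuple(n)


def find_basins(
    profile: FreeEnergyProfile, depth_threshold: float = 0.5
) -> BasinSet:
    """Label local free-energy basins of a profile.

    Local minima are found over the unmasked bin graph (2-neighborhood
    in 1D, 4-neighborhood in 2D) by an ascending sweep. A minimum whose
    depth below its lowest connecting saddle is smaller than
    ``depth_threshold`` (kcal/mol) is merged into the deeper basin it
    meets there. Surviving basins are labeled m1, m2, … by ascending
    free energy; m1 is the global minimum.
    """
    pmf = profile.pmf
    shape = pmf.shape
    unmasked = ~profile.mask
    if not unmasked.any():
        raise EmptyProfileError("profile has no unmasked bins")

    flat_order = sorted(
        (tuple(idx) for idx in np.argwhere(unmasked)),
        key=lambda t: (pmf[t], t),
    )
    # union-find over basin roots; root carries its minimum bin & value
    parent: dict[tuple, tuple] = {}
    root_min: dict[tuple, tuple] = {}       # root -> minimum bin index
    survivors: dict[tuple, bool] = {}       # minimum bin -> still separate

    def find(x: tuple) -> tuple:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    labeled = np.zeros(shape, dtype=bool)
    for bin_idx in flat_order:
        lower_roots = []
        for nb in _neighbors(bin_idx, shape):
            if labeled[nb]:
                r = find(nb)
                if r not in lower_roots:
                    lower_roots.append(r)
        if not lower_roots:
            parent[bin_idx] = bin_idx
            root_min[bin_idx] = bin_idx
            survivors[bin_idx] = True
        else:
            # deepest existing basin absorbs the bin; others meet here
            lower_roots.sort(key=lambda r: (pmf[root_min[r]], root_min[r]))
            deepest = lower_roots[0]
            parent[bin_idx] = deepest
            saddle = pmf[bin_idx]
            for other in lower_roots[1:]:
                persistence = saddle - pmf[root_min[other]]
                if persistence < depth_threshold:
                    survivors[root_min[other]] = False
                parent[other] = deepest
        labeled[bin_idx] = True

    centers = profile.bin_centers
    minima = sorted(
        (m for m, alive in survivors.items() if alive),
        key=lambda m: (pmf[m], m),
    )
    basins = [
        Basin(
            label=f"m{k + 1}",
            bin_index=m,
            pmf_value=float(pmf[m]),
            cv_coordinates=tuple(centers[d][m[d]] for d in range(profile.dims)),
        )
        for k, m in enumerate(minima)
    ]
    return BasinSet(basins=basins)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def anharmonicity_check(
    dv_by_bin: list[np.ndarray], skew_threshold: float = 0.5
) -> np.ndarray:
    """Flag bins whose ΔV distribution departs from Gaussian.

    The second-order cumulant truncation is exact only for bin-wise
    Gaussian ΔV; a bin with excess |skewness| above the threshold is
    flagged as unreliable under that truncation. Bins with fewer than
    three frames or zero variance report skewness 0 (not flagged).
    """
    flags = np.zeros(len(dv_by_bin), dtype=bool)
    for i, dv in enumerate(dv_by_bin):
        dv = np.asarray(dv, dtype=float)
        if len(dv) < 3 or np.ptp(dv) == 0:
            continue
        flags[i] = abs(float(stats.skew(dv))) > skew_threshold
    return flags


def bin_boost_samples(
    cv, dV, bins=50, min_count: int = 20
) -> tuple[list[np.ndarray], np.ndarray]:
    """Group per-frame ΔV by CV bin, keeping bins with ≥ min_count frames.

    Returns the list of per-bin ΔV arrays and the matching bin centers —
    the input :func:`anharmonicity_check` expects.
    """
    values = _as_values(cv)
    dv = np.asarray(dV, dtype=float)
    if len(values) != len(dv):
        raise InputError("cv and dV lengths differ")
    edges = np.histogram_bin_edges(values, bins=bins)
    ix = np.clip(
        np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2
    )
    centers = 0.5 * (edges[1:] + edges[:-1])
    groups, kept = [], []
    for b in range(len(centers)):
        members = np.nonzero(ix == b)[0]
        if len(members) >= min_count:
            groups.append(dv[members])
            kept.append(centers[b])
    return groups, np.asarray(kept)
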