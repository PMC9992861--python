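"""Ground-truth-bearing synthetic inputs for every analysis stage.

Two families of fixtures:

* **Toy motors** — Cα-only two-domain structures built from ideal
  secondary-structure elements, with an exactly planted inter-domain
  "cleft" distance and element crossing angle, optional planted
  conformational clusters, and Gaussian positional jitter. Every frame
  carries its ground truth in a ledger, so distance/angle collective
  variables and RMSD clustering are testable by recovery.

* **Boosted samples** — draws from a known 1D/2D potential V(ξ) under a
  GaMD-form boost ΔV(ξ) = ½k(E − V)² (V < E), sampled at the
  distribution level (inverse-CDF in 1D, Metropolis in 2D). The exact
  per-sample ΔV and the true PMF on a grid are returned, so the
  cumulant-expansion reweighting is testable by recovery of F_true.

Sampling at the distribution level is deliberate: the reweighting
pipeline consumes (ξ, ΔV) pairs only, so simulating dynamics would add
nothing verifiable.

A single global seed expands into independent per-component streams via
``numpy.random.SeedSequence(seed, spawn_key=(component,))`` with
component 0 = toy motor, 1 = boosted sampler, 2 = bimodal series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .geometry import AtomAnchor, CVSeries, fit_axis
from .io import Ensemble, MotifDefinition, Topology
from .reweighting import KB_KCAL

__all__ = [
    "ToyMotorSpec",
    "BoostedSampleSpec",
    "BoostedSample",
    "make_toy_motor",
    "sample_boosted",
    "make_bimodal_series",
    "ideal_helix",
    "ideal_strand",
    "gamd_boost",
]

_COMPONENT_TOY = 0
_COMPONENT_BOOST = 1
_COMPONENT_BIMODAL = 2


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(component,))
    )


# ---------------------------------------------------------------------------
# Ideal secondary-structure elements
# ---------------------------------------------------------------------------

def ideal_helix(
    n_residues: int = 18,
    radius: float = 2.3,
    rise: float = 1.5,
    twist: float = 100.0,
) -> np.ndarray:
    """Cα trace of an ideal α-helix along +z, one point per residue."""
    i = np.arange(n_residues)
    theta = np.radians(twist) * i
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )


def ideal_strand(n_residues: int = 12, rise: float = 3.3,
                 offset: float = 0.95) -> np.ndarray:
    """Cα trace of an idealized β-strand along +z with pleat zigzag.

    The pleat pattern (+, −, −, +) repeats with period 4 so that, for a
    multiple of four residues, the zigzag is exactly uncorrelated with
    the strand direction and the principal axis equals +z.
    """
    i = np.arange(n_residues)
    pattern = np.array([1.0, -1.0, -1.0, 1.0])
    x = offset * pattern[i % 4]
    return np.column_stack([x, np.zeros(n_residues), rise * i])


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


# ---------------------------------------------------------------------------
# Toy motor ensembles
# ---------------------------------------------------------------------------

@dataclass
class ToyMotorSpec:
    """Specification of a synthetic two-domain Cα-only ensemble.

    ``cleft_distance`` (Å) and ``crossing_angle`` (deg) may be scalars
    (all frames identical) or per-frame sequences. Alternatively
    ``cluster_centers`` plants discrete conformers as (cleft, angle)
    pairs with ``cluster_weights`` (default equal); frames are assigned
    to conformers at random with the spec's seed. ``loop_jitter_sd`` is
    the per-coordinate Gaussian jitter in Å applied to every atom.
    """

    n_frames: int = 100
    cleft_distance: float | Sequence[float] = 20.0
    crossing_angle: float | Sequence[float] = 22.0
    loop_jitter_sd: float = 0.0
    cluster_centers: list[tuple[float, float]] | None = None
    cluster_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SpecError("n_frames must be ≥ 1")
        if self.loop_jitter_sd < 0:
            raise SpecError("loop_jitter_sd must be ≥ 0")


# Chain/residue layout of the toy motor (author numbering):
#   chain A: residues 1-18 ideal helix ("HF helix" stand-in),
#            residues 19-30 ideal strand
#   chain B: residues 1-18 ideal helix,
#            residues 19-30 ideal strand ("beta5" stand-in)
# The planted crossing angle is between the chain-A helix and the
# chain-B strand; the planted cleft distance is the Cα–Cα distance
# between residue 10 of chain A and residue 10 of chain B.
TOY_MOTIFS: dict[str, MotifDefinition] = {
    "HF_helix": MotifDefinition("HF_helix", "A", (1, 18), "CA"),
    "strand_A": MotifDefinition("strand_A", "A", (19, 30), "CA"),
    "helix_B": MotifDefinition("helix_B", "B", (1, 18), "CA"),
    "beta5": MotifDefinition("beta5", "B", (19, 30), "CA"),
    "domain_A": MotifDefinition("domain_A", "A", (1, 30), "CA"),
    "domain_B": MotifDefinition("domain_B", "B", (1, 30), "CA"),
}
#: both domains, for whole-complex RMSD clustering
TOY_COMPLEX: tuple[MotifDefinition, MotifDefinition] = (
    TOY_MOTIFS["domain_A"], TOY_MOTIFS["domain_B"],
)
TOY_CLEFT_ANCHORS: tuple[AtomAnchor, AtomAnchor] = (
    AtomAnchor("A", 10, "CA"),
    AtomAnchor("B", 10, "CA"),
)


def _toy_domain() -> tuple[np.ndarray, np.ndarray]:
    """One rigid domain: 18-residue helix + 12-residue strand.

    Returns (coordinates, residue numbers). The strand is placed beside
    the helix, both along +z.
    """
    helix = ideal_helix(18)
    strand = ideal_strand(12) + np.array([7.0, 0.0, 1.0])
    coords = np.vstack([helix, strand])
    resnum = np.arange(1, 31)
    return coords, resnum


def _toy_topology() -> Topology:
    _, resnum = _toy_domain()
    n = len(resnum)
    return Topology(
        atom_serial=np.arange(1, 2 * n + 1),
        atom_name=np.array(["CA"] * (2 * n), dtype=object),
        residue_name=np.array(["GLY"] * (2 * n), dtype=object),
        residue_number=np.concatenate([resnum, resnum]),
        chain_id=np.array(["A"] * n + ["B"] * n, dtype=object),
        element=np.array(["C"] * (2 * n), dtype=object),
        occupancy=np.ones(2 * n),
    )


def _toy_frame(cleft: float, angle: float) -> np.ndarray:
    """Exact-geometry frame for one (cleft, angle) pair, before jitter.

    Domain B is rotated about the y axis — perpendicular to the fitted
    (principal) axes of both reference elements, which lie in the x–z
    plane by construction — so the crossing angle between the chain-A
    helix and the chain-B strand equals ``angle`` exactly (principal
    axes are equivariant under rigid rotation). Domain B is then
    translated so the anchor Cα–Cα distance equals ``cleft`` exactly.
    """
    if cleft < 0:
        raise SpecError(f"infeasible geometry: negative cleft {cleft}")
    coords_a, _ = _toy_domain()
    coords_b0, _ = _toy_domain()

    helix_a_axis = fit_axis(coords_a[:18])
    strand_b_axis = fit_axis(coords_b0[18:])
    # Rotate B so its strand axis starts parallel to A's helix axis,
    # then apply the planted rotation about an axis perpendicular to it.
    align = _align_rotation(strand_b_axis, helix_a_axis)
    coords_b = coords_b0 @ align.T
    perp = np.cross(helix_a_axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(helix_a_axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    rot = _rotation_about(perp, angle)
    coords_b = coords_b @ rot.T
    # Anchor residue 10 => row index 9 in each domain block.
    target = coords_a[9] + cleft * np.array([1.0, 0.0, 0.0])
    coords_b = coords_b + (target - coords_b[9])
    return np.vstack([coords_a, coords_b])


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180°: rotate about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _rotation_about(perp / np.linalg.norm(perp), 180.0)
    axis = np.cross(u, v)
    axis = axis / np.linalg.norm(axis)
    return _rotation_about(axis, np.degrees(np.arccos(c)))


def make_toy_motor(spec: ToyMotorSpec) -> tuple[Ensemble, dict]:
    """Build a toy-motor ensemble plus its ground-truth ledger.

    The ledger records, per frame, the exact pre-jitter cleft distance,
    crossing angle, and (when conformers are planted) cluster label,
    along with the motif definitions and anchors that recover them.
    """
    rng = _rng(spec.seed, _COMPONENT_TOY)
    n = spec.n_frames

    if spec.cluster_centers is not None:
        k = len(spec.cluster_centers)
        if k < 1:
            raise SpecError("cluster_centers must be non-empty when given")
        if spec.cluster_weights is None:
            weights = np.full(k, 1.0 / k)
        else:
            weights = np.asarray(spec.cluster_weights, dtype=float)
            if len(weights) != k or np.any(weights < 0):
                raise SpecError("cluster_weights must be nonnegative, one per center")
            if abs(weights.sum() - 1.0) > 1e-9:
                raise SpecError("cluster_weights must sum to 1")
        labels = rng.choice(k, size=n, p=weights)
        cleft = np.array([spec.cluster_centers[c][0] for c in labels])
        angle = np.array([spec.cluster_centers[c][1] for c in labels])
    else:
        labels = np.zeros(n, dtype=int)
        cleft = np.broadcast_to(
            np.asarray(spec.cleft_distance, dtype=float), (n,)
        ).copy() if np.ndim(spec.cleft_distance) == 0 else np.asarray(
            spec.cleft_distance, dtype=float
        )
        angle = np.broadcast_to(
            np.asarray(spec.crossing_angle, dtype=float), (n,)
        ).copy() if np.ndim(spec.crossing_angle) == 0 else np.asarray(
            spec.crossing_angle, dtype=float
        )
        if len(cleft) != n or len(angle) != n:
            raise SpecError("per-frame cleft/angle sequences must have n_frames entries")
    if np.any(cleft < 0):
        raise SpecError("infeasible geometry: negative cleft distance")

    frames = np.empty((n, 60, 3))
    for f in range(n):
        frames[f] = _toy_frame(float(cleft[f]), float(angle[f]))
    if spec.loop_jitter_sd > 0:
        frames = frames + rng.normal(0.0, spec.loop_jitter_sd, frames.shape)

    ensemble = Ensemble(
        topology=_toy_topology(), coordinates=frames, state_label="custom"
    )
    ledger = {
        "cleft_true": cleft,
        "angle_true": angle,
        "cluster_label": labels,
        "motifs": TOY_MOTIFS,
        "complex_selection": TOY_COMPLEX,
        "cleft_anchors": TOY_CLEFT_ANCHORS,
        "angle_motifs": (TOY_MOTIFS["HF_helix"], TOY_MOTIFS["beta5"]),
        "jitter_sd": spec.loop_jitter_sd,
        "seed": spec.seed,
    }
    return ensemble, ledger


# ---------------------------------------------------------------------------
# Boosted samples from known potentials
# ---------------------------------------------------------------------------

@dataclass
class BoostedSampleSpec:
    """Specification of boosted draws from a known potential.

    Potentials (all energies in kcal/mol):

    * ``harmonic`` — V = ½k(x − x0)²; params ``k`` (kcal/mol/unit²),
      ``x0``.
    * ``double_well`` — V = b·((2(x − c)/s)² − 1)², wells at c ± s/2,
      barrier height ``b`` at x = c; params ``b``, ``s``, optional ``c``.
    * ``gaussian_2d`` — V = ½ k_B T (x − μ)ᵀ Σ⁻¹ (x − μ); params
      ``mean`` (2,), ``cov`` (2×2). The unbiased Boltzmann density at
      ``temperature`` then has exactly that mean and covariance.

    The GaMD boost is ΔV(x) = ½·k_boost·(E − V(x))² wherever V(x) < E
    and zero elsewhere; ``boost_E`` is required when ``k_boost`` > 0.
    """

    potential: str = "double_well"
    params: dict = field(default_factory=lambda: {"b": 3.0, "s": 4.0})
    k_boost: float = 0.0
    boost_E: float | None = None
    temperature: float = 300.0
    n_samples: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise SpecError("n_samples must be ≥ 1")
        if self.temperature <= 0:
            raise SpecError("temperature must be positive")
        if self.k_boost < 0:
            raise SpecError("k_boost must be ≥ 0")
        if self.k_boost > 0 and self.boost_E is None:
            raise SpecError("boost_E is required when k_boost > 0")


@dataclass
class BoostedSample:
    """Boosted draws plus exact per-sample ΔV and the true PMF."""

    samples: np.ndarray       # (n,) in 1D, (n, 2) in 2D
    dV: np.ndarray            # kcal/mol, exact ΔV(x_i)
    grid: list[np.ndarray]    # per-dimension analysis grid
    f_true: np.ndarray        # V − min V on the grid, kcal/mol
    dims: int


def gamd_boost(v: np.ndarray, E: float, k_boost: float) -> np.ndarray:
    """GaMD boost ΔV = ½k(E − V)² below threshold E, zero above."""
    v = np.asarray(v, dtype=float)
    dv = 0.5 * k_boost * (E - v) ** 2
    return np.where(v < E, dv, 0.0)


def _potential_1d(spec: BoostedSampleSpec):
    p = spec.params
    if spec.potential == "harmonic":
        k, x0 = float(p["k"]), float(p.get("x0", 0.0))
        if k <= 0:
            raise SpecError("harmonic potential needs k > 0 (bounded below)")
        return (lambda x: 0.5 * k * (x - x0) ** 2), x0, np.sqrt(
            KB_KCAL * spec.temperature / k
        ) * 8 + 1.0
    if spec.potential == "double_well":
        b, s = float(p["b"]), float(p["s"])
        c = float(p.get("c", 0.0))
        if b <= 0 or s <= 0:
            raise SpecError("double well needs b > 0 and s > 0")
        return (
            lambda x: b * ((2.0 * (x - c) / s) ** 2 - 1.0) ** 2,
            c,
            s * 2.0,
        )
    raise SpecError(f"unknown 1D potential {spec.potential!r}")


def sample_boosted(spec: BoostedSampleSpec) -> BoostedSample:
    """Draw samples from exp(−β[V + ΔV]) with exact ΔV bookkeeping.

    1D potentials are sampled by inverse-CDF on a dense grid (40 001
    points spanning the thermally occupied range); the 2D Gaussian
    basin uses Metropolis with proposal SD = 5 × grid spacing, burn-in
    10 000 and thinning 5. Identical spec + seed gives byte-identical
    output.
    """
    rng = _rng(spec.seed, _COMPONENT_BOOST)
    beta = 1.0 / (KB_KCAL * spec.temperature)

    if spec.potential in ("harmonic", "double_well"):
        vfun, center, half_range = _potential_1d(spec)
        dense = np.linspace(center - half_range, center + half_range, 40_001)
        v = vfun(dense)
        dv = gamd_boost(v, spec.boost_E, spec.k_boost) if spec.k_boost > 0 \
            else np.zeros_like(v)
        log_p = -beta * (v + dv)
        log_p -= log_p.max()
        p = np.exp(log_p)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]))])
        cdf /= cdf[-1]
        u = rng.uniform(0.0, 1.0, spec.n_samples)
        samples = np.interp(u, cdf, dense)
        v_s = vfun(samples)
        dv_s = gamd_boost(v_s, spec.boost_E, spec.k_boost) if spec.k_boost > 0 \
            else np.zeros_like(v_s)
        grid = np.linspace(dense[0], dense[-1], 513)
        f_true = vfun(grid)
        f_true = f_true - f_true.min()
        return BoostedSample(
            samples=samples, dV=dv_s, grid=[grid], f_true=f_true, dims=1
        )

    if spec.potential == "gaussian_2d":
        mean = np.asarray(spec.params["mean"], dtype=float)
        cov = np.asarray(spec.params["cov"], dtype=float)
        if mean.shape != (2,) or cov.shape != (2, 2):
            raise SpecError("gaussian_2d needs mean (2,) and cov (2, 2)")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise SpecError("covariance must be positive definite (bounded potential)")
        prec = np.linalg.inv(cov)
        kt = KB_KCAL * spec.temperature

        def vfun2(x: np.ndarray) -> np.ndarray:
            d = np.atleast_2d(x) - mean
            return 0.5 * kt * np.einsum("ni,ij,nj->n", d, prec, d)

        sd = np.sqrt(np.diag(cov))
        grids = [
            np.linspace(mean[d] - 4 * sd[d], mean[d] + 4 * sd[d], 61)
            for d in range(2)
        ]
        spacing = float(np.mean([g[1] - g[0] for g in grids]))
        proposal_sd = 5.0 * spacing
        burn_in, thinning = 10_000, 5

        def energy(x: np.ndarray) -> float:
            v = float(vfun2(x[None, :])[0])
            dv = float(gamd_boost(np.array([v]), spec.boost_E, spec.k_boost)[0]) \
                if spec.k_boost > 0 else 0.0
            return v + dv

        x = mean.copy()
        e = energy(x)
        n_steps = burn_in + thinning * spec.n_samples
        out = np.empty((spec.n_samples, 2))
        kept = 0
        steps = rng.normal(0.0, proposal_sd, (n_steps, 2))
        accepts = rng.uniform(0.0, 1.0, n_steps)
        for step in range(n_steps):
            cand = x + steps[step]
            e_cand = energy(cand)
            if e_cand <= e or accepts[step] < np.exp(-beta * (e_cand - e)):
                x, e = cand, e_cand
            if step >= burn_in and (step - burn_in) % thinning == thinning - 1:
                out[kept] = x
                kept += 1
                if kept == spec.n_samples:
                    break
        v_s = vfun2(out)
        dv_s = gamd_boost(v_s, spec.boost_E, spec.k_boost) if spec.k_boost > 0 \
            else np.zeros_like(v_s)
        gx, gy = np.meshgrid(grids[0], grids[1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        f_true = vfun2(pts).reshape(gx.shape)
        f_true = f_true - f_true.min()
        return BoostedSample(
            samples=out, dV=dv_s, grid=grids, f_true=f_true, dims=2
        )

    raise SpecError(f"unknown potential {spec.potential!r}")


# ---------------------------------------------------------------------------
# Bimodal CV series
# ---------------------------------------------------------------------------

def make_bimodal_series(
    modes: Sequence[tuple[float, float, float]],
    n: int,
    seed: int = 0,
    name: str = "distance",
    unit: str = "Å",
) -> tuple[CVSeries, dict]:
    """Gaussian-mixture CV samples with a ledger of the true modes.

    ``modes`` is a list of (position, sd, weight) triples whose weights
    must sum to one. Component assignment and draws are deterministic
    in the seed.
    """
    if not modes:
        raise SpecError("need at least one mode")
    positions = np.array([m[0] for m in modes], dtype=float)
    sds = np.array([m[1] for m in modes], dtype=float)
    weights = np.array([m[2] for m in modes], dtype=float)
    if np.any(sds <= 0):
        raise SpecError("mode standard deviations must be positive")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise SpecError("mode weights must be nonnegative and sum to 1")
    rng = _rng(seed, _COMPONENT_BIMODAL)
    component = rng.choice(len(modes), size=n, p=weights)
    values = rng.normal(positions[component], sds[component])
    series = CVSeries(name=name, unit=unit, values=values)
    ledger = {
        "positions": positions,
        "sds": sds,
        "weights": weights,
        "component": component,
        "seed": seed,
    }
    return series, ledger
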