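"""Per-frame collective variables over conformational ensembles.

Implements the geometric observables used to project motor-domain
conformational landscapes: atom-pair distances (salt bridges, the
actin-binding cleft width), crossing angles between secondary-structure
elements (e.g. the HF helix against the β5 strand of the transducer),
motif–motif buried contact areas from solvent-accessible surface area,
and least-squares superposition RMSD against reference structures.

All collective variables are functions of internal geometry only and
are therefore invariant under rigid-body motion of each frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AnchorError,
    CorrespondenceError,
    DefinitionError,
    DegenerateGeometryError,
    InputError,
    RadiusError,
)
from .io import Ensemble, MotifDefinition, StructureModel, resolve_selection

__all__ = [
    "CVSeries",
    "AtomAnchor",
    "VDW_RADII",
    "distance_cv",
    "cleft_width",
    "fit_axis",
    "crossing_angle",
    "fibonacci_sphere",
    "sasa",
    "contact_area",
    "kabsch_superpose",
    "rmsd_series",
]

#: Bondi-style van der Waals radii in Å, by element; the fallback for
#: unlisted elements is carbon-like (1.70 Å). Overridable per call.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}
DEFAULT_RADIUS = 1.70


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CVSeries:
    """A named per-frame scalar collective variable with units.

    ``unit`` is one of ``"Å"``, ``"deg"``, ``"Å^2"``. Values are stored
    in frame order, one per ensemble frame.
    """

    name: str
    unit: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InputError("CVSeries values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise InputError(f"CV {self.name!r} contains non-finite values")
        if self.unit == "deg" and (vals.min() < -1e-9 or vals.max() > 180 + 1e-9):
            raise InputError(f"angle CV {self.name!r} outside [0°, 180°]")
        if self.unit == "Å^2" and vals.min() < -1e-9:
            raise InputError(f"area CV {self.name!r} has negative values")
        self.values = vals

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AtomAnchor:
    """One atom named by chain, author residue number, and atom name."""

    chain_id: str
    residue_number: int
    atom_name: str = "CA"

    def resolve(self, ensemble: Ensemble) -> int:
        top = ensemble.topology
        mask = (
            (top.chain_id == self.chain_id)
            & (top.residue_number == self.residue_number)
            & (top.atom_name == self.atom_name)
        )
        hits = np.nonzero(mask)[0]
        if len(hits) != 1:
            raise AnchorError(
                f"anchor {self.chain_id}/{self.residue_number}/"
                f"{self.atom_name} resolves to {len(hits)} atoms (need 1)"
            )
        return int(hits[0])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def distance_cv(
    ensemble: Ensemble, a: AtomAnchor, b: AtomAnchor, name: str | None = None
) -> CVSeries:
    """Euclidean distance between two anchored atoms, per frame, in Å."""
    ia, ib = a.resolve(ensemble), b.resolve(ensemble)
    delta = ensemble.coordinates[:, ia, :] - ensemble.coordinates[:, ib, :]
    values = np.linalg.norm(delta, axis=1)
    if name is None:
        name = (
            f"d_{a.chain_id}{a.residue_number}{a.atom_name}"
            f"_{b.chain_id}{b.residue_number}{b.atom_name}"
        )
    return CVSeries(name=name, unit="Å", values=values)


def cleft_width(
    ensemble: Ensemble, res_a: AtomAnchor, res_b: AtomAnchor
) -> CVSeries:
    """Actin-binding cleft width: Cα–Cα distance between two residues.

    Semantically-named alias of :func:`distance_cv`; by convention the
    anchors are the Cα atoms of a residue preceding the CM loop and a
    residue in the helix–loop–helix motif, so the value reports the
    separation of the upper and lower 50-kDa subdomains (open ≈ 20 Å,
    closed ≈ 15 Å in cardiac actomyosin).
    """
    series = distance_cv(ensemble, res_a, res_b)
    series.name = "cleft_width"
    return series


# ---------------------------------------------------------------------------
# Axes and crossing angles
# ---------------------------------------------------------------------------

def fit_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis of an ordered run of Cα positions, N→C oriented.

    The axis is the largest-variance direction of the centered points
    (first right-singular vector), with its sign chosen so it points
    from the first residue toward the last. For an ideal α-helix with a
    whole number of turns this is exactly the helix axis; for partial
    turns the tilt is well under a degree for elements of typical
    length.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected (n, 3) coordinates, got {pts.shape}")
    if pts.shape[0] < 3:
        raise InputError(f"axis fit needs ≥3 points, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-12):
        raise DegenerateGeometryError("all points identical; no axis defined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise DegenerateGeometryError("zero spread; no axis defined")
    axis = vt[0]
    chord = pts[-1] - pts[0]
    if np.dot(axis, chord) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _chord_axis(coords: np.ndarray) -> np.ndarray:
    """Two-endpoint chord alternative to the principal-axis fit."""
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 3:
        raise InputError(f"axis fit needs ≥3 points, got {pts.shape[0]}")
    chord = pts[-1] - pts[0]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise DegenerateGeometryError("coincident endpoints; no chord axis")
    return chord / norm


def crossing_angle(
    ensemble: Ensemble,
    elem1: MotifDefinition,
    elem2: MotifDefinition,
    method: str = "principal",
) -> CVSeries:
    """Per-frame crossing angle between two secondary-structure elements.

    Each element's Cα atoms are fitted to a directed (N→C) axis and the
    angle is ``arccos`` of the axes' dot product, in degrees. Using
    directed axes keeps the full [0°, 180°] range, distinguishing
    parallel from antiparallel packing — rigor-state HF/β5 packing sits
    near 5–10°, the prepowerstroke state near 20–25°.

    ``method`` selects the axis fit: ``"principal"`` (default) or
    ``"chord"`` (two-endpoint vector).
    """
    ca1 = _ca_motif(elem1)
    ca2 = _ca_motif(elem2)
    idx1 = resolve_selection(ensemble, ca1)
    idx2 = resolve_selection(ensemble, ca2)
    for motif, idx in ((elem1, idx1), (elem2, idx2)):
        if len(idx) < 3:
            raise InputError(
                f"motif {motif.name!r}: crossing angle needs ≥3 CA atoms, "
                f"got {len(idx)}"
            )
    fit = fit_axis if method == "principal" else _chord_axis
    angles = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        try:
            u = fit(ensemble.coordinates[f, idx1])
            v = fit(ensemble.coordinates[f, idx2])
        except (InputError, DegenerateGeometryError) as exc:
            raise DegenerateGeometryError(
                f"frame {f}, motifs {elem1.name!r}/{elem2.name!r}: {exc}"
            ) from exc
        cosang = np.clip(np.dot(u, v), -1.0, 1.0)
        angles[f] = np.degrees(np.arccos(cosang))
    return CVSeries(
        name=f"crossing_{elem1.name}_{elem2.name}", unit="deg", values=angles
    )


def _ca_motif(motif: MotifDefinition) -> MotifDefinition:
    return MotifDefinition(
        name=motif.name, chain_id=motif.chain_id,
        residue_range=motif.residue_range, atom_filter="CA",
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area and contact area
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic golden-angle lattice of ``n`` points on the unit sphere."""
    if n < 1:
        raise InputError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(
    elements: Sequence[str], radii: Mapping[str, float] | None
) -> np.ndarray:
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el in table:
            out[i] = table[el]
        elif el == "":
            raise RadiusError("atom has no element; cannot assign radius")
        else:
            out[i] = table.get("default", DEFAULT_RADIUS)
    return out


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate a system into its principal-axes frame, deterministically.

    The lattice quadrature is evaluated in this molecule-fixed frame so
    that the computed areas are exactly invariant under rigid-body
    motion of the input (for systems with non-degenerate inertia). Axis
    signs follow the third moment of the projections; a vanishing third
    moment leaves the axis unflipped, which is harmless for the
    symmetric systems where it occurs.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(2):
        s3 = np.sum((centered @ vecs[:, k]) ** 3)
        if s3 < -1e-9:
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])  # proper frame
    return centered @ vecs


def _sasa_points(
    coords: np.ndarray,
    inflated: np.ndarray,
    target: np.ndarray,
    sphere: np.ndarray,
) -> np.ndarray:
    """Shrake–Rupley accessible area for ``target`` atoms within a system.

    ``coords``/``inflated`` describe every occluding atom; a lattice
    point on a target atom's probe-inflated sphere counts as accessible
    when it lies outside every other atom's inflated sphere. The system
    is evaluated in its canonical principal-axes frame (see
    :func:`_canonical_frame`), making the quadrature rigid-motion
    invariant.
    """
    coords = _canonical_frame(coords)
    n_pts = len(sphere)
    tree = cKDTree(coords)
    r_max = inflated.max()
    areas = np.empty(len(target))
    for t, i in enumerate(target):
        pts = coords[i] + inflated[i] * sphere
        neighbors = tree.query_ball_point(coords[i], inflated[i] + r_max)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_pts, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        areas[t] = (
            4.0 * np.pi * inflated[i] ** 2 * np.count_nonzero(accessible) / n_pts
        )
    return areas


def sasa(
    model: StructureModel,
    atom_subset: Sequence[int] | np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, in Å².

    Shrake–Rupley quadrature on a deterministic Fibonacci lattice: each
    atom's sphere is inflated by the probe radius and the accessible
    fraction of lattice points gives the area. The subset defines the
    system — atoms outside it neither occlude nor are reported.
    """
    if atom_subset is None:
        atom_subset = np.arange(model.topology.n_atoms)
    idx = np.asarray(atom_subset, dtype=int)
    if len(idx) == 0:
        raise InputError("atom subset is empty")
    coords = model.coordinates[idx]
    elements = [model.topology.element[i] for i in idx]
    inflated = _radii_for(elements, radii) + probe_radius
    sphere = fibonacci_sphere(n_sphere_points)
    return _sasa_points(coords, inflated, np.arange(len(idx)), sphere)


def contact_area(
    ensemble: Ensemble,
    group_a: MotifDefinition,
    group_b: MotifDefinition,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    context: bool = False,
) -> CVSeries:
    """Per-frame buried contact area between two atom groups, in Å².

    The contact area is half the surface buried on complex formation:

        area = (SASA_A,alone + SASA_B,alone − SASA_AB,complex) / 2

    In the default pairwise mode "alone" means each group in isolation
    and the complex is A∪B only, which makes the value symmetric and
    independent of the rest of the structure. With ``context=True`` all
    other atoms of the model act as occluders in every term.
    """
    idx_a = resolve_selection(ensemble, group_a)
    idx_b = resolve_selection(ensemble, group_b)
    shared = np.intersect1d(idx_a, idx_b)
    if len(shared):
        raise DefinitionError(
            f"groups {group_a.name!r} and {group_b.name!r} share "
            f"{len(shared)} atoms; contact area is undefined"
        )
    top = ensemble.topology
    elements = top.element
    sphere = fibonacci_sphere(n_points)
    all_idx = np.arange(top.n_atoms)
    rest = np.setdiff1d(all_idx, np.concatenate([idx_a, idx_b]))
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        coords = ensemble.coordinates[f]

        def group_total(target: np.ndarray, system: np.ndarray) -> float:
            sys_coords = coords[system]
            inflated = _radii_for([elements[i] for i in system], radii) + probe
            pos = {int(g): k for k, g in enumerate(system)}
            tgt = np.array([pos[int(g)] for g in target])
            return float(np.sum(_sasa_points(sys_coords, inflated, tgt, sphere)))

        if context:
            sys_a = np.sort(np.concatenate([idx_a, rest]))
            sys_b = np.sort(np.concatenate([idx_b, rest]))
            sys_ab = all_idx
        else:
            sys_a, sys_b = idx_a, idx_b
            sys_ab = np.sort(np.concatenate([idx_a, idx_b]))
        sasa_a = group_total(idx_a, sys_a)
        sasa_b = group_total(idx_b, sys_b)
        sasa_ab = group_total(idx_a, sys_ab) + group_total(idx_b, sys_ab)
        values[f] = max(0.0, 0.5 * (sasa_a + sasa_b - sasa_ab))
    return CVSeries(
        name=f"contact_{group_a.name}_{group_b.name}", unit="Å^2", values=values
    )


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` is the least-squares fit.
    The rotation is proper (determinant +1); reflections are corrected
    by flipping the smallest singular direction.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InputError(
            f"point sets must both be (n, 3) with equal n; got "
            f"{mob.shape} and {ref.shape}"
        )
    if mob.shape[0] < 3:
        raise InputError(f"superposition needs ≥3 points, got {mob.shape[0]}")
    if weights is None:
        w = np.full(mob.shape[0], 1.0 / mob.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mob.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be nonnegative, matching length")
        w = w / w.sum()
    cm = w @ mob
    cr = w @ ref
    mob_c = mob - cm
    ref_c = ref - cr
    cov = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-30):
        raise DegenerateGeometryError(
            "rank-deficient covariance; rotation is not determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = cr - rotation @ cm
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd_series(
    ensemble: Ensemble,
    reference: StructureModel,
    fit_selection: MotifDefinition,
    measure_selection: MotifDefinition | None = None,
) -> CVSeries:
    """Per-frame RMSD to a reference after least-squares fitting.

    Atoms are matched between ensemble and reference by
    (chain, residue number, atom name). Each frame is superposed on
    ``fit_selection`` and the RMSD is reported over
    ``measure_selection`` (default: the fit selection itself) — the
    usual way to quote, e.g., motor-core RMSD against deposited
    structures after fitting on the core.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    fit_e, fit_r = _match_atoms(ensemble, reference, fit_selection)
    meas_e, meas_r = _match_atoms(ensemble, reference, measure_selection)
    ref_fit = reference.coordinates[fit_r]
    ref_meas = reference.coordinates[meas_r]
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        rot, trans, _ = kabsch_superpose(
            ensemble.coordinates[f, fit_e], ref_fit
        )
        moved = ensemble.coordinates[f, meas_e] @ rot.T + trans
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return CVSeries(
        name=f"rmsd_{measure_selection.name}", unit="Å", values=values
    )


def _match_atoms(
    ensemble: Ensemble, reference: StructureModel, motif: MotifDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of motif atoms in ensemble and reference, identically ordered."""
    ref_ens = Ensemble(
        topology=reference.topology,
        coordinates=reference.coordinates[None, :, :],
    )
    idx_e = resolve_selection(ensemble, motif)
    idx_r = resolve_selection(ref_ens, motif)
    keys_e = [
        (ensemble.topology.chain_id[i], ensemble.topology.residue_number[i],
         ensemble.topology.atom_name[i]) for i in idx_e
    ]
    keys_r = [
        (reference.topology.chain_id[i], reference.topology.residue_number[i],
         reference.topology.atom_name[i]) for i in idx_r
    ]
    map_r = {k: i for k, i in zip(keys_r, idx_r)}
    matched_e, matched_r, missing = [], [], []
    for k, i in zip(keys_e, idx_e):
        if k in map_r:
            matched_e.append(i)
            matched_r.append(map_r[k])
        else:
            missing.append(k)
    missing += [k for k in keys_r if k not in set(keys_e)]
    if missing:
        shown = ", ".join(f"{c}/{r}/{a}" for c, r, a in missing[:5])
        raise CorrespondenceError(
            f"motif {motif.name!r}: {len(missing)} unmatched atoms between "
            f"ensemble and reference (first: {shown})"
        )
    return np.array(matched_e, dtype=int), np.array(matched_r, dtype=int)
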