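"""Geometric collective variables against independent oracles.

Closed forms (3-4-5 triangles, sphere caps), constructions with known
answers (planted transforms, ideal helices), and brute-force searches
(rotation grid) stand in for the implementation-independent truth.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from motorscape.errors import (
    AnchorError,
    CorrespondenceError,
    DefinitionError,
    DegenerateGeometryError,
    InputError,
)
from motorscape.geometry import (
    AtomAnchor,
    cleft_width,
    contact_area,
    crossing_angle,
    distance_cv,
    fibonacci_sphere,
    fit_axis,
    kabsch_superpose,
    rmsd_series,
    sasa,
)
from motorscape.io import Ensemble, MotifDefinition, StructureModel, Topology
from motorscape.synthetic import ToyMotorSpec, ideal_helix, make_toy_motor

from conftest import build_topology, random_rotation


def _two_atom_ensemble(coords_per_frame):
    top = build_topology(2, atoms_per_residue=("CA",))
    return Ensemble(topology=top,
                    coordinates=np.asarray(coords_per_frame, dtype=float))


def _sphere_model(centers, elements):
    n = len(centers)
    top = Topology(
        atom_serial=np.arange(1, n + 1),
        atom_name=np.array([f"X{i}" for i in range(n)], dtype=object),
        residue_name=np.array(["SPH"] * n, dtype=object),
        residue_number=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n, dtype=object),
        element=np.array(elements, dtype=object),
        occupancy=np.ones(n),
    )
    return StructureModel(top, np.asarray(centers, dtype=float))


class TestDistance:
    def test_three_four_five(self):
        ens = _two_atom_ensemble([[[0, 0, 0], [3, 4, 0]]])
        cv = distance_cv(ens, AtomAnchor("A", 1), AtomAnchor("A", 2))
        assert cv.values[0] == pytest.approx(5.0)
        assert cv.unit == "Å"

    def test_identical_coordinates_zero(self):
        ens = _two_atom_ensemble([[[1, 2, 3], [1, 2, 3]]])
        cv = distance_cv(ens, AtomAnchor("A", 1), AtomAnchor("A", 2))
        assert cv.values[0] == 0.0

    def test_matches_direct_formula_on_random_frames(self, rng):
        coords = rng.normal(0, 20, (100, 2, 1, 3)).reshape(100, 2, 3)
        ens = _two_atom_ensemble(coords)
        cv = distance_cv(ens, AtomAnchor("A", 1), AtomAnchor("A", 2))
        # independent per-frame evaluation
        expected = np.array(
            [np.sqrt(sum((coords[f, 0, k] - coords[f, 1, k]) ** 2
                         for k in range(3))) for f in range(100)]
        )
        assert np.max(np.abs(cv.values - expected)) < 1e-12

    def test_ambiguous_anchor_raises(self, peptide_ensemble):
        with pytest.raises(AnchorError):
            distance_cv(peptide_ensemble, AtomAnchor("A", 1, "CA"),
                        AtomAnchor("A", 99, "CA"))


class TestCleftWidth:
    def test_planted_15_angstrom(self):
        ens = _two_atom_ensemble([[[0, 0, 0], [15, 0, 0]]])
        cv = cleft_width(ens, AtomAnchor("A", 1), AtomAnchor("A", 2))
        assert cv.values[0] == pytest.approx(15.0)
        assert cv.name == "cleft_width"

    def test_degenerate_same_anchor(self):
        ens = _two_atom_ensemble([[[0, 0, 0], [15, 0, 0]]])
        cv = cleft_width(ens, AtomAnchor("A", 1), AtomAnchor("A", 1))
        assert cv.values[0] == 0.0

    def test_equals_distance_cv(self, rng):
        coords = rng.normal(0, 5, (10, 2, 3))
        ens = _two_atom_ensemble(coords)
        a, b = AtomAnchor("A", 1), AtomAnchor("A", 2)
        assert np.array_equal(cleft_width(ens, a, b).values,
                              distance_cv(ens, a, b).values)


class TestFitAxis:
    def test_collinear_points(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        assert np.allclose(fit_axis(pts), [0, 0, 1])

    def test_orientation_follows_point_order(self):
        pts = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        assert np.allclose(fit_axis(pts[::-1]), [0, 0, -1])

    def test_ideal_helix_axis_recovery(self, rng):
        """PCA axis of a 24-residue ideal helix within 1° of the true axis."""
        helix = ideal_helix(24)
        rot = random_rotation(rng)
        true_axis = rot @ np.array([0, 0, 1.0])
        fitted = fit_axis(helix @ rot.T)
        angle = np.degrees(np.arccos(np.clip(fitted @ true_axis, -1, 1)))
        assert angle <= 1.0

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_axis(np.zeros((2, 3)))

    def test_degenerate_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_axis(np.ones((5, 3)))


def _helix_pair_ensemble(angle_deg: float) -> tuple[Ensemble, MotifDefinition,
                                                    MotifDefinition]:
    """Two ideal helices; the second is the first rotated about an axis
    perpendicular to the first's fitted axis, so the planted crossing
    angle is exact by PCA equivariance."""
    helix = ideal_helix(24)
    axis = fit_axis(helix)
    perp = np.cross(axis, [1.0, 0, 0])
    perp /= np.linalg.norm(perp)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * perp).as_matrix()
    second = helix @ rot.T + np.array([20.0, 0, 0])
    n = len(helix)
    top = Topology(
        atom_serial=np.arange(1, 2 * n + 1),
        atom_name=np.array(["CA"] * 2 * n, dtype=object),
        residue_name=np.array(["ALA"] * 2 * n, dtype=object),
        residue_number=np.concatenate([np.arange(1, n + 1)] * 2),
        chain_id=np.array(["A"] * n + ["B"] * n, dtype=object),
        element=np.array(["C"] * 2 * n, dtype=object),
        occupancy=np.ones(2 * n),
    )
    ens = Ensemble(topology=top,
                   coordinates=np.vstack([helix, second])[None, :, :])
    m1 = MotifDefinition("helix_1", "A", (1, n), "CA")
    m2 = MotifDefinition("helix_2", "B", (1, n), "CA")
    return ens, m1, m2


class TestCrossingAngle:
    @pytest.mark.parametrize("angle", [0.0, 22.0, 90.0, 150.0])
    def test_planted_angle_recovery(self, angle):
        ens, m1, m2 = _helix_pair_ensemble(angle)
        cv = crossing_angle(ens, m1, m2)
        assert cv.values[0] == pytest.approx(angle, abs=1.0)
        assert cv.unit == "deg"

    def test_symmetry(self):
        ens, m1, m2 = _helix_pair_ensemble(37.0)
        assert np.allclose(crossing_angle(ens, m1, m2).values,
                           crossing_angle(ens, m2, m1).values)

    def test_toy_motor_planted_angle(self):
        spec = ToyMotorSpec(n_frames=5, cleft_distance=18.0,
                            crossing_angle=22.0, loop_jitter_sd=0.0, seed=9)
        ens, ledger = make_toy_motor(spec)
        cv = crossing_angle(ens, *ledger["angle_motifs"])
        assert np.allclose(cv.values, 22.0, atol=1.0)

    def test_too_few_ca_atoms(self):
        ens, m1, _ = _helix_pair_ensemble(10.0)
        short = MotifDefinition("short", "B", (1, 2), "CA")
        with pytest.raises(InputError, match="short"):
            crossing_angle(ens, m1, short)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        model = _sphere_model([[0, 0, 0]], ["C"])
        area = sasa(model, [0], probe_radius=1.4, n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area[0] == pytest.approx(exact, rel=0.01)

    def test_distant_spheres_unoccluded(self):
        model = _sphere_model([[0, 0, 0], [100, 0, 0]], ["C", "C"])
        areas = sasa(model, [0, 1], probe_radius=1.4, n_sphere_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert np.allclose(areas, exact, rtol=0.01)

    def test_two_sphere_buried_cap_formula(self):
        # inflated radii R = 1.7 + 1.4 = 3.1; separation d < 2R
        R = 3.1
        d = 4.0
        model = _sphere_model([[0, 0, 0], [d, 0, 0]], ["C", "C"])
        areas = sasa(model, [0, 1], probe_radius=1.4, n_sphere_points=960)
        h = R - d / 2.0  # equal spheres: cap height on each
        exact = 4 * np.pi * R**2 - 2 * np.pi * R * h
        assert np.allclose(areas, exact, rtol=0.02)

    def test_quadrature_convergence(self):
        model = _sphere_model([[0, 0, 0], [3.5, 0.5, 0], [1.0, 3.0, 1.0]],
                              ["C", "N", "O"])
        a1 = sasa(model, [0, 1, 2], n_sphere_points=1920)
        a2 = sasa(model, [0, 1, 2], n_sphere_points=3840)
        assert np.all(np.abs(a1 - a2) / a2 < 0.005)

    def test_fibonacci_lattice_is_unit_and_deterministic(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, fibonacci_sphere(960))


def _two_group_ensemble(centers, elements, n_a):
    n = len(centers)
    top = Topology(
        atom_serial=np.arange(1, n + 1),
        atom_name=np.array([f"X{i}" for i in range(n)], dtype=object),
        residue_name=np.array(["SPH"] * n, dtype=object),
        residue_number=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n_a + ["B"] * (n - n_a), dtype=object),
        element=np.array(elements, dtype=object),
        occupancy=np.ones(n),
    )
    ens = Ensemble(topology=top,
                   coordinates=np.asarray(centers, dtype=float)[None, :, :])
    ga = MotifDefinition("ga", "A", (1, n_a), "all")
    gb = MotifDefinition("gb", "B", (n_a + 1, n), "all")
    return ens, ga, gb


class TestContactArea:
    def test_far_apart_is_zero(self):
        ens, ga, gb = _two_group_ensemble(
            [[0, 0, 0], [100, 0, 0]], ["C", "C"], 1
        )
        cv = contact_area(ens, ga, gb)
        assert cv.values[0] <= 0.1

    def test_symmetric(self):
        ens, ga, gb = _two_group_ensemble(
            [[0, 0, 0], [1.5, 0.5, 0.2], [3.9, 0, 0], [5.0, 1.0, 0]],
            ["C", "N", "O", "C"], 2,
        )
        ab = contact_area(ens, ga, gb).values[0]
        ba = contact_area(ens, gb, ga).values[0]
        assert ab == ba

    def test_single_atom_pair_matches_cap_formula(self):
        R = 3.1
        d = 4.0
        ens, ga, gb = _two_group_ensemble([[0, 0, 0], [d, 0, 0]],
                                          ["C", "C"], 1)
        cv = contact_area(ens, ga, gb, probe=1.4, n_points=960)
        h = R - d / 2.0
        buried_total = 2 * (2 * np.pi * R * h)  # both spheres
        assert cv.values[0] == pytest.approx(buried_total / 2.0, rel=0.02)

    def test_vanishes_beyond_geometric_cutoff(self):
        # cutoff 2·(r_max + probe) = 2·(1.7 + 1.4) = 6.2 Å for carbon
        ens, ga, gb = _two_group_ensemble([[0, 0, 0], [6.3, 0, 0]],
                                          ["C", "C"], 1)
        assert contact_area(ens, ga, gb).values[0] == 0.0

    def test_overlapping_groups_rejected(self):
        ens, ga, _ = _two_group_ensemble([[0, 0, 0], [2, 0, 0]],
                                         ["C", "C"], 1)
        with pytest.raises(DefinitionError):
            contact_area(ens, ga, ga)

    def test_context_mode_occlusion(self):
        # a third atom wedged between two groups reduces their pairwise
        # contact only in context mode
        n = 3
        top = Topology(
            atom_serial=np.arange(1, n + 1),
            atom_name=np.array(["X0", "X1", "X2"], dtype=object),
            residue_name=np.array(["SPH"] * n, dtype=object),
            residue_number=np.array([1, 1, 1]),
            chain_id=np.array(["A", "B", "C"], dtype=object),
            element=np.array(["C"] * n, dtype=object),
            occupancy=np.ones(n),
        )
        coords = np.array([[[0, 0, 0], [4.0, 0, 0], [2.0, 1.0, 0]]])
        ens = Ensemble(topology=top, coordinates=coords)
        ga = MotifDefinition("ga", "A", (1, 1), "all")
        gb = MotifDefinition("gb", "B", (1, 1), "all")
        pairwise = contact_area(ens, ga, gb).values[0]
        in_context = contact_area(ens, ga, gb, context=True).values[0]
        assert in_context != pytest.approx(pairwise, rel=1e-6)


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-12)

    def test_pure_translation(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts + [5.0, 5.0, 5.0])
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(trans, [5, 5, 5], atol=1e-9)

    def test_planted_rotation_recovery(self, rng):
        pts = rng.normal(0, 5, (10, 3))
        applied = random_rotation(rng)
        rot, _, rmsd = kabsch_superpose(pts, pts @ applied.T)
        assert rmsd <= 1e-9
        assert np.max(np.abs(rot - applied)) <= 1e-9

    def test_matches_scipy_align_vectors(self, rng):
        mobile = rng.normal(0, 3, (12, 3))
        reference = mobile @ random_rotation(rng).T + rng.normal(0, 2, 3) \
            + rng.normal(0, 0.3, (12, 3))
        rot, _, rmsd = kabsch_superpose(mobile, reference)
        sp_rot, sp_rssd = Rotation.align_vectors(
            reference - reference.mean(0), mobile - mobile.mean(0)
        )
        assert np.allclose(rot, sp_rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(sp_rssd / np.sqrt(12), abs=1e-8)

    def test_brute_force_rotation_grid(self, rng):
        """Optimal RMSD matches a grid+refine search on 5-point instances."""
        for seed in range(3):
            local = np.random.default_rng(seed)
            mobile = local.normal(0, 3, (5, 3))
            reference = local.normal(0, 3, (5, 3))
            _, _, rmsd = kabsch_superpose(mobile, reference)

            mob_c = mobile - mobile.mean(0)
            ref_c = reference - reference.mean(0)

            def cost(rotvec):
                R = Rotation.from_rotvec(rotvec).as_matrix()
                return np.sqrt(np.mean(
                    np.sum((mob_c @ R.T - ref_c) ** 2, axis=1)))

            candidates = []
            grid = np.linspace(0, 2 * np.pi, 13)[:-1]
            for a in grid:
                for b in np.linspace(0, np.pi, 7):
                    for c in grid:
                        R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                        val = np.sqrt(np.mean(
                            np.sum((mob_c @ R.T - ref_c) ** 2, axis=1)))
                        candidates.append(
                            (val, Rotation.from_matrix(R).as_rotvec())
                        )
            candidates.sort(key=lambda t: t[0])
            brute = min(
                minimize(cost, rotvec, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-14,
                                  "maxiter": 5000}).fun
                for _, rotvec in candidates[:5]
            )
            assert abs(rmsd - brute) <= 1e-3
            assert rmsd <= brute + 1e-9  # analytic optimum is a minimum

    def test_reflection_corrected(self):
        pts = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1, 1, 1.0]])
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_count_mismatch(self, rng):
        with pytest.raises(InputError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_degenerate_spread(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def _toy(self, n_frames=1, jitter=0.0, seed=0):
        spec = ToyMotorSpec(n_frames=n_frames, cleft_distance=18.0,
                            crossing_angle=20.0, loop_jitter_sd=jitter,
                            seed=seed)
        return make_toy_motor(spec)

    def test_copies_of_reference_give_zero(self):
        ens, ledger = self._toy(n_frames=3)
        ref = ens.frame(0)
        cv = rmsd_series(ens, ref, ledger["motifs"]["domain_A"])
        assert np.allclose(cv.values, 0.0, atol=1e-9)

    def test_gaussian_noise_rmsd_expectation(self):
        """Mean RMSD of σ-noised copies ≈ σ√3 (df-corrected) at 200 frames."""
        ens, ledger = self._toy(n_frames=200, jitter=0.5, seed=11)
        clean, _ = self._toy(n_frames=1)
        ref = clean.frame(0)
        motif = ledger["motifs"]["domain_A"]
        cv = rmsd_series(ens, ref, motif)
        sigma = 0.5
        n_atoms = 30
        # fitting removes 6 of the 3N noise degrees of freedom
        expected = sigma * np.sqrt((3 * n_atoms - 6) / n_atoms)
        assert cv.values.mean() == pytest.approx(expected, rel=0.05)
        # and the uncorrected σ√3 is also within the 5% contract
        assert cv.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_planted_rigid_displacement(self):
        ens, ledger = self._toy(n_frames=1)
        ref = ens.frame(0)
        moved = ens.coordinates.copy()
        moved[0, 30:, :] += np.array([0, 0, 3.0])  # displace domain B
        moved_ens = Ensemble(topology=ens.topology, coordinates=moved)
        cv = rmsd_series(moved_ens, ref,
                         fit_selection=ledger["motifs"]["domain_A"],
                         measure_selection=ledger["motifs"]["domain_B"])
        assert cv.values[0] == pytest.approx(3.0, abs=1e-9)

    def test_unmatched_atoms_listed(self):
        ens, ledger = self._toy(n_frames=1)
        ref_full = ens.frame(0)
        # renumber one residue in the reference so it no longer matches
        top = ref_full.topology
        resnum = top.residue_number.copy()
        resnum[5] = 99
        bad_top = Topology(
            atom_serial=top.atom_serial, atom_name=top.atom_name,
            residue_name=top.residue_name, residue_number=resnum,
            chain_id=top.chain_id, element=top.element,
            occupancy=top.occupancy,
        )
        bad_ref = StructureModel(bad_top, ref_full.coordinates)
        with pytest.raises(CorrespondenceError, match="unmatched"):
            rmsd_series(ens, bad_ref, ledger["motifs"]["domain_A"])


class TestRigidBodyInvariance:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cvs_invariant_under_rigid_motion(self, seed):
        """Distances, angles and contact areas are unchanged by global
        rotation + translation of every frame."""
        rng = np.random.default_rng(seed)
        spec = ToyMotorSpec(n_frames=2, cleft_distance=16.0,
                            crossing_angle=35.0, loop_jitter_sd=0.2,
                            seed=seed)
        ens, ledger = make_toy_motor(spec)
        moved = np.empty_like(ens.coordinates)
        for f in range(ens.n_frames):
            rot = random_rotation(rng)
            moved[f] = ens.coordinates[f] @ rot.T + rng.normal(0, 50, 3)
        ens2 = Ensemble(topology=ens.topology, coordinates=moved)

        a, b = ledger["cleft_anchors"]
        d1 = distance_cv(ens, a, b).values
        d2 = distance_cv(ens2, a, b).values
        assert np.max(np.abs(d1 - d2)) < 1e-6

        m1, m2 = ledger["angle_motifs"]
        a1 = crossing_angle(ens, m1, m2).values
        a2 = crossing_angle(ens2, m1, m2).values
        assert np.max(np.abs(a1 - a2)) < 1e-6

        ga = ledger["motifs"]["domain_A"]
        gb = ledger["motifs"]["domain_B"]
        c1 = contact_area(ens, ga, gb, n_points=240).values
        c2 = contact_area(ens2, ga, gb, n_points=240).values
        assert np.max(np.abs(c1 - c2)) < 1e-6
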