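"""Angles, ring planes, and the two halogen-bond checks; detector vs oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xbond import (
    DegenerateGeometryError,
    XBondCriteria,
    angle,
    cutoff_for_pair,
    detect_frame_xbonds,
    pi_xbond_check,
    point_xbond_check,
    ring_plane,
)
from xbond.geometry import RingSystem

from _helpers import (
    make_traj,
    observations_to_keys,
    oracle_detect,
    random_active_site_frame,
    random_rigid_transform,
)


class TestAngle:
    @pytest.mark.parametrize(
        "a,c,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
            ((2, 0, 0), (2, 0, 0), 0.0),
        ],
    )
    def test_closed_forms(self, a, c, expected):
        assert angle(np.array(a), np.zeros(3), np.array(c)) == pytest.approx(expected)

    def test_zero_length_arm(self):
        with pytest.raises(DegenerateGeometryError):
            angle(np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]))


class TestCutoffForPair:
    @pytest.mark.parametrize(
        "x,y,expected", [("Cl", "O", 3.27), ("Cl", "N", 3.30), ("Cl", "S", 3.55)]
    )
    def test_printed_sums(self, x, y, expected):
        assert cutoff_for_pair(x, y) == pytest.approx(expected)

    @given(
        x=st.sampled_from(["F", "CL", "BR", "I"]),
        y=st.sampled_from(["O", "N", "S", "C", "H"]),
    )
    def test_symmetric(self, x, y):
        assert cutoff_for_pair(x, y) == cutoff_for_pair(y, x)

    def test_override_wins_either_order(self):
        ov = {("CL", "O"): 3.0}
        assert cutoff_for_pair("O", "Cl", overrides=ov) == 3.0


def _hexagon(radius=1.39, z=0.0):
    return np.array(
        [
            [radius * math.cos(2 * math.pi * k / 6), radius * math.sin(2 * math.pi * k / 6), z]
            for k in range(6)
        ]
    )


def _grid_search_plane(points):
    """Brute-force plane fit: scan unit normals on a fine spherical grid and
    keep the one minimizing the sum of squared point-plane distances."""
    pts = np.asarray(points)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    best = (np.inf, None)
    for theta in np.linspace(0, math.pi, 180):
        for phi in np.linspace(0, 2 * math.pi, 360, endpoint=False):
            n = np.array(
                [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
                 math.cos(theta)]
            )
            cost = float(np.sum((centered @ n) ** 2))
            if cost < best[0]:
                best = (cost, n)
    return best[1]


class TestRingPlane:
    def test_regular_hexagon(self):
        centroid, normal = ring_plane(_hexagon())
        np.testing.assert_allclose(centroid, 0.0, atol=1e-12)
        assert abs(normal[2]) == pytest.approx(1.0, abs=1e-12)

    def test_displaced_atom_matches_grid_search(self):
        pts = _hexagon()
        pts[0, 2] += 0.1
        centroid, normal = ring_plane(pts)
        # still close to the z axis
        assert math.degrees(math.acos(abs(normal[2]))) < 3.0
        # and within the resolution of an independent grid-search fit
        ref = _grid_search_plane(pts)
        cos_sim = abs(float(np.dot(normal, ref)))
        assert math.degrees(math.acos(min(1.0, cos_sim))) < 1.5

    def test_collinear_points_degenerate(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            ring_plane(pts)

    def test_fewer_than_three_points(self):
        with pytest.raises(DegenerateGeometryError):
            ring_plane(np.zeros((2, 3)))


CRIT = XBondCriteria()


class TestPointCheck:
    def test_collinear_in_criteria(self):
        obs = point_xbond_check(
            np.zeros(3), np.array([1.70, 0, 0]), "CL",
            np.array([4.70, 0, 0]), "O", CRIT,
        )
        assert obs is not None
        assert obs.distance == pytest.approx(3.0)
        assert obs.beta == pytest.approx(180.0)

    def test_angle_failure(self):
        obs = point_xbond_check(
            np.zeros(3), np.array([1.70, 0, 0]), "CL",
            np.array([1.70, 3.00, 0]), "O", CRIT,
        )
        assert obs is None

    def test_strict_boundary_distance_is_not_a_bond(self):
        # acceptor exactly at the cutoff distance: strictly-less fails
        cutoff = cutoff_for_pair("Cl", "O")
        obs = point_xbond_check(
            np.array([-1.70, 0, 0]), np.zeros(3), "CL",
            np.array([cutoff, 0, 0]), "O", CRIT,
        )
        assert obs is None

    def test_strict_boundary_angle_is_not_a_bond(self):
        beta = math.radians(140.0)
        y = np.array([1.70, 0, 0]) + 3.0 * np.array(
            [-math.cos(beta), math.sin(beta), 0.0]
        )
        assert point_xbond_check(
            np.zeros(3), np.array([1.70, 0, 0]), "CL", y, "O", CRIT
        ) is None

    def test_coincident_acceptor_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            point_xbond_check(
                np.zeros(3), np.array([1.70, 0, 0]), "CL",
                np.array([1.70, 0, 0]), "O", CRIT,
            )


def _flat_ring() -> RingSystem:
    centroid, normal = ring_plane(_hexagon())
    return RingSystem(("A", "PHE", 202), tuple(range(6)), centroid, normal)


class TestPiCheck:
    def test_axial_approach(self):
        ring = _flat_ring()
        obs = pi_xbond_check(
            np.array([0, 0, 5.2]), np.array([0, 0, 3.5]), ring, CRIT
        )
        assert obs is not None
        assert obs.distance == pytest.approx(3.5)
        assert obs.alpha == pytest.approx(0.0, abs=1e-9)
        assert obs.theta == pytest.approx(180.0)

    def test_in_plane_approach_fails_alpha(self):
        ring = _flat_ring()
        assert pi_xbond_check(
            np.array([6.7, 0, 0]), np.array([5.0, 0, 0]), ring, CRIT
        ) is None

    def test_strict_distance_boundary(self):
        ring = _flat_ring()
        assert pi_xbond_check(
            np.array([0, 0, 5.9]), np.array([0, 0, 4.2]), ring, CRIT
        ) is None

    def test_alpha_invariant_under_normal_flip(self):
        ring = _flat_ring()
        flipped = RingSystem(ring.residue_id, ring.member_indices, ring.centroid,
                             -ring.normal)
        x = np.array([0.5, 0.3, 3.2])
        c = np.array([0.7, 0.4, 5.0])
        a = pi_xbond_check(c, x, ring, CRIT)
        b = pi_xbond_check(c, x, flipped, CRIT)
        assert a is not None and b is not None
        assert a.alpha == pytest.approx(b.alpha, abs=1e-9)


class TestDetectorAgainstOracle:
    def test_planted_point_contact(self):
        atoms = [
            ("C1", "LIG", 1, "L", "C"),
            ("CL", "LIG", 1, "L", "CL"),
            ("O", "GLY", 195, "A", "O"),
        ]
        coords = np.array([[[0.0, 0, 0], [1.77, 0, 0], [4.7, 0, 0]]])
        traj = make_traj(atoms, coords)
        obs = detect_frame_xbonds(traj.frame(0), [(0, 1)])
        assert len(obs) == 1
        assert obs[0].bond_type == "point"
        assert obs[0].acceptor_residue == ("A", "GLY", 195)

    def test_simultaneous_point_and_pi(self):
        atoms = [
            ("C1", "LIG", 1, "L", "C"),
            ("CL", "LIG", 1, "L", "CL"),
            ("O", "GLY", 195, "A", "O"),
        ] + [(n, "PHE", 202, "A", "C") for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        # ring centroid on the C-Cl axis, ring in the y-z plane (normal = x axis)
        ring_pts = np.array(
            [[1.77 + 3.5, 1.39 * math.sin(2 * math.pi * k / 6),
              1.39 * math.cos(2 * math.pi * k / 6)] for k in range(6)]
        )
        coords = np.vstack([[[0.0, 0, 0], [1.77, 0, 0], [4.6, 0.02, 0]], ring_pts])
        traj = make_traj(atoms, coords[None, :, :])
        obs = detect_frame_xbonds(traj.frame(0), [(0, 1)])
        types = sorted(o.bond_type for o in obs)
        assert types == ["pi", "point"]

    def test_ligand_own_acceptors_excluded(self):
        atoms = [
            ("C1", "LIG", 1, "L", "C"),
            ("CL", "LIG", 1, "L", "CL"),
            ("N1", "LIG", 1, "L", "N"),
        ]
        coords = np.array([[[0.0, 0, 0], [1.77, 0, 0], [4.6, 0, 0]]])
        traj = make_traj(atoms, coords)
        assert detect_frame_xbonds(traj.frame(0), [(0, 1)]) == []

    def test_nonbonded_donor_pair_warns_but_runs(self):
        atoms = [("C1", "LIG", 1, "L", "C"), ("CL", "LIG", 1, "L", "CL"),
                 ("O", "GLY", 2, "A", "O")]
        coords = np.array([[[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]]])
        traj = make_traj(atoms, coords)
        with pytest.warns(UserWarning, match="covalent"):
            obs = detect_frame_xbonds(traj.frame(0), [(0, 1)])
        assert len(obs) == 1

    def test_incomplete_ring_skipped_with_warning(self):
        atoms = [("C1", "LIG", 1, "L", "C"), ("CL", "LIG", 1, "L", "CL"),
                 ("CG", "PHE", 202, "A", "C")]
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [1.77, 0, 0]
        coords[0, 2] = [4.0, 0, 0]
        traj = make_traj(atoms, coords)
        with pytest.warns(UserWarning, match="missing ring atoms"):
            assert detect_frame_xbonds(traj.frame(0), [(0, 1)]) == []

    @pytest.mark.parametrize("rep", range(20))
    def test_random_frames_equal_exhaustive_enumeration(self, rep):
        rng = np.random.default_rng(1000 + rep)
        frame, donors = random_active_site_frame(rng, n_filler=41)
        detected = observations_to_keys(detect_frame_xbonds(frame, donors))
        expected = oracle_detect(frame, donors)
        assert detected == expected


class TestRigidMotionInvariance:
    def test_detector_outputs_invariant(self, rng):
        frame, donors = random_active_site_frame(rng)
        base = detect_frame_xbonds(frame, donors)
        base_geo = sorted(
            (o.bond_type, o.distance, o.beta or 0.0, o.alpha or 0.0, o.theta or 0.0)
            for o in base
        )
        traj = make_traj(
            [(a.atom_name, a.residue_name, a.residue_number, a.chain_id, a.element)
             for a in frame.atoms],
            frame.positions[None, :, :],
        )
        for _ in range(10):
            transform = random_rigid_transform(rng)
            moved = traj.with_coords(transform(traj.coords))
            obs = detect_frame_xbonds(moved.frame(0), donors)
            geo = sorted(
                (o.bond_type, o.distance, o.beta or 0.0, o.alpha or 0.0, o.theta or 0.0)
                for o in obs
            )
            assert len(geo) == len(base_geo)
            for g, b in zip(geo, base_geo):
                assert g[0] == b[0]
                np.testing.assert_allclose(g[1:], b[1:], atol=1e-6)
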