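"""Shared test utilities: trajectory builders, rigid transforms, and an
independent brute-force halogen-bond oracle.

The oracle re-implements the geometric definitions from scratch (plain math,
eigendecomposition plane fit, exhaustive enumeration of every donor/acceptor
pair and every ring) so the detector can be checked against it on random
frames without sharing any code path.
"""

from __future__ import annotations

import math

import numpy as np

from xbond.structure_io import AtomRecord, Trajectory

# Bondi radii restated independently for the oracle.
ORACLE_VDW = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
              "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98}

ORACLE_RING_TEMPLATES = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}


def make_traj(atoms: list[tuple], coords: np.ndarray) -> Trajectory:
    """Build a trajectory from (name, resname, resid, chain, element) tuples
    and a (n_frames, n_atoms, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    records = [
        AtomRecord(
            serial=i + 1,
            atom_name=name,
            residue_name=resname,
            residue_number=resid,
            chain_id=chain,
            element=element,
            position=coords[0, i],
        )
        for i, (name, resname, resid, chain, element) in enumerate(atoms)
    ]
    return Trajectory(records, coords)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return lambda xyz: xyz @ rot.T + trans


def _oracle_angle(a, b, c) -> float:
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = float(np.dot(u, v) / (math.sqrt(np.dot(u, u)) * math.sqrt(np.dot(v, v))))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _oracle_plane(points: np.ndarray):
    """Total-least-squares plane via eigendecomposition of the covariance."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    return centroid, evecs[:, 0]  # eigenvector of smallest eigenvalue


def oracle_detect(frame, donors, *, beta_min=140.0, pi_d_max=4.2, alpha_max=60.0,
                  theta_min=146.0, acceptor_elements=("O", "N", "S"),
                  aromatic_residues=("PHE", "TYR", "HIS", "TRP"),
                  water=("HOH", "WAT", "TIP3", "SOL")) -> set[tuple]:
    """Exhaustive halogen-bond enumeration; returns a set of comparable keys
    ``("point", donor_c, halogen, acceptor_atom)`` and
    ``("pi", donor_c, halogen, residue_id, ring_members)``."""
    atoms = frame.atoms
    ligand_residues = {atoms[i].residue_id for pair in donors for i in pair}
    found: set[tuple] = set()
    for c_idx, x_idx in donors:
        cpos = atoms[c_idx].position
        xpos = atoms[x_idx].position
        x_r = ORACLE_VDW[atoms[x_idx].element.upper()]
        for y_idx, y in enumerate(atoms):
            if y.element.upper() not in acceptor_elements:
                continue
            if y.residue_id in ligand_residues or y.residue_name.upper() in water:
                continue
            d = math.dist(xpos, y.position)
            if d < x_r + ORACLE_VDW[y.element.upper()]:
                if _oracle_angle(cpos, xpos, y.position) > beta_min:
                    found.add(("point", c_idx, x_idx, y_idx))
        # rings
        by_res: dict[tuple, dict[str, int]] = {}
        for idx, a in enumerate(atoms):
            if a.residue_name.upper() in aromatic_residues:
                by_res.setdefault(a.residue_id, {})[a.atom_name.upper()] = idx
        for rid, names in by_res.items():
            if rid in ligand_residues:
                continue
            for template in ORACLE_RING_TEMPLATES[rid[1].upper()]:
                if not all(n in names for n in template):
                    continue
                members = tuple(names[n] for n in template)
                centroid, normal = _oracle_plane(
                    np.array([atoms[m].position for m in members])
                )
                v = xpos - centroid
                d = math.sqrt(float(np.dot(v, v)))
                if d >= pi_d_max:
                    continue
                alpha = math.degrees(math.acos(min(1.0, abs(float(np.dot(v / d, normal))))))
                if alpha >= alpha_max:
                    continue
                if _oracle_angle(cpos, xpos, centroid) > theta_min:
                    found.add(("pi", c_idx, x_idx, rid, members))
    return found


def observations_to_keys(observations) -> set[tuple]:
    """Map detector observations onto the oracle's comparable keys."""
    keys = set()
    for o in observations:
        if o.bond_type == "point":
            keys.add(("point", o.donor_carbon, o.halogen, o.acceptor_atom))
        else:
            keys.add(("pi", o.donor_carbon, o.halogen, o.ring.residue_id,
                      o.ring.member_indices))
    return keys


def random_active_site_frame(rng: np.random.Generator, n_filler: int = 30):
    """One random frame: a chloro-ligand, a complete PHE ring, and filler
    protein atoms, with some acceptors deliberately thrown near the C-Cl
    axis so both in- and out-of-criteria geometries occur."""
    atoms = [
        ("C1", "LIG", 1, "L", "C"),
        ("CL", "LIG", 1, "L", "CL"),
        ("O9", "LIG", 1, "L", "O"),  # ligand's own acceptor: must be ignored
    ]
    cpos = rng.uniform(-2, 2, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    xpos = cpos + 1.77 * axis
    coords = [cpos, xpos, cpos + rng.normal(0, 0.5, 3)]
    # PHE ring at a random pose near the halogen
    ring_center = xpos + rng.uniform(2.0, 6.0) * _random_unit(rng)
    e1 = _random_unit(rng)
    e2 = np.cross(e1, _random_unit(rng))
    e2 /= np.linalg.norm(e2)
    for k, name in enumerate(["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]):
        ang = 2 * math.pi * k / 6
        pos = ring_center + 1.39 * (math.cos(ang) * e1 + math.sin(ang) * e2)
        atoms.append((name, "PHE", 202, "A", "C"))
        coords.append(pos + rng.normal(0, 0.05, 3))
    # filler acceptors/others, half clustered near the sigma-hole axis
    elements = ["O", "N", "S", "C", "H"]
    for i in range(n_filler):
        el = elements[int(rng.integers(len(elements)))]
        atoms.append((f"A{i}", "GLY", 10 + i, "A", el))
        if i % 2 == 0:
            direction = axis + rng.normal(0, 0.4, 3)
            direction /= np.linalg.norm(direction)
            coords.append(xpos + rng.uniform(2.0, 5.0) * direction)
        else:
            coords.append(rng.uniform(-8, 8, size=3))
    traj = make_traj(atoms, np.array(coords)[None, :, :])
    return traj.frame(0), [(0, 1)]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
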