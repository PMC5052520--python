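"""Halogen-bond geometry: angles, ring planes, and per-frame detection.

Two geometric models of the halogen bond are implemented:

* **point acceptor** (C-X...Y): the halogen X approaches a lone-pair acceptor
  atom Y (O, N or S).  A bond requires d(X...Y) strictly below the sum of the
  van der Waals radii of X and Y, and the C-X...Y angle beta strictly above
  ``beta_min`` (140 deg by default) — the sigma-hole sits on the extension of
  the C-X axis, so near-linear approach is required.

* **pi acceptor** (C-X...pi): the halogen approaches the face of an aromatic
  ring.  With d the X...centroid distance, alpha the acute angle between the
  centroid->X vector and the ring normal, and theta the C-X...centroid angle,
  a bond requires d < 4.2 A, alpha < 60 deg and theta > 146 deg (defaults).

All comparisons are strict; geometries exactly at a cutoff are never bonds.
Angles are degrees, distances Angstrom, package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, SpecificationError
from .structure_io import AtomRecord, Frame, Trajectory, vdw_radius

__all__ = [
    "XBondCriteria",
    "RingSystem",
    "XBondObservation",
    "angle",
    "cutoff_for_pair",
    "ring_plane",
    "find_rings",
    "point_xbond_check",
    "pi_xbond_check",
    "detect_frame_xbonds",
    "detect_xbonds",
    "find_donor_pairs",
    "HALOGENS",
]

HALOGENS = frozenset({"F", "CL", "BR", "I"})

#: Ring-atom name templates per aromatic residue.  TRP contributes two rings
#: (pyrrole and benzene) because its two pi faces are distinct acceptors.
RING_TEMPLATES: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

#: Maximum C-X distance treated as a covalent bond when auto-discovering
#: donor pairs (Angstrom).
COVALENT_CX_MAX = 2.1


@dataclass(frozen=True)
class XBondCriteria:
    """Geometric thresholds for both halogen-bond types.

    ``point_cutoffs`` overrides the default per-pair distance cutoff (the sum
    of van der Waals radii) for specific (X, Y) element pairs; keys are
    upper-case symbol pairs and lookups are symmetric.
    """

    point_cutoffs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    beta_min: float = 140.0
    pi_d_max: float = 4.2
    alpha_max: float = 60.0
    theta_min: float = 146.0
    acceptor_elements: frozenset[str] = frozenset({"O", "N", "S"})
    aromatic_residues: frozenset[str] = frozenset({"PHE", "TYR", "HIS", "TRP"})
    vdw_table: Mapping[str, float] | None = None
    include_water: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha_max <= 90):
            raise SpecificationError("alpha_max must be in (0, 90]")
        for name in ("beta_min", "theta_min"):
            v = getattr(self, name)
            if not (0 < v < 180):
                raise SpecificationError(f"{name} must be in (0, 180)")
        if self.pi_d_max <= 0 or any(c <= 0 for c in self.point_cutoffs.values()):
            raise SpecificationError("distance cutoffs must be positive")
        object.__setattr__(
            self, "acceptor_elements", frozenset(e.upper() for e in self.acceptor_elements)
        )
        object.__setattr__(
            self, "aromatic_residues", frozenset(r.upper() for r in self.aromatic_residues)
        )

    def cutoff(self, x_element: str, y_element: str) -> float:
        return cutoff_for_pair(x_element, y_element, self.vdw_table, self.point_cutoffs)


@dataclass(frozen=True)
class RingSystem:
    """An aromatic ring: residue identity, member atoms, fitted plane."""

    residue_id: tuple[str, str, int]  # (chain, resname, resid)
    member_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def label(self) -> str:
        chain, resname, resid = self.residue_id
        return f"{resname}{resid}:{chain}"


@dataclass(frozen=True)
class XBondObservation:
    """One detected halogen bond in one frame.

    For ``bond_type == "point"`` the geometry fields are ``distance`` and
    ``beta``; for ``"pi"`` they are ``distance`` (to the ring centroid),
    ``alpha``, ``theta`` and additionally ``nearest_atom_distance`` (to the
    closest ring atom, reported so users can re-filter under the alternative
    distance convention).
    """

    frame_index: int
    bond_type: str  # "point" | "pi"
    donor_carbon: int
    halogen: int
    acceptor_residue: tuple[str, str, int]
    distance: float
    acceptor_atom: int | None = None
    ring: RingSystem | None = None
    beta: float | None = None
    alpha: float | None = None
    theta: float | None = None
    nearest_atom_distance: float | None = None


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex *b* of the triangle a-b-c, in degrees, in [0, 180]."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle undefined: zero-length arm at vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def cutoff_for_pair(
    x: str,
    y: str,
    table: Mapping[str, float] | None = None,
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Distance cutoff for an X...Y pair: the sum of vdW radii, in Angstrom.

    Symmetric in its element arguments.  ``overrides`` may pin specific pairs
    to user-chosen values (also looked up symmetrically).
    """
    xk, yk = x.strip().upper(), y.strip().upper()
    if overrides:
        ov = {(a.upper(), b.upper()): v for (a, b), v in overrides.items()}
        if (xk, yk) in ov:
            return ov[(xk, yk)]
        if (yk, xk) in ov:
            return ov[(yk, xk)]
    return vdw_radius(xk, table) + vdw_radius(yk, table)


def ring_plane(positions: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 points.

    Returns ``(centroid, unit_normal)``.  The normal is the singular vector of
    the centered coordinates with the smallest singular value, i.e. the
    direction minimizing the sum of squared point-plane distances.  Its sign
    is arbitrary; downstream angle definitions are sign-invariant.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("ring plane needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: second singular value ~ 0 -> plane not unique
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("ring atoms are collinear; plane undefined")
    return centroid, vt[2]


def point_xbond_check(
    c: np.ndarray,
    x_pos: np.ndarray,
    x_element: str,
    y_pos: np.ndarray,
    y_element: str,
    criteria: XBondCriteria,
    *,
    frame_index: int = 0,
    donor_carbon: int = -1,
    halogen: int = -1,
    acceptor_atom: int = -1,
    acceptor_residue: tuple[str, str, int] = ("", "", 0),
) -> XBondObservation | None:
    """Test one C-X...Y geometry; return an observation iff it is a bond.

    Both conditions are strict: d(X,Y) < cutoff and beta > beta_min.
    """
    x_pos = np.asarray(x_pos, dtype=float)
    y_pos = np.asarray(y_pos, dtype=float)
    d = float(np.linalg.norm(x_pos - y_pos))
    if d == 0.0:
        raise DegenerateGeometryError("halogen and acceptor coincide")
    if d >= criteria.cutoff(x_element, y_element):
        return None
    beta = angle(c, x_pos, y_pos)
    if beta <= criteria.beta_min:
        return None
    return XBondObservation(
        frame_index=frame_index,
        bond_type="point",
        donor_carbon=donor_carbon,
        halogen=halogen,
        acceptor_atom=acceptor_atom,
        acceptor_residue=acceptor_residue,
        distance=d,
        beta=beta,
    )


def pi_xbond_check(
    c: np.ndarray,
    x_pos: np.ndarray,
    ring: RingSystem,
    criteria: XBondCriteria,
    *,
    frame_index: int = 0,
    donor_carbon: int = -1,
    halogen: int = -1,
    ring_positions: np.ndarray | None = None,
) -> XBondObservation | None:
    """Test one C-X...pi geometry against an aromatic ring.

    d is measured to the ring centroid; alpha is the acute angle between the
    centroid->halogen vector and the ring normal (invariant under normal sign
    flips); theta is the C-X...centroid angle.  All three conditions strict.
    """
    x_pos = np.asarray(x_pos, dtype=float)
    v = x_pos - ring.centroid
    d = float(np.linalg.norm(v))
    if d == 0.0:
        raise DegenerateGeometryError("halogen coincides with ring centroid")
    if d >= criteria.pi_d_max:
        return None
    cosa = abs(float(np.dot(v / d, ring.normal)))
    alpha = float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))
    if alpha >= criteria.alpha_max:
        return None
    theta = angle(c, x_pos, ring.centroid)
    if theta <= criteria.theta_min:
        return None
    nearest = None
    if ring_positions is not None:
        nearest = float(np.min(np.linalg.norm(ring_positions - x_pos, axis=1)))
    return XBondObservation(
        frame_index=frame_index,
        bond_type="pi",
        donor_carbon=donor_carbon,
        halogen=halogen,
        ring=ring,
        acceptor_residue=ring.residue_id,
        distance=d,
        alpha=alpha,
        theta=theta,
        nearest_atom_distance=nearest,
    )


WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


def find_donor_pairs(
    frame: Frame, ligand_indices: Sequence[int]
) -> list[tuple[int, int]]:
    """Auto-discover (carbon, halogen) donor pairs within a ligand selection.

    Any halogen atom in the selection bonded to a carbon (closest carbon at
    < 2.1 A) yields one pair.
    """
    pairs: list[tuple[int, int]] = []
    lig = list(ligand_indices)
    for i in lig:
        if frame.atoms[i].element.upper() not in HALOGENS:
            continue
        best: tuple[float, int] | None = None
        for j in lig:
            if j == i or frame.atoms[j].element.upper() != "C":
                continue
            d = float(np.linalg.norm(frame.atoms[i].position - frame.atoms[j].position))
            if d < COVALENT_CX_MAX and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            pairs.append((best[1], i))
    return pairs


def find_rings(
    frame: Frame,
    aromatic_residues: frozenset[str],
    exclude_residues: frozenset[tuple[str, str, int]] = frozenset(),
) -> list[RingSystem]:
    """Enumerate aromatic rings from residue templates, fitting each plane.

    Residues whose template atoms are incomplete in this frame are skipped
    with a warning (stripped or partially resolved residues are common in MD
    snapshots).
    """
    import warnings

    by_residue: dict[tuple[str, str, int], dict[str, int]] = {}
    for idx, a in enumerate(frame.atoms):
        if a.residue_name.upper() in aromatic_residues:
            by_residue.setdefault(a.residue_id, {})[a.atom_name.upper()] = idx
    rings: list[RingSystem] = []
    for rid, name_map in by_residue.items():
        if rid in exclude_residues:
            continue
        for template in RING_TEMPLATES.get(rid[1].upper(), ()):
            if not all(n in name_map for n in template):
                warnings.warn(
                    f"residue {rid[1]}{rid[2]}:{rid[0]} missing ring atoms; skipped",
                    stacklevel=2,
                )
                continue
            members = tuple(name_map[n] for n in template)
            centroid, normal = ring_plane([frame.atoms[m].position for m in members])
            rings.append(
                RingSystem(
                    residue_id=rid,
                    member_indices=members,
                    centroid=centroid,
                    normal=normal,
                )
            )
    return rings


def detect_frame_xbonds(
    frame: Frame,
    donors: Sequence[tuple[int, int]],
    criteria: XBondCriteria | None = None,
) -> list[XBondObservation]:
    """Detect all halogen bonds in one frame.

    ``donors`` are (carbon index, halogen index) pairs.  Acceptor atoms are
    every protein O/N/S atom (backbone and side chain) outside the donors'
    own residues; pi acceptors are all template rings of aromatic residues.
    Water acceptors are excluded unless ``criteria.include_water`` is set.
    A donor pair further apart than a covalent C-X bond allows is processed
    anyway, with a warning.
    """
    import warnings

    if criteria is None:
        criteria = XBondCriteria()
    ligand_residues = frozenset(
        frame.atoms[i].residue_id for pair in donors for i in pair
    )
    rings = find_rings(frame, criteria.aromatic_residues, exclude_residues=ligand_residues)
    acceptors = [
        idx
        for idx, a in enumerate(frame.atoms)
        if a.element.upper() in criteria.acceptor_elements
        and a.residue_id not in ligand_residues
        and (criteria.include_water or a.residue_name.upper() not in WATER_RESNAMES)
    ]
    observations: list[XBondObservation] = []
    for c_idx, x_idx in donors:
        c_atom, x_atom = frame.atoms[c_idx], frame.atoms[x_idx]
        if np.linalg.norm(c_atom.position - x_atom.position) > COVALENT_CX_MAX:
            warnings.warn(
                f"donor pair ({c_idx}, {x_idx}) further apart than a covalent "
                f"C-X bond; processing anyway",
                stacklevel=2,
            )
        for y_idx in acceptors:
            y_atom = frame.atoms[y_idx]
            obs = point_xbond_check(
                c_atom.position,
                x_atom.position,
                x_atom.element,
                y_atom.position,
                y_atom.element,
                criteria,
                frame_index=frame.index,
                donor_carbon=c_idx,
                halogen=x_idx,
                acceptor_atom=y_idx,
                acceptor_residue=y_atom.residue_id,
            )
            if obs is not None:
                observations.append(obs)
        for ring in rings:
            ring_pos = np.array([frame.atoms[m].position for m in ring.member_indices])
            obs = pi_xbond_check(
                c_atom.position,
                x_atom.position,
                ring,
                criteria,
                frame_index=frame.index,
                donor_carbon=c_idx,
                halogen=x_idx,
                ring_positions=ring_pos,
            )
            if obs is not None:
                observations.append(obs)
    return observations


def detect_xbonds(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    criteria: XBondCriteria | None = None,
) -> list[XBondObservation]:
    """Run :func:`detect_frame_xbonds` over every frame of a trajectory."""
    out: list[XBondObservation] = []
    for frame in traj:
        out.extend(detect_frame_xbonds(frame, donors, criteria))
    return out
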