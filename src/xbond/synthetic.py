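"""Synthetic active-site complexes with planted halogen-bond geometries.

Real halogen-bond occupancy data comes from nanosecond MD trajectories of an
enzyme-substrate complex; those are expensive and not redistributable.  This
module builds small, fully synthetic stand-ins with *known* ground truth:

* a pseudo-ligand with chlorobenzyl-cyanide topology (benzene ring C1-C6, a
  ring chlorine CL, methylene C7, nitrile carbon C8 and nitrogen N1), so
  selections like ``name C8`` or ``element Cl`` look like the real system;
* pseudo protein residues supplying O/N/S point acceptors (backbone O of
  Gly195, side-chain N of Gln205, S of Met180), two aromatic rings (Phe202,
  Tyr173), and the catalytic atoms Cys169 SG and Lys135 HZ;
* planted contacts: for each requested halogen-bond contact, an exact
  fraction of frames is constructed *inside* all geometric criteria (at the
  requested distance/angles) and the remaining frames *outside* by a decisive
  margin (0.5 Angstrom beyond the distance cutoff), so floating-point noise
  can never flip a frame's classification;
* key distances: per frame, D_C8-SG-style atom-pair distances drawn from a
  Gaussian truncated at 0.5 Angstrom.

Default key-distance parameters (mean 3.76 / SD 0.21 and mean 2.83 / SD 0.56
over 1000 frames) mirror the wild-type complex with the meta-chloro substrate
that serves as the screening reference.  One integer seed governs all
randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import SpecificationError
from .geometry import XBondCriteria
from .structure_io import AtomRecord, Trajectory

__all__ = [
    "PlantedContact",
    "SyntheticSpec",
    "make_toy_complex",
    "make_key_distance_frames",
    "wt_vs_mutant_scenario",
]

#: Margin by which out-of-criteria frames exceed the distance cutoff (A).
OUT_MARGIN = 0.5

#: Acceptor residues available for planted point contacts, per element.
POINT_ACCEPTORS = {
    "O": ("A", "GLY", 195, "O"),
    "N": ("A", "GLN", 205, "NE2"),
    "S": ("A", "MET", 180, "SD"),
}

#: Aromatic residues available for planted pi contacts, in assignment order.
PI_ACCEPTORS = (("A", "PHE", 202), ("A", "TYR", 173))

RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
RING_RADIUS = 1.39  # benzene C-C ring circumradius, A


@dataclass(frozen=True)
class PlantedContact:
    """One halogen-bond contact to plant at a chosen occupancy.

    ``angles`` is ``(beta,)`` for a point contact and ``(alpha, theta)`` for
    a pi contact.  ``fraction`` is the target occupancy: the exact number of
    in-criteria frames is ``ceil(fraction * n_frames)``.
    """

    bond_type: str  # "point" | "pi"
    distance: float
    angles: tuple[float, ...]
    fraction: float
    acceptor_element: str = "O"  # point contacts only


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic trajectory."""

    n_frames: int = 1000
    seed: int = 0
    contacts: tuple[PlantedContact, ...] = ()
    key_distances: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"D_C8-SG": (3.76, 0.21), "D_N1-HZ": (2.83, 0.56)}
    )
    jitter_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecificationError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise SpecificationError("jitter_sigma must be >= 0")
        for c in self.contacts:
            if not (0.0 <= c.fraction <= 1.0):
                raise SpecificationError(f"contact fraction {c.fraction} not in [0, 1]")
        for label, (mu, sigma) in self.key_distances.items():
            if mu <= 0:
                raise SpecificationError(f"key distance {label!r}: mean must be > 0")
            if sigma < 0:
                raise SpecificationError(f"key distance {label!r}: SD must be >= 0")


# ---------------------------------------------------------------------------
# topology and base geometry
# ---------------------------------------------------------------------------

def _ligand_atoms() -> list[tuple[str, str, int, str, str, np.ndarray]]:
    """(chain, resname, resid, atom name, element, base position)."""
    atoms = []
    # benzene ring in the z=0 plane, centered at origin
    for k in range(6):
        ang = 2 * math.pi * k / 6
        atoms.append(
            ("L", "LIG", 1, f"C{k + 1}", "C",
             np.array([RING_RADIUS * math.cos(ang), RING_RADIUS * math.sin(ang), 0.0]))
        )
    # chlorine on C1 (at angle 0), C-Cl bond 1.77 A along +x
    atoms.append(("L", "LIG", 1, "CL", "CL", np.array([RING_RADIUS + 1.77, 0.0, 0.0])))
    # benzylic carbon on C4 (-x side), then nitrile C8 and N1
    atoms.append(("L", "LIG", 1, "C7", "C", np.array([-RING_RADIUS - 1.51, 0.0, 0.0])))
    atoms.append(("L", "LIG", 1, "C8", "C", np.array([-RING_RADIUS - 2.97, 0.0, 0.0])))
    atoms.append(("L", "LIG", 1, "N1", "N", np.array([-RING_RADIUS - 4.13, 0.0, 0.0])))
    return atoms


def _rest_direction(i: int) -> np.ndarray:
    """Fixed, well-separated unit directions for parking unplanted residues."""
    dirs = [
        (0.0, 1.0, 0.0),
        (0.0, -1.0, 0.0),
        (0.0, 0.0, 1.0),
        (0.0, 0.0, -1.0),
        (0.0, 0.7071, 0.7071),
        (0.0, -0.7071, 0.7071),
        (0.0, 0.7071, -0.7071),
        (0.0, -0.7071, -0.7071),
    ]
    v = np.array(dirs[i % len(dirs)])
    return v / np.linalg.norm(v)


def _protein_atoms() -> list[tuple[str, str, int, str, str, np.ndarray]]:
    rest = 12.0  # parking distance from the ligand, decisively outside all cutoffs
    atoms: list[tuple[str, str, int, str, str, np.ndarray]] = []
    atoms.append(("A", "LYS", 135, "HZ", "H", rest * _rest_direction(0)))
    atoms.append(("A", "CYS", 169, "SG", "S", rest * _rest_direction(1)))
    for k, name in enumerate(RING_NAMES):  # TYR 173 ring
        ang = 2 * math.pi * k / 6
        base = rest * _rest_direction(2)
        atoms.append(
            ("A", "TYR", 173, name, "C",
             base + np.array([RING_RADIUS * math.cos(ang), RING_RADIUS * math.sin(ang), 0.0]))
        )
    atoms.append(("A", "MET", 180, "SD", "S", rest * _rest_direction(3)))
    atoms.append(("A", "GLY", 195, "O", "O", rest * _rest_direction(4)))
    for k, name in enumerate(RING_NAMES):  # PHE 202 ring
        ang = 2 * math.pi * k / 6
        base = rest * _rest_direction(5)
        atoms.append(
            ("A", "PHE", 202, name, "C",
             base + np.array([RING_RADIUS * math.cos(ang), RING_RADIUS * math.sin(ang), 0.0]))
        )
    atoms.append(("A", "GLN", 205, "NE2", "N", rest * _rest_direction(6)))
    return atoms


def _build_topology() -> tuple[list[AtomRecord], np.ndarray, dict[str, int]]:
    records: list[AtomRecord] = []
    base: list[np.ndarray] = []
    index_of: dict[str, int] = {}
    serial = 1
    for chain, resname, resid, name, element, pos in _protein_atoms() + _ligand_atoms():
        records.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                residue_name=resname,
                residue_number=resid,
                chain_id=chain,
                element=element,
                position=pos,
            )
        )
        index_of[f"{resname}{resid}:{name}"] = serial - 1
        base.append(pos)
        serial += 1
    return records, np.array(base), index_of


def _perp(axis: np.ndarray, hint: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to *axis*, as close to *hint* as possible."""
    v = hint - np.dot(hint, axis) * axis
    n = np.linalg.norm(v)
    if n < 1e-9:
        alt = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = alt - np.dot(alt, axis) * axis
        n = np.linalg.norm(v)
    return v / n


def _validate_contact(c: PlantedContact, criteria: XBondCriteria) -> None:
    if c.bond_type == "point":
        elem = c.acceptor_element.upper()
        if elem not in POINT_ACCEPTORS:
            raise SpecificationError(
                f"no point-acceptor residue for element {c.acceptor_element!r}"
            )
        if len(c.angles) != 1:
            raise SpecificationError("point contact needs exactly one angle (beta)")
        cutoff = criteria.cutoff("CL", elem)
        (beta,) = c.angles
        if c.fraction > 0 and not (c.distance < cutoff and beta > criteria.beta_min):
            raise SpecificationError(
                f"infeasible point contact: d={c.distance}, beta={beta} do not "
                f"satisfy d < {cutoff:.2f} and beta > {criteria.beta_min}"
            )
    elif c.bond_type == "pi":
        if len(c.angles) != 2:
            raise SpecificationError("pi contact needs exactly two angles (alpha, theta)")
        alpha, theta = c.angles
        if c.fraction > 0 and not (
            c.distance < criteria.pi_d_max
            and alpha < criteria.alpha_max
            and theta > criteria.theta_min
        ):
            raise SpecificationError(
                f"infeasible pi contact: d={c.distance}, alpha={alpha}, "
                f"theta={theta} violate the pi criteria"
            )
    else:
        raise SpecificationError(f"unknown bond_type {c.bond_type!r}")


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, n: int, lower: float = 0.5
) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, mu)
    a = (lower - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def make_toy_complex(spec: SyntheticSpec) -> Trajectory:
    """Build the synthetic active-site trajectory described by *spec*.

    Deterministic given ``spec.seed``.  For each planted contact exactly
    ``ceil(fraction * n_frames)`` frames satisfy every criterion of its bond
    type (at the requested distance and angles, measured after jitter), and
    every remaining frame violates the distance criterion by at least
    0.5 Angstrom.  Key-distance atom pairs are planted per frame from the
    requested truncated Gaussians.
    """
    criteria = XBondCriteria()
    for c in spec.contacts:
        _validate_contact(c, criteria)
    point_elems = [c.acceptor_element.upper() for c in spec.contacts if c.bond_type == "point"]
    if len(point_elems) != len(set(point_elems)):
        raise SpecificationError("at most one planted point contact per acceptor element")
    n_pi = sum(1 for c in spec.contacts if c.bond_type == "pi")
    if n_pi > len(PI_ACCEPTORS):
        raise SpecificationError(f"at most {len(PI_ACCEPTORS)} planted pi contacts")

    records, base, index_of = _build_topology()
    n_atoms = len(records)
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)

    # which frames are in-criteria, per contact (exact count, seeded choice)
    in_frames: list[np.ndarray] = []
    for c in spec.contacts:
        k = math.ceil(c.fraction * n)
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:k]] = True
        in_frames.append(mask)

    # key-distance draws
    kd_values: dict[str, np.ndarray] = {}
    for label, (mu, sigma) in spec.key_distances.items():
        kd_values[label] = _truncated_normal(rng, mu, sigma, n)

    # per-frame jitter for the whole scaffold (planted atoms get overwritten)
    coords = np.empty((n, n_atoms, 3))
    jitter = rng.normal(0.0, spec.jitter_sigma, size=(n, n_atoms, 3))
    coords[:] = base[None, :, :] + jitter

    i_c1 = index_of["LIG1:C1"]
    i_cl = index_of["LIG1:CL"]
    # contact directions: spread perpendicular hints around the C-Cl axis
    hints = [
        np.array([0.0, math.cos(2 * math.pi * j / 8), math.sin(2 * math.pi * j / 8)])
        for j in range(8)
    ]

    pi_slot = 0
    for ci, c in enumerate(spec.contacts):
        mask = in_frames[ci]
        hint = hints[ci % len(hints)]
        if c.bond_type == "point":
            chain, resname, resid, aname = POINT_ACCEPTORS[c.acceptor_element.upper()]
            yi = index_of[f"{resname}{resid}:{aname}"]
            cutoff = criteria.cutoff("CL", c.acceptor_element)
            (beta,) = c.angles
            for fi in range(n):
                cpos = coords[fi, i_c1]
                xpos = coords[fi, i_cl]
                a_hat = xpos - cpos
                a_hat /= np.linalg.norm(a_hat)
                p = _perp(a_hat, hint)
                b = math.radians(beta)
                u = math.cos(b) * (-a_hat) + math.sin(b) * p
                d = c.distance if mask[fi] else cutoff + OUT_MARGIN
                coords[fi, yi] = xpos + d * u
        else:  # pi
            chain, resname, resid = PI_ACCEPTORS[pi_slot]
            pi_slot += 1
            ring_idx = [index_of[f"{resname}{resid}:{name}"] for name in RING_NAMES]
            alpha, theta = c.angles
            for fi in range(n):
                cpos = coords[fi, i_c1]
                xpos = coords[fi, i_cl]
                a_hat = xpos - cpos
                a_hat /= np.linalg.norm(a_hat)
                p = _perp(a_hat, hint)
                t = math.radians(theta)
                u = math.cos(t) * (-a_hat) + math.sin(t) * p
                d = c.distance if mask[fi] else criteria.pi_d_max + OUT_MARGIN
                centroid = xpos + d * u
                q = _perp(u, np.cross(u, p))
                al = math.radians(alpha)
                normal = math.cos(al) * (-u) + math.sin(al) * q
                normal /= np.linalg.norm(normal)
                e1 = _perp(normal, p)
                e2 = np.cross(normal, e1)
                for k, ri in enumerate(ring_idx):
                    ang = 2 * math.pi * k / 6
                    coords[fi, ri] = (
                        centroid
                        + RING_RADIUS * math.cos(ang) * e1
                        + RING_RADIUS * math.sin(ang) * e2
                    )

    # key-distance atoms: partner placed at the drawn distance from its
    # ligand anchor, in a fixed direction pointing away from the chlorine
    kd_anchor = {"SG": "LIG1:C8", "HZ": "LIG1:N1"}
    kd_partner = {"SG": "CYS169:SG", "HZ": "LYS135:HZ"}
    kd_dirs = {
        "SG": np.array([-0.8, 0.55, 0.25]),
        "HZ": np.array([-0.8, -0.45, 0.4]),
    }
    for label, values in kd_values.items():
        try:
            _, names = label.split("_", 1)
            a_name, b_name = names.split("-")
        except ValueError:
            raise SpecificationError(
                f"key-distance label {label!r} must look like 'D_<A>-<B>'"
            ) from None
        if b_name not in kd_partner:
            raise SpecificationError(
                f"key-distance label {label!r}: unknown partner atom {b_name!r}; "
                f"supported: {sorted(kd_partner)}"
            )
        ai = index_of[kd_anchor[b_name]]
        bi = index_of[kd_partner[b_name]]
        w = kd_dirs[b_name] / np.linalg.norm(kd_dirs[b_name])
        coords[:, bi, :] = coords[:, ai, :] + values[:, None] * w

    return Trajectory(records, coords)


def make_key_distance_frames(
    label_targets: Mapping[str, tuple[float, float]],
    n_frames: int = 1000,
    seed: int = 0,
) -> Trajectory:
    """Trajectory whose labeled atom-pair distances follow the requested
    truncated Gaussians (lower bound 0.5 Angstrom), with no planted X-bond
    contacts."""
    spec = SyntheticSpec(
        n_frames=n_frames, seed=seed, contacts=(), key_distances=dict(label_targets)
    )
    return make_toy_complex(spec)


def wt_vs_mutant_scenario(
    seed: int, n_frames: int = 200
) -> tuple[Trajectory, Trajectory, str, dict]:
    """A WT/candidate trajectory pair with a planted screening verdict.

    Reference ("WT") key-distance means are drawn uniformly; the candidate
    ("mutant") means sit at least 0.5 Angstrom strictly below or above each
    reference mean, so with per-frame SD 0.2 over ``n_frames`` frames the
    sample means decide the screen the same way the planted means do.

    Returns ``(wt_traj, mutant_traj, expected_verdict, planted)`` where
    ``expected_verdict`` is ``"pass"`` or ``"fail"`` and ``planted`` records
    the drawn means.
    """
    rng = np.random.default_rng(seed)
    labels = ("D_C8-SG", "D_N1-HZ")
    ref_means = {
        "D_C8-SG": float(rng.uniform(3.5, 8.0)),
        "D_N1-HZ": float(rng.uniform(3.0, 9.0)),
    }
    case = rng.choice(["pass", "fail_first", "fail_second", "fail_both"])
    cand_means = {}
    for i, label in enumerate(labels):
        shift = float(rng.uniform(0.5, 2.0))
        shorter = (
            case == "pass"
            or (case == "fail_first" and i == 1)
            or (case == "fail_second" and i == 0)
        )
        mu = ref_means[label] - shift if shorter else ref_means[label] + shift
        cand_means[label] = max(mu, 1.0)
    sigma = 0.2
    wt = make_key_distance_frames(
        {lb: (ref_means[lb], sigma) for lb in labels}, n_frames, seed=int(rng.integers(2**31))
    )
    mut = make_key_distance_frames(
        {lb: (cand_means[lb], sigma) for lb in labels}, n_frames, seed=int(rng.integers(2**31))
    )
    expected = "pass" if all(cand_means[lb] < ref_means[lb] for lb in labels) else "fail"
    planted = {"reference_means": ref_means, "candidate_means": cand_means, "case": str(case)}
    return wt, mut, expected, planted
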