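"""Sigma-hole extra-point (EP) placement for halogenated ligands.

Standard fixed-charge force fields put a single isotropic point charge on a
halogen and therefore miss the sigma-hole — the band of positive
electrostatic potential on the halogen along the extension of the C-X bond.
The positive-extra-point (PEP) correction represents the sigma-hole as a
massless pseudo-atom carrying positive charge, placed on the C-X axis beyond
the halogen at a fixed offset (1.90 Angstrom by default).

This module places EPs geometrically and keeps the charge bookkeeping
consistent: whatever charge the EP carries is subtracted from its parent
halogen so the molecular total is conserved.  EP charge magnitudes are a
parameterization choice (typically from a RESP fit); no default is shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConnectivityError, DegenerateGeometryError
from .geometry import COVALENT_CX_MAX, HALOGENS, find_donor_pairs
from .structure_io import AtomRecord, Trajectory

__all__ = ["DEFAULT_EP_OFFSET", "EPPlacement", "place_ep", "apply_ep", "strip_ep"]

#: Halogen-to-extra-point distance in Angstrom.
DEFAULT_EP_OFFSET = 1.90

EP_NAME_PREFIX = "EP"


@dataclass(frozen=True)
class EPPlacement:
    """Geometry and charge bookkeeping of one placed extra point."""

    halogen_index: int
    carbon_index: int
    offset: float
    ep_position: np.ndarray
    ep_charge: float
    halogen_charge_adjustment: float


def place_ep(c: np.ndarray, x: np.ndarray, offset: float = DEFAULT_EP_OFFSET) -> np.ndarray:
    """Extra-point position: on the ray from carbon through halogen, ``offset``
    Angstrom beyond the halogen.

    ep = x + offset * (x - c) / |x - c|, so C, X and EP are collinear and
    |EP - X| = offset exactly.
    """
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    axis = x - c
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise DegenerateGeometryError("carbon and halogen coincide; C-X axis undefined")
    return x + offset * axis / norm


def apply_ep(
    traj: Trajectory,
    ligand_indices: Sequence[int],
    ep_charge: float,
    offset: float = DEFAULT_EP_OFFSET,
    charges: Mapping[int, float] | None = None,
) -> tuple[Trajectory, dict[int, float], list[EPPlacement]]:
    """Append one EP pseudo-atom per ligand halogen, per frame.

    Every halogen in the ligand selection must have a covalently bonded
    carbon (closest carbon within 2.1 A); otherwise a connectivity error is
    raised.  EP atoms are named EP1, EP2, ... and carry the ligand's residue
    identity.  If per-atom ``charges`` (index -> charge) are supplied, the
    returned charge table has each parent halogen reduced by ``ep_charge``
    and the EP carrying ``ep_charge``, so the molecular total is unchanged.

    Returns ``(new_trajectory, new_charges, placements)``; placements record
    frame-0 geometry.
    """
    frame0 = traj.frame(0)
    halogen_idx = [
        i for i in ligand_indices if frame0.atoms[i].element.upper() in HALOGENS
    ]
    pairs = find_donor_pairs(frame0, ligand_indices)
    carbon_of = {x: c for c, x in pairs}
    for i in halogen_idx:
        if i not in carbon_of:
            a = frame0.atoms[i]
            raise ConnectivityError(
                f"halogen {a.atom_name} (index {i}) has no carbon within "
                f"{COVALENT_CX_MAX} A; cannot place an extra point"
            )

    n_atoms = traj.n_atoms
    max_serial = max(a.serial for a in traj.topology)
    new_meta: list[AtomRecord] = list(traj.topology)
    ep_coords = np.zeros((traj.n_frames, len(halogen_idx), 3))
    placements: list[EPPlacement] = []
    for k, x_idx in enumerate(halogen_idx):
        c_idx = carbon_of[x_idx]
        parent = traj.topology[x_idx]
        new_meta.append(
            AtomRecord(
                serial=max_serial + 1 + k,
                atom_name=f"{EP_NAME_PREFIX}{k + 1}",
                residue_name=parent.residue_name,
                residue_number=parent.residue_number,
                chain_id=parent.chain_id,
                element="",  # massless pseudo-atom, no element
                position=np.zeros(3),
            )
        )
        for fi in range(traj.n_frames):
            ep_coords[fi, k] = place_ep(
                traj.coords[fi, c_idx], traj.coords[fi, x_idx], offset
            )
        placements.append(
            EPPlacement(
                halogen_index=x_idx,
                carbon_index=c_idx,
                offset=offset,
                ep_position=ep_coords[0, k].copy(),
                ep_charge=ep_charge,
                halogen_charge_adjustment=-ep_charge,
            )
        )

    new_coords = np.concatenate([traj.coords, ep_coords], axis=1)
    new_traj = Trajectory(new_meta, new_coords)

    new_charges: dict[int, float] = dict(charges) if charges else {}
    if charges is not None:
        for k, x_idx in enumerate(halogen_idx):
            new_charges[x_idx] = new_charges.get(x_idx, 0.0) - ep_charge
            new_charges[n_atoms + k] = ep_charge
    return new_traj, new_charges, placements


def strip_ep(
    traj: Trajectory, charges: Mapping[int, float] | None = None
) -> tuple[Trajectory, dict[int, float]]:
    """Remove EP pseudo-atoms, restoring parent-halogen charges.

    Inverse of :func:`apply_ep` up to floating point: atom count, order and
    per-atom charges of the original structure are recovered.
    """
    keep = [
        i
        for i, a in enumerate(traj.topology)
        if not (a.atom_name.startswith(EP_NAME_PREFIX) and a.element == "")
    ]
    dropped = [i for i in range(traj.n_atoms) if i not in set(keep)]
    new_traj = Trajectory(
        [traj.topology[i] for i in keep], traj.coords[:, keep, :]
    )
    new_charges: dict[int, float] = {}
    if charges is not None:
        # EP charge flows back to the nearest halogen (its parent lies at the
        # fixed offset, so nearest-halogen recovery is exact for EP geometry)
        charge_arr = {i: charges.get(i, 0.0) for i in range(traj.n_atoms)}
        frame0 = traj.frame(0)
        for d in dropped:
            halogens = [
                i for i in keep if frame0.atoms[i].element.upper() in HALOGENS
            ]
            if halogens:
                nearest = min(
                    halogens,
                    key=lambda i: np.linalg.norm(
                        frame0.atoms[i].position - frame0.atoms[d].position
                    ),
                )
                charge_arr[nearest] += charge_arr[d]
            charge_arr.pop(d)
        new_charges = {new_i: charge_arr[old_i] for new_i, old_i in enumerate(keep)}
    return new_traj, new_charges
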