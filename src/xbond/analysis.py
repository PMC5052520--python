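"""Trajectory-level aggregation: key distances, summaries, occupancies.

The two catalytic key distances of the nitrilase system motivate the distance
machinery: D_C8-SG, from the substrate's nitrile carbon C8 to the catalytic
cysteine's SG sulfur (gatekeeper of nucleophilic attack), and D_N1-HZ, from
the nitrile nitrogen N1 to the catalytic lysine's HZ hydrogen (proxy for
transition-state stabilization).  Both are reported as mean +/- sample
standard deviation over all frames, matching how MD key distances are usually
tabulated.

Halogen-bond occupancy is reported per acceptor residue: the fraction of
frames in which at least one X-bond (of either type, pooled by default) to
that residue is present.  Multiple simultaneous bonds to one residue in one
frame count once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .geometry import XBondCriteria, XBondObservation, detect_frame_xbonds
from .structure_io import Selection, Trajectory, select_atoms

__all__ = [
    "DistanceSpec",
    "DistanceSeries",
    "DistanceSummary",
    "OccupancyProfile",
    "distance_series",
    "summarize",
    "occupancy_profile",
    "analysis_report",
    "observations_to_frame",
]

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DistanceSpec:
    """A labeled atom-pair distance, each side a single-atom selection."""

    label: str
    selection_a: str
    selection_b: str


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame values of one labeled distance, in frame order (Angstrom)."""

    spec: DistanceSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class DistanceSummary:
    """Mean +/- SD of a labeled distance over n_frames frames."""

    label: str
    mean: float
    sd: float
    n_frames: int


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-residue halogen-bond occupancy over a trajectory.

    ``fractions`` maps residue id (chain, resname, resid) to the fraction of
    frames with at least one X-bond to that residue; ``by_type`` breaks the
    same quantity out per bond type.  ``dominant`` is the residue with maximal
    pooled fraction (ties broken by residue id), or None when no bond was
    ever observed.
    """

    fractions: dict[tuple[str, str, int], float]
    by_type: dict[tuple[str, str, int], dict[str, float]]
    n_frames: int

    @property
    def dominant(self) -> tuple[str, str, int] | None:
        if not self.fractions:
            return None
        return max(self.fractions, key=lambda r: (self.fractions[r], tuple(map(str, r))))


def _resolve_single(traj: Trajectory, expression: str, label: str) -> int:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel: Selection = select_atoms(traj, expression)
    if len(sel) != 1:
        raise SpecificationError(
            f"distance {label!r}: selection {expression!r} resolved to "
            f"{len(sel)} atoms; exactly 1 required"
        )
    return sel.indices[0]


def distance_series(traj: Trajectory, spec: DistanceSpec) -> DistanceSeries:
    """Per-frame Euclidean distance between the two selected atoms."""
    ia = _resolve_single(traj, spec.selection_a, spec.label)
    ib = _resolve_single(traj, spec.selection_b, spec.label)
    values = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return DistanceSeries(spec=spec, values=values)


def summarize(series: DistanceSeries, ddof: int = 1) -> DistanceSummary:
    """Mean and sample standard deviation (n-1 denominator by default).

    A single-frame series has no spread estimate; its SD is reported as 0
    with a warning.
    """
    values = series.values
    n = len(values)
    if n == 0:
        raise SpecificationError(f"distance {series.spec.label!r}: empty series")
    if n == 1:
        warnings.warn(
            f"distance {series.spec.label!r}: single frame, SD reported as 0",
            stacklevel=2,
        )
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=ddof))
    return DistanceSummary(
        label=series.spec.label, mean=float(np.mean(values)), sd=sd, n_frames=n
    )


def occupancy_profile(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    criteria: XBondCriteria | None = None,
    observations: Sequence[XBondObservation] | None = None,
) -> OccupancyProfile:
    """Fraction of frames with >= 1 X-bond per acceptor residue.

    Detection runs per frame unless precomputed ``observations`` are given.
    Point and pi bonds are pooled in ``fractions`` and broken out in
    ``by_type``.
    """
    n = traj.n_frames
    if n == 0:
        raise SpecificationError("empty trajectory")
    if observations is None:
        observations = [
            obs for frame in traj for obs in detect_frame_xbonds(frame, donors, criteria)
        ]
    pooled_frames: dict[tuple[str, str, int], set[int]] = {}
    typed_frames: dict[tuple[str, str, int], dict[str, set[int]]] = {}
    for obs in observations:
        rid = obs.acceptor_residue
        pooled_frames.setdefault(rid, set()).add(obs.frame_index)
        typed_frames.setdefault(rid, {}).setdefault(obs.bond_type, set()).add(
            obs.frame_index
        )
    fractions = {rid: len(fr) / n for rid, fr in pooled_frames.items()}
    by_type = {
        rid: {t: len(fr) / n for t, fr in types.items()}
        for rid, types in typed_frames.items()
    }
    return OccupancyProfile(fractions=fractions, by_type=by_type, n_frames=n)


def observations_to_frame(observations: Sequence[XBondObservation]) -> pd.DataFrame:
    """Observations as a tidy table (one row per detected bond)."""
    rows = []
    for o in observations:
        chain, resname, resid = o.acceptor_residue
        rows.append(
            {
                "frame": o.frame_index,
                "type": o.bond_type,
                "donor_carbon": o.donor_carbon,
                "halogen": o.halogen,
                "acceptor_residue": f"{resname}{resid}:{chain}",
                "acceptor_atom": o.acceptor_atom if o.acceptor_atom is not None else -1,
                "distance": o.distance,
                "beta": o.beta if o.beta is not None else np.nan,
                "alpha": o.alpha if o.alpha is not None else np.nan,
                "theta": o.theta if o.theta is not None else np.nan,
                "nearest_atom_distance": (
                    o.nearest_atom_distance
                    if o.nearest_atom_distance is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "type",
            "donor_carbon",
            "halogen",
            "acceptor_residue",
            "acceptor_atom",
            "distance",
            "beta",
            "alpha",
            "theta",
            "nearest_atom_distance",
        ],
    )


def analysis_report(
    traj: Trajectory,
    distance_specs: Sequence[DistanceSpec],
    donors: Sequence[tuple[int, int]],
    criteria: XBondCriteria | None = None,
    label: str = "complex",
) -> dict:
    """Full per-complex analysis: distance summaries, occupancy, counts.

    The returned dict is JSON-serializable with stable key order, so repeated
    runs on identical input produce byte-identical serializations.
    """
    observations = [
        obs for frame in traj for obs in detect_frame_xbonds(frame, donors, criteria)
    ]
    profile = occupancy_profile(traj, donors, criteria, observations=observations)
    per_frame_counts = [0] * traj.n_frames
    for obs in observations:
        per_frame_counts[obs.frame_index] += 1

    summaries = []
    for spec in distance_specs:
        s = summarize(distance_series(traj, spec))
        summaries.append(
            {
                "label": s.label,
                "mean": round(s.mean, 6),
                "sd": round(s.sd, 6),
                "n_frames": s.n_frames,
            }
        )

    def rid_key(rid: tuple[str, str, int]) -> str:
        return f"{rid[1]}{rid[2]}:{rid[0]}"

    dominant = profile.dominant
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "label": label,
        "n_frames": traj.n_frames,
        "distances": summaries,
        "occupancy": {
            rid_key(rid): round(profile.fractions[rid], 6)
            for rid in sorted(profile.fractions, key=rid_key)
        },
        "occupancy_by_type": {
            rid_key(rid): {
                t: round(f, 6) for t, f in sorted(profile.by_type[rid].items())
            }
            for rid in sorted(profile.by_type, key=rid_key)
        },
        "dominant_acceptor": rid_key(dominant) if dominant else None,
        "per_frame_bond_counts": per_frame_counts,
    }
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (insertion order preserved)."""
    return json.dumps(report, indent=2)


def distances_to_csv(traj: Trajectory, specs: Sequence[DistanceSpec]) -> pd.DataFrame:
    """Long-format table (frame, label, value) for all distance specs."""
    frames = []
    for spec in specs:
        series = distance_series(traj, spec)
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(len(series.values)),
                    "label": spec.label,
                    "value": series.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def occupancy_to_csv(profile: OccupancyProfile) -> pd.DataFrame:
    """Table (residue, type, fraction); type 'any' is the pooled fraction."""
    rows = []
    for rid in sorted(profile.fractions, key=lambda r: f"{r[1]}{r[2]}:{r[0]}"):
        label = f"{rid[1]}{rid[2]}:{rid[0]}"
        rows.append({"residue": label, "type": "any", "fraction": profile.fractions[rid]})
        for t, f in sorted(profile.by_type.get(rid, {}).items()):
            rows.append({"residue": label, "type": t, "fraction": f})
    return pd.DataFrame(rows, columns=["residue", "type", "fraction"])
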