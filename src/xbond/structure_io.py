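"""Structures, trajectories and atom selections.

PDB files (single- or multi-MODEL, fixed-width wwPDB v3.3) are the carrier
format for both static structures and trajectory snapshots: one MODEL block is
one frame.  Parsing and serialization are delegated to :mod:`gemmi`; this
module wraps the result in a flat, frame-indexed :class:`Trajectory` container
that the geometry and analysis layers operate on.

Element symbols follow PDB conventions (columns 77-78 when present, otherwise
inferred from the atom name with residue context, e.g. ``CA`` in a protein
residue is carbon).  Van der Waals radii default to the Bondi set.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    PDBParseError,
    SelectionSyntaxError,
    TopologyError,
    UnknownElementError,
)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "BONDI_RADII",
    "vdw_radius",
    "Selection",
    "select_atoms",
    "read_pdb",
    "write_pdb",
]

#: Bondi (1964) van der Waals radii in Angstrom.  This is the default table;
#: pairwise sums of these values give the distance cutoffs used by the
#: halogen-bond detector (Cl+O = 3.27, Cl+N = 3.30, Cl+S = 3.55).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}


def vdw_radius(element: str, table: Mapping[str, float] | None = None) -> float:
    """Van der Waals radius of *element* in Angstrom.

    Parameters
    ----------
    element
        Chemical element symbol, case-insensitive (``"Cl"``, ``"O"`` ...).
    table
        Optional override mapping symbol -> radius.  Defaults to the Bondi set.

    Raises
    ------
    UnknownElementError
        If the symbol is not in the table.
    """
    tab = BONDI_RADII if table is None else {k.upper(): v for k, v in table.items()}
    key = element.strip().upper()
    if key not in tab:
        raise UnknownElementError(
            f"no van der Waals radius for element {element!r}; "
            f"known elements: {sorted(tab)}"
        )
    return tab[key]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: static PDB identity plus a position in Angstrom.

    ``element`` is the upper-case symbol, or ``""`` when it could not be
    determined (explicitly unknown rather than guessed).
    """

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def residue_id(self) -> tuple[str, str, int]:
        """(chain, residue name, residue number) — the residue this atom belongs to."""
        return (self.chain_id, self.residue_name, self.residue_number)


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot: an index and an ordered list of atoms."""

    index: int
    atoms: tuple[AtomRecord, ...]

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


class Trajectory:
    """Ordered frames over a shared topology.

    Internally the per-atom static metadata (the topology) is stored once and
    coordinates live in a ``(n_frames, n_atoms, 3)`` float array, so per-frame
    :class:`AtomRecord` lists are materialized on demand.
    """

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise TopologyError("a trajectory needs at least one frame")
        if coords.shape[1] != len(topology):
            raise TopologyError(
                f"coords have {coords.shape[1]} atoms but topology has {len(topology)}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.topology: tuple[AtomRecord, ...] = tuple(topology)
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        atoms = tuple(
            replace(a, position=self.coords[i, j])
            for j, a in enumerate(self.topology)
        )
        return Frame(index=i, atoms=atoms)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        """Same topology, new coordinate array."""
        return Trajectory(self.topology, coords)


# ---------------------------------------------------------------------------
# PDB reading / writing (via gemmi)
# ---------------------------------------------------------------------------

_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def _validate_pdb_text(path: Path) -> None:
    # gemmi is forgiving about garbage inside coordinate fields; enforce the
    # fixed-width contract up front so errors carry a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}, line {lineno}: ATOM/HETATM record shorter than 54 columns"
                )
            for sl in _COORD_SLICES:
                fieldtxt = line[sl].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: unparsable coordinate field "
                        f"{fieldtxt!r} (columns {sl.start + 1}-{sl.stop})"
                    ) from None


def _flatten_model(model: gemmi.Model) -> tuple[list[AtomRecord], np.ndarray]:
    atoms: list[AtomRecord] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # single-conformer policy: altloc A or blank only
                elem = atom.element.name.upper() if not atom.element.is_metal else atom.element.name.upper()
                if elem in ("X", ""):
                    elem = ""
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        atom_name=atom.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        element=elem,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    return atoms, np.array(xyz, dtype=float).reshape(len(atoms), 3)


def _identity(a: AtomRecord) -> tuple:
    return (a.atom_name, a.residue_name, a.residue_number, a.chain_id)


def read_pdb(path: str | os.PathLike) -> Trajectory:
    """Read a PDB file (or a directory of PDB files) into a :class:`Trajectory`.

    Multi-MODEL files yield one frame per MODEL block; a plain single-model
    file yields a one-frame trajectory.  A directory is treated as a
    trajectory split across sequentially named ``*.pdb`` files (sorted by
    name), concatenated in order.

    Raises
    ------
    PDBParseError
        Malformed fixed-width ATOM/HETATM record (message names the line).
    TopologyError
        MODEL blocks disagree on atom count or atom identity.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.pdb"))
        if not files:
            raise FileNotFoundError(f"no *.pdb files in directory {p}")
        parts = [read_pdb(f) for f in files]
        ref = parts[0]
        for part, f in zip(parts[1:], files[1:]):
            if tuple(map(_identity, part.topology)) != tuple(map(_identity, ref.topology)):
                raise TopologyError(f"{f}: topology differs from {files[0]}")
        return Trajectory(ref.topology, np.concatenate([t.coords for t in parts]))

    if not p.is_file():
        raise FileNotFoundError(str(p))
    _validate_pdb_text(p)
    try:
        st = gemmi.read_pdb(str(p))
    except (RuntimeError, ValueError) as exc:  # gemmi reports its own line numbers
        raise PDBParseError(f"{p}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{p}: no MODEL/ATOM records found")

    first_atoms, first_xyz = _flatten_model(st[0])
    if not first_atoms:
        raise PDBParseError(f"{p}: no ATOM/HETATM records found")
    frames_xyz = [first_xyz]
    ref_ids = [_identity(a) for a in first_atoms]
    for mi in range(1, len(st)):
        atoms, xyz = _flatten_model(st[mi])
        if len(atoms) != len(first_atoms):
            raise TopologyError(
                f"{p}: MODEL {mi + 1} has {len(atoms)} atoms "
                f"but MODEL 1 has {len(first_atoms)}"
            )
        if [_identity(a) for a in atoms] != ref_ids:
            raise TopologyError(f"{p}: MODEL {mi + 1} atom identities differ from MODEL 1")
        frames_xyz.append(xyz)
    return Trajectory(first_atoms, np.stack(frames_xyz))


def write_pdb(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a (multi-)MODEL PDB file.

    Coordinates are serialized at PDB precision (3 decimals); a read/write
    round trip therefore preserves them to 1e-3 Angstrom.
    """
    st = gemmi.Structure()
    st.name = "xbond"
    for fi in range(traj.n_frames):
        model = gemmi.Model(fi + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_key = None
        cur_res = None
        for j, meta in enumerate(traj.topology):
            ch = chain_map.get(meta.chain_id)
            if ch is None:
                ch = gemmi.Chain(meta.chain_id or "A")
                chain_map[meta.chain_id] = ch
                model.add_chain(ch)
                ch = model[len(model) - 1]
                chain_map[meta.chain_id] = ch
                res_key = None
            key = (meta.chain_id, meta.residue_name, meta.residue_number)
            if key != res_key:
                res = gemmi.Residue()
                res.name = meta.residue_name
                res.seqid = gemmi.SeqId(meta.residue_number, " ")
                res.het_flag = "A"
                ch.add_residue(res)
                cur_res = ch[len(ch) - 1]
                res_key = key
            atom = gemmi.Atom()
            atom.name = meta.atom_name
            atom.serial = meta.serial
            atom.element = gemmi.Element(meta.element if meta.element else "X")
            x, y, z = traj.coords[fi, j]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            cur_res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Atom selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = ("resid", "resname", "name", "chain", "element")


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the source expression and matching indices."""

    expression: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for `clause (and|or clause)*` with parentheses."""

    def __init__(self, expr: str, topology: Sequence[AtomRecord]):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.topology = topology

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError(
                f"unexpected end of expression {self.expr!r} at position {len(self.expr)}"
            )
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self._or_expr()
        tok = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(
                f"unexpected token {tok[0]!r} at position {tok[1]} in {self.expr!r}"
            )
        return result

    def _or_expr(self) -> set[int]:
        acc = self._and_expr()
        while (tok := self._peek()) is not None and tok[0].lower() == "or":
            self._next()
            acc |= self._and_expr()
        return acc

    def _and_expr(self) -> set[int]:
        acc = self._factor()
        while (tok := self._peek()) is not None and tok[0].lower() == "and":
            self._next()
            acc &= self._factor()
        return acc

    def _factor(self) -> set[int]:
        tok = self._next()
        word, at = tok
        if word == "(":
            inner = self._or_expr()
            close = self._next()
            if close[0] != ")":
                raise SelectionSyntaxError(
                    f"expected ')' at position {close[1]} in {self.expr!r}"
                )
            return inner
        if word == ")":
            raise SelectionSyntaxError(f"unmatched ')' at position {at} in {self.expr!r}")
        if word.lower() not in _KEYWORDS:
            raise SelectionSyntaxError(
                f"unknown clause keyword {word!r} at position {at} in {self.expr!r}; "
                f"expected one of {_KEYWORDS}"
            )
        value_tok = self._next()
        value, vat = value_tok
        if value in ("(", ")") or value.lower() in ("and", "or"):
            raise SelectionSyntaxError(
                f"clause {word!r} missing value at position {vat} in {self.expr!r}"
            )
        return self._match(word.lower(), value, vat)

    def _match(self, key: str, value: str, at: int) -> set[int]:
        if key == "resid":
            try:
                num = int(value)
            except ValueError:
                raise SelectionSyntaxError(
                    f"resid expects an integer, got {value!r} at position {at}"
                ) from None
            return {i for i, a in enumerate(self.topology) if a.residue_number == num}
        v = value.upper()
        if key == "resname":
            return {i for i, a in enumerate(self.topology) if a.residue_name.upper() == v}
        if key == "name":
            return {i for i, a in enumerate(self.topology) if a.atom_name.upper() == v}
        if key == "chain":
            return {i for i, a in enumerate(self.topology) if a.chain_id.upper() == v}
        # element
        return {i for i, a in enumerate(self.topology) if a.element.upper() == v}


def select_atoms(traj: Trajectory, expression: str) -> Selection:
    """Resolve a selection expression against the trajectory topology.

    Grammar: clauses ``resid <n>``, ``resname <s>``, ``name <s>``,
    ``chain <s>``, ``element <s>`` combined with ``and`` / ``or`` and
    parentheses.  Matching is case-insensitive.  Resolution is deterministic
    and returns indices in topology order; an empty match is allowed but
    triggers a warning.
    """
    if not expression.strip():
        raise SelectionSyntaxError("empty selection expression")
    matched = _Parser(expression, traj.topology).parse()
    if not matched:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(expression=expression, indices=tuple(sorted(matched)))
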