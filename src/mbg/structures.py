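"""Hierarchical macromolecular coordinate model and fixed-column PDB I/O.

The model is a plain chain -> residue -> atom hierarchy with coordinates in
Angstroms.  Only the coordinate section of the PDB format is interpreted
(ATOM / HETATM / TER / END / MODEL / ENDMDL); for multi-model files only
model 1 is kept, and alternate locations are collapsed to the
highest-occupancy conformer (ties broken by alt_loc character order).
Residue numbering is taken verbatim from the file and all residue-range
selections are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PDBError",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
    "parse_selection",
    "chain_breaks",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBError(Exception):
    """Base error for PDB reading/writing problems."""


class PDBParseError(PDBError):
    """A coordinate record could not be parsed (carries the line number)."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class SelectionError(Exception):
    """A selection referenced chains/residues/atoms that do not exist."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insert_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insert_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_num, self.insert_code,
                       self.res_name, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    id: str = ""
    chains: list[Chain] = field(default_factory=list)
    source_path: str | None = None

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise SelectionError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues():
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self, atom_name: str | None = None,
               heavy_only: bool = False) -> np.ndarray:
        """Stacked coordinates, optionally restricted to one atom name /
        heavy atoms.  Shape (n, 3); empty selection gives shape (0, 3)."""
        pts = [a.coords for a in self.atoms()
               if (atom_name is None or a.name == atom_name)
               and not (heavy_only and a.is_hydrogen)]
        if not pts:
            return np.empty((0, 3))
        return np.array(pts)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with all atom coordinates replaced, in
        atom-iteration order."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected {(self.n_atoms, 3)} coords, got {coords.shape}")
        out = self.copy()
        for a, xyz in zip(out.atoms(), coords):
            a.coords = np.array(xyz, dtype=float)
        return out

    def copy(self) -> "Structure":
        return Structure(self.id, [c.copy() for c in self.chains], self.source_path)


# ---------------------------------------------------------------------------
# Reading

def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, str, int, str, str]:
    """Parse one ATOM/HETATM record.  Returns (atom, chain_id, seq, icode, resname)."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(lineno, "record shorter than 54 columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21]
        seq_num = int(line[22:26])
        insert_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError as exc:
        raise PDBParseError(lineno, f"malformed fixed-width field ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: col 13 blank => col 14 is the
        # element; otherwise a two-char element (or a digit-prefixed H)
        nm = line[12:16]
        element = nm[1] if nm[0] in (" ", *"0123456789") else nm[0:2].strip()
        element = element.strip() or name[:1]
    atom = Atom(serial=serial, name=name, element=element, alt_loc=alt_loc,
                coords=np.array([x, y, z]), occupancy=occ, b_factor=bfac,
                is_hetero=line.startswith("HETATM"))
    return atom, chain_id, seq_num, insert_code, res_name


def _collapse_altlocs(residue: Residue) -> None:
    """Keep, per atom name, the highest-occupancy conformer (ties by alt_loc)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in residue.atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        else:
            b = best[a.name]
            if (a.occupancy, _neg_ord(a.alt_loc)) > (b.occupancy, _neg_ord(b.alt_loc)):
                best[a.name] = a
    residue.atoms = [best[n] for n in order]
    for a in residue.atoms:
        a.alt_loc = ""


def _neg_ord(alt: str) -> int:
    # higher is better: earlier alt_loc char wins ties
    return -ord(alt) if alt else 0


def read_pdb(path: str, structure_id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` (model 1 only).

    Raises :class:`PDBError` if the file has no coordinate records and
    :class:`PDBParseError` (naming the offending line) on malformed records.
    """
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise PDBError(f"cannot read {path}: {exc}") from exc

    chains: list[Chain] = []
    chain_index: dict[str, Chain] = {}
    res_index: dict[tuple[str, int, str], Residue] = {}
    model = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            model += 1
            if model > 1:
                break
        elif rec.startswith("ENDMDL"):
            break
        elif rec in ("ATOM  ", "HETATM"):
            atom, cid, seq, icode, rname = _parse_atom_record(line, lineno)
            key = (cid, seq, icode)
            res = res_index.get(key)
            if res is None:
                res = Residue(cid, seq, icode, rname)
                res_index[key] = res
                if cid not in chain_index:
                    chain_index[cid] = Chain(cid)
                    chains.append(chain_index[cid])
                chain_index[cid].residues.append(res)
            res.atoms.append(atom)

    if not res_index:
        raise PDBError(f"{path}: no ATOM/HETATM records found")
    for res in res_index.values():
        _collapse_altlocs(res)
    import os
    sid = structure_id if structure_id is not None else \
        os.path.splitext(os.path.basename(path))[0]
    return Structure(id=sid, chains=chains, source_path=str(path))


# ---------------------------------------------------------------------------
# Writing

def _format_atom_name(name: str, element: str) -> str:
    # one/two-letter elements start in column 14/13 respectively
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str) -> None:
    """Write fixed-column ATOM/HETATM records with TER after each chain and
    END at EOF.  Coordinates are emitted in 8.3 format, so a written file
    re-read with :func:`read_pdb` reproduces coordinates to 3 decimals and a
    write-read-write cycle is byte-stable."""
    if structure.n_atoms == 0:
        raise PDBError("refusing to write an empty structure")
    out_lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                if serial > 99999:
                    raise PDBError("atom serial overflow (> 99999)")
                if np.any(np.abs(atom.coords) >= 10000.0):
                    raise PDBError(
                        f"coordinate magnitude >= 10000 A at atom {atom.name} "
                        f"{res.res_name} {chain.chain_id}{res.seq_num}")
                rec = "HETATM" if atom.is_hetero else "ATOM  "
                x, y, z = atom.coords
                out_lines.append(
                    f"{rec}{serial:>5d} {_format_atom_name(atom.name, atom.element):<4s}"
                    f"{atom.alt_loc or ' ':1s}"
                    f"{res.res_name:>3s} {chain.chain_id:1s}{res.seq_num:>4d}"
                    f"{res.insert_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}\n")
            last_res = res
        serial += 1
        if serial > 99999:
            raise PDBError("atom serial overflow (> 99999)")
        assert last_res is not None
        out_lines.append(
            f"TER   {serial:>5d}      {last_res.res_name:>3s} "
            f"{chain.chain_id:1s}{last_res.seq_num:>4d}{last_res.insert_code or ' ':1s}\n")
    out_lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(out_lines)


# ---------------------------------------------------------------------------
# Selection

def parse_selection(spec: str) -> tuple[str, tuple[int, int] | None, str | None]:
    """Parse a ``chain[:start-end[:atomname]]`` selection string.

    Examples: ``"A"``, ``"A:3-123"``, ``"A:3-123:CA"``, ``"B::P"``.
    """
    parts = spec.split(":")
    if not parts or not parts[0]:
        raise SelectionError(f"invalid selection {spec!r}")
    chain_id = parts[0]
    rng: tuple[int, int] | None = None
    atom_name: str | None = None
    if len(parts) >= 2 and parts[1]:
        try:
            lo, _, hi = parts[1].partition("-")
            rng = (int(lo), int(hi) if hi else int(lo))
        except ValueError:
            raise SelectionError(f"invalid residue range in {spec!r}") from None
    if len(parts) >= 3 and parts[2]:
        atom_name = parts[2]
    return chain_id, rng, atom_name


def select(structure: Structure,
           chain_ids: str | Sequence[str] | None = None,
           residue_range: tuple[int, int] | None = None,
           atom_names: str | Iterable[str] | None = None) -> Structure:
    """Sub-structure by chain, inclusive residue-number range, and atom name.

    Order is preserved; an empty result is allowed.  Unknown chain ids raise
    :class:`SelectionError`.
    """
    if isinstance(chain_ids, str):
        chain_ids = [chain_ids]
    if isinstance(atom_names, str):
        atom_names = [atom_names]
    names = set(atom_names) if atom_names is not None else None
    if chain_ids is not None:
        known = set(structure.chain_ids)
        for cid in chain_ids:
            if cid not in known:
                raise SelectionError(f"no chain {cid!r} in structure {structure.id!r}")
    out = Structure(id=structure.id, source_path=structure.source_path)
    for chain in structure.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        new_chain = Chain(chain.chain_id)
        for res in chain.residues:
            if residue_range is not None and not (
                    residue_range[0] <= res.seq_num <= residue_range[1]):
                continue
            kept = [a.copy() for a in res.atoms if names is None or a.name in names]
            if kept:
                new_chain.residues.append(
                    Residue(res.chain_id, res.seq_num, res.insert_code,
                            res.res_name, kept))
        if new_chain.residues:
            out.chains.append(new_chain)
    return out


def select_spec(structure: Structure, spec: str) -> Structure:
    """Apply a ``chain[:start-end[:atom]]`` selection string."""
    cid, rng, aname = parse_selection(spec)
    return select(structure, chain_ids=cid, residue_range=rng, atom_names=aname)


def chain_breaks(structure: Structure, max_c_n: float = 2.5) -> list[tuple[str, int, int]]:
    """Detect chain breaks: consecutive residues whose C(i)-N(i+1) distance
    exceeds ``max_c_n`` Angstrom (or that lack the backbone atoms needed to
    check).  Returns (chain_id, seq_i, seq_i+1) tuples."""
    breaks = []
    for chain in structure.chains:
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            c = r1.atom("C")
            n = r2.atom("N")
            if c is None or n is None:
                continue
            if float(np.linalg.norm(c.coords - n.coords)) > max_c_n:
                breaks.append((chain.chain_id, r1.seq_num, r2.seq_num))
    return breaks
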