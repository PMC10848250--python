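"""Molecular structures, conformer ensembles, and file I/O.

Molecules are plain containers: element symbols, Cartesian coordinates in
Angstrom, and an explicit bond graph. Supported formats are SDF/MOL (V2000
connection table), XYZ (bonds perceived from covalent radii) and PDB
(ATOM/HETATM; MODEL/ENDMDL records delimit conformer ensembles).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "ConformerEnsemble",
    "StructureError",
    "StructureParseError",
    "EnsembleError",
    "UnknownElementError",
    "ATOMIC_WEIGHTS",
    "COVALENT_RADII",
    "normalized_masses",
    "center_coordinates",
    "perceive_bonds",
    "read_structure",
    "write_structure",
]


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class StructureParseError(StructureError):
    """Malformed structure file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EnsembleError(StructureError):
    """Conformer records that cannot form a consistent ensemble."""


class UnknownElementError(StructureError, KeyError):
    """Element symbol absent from the weight/radius tables."""


# IUPAC conventional standard atomic weights (abridged to the elements that
# occur in small-molecule pharmaceuticals).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.904,
}

# Cordero single-bond covalent radii, Angstrom.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "K": 2.03, "Ca": 1.76, "Fe": 1.32,
    "Zn": 1.22, "Se": 1.20, "Br": 1.20, "I": 1.39,
}

Bond = tuple[int, int]


def _canonical_bond(i: int, j: int) -> Bond:
    if i == j:
        raise StructureError(f"self-bond on atom {i}")
    return (i, j) if i < j else (j, i)


def _normalize_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def _lookup(table: dict[str, float], symbol: str, what: str) -> float:
    s = _normalize_symbol(symbol)
    try:
        return table[s]
    except KeyError:
        raise UnknownElementError(f"no {what} tabulated for element {s!r}") from None


@dataclass
class Molecule:
    """One conformation: elements, A x 3 coordinates (Angstrom), bond graph."""

    elements: list[str]
    coordinates: np.ndarray
    bonds: frozenset[Bond] = field(default_factory=frozenset)
    name: str = ""

    def __post_init__(self) -> None:
        self.elements = [_normalize_symbol(e) for e in self.elements]
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("coordinates must be an A x 3 matrix")
        if self.coordinates.shape[0] != len(self.elements):
            raise StructureError(
                f"{len(self.elements)} elements but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        a = self.n_atoms
        canon = set()
        for i, j in self.bonds:
            if not (0 <= i < a and 0 <= j < a):
                raise StructureError(f"bond ({i},{j}) outside atom range 0..{a - 1}")
            canon.add(_canonical_bond(i, j))
        self.bonds = frozenset(canon)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centered(self) -> "Molecule":
        return Molecule(
            list(self.elements), center_coordinates(self.coordinates),
            self.bonds, self.name,
        )


@dataclass
class ConformerEnsemble:
    """One topology (elements + bonds), many coordinate frames."""

    elements: list[str]
    bonds: frozenset[Bond]
    frames: list[np.ndarray]
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.elements = [_normalize_symbol(e) for e in self.elements]
        if not self.frames:
            raise EnsembleError("ensemble must contain at least one frame")
        a = len(self.elements)
        frames = []
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (a, 3):
                raise EnsembleError(
                    f"frame {k} has shape {f.shape}, expected ({a}, 3)"
                )
            frames.append(f)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def molecule(self, index: int) -> Molecule:
        """Extract frame ``index`` as a standalone Molecule."""
        name = f"{self.name}[{index}]" if self.name else f"frame {index}"
        return Molecule(list(self.elements), self.frames[index], self.bonds, name)

    def molecules(self) -> Iterable[Molecule]:
        return (self.molecule(i) for i in range(self.n_frames))


def normalized_masses(elements: Sequence[str]) -> np.ndarray:
    """Atomic masses normalized to carbon: m_i = weight(el_i) / weight(C)."""
    carbon = ATOMIC_WEIGHTS["C"]
    return np.array(
        [_lookup(ATOMIC_WEIGHTS, e, "atomic weight") / carbon for e in elements]
    )


def center_coordinates(coordinates: np.ndarray) -> np.ndarray:
    """Translate so the unweighted geometric center sits at the origin."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise StructureError("coordinates must be a non-empty A x 3 matrix")
    return coords - coords.mean(axis=0)


def perceive_bonds(
    elements: Sequence[str],
    coordinates: np.ndarray,
    factor: float = 1.2,
) -> frozenset[Bond]:
    """Distance-based bond perception.

    Atoms i and j are bonded iff r_ij < factor * (rcov_i + rcov_j), with
    Cordero single-bond covalent radii. Deterministic in input order.
    """
    coords = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise StructureError("non-finite coordinates")
    radii = np.array([_lookup(COVALENT_RADII, e, "covalent radius") for e in elements])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    cutoff = factor * (radii[:, None] + radii[None, :])
    bonded = dist < cutoff
    a = len(elements)
    return frozenset(
        (i, j) for i in range(a) for j in range(i + 1, a) if bonded[i, j]
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_sdf_record(lines: list[str], offset: int) -> Molecule:
    """Parse one MOL V2000 block. ``offset`` is the 1-based file line of lines[0]."""
    if len(lines) < 4:
        raise StructureParseError("truncated MOL block", offset + len(lines))
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise StructureParseError(
            f"unreadable counts line {counts.rstrip()!r}", offset + 3
        ) from None
    if len(lines) < 4 + n_atoms + n_bonds:
        raise StructureParseError(
            f"block declares {n_atoms} atoms / {n_bonds} bonds but ends early",
            offset + len(lines),
        )
    elements, coords = [], []
    for k in range(n_atoms):
        line = lines[4 + k]
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            symbol = line[31:34].strip()
            if not symbol:
                raise ValueError
        except (ValueError, IndexError):
            raise StructureParseError(
                f"unreadable atom line {line.rstrip()!r}", offset + 4 + k
            ) from None
        elements.append(symbol)
        coords.append((x, y, z))
    bonds = set()
    for k in range(n_bonds):
        line = lines[4 + n_atoms + k]
        try:
            i, j = int(line[0:3]), int(line[3:6])
        except (ValueError, IndexError):
            raise StructureParseError(
                f"unreadable bond line {line.rstrip()!r}", offset + 4 + n_atoms + k
            ) from None
        bonds.add(_canonical_bond(i - 1, j - 1))  # file is 1-based
    return Molecule(elements, np.array(coords), frozenset(bonds), name)


def _read_sdf(lines: list[str], name: str) -> Molecule | ConformerEnsemble:
    # split on $$$$ record delimiters, remembering file line offsets
    records: list[tuple[list[str], int]] = []
    current: list[str] = []
    start = 0
    for n, line in enumerate(lines):
        if line.strip() == "$$$$":
            if any(s.strip() for s in current):
                records.append((current, start))
            current, start = [], n + 1
        else:
            current.append(line)
    if any(s.strip() for s in current):
        records.append((current, start))
    if not records:
        raise StructureParseError("no MOL records found", 1)
    mols = [_parse_sdf_record(rec, off + 1) for rec, off in records]
    if len(mols) == 1:
        if name and not mols[0].name:
            mols[0].name = name
        return mols[0]
    return _ensemble_from_molecules(mols, name or mols[0].name, "multi-record SDF")


def _ensemble_from_molecules(
    mols: list[Molecule], name: str, provenance: str
) -> ConformerEnsemble:
    first = mols[0]
    for k, m in enumerate(mols[1:], start=2):
        if m.elements != first.elements:
            raise EnsembleError(
                f"record {k} atom list differs from record 1 "
                f"({m.n_atoms} vs {first.n_atoms} atoms)"
            )
        if m.bonds != first.bonds:
            raise EnsembleError(f"record {k} bond graph differs from record 1")
    return ConformerEnsemble(
        list(first.elements), first.bonds, [m.coordinates for m in mols],
        name=name, provenance=provenance,
    )


_XYZ_LINE = re.compile(r"^\s*(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s*$")


def _read_xyz(lines: list[str], name: str) -> Molecule | ConformerEnsemble:
    frames: list[tuple[list[str], np.ndarray]] = []
    comment = ""
    n = 0
    while n < len(lines):
        if not lines[n].strip():
            n += 1
            continue
        try:
            count = int(lines[n].strip())
        except ValueError:
            raise StructureParseError(
                f"expected atom count, got {lines[n].strip()!r}", n + 1
            ) from None
        if n + 1 >= len(lines):
            raise StructureParseError("missing comment line", n + 2)
        if not frames:
            comment = lines[n + 1].strip()
        elements, coords = [], []
        for k in range(count):
            ln = n + 2 + k
            if ln >= len(lines):
                raise StructureParseError(
                    f"expected {count} atom lines, file ends after {k}", ln
                )
            m = _XYZ_LINE.match(lines[ln])
            if m is None:
                raise StructureParseError(
                    f"unreadable XYZ atom line {lines[ln].rstrip()!r}", ln + 1
                )
            try:
                xyz = tuple(float(v) for v in m.group(2, 3, 4))
            except ValueError:
                raise StructureParseError(
                    f"non-numeric coordinate in {lines[ln].rstrip()!r}", ln + 1
                ) from None
            elements.append(m.group(1))
            coords.append(xyz)
        frames.append((elements, np.array(coords)))
        n += 2 + count
    if not frames:
        raise StructureParseError("empty XYZ file", 1)
    mols = []
    bonds = perceive_bonds(frames[0][0], frames[0][1])
    for els, coords in frames:
        mols.append(Molecule(els, coords, bonds, name or comment))
    if len(mols) == 1:
        return mols[0]
    return _ensemble_from_molecules(mols, name or comment, "multi-frame XYZ")


def _read_pdb(lines: list[str], name: str) -> Molecule | ConformerEnsemble:
    frames: list[tuple[list[str], np.ndarray]] = []
    conect: set[Bond] = set()
    serial_to_index: dict[int, int] = {}
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    in_model = False
    seen_model = False

    def flush() -> None:
        nonlocal elements, coords
        if elements:
            frames.append((elements, np.array(coords)))
        elements, coords = [], []

    for n, line in enumerate(lines):
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model = True
            in_model = True
        elif rec == "ENDMDL":
            in_model = False
            flush()
        elif rec in ("ATOM", "HETATM"):
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                raise StructureParseError(
                    f"unreadable coordinates in {line.rstrip()!r}", n + 1
                ) from None
            symbol = line[76:78].strip()
            if not symbol:  # fall back to the atom-name column
                symbol = re.sub(r"[^A-Za-z]", "", line[12:16].strip())[:2]
                if len(symbol) == 2 and symbol[1].isupper():
                    symbol = symbol[0]
            if not symbol:
                raise StructureParseError(
                    f"no element symbol in {line.rstrip()!r}", n + 1
                )
            try:
                serial = int(line[6:11])
            except (ValueError, IndexError):
                serial = len(elements) + 1
            if not frames:  # serials map onto the first frame only
                serial_to_index[serial] = len(elements)
            elements.append(symbol)
            coords.append((x, y, z))
        elif rec == "CONECT":
            fields = [int(v) for v in line[6:].split() if v.strip()]
            if len(fields) >= 2:
                for other in fields[1:]:
                    if fields[0] in serial_to_index and other in serial_to_index:
                        conect.add(
                            _canonical_bond(
                                serial_to_index[fields[0]], serial_to_index[other]
                            )
                        )
    if in_model:
        raise StructureParseError("MODEL record without matching ENDMDL", len(lines))
    flush()
    if not frames:
        raise StructureParseError("no ATOM/HETATM records found", 1)
    bonds = frozenset(conect) if conect else perceive_bonds(*frames[0])
    mols = [Molecule(els, c, bonds, name) for els, c in frames]
    if len(mols) == 1 and not seen_model:
        return mols[0]
    if len(mols) == 1:
        return mols[0]
    return _ensemble_from_molecules(mols, name, "multi-MODEL PDB")


_FORMAT_BY_SUFFIX = {
    ".sdf": "sdf", ".mol": "sdf", ".xyz": "xyz", ".pdb": "pdb", ".ent": "pdb",
}


def read_structure(
    path: str | Path, format: str | None = None
) -> Molecule | ConformerEnsemble:
    """Read a structure file; multi-record inputs yield a ConformerEnsemble.

    ``format`` is one of ``{"sdf", "xyz", "pdb"}``; inferred from the file
    suffix when omitted. XYZ input triggers covalent-radius bond perception.
    """
    path = Path(path)
    if format is None:
        format = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
        if format is None:
            raise StructureError(
                f"cannot infer format from suffix {path.suffix!r}; pass format="
            )
    fmt = format.lower()
    lines = path.read_text().splitlines()
    stem = path.stem
    if fmt == "sdf":
        return _read_sdf(lines, stem)
    if fmt == "xyz":
        return _read_xyz(lines, stem)
    if fmt == "pdb":
        return _read_pdb(lines, stem)
    raise StructureError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _mol_block(elements, coords, bonds, name) -> str:
    out = [name, "  rgetaway", "", f"{len(elements):>3}{len(bonds):>3}  0  0  0  0  0  0  0  0999 V2000"]
    for e, (x, y, z) in zip(elements, coords):
        out.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {e:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in sorted(bonds):
        out.append(f"{i + 1:>3}{j + 1:>3}  1  0")
    out.append("M  END")
    return "\n".join(out)


def write_structure(
    obj: Molecule | ConformerEnsemble, path: str | Path, format: str | None = None
) -> Path:
    """Write a Molecule or ConformerEnsemble to SDF, XYZ or PDB."""
    path = Path(path)
    if format is None:
        format = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
        if format is None:
            raise StructureError(
                f"cannot infer format from suffix {path.suffix!r}; pass format="
            )
    fmt = format.lower()
    if isinstance(obj, Molecule):
        mols = [obj]
        name = obj.name
    else:
        mols = list(obj.molecules())
        name = obj.name
    if fmt == "sdf":
        text = "\n$$$$\n".join(
            _mol_block(m.elements, m.coordinates, m.bonds, m.name or name)
            for m in mols
        ) + "\n$$$$\n"
    elif fmt == "xyz":
        blocks = []
        for m in mols:
            lines = [str(m.n_atoms), m.name or name]
            for e, (x, y, z) in zip(m.elements, m.coordinates):
                lines.append(f"{e} {x:.8f} {y:.8f} {z:.8f}")
            blocks.append("\n".join(lines))
        text = "\n".join(blocks) + "\n"
    elif fmt == "pdb":
        lines = []
        multi = len(mols) > 1
        for k, m in enumerate(mols, start=1):
            if multi:
                lines.append(f"MODEL     {k:>4}")
            for a, (e, (x, y, z)) in enumerate(
                zip(m.elements, m.coordinates), start=1
            ):
                lines.append(
                    f"HETATM{a:>5} {e:<4} LIG A   1    "
                    f"{x:>8.3f}{y:>8.3f}{z:>8.3f}  1.00  0.00          {e:>2}"
                )
            if multi:
                lines.append("ENDMDL")
        for i, j in sorted(mols[0].bonds):
            lines.append(f"CONECT{i + 1:>5}{j + 1:>5}")
        lines.append("END")
        text = "\n".join(lines) + "\n"
    else:
        raise StructureError(f"unsupported format {format!r}")
    path.write_text(text)
    return path
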