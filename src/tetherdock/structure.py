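"""Lightweight PDB structures, multi-model ensembles, and residue selection.

The containers here are deliberately minimal: an ordered list of heavy-atom
records with (chain, resseq, icode) residue keys, plus a multi-frame wrapper
whose frames share one topology. Every downstream metric (torsion coupling,
pose geometry, interface analysis, RMSF) selects atoms through this module.

Conventions: residue numbering is 1-based as in PDB files; domain selections
are closed intervals [first, last]; alternate conformers keep the
highest-occupancy altloc (ties broken by file order); waters and HETATM
records are skipped by default.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "DomainDefinition",
    "ResidueClassTable",
    "DEFAULT_CLASS_TABLE",
    "PDBParseError",
    "EmptyStructureError",
    "TopologyMismatchError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "read_ensemble",
    "write_ensemble",
    "select",
]

ResidueKey = tuple[str, int, str]

WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}


class PDBParseError(ValueError):
    """A coordinate record could not be parsed; carries the 1-based line number."""


class EmptyStructureError(ValueError):
    """A model contained no usable ATOM records."""


class TopologyMismatchError(ValueError):
    """Ensemble frames disagree on atom count, names, or residue keys."""


class EmptySelectionError(ValueError):
    """A selection matched no atoms."""


@dataclass(frozen=True)
class Atom:
    """One heavy-atom record.

    position is in Å; residue_key is (chain id, residue number, insertion code).
    """

    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    residue_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")


@dataclass
class Structure:
    """An ordered collection of atoms with optional named domain annotations."""

    atoms: list[Atom]
    annotations: dict[str, set[ResidueKey]] = field(default_factory=dict)

    @property
    def residues(self) -> list[ResidueKey]:
        """Ordered unique residue keys, following atom order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms, annotations=dict(self.annotations))

    def residue_name(self, key: ResidueKey) -> str:
        for a in self.atoms:
            if a.residue_key == key:
                return a.residue_name
        raise KeyError(key)

    def atom_index(
        self, residue_key: ResidueKey, atom_name: str
    ) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_key == residue_key and a.name == atom_name:
                return i
        raise KeyError((residue_key, atom_name))

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """N frames of identical topology (only positions differ)."""

    frames: list[Structure]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble must have at least one frame")
        ref = self.frames[0]
        ref_sig = [(a.name, a.residue_key) for a in ref.atoms]
        for k, fr in enumerate(self.frames[1:], start=1):
            if len(fr.atoms) != len(ref.atoms):
                raise TopologyMismatchError(
                    f"frame {k}: {len(fr.atoms)} atoms, expected {len(ref.atoms)}"
                )
            sig = [(a.name, a.residue_key) for a in fr.atoms]
            if sig != ref_sig:
                raise TopologyMismatchError(f"frame {k}: atom names/residues differ")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology_hash(self) -> str:
        sig = ";".join(
            f"{a.name}|{a.residue_key[0]}|{a.residue_key[1]}|{a.residue_key[2]}"
            for a in self.frames[0].atoms
        )
        return hashlib.sha1(sig.encode()).hexdigest()[:16]

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])

    def with_coords(self, coords: np.ndarray) -> "Ensemble":
        coords = np.asarray(coords, dtype=float)
        return Ensemble([self.frames[0].with_coords(c) for c in coords])


@dataclass(frozen=True)
class DomainDefinition:
    """A contiguous residue range on one chain, e.g. a kinase domain."""

    label: str
    chain: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"{self.label}: first_residue {self.first_residue} > "
                f"last_residue {self.last_residue}"
            )

    def contains(self, key: ResidueKey) -> bool:
        return key[0] == self.chain and self.first_residue <= key[1] <= self.last_residue


@dataclass
class ResidueClassTable:
    """Residue chemistry used by the contact metrics.

    hydrophobic/positive/negative/aromatic flag sets use 3-letter codes;
    charged_group_atoms and ring_atoms name the side-chain atoms that define
    ionic and stacking geometry. User-overridable.
    """

    hydrophobic: set[str]
    positive: set[str]
    negative: set[str]
    aromatic: set[str]
    charged_group_atoms: dict[str, tuple[str, ...]]
    ring_atoms: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        both = self.positive & self.negative
        if both:
            raise ValueError(f"codes both positive and negative: {both}")
        for code in self.aromatic:
            if not self.ring_atoms.get(code):
                raise ValueError(f"aromatic code {code} lacks ring_atoms")

    def charge_sign(self, code: str) -> int:
        if code in self.positive:
            return 1
        if code in self.negative:
            return -1
        return 0


DEFAULT_CLASS_TABLE = ResidueClassTable(
    hydrophobic={"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"},
    positive={"LYS", "ARG", "HIS"},
    negative={"ASP", "GLU"},
    aromatic={"PHE", "TYR", "TRP", "HIS"},
    charged_group_atoms={
        "ASP": ("OD1", "OD2"),
        "GLU": ("OE1", "OE2"),
        "LYS": ("NZ",),
        "ARG": ("NE", "NH1", "NH2"),
        "HIS": ("ND1", "NE2"),
    },
    ring_atoms={
        "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
        "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    },
)


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1] in "0123456789":
        stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "SE"}:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, float]:
    """Parse one fixed-column ATOM/HETATM record -> (atom, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}") from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_key=(chain, resseq, icode),
        residue_name=resname,
        position=np.array([x, y, z]),
    )
    return atom, altloc, occupancy


def _resolve_altlocs(
    records: list[tuple[Atom, str, float]]
) -> list[Atom]:
    """Keep highest-occupancy altloc per (residue, atom name); tie -> first seen."""
    best: dict[tuple[ResidueKey, str], tuple[float, int]] = {}
    for i, (atom, altloc, occ) in enumerate(records):
        if not altloc:
            continue
        k = (atom.residue_key, atom.name)
        if k not in best or occ > best[k][0]:
            best[k] = (occ, i)
    out = []
    for i, (atom, altloc, occ) in enumerate(records):
        if altloc and best[(atom.residue_key, atom.name)][1] != i:
            continue
        out.append(atom)
    return out


def read_pdb(
    path,
    *,
    include_hetatm: bool = False,
    include_waters: bool = False,
) -> Structure:
    """Read the first model of a PDB file into a Structure.

    HETATM records and waters are skipped by default. Raises PDBParseError
    (naming the offending line) for malformed coordinates and
    EmptyStructureError if no usable ATOM record is found.
    """
    records: list[tuple[Atom, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            if rec == "HETATM" and not include_hetatm:
                continue
            atom, altloc, occ = _parse_atom_line(line, lineno)
            if not include_waters and atom.residue_name in WATER_NAMES:
                continue
            records.append((atom, altloc, occ))
    if not records:
        raise EmptyStructureError(f"{path}: no ATOM records found")
    return Structure(_resolve_altlocs(records))


def _format_atom_line(atom: Atom, serial: int) -> str:
    name = atom.name
    # PDB column convention: 1-3 char names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    chain, resseq, icode = atom.residue_key
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{chain:1.1s}{resseq:>4d}{icode:<1.1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2.2s}\n"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB (coordinates at the format's 3-decimal precision)."""
    with open(path, "w") as fh:
        for i, atom in enumerate(structure.atoms, start=1):
            fh.write(_format_atom_line(atom, i))
        fh.write("END\n")


def read_ensemble(path, **kwargs) -> Ensemble:
    """Read a multi-model PDB into an Ensemble (one frame per MODEL record).

    A file without MODEL records yields a single-frame ensemble. Frames with
    differing topology raise TopologyMismatchError naming the model index.
    """
    include_hetatm = kwargs.get("include_hetatm", False)
    include_waters = kwargs.get("include_waters", False)
    frames: list[Structure] = []
    records: list[tuple[Atom, str, float]] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                records = []
            elif rec == "ENDMDL":
                if not records:
                    raise EmptyStructureError(
                        f"{path}: model {len(frames) + 1} has no atoms"
                    )
                frames.append(Structure(_resolve_altlocs(records)))
                records = []
            elif rec in ("ATOM", "HETATM"):
                if rec == "HETATM" and not include_hetatm:
                    continue
                atom, altloc, occ = _parse_atom_line(line, lineno)
                if not include_waters and atom.residue_name in WATER_NAMES:
                    continue
                records.append((atom, altloc, occ))
    if records and not saw_model:
        frames.append(Structure(_resolve_altlocs(records)))
    if not frames:
        raise EmptyStructureError(f"{path}: no models found")
    ref = frames[0]
    ref_sig = [(a.name, a.residue_key) for a in ref.atoms]
    for k, fr in enumerate(frames[1:], start=2):
        if [(a.name, a.residue_key) for a in fr.atoms] != ref_sig:
            raise TopologyMismatchError(
                f"{path}: model {k} topology differs from model 1"
            )
    return Ensemble(frames)


def write_ensemble(ensemble: Ensemble, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            for i, atom in enumerate(frame.atoms, start=1):
                fh.write(_format_atom_line(atom, i))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _atom_predicate(atom_filter) -> Callable[[Atom], bool]:
    if atom_filter is None:
        return lambda a: True
    if callable(atom_filter):
        return atom_filter
    if isinstance(atom_filter, str):
        names = {atom_filter}
    else:
        names = set(atom_filter)
    return lambda a: a.name in names


def select(
    structure: Structure,
    domain: DomainDefinition | None = None,
    atom_filter: str | Iterable[str] | Callable[[Atom], bool] | None = None,
) -> Structure:
    """Sub-structure of atoms in `domain` passing `atom_filter`, order preserved.

    atom_filter may be an atom name ("CA"), an iterable of names, or a
    predicate on Atom. Raises EmptySelectionError if nothing matches.
    """
    pred = _atom_predicate(atom_filter)
    atoms = [
        a
        for a in structure.atoms
        if (domain is None or domain.contains(a.residue_key)) and pred(a)
    ]
    if not atoms:
        raise EmptySelectionError(
            f"selection matched no atoms (domain={domain}, filter={atom_filter})"
        )
    return Structure(atoms)


def select_indices(
    structure: Structure,
    domain: DomainDefinition | None = None,
    atom_filter=None,
) -> np.ndarray:
    """Indices into structure.atoms for the same selection as `select`."""
    pred = _atom_predicate(atom_filter)
    idx = [
        i
        for i, a in enumerate(structure.atoms)
        if (domain is None or domain.contains(a.residue_key)) and pred(a)
    ]
    if not idx:
        raise EmptySelectionError(
            f"selection matched no atoms (domain={domain}, filter={atom_filter})"
        )
    return np.array(idx, dtype=int)


def select_ensemble(ensemble: Ensemble, domain=None, atom_filter=None) -> Ensemble:
    """Apply the same selection to every frame (commutes with frame access)."""
    return Ensemble([select(f, domain, atom_filter) for f in ensemble.frames])
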