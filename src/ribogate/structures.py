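"""Atomic data model and coordinate-file I/O for RNA structures.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each holding named :class:`Atom` records with
coordinates in Angstrom. Author residue numbering (the numbering printed in
structure papers, e.g. G75) is the canonical addressing scheme throughout the
package; mmCIF ``label_seq`` is ignored.

Parsing and writing of PDB/mmCIF goes through :mod:`gemmi`. On read,
hydrogens and waters are dropped and alternate locations are collapsed to the
highest-occupancy conformer, so every atom has exactly one coordinate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Selection",
    "SelectionResult",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "resolve_selection",
]

#: residue names treated as water on read
_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: standard ribo- and deoxyribonucleotide residue names
_NUCLEIC_NAMES = {
    "A", "C", "G", "U", "I", "N",
    "DA", "DC", "DG", "DT", "DU", "DI",
    "RA", "RC", "RG", "RU",
}


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent structures."""


class SelectionError(ValueError):
    """Raised when a selection references entities absent from a structure."""


@dataclass
class Atom:
    """A single atom: name, element, coordinate (Å), occupancy, B factor."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")


@dataclass
class Residue:
    """One residue addressed by (chain_id, seq_num, insertion_code)."""

    chain_id: str
    seq_num: int
    res_name: str
    insertion_code: Optional[str] = None
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code or "")

    @property
    def is_nucleic(self) -> bool:
        """Heuristic nucleic-acid test: standard name or a ribose C1' atom."""
        return self.res_name.strip() in _NUCLEIC_NAMES or self.atom("C1'") is not None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def add_atom(self, atom: Atom) -> None:
        if self.atom(atom.name) is not None:
            raise StructureError(
                f"duplicate atom {atom.name!r} in residue {self.chain_id}:{self.seq_num}"
            )
        self.atoms.append(atom)


@dataclass
class Structure:
    """An ordered collection of residues parsed from one coordinate model."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_format: str = "internal"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError(f"structure {self.id!r}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def residue(self, chain_id: str, seq_num: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.key == (chain_id, seq_num, insertion_code):
                return r
        return None

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def atom_map(self, heavy_only: bool = True) -> dict[tuple[str, int, str, str], np.ndarray]:
        """Map (chain, seq_num, icode, atom name) -> coordinate.

        Used for pairing atoms across models by identity.
        """
        out: dict[tuple[str, int, str, str], np.ndarray] = {}
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.element.upper() in ("H", "D"):
                    continue
                out[(r.chain_id, r.seq_num, r.insertion_code or "", a.name)] = a.coord
        return out

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                Residue(
                    chain_id=r.chain_id,
                    seq_num=r.seq_num,
                    res_name=r.res_name,
                    insertion_code=r.insertion_code,
                    atoms=[Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.b_iso) for a in r.atoms],
                )
                for r in self.residues
            ],
            source_format=self.source_format,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every coordinate mapped to R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = self.copy()
        for r in out.residues:
            for a in r.atoms:
                a.coord = rotation @ a.coord + translation
        return out


@dataclass(frozen=True)
class Selection:
    """Residue ranges plus an optional atom-name filter.

    ``residue_ranges`` is a tuple of ``(chain_id, start_seq, end_seq)``
    inclusive ranges; ``atom_names`` restricts to the named atoms if given.
    """

    residue_ranges: tuple[tuple[str, int, int], ...]
    atom_names: Optional[frozenset[str]] = None
    name: str = ""

    def __post_init__(self) -> None:
        for chain, start, end in self.residue_ranges:
            if start > end:
                raise SelectionError(f"range {chain}:{start}-{end}: start > end")

    @staticmethod
    def from_ranges(
        chain: str,
        ranges: Iterable[tuple[int, int]],
        atoms: Optional[Iterable[str]] = None,
        name: str = "",
    ) -> "Selection":
        return Selection(
            residue_ranges=tuple((chain, int(a), int(b)) for a, b in ranges),
            atom_names=frozenset(atoms) if atoms is not None else None,
            name=name,
        )

    def with_atoms(self, atoms: Optional[Iterable[str]]) -> "Selection":
        return Selection(
            residue_ranges=self.residue_ranges,
            atom_names=frozenset(atoms) if atoms is not None else None,
            name=self.name,
        )

    def contains(self, chain_id: str, seq_num: int) -> bool:
        return any(
            chain_id == c and a <= seq_num <= b for c, a, b in self.residue_ranges
        )


@dataclass
class SelectionResult:
    """Ordered resolved atoms plus a tally of what the model was missing."""

    atoms: list[tuple[Residue, Atom]]
    missing_residues: int
    missing_atoms: int

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for _, a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# gemmi-backed I/O


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    return "pdb"


def read_structure(path: os.PathLike | str, fmt: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The first model is used; hydrogens and waters are dropped, alternate
    locations are collapsed to the highest-occupancy conformer, and author
    numbering is preserved. Raises :class:`StructureError` if no residues
    survive filtering.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such coordinate file: {path}")
    kind = _infer_format(path, fmt)
    try:
        if kind == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"could not parse {path}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()

    residues: list[Residue] = []
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name.strip() in _WATER_NAMES:
                continue
            r = Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                res_name=res.name.strip(),
                insertion_code=(res.seqid.icode.strip() or None),
            )
            for at in res:
                r.add_atom(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_iso=at.b_iso,
                    )
                )
            if r.atoms:
                residues.append(r)

    out = Structure(id=path.stem, residues=residues, source_format=kind)
    if not any(r.is_nucleic for r in out.residues):
        raise StructureError(f"{path}: no nucleic-acid residues found")
    return out


def write_structure(s: Structure, path: os.PathLike | str) -> None:
    """Write a :class:`Structure` as a standards-conformant PDB file."""
    if len(s.residues) == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for r in s.residues:
        chain = chain_map.get(r.chain_id)
        if chain is None:
            chain = gemmi.Chain(r.chain_id)
            chain_map[r.chain_id] = chain
        res = gemmi.Residue()
        res.name = r.res_name
        res.seqid = gemmi.SeqId(r.seq_num, r.insertion_code or " ")
        for a in r.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element or a.name[0])
            at.pos = gemmi.Position(*a.coord)
            at.occ = a.occupancy
            at.b_iso = a.b_iso
            res.add_atom(at)
        chain.add_residue(res)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def resolve_selection(s: Structure, sel: Selection) -> SelectionResult:
    """Resolve a :class:`Selection` to an ordered atom list.

    Atoms come back ordered by (chain, seq_num, file atom order). Residues or
    atoms the model lacks are skipped silently but counted in the returned
    missing tallies. A range naming a chain that does not exist at all raises
    :class:`SelectionError`.
    """
    chains_present = set(s.chain_ids)
    for chain, _, _ in sel.residue_ranges:
        if chain not in chains_present:
            raise SelectionError(f"selection references chain {chain!r} not in structure {s.id!r}")

    by_key: dict[tuple[str, int], Residue] = {}
    for r in s.residues:
        if r.is_nucleic:
            by_key.setdefault((r.chain_id, r.seq_num), r)

    atoms: list[tuple[Residue, Atom]] = []
    missing_residues = 0
    missing_atoms = 0
    seen: set[tuple[str, int]] = set()
    for chain, start, end in sel.residue_ranges:
        for seq in range(start, end + 1):
            if (chain, seq) in seen:
                continue
            seen.add((chain, seq))
            res = by_key.get((chain, seq))
            if res is None:
                missing_residues += 1
                continue
            if sel.atom_names is None:
                picked = [a for a in res.atoms if a.element.upper() not in ("H", "D")]
            else:
                picked = []
                for name in sorted(sel.atom_names):
                    a = res.atom(name)
                    if a is None:
                        missing_atoms += 1
                    else:
                        picked.append(a)
                # keep file atom order within the residue
                order = {id(a): i for i, a in enumerate(res.atoms)}
                picked.sort(key=lambda a: order[id(a)])
            atoms.extend((res, a) for a in picked)

    # global ordering: chain (first-appearance order), then seq, then file order
    chain_rank = {c: i for i, c in enumerate(s.chain_ids)}
    atoms.sort(key=lambda ra: (chain_rank[ra[0].chain_id], ra[0].seq_num))
    return SelectionResult(atoms=atoms, missing_residues=missing_residues, missing_atoms=missing_atoms)
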