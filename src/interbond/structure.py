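"""PDB input, interface selection and bond-table output.

Parsing is delegated to gemmi; this module reduces the parsed structure to
the minimal model the detectors need: protein chains of canonical residues
with resolved alternate locations.  Waters and HETATM records are dropped,
only the first MODEL of multi-model files is kept, and author residue
numbering (with insertion codes) is the canonical residue identifier.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import gemmi
import numpy as np

from .chemistry import CANONICAL_RESIDUES, normalize_residue_name

__all__ = [
    "Atom",
    "Residue",
    "ResidueId",
    "StructureModel",
    "InterfaceSpec",
    "EmptyStructureError",
    "PdbParseError",
    "ConfigurationError",
    "parse_pdb",
    "select_interface",
    "write_bond_table",
]


class EmptyStructureError(ValueError):
    """No protein ATOM records could be parsed."""


class PdbParseError(ValueError):
    """Malformed PDB input."""


class ConfigurationError(ValueError):
    """Invalid run configuration (unknown chain, bad format name, ...)."""


class ResidueId(NamedTuple):
    """Author-numbering residue identifier used throughout the package."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name: str

    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_number}{self.insertion_code}".strip()


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False
    auto_placed: bool = False  # hydrogen added by idealized placement
    rotatable: bool = False  # hydroxyl/thiol hydrogen with free dihedral

    def copy(self) -> "Atom":
        return replace(self, coord=np.array(self.coord, float))


@dataclass
class Residue:
    name: str
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.seq_number, self.insertion_code, self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def hydrogens_on(self, heavy_name: str, max_bond: float = 1.3) -> list[Atom]:
        """Hydrogens covalently attached to the named heavy atom (by distance)."""
        heavy = self.atom(heavy_name)
        if heavy is None:
            return []
        return [
            a
            for a in self.atoms
            if a.is_hydrogen and np.linalg.norm(a.coord - heavy.coord) <= max_bond
        ]

    def copy(self) -> "Residue":
        return Residue(
            self.name,
            self.chain_id,
            self.seq_number,
            self.insertion_code,
            [a.copy() for a in self.atoms],
        )


@dataclass
class StructureModel:
    entry_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.entry_id,
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()},
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transform every coordinate (new model)."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for res in out.residues():
            for a in res.atoms:
                a.coord = R @ a.coord + t
        return out


@dataclass(frozen=True)
class InterfaceSpec:
    """The two chain groups between which intermolecular bonds are counted."""

    group1: frozenset[str]
    group2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ConfigurationError("both interface groups must be nonempty")
        if self.group1 & self.group2:
            raise ConfigurationError("interface groups must be disjoint")

    @classmethod
    def from_string(cls, text: str) -> "InterfaceSpec":
        """Parse 'A:D' or 'A,B:C,D' (colon separates the two sides)."""
        parts = text.split(":")
        if len(parts) != 2:
            raise ConfigurationError(f"group spec must contain exactly one ':': {text!r}")
        g1 = frozenset(c.strip() for c in parts[0].split(",") if c.strip())
        g2 = frozenset(c.strip() for c in parts[1].split(",") if c.strip())
        return cls(g1, g2)

    def swapped(self) -> "InterfaceSpec":
        return InterfaceSpec(self.group2, self.group1)

    def validate(self, model: StructureModel) -> None:
        missing = (self.group1 | self.group2) - set(model.chains)
        if missing:
            raise ConfigurationError(
                f"chains {sorted(missing)} named in the interface spec are absent "
                f"from the model (present: {sorted(model.chains)})"
            )


def _resolve_altlocs(atoms: list[tuple[str, Atom]]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc 'A'
    (blank altloc sorts first, then alphabetical)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for name, atom in atoms:
        if name not in by_name:
            order.append(name)
        by_name.setdefault(name, []).append(atom)
    resolved = []
    for name in order:
        group = by_name[name]
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        resolved.append(group[0])
    return resolved


def parse_pdb(source: str | Path | io.TextIOBase) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    ``source`` may be a path, PDB text, or an open text stream.  Waters and
    HETATM records are excluded; non-canonical residues are skipped with a
    warning; alternate locations are resolved to the highest-occupancy
    conformer; hydrogens are retained and flagged.
    """
    entry_id = "structure"
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
        entry_id = source.stem
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        p = Path(source)
        text = p.read_text()
        entry_id = p.stem
    else:
        text = str(source)

    # gemmi is lenient about unparseable coordinate fields; reject them
    # explicitly so corrupt input fails loudly with a line number
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                field = line[lo:hi].strip()
                try:
                    float(field)
                except ValueError:
                    raise PdbParseError(
                        f"malformed coordinate field {field!r} on line {lineno}"
                    ) from None

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(str(exc)) from exc
    if st.name and st.name not in ("string", ""):
        entry_id = st.name.lower()

    if len(st) == 0:
        raise EmptyStructureError("no model in PDB input")

    model = StructureModel(entry_id)
    skipped: set[str] = set()
    for chain in st[0]:  # first MODEL only
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag != "A" or res.name == "HOH":
                continue
            name = normalize_residue_name(res.name)
            if name not in CANONICAL_RESIDUES:
                skipped.add(res.name)
                continue
            pending = []
            for a in res:
                altloc = a.altloc if a.altloc != "\x00" else ""
                coord = np.array(a.pos.tolist(), float)
                if not np.all(np.isfinite(coord)):
                    raise PdbParseError(
                        f"non-finite coordinates for atom {a.name} in "
                        f"{name} {chain.name}{res.seqid.num}"
                    )
                pending.append(
                    (
                        a.name,
                        Atom(
                            serial=a.serial,
                            name=a.name,
                            element=a.element.name,
                            coord=coord,
                            occupancy=float(a.occ),
                            altloc=altloc,
                            is_hydrogen=bool(a.is_hydrogen()),
                        ),
                    )
                )
            if not pending:
                continue
            residues.append(
                Residue(
                    name=name,
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(pending),
                )
            )
        if residues:
            model.chains[chain.name] = residues

    if skipped:
        warnings.warn(
            f"skipped non-canonical residues: {sorted(skipped)}", stacklevel=2
        )
    if not model.chains:
        raise EmptyStructureError("no protein ATOM records in PDB input")
    return model


def select_interface(
    model: StructureModel, spec: InterfaceSpec
) -> tuple[list[Residue], list[Residue]]:
    """Residues of the two interface groups; detection considers only pairs
    with one residue from each."""
    spec.validate(model)
    g1 = [r for cid in sorted(spec.group1) for r in model.chains[cid]]
    g2 = [r for cid in sorted(spec.group2) for r in model.chains[cid]]
    return g1, g2


_TSV_COLUMNS = [
    "bond_type",
    "chain1",
    "resname1",
    "resnum1",
    "chain2",
    "resname2",
    "resnum2",
    "atom1",
    "atom2",
    "distance_A",
    "dha_angle_deg",
    "centroid_distance_A",
]


def _bond_sort_key(b) -> tuple:
    return (
        b.bond_type,
        b.res1.chain_id,
        b.res1.seq_number,
        b.res1.insertion_code,
        b.distance,
        b.res2.chain_id,
        b.res2.seq_number,
    )


def write_bond_table(bonds: Iterable, format: str = "tsv") -> str:
    """Serialize bond records deterministically as TSV or JSON text."""
    rows = []
    for b in sorted(bonds, key=_bond_sort_key):
        rows.append(
            {
                "bond_type": b.bond_type,
                "chain1": b.res1.chain_id,
                "resname1": b.res1.name,
                "resnum1": f"{b.res1.seq_number}{b.res1.insertion_code}",
                "chain2": b.res2.chain_id,
                "resname2": b.res2.name,
                "resnum2": f"{b.res2.seq_number}{b.res2.insertion_code}",
                "atom1": b.atom1,
                "atom2": b.atom2,
                "distance_A": f"{b.distance:.3f}",
                "dha_angle_deg": "" if b.dha_angle is None else f"{b.dha_angle:.1f}",
                "centroid_distance_A": (
                    "" if b.centroid_distance is None else f"{b.centroid_distance:.3f}"
                ),
            }
        )
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        lines += ["\t".join(str(r[c]) for c in _TSV_COLUMNS) for r in rows]
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(rows, indent=1) + "\n"
    raise ConfigurationError(f"unknown bond-table format: {format!r}")
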