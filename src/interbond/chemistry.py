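"""Static amino-acid chemistry: formal charges, hydrogen-bond donors and
acceptors, charged side-chain atoms, and side-chain reach.

Conventions
-----------
* Only the 20 canonical residues are known.  Protonation variants of
  histidine (HID/HIE/HIP/HSD/HSE/HSP) are normalized to ``HIS``.
* At physiological pH the basic residues ARG, HIS and LYS carry formal
  charge +1 and the acidic residues ASP and GLU carry -1; histidine is
  treated as protonated, so both ring nitrogens count as charged atoms and
  as donors (and consequently not as acceptors).
* Every residue donates through its backbone amide N (one hydrogen) except
  proline, and accepts through its carbonyl O (antecedent C); a terminal
  OXT is likewise an acceptor.  Chain-terminal charges (NH3+/COO-) are not
  treated as charged atoms.
* Side-chain entries are loaded from ``data/residue_chemistry.tsv`` so the
  tables are auditable and can be overridden by passing an alternative path
  to :func:`load_chemistry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ResidueChemistry",
    "UnrecognizedResidueError",
    "CANONICAL_RESIDUES",
    "BACKBONE_ATOMS",
    "ROTATABLE_HYDROXYLS",
    "load_chemistry",
    "get_chemistry",
    "normalize_residue_name",
    "formal_charge",
    "charged_atoms",
    "donor_acceptor_table",
    "sidechain_reach",
]

CANONICAL_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Histidine protonation-variant aliases normalized to HIS.
_HIS_ALIASES = frozenset({"HID", "HIE", "HIP", "HSD", "HSE", "HSP"})

#: Atom names belonging to the peptide backbone (hydrogens aside).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: (residue, atom) hydroxyl/thiol donors whose hydrogen position is a free
#: rotamer; detection samples the dihedral instead of fixing it.
ROTATABLE_HYDROXYLS = frozenset({("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG")})


class UnrecognizedResidueError(KeyError):
    """Raised for residue names outside the 20 canonical amino acids."""


@dataclass(frozen=True)
class ResidueChemistry:
    """Chemical roles of one amino-acid type.

    ``donor_atoms`` maps heavy-atom name -> number of attached polar
    hydrogens; ``acceptor_atoms`` maps heavy-atom name -> tuple of
    antecedent (covalently bonded heavy neighbour) names.  Both include the
    backbone entries.
    """

    residue_name: str
    formal_charge: int
    donor_atoms: dict[str, int] = field(default_factory=dict)
    acceptor_atoms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    charged_atoms: frozenset[str] = frozenset()
    sidechain_reach: float = 0.0


def normalize_residue_name(name: str) -> str:
    """Uppercase and map histidine protonation variants to HIS."""
    name = name.strip().upper()
    return "HIS" if name in _HIS_ALIASES else name


def _parse_table(text: str) -> dict[str, ResidueChemistry]:
    charge: dict[str, int] = {res: 0 for res in CANONICAL_RESIDUES}
    charged: dict[str, set[str]] = {res: set() for res in CANONICAL_RESIDUES}
    donors: dict[str, dict[str, int]] = {res: {} for res in CANONICAL_RESIDUES}
    acceptors: dict[str, dict[str, tuple[str, ...]]] = {res: {} for res in CANONICAL_RESIDUES}
    reach: dict[str, float] = {res: 0.0 for res in CANONICAL_RESIDUES}

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        res, role, atom, detail = line.split("\t")
        if res not in CANONICAL_RESIDUES:
            raise ValueError(f"non-canonical residue in chemistry table: {res}")
        if role == "charge":
            charge[res] = int(detail)
        elif role == "charged_atom":
            charged[res].add(atom)
        elif role == "donor":
            donors[res][atom] = int(detail)
        elif role == "acceptor":
            acceptors[res][atom] = tuple(detail.split(","))
        elif role == "reach":
            reach[res] = float(detail)
        else:
            raise ValueError(f"unknown role in chemistry table: {role}")

    table: dict[str, ResidueChemistry] = {}
    for res in sorted(CANONICAL_RESIDUES):
        d = dict(donors[res])
        a = dict(acceptors[res])
        if res != "PRO":
            d["N"] = 1  # backbone amide
        a["O"] = ("C",)
        a["OXT"] = ("C",)
        table[res] = ResidueChemistry(
            residue_name=res,
            formal_charge=charge[res],
            donor_atoms=d,
            acceptor_atoms=a,
            charged_atoms=frozenset(charged[res]),
            sidechain_reach=reach[res],
        )
    return table


def load_chemistry(path: str | Path | None = None) -> dict[str, ResidueChemistry]:
    """Load the chemistry table, from ``path`` or the packaged default."""
    if path is None:
        text = (resources.files("interbond") / "data" / "residue_chemistry.tsv").read_text()
    else:
        text = Path(path).read_text()
    return _parse_table(text)


_DEFAULT: dict[str, ResidueChemistry] | None = None


def get_chemistry(residue_name: str) -> ResidueChemistry:
    """Chemistry record for one residue; raises UnrecognizedResidueError."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_chemistry()
    name = normalize_residue_name(residue_name)
    try:
        return _DEFAULT[name]
    except KeyError:
        raise UnrecognizedResidueError(residue_name) from None


def formal_charge(residue_name: str) -> int:
    """Formal side-chain charge at physiological pH (+1, 0 or -1)."""
    return get_chemistry(residue_name).formal_charge


def charged_atoms(residue_name: str) -> frozenset[str]:
    """Side-chain atoms carrying the formal charge (N basic / O acidic)."""
    return get_chemistry(residue_name).charged_atoms


def donor_acceptor_table(residue_name: str) -> tuple[dict[str, int], dict[str, tuple[str, ...]]]:
    """(donor atom -> hydrogen count, acceptor atom -> antecedent names)."""
    chem = get_chemistry(residue_name)
    return dict(chem.donor_atoms), dict(chem.acceptor_atoms)


def sidechain_reach(residue_name: str) -> float:
    """Distance (angstrom) from Cbeta to the farthest polar/charged
    side-chain atom in an extended conformation."""
    return get_chemistry(residue_name).sidechain_reach
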