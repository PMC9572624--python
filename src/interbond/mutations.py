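"""Binding-affinity change (ddG) machinery and bond-change classification.

From an affinity table (SKEMPI-style: complex, chain, point mutation,
wild-type and mutant equilibrium dissociation constants, temperature) the
module computes per-mutation binding free energies dG = RT ln Kd, their
change ddG = dG_mut - dG_wt (positive = destabilizing), and a per-complex
min-max normalization of ddG to [0, 1] so free-energy scales are comparable
across complexes.  Each record's own experimental temperature enters RT
directly (298.15 K when absent).

Each mutation is then classified against the wild-type bond predictions:
a bond of a given type touching the mutated residue through its side chain
is *broken* if the mutant loses the required chemistry with the same
partner and *intact* if it keeps it (charged-to-like-charged mutations);
backbone-mediated bonds survive any point mutation.  Where the wild type
has no bond of that type, the mutation is *formed* if the mutant's
chemistry permits one with an opposite-group residue whose relevant atoms
lie within (bond cutoff + side-chain reach) of the site's C-beta -- a
reach heuristic on the wild-type structure, not mutant modelling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import chemistry
from .chemistry import BACKBONE_ATOMS
from .detect import BondRecord, DetectionParams
from .structure import InterfaceSpec, Residue, ResidueId, StructureModel

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "MutationRecord",
    "DdgRecord",
    "BondChange",
    "SiteNotFoundError",
    "delta_g",
    "compute_ddg",
    "normalize_ddg",
    "classify_bond_change",
    "group_summary",
    "parse_mutation_code",
    "read_mutation_table",
    "SKEMPI2_COLUMNS",
]

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K

_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class SiteNotFoundError(KeyError):
    """Mutation site absent from the structure."""


@dataclass(frozen=True)
class MutationRecord:
    """One point mutation with its measured equilibrium constants (molar
    dissociation constants) before and after mutation."""

    complex_id: str
    chain_id: str
    position: int
    wt_residue: str
    mut_residue: str
    keq_wt: float
    keq_mut: float
    temperature: float | None = None
    insertion_code: str = ""


@dataclass(frozen=True)
class DdgRecord:
    mutation: MutationRecord
    dg_wt: float
    dg_mut: float
    ddg: float
    ddg_normalized: float = float("nan")


@dataclass(frozen=True)
class BondChange:
    bond_type: str
    classification: str  # broken | intact | formed | none
    partner: ResidueId | None = None


def delta_g(keq: float, temperature: float | None = None) -> float:
    """Binding free energy dG = RT ln(Kd) in kcal/mol (Kd in molar)."""
    if keq <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {keq}")
    T = DEFAULT_TEMPERATURE if temperature is None else temperature
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return GAS_CONSTANT_KCAL * T * float(np.log(keq))


def compute_ddg(record: MutationRecord) -> DdgRecord:
    """ddG = dG_mut - dG_wt; positive values are destabilizing."""
    dg_wt = delta_g(record.keq_wt, record.temperature)
    dg_mut = delta_g(record.keq_mut, record.temperature)
    return DdgRecord(record, dg_wt, dg_mut, dg_mut - dg_wt)


def normalize_ddg(records: list[DdgRecord]) -> list[DdgRecord]:
    """Min-max normalize ddG to [0, 1] within each complex; a complex with
    a single ddG value (or all-equal values) maps to 0.5."""
    by_complex: dict[str, list[DdgRecord]] = {}
    for r in records:
        by_complex.setdefault(r.mutation.complex_id, []).append(r)
    bounds = {
        cid: (min(r.ddg for r in recs), max(r.ddg for r in recs))
        for cid, recs in by_complex.items()
    }
    out = []
    for r in records:  # input order preserved
        lo, hi = bounds[r.mutation.complex_id]
        norm = 0.5 if hi == lo else (r.ddg - lo) / (hi - lo)
        out.append(replace(r, ddg_normalized=float(norm)))
    return out


# ---------------------------------------------------------------------------
# mutation-table input

#: column mapping for SKEMPI 2 dumps
SKEMPI2_COLUMNS = {
    "complex": "#Pdb",
    "mutation": "Mutation(s)_cleaned",
    "keq_wt": "Affinity_wt_parsed",
    "keq_mut": "Affinity_mut_parsed",
    "temperature": "Temperature",
}

_DEFAULT_COLUMNS = {
    "complex": "complex_id",
    "mutation": "mutation",
    "keq_wt": "keq_wt",
    "keq_mut": "keq_mut",
    "temperature": "temperature",
}

_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z])(\d+)([A-Za-z]?)([A-Z])$")


def parse_mutation_code(code: str) -> tuple[str, str, int, str, str]:
    """Parse a SKEMPI-style code like ``RA59A`` into (wt 3-letter code,
    chain, position, insertion code, mutant 3-letter code)."""
    m = _MUTATION_RE.match(code.strip())
    if not m:
        raise ValueError(f"unparseable mutation code: {code!r}")
    wt1, chain, pos, icode, mut1 = m.groups()
    if wt1 not in _AA_1TO3 or mut1 not in _AA_1TO3:
        raise ValueError(f"unknown amino-acid letter in mutation code: {code!r}")
    return _AA_1TO3[wt1], chain, int(pos), icode.upper(), _AA_1TO3[mut1]


def read_mutation_table(
    source: str | Path | pd.DataFrame,
    columns: dict[str, str] | None = None,
    sep: str = "\t",
) -> list[MutationRecord]:
    """Read an affinity table into MutationRecords.

    Multi-point mutations (comma-separated codes) and unparseable rows are
    skipped with a warning; exact duplicate rows are collapsed.
    """
    cols = dict(_DEFAULT_COLUMNS)
    cols.update(columns or {})
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep)
    n_dup = int(df.duplicated().sum())
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate mutation rows", stacklevel=2)
        df = df.drop_duplicates()
    records, skipped = [], 0
    for _, row in df.iterrows():
        code = str(row[cols["mutation"]]).strip()
        if "," in code:
            skipped += 1
            continue
        try:
            wt3, chain, pos, icode, mut3 = parse_mutation_code(code)
            keq_wt = float(row[cols["keq_wt"]])
            keq_mut = float(row[cols["keq_mut"]])
        except (ValueError, KeyError):
            skipped += 1
            continue
        temp = row.get(cols["temperature"])
        try:
            temp = float(temp)
            if not np.isfinite(temp):
                temp = None
        except (TypeError, ValueError):
            temp = None
        records.append(
            MutationRecord(
                complex_id=str(row[cols["complex"]]),
                chain_id=chain,
                position=pos,
                insertion_code=icode,
                wt_residue=wt3,
                mut_residue=mut3,
                keq_wt=keq_wt,
                keq_mut=keq_mut,
                temperature=temp,
            )
        )
    if skipped:
        warnings.warn(
            f"skipped {skipped} rows (multi-point or unparseable mutations)", stacklevel=2
        )
    return records


# ---------------------------------------------------------------------------
# bond-change classification

def _is_sidechain_atom(name: str) -> bool:
    return name not in BACKBONE_ATOMS and not name.startswith("H")


def _bond_atom_on(bond: BondRecord, rid: ResidueId) -> tuple[str, bool]:
    """(atom name on the mutated residue, mutated residue is res1)."""
    if bond.res1[:3] == rid[:3]:
        return bond.atom1, True
    return bond.atom2, False


def _site_anchor(residue: Residue) -> np.ndarray:
    anchor = residue.atom("CA") if residue.name == "GLY" else residue.atom("CB")
    if anchor is None:
        anchor = residue.atom("CA")
    if anchor is None:
        raise SiteNotFoundError(f"residue {residue.id.label()} has no CB/CA anchor")
    return anchor.coord


def _sidechain_donors(res_name: str) -> set[str]:
    return set(chemistry.get_chemistry(res_name).donor_atoms) - {"N"}


def _sidechain_acceptors(res_name: str) -> set[str]:
    return set(chemistry.get_chemistry(res_name).acceptor_atoms) - {"O", "OXT"}


def classify_bond_change(
    wt_bonds: dict[str, list[BondRecord]],
    mutation: MutationRecord,
    model: StructureModel,
    spec: InterfaceSpec,
    params: DetectionParams = DetectionParams(),
) -> list[BondChange]:
    """Classify the mutation's effect per bond type (one BondChange each).

    ``wt_bonds`` is the detect_all output on the wild-type structure.
    """
    site = model.residue(mutation.chain_id, mutation.position, mutation.insertion_code)
    if site is None:
        raise SiteNotFoundError(
            f"mutation site {mutation.chain_id}:{mutation.position}"
            f"{mutation.insertion_code} not in structure"
        )
    if site.name != mutation.wt_residue:
        warnings.warn(
            f"wild-type residue mismatch at {site.id.label()}: table says "
            f"{mutation.wt_residue}, structure has {site.name}",
            stacklevel=2,
        )
    rid = site.id
    mut_name = mutation.mut_residue
    same_residue = mut_name == site.name
    mut_charge = chemistry.formal_charge(mut_name)

    if mutation.chain_id in spec.group1:
        opposite = [r for cid in sorted(spec.group2) for r in model.chains[cid]]
    elif mutation.chain_id in spec.group2:
        opposite = [r for cid in sorted(spec.group1) for r in model.chains[cid]]
    else:
        raise SiteNotFoundError(
            f"mutated chain {mutation.chain_id} is not part of the interface spec"
        )

    anchor = _site_anchor(site)
    reach = chemistry.sidechain_reach(mut_name)
    changes: list[BondChange] = []

    for bond_type in ("hydrogen", "ionic", "salt_bridge"):
        touching = [
            b for b in wt_bonds.get(bond_type, [])
            if b.res1[:3] == rid[:3] or b.res2[:3] == rid[:3]
        ]
        if touching:
            classification = "broken"
            partner = None
            for b in touching:
                atom_here, here_is_res1 = _bond_atom_on(b, rid)
                other = b.res2 if here_is_res1 else b.res1
                if not _is_sidechain_atom(atom_here):
                    classification = "intact"  # backbone-mediated: survives
                    partner = other
                    break
                if bond_type in ("ionic", "salt_bridge"):
                    partner_charge = chemistry.formal_charge(other.name)
                    if mut_charge * partner_charge < 0:
                        classification = "intact"
                        partner = other
                        break
                else:
                    donor_here = (
                        b.donor_is_res1 if here_is_res1 else
                        (None if b.donor_is_res1 is None else not b.donor_is_res1)
                    )
                    if donor_here is None:
                        donor_here = atom_here in chemistry.get_chemistry(rid.name).donor_atoms
                    retains = (
                        _sidechain_donors(mut_name) if donor_here
                        else _sidechain_acceptors(mut_name)
                    )
                    if retains:
                        classification = "intact"
                        partner = other
                        break
                partner = partner or other
            changes.append(BondChange(bond_type, classification, partner))
            continue

        # no wild-type bond of this type at the site: formed or none
        if same_residue:
            changes.append(BondChange(bond_type, "none"))
            continue
        formed_partner: ResidueId | None = None
        if bond_type in ("ionic", "salt_bridge"):
            cutoff = (
                params.salt_cutoff if bond_type == "salt_bridge" else params.ionic_atom_cutoff
            )
            if mut_charge != 0:
                best = None
                for other in opposite:
                    if chemistry.formal_charge(other.name) * mut_charge >= 0:
                        continue
                    for aname in sorted(chemistry.charged_atoms(other.name)):
                        atom = other.atom(aname)
                        if atom is None:
                            continue
                        dist = float(np.linalg.norm(atom.coord - anchor))
                        if dist <= cutoff + reach and (best is None or dist < best):
                            best = dist
                            formed_partner = other.id
        else:
            has_donor = bool(_sidechain_donors(mut_name))
            has_acceptor = bool(_sidechain_acceptors(mut_name))
            if has_donor or has_acceptor:
                best = None
                for other in opposite:
                    ochem = chemistry.get_chemistry(other.name)
                    names: set[str] = set()
                    if has_donor:
                        names |= set(ochem.acceptor_atoms)
                    if has_acceptor:
                        names |= set(ochem.donor_atoms)
                    for aname in sorted(names):
                        atom = other.atom(aname)
                        if atom is None:
                            continue
                        dist = float(np.linalg.norm(atom.coord - anchor))
                        if dist <= params.da_cutoff + reach and (best is None or dist < best):
                            best = dist
                            formed_partner = other.id
        if formed_partner is not None:
            changes.append(BondChange(bond_type, "formed", formed_partner))
        else:
            changes.append(BondChange(bond_type, "none"))
    return changes


# ---------------------------------------------------------------------------
# group statistics

def group_summary(
    frame: pd.DataFrame,
    value_col: str = "ddg_normalized",
    group_cols: list[str] | None = None,
    expected_groups: list[tuple] | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-group mean, two-sided t confidence interval, coefficient of
    variation and count.

    Groups with one value get no interval (NaN bounds); expected groups
    with no values are reported with ``marker='*'`` and no statistics.
    """
    group_cols = group_cols or ["bond_type", "classification", "complex_id"]
    rows = []
    seen = set()
    for key, sub in frame.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        seen.add(key)
        vals = sub[value_col].to_numpy(float)
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        if n >= 2 and sd > 0:
            lo, hi = stats.t.interval(confidence, n - 1, loc=mean, scale=sd / np.sqrt(n))
        elif n >= 2:
            lo = hi = mean
        else:
            lo = hi = float("nan")
        cv = sd / mean if n >= 2 and mean != 0 else float("nan")
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n": n,
                "mean": mean,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "cv": float(cv),
                "marker": "",
            }
        )
    for key in expected_groups or []:
        key = key if isinstance(key, tuple) else (key,)
        if key not in seen:
            rows.append(
                dict(zip(group_cols, key))
                | {
                    "n": 0,
                    "mean": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "cv": float("nan"),
                    "marker": "*",
                }
            )
    return pd.DataFrame(rows).sort_values(group_cols).reset_index(drop=True)
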