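"""Synthetic structure and mutation-table generators.

The package is testable without any downloaded structure: this module emits
valid PDB files containing residue pairs on two chains posed so that a
controlled geometric quantity (charged-atom distance, donor-acceptor
distance, donor-hydrogen-acceptor angle) takes a requested value, plus
decoy pairs violating a single named criterion.  Each file ships with its
*planted truth* -- the exact residue-pair bond list a correct detector must
report -- derived from the emitted coordinates by the generator's own
plain-loop bookkeeping (cross-type implications included: a tight ionic
pair whose idealized hydrogens point at the acceptor genuinely is a
hydrogen bond too, and the truth says so).

Residue geometry comes from idealized internal coordinates (standard bond
lengths/angles, extended side chains); no rotamer library, no solvent, no
realistic fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import chemistry
from .detect import DetectionParams, residue_centroid
from .geometry import (
    angle_deg,
    place_internal,
    random_rotation,
    rotation_about_axis,
    unit,
)
from .hydrogens import place_polar_hydrogens
from .structure import Atom, InterfaceSpec, Residue, StructureModel

__all__ = [
    "PlantSpec",
    "TruthBond",
    "PlantedTruth",
    "InfeasibleSpecError",
    "make_pair_complex",
    "min_feasible_dha_angle",
    "make_interface_complex",
    "make_mutation_table",
    "synthetic_barnase_barstar_interface",
    "model_to_pdb",
    "write_fixture_suite",
    "GAS_CONSTANT_KCAL",
]

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)


class InfeasibleSpecError(ValueError):
    """The requested plant geometry cannot be realized."""


# ---------------------------------------------------------------------------
# idealized residue templates (internal-coordinate construction)

# (atom, ref1, ref2, ref3, bond length, bond angle, dihedral); the new atom
# bonds to ref3.  Side chains are extended (chi = 180) with carboxylates,
# amides and guanidinium groups planar.
_SIDE_CHAINS: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, 180.0)],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, 180.0),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, 60.0),
    ],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 114.4, 180.0)],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, 180.0),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, 180.0),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, 60.0),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, 0.0),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, 180.0),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, 180.0),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, 0.0),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, 180.0),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, 0.0),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, 180.0),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, 180.0),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, 0.0),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, 180.0),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.530, 111.3, 180.0),
        ("CE", "CB", "CG", "CD", 1.520, 111.9, 180.0),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, 180.0),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.530, 114.1, 180.0),
        ("CD", "CA", "CB", "CG", 1.530, 111.3, 180.0),
        ("NE", "CB", "CG", "CD", 1.461, 112.0, 180.0),
        ("CZ", "CG", "CD", "NE", 1.329, 124.2, 180.0),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.497, 113.8, 180.0),
        ("ND1", "CA", "CB", "CG", 1.378, 122.7, 0.0),
        ("CD2", "CA", "CB", "CG", 1.356, 131.2, 180.0),
        ("CE1", "CB", "CG", "ND1", 1.326, 109.2, 180.0),
        ("NE2", "CG", "ND1", "CE1", 1.320, 111.7, 0.0),
    ],
}

#: charged side-chain "tip" atom and its heavy neighbour, per residue
_TIPS = {
    "ARG": ("NH1", "CZ"),
    "LYS": ("NZ", "CE"),
    "HIS": ("NE2", "CE1"),
    "ASP": ("OD1", "CG"),
    "GLU": ("OE1", "CD"),
}

#: sp2 NH2 donors usable for hydrogen-bond plants
_NH2_DONORS = {"ASN": "ND2", "GLN": "NE2"}
#: side-chain carbonyl acceptors usable for hydrogen-bond plants
_CO_ACCEPTORS = {"ASN": ("OD1", "CG"), "GLN": ("OE1", "CD")}


def _element_of(name: str) -> str:
    return name[0]


def residue_template(res_name: str) -> dict[str, np.ndarray]:
    """Idealized heavy-atom coordinates of one residue, local frame."""
    if res_name not in _SIDE_CHAINS:
        raise InfeasibleSpecError(f"no idealized template for residue {res_name}")
    coords: dict[str, np.ndarray] = {}
    coords["N"] = np.zeros(3)
    coords["CA"] = np.array([1.458, 0.0, 0.0])
    t = np.radians(180.0 - 111.0)
    coords["C"] = coords["CA"] + 1.525 * np.array([np.cos(t), np.sin(t), 0.0])
    coords["O"] = place_internal(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, 180.0)
    if res_name != "GLY":
        coords["CB"] = place_internal(coords["C"], coords["N"], coords["CA"], 1.530, 110.5, 122.5)
    for name, r1, r2, r3, length, ang, dih in _SIDE_CHAINS[res_name]:
        coords[name] = place_internal(coords[r1], coords[r2], coords[r3], length, ang, dih)
    return coords


def _make_residue(
    res_name: str, chain_id: str, seq: int, coords: dict[str, np.ndarray]
) -> Residue:
    atoms = [
        Atom(serial=0, name=n, element=_element_of(n), coord=np.array(c, float),
             is_hydrogen=_element_of(n) == "H")
        for n, c in coords.items()
    ]
    return Residue(name=res_name, chain_id=chain_id, seq_number=seq, atoms=atoms)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    a, b = unit(a), unit(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        from .geometry import perpendicular

        return rotation_about_axis(perpendicular(a), 180.0)
    v = np.cross(a, b)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _transform_coords(
    coords: dict[str, np.ndarray], R: np.ndarray, t: np.ndarray
) -> dict[str, np.ndarray]:
    return {n: R @ c + t for n, c in coords.items()}


def _orient_tip(
    coords: dict[str, np.ndarray], tip: str, neighbor: str,
    tip_position: np.ndarray, outward: np.ndarray,
) -> dict[str, np.ndarray]:
    """Pose so the neighbour->tip direction equals ``outward`` and the tip
    sits at ``tip_position``."""
    R = _rotation_between(coords[tip] - coords[neighbor], outward)
    moved = _transform_coords(coords, R, np.zeros(3))
    t = np.asarray(tip_position, float) - moved[tip]
    return _transform_coords(moved, np.eye(3), t)


# ---------------------------------------------------------------------------
# planted truth

@dataclass(frozen=True)
class TruthBond:
    bond_type: str
    chain1: str
    seq1: int
    chain2: str
    seq2: int
    distance: float

    def pair(self) -> tuple[str, tuple[str, int], tuple[str, int]]:
        return (self.bond_type, (self.chain1, self.seq1), (self.chain2, self.seq2))


@dataclass
class PlantedTruth:
    """Exact bond list a correct detector must report for one fixture."""

    bonds: list[TruthBond] = field(default_factory=list)

    def pairs(self, bond_type: str | None = None) -> set:
        return {
            b.pair()[1:] for b in self.bonds if bond_type is None or b.bond_type == bond_type
        }

    def by_type(self) -> dict[str, set]:
        return {t: self.pairs(t) for t in ("hydrogen", "ionic", "salt_bridge")}


def _implied_truth(
    model: StructureModel, spec: InterfaceSpec, params: DetectionParams
) -> PlantedTruth:
    """Derive the full bond list from coordinates with plain double loops.

    This is the generator's own bookkeeping, kept deliberately simple: all
    cross-group residue pairs are enumerated and every criterion evaluated
    directly.  Rotatable-hydroxyl donors are not supported here (fixtures
    avoid them).
    """
    with warnings.catch_warnings():
        # single-residue fixture chains have no preceding carbonyl, so the
        # backbone amide H is expectedly unplaceable
        warnings.filterwarnings("ignore", message="could not place hydrogens")
        protonated = place_polar_hydrogens(model)
    g1 = [r for cid in sorted(spec.group1) for r in protonated.chains[cid]]
    g2 = [r for cid in sorted(spec.group2) for r in protonated.chains[cid]]
    truth: list[TruthBond] = []

    for r1 in g1:
        for r2 in g2:
            c1 = chemistry.get_chemistry(r1.name)
            c2 = chemistry.get_chemistry(r2.name)
            # ionic / salt bridge
            if c1.formal_charge * c2.formal_charge < 0:
                a1 = [r1.atom(n).coord for n in sorted(c1.charged_atoms) if r1.atom(n)]
                a2 = [r2.atom(n).coord for n in sorted(c2.charged_atoms) if r2.atom(n)]
                if a1 and a2:
                    dmin = min(float(np.linalg.norm(p - q)) for p in a1 for q in a2)
                    cdist = float(np.linalg.norm(residue_centroid(r1) - residue_centroid(r2)))
                    if cdist < params.ionic_centroid_cutoff and dmin <= params.ionic_atom_cutoff:
                        truth.append(
                            TruthBond("ionic", r1.chain_id, r1.seq_number,
                                      r2.chain_id, r2.seq_number, dmin)
                        )
                    if dmin <= params.salt_cutoff:
                        truth.append(
                            TruthBond("salt_bridge", r1.chain_id, r1.seq_number,
                                      r2.chain_id, r2.seq_number, dmin)
                        )
            # hydrogen bonds, both directions
            best = None
            for donor_res, acc_res in ((r1, r2), (r2, r1)):
                dchem = chemistry.get_chemistry(donor_res.name)
                achem = chemistry.get_chemistry(acc_res.name)
                for dname in sorted(dchem.donor_atoms):
                    if (donor_res.name, dname) in chemistry.ROTATABLE_HYDROXYLS:
                        raise InfeasibleSpecError(
                            "fixtures with rotatable hydroxyl donors are unsupported"
                        )
                    datom = donor_res.atom(dname)
                    if datom is None:
                        continue
                    hs = donor_res.hydrogens_on(dname)
                    for aname, antecedent_names in sorted(achem.acceptor_atoms.items()):
                        aatom = acc_res.atom(aname)
                        if aatom is None:
                            continue
                        da = float(np.linalg.norm(datom.coord - aatom.coord))
                        if da > params.da_cutoff:
                            continue
                        aas = [acc_res.atom(n).coord for n in antecedent_names if acc_res.atom(n)]
                        if any(
                            angle_deg(datom.coord, aatom.coord, aa) < params.antecedent_min_angle
                            for aa in aas
                        ):
                            continue
                        for h in hs:
                            if np.linalg.norm(h.coord - aatom.coord) > params.ha_cutoff:
                                continue
                            if angle_deg(datom.coord, h.coord, aatom.coord) <= params.dha_min_angle:
                                continue
                            if any(
                                angle_deg(h.coord, aatom.coord, aa) < params.antecedent_min_angle
                                for aa in aas
                            ):
                                continue
                            best = da if best is None else min(best, da)
                            break
            if best is not None:
                truth.append(
                    TruthBond("hydrogen", r1.chain_id, r1.seq_number,
                              r2.chain_id, r2.seq_number, best)
                )
    return PlantedTruth(truth)


# ---------------------------------------------------------------------------
# PDB output

def model_to_pdb(model: StructureModel) -> str:
    """Serialize a StructureModel as PDB text (ATOM/TER/END records)."""
    lines = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
                x, y, z = a.coord
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1}{res.name:>3} {chain_id}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1].name:>3} {chain_id}"
                     f"{residues[-1].seq_number:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _quantize(model: StructureModel) -> None:
    """Round coordinates to PDB precision so the emitted text is exact."""
    for res in model.residues():
        for a in res.atoms:
            a.coord = np.round(a.coord, 3)


# ---------------------------------------------------------------------------
# pair posing

@dataclass(frozen=True)
class PlantSpec:
    """Requested geometry for one two-residue plant.

    ``key_distance`` is the controlled distance (charged-atom N...O for
    ionic/salt plants, donor-acceptor for hydrogen plants, in angstroms);
    ``key_angle`` is the D-H-A angle for hydrogen plants (degrees);
    ``violated_criterion`` marks a decoy (bond_type must then be "none"):
    one of charge, salt_distance, ionic_centroid, ionic_atom_distance,
    da_distance, ha_distance, dha_angle, antecedent_angle.
    """

    bond_type: str
    residue_pair: tuple[str, str]
    key_distance: float
    key_angle: float | None = None
    violated_criterion: str | None = None

    def __post_init__(self) -> None:
        if self.bond_type not in ("hydrogen", "ionic", "salt_bridge", "none"):
            raise InfeasibleSpecError(f"unknown bond_type {self.bond_type!r}")
        if (self.violated_criterion is not None) != (self.bond_type == "none"):
            raise InfeasibleSpecError(
                "violated_criterion is required for (and only for) decoy plants"
            )
        if self.key_distance <= 0:
            raise InfeasibleSpecError("key_distance must be positive")


def _roll_into_plane(coords: dict[str, np.ndarray], tip: str) -> dict[str, np.ndarray]:
    """Rotate about the x axis through the tip so the residue centroid lies
    in the xy-plane on the -y side."""
    t = coords[tip]
    c = np.mean(list(coords.values()), axis=0) - t
    r = np.hypot(c[1], c[2])
    if r < 1e-9:
        return coords
    phi = np.degrees(np.arctan2(c[2], c[1]))
    R = rotation_about_axis(np.array([1.0, 0, 0]), 180.0 - phi)
    return {n: R @ (v - t) + t for n, v in coords.items()}


def _tune_separation(
    name_a: str,
    ca: dict[str, np.ndarray],
    name_b: str,
    cb: dict[str, np.ndarray],
    d: float,
) -> dict[str, np.ndarray]:
    """Slide residue B along +x so the minimum charged-atom distance equals
    ``d`` exactly (tilted poses can bring a non-tip charged atom closest)."""

    def shifted(off: float) -> dict[str, np.ndarray]:
        return {n: c + np.array([off, 0.0, 0.0]) for n, c in cb.items()}

    def excess(off: float) -> float:
        return _charged_min_distance(name_a, ca, name_b, shifted(off)) - d

    if abs(excess(0.0)) < 1e-9:
        return cb
    off = float(brentq(excess, -d + 0.1, 6.0, xtol=1e-9))
    return shifted(off)


def _pose_charged_tips(
    name_a: str, name_b: str, d: float, theta: float = 0.0
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Tip-to-tip pose: charged tips on the x axis ``d`` apart, bodies in
    the xy-plane tilted toward -y by ``theta`` degrees (0 = head-on), with
    the separation tuned so the minimum charged-atom distance is ``d``."""
    tip_a, nb_a = _TIPS[name_a]
    tip_b, nb_b = _TIPS[name_b]
    ca = _orient_tip(residue_template(name_a), tip_a, nb_a, np.zeros(3), np.array([1.0, 0, 0]))
    cb = _orient_tip(residue_template(name_b), tip_b, nb_b, np.array([d, 0.0, 0]), np.array([-1.0, 0, 0]))
    ca = _roll_into_plane(ca, tip_a)
    cb = _roll_into_plane(cb, tip_b)
    Ra = rotation_about_axis(np.array([0.0, 0, 1.0]), theta)
    Rb = rotation_about_axis(np.array([0.0, 0, 1.0]), -theta)
    ca = {n: Ra @ c for n, c in ca.items()}
    shift = np.array([d, 0.0, 0])
    cb = {n: Rb @ (c - shift) + shift for n, c in cb.items()}
    cb = _tune_separation(name_a, ca, name_b, cb, d)
    return ca, cb


def _pose_back_to_back(
    name_a: str, name_b: str, lateral: float
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Antiparallel pose with side chains pointing away from each other and
    centroids ``lateral`` angstroms apart: close centroids, distant tips."""
    tip_a, nb_a = _TIPS[name_a]
    tip_b, nb_b = _TIPS[name_b]
    ca = _orient_tip(residue_template(name_a), tip_a, nb_a, np.zeros(3), np.array([1.0, 0, 0]))
    cb = _orient_tip(residue_template(name_b), tip_b, nb_b, np.zeros(3), np.array([-1.0, 0, 0]))
    cen_a = np.mean(list(ca.values()), axis=0)
    cen_b = np.mean(list(cb.values()), axis=0)
    t = cen_a + np.array([0.0, lateral, 0.0]) - cen_b
    cb = {n: c + t for n, c in cb.items()}
    return ca, cb


def _charged_min_distance(
    name_a: str, ca: dict[str, np.ndarray], name_b: str, cb: dict[str, np.ndarray]
) -> float:
    aa = [ca[n] for n in sorted(chemistry.charged_atoms(name_a)) if n in ca]
    bb = [cb[n] for n in sorted(chemistry.charged_atoms(name_b)) if n in cb]
    return min(float(np.linalg.norm(p - q)) for p in aa for q in bb)


def _centroid_distance(ca: dict[str, np.ndarray], cb: dict[str, np.ndarray]) -> float:
    return float(
        np.linalg.norm(np.mean(list(ca.values()), axis=0) - np.mean(list(cb.values()), axis=0))
    )


def _solve_ionic_tilt(
    name_a: str, name_b: str, d: float, target: float, params: DetectionParams
) -> float:
    """Tilt angle bringing the whole-residue centroids to ``target`` (or as
    close as theta=90 allows while staying inside the centroid cutoff)."""

    def cdist(theta: float) -> float:
        return _centroid_distance(*_pose_charged_tips(name_a, name_b, d, theta))

    if cdist(0.0) < target:
        return 0.0
    if cdist(90.0) > target:
        if cdist(90.0) < params.ionic_centroid_cutoff - 0.05:
            return 90.0
        raise InfeasibleSpecError(
            f"cannot bring centroids of {name_a}/{name_b} below the "
            f"{params.ionic_centroid_cutoff} A cutoff at {d} A tip distance"
        )
    return float(brentq(lambda t: cdist(t) - target, 0.0, 90.0, xtol=1e-6))


def _hbond_geometry(d: float, alpha: float) -> tuple[np.ndarray, float]:
    """Acceptor position for donor at origin, donor H at (1,0,0), requested
    D-A distance ``d`` and D-H-A angle ``alpha``; returns (A, |H-A|)."""
    from .hydrogens import NH_LENGTH

    s = np.sin(np.radians(alpha))
    c = np.cos(np.radians(alpha))
    disc = d * d - NH_LENGTH * NH_LENGTH * s * s
    if disc < 0:
        raise InfeasibleSpecError(f"D-H-A angle {alpha} infeasible at D-A distance {d}")
    h_a = NH_LENGTH * c + np.sqrt(disc)
    if h_a <= 0:
        raise InfeasibleSpecError(f"degenerate hydrogen geometry (d={d}, alpha={alpha})")
    A = np.array([NH_LENGTH, 0.0, 0.0]) + h_a * np.array([-c, s, 0.0])
    return A, float(h_a)


def min_feasible_dha_angle(d: float, params: DetectionParams = DetectionParams()) -> float:
    """Smallest D-H-A angle (degrees) at donor-acceptor distance ``d`` for
    which the hydrogen-acceptor distance still meets the H-A cutoff.

    With a 1.0 A donor hydrogen, |H-A| >= d - 1, so no angle is feasible
    beyond d = ha_cutoff + 1 (raises InfeasibleSpecError).
    """

    def excess(alpha: float) -> float:
        return _hbond_geometry(d, alpha)[1] - params.ha_cutoff

    hi = 179.9
    if excess(hi) > 0:
        raise InfeasibleSpecError(
            f"no D-H-A angle satisfies the {params.ha_cutoff} A hydrogen-acceptor "
            f"cutoff at D-A distance {d}"
        )
    lo = params.dha_min_angle + 0.1
    if excess(lo) <= 0:
        return lo
    return float(brentq(excess, lo, hi, xtol=1e-6))


def _pose_hbond_pair(
    donor_name: str, acceptor_name: str, d: float, alpha: float,
    antecedent_angle: float = 180.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Donor sp2-NH2 residue with its first amide hydrogen along +x from the
    donor nitrogen at the origin; acceptor carbonyl placed so the D-A
    distance is ``d``, the D-H-A angle is ``alpha`` and the D-A-antecedent
    angle is ``antecedent_angle``."""
    if donor_name not in _NH2_DONORS or acceptor_name not in _CO_ACCEPTORS:
        raise InfeasibleSpecError(
            f"hydrogen plants need an sp2 NH2 donor ({sorted(_NH2_DONORS)}) and a "
            f"side-chain carbonyl acceptor ({sorted(_CO_ACCEPTORS)})"
        )
    dname = _NH2_DONORS[donor_name]
    res = _make_residue(donor_name, "A", 1, residue_template(donor_name))
    mini = StructureModel("tmp", {"A": [res]})
    placed = place_polar_hydrogens(mini).chains["A"][0]
    hs = placed.hydrogens_on(dname)
    if len(hs) != 2:
        raise InfeasibleSpecError(f"expected 2 amide hydrogens on {donor_name}.{dname}")
    coords = {a.name: np.array(a.coord) for a in placed.atoms if not a.is_hydrogen}
    h1, h2 = hs[0].coord, hs[1].coord
    D = coords[dname]
    f1 = unit(h1 - D)
    v2 = h2 - D
    f2 = -unit(v2 - np.dot(v2, f1) * f1)  # second hydrogen to -y
    f3 = np.cross(f1, f2)
    R = np.vstack([f1, f2, f3])
    donor_coords = {n: R @ (c - D) for n, c in coords.items()}

    A, _ = _hbond_geometry(d, alpha)
    e = unit(A)  # donor N is at the origin
    aname, ante = _CO_ACCEPTORS[acceptor_name]
    # place the antecedent so the D-A-antecedent angle equals the request,
    # swinging the acceptor body out of the donor plane (+z) when bent
    beta = np.radians(antecedent_angle)
    g = np.cos(beta) * (-e) + np.sin(beta) * np.array([0.0, 0.0, 1.0])
    acc_coords = _orient_tip(residue_template(acceptor_name), aname, ante, A, -g)
    return donor_coords, acc_coords


def _pose_plant(
    spec: PlantSpec, params: DetectionParams
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    name_a, name_b = spec.residue_pair
    bt, vc, d = spec.bond_type, spec.violated_criterion, spec.key_distance

    def charges() -> tuple[int, int]:
        return chemistry.formal_charge(name_a), chemistry.formal_charge(name_b)

    if bt == "salt_bridge":
        qa, qb = charges()
        if qa * qb >= 0:
            raise InfeasibleSpecError("salt-bridge plants need oppositely charged residues")
        if d > params.salt_cutoff:
            raise InfeasibleSpecError(f"salt plant distance {d} exceeds {params.salt_cutoff} A")
        return _pose_charged_tips(name_a, name_b, d)

    if bt == "ionic":
        qa, qb = charges()
        if qa * qb >= 0:
            raise InfeasibleSpecError("ionic plants need oppositely charged residues")
        if d > params.ionic_atom_cutoff:
            raise InfeasibleSpecError(f"ionic plant distance {d} exceeds the atom cutoff")
        theta = _solve_ionic_tilt(name_a, name_b, d, params.ionic_centroid_cutoff - 0.5, params)
        return _pose_charged_tips(name_a, name_b, d, theta)

    if bt == "hydrogen":
        alpha = 155.0 if spec.key_angle is None else spec.key_angle
        if d > params.da_cutoff:
            raise InfeasibleSpecError(f"hydrogen plant D-A distance {d} exceeds the cutoff")
        if alpha <= params.dha_min_angle:
            raise InfeasibleSpecError(f"hydrogen plant D-H-A angle {alpha} is not above 90")
        if alpha < min_feasible_dha_angle(d, params) - 1e-9:
            raise InfeasibleSpecError(
                f"D-H-A angle {alpha} puts the hydrogen beyond the "
                f"{params.ha_cutoff} A H-A cutoff at D-A distance {d}"
            )
        return _pose_hbond_pair(name_a, name_b, d, alpha)

    # decoys
    if vc == "charge":
        qa, qb = charges()
        if qa * qb <= 0:
            raise InfeasibleSpecError("charge decoys need like-charged residues")
        return _pose_charged_tips(name_a, name_b, d)
    if vc == "salt_distance":
        if not params.salt_cutoff < d:
            raise InfeasibleSpecError("salt_distance decoy needs distance above the salt cutoff")
        return _pose_charged_tips(name_a, name_b, d)
    if vc == "ionic_centroid":
        if not (params.salt_cutoff < d <= params.ionic_atom_cutoff):
            raise InfeasibleSpecError(
                "ionic_centroid decoy distance must lie between the salt and ionic cutoffs"
            )
        return _pose_charged_tips(name_a, name_b, d)  # theta=0: centroids far apart
    if vc == "ionic_atom_distance":
        return _pose_back_to_back(name_a, name_b, d)
    if vc in ("da_distance", "ha_distance", "dha_angle", "antecedent_angle"):
        alpha = spec.key_angle if spec.key_angle is not None else 155.0
        ante = 60.0 if vc == "antecedent_angle" else 180.0
        return _pose_hbond_pair(name_a, name_b, d, alpha, antecedent_angle=ante)
    raise InfeasibleSpecError(f"unknown violated_criterion {vc!r}")


def _assemble(
    coords_a: dict[str, np.ndarray],
    coords_b: dict[str, np.ndarray],
    spec: PlantSpec,
    rng: np.random.Generator,
    chain1: str = "A",
    chain2: str = "B",
    seq1: int = 1,
    seq2: int = 1,
) -> StructureModel:
    R = random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, 3)
    ca = {n: R @ c + t for n, c in coords_a.items()}
    cb = {n: R @ c + t for n, c in coords_b.items()}
    model = StructureModel(
        "synthetic",
        {
            chain1: [_make_residue(spec.residue_pair[0], chain1, seq1, ca)],
            chain2: [_make_residue(spec.residue_pair[1], chain2, seq2, cb)],
        },
    )
    _quantize(model)
    return model


def _expected_pair_truth(spec: PlantSpec, truth: PlantedTruth, where: str) -> None:
    if spec.bond_type == "none":
        if truth.bonds:
            raise InfeasibleSpecError(
                f"decoy {spec.violated_criterion} still produces bonds: {truth.bonds} ({where})"
            )
    else:
        if not truth.pairs(spec.bond_type):
            raise InfeasibleSpecError(
                f"planted {spec.bond_type} bond missing from implied truth ({where})"
            )


def make_pair_complex(
    spec: PlantSpec,
    seed: int,
    params: DetectionParams = DetectionParams(),
    chain1: str = "A",
    chain2: str = "B",
    seq1: int = 1,
    seq2: int = 1,
) -> tuple[str, PlantedTruth]:
    """One residue per chain, posed per ``spec``; returns (PDB text, truth).

    Deterministic per seed; the controlled quantity is exact to PDB
    coordinate precision (0.01 A / 0.5 degrees after rounding).
    """
    rng = np.random.default_rng(seed)
    ca, cb = _pose_plant(spec, params)
    model = _assemble(ca, cb, spec, rng, chain1, chain2, seq1, seq2)
    ispec = InterfaceSpec(frozenset({chain1}), frozenset({chain2}))
    truth = _implied_truth(model, ispec, params)
    _expected_pair_truth(spec, truth, f"seed={seed}")
    return model_to_pdb(model), truth


def make_interface_complex(
    n_pairs: int,
    bond_mix: dict[str, float] | None = None,
    seed: int = 0,
    params: DetectionParams = DetectionParams(),
) -> tuple[str, PlantedTruth]:
    """Multi-residue two-chain complex with ``n_pairs`` planted interactions
    spaced far enough apart (>= 12 A between plant envelopes) that plants
    cannot interact across sites."""
    if n_pairs < 1:
        raise InfeasibleSpecError("n_pairs must be >= 1")
    mix = bond_mix or {"hydrogen": 1.0, "ionic": 1.0, "salt_bridge": 1.0}
    total = sum(mix.values())
    if total <= 0:
        raise InfeasibleSpecError("bond_mix proportions must sum to a positive value")
    rng = np.random.default_rng(seed)
    types = sorted(mix)
    counts = {t: int(round(mix[t] / total * n_pairs)) for t in types}
    while sum(counts.values()) < n_pairs:
        counts[types[sum(counts.values()) % len(types)]] += 1
    while sum(counts.values()) > n_pairs:
        t = max(types, key=lambda t: counts[t])
        counts[t] -= 1
    schedule = [t for t in types for _ in range(counts[t])]

    residues_a: list[Residue] = []
    residues_b: list[Residue] = []
    z = 0.0
    prev_radius = 0.0
    for k, bond_type in enumerate(schedule, start=1):
        if bond_type == "hydrogen":
            d = float(rng.uniform(2.7, 3.4))
            alpha_lo = max(min_feasible_dha_angle(d, params) + 3.0, 100.0)
            spec = PlantSpec("hydrogen", ("ASN", "GLN"), d,
                             float(rng.uniform(alpha_lo, 175.0)))
        elif bond_type == "ionic":
            spec = PlantSpec("ionic", ("LYS", "ASP"), float(rng.uniform(2.9, 4.4)))
        else:
            spec = PlantSpec("salt_bridge", ("LYS", "ASP"), float(rng.uniform(2.9, 3.9)))
        ca, cb = _pose_plant(spec, params)
        R = random_rotation(rng)
        ca = {n: R @ c for n, c in ca.items()}
        cb = {n: R @ c for n, c in cb.items()}
        radius = max(
            float(np.linalg.norm(c)) for c in list(ca.values()) + list(cb.values())
        )
        if k > 1:
            z += prev_radius + radius + 12.0
        site = np.array([0.0, 0.0, z])
        prev_radius = radius
        residues_a.append(
            _make_residue(spec.residue_pair[0], "A", k, {n: c + site for n, c in ca.items()})
        )
        residues_b.append(
            _make_residue(spec.residue_pair[1], "B", k, {n: c + site for n, c in cb.items()})
        )

    model = StructureModel("synthetic", {"A": residues_a, "B": residues_b})
    _quantize(model)
    ispec = InterfaceSpec(frozenset({"A"}), frozenset({"B"}))
    truth = _implied_truth(model, ispec, params)
    for k, bond_type in enumerate(schedule, start=1):
        if (("A", k), ("B", k)) not in truth.pairs(bond_type):
            raise InfeasibleSpecError(f"planted {bond_type} bond at site {k} not realized")
    for b in truth.bonds:
        if b.seq1 != b.seq2:
            raise InfeasibleSpecError("cross-site bond violates plant spacing")
    return model_to_pdb(model), truth


# ---------------------------------------------------------------------------
# synthetic worked example

def synthetic_barnase_barstar_interface() -> tuple[str, PlantedTruth]:
    """Synthetic reconstruction of the barnase Arg59 / barstar Glu76
    salt-bridge geometry (chains A and D, guanidinium-to-carboxylate
    N...O below 4 A).  This is an idealized stand-in built from templates,
    not the crystal structure."""
    spec = PlantSpec("salt_bridge", ("ARG", "GLU"), 2.95)
    return make_pair_complex(spec, seed=1905, chain1="A", chain2="D", seq1=59, seq2=76)


# ---------------------------------------------------------------------------
# synthetic mutation tables

#: like-for-like substitutions preserving the side-chain chemistry class
_LIKE_SWAP = {"LYS": "ARG", "ARG": "LYS", "HIS": "ARG", "ASP": "GLU",
              "GLU": "ASP", "ASN": "GLN", "GLN": "ASN", "SER": "THR", "THR": "SER"}
_AA_3TO1 = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
            "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
            "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
            "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}


def make_mutation_table(
    n_mutations: int,
    effect_model: str = "broken_high_ddg",
    seed: int = 0,
    shift: float = 1.5,
    baseline_ddg: float = 0.5,
    sigma: float = 0.75,
    temperature: float = 298.15,
    sites: list[tuple[str, int, str]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Affinity table with a planted bond-effect structure.

    Under ``broken_high_ddg`` the ddG of bond-breaking mutations is drawn
    ``shift`` kcal/mol (default +1.5) above bond-preserving ones; under
    ``null`` both groups share the same distribution.  Wild-type Kd is
    1e-9 M and mutant Kd is back-computed from the drawn ddG at the stated
    temperature.  Returns (table, labels) with labels in
    {"broken", "intact"}; bond-breaking rows mutate a charged residue to
    ALA, bond-preserving rows swap it for the like-charged residue.

    When ``sites`` is given (list of (chain, position, wild-type 3-letter
    code), e.g. taken from a planted fixture structure), mutations cycle
    through those sites so the table lines up with the structure.
    """
    if n_mutations < 2:
        raise ValueError("n_mutations must be >= 2")
    if effect_model not in ("broken_high_ddg", "null"):
        raise ValueError(f"unknown effect_model {effect_model!r}")
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(n_mutations) < 0.5, "broken", "intact")
    ddg = rng.normal(baseline_ddg, sigma, n_mutations)
    if effect_model == "broken_high_ddg":
        ddg = ddg + shift * (labels == "broken")
    keq_wt = 1e-9
    keq_mut = keq_wt * np.exp(ddg / (GAS_CONSTANT_KCAL * temperature))
    complexes = np.where(np.arange(n_mutations) % 2 == 0, "SYN1", "SYN2")
    chains, codes = [], []
    if sites is None:
        wt = np.where(labels == "broken", "K", rng.choice(["K", "R"], n_mutations))
        mut = np.where(labels == "broken", "A", np.where(wt == "K", "R", "K"))
        for i, (w, m) in enumerate(zip(wt, mut)):
            chains.append("A")
            codes.append(f"{w}A{100 + i}{m}")
    else:
        for i, label in enumerate(labels):
            chain, pos, wt3 = sites[i % len(sites)]
            mut3 = "ALA" if label == "broken" else _LIKE_SWAP.get(wt3, wt3)
            chains.append(chain)
            codes.append(f"{_AA_3TO1[wt3]}{chain}{pos}{_AA_3TO1[mut3]}")
    rows = {
        "complex_id": complexes,
        "chain": chains,
        "mutation": codes,
        "keq_wt": np.full(n_mutations, keq_wt),
        "keq_mut": keq_mut,
        "temperature": np.full(n_mutations, temperature),
    }
    return pd.DataFrame(rows), labels


# ---------------------------------------------------------------------------
# fixture suite for the CLI

def write_fixture_suite(outdir, seed: int = 0) -> list[str]:
    """Materialize a small fixture suite (PDBs + truth tables + mutation
    table) into ``outdir``; returns the file names written."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cases = {
        "salt_bridge_pair": PlantSpec("salt_bridge", ("LYS", "ASP"), 3.2),
        "ionic_pair": PlantSpec("ionic", ("LYS", "ASP"), 3.6),
        "hydrogen_pair": PlantSpec("hydrogen", ("ASN", "GLN"), 2.9, 155.0),
        "decoy_salt_distance": PlantSpec("none", ("ARG", "GLU"), 4.5,
                                         violated_criterion="salt_distance"),
        "decoy_like_charge": PlantSpec("none", ("ARG", "LYS"), 3.0,
                                       violated_criterion="charge"),
    }
    for stem, spec in cases.items():
        pdb, truth = make_pair_complex(spec, seed)
        (outdir / f"{stem}.pdb").write_text(pdb)
        (outdir / f"{stem}.truth.json").write_text(
            json.dumps([b.__dict__ for b in truth.bonds], indent=1) + "\n"
        )
        written += [f"{stem}.pdb", f"{stem}.truth.json"]

    pdb, truth = make_interface_complex(6, seed=seed)
    (outdir / "interface_complex.pdb").write_text(pdb)
    (outdir / "interface_complex.truth.json").write_text(
        json.dumps([b.__dict__ for b in truth.bonds], indent=1) + "\n"
    )
    written += ["interface_complex.pdb", "interface_complex.truth.json"]

    from .structure import parse_pdb

    complex_model = parse_pdb(pdb)
    sites = [(r.chain_id, r.seq_number, r.name) for r in complex_model.chains["A"]]
    table, labels = make_mutation_table(60, seed=seed, sites=sites)
    table.assign(planted_label=labels).to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    written.append("mutations.tsv")
    return written
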