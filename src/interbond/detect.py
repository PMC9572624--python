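"""Intermolecular bond detectors.

Three independent geometric detectors operate on residue pairs that span
the interface (one residue from each chain group):

* **hydrogen bonds** -- donor D within 3.9 A of acceptor A, a donor
  hydrogen within 2.5 A of A, D-H-A angle strictly greater than 90
  degrees, and both the D-A-antecedent and H-A-antecedent angles at least
  90 degrees for every antecedent of the acceptor;
* **ionic bonds** -- oppositely charged residues with centroid distance
  strictly below the cutoff (5 A by default; 7.5 and 10 A variants) whose
  charged side-chain atoms (N on basic, O on acidic residues) also come
  within the cutoff;
* **salt bridges** -- oppositely charged residues whose side-chain charged
  N...O atoms come within 4 A; no centroid requirement.

Boundary semantics: the centroid test is strict ``<``; atom-distance and
angle-minimum tests are inclusive; the D-H-A test is strict ``>``.

The default candidate search uses a k-d tree with the relevant cutoff; the
``backend="brute"`` path enumerates all cross-group pairs.  The two are
exactly equivalent -- the tree is an invisible optimization, and the brute
path doubles as the reference implementation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry
from .geometry import angle_deg, rotation_about_axis, unit
from .hydrogens import place_polar_hydrogens
from .structure import InterfaceSpec, Residue, ResidueId, StructureModel, select_interface

__all__ = [
    "BondRecord",
    "DetectionParams",
    "BOND_TYPES",
    "residue_centroid",
    "find_hydrogen_bonds",
    "find_ionic_bonds",
    "find_salt_bridges",
    "detect_all",
]

BOND_TYPES = ("hydrogen", "ionic", "salt_bridge")


@dataclass(frozen=True)
class DetectionParams:
    """Geometric cutoffs of the three detectors (angstroms / degrees)."""

    da_cutoff: float = 3.9
    ha_cutoff: float = 2.5
    dha_min_angle: float = 90.0  # exclusive
    antecedent_min_angle: float = 90.0  # inclusive
    ionic_centroid_cutoff: float = 5.0  # exclusive; 7.5 and 10.0 variants
    ionic_atom_cutoff: float | None = None  # defaults to the centroid cutoff
    salt_cutoff: float = 4.0  # inclusive
    hydroxyl_step_deg: float = 10.0

    def __post_init__(self) -> None:
        for name in ("da_cutoff", "ha_cutoff", "ionic_centroid_cutoff", "salt_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ionic_atom_cutoff is None:
            object.__setattr__(self, "ionic_atom_cutoff", self.ionic_centroid_cutoff)
        if self.salt_cutoff > self.ionic_atom_cutoff:
            warnings.warn(
                "salt_cutoff exceeds ionic_atom_cutoff; salt bridges will not "
                "be a subset of ionic charged-atom contacts",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BondRecord:
    """One detected intermolecular interaction.

    ``res1`` always belongs to interface group 1 and ``res2`` to group 2;
    ``atom1``/``atom2`` are the atoms on ``res1``/``res2`` realizing the
    bond (donor/acceptor for hydrogen bonds, the closest charged N/O pair
    otherwise).
    """

    bond_type: str
    res1: ResidueId
    res2: ResidueId
    atom1: str
    atom2: str
    distance: float
    dha_angle: float | None = None
    centroid_distance: float | None = None
    donor_is_res1: bool | None = None

    def pair_key(self) -> frozenset:
        return frozenset((self.res1[:3], self.res2[:3]))


def residue_centroid(residue: Residue) -> np.ndarray:
    """Unweighted mean of the residue's heavy-atom coordinates."""
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.id.label()} has no heavy atoms")
    return np.mean([a.coord for a in heavy], axis=0)


# ---------------------------------------------------------------------------
# charged-residue bookkeeping shared by the ionic and salt-bridge detectors

@dataclass
class _ChargedResidue:
    residue: Residue
    charge: int
    atom_names: list[str]
    atom_coords: np.ndarray  # (n, 3)
    centroid: np.ndarray


def _charged_residues(residues: Iterable[Residue]) -> list[_ChargedResidue]:
    out = []
    for res in residues:
        try:
            chem = chemistry.get_chemistry(res.name)
        except chemistry.UnrecognizedResidueError:
            continue
        if chem.formal_charge == 0:
            continue
        names, coords = [], []
        for name in sorted(chem.charged_atoms):
            a = res.atom(name)
            if a is not None:
                names.append(name)
                coords.append(a.coord)
        if not names:
            warnings.warn(
                f"residue {res.id.label()} is charged but its side-chain "
                "charged atoms are missing; skipped by ionic/salt detectors",
                stacklevel=3,
            )
            continue
        out.append(
            _ChargedResidue(res, chem.formal_charge, names, np.array(coords), residue_centroid(res))
        )
    return out


def _closest_atom_pair(a: _ChargedResidue, b: _ChargedResidue) -> tuple[str, str, float]:
    diff = a.atom_coords[:, None, :] - b.atom_coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return a.atom_names[i], b.atom_names[j], float(d[i, j])


def _charged_pair_candidates(
    g1: list[_ChargedResidue],
    g2: list[_ChargedResidue],
    radius: float,
    mode: str,
    backend: str,
) -> set[tuple[int, int]]:
    """Index pairs (i, j) whose centroids (mode='centroid') or whose charged
    atoms (mode='atom') come within ``radius``."""
    if not g1 or not g2:
        return set()
    if backend == "brute":
        return {(i, j) for i in range(len(g1)) for j in range(len(g2))}
    if mode == "centroid":
        t1 = cKDTree(np.array([c.centroid for c in g1]))
        t2 = cKDTree(np.array([c.centroid for c in g2]))
        return {(i, j) for i, js in enumerate(t1.query_ball_tree(t2, radius)) for j in js}
    pts1, idx1 = [], []
    for i, c in enumerate(g1):
        pts1.extend(c.atom_coords)
        idx1.extend([i] * len(c.atom_coords))
    pts2, idx2 = [], []
    for j, c in enumerate(g2):
        pts2.extend(c.atom_coords)
        idx2.extend([j] * len(c.atom_coords))
    t1, t2 = cKDTree(np.array(pts1)), cKDTree(np.array(pts2))
    pairs = set()
    for k, ms in enumerate(t1.query_ball_tree(t2, radius)):
        for m in ms:
            pairs.add((idx1[k], idx2[m]))
    return pairs


def find_ionic_bonds(
    model: StructureModel,
    spec: InterfaceSpec,
    params: DetectionParams = DetectionParams(),
    backend: str = "grid",
) -> list[BondRecord]:
    """Oppositely charged cross-interface residue pairs passing both the
    centroid (< cutoff) and charged-atom (<= cutoff) distance tests."""
    r1, r2 = select_interface(model, spec)
    g1, g2 = _charged_residues(r1), _charged_residues(r2)
    candidates = _charged_pair_candidates(
        g1, g2, params.ionic_centroid_cutoff, "centroid", backend
    )
    bonds = []
    for i, j in sorted(candidates):
        a, b = g1[i], g2[j]
        if a.charge * b.charge >= 0:
            continue
        cdist = float(np.linalg.norm(a.centroid - b.centroid))
        if not cdist < params.ionic_centroid_cutoff:
            continue
        n1, n2, dmin = _closest_atom_pair(a, b)
        if dmin <= params.ionic_atom_cutoff:
            bonds.append(
                BondRecord(
                    "ionic", a.residue.id, b.residue.id, n1, n2, dmin,
                    centroid_distance=cdist,
                )
            )
    return bonds


def find_salt_bridges(
    model: StructureModel,
    spec: InterfaceSpec,
    params: DetectionParams = DetectionParams(),
    backend: str = "grid",
) -> list[BondRecord]:
    """Oppositely charged cross-interface residue pairs whose side-chain
    charged N...O atoms come within the salt cutoff (4 A by default)."""
    r1, r2 = select_interface(model, spec)
    g1, g2 = _charged_residues(r1), _charged_residues(r2)
    candidates = _charged_pair_candidates(g1, g2, params.salt_cutoff, "atom", backend)
    bonds = []
    for i, j in sorted(candidates):
        a, b = g1[i], g2[j]
        if a.charge * b.charge >= 0:
            continue
        n1, n2, dmin = _closest_atom_pair(a, b)
        if dmin <= params.salt_cutoff:
            bonds.append(BondRecord("salt_bridge", a.residue.id, b.residue.id, n1, n2, dmin))
    return bonds


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class _Donor:
    residue: Residue
    name: str
    coord: np.ndarray
    hydrogens: list[np.ndarray]
    rotamer_axis: tuple[np.ndarray, np.ndarray] | None  # (parent, donor) for sampling


@dataclass
class _Acceptor:
    residue: Residue
    name: str
    coord: np.ndarray
    antecedents: list[np.ndarray]


def _collect_donors(residues: Iterable[Residue], params: DetectionParams) -> list[_Donor]:
    out = []
    for res in residues:
        try:
            chem = chemistry.get_chemistry(res.name)
        except chemistry.UnrecognizedResidueError:
            continue
        for name in sorted(chem.donor_atoms):
            heavy = res.atom(name)
            if heavy is None:
                continue
            hs = res.hydrogens_on(name)
            if not hs:
                continue
            axis = None
            if (res.name, name) in chemistry.ROTATABLE_HYDROXYLS and all(
                h.auto_placed for h in hs
            ):
                antecedent = chem.acceptor_atoms.get(name)
                parent = res.atom(antecedent[0]) if antecedent else None
                if parent is not None:
                    axis = (parent.coord, heavy.coord)
            out.append(_Donor(res, name, heavy.coord, [h.coord for h in hs], axis))
    return out


def _collect_acceptors(residues: Iterable[Residue]) -> list[_Acceptor]:
    out = []
    for res in residues:
        try:
            chem = chemistry.get_chemistry(res.name)
        except chemistry.UnrecognizedResidueError:
            continue
        for name, antecedent_names in sorted(chem.acceptor_atoms.items()):
            atom = res.atom(name)
            if atom is None:
                continue
            antecedents = [
                res.atom(an).coord for an in antecedent_names if res.atom(an) is not None
            ]
            out.append(_Acceptor(res, name, atom.coord, antecedents))
    return out


def _hydrogen_positions(donor: _Donor, params: DetectionParams) -> list[np.ndarray]:
    """Hydrogen candidates; rotatable hydroxyls are sampled about the
    parent->donor axis in ``hydroxyl_step_deg`` increments."""
    if donor.rotamer_axis is None:
        return donor.hydrogens
    parent, center = donor.rotamer_axis
    axis = unit(center - parent)
    positions = []
    h0 = donor.hydrogens[0]
    steps = int(round(360.0 / params.hydroxyl_step_deg))
    for k in range(steps):
        rot = rotation_about_axis(axis, k * params.hydroxyl_step_deg)
        positions.append(center + rot @ (h0 - center))
    return positions


def _best_dha(
    donor: _Donor, acceptor: _Acceptor, params: DetectionParams
) -> float | None:
    """Largest qualifying D-H-A angle over the donor's hydrogens, or None."""
    best = None
    for h in _hydrogen_positions(donor, params):
        if np.linalg.norm(h - acceptor.coord) > params.ha_cutoff:
            continue
        dha = angle_deg(donor.coord, h, acceptor.coord)
        if not dha > params.dha_min_angle:
            continue
        ok = True
        for aa in acceptor.antecedents:
            if angle_deg(h, acceptor.coord, aa) < params.antecedent_min_angle:
                ok = False
                break
        if ok and (best is None or dha > best):
            best = dha
    return best


def _covalent_separation_ok(donor: _Donor, acceptor: _Acceptor) -> bool:
    # Donor and acceptor must be at least three covalent bonds apart.  Across
    # the interface the residues sit on different chains, so this is always
    # true; the guard only excludes the degenerate same-residue case.
    return donor.residue is not acceptor.residue


def _hbond_pairs(
    donors: list[_Donor],
    acceptors: list[_Acceptor],
    params: DetectionParams,
    backend: str,
) -> Iterable[tuple[_Donor, _Acceptor]]:
    if backend == "brute" or not donors or not acceptors:
        for d in donors:
            for a in acceptors:
                yield d, a
        return
    tree = cKDTree(np.array([a.coord for a in acceptors]))
    for d in donors:
        for j in sorted(tree.query_ball_point(d.coord, params.da_cutoff)):
            yield d, acceptors[j]


def find_hydrogen_bonds(
    model: StructureModel,
    spec: InterfaceSpec,
    params: DetectionParams = DetectionParams(),
    backend: str = "grid",
) -> list[BondRecord]:
    """Cross-interface donor/acceptor pairs satisfying all hydrogen-bond
    criteria; one record per (donor atom, acceptor atom) pair keeping the
    best D-H-A angle.  Missing polar hydrogens are placed first."""
    protonated = place_polar_hydrogens(model)
    r1, r2 = select_interface(protonated, spec)
    bonds: list[BondRecord] = []
    for donors, acceptors, donor_first in (
        (_collect_donors(r1, params), _collect_acceptors(r2), True),
        (_collect_donors(r2, params), _collect_acceptors(r1), False),
    ):
        for d, a in _hbond_pairs(donors, acceptors, params, backend):
            if not _covalent_separation_ok(d, a):
                continue
            dist = float(np.linalg.norm(d.coord - a.coord))
            if dist > params.da_cutoff:
                continue
            ok_da = all(
                angle_deg(d.coord, a.coord, aa) >= params.antecedent_min_angle
                for aa in a.antecedents
            )
            if not ok_da:
                continue
            dha = _best_dha(d, a, params)
            if dha is None:
                continue
            if donor_first:
                bonds.append(
                    BondRecord(
                        "hydrogen", d.residue.id, a.residue.id, d.name, a.name,
                        dist, dha_angle=dha, donor_is_res1=True,
                    )
                )
            else:
                bonds.append(
                    BondRecord(
                        "hydrogen", a.residue.id, d.residue.id, a.name, d.name,
                        dist, dha_angle=dha, donor_is_res1=False,
                    )
                )
    return bonds


def detect_all(
    model: StructureModel,
    spec: InterfaceSpec,
    params: DetectionParams = DetectionParams(),
    backend: str = "grid",
) -> dict[str, list[BondRecord]]:
    """Run the three detectors independently and return their outputs keyed
    by bond type.  The detectors share no state."""
    return {
        "hydrogen": find_hydrogen_bonds(model, spec, params, backend),
        "ionic": find_ionic_bonds(model, spec, params, backend),
        "salt_bridge": find_salt_bridges(model, spec, params, backend),
    }
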