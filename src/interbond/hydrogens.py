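"""Idealized placement of polar hydrogens on donor atoms.

Crystal structures usually lack hydrogens, but the hydrogen-bond criteria
are defined on the donor hydrogen.  Missing polar hydrogens are therefore
added at 1.0 angstrom bond length with idealized geometry:

* backbone amide H in the C-N-CA plane, opposite the bisector of the two
  heavy-atom bonds (requires the preceding residue's carbonyl C);
* sp2 ring/secondary-amine NH (HIS ND1/NE2, TRP NE1, ARG NE) along the
  in-plane bisector of the two ring/chain bonds;
* sp2 NH2 (ARG NH1/NH2, ASN ND2, GLN NE2) planar, 120 degree H-N-H;
* sp3 NH3 (LYS NZ) staggered with respect to the CD-CE bond;
* hydroxyls/thiols (SER OG, THR OG1, TYR OH, CYS SG) placed at an arbitrary
  dihedral and marked rotatable -- the hydrogen-bond detector samples their
  dihedral instead of trusting the placed position.

Pre-existing hydrogens are kept untouched; donors whose geometry-defining
heavy neighbours are missing are skipped with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import chemistry
from .geometry import place_internal, perpendicular, unit
from .structure import Residue, StructureModel

__all__ = ["place_polar_hydrogens"]

NH_LENGTH = 1.0  # angstrom, all placed polar hydrogens

#: sp2 NH2 groups: donor -> (parent, atom defining the plane through parent)
_SP2_NH2 = {
    ("ARG", "NH1"): ("CZ", "NE"),
    ("ARG", "NH2"): ("CZ", "NE"),
    ("ASN", "ND2"): ("CG", "OD1"),
    ("GLN", "NE2"): ("CD", "OE1"),
}

#: secondary sp2 NH: donor -> its two heavy neighbours
_SP2_NH = {
    ("ARG", "NE"): ("CD", "CZ"),
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
}

#: hydroxyl/thiol: donor -> (parent, reference for the dihedral, H-O-parent angle)
_HYDROXYL = {
    ("SER", "OG"): ("CB", "CA", 109.5),
    ("THR", "OG1"): ("CB", "CA", 109.5),
    ("TYR", "OH"): ("CZ", "CE1", 113.0),
    ("CYS", "SG"): ("CB", "CA", 96.0),
}


def _add_h(res: Residue, name: str, coord: np.ndarray, rotatable: bool = False) -> None:
    from .structure import Atom

    res.atoms.append(
        Atom(
            serial=0,
            name=name,
            element="H",
            coord=np.asarray(coord, float),
            is_hydrogen=True,
            auto_placed=True,
            rotatable=rotatable,
        )
    )


def _preceding_carbonyl(chain: list[Residue], res: Residue) -> np.ndarray | None:
    """Carbonyl C of the peptide bond preceding ``res`` (within 1.7 A of N)."""
    n = res.atom("N")
    if n is None:
        return None
    for other in chain:
        if other is res:
            continue
        c = other.atom("C")
        if c is not None and np.linalg.norm(c.coord - n.coord) <= 1.7:
            return c.coord
    return None


def _place_backbone_h(chain: list[Residue], res: Residue) -> bool:
    n = res.atom("N")
    ca = res.atom("CA")
    c_prev = _preceding_carbonyl(chain, res)
    if n is None or ca is None or c_prev is None:
        return False
    direction = unit(unit(n.coord - c_prev) + unit(n.coord - ca.coord))
    _add_h(res, "H", n.coord + NH_LENGTH * direction)
    return True


def _place_sp2_nh(res: Residue, donor: str, n1: str, n2: str) -> bool:
    d, a1, a2 = res.atom(donor), res.atom(n1), res.atom(n2)
    if d is None or a1 is None or a2 is None:
        return False
    direction = unit(unit(d.coord - a1.coord) + unit(d.coord - a2.coord))
    _add_h(res, "H" + donor[1:], d.coord + NH_LENGTH * direction)
    return True


def _place_sp2_nh2(res: Residue, donor: str, parent: str, plane_ref: str) -> bool:
    d, p, q = res.atom(donor), res.atom(parent), res.atom(plane_ref)
    if d is None or p is None or q is None:
        return False
    a = unit(d.coord - p.coord)
    v = q.coord - p.coord
    m = v - np.dot(v, a) * a
    m = perpendicular(a) if np.linalg.norm(m) < 1e-6 else unit(m)
    cos60, sin60 = np.cos(np.radians(60.0)), np.sin(np.radians(60.0))
    for i, sign in enumerate((1.0, -1.0), start=1):
        direction = cos60 * a + sign * sin60 * m
        _add_h(res, f"H{donor[1:]}{i}"[:4], d.coord + NH_LENGTH * direction)
    return True


def _place_sp3_nh3(res: Residue, donor: str, parent: str, ref: str) -> bool:
    d, p, q = res.atom(donor), res.atom(parent), res.atom(ref)
    if d is None or p is None or q is None:
        return False
    for i, dihedral in enumerate((60.0, 180.0, 300.0), start=1):
        h = place_internal(q.coord, p.coord, d.coord, NH_LENGTH, 109.5, dihedral)
        _add_h(res, f"H{donor[1:]}{i}"[:4], h)
    return True


def _place_hydroxyl(res: Residue, donor: str, parent: str, ref: str, angle: float) -> bool:
    d, p, q = res.atom(donor), res.atom(parent), res.atom(ref)
    if d is None or p is None or q is None:
        return False
    h = place_internal(q.coord, p.coord, d.coord, NH_LENGTH, angle, 180.0)
    _add_h(res, "H" + donor[1:], h, rotatable=True)
    return True


def place_polar_hydrogens(model: StructureModel) -> StructureModel:
    """Return a copy of ``model`` with missing polar hydrogens added.

    Donors that already carry at least one hydrogen are left untouched.
    Unplaceable donors (missing geometric neighbours, e.g. the backbone N
    of a chain-initial residue) are skipped with a warning.
    """
    out = model.copy()
    unplaceable: list[str] = []
    for chain_id, chain in out.chains.items():
        for res in chain:
            try:
                chem = chemistry.get_chemistry(res.name)
            except chemistry.UnrecognizedResidueError:
                continue
            for donor in sorted(chem.donor_atoms):
                heavy = res.atom(donor)
                if heavy is None:
                    continue
                if res.hydrogens_on(donor):
                    continue  # keep pre-existing hydrogens
                key = (res.name, donor)
                if donor == "N":
                    ok = _place_backbone_h(chain, res)
                elif key in _SP2_NH:
                    ok = _place_sp2_nh(res, donor, *_SP2_NH[key])
                elif key in _SP2_NH2:
                    ok = _place_sp2_nh2(res, donor, *_SP2_NH2[key])
                elif key == ("LYS", "NZ"):
                    ok = _place_sp3_nh3(res, "NZ", "CE", "CD")
                elif key in _HYDROXYL:
                    ok = _place_hydroxyl(res, donor, *_HYDROXYL[key])
                else:
                    ok = False
                if not ok:
                    unplaceable.append(f"{res.id.label()}.{donor}")
    if unplaceable:
        warnings.warn(
            f"could not place hydrogens on donors: {unplaceable}", stacklevel=2
        )
    return out
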