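"""Bond detectors: hand-constructed geometric oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import interbond as ib
from interbond import DetectionParams, InterfaceSpec
from interbond.detect import find_hydrogen_bonds, find_ionic_bonds, find_salt_bridges
from interbond.geometry import angle_deg
from interbond.structure import parse_pdb
from interbond.synthetic import (
    PlantSpec,
    _centroid_distance,
    _pose_charged_tips,
    make_interface_complex,
    make_pair_complex,
    _make_residue,
)

from conftest import build_model, build_residue, detected_pairs


# ---------------------------------------------------------------------------
# hydrogen-bond criteria on hand-built coordinates

def _hbond_model(d, alpha, antecedent_angle=180.0, acceptor_chain="B"):
    """Donor backbone N-H (chain A) and acceptor carbonyl O (chain B) with
    exact D-A distance, D-H-A angle and D-A-antecedent angle.

    The construction is the independent oracle: every criterion can be
    recomputed from the placed points directly.
    """
    D = np.zeros(3)
    H = np.array([1.0, 0.0, 0.0])
    h = np.cos(np.radians(alpha)) + np.sqrt(
        d * d - np.sin(np.radians(alpha)) ** 2
    )
    w = np.array([-np.cos(np.radians(alpha)), np.sin(np.radians(alpha)), 0.0])
    A = H + h * w
    beta = np.radians(antecedent_angle)
    e = A / np.linalg.norm(A)
    g = np.cos(beta) * (-e) + np.sin(beta) * np.array([0.0, 0.0, 1.0])
    C = A + 1.231 * g
    donor = build_residue(
        "GLY", "A", 1,
        {"N": D, "CA": (-1.0, -1.0, 0.0), "C": (-2.4, -1.2, 0.0), "O": (-2.9, -2.3, 0.0)},
        hydrogens=[("H", H)],
    )
    acceptor = build_residue(
        "GLY", acceptor_chain, 1 if acceptor_chain != "A" else 2,
        {"O": A, "C": C, "CA": C + 1.4 * g, "N": C + 2.6 * g},
    )
    return build_model(donor, acceptor), (D, H, A, C)


def test_hydrogen_bond_good_geometry_detected(spec_ab, params):
    model, (D, H, A, C) = _hbond_model(2.9, 160.0)
    # sanity-check the oracle geometry itself
    assert np.linalg.norm(D - A) == pytest.approx(2.9, abs=1e-9)
    assert angle_deg(D, H, A) == pytest.approx(160.0, abs=1e-9)
    assert np.linalg.norm(H - A) <= 2.5
    assert angle_deg(D, A, C) == pytest.approx(180.0, abs=1e-6)
    bonds = find_hydrogen_bonds(model, spec_ab, params)
    assert len(bonds) == 1
    b = bonds[0]
    assert (b.atom1, b.atom2) == ("N", "O")
    assert b.distance == pytest.approx(2.9, abs=1e-6)
    assert b.dha_angle == pytest.approx(160.0, abs=1e-6)


@pytest.mark.parametrize(
    "d,alpha,antecedent",
    [
        (4.5, 160.0, 180.0),  # D-A beyond 3.9
        (3.5, 100.0, 180.0),  # H-A beyond 2.5 (D-A and angle both pass)
        (2.5, 85.0, 180.0),  # D-H-A not above 90 (distances pass)
        (2.9, 160.0, 60.0),  # antecedent angle below 90
    ],
)
def test_hydrogen_bond_single_criterion_violations(spec_ab, params, d, alpha, antecedent):
    model, _ = _hbond_model(d, alpha, antecedent)
    assert find_hydrogen_bonds(model, spec_ab, params) == []


def test_hydrogen_bond_requires_opposite_groups(params):
    model, _ = _hbond_model(2.9, 160.0, acceptor_chain="A")
    spec = InterfaceSpec(frozenset("A"), frozenset("B"))
    model.chains["B"] = [
        build_residue("GLY", "B", 1, {"N": (50.0, 50, 50), "CA": (51.5, 50, 50)})
    ]
    assert find_hydrogen_bonds(model, spec, params) == []


# ---------------------------------------------------------------------------
# ionic bonds and salt bridges

def _charged_model(name_a, name_b, d, theta=0.0, chain_b="B"):
    ca, cb = _pose_charged_tips(name_a, name_b, d, theta)
    return build_model(
        _make_residue(name_a, "A", 1, ca), _make_residue(name_b, chain_b, 1, cb)
    )


def test_ionic_bond_close_pair(spec_ab):
    """ARG/ASP with tight charged atoms and centroids brought within 5 A."""
    theta = brentq(
        lambda t: _centroid_distance(*_pose_charged_tips("ARG", "ASP", 3.5, t)) - 4.2,
        0.0, 90.0,
    )
    model = _charged_model("ARG", "ASP", 3.5, theta)
    bonds = find_ionic_bonds(model, spec_ab)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(3.5, abs=1e-6)
    assert bonds[0].centroid_distance == pytest.approx(4.2, abs=1e-3)


def test_like_charges_cannot_bond(spec_ab):
    model = _charged_model("ARG", "LYS", 3.0)
    assert find_ionic_bonds(model, spec_ab) == []
    assert find_salt_bridges(model, spec_ab) == []


def test_ionic_centroid_cutoff_variants(spec_ab):
    """A pair with centroids ~6.5 A apart is invisible at the 5 A cutoff
    but reported at 7.5 A (atom cutoff scaled identically)."""
    theta = brentq(
        lambda t: _centroid_distance(*_pose_charged_tips("ARG", "ASP", 4.2, t)) - 6.5,
        0.0, 90.0,
    )
    model = _charged_model("ARG", "ASP", 4.2, theta)
    assert find_ionic_bonds(model, spec_ab, DetectionParams()) == []
    wide = DetectionParams(ionic_centroid_cutoff=7.5)
    bonds = find_ionic_bonds(model, spec_ab, wide)
    assert len(bonds) == 1
    assert bonds[0].centroid_distance == pytest.approx(6.5, abs=1e-3)


def test_salt_bridge_distance_boundary(spec_ab):
    near = _charged_model("ARG", "GLU", 3.2)
    bonds = find_salt_bridges(near, spec_ab)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(3.2, abs=1e-6)
    far = _charged_model("ARG", "GLU", 4.5)
    assert find_salt_bridges(far, spec_ab) == []


def test_salt_bridge_distance_matches_brute_force_recomputation(spec_ab):
    """The reported minimum N...O distance equals an independent all-pairs
    recomputation on the emitted PDB coordinates."""
    pdb, _ = make_pair_complex(PlantSpec("salt_bridge", ("LYS", "ASP"), 3.2), seed=9)
    model = parse_pdb(pdb)
    (bond,) = find_salt_bridges(model, spec_ab)
    lys = model.chains["A"][0]
    asp = model.chains["B"][0]
    dmin = min(
        np.linalg.norm(lys.atom("NZ").coord - asp.atom(o).coord) for o in ("OD1", "OD2")
    )
    assert bond.distance == pytest.approx(dmin, abs=1e-9)
    assert dmin == pytest.approx(3.2, abs=0.005)


def test_disordered_sidechain_skipped_with_warning(spec_ab):
    model = _charged_model("LYS", "ASP", 3.2)
    lys = model.chains["A"][0]
    lys.atoms = [a for a in lys.atoms if a.name != "NZ"]
    with pytest.warns(UserWarning, match="charged atoms are missing"):
        assert find_salt_bridges(model, spec_ab) == []


# ---------------------------------------------------------------------------
# detect_all and structural invariants

def test_detect_all_equals_union_and_is_deterministic(spec_ab):
    pdb, truth = make_interface_complex(6, seed=4)
    model = parse_pdb(pdb)
    all1 = ib.detect_all(model, spec_ab)
    assert all1["hydrogen"] == find_hydrogen_bonds(model, spec_ab)
    assert all1["ionic"] == find_ionic_bonds(model, spec_ab)
    assert all1["salt_bridge"] == find_salt_bridges(model, spec_ab)
    assert detected_pairs(ib.detect_all(model, spec_ab)) == detected_pairs(all1)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """Rotating and translating all coordinates leaves bond sets, distances
    and angles unchanged."""
    spec = InterfaceSpec(frozenset("A"), frozenset("B"))
    rng = np.random.default_rng(seed)
    pdb, _ = make_interface_complex(4, seed=seed)
    model = parse_pdb(pdb)
    from interbond.geometry import random_rotation

    moved = model.transformed(random_rotation(rng), rng.uniform(-30, 30, 3))
    b1 = ib.detect_all(model, spec)
    b2 = ib.detect_all(moved, spec)
    for t in b1:
        k1 = sorted((x.res1, x.res2, x.atom1, x.atom2) for x in b1[t])
        k2 = sorted((x.res1, x.res2, x.atom1, x.atom2) for x in b2[t])
        assert k1 == k2
        d1 = sorted(round(x.distance, 6) for x in b1[t])
        d2 = sorted(round(x.distance, 6) for x in b2[t])
        assert d1 == d2
        a1 = sorted(round(x.dha_angle, 5) for x in b1[t] if x.dha_angle is not None)
        a2 = sorted(round(x.dha_angle, 5) for x in b2[t] if x.dha_angle is not None)
        assert a1 == a2


def test_group_swap_symmetry(spec_ab):
    pdb, _ = make_interface_complex(5, seed=8)
    model = parse_pdb(pdb)
    fwd = ib.detect_all(model, spec_ab)
    rev = ib.detect_all(model, spec_ab.swapped())
    for t in fwd:
        fwd_keys = {(b.res1[:3], b.res2[:3], b.atom1, b.atom2) for b in fwd[t]}
        rev_keys = {(b.res2[:3], b.res1[:3], b.atom2, b.atom1) for b in rev[t]}
        assert fwd_keys == rev_keys


def test_ionic_cutoff_monotonicity(spec_ab):
    """Ionic bond sets nest as the cutoff widens: 5 within 7.5 within 10."""
    for seed in range(4):
        pdb, _ = make_interface_complex(6, seed=seed)
        model = parse_pdb(pdb)
        sets = []
        for cutoff in (5.0, 7.5, 10.0):
            bonds = find_ionic_bonds(
                model, spec_ab, DetectionParams(ionic_centroid_cutoff=cutoff)
            )
            sets.append({(b.res1[:3], b.res2[:3]) for b in bonds})
        assert sets[0] <= sets[1] <= sets[2]


def test_neighbor_search_equals_brute_force(spec_ab):
    """The k-d tree candidate search returns exactly the brute-force
    all-pairs bond set."""
    for seed in range(3):
        pdb, _ = make_interface_complex(8, seed=100 + seed)
        model = parse_pdb(pdb)
        fast = ib.detect_all(model, spec_ab, backend="grid")
        slow = ib.detect_all(model, spec_ab, backend="brute")
        for t in fast:
            key = lambda b: (b.res1, b.res2, b.atom1, b.atom2, round(b.distance, 9))
            assert sorted(map(key, fast[t])) == sorted(map(key, slow[t]))


def test_empty_interface_detects_nothing(spec_ab, params):
    donor = build_residue("GLY", "A", 1, {"N": (0.0, 0, 0), "CA": (1.5, 0, 0)})
    far = build_residue("GLY", "B", 1, {"N": (50.0, 0, 0), "CA": (51.5, 0, 0)})
    model = build_model(donor, far)
    result = ib.detect_all(model, spec_ab, params)
    assert all(v == [] for v in result.values())


# ---------------------------------------------------------------------------
# residue centroid

def test_residue_centroid_is_heavy_atom_mean():
    single = build_residue("GLY", "A", 1, {"N": (1.0, 2.0, 3.0)})
    np.testing.assert_allclose(ib.residue_centroid(single), [1, 2, 3])
    two = build_residue("GLY", "A", 1, {"N": (0.0, 0, 0), "CA": (2.0, 0, 0)})
    np.testing.assert_allclose(ib.residue_centroid(two), [1, 0, 0])
    arg = _make_residue("ARG", "A", 1, __import__("interbond.synthetic", fromlist=["x"]).residue_template("ARG"))
    expected = np.mean([a.coord for a in arg.atoms if not a.is_hydrogen], axis=0)
    np.testing.assert_allclose(ib.residue_centroid(arg), expected)


def test_residue_centroid_excludes_hydrogens_and_rejects_empty():
    res = build_residue("GLY", "A", 1, {"N": (0.0, 0, 0)}, hydrogens=[("H", (9.0, 9, 9))])
    np.testing.assert_allclose(ib.residue_centroid(res), [0, 0, 0])
    res.atoms = [a for a in res.atoms if a.is_hydrogen]
    with pytest.raises(ValueError):
        ib.residue_centroid(res)
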