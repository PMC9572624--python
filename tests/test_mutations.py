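"""ddG computation, normalization, bond-change classes, group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import interbond as ib
from interbond import mutations as mut
from interbond.structure import StructureModel, parse_pdb
from interbond.synthetic import (
    PlantSpec,
    _make_residue,
    _orient_tip,
    make_pair_complex,
    residue_template,
)


def _rec(wt="LYS", m="ALA", kw=1e-9, km=1e-6, T=None, cplx="C1", chain="A", pos=1):
    return mut.MutationRecord(cplx, chain, pos, wt, m, kw, km, T)


# ---------------------------------------------------------------------------
# dG / ddG arithmetic

def test_delta_g_reference_values():
    assert mut.delta_g(1.0) == 0.0
    assert mut.delta_g(1.0, 310.0) == 0.0
    # RT ln(1e-9) at 298.15 K with R = 0.0019872 kcal/mol/K
    assert mut.delta_g(1e-9, 298.15) == pytest.approx(-12.278, abs=0.005)
    ratio = mut.delta_g(1e-6, 298.15) / mut.delta_g(1e-6, 310.0)
    assert ratio == pytest.approx(298.15 / 310.0, rel=1e-12)
    with pytest.raises(ValueError):
        mut.delta_g(0.0)
    with pytest.raises(ValueError):
        mut.delta_g(-1e-9)


def test_compute_ddg_sign_convention():
    """Weaker mutant binding (larger Kd) gives positive, destabilizing ddG."""
    r = mut.compute_ddg(_rec(kw=1e-9, km=1e-6, T=298.15))
    assert r.ddg == pytest.approx(4.093, abs=0.005)
    flipped = mut.compute_ddg(_rec(kw=1e-6, km=1e-9, T=298.15))
    assert flipped.ddg == pytest.approx(-r.ddg, rel=1e-12)
    assert mut.compute_ddg(_rec(km=1e-9, kw=1e-9)).ddg == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(1e-12, 1e-3), st.floats(1e-12, 1e-3),
    st.floats(1e-6, 1e6),
)
def test_ddg_depends_only_on_keq_ratio(kw, km, scale):
    """Rescaling both equilibrium constants leaves ddG unchanged."""
    a = mut.compute_ddg(_rec(kw=kw, km=km)).ddg
    b = mut.compute_ddg(_rec(kw=kw * scale, km=km * scale)).ddg
    assert a == pytest.approx(b, abs=1e-9)


def test_normalize_ddg_minmax_per_complex():
    recs = [
        mut.compute_ddg(_rec(cplx="C1", km=k)) for k in (1e-8, 1e-7, 1e-6)
    ]
    normed = mut.normalize_ddg(recs)
    assert [round(r.ddg_normalized, 6) for r in normed] == [0.0, 0.5, 1.0]
    # independent complexes normalize independently; singletons map to 0.5
    recs = [
        mut.compute_ddg(_rec(cplx="C1", km=1e-8)),
        mut.compute_ddg(_rec(cplx="C1", km=1e-6)),
        mut.compute_ddg(_rec(cplx="C2", km=1e-5)),
    ]
    normed = mut.normalize_ddg(recs)
    assert [round(r.ddg_normalized, 6) for r in normed] == [0.0, 1.0, 0.5]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 9999))
def test_normalized_ddg_bounded_and_attains_extremes(seed):
    rng = np.random.default_rng(seed)
    recs = [
        mut.compute_ddg(_rec(cplx=f"C{i % 2}", km=float(k)))
        for i, k in enumerate(rng.uniform(1e-9, 1e-4, 12))
    ]
    normed = mut.normalize_ddg(recs)
    vals = {}
    for r in normed:
        assert 0.0 <= r.ddg_normalized <= 1.0
        vals.setdefault(r.mutation.complex_id, []).append(r.ddg_normalized)
    for v in vals.values():
        if len(set(np.round(v, 12))) >= 2:
            assert min(v) == 0.0 and max(v) == 1.0


# ---------------------------------------------------------------------------
# mutation-table input

def test_parse_mutation_code():
    assert mut.parse_mutation_code("RA59A") == ("ARG", "A", 59, "", "ALA")
    assert mut.parse_mutation_code("KD100aR") == ("LYS", "D", 100, "A", "ARG")
    with pytest.raises(ValueError):
        mut.parse_mutation_code("R59A")  # missing chain
    with pytest.raises(ValueError):
        mut.parse_mutation_code("XA59A")  # unknown amino acid


def test_read_mutation_table_skips_and_deduplicates():
    df = pd.DataFrame(
        {
            "complex_id": ["C1"] * 4,
            "chain": ["A"] * 4,
            "mutation": ["RA59A", "RA59A", "KA10R,EA11Q", "garbage"],
            "keq_wt": [1e-9] * 4,
            "keq_mut": [1e-8] * 4,
            "temperature": [298.15] * 4,
        }
    )
    with pytest.warns(UserWarning):
        records = mut.read_mutation_table(df)
    assert len(records) == 1
    assert records[0].wt_residue == "ARG"
    assert records[0].temperature == 298.15


# ---------------------------------------------------------------------------
# bond-change classification

@pytest.fixture(scope="module")
def salt_fixture():
    pdb, _ = make_pair_complex(PlantSpec("salt_bridge", ("LYS", "ASP"), 3.2), seed=1)
    model = parse_pdb(pdb)
    spec = ib.InterfaceSpec(frozenset("A"), frozenset("B"))
    return model, spec, ib.detect_all(model, spec)


def _classes(changes):
    return {c.bond_type: c.classification for c in changes}


def test_charged_to_uncharged_breaks_salt_bridge(salt_fixture):
    model, spec, wt = salt_fixture
    ch = _classes(ib.classify_bond_change(wt, _rec("LYS", "ALA"), model, spec))
    assert ch["salt_bridge"] == "broken"


def test_charged_to_like_charged_keeps_bond_intact(salt_fixture):
    model, spec, wt = salt_fixture
    ch = _classes(ib.classify_bond_change(wt, _rec("LYS", "ARG"), model, spec))
    assert ch["salt_bridge"] == "intact"


def test_identity_mutation_never_breaks_or_forms(salt_fixture):
    model, spec, wt = salt_fixture
    ch = _classes(ib.classify_bond_change(wt, _rec("LYS", "LYS"), model, spec))
    assert set(ch.values()) <= {"intact", "none"}


def test_unknown_site_raises(salt_fixture):
    model, spec, wt = salt_fixture
    with pytest.raises(mut.SiteNotFoundError):
        ib.classify_bond_change(wt, _rec(pos=99), model, spec)


def test_wt_mismatch_warns(salt_fixture):
    model, spec, wt = salt_fixture
    with pytest.warns(UserWarning, match="mismatch"):
        ib.classify_bond_change(wt, _rec("GLY", "ALA"), model, spec)


def test_mutation_to_charged_forms_bond_within_reach():
    """ALA site with a glutamate carboxylate 6 A from C-beta: mutating to
    ARG (reach 6.4 A) predicts ionic/salt formation; mutating to ASP
    (like charge with GLU) does not."""
    ala = _make_residue("ALA", "A", 1, residue_template("ALA"))
    cb = ala.atom("CB").coord
    glu_coords = _orient_tip(
        residue_template("GLU"), "OE1", "CD", cb + np.array([6.0, 0, 0]),
        np.array([-1.0, 0, 0]),
    )
    glu = _make_residue("GLU", "B", 1, glu_coords)
    model = StructureModel("m", {"A": [ala], "B": [glu]})
    spec = ib.InterfaceSpec(frozenset("A"), frozenset("B"))
    wt = ib.detect_all(model, spec)
    assert all(v == [] for v in wt.values())
    ch = _classes(ib.classify_bond_change(wt, _rec("ALA", "ARG"), model, spec))
    assert ch["ionic"] == "formed"
    assert ch["salt_bridge"] == "formed"
    ch2 = _classes(ib.classify_bond_change(wt, _rec("ALA", "ASP"), model, spec))
    assert ch2["ionic"] == "none"
    # ASN within reach of the carboxylate acceptor? ASN has donors, so a
    # hydrogen bond could form; ionic cannot
    ch3 = _classes(ib.classify_bond_change(wt, _rec("ALA", "GLY"), model, spec))
    assert ch3 == {"hydrogen": "none", "ionic": "none", "salt_bridge": "none"}


def test_backbone_mediated_hydrogen_bond_survives_mutation():
    """A hydrogen bond through the backbone amide is intact under any
    point mutation of that residue."""
    from conftest import build_model, build_residue

    D = np.zeros(3)
    H = np.array([1.0, 0.0, 0.0])
    A = np.array([2.9, 0.35, 0.0])
    C = A + 1.231 * (A / np.linalg.norm(A))
    donor = build_residue(
        "SER", "A", 1,
        {"N": D, "CA": (-1.0, -1.0, 0.0), "C": (-2.4, -1.2, 0.0),
         "O": (-2.9, -2.3, 0.0), "CB": (-1.2, -2.4, 0.5), "OG": (-1.4, -3.0, 1.6)},
        hydrogens=[("H", H)],
    )
    acceptor = build_residue("GLY", "B", 1, {"O": A, "C": C, "CA": C + 1.4, "N": C + 2.6})
    model = build_model(donor, acceptor)
    spec = ib.InterfaceSpec(frozenset("A"), frozenset("B"))
    wt = ib.detect_all(model, spec)
    assert len(wt["hydrogen"]) == 1
    assert wt["hydrogen"][0].atom1 == "N"
    ch = _classes(ib.classify_bond_change(wt, _rec("SER", "ALA"), model, spec))
    assert ch["hydrogen"] == "intact"


# ---------------------------------------------------------------------------
# group statistics

def test_group_summary_degenerate_and_single_values():
    frame = pd.DataFrame(
        {
            "bond_type": ["ionic"] * 3 + ["ionic"],
            "classification": ["broken"] * 3 + ["intact"],
            "complex_id": ["C1"] * 4,
            "ddg_normalized": [0.5, 0.5, 0.5, 0.7],
        }
    )
    out = mut.group_summary(frame)
    broken = out[out["classification"] == "broken"].iloc[0]
    assert broken["n"] == 3
    assert broken["mean"] == pytest.approx(0.5)
    assert broken["cv"] == pytest.approx(0.0)
    assert broken["ci_low"] == pytest.approx(broken["ci_high"])
    single = out[out["classification"] == "intact"].iloc[0]
    assert single["n"] == 1
    assert single["mean"] == pytest.approx(0.7)
    assert np.isnan(single["ci_low"]) and np.isnan(single["ci_high"])


def test_group_summary_marks_empty_groups():
    frame = pd.DataFrame(
        {
            "bond_type": ["ionic"],
            "classification": ["broken"],
            "complex_id": ["C1"],
            "ddg_normalized": [0.4],
        }
    )
    out = mut.group_summary(
        frame, expected_groups=[("ionic", "broken", "C1"), ("ionic", "formed", "C1")]
    )
    empty = out[out["classification"] == "formed"].iloc[0]
    assert empty["n"] == 0
    assert empty["marker"] == "*"
    assert np.isnan(empty["mean"])


def test_group_summary_t_interval_matches_scipy():
    vals = np.array([0.2, 0.4, 0.6, 0.8, 0.5])
    frame = pd.DataFrame(
        {
            "bond_type": "ionic", "classification": "broken", "complex_id": "C1",
            "ddg_normalized": vals,
        }
    )
    out = mut.group_summary(frame).iloc[0]
    from scipy import stats

    lo, hi = stats.t.interval(
        0.95, len(vals) - 1, loc=vals.mean(),
        scale=vals.std(ddof=1) / np.sqrt(len(vals)),
    )
    assert out["ci_low"] == pytest.approx(lo)
    assert out["ci_high"] == pytest.approx(hi)
    assert out["cv"] == pytest.approx(vals.std(ddof=1) / vals.mean())


def test_planted_effect_recovered_through_full_pipeline():
    """Synthetic tables with a planted ddG shift: the broken group's mean
    normalized ddG exceeds the intact group's."""
    table, labels = ib.make_mutation_table(200, "broken_high_ddg", seed=3)
    records = mut.read_mutation_table(table)
    normed = mut.normalize_ddg([mut.compute_ddg(r) for r in records])
    frame = pd.DataFrame(
        {
            "bond_type": "salt_bridge",
            "classification": labels,
            "complex_id": [r.mutation.complex_id for r in normed],
            "ddg_normalized": [r.ddg_normalized for r in normed],
        }
    )
    out = mut.group_summary(frame)
    broken = out[out["classification"] == "broken"]["mean"].mean()
    intact = out[out["classification"] == "intact"]["mean"].mean()
    assert broken > intact
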