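"""Self-validation protocols built on the synthetic generators.

Three reusable checks quantify detector correctness without any external
structure:

* a planted-bond sweep across the feasible geometry ranges of all three
  bond types plus single-criterion decoys (recall on plants, detections on
  decoys);
* an equivalence trial comparing the k-d tree candidate search against
  brute-force all-pairs detection on random multi-plant complexes;
* a simulation-recovery run checking that group statistics recover the
  ddG shift planted in synthetic mutation tables.
"""

from __future__ import annotations

import numpy as np

from .detect import DetectionParams, detect_all
from .mutations import compute_ddg, group_summary, normalize_ddg, read_mutation_table
from .structure import InterfaceSpec, parse_pdb
from .synthetic import (
    PlantSpec,
    make_interface_complex,
    make_mutation_table,
    make_pair_complex,
    min_feasible_dha_angle,
)

__all__ = [
    "planted_sweep_specs",
    "run_planted_sweep",
    "run_backend_equivalence",
    "run_simulation_recovery",
]

_AB = InterfaceSpec(frozenset("A"), frozenset("B"))


def planted_sweep_specs(params: DetectionParams = DetectionParams()) -> list[PlantSpec]:
    """Plant specifications spanning the feasible geometry of each bond
    type (salt bridges up to the 4 A cutoff, ionic pairs up to the point
    where centroids can still pass, hydrogen bonds over D-A distance and
    D-H-A angle) plus decoys violating each criterion in turn."""
    specs: list[PlantSpec] = []
    for pair in (("LYS", "ASP"), ("ARG", "GLU"), ("HIS", "GLU"), ("LYS", "GLU")):
        for d in np.linspace(2.8, 3.95, 12):
            specs.append(PlantSpec("salt_bridge", pair, round(float(d), 3)))
        for d in np.linspace(2.8, 4.6, 12):
            specs.append(PlantSpec("ionic", pair, round(float(d), 3)))
    for pair in (("ASN", "GLN"), ("GLN", "ASN"), ("ASN", "ASN")):
        for d in np.linspace(2.65, 3.4, 6):
            lo = max(min_feasible_dha_angle(float(d), params) + 2.0, 95.0)
            for alpha in np.linspace(lo, 177.0, 5):
                specs.append(
                    PlantSpec("hydrogen", pair, round(float(d), 3), round(float(alpha), 2))
                )
    # decoys: each violates exactly the named criterion
    for d in (4.05, 4.3, 4.6, 4.9):
        specs.append(PlantSpec("none", ("ARG", "GLU"), d, violated_criterion="salt_distance"))
    for d in (4.1, 4.5, 4.9):
        specs.append(PlantSpec("none", ("ARG", "GLU"), d, violated_criterion="ionic_centroid"))
        specs.append(PlantSpec("none", ("LYS", "ASP"), d,
                               violated_criterion="ionic_atom_distance"))
    for pair in (("ARG", "LYS"), ("ASP", "GLU"), ("HIS", "LYS")):
        specs.append(PlantSpec("none", pair, 3.0, violated_criterion="charge"))
    for d in (4.0, 4.5, 5.0):
        specs.append(PlantSpec("none", ("ASN", "GLN"), d, 160.0,
                               violated_criterion="da_distance"))
    for d, alpha in ((3.3, 95.0), (3.4, 100.0), (3.2, 91.0)):
        specs.append(PlantSpec("none", ("ASN", "GLN"), d, alpha,
                               violated_criterion="ha_distance"))
    for d, alpha in ((2.5, 80.0), (2.4, 70.0), (2.55, 88.0)):
        specs.append(PlantSpec("none", ("ASN", "GLN"), d, alpha,
                               violated_criterion="dha_angle"))
    for d, alpha in ((2.9, 160.0), (3.1, 150.0), (2.7, 130.0)):
        specs.append(PlantSpec("none", ("ASN", "GLN"), d, alpha,
                               violated_criterion="antecedent_angle"))
    return specs


def run_planted_sweep(
    seed: int = 0, params: DetectionParams = DetectionParams()
) -> dict[str, float]:
    """Detect on every sweep fixture; returns plant/decoy case counts,
    recall on planted bonds, and the total detections on decoys."""
    specs = planted_sweep_specs(params)
    rng = np.random.default_rng(seed)
    n_plant = n_recovered = n_decoy = n_decoy_detections = 0
    for ps in specs:
        pdb, truth = make_pair_complex(ps, seed=int(rng.integers(2**31 - 1)), params=params)
        bonds = detect_all(parse_pdb(pdb), _AB, params)
        if ps.bond_type == "none":
            n_decoy += 1
            n_decoy_detections += sum(len(v) for v in bonds.values())
        else:
            n_plant += 1
            n_recovered += int(
                any(
                    (b.res1.seq_number, b.res2.seq_number) == (1, 1)
                    for b in bonds[ps.bond_type]
                )
            )
    return {
        "planted_cases": n_plant,
        "recovered": n_recovered,
        "recall": n_recovered / n_plant,
        "decoy_cases": n_decoy,
        "decoy_detections": n_decoy_detections,
    }


def run_backend_equivalence(
    n_fixtures: int = 50,
    seed: int = 0,
    max_pairs: int = 110,
    params: DetectionParams = DetectionParams(),
) -> dict[str, float]:
    """Compare grid and brute-force backends bond-for-bond on random
    multi-plant complexes (up to ~2,000 atoms); returns the mismatch and
    atom counts."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    max_atoms = 0
    for _ in range(n_fixtures):
        n_pairs = int(rng.integers(3, max_pairs + 1))
        pdb, _ = make_interface_complex(n_pairs, seed=int(rng.integers(2**31 - 1)),
                                        params=params)
        model = parse_pdb(pdb)
        max_atoms = max(max_atoms, model.n_atoms())
        fast = detect_all(model, _AB, params, backend="grid")
        slow = detect_all(model, _AB, params, backend="brute")
        for t in fast:
            key = lambda b: (b.res1, b.res2, b.atom1, b.atom2, round(b.distance, 9))
            if sorted(map(key, fast[t])) != sorted(map(key, slow[t])):
                mismatches += 1
    return {"fixtures": n_fixtures, "mismatches": mismatches, "max_atoms": max_atoms}


def run_simulation_recovery(
    n_mutations: int = 200, seed: int = 0, shift: float = 1.5
) -> dict[str, float]:
    """Generate planted-effect and null mutation tables, push them through
    the ddG pipeline and group statistics, and report the recovered group
    difference in raw ddG (kcal/mol) and in normalized ddG."""
    import pandas as pd

    out: dict[str, float] = {"planted_shift": shift, "n": n_mutations}
    for model_name, key in (("broken_high_ddg", "effect"), ("null", "null")):
        table, labels = make_mutation_table(n_mutations, model_name, seed=seed, shift=shift)
        records = read_mutation_table(table)
        normed = normalize_ddg([compute_ddg(r) for r in records])
        frame = pd.DataFrame(
            {
                "bond_type": "salt_bridge",
                "classification": labels,
                "complex_id": [r.mutation.complex_id for r in normed],
                "ddg": [r.ddg for r in normed],
                "ddg_normalized": [r.ddg_normalized for r in normed],
            }
        )
        raw = group_summary(frame, value_col="ddg")
        norm = group_summary(frame)
        raw_diff = (
            raw[raw["classification"] == "broken"]["mean"].mean()
            - raw[raw["classification"] == "intact"]["mean"].mean()
        )
        norm_diff = (
            norm[norm["classification"] == "broken"]["mean"].mean()
            - norm[norm["classification"] == "intact"]["mean"].mean()
        )
        out[f"{key}_ddg_diff_kcal"] = float(raw_diff)
        out[f"{key}_normalized_diff"] = float(norm_diff)
    return out
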