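"""Scoring predicted bonds against a curated reference bond list.

The reference is a literature-derived list of residue pairs with an
explicit bond type.  Matching is on unordered residue-pair identity plus
bond type; atom-level detail is ignored.  True negatives are unknowable in
this setting (no study exhaustively tests every residue pair), so the
counts carry an explicit "Unknown" marker for TN, and reported precision
is a lower bound: false positives include bonds that simply have not been
tested experimentally.

Because chemical literature defines a salt bridge as the co-occurrence of
an ionic bond and a hydrogen bond, a residue pair carrying both reference
entries implies a salt-bridge reference entry even if none is stated
(:func:`infer_reference_salt_bridges`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "ReferenceBond",
    "ConfusionCounts",
    "infer_reference_salt_bridges",
    "score_predictions",
    "precision_recall",
    "read_reference_bonds",
    "format_report",
]

_BOND_TYPES = ("ionic", "hydrogen", "salt_bridge")


@dataclass(frozen=True)
class ReferenceBond:
    """One literature-verified bond between two interface residues.

    ``resnum`` fields are author numbering as text (insertion codes
    appended, e.g. "100A").
    """

    chain1: str
    resnum1: str
    resname1: str
    chain2: str
    resnum2: str
    resname2: str
    bond_type: str
    source: str = ""

    def pair_key(self) -> frozenset:
        return frozenset({(self.chain1, self.resnum1), (self.chain2, self.resnum2)})


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN tallies for one bond type; TN is structurally unknowable."""

    tp: int
    fp: int
    fn: int
    tn: str = "Unknown"

    @property
    def total_predictions(self) -> int:
        return self.tp + self.fp

    @property
    def total_known(self) -> int:
        return self.tp + self.fn


def infer_reference_salt_bridges(reference: Iterable[ReferenceBond]) -> list[ReferenceBond]:
    """Add an implied salt-bridge entry for every residue pair that has
    both a hydrogen-bond and an ionic-bond entry.  Idempotent."""
    ref = list(reference)
    by_pair: dict[frozenset, set[str]] = {}
    for b in ref:
        by_pair.setdefault(b.pair_key(), set()).add(b.bond_type)
    out = list(ref)
    for b in ref:
        types = by_pair[b.pair_key()]
        if b.bond_type == "ionic" and "hydrogen" in types and "salt_bridge" not in types:
            out.append(
                ReferenceBond(
                    b.chain1, b.resnum1, b.resname1, b.chain2, b.resnum2, b.resname2,
                    "salt_bridge", source="implied: hydrogen + ionic",
                )
            )
            by_pair[b.pair_key()].add("salt_bridge")
    return out


def _predicted_pair_keys(predicted: Iterable, bond_type: str) -> set[frozenset]:
    keys = set()
    for p in predicted:
        if p.bond_type != bond_type:
            continue
        keys.add(
            frozenset(
                {
                    (p.res1.chain_id, f"{p.res1.seq_number}{p.res1.insertion_code}"),
                    (p.res2.chain_id, f"{p.res2.seq_number}{p.res2.insertion_code}"),
                }
            )
        )
    return keys


def score_predictions(
    predicted: Iterable, reference: Iterable[ReferenceBond], bond_type: str
) -> ConfusionCounts:
    """Count TP (predicted pair present in the reference with matching
    type), FP (predicted, not in reference) and FN (reference pair of the
    type not predicted).  Pairs are unordered; duplicates collapse."""
    pred_keys = _predicted_pair_keys(predicted, bond_type)
    ref_list = [b for b in reference if b.bond_type == bond_type]
    ref_keys: set[frozenset] = set()
    dup = 0
    for b in ref_list:
        k = b.pair_key()
        if k in ref_keys:
            dup += 1
        ref_keys.add(k)
    if dup:
        warnings.warn(f"collapsed {dup} duplicated reference entries", stacklevel=2)
    tp = len(pred_keys & ref_keys)
    return ConfusionCounts(tp=tp, fp=len(pred_keys) - tp, fn=len(ref_keys) - tp)


def precision_recall(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(precision, recall) = (tp/(tp+fp), tp/(tp+fn)); a zero denominator
    yields None (undefined), never 0."""
    precision = counts.tp / counts.total_predictions if counts.total_predictions else None
    recall = counts.tp / counts.total_known if counts.total_known else None
    return precision, recall


def read_reference_bonds(path: str | Path) -> list[ReferenceBond]:
    """Read a reference bond list TSV with columns chain1, resnum1,
    resname1, chain2, resnum2, resname2, bond_type[, source]."""
    bonds = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    required = ["chain1", "resnum1", "resname1", "chain2", "resnum2", "resname2", "bond_type"]
    missing = [c for c in required if c not in idx]
    if missing:
        raise ValueError(f"reference list missing columns: {missing}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        bonds.append(
            ReferenceBond(
                *(parts[idx[c]] for c in required),
                source=parts[idx["source"]] if "source" in idx and len(parts) > idx["source"] else "",
            )
        )
    return bonds


def format_report(counts_by_type: dict[str, ConfusionCounts]) -> str:
    """Per-type TP/FP/FN/TN table with precision, recall and recomputed
    totals, TSV text."""
    types = [t for t in _BOND_TYPES if t in counts_by_type]
    rows = [["metric"] + types]

    def fmt_pct(x: float | None) -> str:
        return "undefined" if x is None else f"{100 * x:.1f}%"

    grid: dict[str, list[str]] = {
        "true_positive": [], "false_positive": [], "false_negative": [],
        "true_negative": [], "precision": [], "recall": [],
        "total_known_bonds": [], "total_predictions": [],
    }
    for t in types:
        c = counts_by_type[t]
        p, r = precision_recall(c)
        grid["true_positive"].append(str(c.tp))
        grid["false_positive"].append(str(c.fp))
        grid["false_negative"].append(str(c.fn))
        grid["true_negative"].append(c.tn)
        grid["precision"].append(fmt_pct(p))
        grid["recall"].append(fmt_pct(r))
        grid["total_known_bonds"].append(str(c.total_known))
        grid["total_predictions"].append(str(c.total_predictions))
    for name, values in grid.items():
        rows.append([name] + values)
    return "\n".join("\t".join(r) for r in rows) + "\n"
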