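# interbond

Geometric detection and classification of intermolecular bonds at
protein–protein interfaces, for structural biologists studying how charged
and polar residues drive binding specificity. Given a complex in PDB
format and a partition of its chains into two interface groups, the
package reports every cross-interface **hydrogen bond**, **ionic bond**
and **salt bridge**, classifies the effect of point mutations on those
bonds (*broken* / *intact* / *formed*), normalizes binding-affinity
changes (ΔΔG) for cross-complex comparison, and scores bond predictions
against curated reference lists with TP/FP/FN accounting.

## Detection criteria

All detectors operate on residue pairs spanning the interface (one
residue per chain group) and nothing else.

**Hydrogen bond** — donor heavy atom D with hydrogen H, acceptor A with
antecedents AA (covalent neighbours of A):

- |D−A| ≤ 3.9 Å and |H−A| ≤ 2.5 Å
- ∠(D,H,A) > 90°
- ∠(D,A,AA) ≥ 90° and ∠(H,A,AA) ≥ 90° for every antecedent
- D and A at least three covalent bonds apart (automatic across an
  interface)

Missing polar hydrogens are placed at 1.0 Å with idealized geometry;
hydroxyl hydrogens (Ser/Thr/Tyr, and Cys thiols) are treated as rotatable
and their dihedral sampled in 10° steps.

**Ionic bond** — residues with opposite formal side-chain charge at
physiological pH (Arg/His/Lys +1 vs Asp/Glu −1), whole-residue heavy-atom
centroids **< 5 Å** apart (7.5 Å and 10 Å variants available), and charged
side-chain atoms (N on basic, O on acidic residues) within the same
cutoff.

**Salt bridge** — oppositely charged residues whose side-chain charged
N···O atoms come within **4 Å**; no centroid requirement.

## Worked example

A synthetic reconstruction of the classic barnase–barstar contact —
guanidinium of Arg59 (chain A) facing the Glu76 carboxylate (chain D) —
ships with the package:

```python
import interbond as ib

pdb_text, _ = ib.synthetic_barnase_barstar_interface()
model = ib.parse_pdb(pdb_text)
spec = ib.InterfaceSpec(frozenset("A"), frozenset("D"))
for bond in ib.find_salt_bridges(model, spec):
    print(bond.res1.label(), bond.res2.label(), bond.atom1, bond.atom2,
          f"{bond.distance:.2f}")
```

prints

```
A:ARG59 D:GLU76 NH1 OE1 2.95
```

i.e. the two residues are oppositely charged and their closest charged
N···O pair is 2.95 Å apart — within the 4 Å cutoff, so a salt bridge is
predicted.

The same analysis from the shell:

```sh
interbond fixtures --outdir fx --seed 0          # synthetic test complexes
interbond detect fx/interface_complex.pdb --groups A:B
interbond ddg --pdb fx/interface_complex.pdb --groups A:B --mutations fx/mutations.tsv
interbond evaluate --predictions bonds.tsv --reference reference.tsv
```

`detect` writes one row per bond with the realizing atom pair, distance
and (for hydrogen bonds) the D–H–A angle; `ddg` writes per-mutation
normalized ΔΔG with bond-change classes and per-group mean / 95% CI /
coefficient-of-variation summaries; `evaluate` prints a per-type
TP/FP/FN/precision/recall table (TN is reported as "Unknown": no
experiment exhaustively tests every residue pair, so true negatives are
uncountable and reported precision is a lower bound).

## Mutation analysis

From equilibrium dissociation constants, ΔG = RT ln K_d (R = 0.0019872
kcal mol⁻¹ K⁻¹, each record's own temperature, 298.15 K default), and
ΔΔG = ΔG_mut − ΔG_wt, so positive ΔΔG is destabilizing. ΔΔG is then
min–max normalized to [0, 1] within each complex so energies are
comparable across complexes. Each mutation is classified per bond type
against the wild-type predictions: side-chain-mediated bonds are *broken*
when the mutant loses the required chemistry and *intact* when it keeps
it (charged → like-charged); backbone-mediated bonds survive any point
mutation; *formed* uses a side-chain-reach heuristic on the wild-type
structure.

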