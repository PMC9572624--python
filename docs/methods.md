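# Methods

## Scope and model

`interbond` treats intermolecular bond prediction as a purely geometric
classification problem on a static crystal structure: a bond of a given
type exists exactly when the published distance/angle criteria for that
type hold between two residues on opposite sides of a declared chain
partition (the *interface groups*). There is no energy model, no
electrostatics solver and no conformational sampling; the assumptions are
those of the criteria themselves — physiological-pH protonation states,
rigid heavy-atom coordinates, and idealized hydrogen positions where the
structure provides none.

The three detectors are deliberately independent ("bottom-up"): a salt
bridge is *not* computed as the intersection of the other two detectors'
outputs, it has its own 4 Å side-chain charged-atom criterion. A pair can
therefore appear in one, two or all three lists, which mirrors how the
classes are defined chemically (a salt bridge is ionic + hydrogen-bonding
character).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `da_cutoff` | 3.9 Å | max donor–acceptor heavy-atom distance |
| `ha_cutoff` | 2.5 Å | max hydrogen–acceptor distance |
| `dha_min_angle` | 90° (exclusive) | min donor–hydrogen–acceptor angle |
| `antecedent_min_angle` | 90° (inclusive) | min D–A–AA and H–A–AA angles |
| `ionic_centroid_cutoff` | 5.0 Å (exclusive) | residue-centroid distance; 7.5/10 Å variants for longer-range pairs |
| `ionic_atom_cutoff` | = centroid cutoff | charged N···O distance for ionic pairs |
| `salt_cutoff` | 4.0 Å (inclusive) | charged N···O distance for salt bridges |
| `hydroxyl_step_deg` | 10° | rotamer sampling step for hydroxyl donors |

Boundary semantics follow the wording of the criteria: "less than" for
the centroid test (strict `<`), "within" for atom distances (inclusive
`≤`), "greater than 90°" for D–H–A (strict), "minimum of 90°" for the
antecedent angles (inclusive). All comparisons are plain double-precision
with no tolerance fudge; boundary cases are measure-zero on real
coordinates.

Design choices made where the criteria leave room:

* **Centroid** = unweighted mean of *all* heavy atoms of the residue
  (backbone + side chain), the plainest reading of "amino acid centroid".
  A side-chain-only centroid would admit a few more extended pairs at the
  5 Å cutoff.
* **Histidine** is treated as protonated (+1), with both ring nitrogens
  charged and donating; consequently His N atoms are not acceptors.
  HID/HIE/HIP-style names are normalized to HIS.
* **Terminal charges** (N-terminal ammonium, C-terminal carboxylate) are
  not charged atoms; only side-chain chemistry counts. HETATM records,
  waters and non-canonical residues are excluded at parse time.
* **The ionic atom cutoff defaults to the centroid cutoff** (both scale
  together for the 7.5/10 Å variants), since the charged atoms are
  required to be "within the distance cutoff" — the same one.
* Residues whose charged side-chain atoms are missing (disorder) are
  skipped by the ionic/salt detectors with a warning rather than
  imputed.

## Hydrogen placement

Crystal structures usually omit hydrogens, so donors gain them at 1.0 Å
with idealized geometry: backbone amide H in the C–N–CA plane along the
reverse bisector (requires the preceding residue's carbonyl C — a
chain-initial N is flagged unplaceable and skipped); sp2 NH and NH2
groups planar; Lys ammonium staggered against the CD–CE bond. Hydroxyl
and thiol hydrogens have a free dihedral; they are marked rotatable and
the detector accepts the bond if *any* rotamer sampled in 10° steps
satisfies the hydrogen-dependent criteria (pre-existing hydrogens are
trusted as fixed). Per (donor atom, acceptor atom) pair one record is
kept, with the largest qualifying D–H–A angle.

## Neighbor search

Candidate pairs come from `scipy.spatial.cKDTree` queries at the active
cutoff (centroids for the ionic detector, charged atoms for salt
bridges, acceptor atoms for hydrogen bonds); every candidate is then
tested exactly. The `backend="brute"` path enumerates all cross-group
pairs instead, and the test suite asserts bond-for-bond equality of the
two backends on random fixtures, so the tree is an invisible
optimization, not an approximation.

## ΔΔG machinery

ΔG = RT ln K_d with R = 0.0019872 kcal mol⁻¹ K⁻¹ and K_d in molar;
ΔΔG = ΔG_mut − ΔG_wt, positive = destabilizing. Each record's own
experimental temperature enters RT (default 298.15 K when absent), which
is what makes K_d values measured at different temperatures comparable.
Within each complex ΔΔG is min–max normalized to [0, 1]; a degenerate
complex (single record, or all-equal ΔΔG) maps to 0.5.

Bond-change classification works on the wild-type structure only — no
mutant side-chain modelling. A wild-type bond touching the mutated
residue through a side-chain atom is *broken*/*intact* according to
whether the mutant residue retains the relevant chemistry (opposite
charge to the partner for ionic/salt; any side-chain donor or acceptor
matching the role played for hydrogen bonds); bonds through backbone
atoms are always *intact* since a point mutation keeps the backbone.
Where no wild-type bond exists, *formed* is predicted when the mutant's
chemistry permits the bond with an opposite-group residue whose relevant
atoms lie within (bond cutoff + side-chain reach) of the site's Cβ (Cα
for glycine) — a deliberately permissive reach heuristic; the vendored
reach constants are Cβ-to-tip distances of extended side chains. A
mutation to the identical residue can only yield *intact*/*none*.

Group statistics are mean, two-sided 95% Student-t interval and
coefficient of variation (sample SD / mean) per bond type ×
classification × complex; single-value groups get no interval and empty
expected groups are reported with a `*` marker rather than silently
dropped.

## Evaluation conventions

Matching against a curated reference list is by unordered residue pair
plus bond type; atom detail is ignored because literature statements name
residues, not atoms. A pair with both hydrogen and ionic reference
entries implies a salt-bridge entry (chemical definition of a salt
bridge). Precision = TP/(TP+FP), recall = TP/(TP+FN); zero denominators
yield "undefined", never 0. True negatives are structurally unknowable in
this field and always reported as "Unknown"; because untested pairs count
as FP, reported precision is a lower bound.

## Synthetic fixtures

The generator builds residues from idealized internal coordinates
(standard bond lengths/angles, extended side chains, planar carboxylate /
amide / guanidinium groups) and poses pairs on chains A and B so one
controlled quantity matches the request to PDB precision: tip-to-tip
charged-atom distance for ionic/salt plants (with a solved tilt angle
bringing whole-residue centroids under the ionic cutoff where needed, and
a final 1-D adjustment so the *minimum* charged N···O distance is exact),
or donor-H direction and acceptor placement realizing an exact D–A
distance, D–H–A angle and antecedent angle for hydrogen plants. Decoys
violate exactly one named criterion. Geometry couples the criteria in
places — with a 1.0 Å N–H bond, |H−A| ≥ |D−A| − 1, so hydrogen plants
are only feasible for D–A ≤ 3.5 Å, and a D–A distance decoy necessarily
also exceeds the H–A cutoff; the sweep ranges respect these per-type
feasibility limits.

Each fixture ships with its *planted truth*: the exact bond list a
correct detector must report, derived from the emitted coordinates by
plain double loops inside the generator. Cross-type implications are
included honestly — a tight tilted ionic pair whose idealized ammonium
hydrogen points at the carboxylate *is* a hydrogen bond, and the truth
says so. Multi-plant complexes space plant envelopes ≥ 12 Å apart
(beyond the largest 10 Å cutoff) so sites cannot interact; generation
fails loudly rather than emit a fixture whose truth is inconsistent.

What the fixtures do **not** emulate: real folds, rotamer distributions,
crystallographic noise, solvent, disorder, or hydroxyl donors (excluded
from fixtures so the planted truth needs no rotamer search). Passing the
planted-truth suite therefore demonstrates that the geometric criteria
are implemented exactly, not that the criteria themselves capture every
bond in real structures.

The synthetic mutation tables draw ΔΔG ~ Normal(0.5, 0.75²) kcal/mol for
bond-preserving mutations and shift bond-breaking ones by +1.5 kcal/mol
(the `null` model omits the shift), then back-compute mutant K_d from a
1 nM wild-type at 298.15 K. The baseline and spread are typical of
single-point interface mutations; the +1.5 kcal/mol shift is the size of
effect expected from deleting one charged contact.

The packaged barnase–barstar worked example is a synthetic
reconstruction of the Arg59/Glu76 contact built from the same templates
(chains A and D, author numbering, closest N···O at 2.95 Å), not crystal
coordinates.

## Problem sizes

The self-validation protocols use ~210 single-pair fixtures for the
geometry sweep, 50 random complexes of up to ~2,000 atoms for the
backend-equivalence trial, and n = 200 mutations for the simulation
recovery — sizes at which the Monte-Carlo error of the recovered ΔΔG
shift (≈ 0.11 kcal/mol standard error) is well below the planted effect.

## Known limitations

* Formal charges are fixed; no pKa shifts, no metal sites, no ligands.
* π-cation, π–π, disulfide and water-mediated interactions are out of
  scope, as are intramolecular bonds.
* The *formed* classification is a reach heuristic on the wild-type
  structure; it cannot see steric exclusion of the modelled mutant side
  chain and so over-predicts formation in crowded interfaces.
* Hydroxyl rotamer sampling at 10° can in principle miss a pass band
  narrower than the step; at the default cutoffs no such case has been
  observed.
* Only the first MODEL of multi-model files is read; occupancy ties at
  alternate locations resolve to conformer A.
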