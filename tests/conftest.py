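import numpy as np
import pytest

from interbond import DetectionParams, InterfaceSpec
from interbond.structure import Atom, Residue, StructureModel


@pytest.fixture
def spec_ab() -> InterfaceSpec:
    return InterfaceSpec(frozenset("A"), frozenset("B"))


@pytest.fixture
def params() -> DetectionParams:
    return DetectionParams()


def build_residue(name, chain_id, seq, atom_coords, hydrogens=()):
    """Assemble a Residue from {atom name: coordinate} plus explicit
    hydrogen entries (name, coordinate)."""
    atoms = [
        Atom(serial=i + 1, name=n, element=n[0], coord=np.asarray(c, float))
        for i, (n, c) in enumerate(atom_coords.items())
    ]
    for n, c in hydrogens:
        atoms.append(
            Atom(serial=0, name=n, element="H", coord=np.asarray(c, float), is_hydrogen=True)
        )
    return Residue(name=name, chain_id=chain_id, seq_number=seq, atoms=atoms)


def build_model(*residues) -> StructureModel:
    chains: dict[str, list] = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return StructureModel("test", chains)


def detected_pairs(bonds_by_type):
    """Bond sets as {(type, (chain, seq), (chain, seq))} for comparison."""
    return {
        (t, (b.res1.chain_id, b.res1.seq_number), (b.res2.chain_id, b.res2.seq_number))
        for t, lst in bonds_by_type.items()
        for b in lst
    }


def truth_pairs(truth):
    return {
        (b.bond_type, (b.chain1, b.seq1), (b.chain2, b.seq2)) for b in truth.bonds
    }
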