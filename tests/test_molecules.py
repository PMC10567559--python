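"""Molecular graphs and the bond-based assembly index."""

import numpy as np
import pytest

from assemblykit.fixtures import random_molecules
from assemblykit.molecules import (
    MolGraph,
    is_valid_join,
    join_graphs,
    molecular_assembly_index,
    parse_molecule,
)
from oracles import mol_index_oracle


class TestParse:
    def test_ethane(self):
        mol = parse_molecule("CC")
        assert len(mol.atoms) == 2 and mol.n_bonds == 1

    def test_benzene_uniform_aromatic(self):
        mol = parse_molecule("c1ccccc1")
        assert len(mol.atoms) == 6 and mol.n_bonds == 6
        assert {lab for _, _, lab in mol.bonds} == {"a"}

    def test_parse_failure_names_input(self):
        with pytest.raises(ValueError, match="not_a_smiles"):
            parse_molecule("not_a_smiles")

    def test_molfile_roundtrip(self):
        from rdkit import Chem

        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CCO"))
        mol = parse_molecule(block)
        assert mol.formula == "C2O" and mol.n_bonds == 2

    def test_hydrogens_suppressed(self):
        assert parse_molecule("[H]C([H])([H])C([H])([H])[H]").n_bonds == 1


class TestMolGraphInvariants:
    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            MolGraph(atoms=("C", "C", "C", "C"), bonds=((0, 1, "1"), (2, 3, "1")))

    def test_bondless_rejected(self):
        with pytest.raises(ValueError, match="bond"):
            MolGraph(atoms=("C",), bonds=())

    def test_certificate_invariant_under_relabeling(self, rng):
        for mol in random_molecules(10, max_bonds=8, rng=rng):
            n = len(mol.atoms)
            perm = rng.permutation(n)
            bonds = tuple(
                sorted(
                    (min(perm[i], perm[j]), max(perm[i], perm[j]), lab)
                    for i, j, lab in mol.bonds
                )
            )
            atoms = [None] * n
            for old, new in enumerate(perm):
                atoms[new] = mol.atoms[old]
            shuffled = MolGraph(atoms=tuple(atoms), bonds=bonds)
            assert shuffled.certificate == mol.certificate

    def test_certificate_separates_labels(self):
        a = MolGraph(atoms=("C", "O"), bonds=((0, 1, "1"),))
        b = MolGraph(atoms=("C", "O"), bonds=((0, 1, "2"),))
        c = MolGraph(atoms=("C", "N"), bonds=((0, 1, "1"),))
        assert len({a.certificate, b.certificate, c.certificate}) == 3


class TestAssemblyIndex:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("CC", 0), ("CCCC", 2), ("c1ccccc1", 3), ("CCO", 1), ("CCCCCCCC", 4)],
    )
    def test_reference_values(self, smiles, expected):
        index, pathway = molecular_assembly_index(smiles)
        assert index == expected
        pathway.validate()
        assert pathway.length == index

    def test_isomorphic_inputs_same_index(self):
        assert molecular_assembly_index("OCC")[0] == molecular_assembly_index("CCO")[0]

    def test_matches_exhaustive_enumeration_small(self, rng):
        for mol in random_molecules(12, max_bonds=5, rng=rng):
            assert molecular_assembly_index(mol)[0] == mol_index_oracle(mol)

    def test_log2_lower_and_linear_upper_bounds(self, rng):
        for mol in random_molecules(8, max_bonds=9, rng=rng):
            e = mol.n_bonds
            index, _ = molecular_assembly_index(mol)
            assert max(0, (e - 1).bit_length()) <= index <= e - 1

    def test_no_reusable_duplicates_means_linear_cost(self):
        # all four bonds pairwise distinct: N-C, C=O, C-O, O-O is impossible;
        # use N-C(=O)-O-C? bonds: N-C, C=O, C-O, O-C -> C-O repeats.
        # O=C-N with bonds C=O and C-N only:
        index, _ = molecular_assembly_index("O=CN")
        assert index == 1  # E - 1 with E = 2
        # four distinct bond types: N#C-C=O : N#C, C-C, C=O
        index, _ = molecular_assembly_index("N#CC=O")
        assert index == 2  # E - 1 with E = 3

    def test_duplicated_fragment_beats_linear_bound(self):
        # octane: path of 7 identical C-C bonds; doubling gives 4 < 6
        index, _ = molecular_assembly_index("CCCCCCCC")
        assert index < 7 - 1

    def test_over_limit_refusal_reports_bounds(self):
        with pytest.raises(ValueError, match="bonds"):
            molecular_assembly_index("C" * 40, max_bonds=30)

    def test_ring_closure_toggle(self):
        # cyclopropane needs a lone bond fused at both endpoints
        assert molecular_assembly_index("C1CC1")[0] == 2
        with pytest.raises(ValueError, match="pathway"):
            molecular_assembly_index("C1CC1", allow_ring_closure=False)
        # benzene closes its ring with a two-bond motif: allowed either way
        assert molecular_assembly_index("c1ccccc1", allow_ring_closure=False)[0] == 3


class TestJoins:
    def test_join_graphs_fuses_atoms(self):
        cc = MolGraph(atoms=("C", "C"), bonds=((0, 1, "1"),))
        product = join_graphs(cc, cc, fuse={0: 1})
        assert product.n_bonds == 2 and len(product.atoms) == 3

    def test_join_graphs_rejects_element_mismatch(self):
        cc = MolGraph(atoms=("C", "C"), bonds=((0, 1, "1"),))
        co = MolGraph(atoms=("C", "O"), bonds=((0, 1, "1"),))
        with pytest.raises(ValueError, match="fuse"):
            join_graphs(cc, co, fuse={1: 0})

    def test_is_valid_join_by_isomorphism(self):
        butane = parse_molecule("CCCC")
        cc = MolGraph(atoms=("C", "C"), bonds=((0, 1, "1"),))
        ccc = MolGraph(atoms=("C", "C", "C"), bonds=((0, 1, "1"), (1, 2, "1")))
        assert is_valid_join(ccc, cc, butane)
        assert not is_valid_join(cc, cc, butane)
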