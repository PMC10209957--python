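"""The edit algebra and the deterministic application engine."""

import pytest

from retroedits.edits import (
    AttachLG,
    ChangeAtom,
    ChangeBond,
    DeleteBond,
    Edit,
    SiteError,
    Terminate,
    apply_edit,
    apply_sequence,
    attach_leaving_group,
    edits_from_jsonl,
    edits_to_jsonl,
)
from retroedits.mol_graph import ChemistryError, MolecularGraph


class TestApplyEdit:
    def test_delete_bond_splits_fragment(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH2:2][O:3][CH3:4]")
        out = apply_edit(g, DeleteBond(2, 3))
        assert out.num_fragments() == g.num_fragments() + 1

    def test_delete_bond_frees_hydrogens(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        out = apply_edit(g, DeleteBond(1, 2))
        atom = out.mol.GetAtomWithIdx(out.atom_index_by_map(1))
        assert atom.GetTotalNumHs() == 4

    def test_terminate_is_identity(self):
        g = MolecularGraph.from_smiles("[CH3:1][OH:2]")
        assert apply_edit(g, Terminate()).to_smiles() == g.to_smiles()

    def test_input_graph_never_mutated(self):
        g = MolecularGraph.from_smiles("[CH3:1][OH:2]")
        before = g.to_smiles()
        apply_edit(g, DeleteBond(1, 2))
        apply_edit(g, ChangeAtom(1, 2, 0))
        assert g.to_smiles() == before

    def test_missing_site_raises(self):
        g = MolecularGraph.from_smiles("[CH3:1][OH:2]")
        with pytest.raises(SiteError):
            apply_edit(g, DeleteBond(1, 9))
        with pytest.raises(SiteError):
            apply_edit(g, ChangeBond(1, 9, 2, 0))

    def test_change_bond_adjusts_hydrogens(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        out = apply_edit(g, ChangeBond(1, 2, 2, 0))
        assert out.to_smiles(strip_maps=True) == "C=C"

    def test_change_atom_sets_h_and_parity(self):
        g = MolecularGraph.from_smiles("[CH3:1][NH2:2]")
        out = apply_edit(g, ChangeAtom(2, 0, 0))
        atom = out.mol.GetAtomWithIdx(out.atom_index_by_map(2))
        assert atom.GetTotalNumHs() == 0

    def test_map_numbers_preserved(self, records16):
        for rec in records16[:6]:
            maps = rec.product.map_numbers()
            result = apply_sequence(rec.product, rec.edits)
            assert maps <= result.final.map_numbers()


class TestAttachLeavingGroup:
    def test_hydroxyl_on_methane(self):
        g = MolecularGraph.from_smiles("[CH4:1]")
        direct = MolecularGraph.from_smiles("CO")  # independent construction
        out = attach_leaving_group(g, 1, "*O")
        assert out.to_smiles(strip_maps=True) == direct.to_smiles(strip_maps=True)

    def test_bromide_single_bond(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        out = attach_leaving_group(g, 1, "*Br")
        assert out.to_smiles(strip_maps=True) == "CCBr"

    def test_double_bond_oxygen_drops_two_hydrogens(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH2:2][CH3:3]")
        out = attach_leaving_group(g, 2, "*=O")
        atom = out.mol.GetAtomWithIdx(out.atom_index_by_map(2))
        assert atom.GetTotalNumHs() == 0
        assert out.to_smiles(strip_maps=True) == "CC(C)=O"

    def test_two_dummy_group_closes_ring(self):
        g = MolecularGraph.from_smiles("[CH3:2][NH2:1]")
        seq = [ChangeAtom(1, 0, 0), AttachLG(1, "*C(=O)c1ccccc1C(*)=O"), Terminate()]
        result = apply_sequence(g, seq)
        assert result.final.to_smiles(strip_maps=True) == "CN1C(=O)c2ccccc2C1=O"

    def test_new_atoms_get_fresh_maps(self):
        g = MolecularGraph.from_smiles("[CH4:1]")
        out = attach_leaving_group(g, 1, "*N(C)C")
        assert out.map_numbers() == {1, 2, 3, 4}

    def test_no_dummy_rejected(self):
        g = MolecularGraph.from_smiles("[CH4:1]")
        with pytest.raises(ChemistryError):
            attach_leaving_group(g, 1, "O")

    def test_valence_overflow_rejected(self):
        # quaternary carbon has no hydrogens to trim: a fifth bond is a
        # hard chemistry error
        g = MolecularGraph.from_smiles("[C:1](C)(C)(C)C")
        with pytest.raises(ChemistryError):
            attach_leaving_group(g, 1, "*Br")


class TestApplySequence:
    def test_terminate_only(self):
        g = MolecularGraph.from_smiles("[CH3:1][OH:2]")
        result = apply_sequence(g, [Terminate()])
        assert result.terminated
        assert result.final.to_smiles() == g.to_smiles()
        assert result.intermediates == []

    def test_bond_center_coupling(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH2:2][CH2:3][CH3:4]")
        seq = [DeleteBond(2, 3), AttachLG(2, "*N(C)C"), AttachLG(3, "*Br"), Terminate()]
        result = apply_sequence(g, seq)
        frags = sorted(result.final.to_smiles(strip_maps=True).split("."))
        assert frags == ["CCBr", "CCN(C)C"]

    def test_missing_terminate_flagged_incomplete(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        result = apply_sequence(g, [DeleteBond(1, 2)])
        assert not result.terminated

    def test_misplaced_terminate_rejected(self):
        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        with pytest.raises(ValueError):
            apply_sequence(g, [Terminate(), DeleteBond(1, 2)])
        with pytest.raises(ValueError):
            apply_sequence(g, [])

    def test_step_error_carries_index(self):
        from retroedits.edits import EditApplicationError

        g = MolecularGraph.from_smiles("[CH3:1][CH3:2]")
        with pytest.raises(EditApplicationError) as exc:
            apply_sequence(g, [DeleteBond(1, 2), DeleteBond(1, 2), Terminate()])
        assert exc.value.step == 1

    def test_fixture_roundtrip(self, records16):
        for rec in records16:
            result = apply_sequence(rec.product, rec.edits)
            assert result.final.to_smiles(strip_maps=True) == rec.reactants_smiles()


class TestSerialization:
    def test_jsonl_roundtrip(self):
        seq = [
            DeleteBond(2, 3),
            ChangeBond(1, 2, 2, 0),
            ChangeAtom(4, 1, 2),
            AttachLG(4, "*O"),
            Terminate(),
        ]
        assert edits_from_jsonl(edits_to_jsonl(seq)) == seq

    def test_dict_layout(self):
        d = AttachLG(4, "*O").to_dict()
        assert d == {"type": "AttachLG", "site": 4, "payload": "*O"}
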