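"""Edit-sequence extraction by reaction diffing, and the vocabulary."""

import pytest

from retroedits.edits import EditVocabulary, Terminate
from retroedits.extraction import (
    UnextractableReactionError,
    build_vocabulary,
    edit_coverage,
    extract_edit_sequence,
    preprocess_records,
    validate_applicability,
)
from retroedits.fixtures import TEMPLATE_KINDS, generate_reactions
from retroedits.mol_graph import parse_reaction


def _kinds(seq):
    return [e.kind for e in seq]


class TestExtractEditSequence:
    def test_identity_reaction_terminate_only(self):
        rec = parse_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        assert _kinds(extract_edit_sequence(rec)) == ["Terminate"]

    def test_deprotection_atom_center(self):
        # free amine -> phthalimide-protected amine: first reduce the
        # nitrogen's hydrogens, then attach the two-dummy leaving group
        rec = parse_reaction("[CH3:2][N:1]1C(=O)c2ccccc2C1=O>>[CH3:2][NH2:1]")
        seq = extract_edit_sequence(rec)
        assert _kinds(seq) == ["ChangeAtom", "AttachLG", "Terminate"]
        assert seq[0].payload_key() == ("ChangeAtom", 0, 0)
        assert seq[1].smiles == "*C(=O)c1ccccc1C(*)=O"
        assert seq[0].site == seq[1].site

    def test_bond_center_two_leaving_groups(self):
        rec = parse_reaction(
            "[CH3:1][CH2:2]N(C)C.[CH3:4][CH2:3]Br>>[CH3:1][CH2:2][CH2:3][CH3:4]"
        )
        seq = extract_edit_sequence(rec)
        assert _kinds(seq) == ["DeleteBond", "AttachLG", "AttachLG", "Terminate"]
        assert sorted(e.smiles for e in seq[1:3]) == ["*Br", "*N(C)C"]

    def test_multi_center_ring_opening(self):
        # pyrrole-forming condensation in retro: two deletes, then bond
        # order changes, then the two carbonyl leaving groups
        rec = parse_reaction(
            "[CH3:6][NH2:1].[CH3:7][C:2](=O)[CH2:3][CH2:4][C:5](=O)[CH3:8]"
            ">>[CH3:6][n:1]1[c:2]([CH3:7])[cH:3][cH:4][c:5]1[CH3:8]"
        )
        seq = extract_edit_sequence(rec)
        assert _kinds(seq) == [
            "DeleteBond", "DeleteBond", "ChangeBond", "ChangeBond",
            "AttachLG", "AttachLG", "Terminate",
        ]
        assert all(e.smiles == "*=O" for e in seq[4:6])

    def test_chirality_inversion_emits_change_atom(self):
        rec = parse_reaction(
            "[CH3:1][C@@H:2]([CH2:3][CH3:4])O.[OH:5][CH3:6]"
            ">>[CH3:1][C@H:2]([CH2:3][CH3:4])[O:5][CH3:6]"
        )
        seq = extract_edit_sequence(rec)
        assert _kinds(seq) == ["DeleteBond", "ChangeAtom", "AttachLG", "Terminate"]
        assert seq[1].chiral in (1, 2)

    def test_bond_formation_unextractable(self):
        # the reactants close a ring between two mapped atoms: the bond
        # formation cannot be expressed in the edit scheme
        rec = parse_reaction(
            "[CH2:1]1[CH2:2][CH2:3]1>>[CH3:1][CH2:2][CH3:3]"
        )
        with pytest.raises(UnextractableReactionError):
            extract_edit_sequence(rec)

    def test_spectator_fragment_unextractable(self):
        rec = parse_reaction("[CH3:1][OH:2].CCCC>>[CH3:1][OH:2]")
        with pytest.raises(UnextractableReactionError):
            extract_edit_sequence(rec)

    def test_deterministic(self, records16):
        for rec in records16[:5]:
            a = extract_edit_sequence(rec, assume_canonical=True)
            b = extract_edit_sequence(rec, assume_canonical=True)
            assert a == b

    def test_priority_order(self, records16):
        rank = {"DeleteBond": 0, "ChangeBond": 1, "ChangeAtom": 2, "AttachLG": 3,
                "Terminate": 4}
        for rec in records16:
            ranks = [rank[e.kind] for e in rec.edits]
            assert ranks == sorted(ranks)


class TestBuildVocabulary:
    def test_empty_input_terminate_only(self):
        vocab = build_vocabulary([])
        assert len(vocab) == 1
        assert vocab.contains_edit(Terminate())

    def test_template_implied_payloads(self):
        # with every template active, the vocabulary is exactly the union
        # of payloads the templates can emit
        recs = generate_reactions(100, seed=1)
        vocab = build_vocabulary(recs)
        bond = set(vocab.bond_payloads)
        assert bond <= {("DeleteBond",), ("ChangeBond", 2, 0), ("ChangeBond", 1, 0)}
        assert ("DeleteBond",) in bond
        lgs = {p[1] for p in vocab.atom_payloads if p[0] == "AttachLG"}
        assert lgs <= {
            "*C(=O)c1ccccc1C(*)=O", "*C(=O)OC(C)(C)C", "*N(C)C", "*Br", "*Cl",
            "*I", "*O", "*=O", "*OC", "*OCC",
        }

    def test_min_lg_count_filters_rare_groups(self, records16):
        full = build_vocabulary(records16, min_lg_count=1)
        filtered = build_vocabulary(records16, min_lg_count=1000)
        assert not any(p[0] == "AttachLG" for p in filtered.atom_payloads)
        assert any(p[0] == "AttachLG" for p in full.atom_payloads)
        # ChangeAtom payloads are never filtered by the leaving-group rule
        change_full = {p for p in full.atom_payloads if p[0] == "ChangeAtom"}
        change_filt = {p for p in filtered.atom_payloads if p[0] == "ChangeAtom"}
        assert change_full == change_filt

    def test_order_independent(self, records16):
        a = build_vocabulary(records16)
        b = build_vocabulary(list(reversed(records16)))
        assert a.bond_payloads == b.bond_payloads
        assert a.atom_payloads == b.atom_payloads

    def test_save_load_roundtrip(self, tmp_path, vocab16):
        path = tmp_path / "vocab.json"
        vocab16.save(path)
        loaded = EditVocabulary.load(path)
        assert loaded.bond_payloads == vocab16.bond_payloads
        assert loaded.atom_payloads == vocab16.atom_payloads
        assert loaded.content_hash() == vocab16.content_hash()


class TestDatasetOperations:
    def test_applicability_on_fixtures_is_one(self, records16):
        frac, failures = validate_applicability(records16)
        assert frac == 1.0
        assert failures == []

    def test_applicability_counts_unsupported(self, records16):
        bad = parse_reaction("[CH3:1][OH:2].CCCC>>[CH3:1][OH:2]")
        frac, failures = validate_applicability(list(records16) + [bad])
        assert frac == len(records16) / (len(records16) + 1)
        assert len(failures) == 1
        assert "Unextractable" in failures[0][1]

    def test_preprocess_drops_and_counts_failures(self, records16):
        bad = parse_reaction("[CH3:1][OH:2].CCCC>>[CH3:1][OH:2]")
        kept, report = preprocess_records(list(records16) + [bad])
        assert report.n_total == len(records16) + 1
        assert report.n_failed == 1
        assert len(kept) == len(records16)
        assert sum(report.length_histogram.values()) == report.n_extracted

    def test_edit_coverage_monotone_in_training_size(self):
        recs = generate_reactions(60, seed=9)
        train_small, train_big, held = recs[:10], recs[:40], recs[40:]
        cov_small = edit_coverage(held, build_vocabulary(train_small))
        cov_big = edit_coverage(held, build_vocabulary(train_big))
        assert cov_big >= cov_small
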