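"""Beam-search decoding against brute-force enumeration."""

import numpy as np
import pytest

from retroedits.beam import beam_search
from retroedits.edits import Terminate, apply_edit
from retroedits.extraction import build_vocabulary
from retroedits.fixtures import generate_reactions
from retroedits.mol_graph import MolecularGraph, featurize
from retroedits.policy import (
    ModelConfig,
    align_h_prev,
    init_model_params,
    prepare_sequence_samples,
    score_step,
)


def _toy_model():
    """A tiny random-weight model over a 3-candidate step space.

    Methane with a vocabulary of two atom payloads gives exactly
    ChangeAtom / AttachLG / Terminate as candidates each step.
    """
    recs = generate_reactions(6, seed=2)
    vocab = build_vocabulary(recs)
    # restrict to two atom payloads and no bond payloads
    vocab = type(vocab)(
        bond_payloads=[],
        atom_payloads=[("ChangeAtom", 3, 0), ("AttachLG", "*O")],
    )
    cfg = ModelConfig(hidden_size=8, depth=1, seed=0, beam_width=10, max_steps=2)
    params = init_model_params(np.random.default_rng(4), cfg, vocab)
    return cfg, params, vocab


def _enumerate_all(product, params, cfg, vocab, max_steps):
    """Exhaustively expand every candidate sequence (the oracle)."""
    results = []

    def recurse(graph, h_prev, prev_maps, logp, edits, depth):
        if depth == max_steps:
            return
        fg = featurize(graph)
        aligned = (
            align_h_prev(h_prev, prev_maps, fg.atom_maps)
            if h_prev is not None
            else None
        )
        sc = score_step(fg, aligned, params, cfg, vocab)
        for ci in range(sc.n_candidates):
            edit = sc.candidate_edit(ci, vocab)
            lp = logp + float(sc.log_probs.data[ci])
            if isinstance(edit, Terminate):
                try:
                    smiles = graph.to_smiles(keep_stereo=True, strip_maps=True)
                except Exception:
                    continue
                results.append((lp, smiles, edits + [edit]))
                continue
            try:
                new_graph = apply_edit(graph, edit)
            except Exception:
                continue
            recurse(
                new_graph, sc.fused.data, fg.atom_maps, lp, edits + [edit], depth + 1
            )

    recurse(product, None, None, 0.0, [], 0)
    results.sort(key=lambda t: -t[0])
    # dedupe by reactant SMILES keeping the best score
    seen, unique = set(), []
    for lp, smiles, edits in results:
        if smiles in seen:
            continue
        seen.add(smiles)
        unique.append((lp, smiles, edits))
    return unique


class TestBeamAgainstOracle:
    def test_wide_beam_equals_exhaustive_enumeration(self):
        cfg, params, vocab = _toy_model()
        product = MolecularGraph.from_smiles("[CH4:1]")
        oracle = _enumerate_all(product, params, cfg, vocab, max_steps=2)
        preds = beam_search(product, params, cfg, vocab, k=9, max_steps=2)
        assert len(preds) == len(oracle)
        for p, (lp, smiles, edits) in zip(preds, oracle):
            assert p.reactants == smiles
            assert p.log_prob == pytest.approx(lp, abs=1e-12)
            assert p.edits == edits

    def test_greedy_is_width_one_beam(self):
        cfg, params, vocab = _toy_model()
        product = MolecularGraph.from_smiles("[CH4:1]")
        greedy = beam_search(product, params, cfg, vocab, k=1, max_steps=2)
        wide = beam_search(product, params, cfg, vocab, k=9, max_steps=2)
        if greedy:  # greedy may end un-terminated; wide always ranks more
            # the greedy result must be reproducible by following argmax
            fg = featurize(product)
            sc = score_step(fg, None, params, cfg, vocab)
            best = int(np.argmax(sc.log_probs.data))
            assert greedy[0].edits[0] == sc.candidate_edit(best, vocab)

    def test_widening_the_beam_never_loses_better_sequences(self):
        cfg, params, vocab = _toy_model()
        product = MolecularGraph.from_smiles("[CH4:1]")
        small = beam_search(product, params, cfg, vocab, k=3, max_steps=2)
        large = beam_search(product, params, cfg, vocab, k=9, max_steps=2)
        top = min(len(small), len(large))
        for a, b in zip(small[:1], large[:1]):
            assert b.log_prob >= a.log_prob - 1e-12


@pytest.fixture(scope="module")
def fitted(vocab16):
    cfg = ModelConfig(hidden_size=16, depth=2, seed=1)
    params = init_model_params(np.random.default_rng(1), cfg, vocab16)
    return cfg, params


class TestBeamInvariants:
    def test_scores_nonpositive_and_sorted(self, fitted, records16, vocab16):
        cfg, params = fitted
        preds = beam_search(records16[0].product, params, cfg, vocab16, k=5)
        lps = [p.log_prob for p in preds]
        assert all(lp <= 1e-12 for lp in lps)
        assert lps == sorted(lps, reverse=True)

    def test_deterministic(self, fitted, records16, vocab16):
        cfg, params = fitted
        a = beam_search(records16[1].product, params, cfg, vocab16, k=5)
        b = beam_search(records16[1].product, params, cfg, vocab16, k=5)
        assert [(p.reactants, p.log_prob) for p in a] == [
            (p.reactants, p.log_prob) for p in b
        ]

    def test_duplicate_reactants_deduplicated(self, fitted, records16, vocab16):
        cfg, params = fitted
        for rec in records16[:4]:
            preds = beam_search(rec.product, params, cfg, vocab16, k=8)
            smiles = [p.reactants for p in preds]
            assert len(smiles) == len(set(smiles))

    def test_ranks_are_contiguous(self, fitted, records16, vocab16):
        cfg, params = fitted
        preds = beam_search(records16[2].product, params, cfg, vocab16, k=6)
        assert [p.rank for p in preds] == list(range(1, len(preds) + 1))

    def test_invalid_product_rejected(self, fitted, vocab16):
        from retroedits.mol_graph import ChemistryError

        cfg, params = fitted
        bad = MolecularGraph.from_smiles("C")
        bad.mol.GetAtomWithIdx(0).SetNumExplicitHs(7)
        with pytest.raises(ChemistryError):
            beam_search(bad, params, cfg, vocab16, k=2)
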