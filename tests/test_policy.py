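"""Edit scoring heads, teacher-forced loss and training behavior."""

import numpy as np
import pytest

from retroedits.edits import Terminate
from retroedits.extraction import build_vocabulary
from retroedits.fixtures import generate_reactions
from retroedits.mol_graph import parse_reaction
from retroedits.policy import (
    DataError,
    ModelConfig,
    init_model_params,
    prepare_sequence_samples,
    score_step,
    sequence_loss,
    teacher_forced_accuracy,
    train_model,
)


@pytest.fixture(scope="module")
def setup(records16, vocab16):
    cfg = ModelConfig(hidden_size=16, depth=2, seed=0)
    params = init_model_params(np.random.default_rng(0), cfg, vocab16)
    samples = prepare_sequence_samples(records16, vocab16)
    return cfg, params, samples


class TestScoreStep:
    def test_probabilities_sum_to_one(self, setup, vocab16):
        cfg, params, samples = setup
        for sample in samples[:4]:
            sc = score_step(sample.steps[0].fg, None, params, cfg, vocab16)
            assert np.exp(sc.log_probs.data).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_head_weights_give_uniform(self, setup, vocab16):
        cfg, params, samples = setup
        params = {k: type(p)(p.data.copy()) for k, p in params.items()}
        for k in ("head.bond.u", "head.atom.u", "head.graph.u"):
            params[k].data[:] = 0.0
        sc = score_step(samples[0].steps[0].fg, None, params, cfg, vocab16)
        n = sc.n_candidates
        assert np.allclose(np.exp(sc.log_probs.data), 1.0 / n)

    def test_candidate_roundtrip(self, setup, vocab16):
        cfg, params, samples = setup
        sc = score_step(samples[0].steps[0].fg, None, params, cfg, vocab16)
        edits = [sc.candidate_edit(i, vocab16) for i in range(sc.n_candidates)]
        assert isinstance(edits[-1], Terminate)
        assert len({repr(e) for e in edits}) == len(edits)


class TestSequenceLoss:
    def test_uniform_model_closed_form(self, setup, vocab16):
        """With zero output weights the loss is sum_t log(M_t) exactly."""
        cfg, params, samples = setup
        params = {k: type(p)(p.data.copy()) for k, p in params.items()}
        for k in ("head.bond.u", "head.atom.u", "head.graph.u"):
            params[k].data[:] = 0.0
        loss = float(sequence_loss(samples, params, cfg, vocab16).data)
        expect = np.mean(
            [sum(np.log(st.n_candidates) for st in s.steps) for s in samples]
        )
        assert loss == pytest.approx(expect, abs=1e-6)

    def test_single_candidate_model_has_zero_loss(self):
        """A vocabulary holding only Terminate makes every step a
        single-candidate distribution: probability one on ground truth."""
        rec = parse_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        rec.edits = [Terminate()]
        vocab = build_vocabulary([])
        cfg = ModelConfig(hidden_size=8, depth=1, seed=0)
        params = init_model_params(np.random.default_rng(0), cfg, vocab)
        samples = prepare_sequence_samples([rec], vocab)
        loss = float(sequence_loss(samples, params, cfg, vocab).data)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_loss_matches_independent_step_products(self, setup, vocab16):
        """-log of independently recomputed per-step target probabilities."""
        cfg, params, samples = setup
        from retroedits.policy import align_h_prev

        want = []
        for s in samples[:3]:
            h_prev = prev_maps = None
            nll = 0.0
            for st in s.steps:
                aligned = (
                    align_h_prev(h_prev, prev_maps, st.fg.atom_maps)
                    if h_prev is not None
                    else None
                )
                sc = score_step(st.fg, aligned, params, cfg, vocab16)
                probs = np.exp(sc.log_probs.data)
                nll -= np.log(probs[st.target])
                h_prev, prev_maps = sc.fused.data, st.fg.atom_maps
            want.append(nll)
        got = float(sequence_loss(samples[:3], params, cfg, vocab16).data)
        assert got == pytest.approx(np.mean(want), rel=1e-9)

    def test_batch_order_invariance(self, setup, vocab16):
        cfg, params, samples = setup
        a = float(sequence_loss(samples[:4], params, cfg, vocab16).data)
        b = float(sequence_loss(samples[:4][::-1], params, cfg, vocab16).data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_payload_is_data_error(self, records16):
        vocab = build_vocabulary([])  # Terminate only
        with pytest.raises(DataError):
            prepare_sequence_samples(records16, vocab)

    def test_first_step_prev_term_is_zero_contribution(self, setup, vocab16):
        """Zeroing W_v changes nothing at step one (previous states are
        zero-padded there)."""
        cfg, params, samples = setup
        params_zero = {k: type(p)(p.data.copy()) for k, p in params.items()}
        params_zero["fuse.W_v"].data[:] = 0.0
        st = samples[0].steps[0]
        a = score_step(st.fg, None, params, cfg, vocab16).log_probs.data
        b = score_step(st.fg, None, params_zero, cfg, vocab16).log_probs.data
        assert np.allclose(a, b)


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, records16, vocab16):
        cfg = ModelConfig(
            hidden_size=24, depth=2, epochs=8, batch_size=8, seed=3,
            mpnn_dropout=0.0, head_dropout=0.0,
        )
        res1 = train_model(records16, vocab16, cfg)
        res2 = train_model(records16, vocab16, cfg)
        losses = [h["loss"] for h in res1.history]
        assert losses[-1] < losses[0]
        assert res1.history[0]["loss"] == res2.history[0]["loss"]
        assert res1.history[-1]["loss"] == res2.history[-1]["loss"]

    def test_empty_dataset_rejected(self, vocab16):
        cfg = ModelConfig(hidden_size=8, depth=1, epochs=1)
        with pytest.raises(ValueError):
            train_model([], vocab16, cfg)

    def test_accuracy_metric_in_unit_interval(self, setup, vocab16):
        cfg, params, samples = setup
        acc = teacher_forced_accuracy(samples, params, cfg, vocab16)
        assert 0.0 <= acc <= 1.0


class TestCheckpoint:
    def test_roundtrip_and_hash_guard(self, tmp_path, records16, vocab16):
        from retroedits.policy import load_checkpoint, save_checkpoint

        cfg = ModelConfig(hidden_size=8, depth=1, seed=0)
        params = init_model_params(np.random.default_rng(0), cfg, vocab16)
        save_checkpoint(tmp_path / "ckpt", params, cfg, vocab16)
        p2, c2, v2 = load_checkpoint(tmp_path / "ckpt")
        assert c2 == cfg
        assert v2.content_hash() == vocab16.content_hash()
        for k in params:
            assert np.allclose(params[k].data, p2[k].data)
        # corrupt the vocabulary: load must refuse
        other = build_vocabulary(generate_reactions(4, seed=99))
        other.save(tmp_path / "ckpt" / "vocab.json")
        if other.content_hash() != vocab16.content_hash():
            with pytest.raises(ValueError):
                load_checkpoint(tmp_path / "ckpt")

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig.from_dict({"hidden_size": 8, "bogus_knob": 1})
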