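"""Autoregressive edit scoring, teacher-forced loss and training.

At each generation step the current intermediate graph is encoded, fused
with the previous step's atom states (zero-padded for freshly attached
atoms, and all-zero at the first step), and scored by three fully
connected heads: one logit per existing bond x bond-edit payload, one per
atom x atom-edit payload, and a single terminate logit on the summed
graph vector.  A single softmax over the concatenation of all logits
yields the step's edit distribution, used both for the cross-entropy
training objective (teacher forcing on ground-truth intermediates) and
for beam scoring, so training and inference optimize the same quantity.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .edits import Edit, EditVocabulary, Terminate, apply_sequence
from .encoder import EncoderConfig, encode_graph, init_encoder_params
from .mol_graph import FeaturizedGraph, MolecularGraph, ReactionRecord, featurize


class DataError(ValueError):
    """A record's ground-truth edit cannot be represented for its graph."""


@dataclass
class ModelConfig:
    """All hyperparameters of the encoder, heads and trainer."""

    hidden_size: int = 256
    depth: int = 10
    encoder: str = "dmpnn"
    mpnn_dropout: float = 0.15
    head_hidden: int = 512
    head_dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 32
    lr_factor: float = 0.8
    lr_patience: int = 5
    lr_threshold: float = 0.01
    clip_norm: float = 10.0
    beam_width: int = 10
    max_steps: int = 9
    min_lg_count: int = 1
    seed: int = 0

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            hidden_size=self.hidden_size,
            depth=self.depth,
            dropout=self.mpnn_dropout,
            variant=self.encoder,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def init_model_params(
    rng: np.random.Generator, config: ModelConfig, vocab: EditVocabulary
) -> dict[str, Tensor]:
    h = config.hidden_size
    hh = config.head_hidden
    enc = init_encoder_params(rng, config.encoder_config())
    p: dict[str, np.ndarray] = {
        "fuse.W_v": ag.glorot(rng, h, h),
        "fuse.W_c": ag.glorot(rng, h, h),
        "head.bond.W": ag.glorot(rng, 2 * h, hh),
        "head.bond.c": np.zeros((1, hh)),
        "head.bond.u": ag.glorot(rng, hh, max(vocab.n_bond, 1)),
        "head.atom.W": ag.glorot(rng, h, hh),
        "head.atom.c": np.zeros((1, hh)),
        "head.atom.u": ag.glorot(rng, hh, max(vocab.n_atom, 1)),
        "head.graph.W": ag.glorot(rng, h, hh),
        "head.graph.c": np.zeros((1, hh)),
        "head.graph.u": ag.glorot(rng, hh, 1),
    }
    params = {k: Tensor(v) for k, v in p.items()}
    params.update(enc)
    return params


# --------------------------------------------------------------------------
# Step scoring
# --------------------------------------------------------------------------


@dataclass
class StepScores:
    """Joint log-probabilities over all candidate edits of one step.

    Candidate order: bond-major (bond b x bond payload p at ``b * n_bond
    + p``), then atom-major, then the terminate symbol last.
    """

    log_probs: Tensor              # (n_candidates,)
    fused: Tensor                  # (n_atoms, hidden) -- next step's h_prev
    fg: FeaturizedGraph
    n_bond_payloads: int
    n_atom_payloads: int

    @property
    def n_candidates(self) -> int:
        return self.log_probs.data.shape[0]

    def candidate_edit(self, index: int, vocab: EditVocabulary) -> Edit:
        nb, na = self.n_bond_payloads, self.n_atom_payloads
        n_bonds = self.fg.bond_maps.shape[0]
        n_atoms = self.fg.atom_maps.shape[0]
        if index < n_bonds * nb:
            b, p = divmod(index, nb)
            site = tuple(int(x) for x in self.fg.bond_maps[b])
            return vocab.bond_edit(vocab.bond_payloads[p], site)
        index -= n_bonds * nb
        if index < n_atoms * na:
            a, p = divmod(index, na)
            return vocab.atom_edit(
                vocab.atom_payloads[p], int(self.fg.atom_maps[a])
            )
        return Terminate()


def score_step(
    fg: FeaturizedGraph,
    h_prev: Optional[np.ndarray],
    params: dict[str, Tensor],
    config: ModelConfig,
    vocab: EditVocabulary,
    dropout_rng: Optional[np.random.Generator] = None,
) -> StepScores:
    """Score every candidate edit of the current graph.

    ``h_prev`` holds the previous step's fused atom states aligned to this
    graph's atom order (zero rows for new atoms); None means first step.
    """
    n = fg.atom_x.shape[0]
    h = config.hidden_size
    enc = encode_graph(fg, params, config.encoder_config(), dropout_rng)
    if h_prev is None:
        prev = ag.constant(np.zeros((n, h)))
    elif isinstance(h_prev, Tensor):
        prev = h_prev
    else:
        prev = ag.constant(np.asarray(h_prev))
    fused = ag.relu(prev @ params["fuse.W_v"] + enc @ params["fuse.W_c"])

    logits = []
    n_bonds = fg.bond_pairs.shape[0]
    if n_bonds and vocab.n_bond:
        bond_rep = ag.concat(
            [ag.rows(fused, fg.bond_pairs[:, 0]), ag.rows(fused, fg.bond_pairs[:, 1])],
            axis=1,
        )
        hid = ag.relu(bond_rep @ params["head.bond.W"] + params["head.bond.c"])
        hid = ag.dropout(hid, config.head_dropout, dropout_rng)
        logits.append((hid @ params["head.bond.u"]).reshape(-1))
    if vocab.n_atom:
        hid = ag.relu(fused @ params["head.atom.W"] + params["head.atom.c"])
        hid = ag.dropout(hid, config.head_dropout, dropout_rng)
        logits.append((hid @ params["head.atom.u"]).reshape(-1))
    graph_vec = ag.segment_sum(fused, np.zeros(n, dtype=np.int64), 1)
    hid = ag.relu(graph_vec @ params["head.graph.W"] + params["head.graph.c"])
    hid = ag.dropout(hid, config.head_dropout, dropout_rng)
    logits.append((hid @ params["head.graph.u"]).reshape(-1))

    flat = ag.concat(logits, axis=0) if len(logits) > 1 else logits[0]
    return StepScores(
        log_probs=ag.log_softmax(flat),
        fused=fused,
        fg=fg,
        n_bond_payloads=vocab.n_bond if n_bonds else 0,
        n_atom_payloads=vocab.n_atom,
    )


def align_h_prev(
    fused: np.ndarray, prev_maps: np.ndarray, next_maps: np.ndarray
) -> np.ndarray:
    """Re-align fused states to the next graph's atom order, zero-padding
    atoms that did not exist at the previous step."""
    h = fused.shape[1]
    out = np.zeros((len(next_maps), h))
    lookup = {int(m): i for i, m in enumerate(prev_maps)}
    for row, m in enumerate(next_maps):
        i = lookup.get(int(m))
        if i is not None:
            out[row] = fused[i]
    return out


def _align_h_prev_tensor(
    fused: Tensor, prev_maps: np.ndarray, next_maps: np.ndarray
) -> Tensor:
    """Autograd-aware version of :func:`align_h_prev`: gradient flows back
    into the previous step's fused states (zero row for new atoms)."""
    n_prev, h = fused.data.shape
    padded = ag.concat([fused, ag.constant(np.zeros((1, h)))], axis=0)
    lookup = {int(m): i for i, m in enumerate(prev_maps)}
    idx = np.asarray(
        [lookup.get(int(m), n_prev) for m in next_maps], dtype=np.int64
    )
    return ag.rows(padded, idx)


# --------------------------------------------------------------------------
# Teacher-forced sequences
# --------------------------------------------------------------------------


@dataclass
class StepSample:
    fg: FeaturizedGraph
    target: int
    n_candidates: int


@dataclass
class SequenceSample:
    record_id: Optional[str]
    steps: list[StepSample]


def _target_index(
    fg: FeaturizedGraph, edit: Edit, vocab: EditVocabulary, record_id
) -> int:
    nb, na = vocab.n_bond, vocab.n_atom
    n_bonds = fg.bond_maps.shape[0]
    n_atoms = fg.atom_maps.shape[0]
    key = edit.payload_key()
    if isinstance(edit, Terminate):
        return n_bonds * nb + n_atoms * na
    if key[0] in ("DeleteBond", "ChangeBond"):
        p = vocab.bond_payload_index(key)
        if p is None:
            raise DataError(f"record {record_id}: bond payload {key} not in vocabulary")
        site = np.asarray(sorted(edit.site))
        rows_match = np.nonzero((fg.bond_maps == site).all(axis=1))[0]
        if rows_match.size == 0:
            raise DataError(f"record {record_id}: bond site {edit.site} vanished")
        return int(rows_match[0]) * nb + p
    p = vocab.atom_payload_index(key)
    if p is None:
        raise DataError(f"record {record_id}: atom payload {key} not in vocabulary")
    rows_match = np.nonzero(fg.atom_maps == edit.site)[0]
    if rows_match.size == 0:
        raise DataError(f"record {record_id}: atom site {edit.site} vanished")
    return n_bonds * nb + int(rows_match[0]) * na + p


def prepare_sequence_samples(
    records: Iterable[ReactionRecord], vocab: EditVocabulary
) -> list[SequenceSample]:
    """Featurize every teacher-forcing step of every record."""
    samples = []
    for rec in records:
        if rec.edits is None:
            raise DataError(f"record {rec.record_id}: missing edit sequence")
        graphs = [rec.product]
        result = apply_sequence(rec.product, rec.edits)
        graphs.extend(result.intermediates[:-1] if not result.terminated else result.intermediates)
        # graphs[t] is the input graph at step t (Terminate scores on the
        # final intermediate, which equals the last entry)
        steps = []
        for t, edit in enumerate(rec.edits):
            fg = featurize(graphs[t])
            target = _target_index(fg, edit, vocab, rec.record_id)
            n_cand = (
                fg.bond_maps.shape[0] * vocab.n_bond
                + fg.atom_maps.shape[0] * vocab.n_atom
                + 1
            )
            steps.append(StepSample(fg=fg, target=target, n_candidates=n_cand))
        samples.append(SequenceSample(record_id=rec.record_id, steps=steps))
    return samples


def sequence_loss(
    samples: Sequence[SequenceSample],
    params: dict[str, Tensor],
    config: ModelConfig,
    vocab: EditVocabulary,
    dropout_rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """Cross-entropy of ground-truth edits, teacher-forced.

    Summed over steps of each sequence, averaged over the batch.
    """
    if not samples:
        raise ValueError("empty batch")
    total = None
    for sample in samples:
        h_prev: Optional[Tensor] = None
        prev_maps = None
        seq_loss = None
        for step in sample.steps:
            if h_prev is not None:
                h_prev_aligned = _align_h_prev_tensor(
                    h_prev, prev_maps, step.fg.atom_maps
                )
            else:
                h_prev_aligned = None
            scores = score_step(
                step.fg, h_prev_aligned, params, config, vocab, dropout_rng
            )
            nll = -ag.rows(
                scores.log_probs.reshape(-1, 1), [step.target]
            ).sum()
            seq_loss = nll if seq_loss is None else seq_loss + nll
            h_prev = scores.fused
            prev_maps = step.fg.atom_maps
        total = seq_loss if total is None else total + seq_loss
    return total / len(samples)


def teacher_forced_accuracy(
    samples: Sequence[SequenceSample],
    params: dict[str, Tensor],
    config: ModelConfig,
    vocab: EditVocabulary,
) -> float:
    """Fraction of teacher-forced steps whose argmax is the true edit."""
    hits = total = 0
    for sample in samples:
        h_prev = None
        prev_maps = None
        for step in sample.steps:
            aligned = (
                align_h_prev(h_prev, prev_maps, step.fg.atom_maps)
                if h_prev is not None
                else None
            )
            scores = score_step(step.fg, aligned, params, config, vocab)
            hits += int(int(np.argmax(scores.log_probs.data)) == step.target)
            total += 1
            h_prev = scores.fused.data
            prev_maps = step.fg.atom_maps
    return hits / total if total else 0.0


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when a monitored accuracy
    stops improving by ``threshold`` within ``patience`` epochs."""

    def __init__(self, optimizer: Adam, factor: float, patience: int, threshold: float):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric > self.best + self.threshold:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0


@dataclass
class TrainResult:
    params: dict[str, Tensor]
    history: list[dict]
    best_epoch: int


def train_model(
    records: Sequence[ReactionRecord],
    vocab: EditVocabulary,
    config: ModelConfig,
    validation_records: Optional[Sequence[ReactionRecord]] = None,
    target_accuracy: Optional[float] = None,
    verbose: bool = False,
) -> TrainResult:
    """Teacher-forced training with Adam, plateau LR decay and clipping.

    The plateau scheduler monitors teacher-forced per-step edit accuracy
    on the validation records (the training records when none are given).
    The best-accuracy parameters are retained.  Training stops early once
    ``target_accuracy`` is reached, if given.  All randomness is seeded
    from ``config.seed``.
    """
    if not records:
        raise ValueError("empty training set")
    samples = prepare_sequence_samples(records, vocab)
    val_samples = (
        prepare_sequence_samples(validation_records, vocab)
        if validation_records
        else samples
    )
    rng = np.random.default_rng(config.seed)
    params = init_model_params(rng, config, vocab)
    opt = Adam(params, lr=config.learning_rate, clip_norm=config.clip_norm)
    sched = ReduceLROnPlateau(
        opt, config.lr_factor, config.lr_patience, config.lr_threshold
    )

    history: list[dict] = []
    best_acc, best_epoch = -np.inf, -1
    best_params = {k: p.data.copy() for k, p in params.items()}
    order = np.arange(len(samples))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), config.batch_size):
            batch = [samples[i] for i in order[lo:lo + config.batch_size]]
            opt.zero_grad()
            loss = sequence_loss(batch, params, config, vocab, dropout_rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_acc = teacher_forced_accuracy(val_samples, params, config, vocab)
        sched.step(val_acc)
        history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / max(n_batches, 1),
                "val_acc": val_acc,
                "lr": opt.lr,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d} loss {epoch_loss / max(n_batches,1):8.4f} "
                f"val_acc {val_acc:.3f} lr {opt.lr:.2e}"
            )
        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in params.items()}
        if target_accuracy is not None and val_acc >= target_accuracy:
            break
    for k, p in params.items():
        p.data = best_params[k]
    return TrainResult(params=params, history=history, best_epoch=best_epoch)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------


def save_checkpoint(
    path,
    params: dict[str, Tensor],
    config: ModelConfig,
    vocab: EditVocabulary,
) -> None:
    """Write params, config and vocabulary (with hash) to a directory."""
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "params.npz"), **{k: p.data for k, p in params.items()})
    with open(os.path.join(path, "config.json"), "w") as fh:
        json.dump(
            {"config": config.to_dict(), "vocab_hash": vocab.content_hash()},
            fh,
            indent=1,
        )
    vocab.save(os.path.join(path, "vocab.json"))


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, EditVocabulary]:
    vocab = EditVocabulary.load(os.path.join(path, "vocab.json"))
    with open(os.path.join(path, "config.json")) as fh:
        meta = json.load(fh)
    if meta["vocab_hash"] != vocab.content_hash():
        raise ValueError("checkpoint vocabulary hash mismatch; refusing to load")
    config = ModelConfig.from_dict(meta["config"])
    with np.load(os.path.join(path, "params.npz")) as npz:
        params = {k: Tensor(npz[k]) for k in npz.files}
    return params, config, vocab
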