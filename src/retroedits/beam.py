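"""Beam-search decoding of ranked edit sequences for a product.

Each live hypothesis proposes its k best edits per step; of the up-to-k^2
candidates the global top k by cumulative log-probability survive.
Hypotheses terminate on the Terminate symbol (after which their final
graph must fully sanitize) or die silently at the step limit; edits whose
application fails chemistry are dropped without renormalizing the
remaining probability mass, so scores stay comparable across branches.
Terminated hypotheses stay frozen in the beam and compete by score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .edits import Edit, EditVocabulary, Terminate, apply_edit
from .mol_graph import ChemistryError, MolecularGraph, ensure_atom_maps, featurize
from .policy import ModelConfig, align_h_prev, score_step


@dataclass
class BeamHypothesis:
    """A partial edit sequence under beam search."""

    graph: MolecularGraph
    edits: list[Edit]
    log_prob: float
    terminated: bool
    h_prev: Optional[np.ndarray]     # fused atom states of the last step
    prev_maps: Optional[np.ndarray]
    choice_path: tuple[int, ...] = ()  # candidate indices, for tie-breaking

    @property
    def n_steps(self) -> int:
        return len(self.edits)


@dataclass
class Prediction:
    """One ranked reactant-set prediction."""

    rank: int
    reactants: str
    edits: list[Edit]
    log_prob: float

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "reactants": self.reactants,
            "edits": [e.to_dict() for e in self.edits],
            "log_prob": self.log_prob,
        }


def _sort_key(h: BeamHypothesis):
    return (-h.log_prob, h.n_steps, h.choice_path)


def beam_search(
    product: MolecularGraph,
    params,
    config: ModelConfig,
    vocab: EditVocabulary,
    k: Optional[int] = None,
    max_steps: Optional[int] = None,
) -> list[Prediction]:
    """Top-k reactant predictions for a product by beam search.

    Ranking is by cumulative log-probability, ties broken by shorter
    sequence then lexicographic candidate indices; duplicate reactant sets
    are deduplicated keeping the best-scoring hypothesis.  ``k = 1`` is
    exactly greedy decoding.  Returns an empty list (with a warning) if no
    hypothesis terminates.
    """
    k = config.beam_width if k is None else k
    max_steps = config.max_steps if max_steps is None else max_steps
    if k < 1:
        raise ValueError("beam width must be >= 1")
    product.sanitized_copy()  # raises ChemistryError for invalid input
    product = ensure_atom_maps(product)  # edits address atoms by map number

    beam = [
        BeamHypothesis(
            graph=product,
            edits=[],
            log_prob=0.0,
            terminated=False,
            h_prev=None,
            prev_maps=None,
        )
    ]
    for _step in range(max_steps):
        live = [h for h in beam if not h.terminated]
        if not live:
            break
        pool: list[BeamHypothesis] = [h for h in beam if h.terminated]
        for hyp in live:
            fg = featurize(hyp.graph)
            aligned = (
                align_h_prev(hyp.h_prev, hyp.prev_maps, fg.atom_maps)
                if hyp.h_prev is not None
                else None
            )
            scores = score_step(fg, aligned, params, config, vocab)
            logp = scores.log_probs.data
            top = np.argsort(-logp, kind="stable")[: min(k, logp.shape[0])]
            for ci in top:
                edit = scores.candidate_edit(int(ci), vocab)
                new_lp = hyp.log_prob + float(logp[ci])
                if isinstance(edit, Terminate):
                    try:
                        hyp.graph.sanitized_copy()
                    except ChemistryError:
                        continue
                    pool.append(
                        BeamHypothesis(
                            graph=hyp.graph,
                            edits=hyp.edits + [edit],
                            log_prob=new_lp,
                            terminated=True,
                            h_prev=None,
                            prev_maps=None,
                            choice_path=hyp.choice_path + (int(ci),),
                        )
                    )
                    continue
                try:
                    new_graph = apply_edit(hyp.graph, edit)
                except Exception:
                    continue  # invalid chemistry: drop, no renormalization
                pool.append(
                    BeamHypothesis(
                        graph=new_graph,
                        edits=hyp.edits + [edit],
                        log_prob=new_lp,
                        terminated=False,
                        h_prev=scores.fused.data,
                        prev_maps=fg.atom_maps,
                        choice_path=hyp.choice_path + (int(ci),),
                    )
                )
        pool.sort(key=_sort_key)
        beam = pool[:k]

    finished = sorted((h for h in beam if h.terminated), key=_sort_key)
    if not finished:
        warnings.warn("beam search: no hypothesis reached Terminate")
        return []

    predictions: list[Prediction] = []
    seen: dict[str, int] = {}
    for hyp in finished:
        try:
            smiles = hyp.graph.to_smiles(keep_stereo=True, strip_maps=True)
        except ChemistryError:  # pragma: no cover - screened at Terminate
            continue
        if smiles in seen:
            continue
        seen[smiles] = len(predictions)
        predictions.append(
            Prediction(
                rank=len(predictions) + 1,
                reactants=smiles,
                edits=hyp.edits,
                log_prob=hyp.log_prob,
            )
        )
    return predictions
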