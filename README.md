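# retroedits

Single-step retrosynthesis prediction by autoregressive molecular graph
editing.

Given a target product molecule, retrosynthesis asks which reactants it
could be made from. `retroedits` treats the retro-reaction as a short
sequence of graph edits applied to the product — delete a bond, change a
bond's order or stereo, change an atom's hydrogen count or chirality,
attach a leaving group, terminate — so that the product is transformed
through synthon-like intermediates into a complete reactant set. The
edit sequence is both the prediction target and an interpretable,
mechanism-like explanation of the transformation.

## Method

**Edit extraction.** Because training reactions are atom-mapped
(`reactants>>product` with shared map numbers), the ground-truth edit
sequence is read off the structural diff between product and reactants:
bonds present only in the product are deleted, bonds with changed
order/stereo are changed, hydrogen/parity differences become atom edits,
and maximal connected reactant subgraphs of unmapped atoms become
leaving groups (serialized as dummy-rooted SMILES such as `*Br` or
`*C(=O)c1ccccc1C(*)=O`), attached to their mapped anchor atom. Edits are
ordered DeleteBond > ChangeBond > ChangeAtom > AttachLG and end with a
terminate symbol. A deterministic engine replays the sequence with
explicit valence bookkeeping, and extraction is only accepted when the
replay reproduces the reactant canonical SMILES exactly, stereochemistry
included.

**Model.** A directed message-passing network (D-MPNN) encodes each
intermediate graph 𝒢 = (𝒱, ℰ): edge states are initialized as
h⁰ᵢⱼ = Wᵢ(xᵢ ∥ xᵢⱼ), updated for L layers by a GRU whose input is
h⁰ᵢⱼ plus the sum of incoming states h_{k→i} over neighbors k ≠ j (so
information never immediately flows back along the reverse edge), and
read out per atom as hᵢ = ReLU(W_o(xᵢ ∥ Σⱼ h_{j→i}) + c). A
conventional node-message MPNN is available as a config toggle. At
generation step t the atom states are fused with the previous step's
states, hᵢ⁽ᵗ⁾ = σ(W_v hᵢ⁽ᵗ⁻¹⁾ + W_c hᵢ⁽ᵗ⁾) (zero-padded for new
atoms), and three fully connected heads score every bond × bond-edit
payload, every atom × atom-edit payload, and a terminate symbol. One
softmax over all logits defines the step distribution; training
minimizes its cross-entropy under teacher forcing, and beam search
(width 10, at most 9 steps) decodes ranked reactant sets, dropping
hypotheses whose edits fail chemical valence rules.

The network and its training loop (Adam, plateau learning-rate decay,
gradient clipping) run on a small NumPy reverse-mode autodiff engine
included in the package — there is no deep-learning framework
dependency.

## Worked example

The built-in generator produces atom-mapped reactions from retro-
templates (deprotections, couplings, ester reductions, multi-center ring
openings, stereo inversions, hydrogenations) with known ground-truth
edits:

```python
from retroedits import generate_reactions, EditSequenceRetrosynthesizer

reactions = generate_reactions(64, seed=11)
model = EditSequenceRetrosynthesizer(
    hidden_size=64, depth=3, epochs=200, mpnn_dropout=0.0,
    head_dropout=0.0, lr_patience=15, target_accuracy=1.0,
    random_state=0)
model.fit(reactions)

product = reactions[0].product.to_smiles(strip_maps=True)
for preds in model.predict_detailed([product], top_k=3):
    for p in preds:
        print(f"rank {p.rank}  logP {p.log_prob:7.3f}  {p.reactants}")
```

prints (61 training epochs, vocabulary of 3 bond + 13 atom edits):

```
rank 1  logP  -0.007  CCCCI.COc1ccc(CN(C)C)cc1
rank 2  logP  -4.945  CCCCCl.COc1ccc(CN(C)C)cc1
rank 3  logP  -9.603  CCCCI.COc1ccc(CBr)cc1
```

The product `CCCCCc1ccc(OC)cc1` is split at the benzylic C–C bond and
completed with an iodide and a dimethylamine leaving group; the rank-1
prediction (cumulative log-probability −0.007) is exactly the recorded
reactant set, and `model.score(reactions)` reports a top-1 exact-match
accuracy of 1.0 on these training reactions. Scores are comparable
across ranks because hypotheses that fail valence rules are dropped
without renormalization.

The same pipeline is scriptable from the shell:

```bash
retroedits fixtures   --n 500 --seed 42 --out fixtures.csv
retroedits preprocess --in fixtures.csv --out edits.jsonl --vocab vocab.json --report prep.json
retroedits train      --data fixtures.csv --config config.yaml --out ckpt/
retroedits predict    --ckpt ckpt/ --smiles "CCCCCc1ccc(OC)cc1" --out pred.jsonl
retroedits evaluate   --pred pred.jsonl --truth fixtures.csv --ks 1,3,5,10 --report report.json
```

The training config YAML mirrors the estimator's hyperparameters
(`hidden_size`, `depth`, `encoder: dmpnn|mpnn`, `mpnn_dropout`,
`head_hidden`, `head_dropout`, `learning_rate`, `epochs`, `batch_size`,
`lr_factor`, `lr_patience`, `lr_threshold`, `clip_norm`, `beam_width`,
`max_steps`, `min_lg_count`, `seed`); unknown keys are rejected.

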