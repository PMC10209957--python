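# Methods

## Problem framing

A single-step retro-reaction is modeled as an ordered sequence of graph
edits e₁…e_T applied to the product graph, where each edit is one of
five variants: DeleteBond, ChangeBond, ChangeAtom, AttachLG (leaving
group) and Terminate. Applying the edits in order yields intermediates
(synthons, possibly valence-incomplete) and finally the reactant set.
Because completion happens by attaching whole substructures rather than
single atoms, realistic reactions need only short sequences (mostly 2–4
edits), which keeps the autoregressive decoding problem tractable.

The scheme deliberately has no bond *addition* between two already
mapped atoms: reactions that require it (for example cyclic-acetal
protections, where one leaving group would bridge two centers) are
detected during extraction and rejected, not mislabeled.

## Molecule representation and the edit engine

Molecules are held kekulized with hydrogen counts pinned as explicit
counts (`NoImplicit`), so the engine — not the toolkit's implicit-H
heuristics — owns valence bookkeeping. Canonical aromatic SMILES are
produced on demand by re-sanitizing a copy; fragments are individually
canonicalized and joined sorted, so fragment and atom order never
affect comparisons. Atoms are addressed externally by atom-map number,
which survives canonicalization; indices do not.

Edit semantics, chosen so that extraction and replay are exact inverses
on valence-saturated neutral molecules:

* **DeleteBond** removes the bond and adds one hydrogen per freed
  valence unit to both ends (synthons stay chemically sensible).
* **ChangeBond** sets the new order/stereo and adjusts both ends'
  hydrogens by (old − new), clamped at zero. When several bonds of one
  atom change, changes to lower orders are applied before changes to
  higher orders, so the clamp never strands an atom at zero hydrogens
  mid-sequence.
* **ChangeAtom** sets the atom's hydrogen count and tetrahedral parity
  to target values (a `(H, parity)` pair, always both slots).
* **AttachLG** merges the dummy-rooted leaving-group graph, bonds every
  dummy position to the target atom (multi-dummy groups such as the
  phthalimide `*C(=O)c1ccccc1C(*)=O` close rings on a single target),
  assigns fresh map numbers to new atoms, and then trims the target's
  hydrogens down to its allowed valence. Trimming — rather than blind
  subtraction of the new bond order — is what makes sequences in which
  a ChangeAtom already lowered the hydrogen count replay correctly.
* **Terminate** leaves the graph unchanged; the final graph must then
  fully sanitize.

Chirality is recorded as an RDKit tetrahedral parity normalized to an
atom-map-sorted neighbor frame (hydrogens last). This makes parity
comparable between product and reactant atoms whose bond lists are
ordered differently, and lets ChangeAtom set an absolute configuration
deterministically. These are parity codes, not CIP R/S labels; they
coincide with R/S only up to the frame convention, which is applied
identically on both sides of every comparison. Bond stereo (cis/trans)
is normalized the same way, to the lowest-map neighbor on each end.

Known limitation: an atom whose bonds change while its chirality is
*unchanged* keeps its stored parity through the neighbor-set change,
which can mis-specify the configuration in rare cases; reactions where
that happens fail the replay check and are dropped (counted) rather
than kept with wrong labels. Formal-charge changes between product and
reactants are likewise not expressible as edits and fail the same
check.

## Extraction

Given a canonicalized record (product maps 1..n in canonical order,
mapped reactant atoms following, leaving-group atoms numbered n+1…),
extraction emits: DeleteBond for product bonds missing in the
reactants; ChangeBond for bonds with changed (order, stereo); ChangeAtom
for mapped atoms whose parity differs, or whose raw hydrogen count
differs when no bond edit touches the atom (bond-edit bookkeeping
accounts for those); and AttachLG per unmapped connected reactant
component, anchored at its unique mapped neighbor. Components with no
anchor (spectators) or several anchors (bond formation) raise an
unextractable-reaction error. The sequence is ordered DeleteBond >
ChangeBond > ChangeAtom > AttachLG — attach order is a convention, fixed
for label determinism — and verified by replay before a record is
accepted, so dataset applicability is measured, never assumed.

## Encoder

Default is a directed-edge message-passing network. With atom features
xᵢ (element one-hot over a fixed 65-symbol table plus "other", degree,
formal charge, parity code, total hydrogens, aromaticity) and bond
features xᵢⱼ (order one-hot, conjugation, ring, stereo code):

    h⁰ᵢⱼ = Wᵢ(xᵢ ∥ xᵢⱼ)
    mᵢⱼ = Σ_{k∈N(i)\{j}} h_{k→i}          (messages skip the reverse edge)
    hᵢⱼ ← GRU(input = h⁰ᵢⱼ + mᵢⱼ, state = hᵢⱼ),  L layers, shared weights
    hᵢ  = ReLU(W_o(xᵢ ∥ Σⱼ h_{j→i}) + c)

The one-argument GRU notation is resolved as: state = previous edge
hidden, input = initial state plus message — the only reading that uses
both update-function arguments. The node-message variant (config
`encoder: mpnn`) sums messages over all neighbors and shares the same
readout. Features are computed on the re-aromatized form when the graph
sanitizes (so all benzene bonds look alike) and on the kekulized
editing form for valence-incomplete synthons. Weight initialization is
uniform Glorot from a seeded generator; dropout on the atom embeddings
is active only in training.

## Decoder, loss, training

Per step, atom states are fused with the previous step's states
(zero-padded for atoms the last edit introduced; all-zero at step one),
bond representations concatenate the two endpoint states in ascending
map order, and the graph vector is the atom-state sum. Three two-layer
heads score bond payloads per bond, atom payloads per atom, and the
terminate symbol; one softmax over the concatenation defines the step
distribution. Using a single joint softmax for both the training
cross-entropy and beam scoring keeps the objective and the search
ranking consistent. Gradients flow through the fused states across
steps (verified by finite differences).

Defaults mirror the reference regime: hidden 256, depth 10, encoder
dropout 0.15, head hidden 512, head dropout 0.2, Adam at 1e-3, 150
epochs, batch 32, gradient-norm clip 10, and plateau decay ×0.8 with
patience 5 and improvement threshold 0.01 monitoring teacher-forced
per-step validation accuracy (cheap, unlike per-epoch beam decoding);
the best-accuracy parameters are retained. Everything is seeded; two
runs with one seed are bit-identical.

The whole network runs on the package's ~300-line NumPy reverse-mode
autodiff engine (float64), with gather/scatter primitives for message
passing. At the sizes this package targets that is fast enough: the
overfit benchmark below trains in about two minutes on one CPU.

## Beam search

Width k (default 10), at most 9 steps. Each live hypothesis proposes
its k best edits; of the ≤ k² candidates the global top k by cumulative
log-probability survive. Terminated hypotheses stay frozen in the beam
and compete by score. Edits that fail valence rules are dropped without
renormalizing the remaining mass — renormalization would inflate
branches with many invalid siblings. Final ranking is by raw cumulative
log-likelihood (no length normalization), ties broken by shorter
sequence then lexicographic candidate indices; duplicate reactant sets
keep their best score. Products given without atom maps receive
canonical map numbers internally. Only hypotheses that emitted
Terminate (and sanitize) become predictions.

## Metrics

Top-k exact match compares canonical reactant SMILES with stereo
retained and maps stripped. MaxFrag restricts the comparison to the
largest fragment by heavy atoms (ties broken lexicographically).
Diversity is the mean pairwise Tanimoto similarity over concatenated
per-fragment ECFP4 fingerprints (radius 2, 2048 bits per fragment,
fragments in sorted order; differing lengths are zero-padded), with an
optional k-means summary clustering products on that scalar — the
scalar reading is a deliberate simplification of an under-specified
clustering protocol. The Tanimoto-based splitter moves held-out records
whose product exceeds a similarity threshold to any training product
into the training set, removing scaffold leakage.

## Synthetic data

The generator builds records by applying hand-coded retro-template edit
sequences to assembled scaffolds, then keeps a record only if the
extractor independently reproduces the template's edit kinds and the
replay reproduces the reactants — generator and extractor cross-validate
each other. Eight templates cover all edit variants and lengths 1–7:
phthalimide and Boc deprotections, an aryl–alkyl amine/halide coupling,
an ester reduction, a seven-edit multi-center ring opening (two deletes,
three bond changes, two attachments), an ether cleavage with chirality
inversion, a pure chirality flip, and an alkene hydrogenation. The
default template mix makes lengths 2–3 dominate, with long multi-center
and stereochemical transformations as minorities, echoing the skewed
length distribution of curated reaction data.

Two design rules keep the data learnable and honest. Product families
are disjoint across templates, and every within-template choice (which
protecting group, which halide, which ester) is a deterministic
function of structure within three bonds of the edit site — so a
product implies a unique retro-route, and the label is a function of
what a shallow message-passing encoder can actually see. Without the
second rule a depth-3 encoder faces labels it provably cannot predict.
What the fixtures do **not** emulate: reagent/condition dependence,
competing feasible routes for one product, atom-mapping noise, charged
species, and the long-tail leaving-group distribution of real corpora —
so passing tests demonstrate correctness of the machinery, not chemical
coverage of real reaction space.

## Benchmarks in the acceptance script

Problem sizes are chosen for a single-CPU workflow: 500 generated
reactions for replay applicability, a 64-reaction / hidden-64 / depth-3
memorization run (early-stopped at perfect teacher-forced accuracy, cap
200 epochs; dropout off and scheduler patience 15, the appropriate
configuration for a memorization check), a 3-candidate 2-step toy for
exhaustive beam verification, and 50 random graphs for the encoder
symmetry properties. Full-corpus training (tens of thousands of
reactions, hidden 256, depth 10) follows the same code paths but is a
multi-day CPU undertaking and is not part of the test suite.
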