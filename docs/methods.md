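# Methods

## Problem and model

`ppilink` treats multi-label PPI prediction as inductive link labelling on
an undirected protein graph. Inputs are amino-acid sequences and a set of
training interactions, each labelled with a subset of seven interaction
types. The model composes four stages — residue embedding, convolutional
sequence encoding, graph feature propagation, and pairwise relational
classification — and is trained end to end by gradient descent.

### Residue embedding (13 = 5 + 8)

Each residue letter maps to the concatenation of

* a 5-dim **co-occurrence vector** pre-trained with skip-gram and negative
  sampling. Tokens are single residues with a context window of 1 on each
  side, so each center's context is exactly its overlapping 3-mer. The
  alternative reading — embed 3-mer tokens and average the up-to-3 3-mers
  covering a residue — is implemented behind `cooc_token_mode: kmer`. Both
  produce one 5-vector per residue; the residue-token reading is the
  default because it does so directly. Out-of-vocabulary tokens map to the
  zero vector so unseen proteins remain encodable. The pre-training corpus
  is the training-split sequences by default (`cooc_corpus: train`) to
  avoid information flow into unknown-protein evaluation.
* an 8-way one-hot **physicochemical class**: the conjoint-triad partition
  of the 20 canonical residues into 7 groups by dipole and side-chain
  volume, plus an eighth class absorbing selenocysteine (U), pyrrolysine
  (O) and every unrecognized letter. The "+1" of the 13-dim total is read
  as this eighth class dimension.

Sequences are truncated on the right at `max_length` (default 2000). In
residue-token mode truncation never changes the surviving columns; in kmer
mode the final two columns see a shorter covering set (truncate-then-encode
semantics).

### Sequence encoder

`n_submodules` (default 4) identical Inception-style blocks. Each block has
four length-preserving branches: 1-D convolutions with kernels 1, 3, 5 and
a stride-1 max-pool (window 3) followed by a 1×1 projection; branch outputs
are channel-concatenated. Defaults: 32 channels per branch (node dimension
4 × 32 = 128), ReLU nonlinearities, zeros same-padding, per-branch
normalization (per-channel standardization over the protein's valid
positions with learnable scale/shift — an instance-norm flavor that keeps
single-protein and batched encoding bit-identical; toggleable with
`branch_norm`). The temporal axis is collapsed by average pooling by
default; `encoder_pooling: max` is the right choice when sparse, localized
motifs carry the signal, since average pooling dilutes a single motif
activation by 1/L. 2-D kernel factorization from the Inception-V3 lineage
is deliberately not used: the input is 1-D, so kernels {1,3,5} already
realize the multi-scale design. The max-pool branch pads with zeros; a
boundary window may take the pad value when all in-window activations are
negative, which is harmless after ReLU stages and documented as the
pooling convention.

### Graph propagation

The graph contains every protein as a node and one structural edge per
*training* pair (label multiplicity collapsed). One GIN layer (default;
`n_graph_layers` configurable) updates features by
`MLP((1+ε)·g_p + Σ_{p′∈N(p)} g_{p′})` with ε learnable and initialized to
0; the MLP is two linear layers with ReLU, hidden width equal to the node
dimension. Test proteins participate as isolated nodes: their update sees
only `(1+ε)·g_p`, so inference for unknown proteins uses their sequence
features plus whatever training-edge neighbors they happen to have, and no
test edge ever enters the adjacency.

### Pair head

For a pair, the two propagated vectors are stacked into a 2-row matrix and
refined by single-head scaled dot-product self-attention
(`softmax(QKᵀ/√d_k)V`; the 1/√d_k scaling is kept and can be disabled with
`attention_scale: false`). The relational score is either

* **FRN**: `tanh((e1+e2)ᵀW^[i](e1−e2) + (V[e1;e2])_i·cos(e1,e2) + b_i)`,
  i = 1..k — bilinear term antisymmetric under swapping the pair and zero
  at e1 = e2; the cosine uses the convention cos := 0 when either norm is
  0 (no direction information in a dead feature); or
* **NTN** baseline: the k-vector `tanh(e1ᵀW^[i]e2 + (V[e1;e2])_i + b_i)`,
  with the scalar score `uᵀ(·)` exposed separately.

The classifier input is the k-dim relational vector concatenated with the
element-wise product `e1 ∘ e2` (`pair_fusion: frn+product`; `frn` and
`product` variants support ablations). "e1 · e2" is read as the
element-wise product — an inner product would collapse the pair to a
scalar and make the classifier degenerate. A fully connected stage (hidden
width 64, ReLU) produces 7 logits; sigmoids give per-type probabilities;
the decision threshold is 0.5 per label. k defaults to 8.

### Loss and optimization

Multi-task binary cross-entropy summed over the 7 label tasks and all
training pairs. The probability-facing loss clamps predictions to
[1e-7, 1 − 1e-7]; the training path evaluates the identical quantity from
logits via `softplus(z) − y·z`, whose gradient `σ(z) − y` cannot vanish at
saturation (early experiments with the clamped-probability path showed
irrecoverable all-negative collapse at larger widths). Adam with learning
rate 0.001, batch size 2048 (capped at the training-set size), 300 epochs
are the reference defaults; an optional cosine annealing schedule
(`lr_schedule: cosine`) suppresses late-training oscillation on small
datasets. Batches are sets of training pairs; the encoder and graph run in
full per step, which is the honest (and affordable) semantics at
desk-scale graph sizes. Early stopping is off by default.

Rare-positive multi-label problems have a strong degenerate attractor —
predicting every label below threshold — and whether a run escapes it is
sensitive to the parameter draw. The trainer therefore supports seeded
collapse recovery (`restart_on_collapse`): a run that still makes zero
positive training predictions at `collapse_check_epoch` (default 30) is
re-initialized with a derived seed, at most the configured number of
times. Optional linear warmup (`lr_warmup_epochs`), global gradient-norm
clipping (`grad_clip`) and base-rate output-bias initialization
(`init_output_bias`) are available but off by default; in our experiments
on the synthetic study they did not help escape the attractor (warmup and
clipping made it worse by damping the early gradients that break the
symmetry), so the study protocol relies on collapse recovery instead.

## Splits and metrics

* `random`: exactly `round(0.2·|E|)` uniformly chosen test edges.
* `bfs`/`dfs`: traverse the protein graph from a seeded random root; every
  edge with ≥1 visited endpoint goes to test; stop as soon as the target
  fraction is reached (the set may overshoot by the last node's incident
  edges); exhausted components trigger a restart from a fresh random root.
  This node-visitation/incident-edge rule is the declared reference
  behavior for the traversal protocol.
* Test stratification: an edge is *homologous* iff both endpoints occur in
  some training edge, else *unknown*. Under the incident-edge traversal
  rule every visited protein is absent from all training edges, so BFS/DFS
  test sets consist entirely of unknown edges; homologous strata arise
  from random splits.

Micro-F1 pools TP/FP/FN over all labels and pairs before computing
precision, recall and F1 once; zero denominators yield 0 rather than NaN.
Macro-F1 and per-label counts are supplementary outputs.

## Synthetic data generator

Emulates a STRING-like multi-label network at desk scale. Defaults — 50
proteins, lengths uniform in [50, 200], 150 edges, no label noise — are
the standard study conditions used by the acceptance run. Sequences are
uniform over the 20 canonical letters with U/X substituted at rate 0.1%.
Each protein carries 0–3 planted 4-mer motifs (probabilities 0.1/0.2/
0.3/0.4 for 0/1/2/3; weighted toward more motifs so that a realistic
fraction of pairs shares one), one distinct motif per interaction type.
Edges are sampled by sequential preferential attachment (each arriving
node links to earlier nodes with probability ∝ degree+1, topped up with
degree-weighted extra pairs), producing the right-skewed hub structure of
real PPI networks, which in turn makes BFS/DFS splits qualitatively harder
than random ones. An edge's labels are the types whose motif occurs in
both endpoints; a pair sharing no motif falls back to a single type chosen
deterministically from the two sequences, keeping the noise-free
sequences→labels mapping an exact function (so a sufficiently expressive
model can in principle reach micro-F1 = 1 on its training set). With
`label_noise > 0` each label flips independently with that probability.

What the generator does **not** emulate: realistic amino-acid composition,
homologous sequence families, negative-pair sampling, and confidence
scores. Passing the end-to-end tests therefore demonstrates that the
architecture can discover motif-AND label rules and memorize residual pair
structure on networks of this shape — not that it attains any particular
accuracy on real STRING-derived data.

## Acceptance-study configuration

The end-to-end study (tests and `scripts/acceptance.py`) trains the full
model — Inception encoder, GIN, attention, FRN — on the generator defaults
with a configuration scaled to a single CPU: 8 channels per branch (node
dimension 32), max temporal pooling, 16 relational slices, classifier
hidden width 128, batch size 16, learning rate 0.01 with cosine annealing,
200 epochs, and collapse recovery (re-init on zero positive predictions at
epoch 30 or training micro-F1 < 0.3 at epoch 75, at most 3 retries). The same data are split randomly and by
BFS with the same seed; the study reports training-set micro-F1 (expected
≥ 0.95 on the noise-free rule) and the random-vs-BFS test-set ordering
(random expected easier). Reference-protocol defaults (128-dim nodes,
lr 0.001, batch 2048, 300 epochs) remain the package defaults.

## Numerical choices and edge cases

* Everything is float64; analytic gradients are validated against central
  finite differences to relative error ≤ 1e-4 (FRN, loss), and the GIN/NTN
  implementations against closed-form/brute-force oracles at 1e-10.
* Convolution/pooling on batches uses zero-padded same-length semantics
  with post-operation masking; a mixed-length batch encodes every protein
  exactly as it would alone.
* Zero-norm cosine ⇒ 0; the batched training path guards the denominator
  with 1e-24 under the square root.
* Ties in traversal order are broken by sorted node id; the traversal root
  is drawn from the split seed (overridable for worked examples).
* Duplicate unordered pairs in edge files merge by label union; self-loops
  and unknown label strings are rejected with explicit errors.
* Empty test sets are accepted with a warning; empty evaluation strata are
  reported as n/a rather than 0.

## Known limitations

* Single-head attention over exactly the two pair members (no multi-head,
  no cross-pair attention); a single shared FRN parameter bank rather than
  per-relation banks.
* Full-batch graph propagation bounds practical graph size to a few
  thousand proteins on one CPU.
* The skip-gram trainer is a faithful but compact SGD implementation — one
  epoch over a large corpus is slower than optimized C implementations.
* Micro-F1 at a fixed 0.5 threshold is the only headline metric; no
  ROC/AUPR or calibration analysis.
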