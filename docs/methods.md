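# Methods

## The prediction problem

Anti-CRISPR proteins (Acrs) are phage-encoded inhibitors of bacterial
CRISPR-Cas immunity. Given a protein sequence, the package answers two
questions in sequence: *is this an Acr?* (binary screen) and, for
positive calls, *which CRISPR-Cas subtype does it inhibit?* (5-way type
assignment). Acrs are short (roughly 50–350 residues), fast-evolving and
scarce — on the order of a thousand non-redundant positives exist — so
the classifier fuses three complementary feature families rather than
relying on sequence alone.

## Features

**One-hot channels (L x 34).** Per residue: 20 amino-acid channels, 3
three-class and 8 eight-class secondary-structure channels, 3
solvent-accessibility channels, concatenated in that fixed order.
Nonstandard residues (X/B/Z/U/O) encode as all-zero amino-acid rows,
keeping the 20 columns aligned with the PSSM column order
`ARNDCQEGHILKMFPSTVWY`. Structure and accessibility strings are
*inputs* (derived upstream by structure-prediction tools); the package
validates and encodes them but never predicts them.

**Evolutionary descriptors (1110-d).** Four fixed-size summaries of the
L x 20 position-specific scoring matrix, concatenated as
[composition | DPC | AC | RPSSM]:

- *PSSM-composition* (400): per residue type `a` and column `j`,
  `(1/L) * Σ_{k: seq_k=a} S[k,j]`. Normalization is by `L`, not by
  per-residue counts, so rare residues contribute boundedly.
- *DPC-PSSM* (400): adjacent-position products
  `(1/(L-1)) * Σ_k S[k,i] S[k+1,j]`.
- *PSSM-AC* (20·G, G=10 by default): per-column lagged auto-covariance
  after centering each column at its mean; captures local
  sequence-order effects and is invariant to per-column shifts.
- *RPSSM* (110): columns averaged into 10 physicochemical groups
  ({FYW}, {ML}, {IV}, {ATS}, {NH}, {QED}, {RK}, {C}, {G}, {P}), then
  100 adjacent-row half-squared-difference pair terms plus 10 column
  variances.

Raw log-odds scores are used by default; an optional elementwise
logistic squashing (`sigmoid=True`) is available since both conventions
circulate. The total dimension (1110) follows from G=10 and is
configuration, not a law; `evolutionary_dimension(G)` gives the general
formula 810 + 20·G.

**Protein-embedding vector.** A fixed-width per-protein vector from a
pretrained protein language model. The interface is a backend: `table`
(precomputed vectors by id), `stub` (deterministic content-seeded
pseudo-vector, components in [-1, 1]) and `esm` (real
language model; mean pooling over the per-residue representations of
the final layer — the pooling choice is ours, as the upstream
publications leave it open). The package never trains the language
model; the interface default width is 1280 (the width of large
ESM-style models).

## Model

A CNN+FCN fusion network (NumPy implementation with hand-written
backpropagation — the model is small and trains in minutes on one CPU):

1. conv stack over the L x 34 channel matrix (same-length padding, ReLU;
   default `[(64, 7), (128, 5)]`); after each layer, activations at
   padding positions are zeroed so deeper layers see identical context
   no matter how much padding a batch carries;
2. global max pool along the sequence axis restricted to mask-valid
   positions (−inf fill), making variable-length proteins batchable and
   the output provably invariant to padding amount;
3. concatenation with the evolutionary and embedding vectors — each
   z-scored per dimension with training-set statistics, since the three
   blocks arrive on very different scales;
4. fully connected head (default widths [512, 128], ReLU, dropout 0.3)
   with 2 or 5 softmax output units (6 for the joint variant with
   non-Acr as a sixth class). Binary convention: index 1 = Acr.

Any subset of the three feature blocks can be enabled ("variant
features"); disabled blocks contribute zero width. Argmax ties resolve
to the lowest class index. Checkpoints are single `.npz` files holding
parameters, normalization statistics and the embedded config.

**Training.** Cross-entropy loss, Adam (lr 3e-3, batch 32) with
decoupled weight decay 1e-3 on weight matrices, fixed budget of 60
epochs. Minibatches are bucketed by sequence length and packed once;
the per-epoch loss history is the evaluation-mode (dropout-free) loss
over the training split, so it is an exact function of the parameter
trajectory (and exactly constant at learning rate 0). All randomness —
initialization, shuffling, dropout, splits — derives from explicit
seeds; identical seeds give bitwise-identical histories on one
platform. Validation-based early stopping (10% split, configurable
patience) is implemented but off by default: at the dataset sizes this
package targets, a tiny validation split selects underfit parameters
(measured cost of 3–5 accuracy points across seeds), whereas the fixed
budget with weight decay is stable. A per-sample *block dropout* option
(`TrainConfig.block_dropout`) independently silences whole feature
families during training (inverted-dropout rescaled); it counteracts
the tendency of the quickest feature family to saturate the loss before
the others train, at some cost in peak accuracy, and is off by default.

**Hierarchy.** A protein is called Acr when P(Acr) ≥ 0.5 (threshold
configurable); only Acr calls are passed to the 5-way type model, which
avoids both class imbalance against the non-Acr majority and mixing the
"is-an-Acr" and "which-Acr" signals.

## Evaluation protocols

Confusion counts with Acr positive; accuracy, precision, recall,
specificity, F1 and MCC derived from them (0/0 denominators report 0
with a warning, never an exception mid-sweep). Stratified 5-fold
cross-validation; multi-seed averaging re-seeds both initialization and
the sample split and averages the metric suite arithmetically. The
cross-dataset protocol holds out whole Acr types: separation 1 tests on
{I-F, II-C, I-D}, separation 2 on {I-F, I-E, V-A, I-C, VI-A, VI-B,
III-I, III-B, I-B}, separation 3 on {I-D, II-C, I-E, V-A, I-C, VI-A,
VI-B, III-I, III-B, I-B}; negatives follow a supplied test membership.
ROC curves use a standard threshold sweep with trapezoid-rule area.

The 12 known Acr types map onto 5 classes: II-A, I-F, I-D and II-C keep
their own class (indices 0–3, frozen for checkpoint compatibility); the
eight rare types pool into "others" (index 4). Unknown type strings are
an error, never a silent "others".

## Motif-mutation experiment

Motif spans (0-based, half-open; discovered upstream, supplied as TSV)
are replaced by residues drawn uniformly from the 20 standard letters;
`complement_spans` yields the non-motif regions for the control
experiment. Native and mutant sequences are featurized identically and
scored by the trained binary model; a *flip* is a change of the
0.5-threshold call. Flip rates are computed over positives the model
itself calls Acr natively. For real data the mutant's PSSM and
structure annotations must be re-derived by the upstream tools; the
synthetic generator sidesteps this because all its derived features are
deterministic functions of the sequence bytes.

## Synthetic data: what it emulates and what it does not

The generator produces complete datasets — records, PSSMs, SS3/SS8/RSA
strings, an embedding table, a manifest and the true motif spans — in
exactly the formats the readers parse. Defaults are the package's study
conditions:

- **Sizes**: 400 positives / 400 negatives (desk-scale stand-in for the
  ~1100-per-class real datasets, chosen so a full train/evaluate cycle
  fits a single-CPU budget); lengths uniform in 50–350, matching the
  envelope of real Acr data.
- **Motifs**: each Acr type has one fixed 21-residue motif drawn from a
  type-specific pair of residues (seeded shuffle of the alphabet
  assigns disjoint pairs). Positives carry their type's motif exactly
  once at a random position; negatives never contain one. The strong
  composition bias is deliberate: real Acr motifs are low-complexity
  conserved patterns tied to shared local structure, and uniform-random
  21-mers are not learnable by a gradient-trained CNN at a few hundred
  samples (memorization wins), whereas composition-biased motifs are
  learnable and also give the PSSM-composition descriptors genuine
  type signal.
- **PSSMs**: +7 log-odds at the true residue, integer-rounded Gaussian
  noise (sd 1.5) clipped to [-5, 5] elsewhere — the typical range of
  iterated-homology-search profiles, with conservation clearly dominating
  the off-residue noise. Row argmax recovers the true residue
  essentially always.
- **Structure**: SS3/SS8 from a 2-state helix/coil persistence process
  (stay probability 0.9; SS8 refines each state into its sub-states);
  RSA by 3-quantile thresholding of a smoothed random walk. These
  strings are label-free by construction.
- **Embeddings**: the deterministic stub vector plus a magnitude-2
  offset along one fixed random direction whenever the sequence
  contains a planted motif (for generated data: exactly the positives).
  Tying the offset to motif presence rather than to the label keeps
  mutant re-featurization consistent and makes the offset disappear
  when the motif is scrambled — the mechanism the mutation experiment
  probes. Synthetic embedding width is 256 (desk-scale stand-in for the
  1280-wide real embeddings; with a few hundred training samples the
  offset direction is estimable at 256 dimensions and is not at 1280).
- Every derived feature is a deterministic function of the sequence
  bytes (seeded via a stable content hash), so the same sequence always
  maps to the same features, including after mutation.

What passing tests on this generator show: the implementation trains,
discriminates a planted two-level signal, respects its contracts
(masking, determinism, hierarchy), and reproduces the qualitative
motif-dependence pattern. What they do not show: performance on real
Acr data — the generator mimics neither true residue statistics, nor
homology structure between sequences, nor realistic PSSM correlations,
nor a real language model's embedding geometry.

## Numerical choices and degenerate inputs

- Masked pooling uses −inf fill; with ReLU activations the pooled
  values are nonnegative for any real (mask-valid) input.
- float32 parameters and activations; probability sums hold to 1e-6.
- 0/0 metric denominators → 0 with a warning.
- Empty sequences, length-mismatched annotations, unknown residues or
  type strings, ragged embedding tables, truncated PSSM rows: loud
  errors naming the offending record, never silent repair.
- DPC/RPSSM require L ≥ 2; PSSM-AC requires L > G.
- Stratified splits fall back to unstratified when a class cannot fill
  its slice (tiny datasets).

## Known limitations

- The NumPy network is single-threaded and desk-scale; it is not a
  drop-in for GPU-scale retraining on real corpora.
- The real language-model backend requires optional packages and
  weights not shipped here; tests never exercise it.
- Absolute benchmark figures from the real datasets are out of scope —
  they require external data, real PSSMs and the pretrained language
  model. The package reproduces the protocols and the worked
  contingency-table examples, not those absolute numbers.
- The parameter count of the reference network is not reproduced; the
  sizes here are chosen for CPU training, and all are configurable.
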