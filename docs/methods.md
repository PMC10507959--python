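# Methods

## Problem

A compound can participate in several metabolic pathways at once, so
pathway assignment from structure is a multi-label classification problem:
given a SMILES string, predict an L-bit membership vector (11 KEGG pathway
classes, 18 plant secondary-metabolism sub-classes, or 7 natural-product
categories, depending on the task). Label matrices in this domain are
sparse and strongly imbalanced, and the plant task in particular is
data-poor, which motivates transfer from the better-annotated KEGG-style
task.

## Model

The network encodes each molecule along two parallel branches and fuses
them.

**Graph branch (Block1).** The molecule is a graph with atoms as nodes and
bonds as edges; every bond contributes both directed edges. Each atom i is
featurized as the concatenation of eight property blocks: element one-hot
(20 elements common in biological small molecules + other), heavy-atom
degree (0–5 + overflow), attached hydrogens (0–4 + overflow), formal charge
(plain integer), implicit valence (0–6 + overflow), chirality tag (none /
CW / CCW / other), ring membership, and aromaticity — d = 49 dimensions in
total. A stack of graph-transformer layers updates node features: for head
c,

    x'_{c,i} = W_{c,l} x_i + Σ_{j∈N(i)} α_{c,i,j} W_{c,v} x_j
    α_{c,i,j} = softmax_{j∈N(i)} ( (W_{c,q} x_i)ᵀ (W_{c,k} x_j) / √d )

where d is the input feature dimension of the layer (recomputed per
layer), and the per-head outputs are concatenated. Isolated atoms (e.g. in
disconnected salts) keep only the self term W_l x_i; no artificial
self-loops are added. A ReLU is applied between stacked layers (the layer
itself, as tested against the double-loop oracle, is the bare propagation
rule). Readout is global mean pooling and global max pooling in parallel,
followed by a fully connected layer to a 2000-dimensional molecule vector.

**Text branch (Block2).** The SMILES string is tokenized at character
level with a merge table: `Cl`, `Br`, `@@`, `%NN` ring closures and whole
bracket atoms (`[nH]`) are single tokens. Tokens pass through a learned
embedding table trained end-to-end, a 1-D convolution, a masked global
max-pool over positions whose window lies entirely within the real tokens,
and a fully connected layer to 2000 dimensions. The embedding table is
learned jointly with the rest of the network, preserving the contract that
a sequence of per-character vectors enters the Conv1D/Pool1D stack.

**Fusion.** The two 2000-vectors are concatenated to 4000 dimensions,
passed through a small 1-D CNN (the concatenated vector treated as a
length-4000 single-channel sequence: Conv1D, ReLU, window max-pooling,
flatten), a dropout layer, and a final fully connected layer ("last FC")
with one independent sigmoid per pathway. Prediction thresholds each
probability at 0.5; a probability exactly equal to the threshold predicts
membership (≥ convention). All-zero predictions are legal (compound
assigned to no pathway).

**Ablation switches.** `use_block1=False` or `use_block2=False` routes the
remaining branch's 2000-vector directly into the fusion head (no
zero-padding); `use_fusion_cnn=False` sends the concatenated vector
straight to the last FC. Disabling both branches is rejected at config
validation.

## Numerical core

The network runs on a compact reverse-mode automatic-differentiation
engine written on NumPy (`molpath.nn`): dense float64 tensors, matmul /
elementwise ops, 1-D convolution via im2col, non-overlapping max pooling,
and segment operations (segment sum / max / softmax over row groups),
which express both per-neighbourhood attention normalisation and per-graph
pooling of batched disjoint-union graphs. Gradients of every operation are
verified against central finite differences in the test suite. Tied maxima
in `segment_max` split the gradient equally (a valid subgradient);
`maxpool1d` routes to the first maximum. The softmax max-shift uses
detached values, which leaves gradients unchanged by shift invariance.

## Training protocol

* Loss: mean binary cross-entropy over the batch × label matrix (standard
  for independent-sigmoid multi-label output), with probabilities clipped
  at 1e-7 inside the engine.
* Optimizer: Adam; learning rate 3e-4 for (pre-)training from scratch and
  1e-4 for fine-tuning; batch size default 32.
* Five-fold cross-validation with shuffled, seed-deterministic splits;
  per-fold metrics are reported as mean ± standard deviation, and the fold
  with the highest validation accuracy (measured on its held-out split;
  ties to the lowest fold index) is selected for transfer.
* Transfer: the output layer is replaced by a fresh layer of the new label
  width and is always trainable; one of five freezing strategies withholds
  parameter groups from the optimiser — `entire_model_frozen` (block1 +
  block2 + fusion CNN frozen), `block1_frozen`, `block2_frozen`,
  `block1_block2_frozen`, `no_module_frozen`. Withholding from the
  optimiser (rather than zeroing gradients) guarantees frozen tensors are
  bitwise unchanged.
* Stochasticity: one seed drives weight initialisation, shuffling and
  dropout; loss trajectories are reproducible single-threaded. A NaN loss
  aborts with the offending epoch.
* If a fine-tuning corpus contains tokens outside the pre-trained
  vocabulary, the tokenizer and embedding table are extended; the new rows
  follow block2's freeze state and are random if block2 is frozen.

## Evaluation

Accuracy, precision, recall and F1 are micro-averaged: true/false
positives/negatives are pooled over all N×L cells before computing ratios.
Accuracy is therefore element-wise over the indicator matrix — the only
reading under which accuracy near 97% coexists with F1 near 84% on a
sparse 11-label task. Undefined divisions return 0 with an explicit
warning flag. Per-class tables report one-vs-rest micro metrics per label
and pool back exactly to the overall report. Model comparison uses a
two-tailed two-sample Student t-test (equal variance) on the k = 5 fold
scores — the pairing of folds across models is not assumed — with
significance stars at 0.05 / 0.01 / 0.001; zero pooled variance raises
instead of returning a fake p-value.

## Data augmentation

* **alpha / beta** — methoxy↔hydroxy substitution: one product per
  matching site, products inherit the parent's labels, originals are
  retained, duplicates are merged by canonical SMILES with label union.
  `beta` runs three sequential whole-dataset passes, each applied to the
  previous round's output (the accumulation reading of "applied three
  times"). Matching uses SMARTS with exclusions: hydroxyls on carbonyl
  carbons (carboxylic acids) and methyl esters are not edited, so the swap
  stays within alcohol/ether chemistry. Symmetric sites can collapse to a
  single canonical product, so the product count is at most, not exactly,
  the site count.
* **gamma / theta** — fingerprint-similarity mining against a user-supplied
  compound library (Morgan radius 2, 2048 bits, binary for Tanimoto; a
  counted variant is available): library molecules whose similarity to a
  dataset molecule falls within [0.99, 1] (gamma) or [0.96, 1] (theta) are
  recruited with the union of their parents' labels. Widening the band can
  only grow the result.

## Synthetic data generator

`generate_fixture_dataset` emits deterministic multi-label SMILES tables
shaped like pathway-membership data: molecules are ring or chain scaffolds
(benzene, cyclohexane, pyridine, thiophene, furan, cyclopentane, alkane
chains of length 3–8) carrying 1–3 functional-group decorations from an
18-fragment list (hydroxy, methoxy, amino, halogens, nitrile, carboxyl,
amide, thiol, CF3, vinyl, alkynyl, ...). Label marginals decay
geometrically (weights ∝ 0.85^l), emulating strong class imbalance; 30% of
rows carry two or three labels by default. Two labelling modes:

* *random*: labels are drawn from the weight distribution independently of
  structure — used for format, I/O and distributional tests;
* *structural*: label l indicates that decoration l is present — a
  perfectly recoverable task used for capacity and transfer experiments
  (the source and target tasks share the marker chemistry, which is
  exactly the shared structure transfer learning is supposed to exploit).

What the generator does **not** emulate: real pathway labels are not
determined by single functional groups; real compounds are far larger and
more diverse (stereochemistry-rich natural products); label correlations
and annotation noise are absent. Passing the capacity and transfer tests
therefore demonstrates that the architecture, optimisation and freezing
machinery work as specified — not that headline accuracies on curated
pathway databases are reproduced.

## Default hyperparameters

| parameter | default | notes |
| --- | --- | --- |
| graph layers / heads / head dim | 3 / 4 / 64 | free choices; recorded in config |
| branch output dims | 2000 / 2000 | structural constants of the method |
| token embedding dim | 64 | learned end-to-end |
| text conv | 64 channels, kernel 3 | |
| fusion conv | 16 channels, kernel 3, pool 8 | over the 4000-vector |
| dropout | 0.2 | fusion head only, training mode only |
| threshold | 0.5 | ties predict membership |
| learning rates | 3e-4 → 1e-4 | pre-train → fine-tune |
| batch size / folds | 32 / 5 | |

## Scaled-down study sizes

The acceptance script and the learning tests run the full pipeline at desk
scale, chosen so a complete run finishes in minutes on one CPU while every
qualitative claim is still exercised: source task 240 molecules × 11
labels (20-epoch five-fold pre-training CV), target task 140 molecules ×
18 labels (12-epoch fine-tuning CV for two strategies, 20-epoch final
training, 60 unseen test molecules), capacity check 200 molecules × 8
labels, transfer-direction check 150-source / 120-target molecules with a
10-epoch budget. At these sizes the directional results (fine-tuning beats
scratch; freezing everything underperforms freezing only the text branch)
are stable; absolute metric values are specific to the synthetic
conditions.

## Known limitations

* No bond/edge features in attention; atom featurization is the eight
  listed blocks only; no 3-D information.
* Exact reproduction of published database-scale scores is out of scope:
  fold partitions, element vocabularies and several architecture sizes are
  not recoverable from the method description, and the engine targets
  correctness and reproducibility, not GPU-scale throughput.
* Character-level tokens outside the fitted vocabulary at prediction time
  raise an error naming the token rather than mapping to an unknown bucket.
* Determinism is guaranteed single-threaded; multi-threaded BLAS may
  introduce rounding-level run-to-run differences.
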