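# Methods

## Model

`linemol` encodes a molecule as a **molecular line graph**: heavy atoms and
bonds are read from SMILES (RDKit), and the line-graph transform creates one
node per bond, with two nodes adjacent exactly when their source bonds share
an atom. Working at bond granularity keeps the full bond feature set
(type, conjugation, ring membership, stereo) in the nodes themselves rather
than relegating it to edge attributes. A single-heavy-atom molecule, which
has no bonds, is represented by one node storing (atom features, atom
features, zero bond vector) so every parseable molecule is encodable.

Each line-graph node embeds as

    h = concat(W_v x_i + W_v x_j,  W_e x_e)

— the *sum* over the two endpoint atoms makes the embedding invariant to
their storage order. A transformer stack processes the node matrix with
multi-head self-attention whose logits carry two additive structural biases
shared by all layers and heads:

* **path bias** `a^p_ij = W_a · mean_n(W_n h_pn)`: the initial embeddings of
  the nodes along the BFS shortest path from i to j, each position passed
  through its own projection from a fixed-size bank (default 5 positions;
  longer paths are truncated to their first 5 nodes);
* **distance bias** `a^d_ij = W_2 GELU(W_1 d_ij)`: a two-layer perceptron on
  the hop count, clipped at 20 so the perceptron sees bounded inputs.

Attention is `softmax(QK^T/sqrt(D_h) + A^p + A^d)`, and each layer finishes
with a post-norm residual feed-forward block
`out = LN(W_2 GELU(W_1 LN(H_prev + H_attn)) + LN(H_prev + H_attn))`, exactly
in that arrangement (post-norm, not the pre-norm variant common elsewhere).
GELU is the exact Gaussian-CDF form `x·Φ(x)`. Readout is a mean pool over
nodes.

### The knowledge node

Every graph is augmented with one extra node connected to all others. Its
input is a 712-vector: 200 molecular descriptors (normalized, below) and a
512-bit hashed path-based topological fingerprint. The knowledge node and
all unreachable node pairs bypass the path/distance formulas and receive
dedicated learned scalar biases. This is a deliberate design point: the
knowledge node is adjacent to everything, so routing it through the
shortest-path machinery would collapse every pairwise distance to ≤ 2 hops
and erase the structural encoding the biases exist to provide. The biases
are computed once per graph from the initial embeddings and shared across
layers and heads, following the model equations, which write `A^p` and
`A^d` without layer or head indices; a switch (`recompute_bias_per_layer`)
re-derives them from each layer's hidden states instead. Whether the
knowledge node joins the mean pool is configurable (`include_k_in_pool`,
default on).

### Descriptor normalization

The 200 descriptors span wildly different scales (molecular weight in the
hundreds, fraction-type descriptors in [0,1], some descriptors occasionally
infinite). Both as network inputs and as regression targets they are
standardized robustly: per-descriptor median location, IQR/1.349 scale
(consistent for σ under normality), z-scores clipped at ±10, non-finite
values imputed to 0, constant descriptors given scale 1. The normalizer is
fitted on the pre-training corpus, serialized as JSON, and carried inside
every checkpoint. Raw-scale regression targets would let a handful of
large-magnitude descriptors dominate the reconstruction loss; this choice
balances the 200 regression targets.

The descriptor list is the first 200 entries of RDKit's descriptor registry
in registry order; the names are frozen into the normalizer so toolkit drift
is detectable. Fingerprints use RDKit's path-based fingerprint folded to
512 bits at toolkit-default path lengths.

## Pre-training objective

Masked-graph reconstruction with three terms, summed with weights 1:1:1
(configurable):

1. **Node type.** Each base node is independently selected with probability
   0.5 (the default masking rate). A selected node is replaced by a learned
   mask token (probability 0.8), by the raw feature triple of a random node
   from the current batch (0.1), or kept (0.1). The model predicts the
   original node's type — the unordered pair of endpoint elements plus the
   bond type, with an UNK class for unseen types — via cross-entropy over
   selected nodes. The (element pair, bond type) label space is the minimal
   reading of "node type" at bond granularity; predicting full raw feature
   tuples would make the label space enormous and mostly singleton.
2. **Masked descriptors.** Knowledge entries are masked independently at the
   same rate (zeroed, with the mask itself fed to the model through a
   separate learned indicator projection added into the knowledge-node
   embedding). Masked descriptor entries are reconstructed from the
   knowledge node's final embedding under an RMSE loss computed over masked
   entries only.
3. **Masked fingerprint bits,** same masking, binary cross-entropy over
   masked bits only.

The mask token is a dedicated learned embedding vector, not zeros, so the
model can distinguish "masked" from "genuinely zero features". Random
replacements are drawn from the current mini-batch's node pool — a cheap
approximation of the corpus node distribution that needs no global store.

## Training

All training runs on the package's own reverse-mode autodiff core
(`linemol.nn`), a minimal tensor-autograd engine over float64 NumPy arrays;
every primitive's gradient is verified against central finite differences in
the test suite. The optimizer is Adam with decoupled weight decay
(reference configuration: lr 2e-4, weight decay 1e-6, batch 1024, 100,000
steps, 12 layers × 768 hidden × 12 heads — about 1e8 parameters).
Initialization is truncated-normal (σ = 0.02, clipped at 2σ) for projection
matrices, zeros for biases, ones for LayerNorm gains, all drawn from a
single seeded generator; runs are bit-reproducible.

Desk-scale defaults, used by the test suite: 2 layers, 128 hidden units,
4 heads, a 200-molecule corpus, 200 optimization steps. At a 200-step
horizon the reference learning rate barely moves a freshly initialized
post-norm transformer, so the desk configuration pairs a large batch (128)
with a proportionally raised learning rate (3e-3) and a linear warmup over
the first 10% of steps — standard small-transformer, large-batch practice.
A cosine decay option exists but is off by default: over 200 steps it
halves the effective learning-rate budget and demonstrably under-trains.
These are configuration defaults of the scaled-down setting, not changes to
the objective: masking rate, the 8:1:1 replacement ratio, and the loss
weighting are identical to the reference configuration.

## Transfer learning

Finetuning strategies are independently switchable, with defaults (when
enabled) γ = 0.95 for layer-wise learning-rate decay, n = 1 re-initialized
top layers, m = 3 ascent steps of size α = 1e-3 for adversarial feature
augmentation (FLAG), and λ = 1e-4 for the L²-SP pull toward the pre-trained
weights:

* **LLRD** builds per-block learning rates: head and top layer at the base
  rate, each lower layer decayed by γ, the embedding + bias banks (the
  bottom-most block) by γ^L.
* **ReInit** freshly initializes the top n transformer layers; everything
  else is left bitwise-unchanged.
* **FLAG** perturbs the *initial node embeddings* (perturbing discrete
  one-hot inputs is ill-defined) with m sign-gradient ascent steps of size
  α, so ‖δ‖∞ ≤ m·α, and averages the loss over steps; m = 0 reduces exactly
  to plain training. The embedding tensor stays attached to the autodiff
  graph, so embedding weights keep training.
* **L²-SP** penalizes λ‖θ − θ_ref‖² over encoder parameters; the freshly
  initialized head has no pre-trained reference and is exempt.

Feature extraction freezes the encoder entirely: pooled embeddings ("neural
fingerprints") feed either a trainable two-layer perceptron head or a
k-nearest-neighbour probe (Euclidean, majority vote, vote fraction as the
score, distance ties broken by the smaller training index, split votes by
the nearest neighbour).

Classification uses per-task binary cross-entropy with missing-label
masking; regression uses mean squared error. Epochs are selected on the
validation metric (AUROC up / RMSE down); test metrics are reported at the
selected epoch only.

## Datasets and evaluation

Scaffold splitting groups molecules by Bemis–Murcko framework; acyclic
molecules form singleton groups keyed by canonical SMILES (one giant
"empty-scaffold" group would defeat the split's purpose). Groups are
ordered by size descending, ties broken by scaffold string, and filled
greedily into train until it holds ≥ 80% of molecules, then validation
(≥ 10%), then test — deterministic and invariant to input row order; exact
ratios are approximate because groups are atomic. Metrics: AUROC and AUPRC
for classification (undefined single-class cases reported as missing),
RMSE / MAE / Spearman / Pearson for regression, per-task then averaged for
multi-task data. AUROC ties receive the standard half-credit, verified
against a brute-force pairwise-concordance oracle.

## The fixture generator

`generate_fixture_molecules` composes drug-like fragments — aromatic and
saturated (hetero)cycles, fused bicyclics, common substituents, ring–ring
linkers, and acyclic chains — into deterministic, always-parseable SMILES
(well over 20 Bemis–Murcko scaffolds at n ≥ 100). Synthetic labels are a
stated function of a computed descriptor (Crippen logP above the set median
for classification; standardized logP for regression), so tasks are
learnable by construction. What the generator does *not* emulate: the scale
and chemical breadth of a real pre-training corpus (millions of molecules,
charged species, stereochemistry-rich drugs, exotic ring systems),
measurement noise in real assay labels, and real-world label sparsity.
Passing tests therefore demonstrate the machinery — representations,
objectives, optimization, splits, metrics — behaves correctly and
deterministically at desk scale, not that the model attains
publication-level accuracy on external benchmarks, which requires the
full-scale corpus and configuration.

## Numerical choices and degenerate inputs

* float64 throughout; attention softmax and binary cross-entropy computed
  in numerically stable forms.
* BFS tie-breaks by ascending neighbour index: stored shortest paths are
  unique and reproducible.
* Unreachable pairs carry the sentinel distance −1 and a dedicated learned
  bias — never a large numeric distance, which would saturate the distance
  perceptron.
* Descriptors and fingerprints are computed on the canonicalized molecule,
  making knowledge vectors bitwise invariant to SMILES spelling.
* Multi-fragment SMILES are reduced to the largest fragment at parse time.
* Classification labels are validated as {0, 1, missing} at CSV load; a
  violating cell is reported with its row number.
* Empty loss terms (no masked entries) are exactly zero and detached from
  the gradient.

## Known limitations

* CPU-only and single-graph (no batched padding) — throughput is adequate
  for desk-scale experiments, orders of magnitude below GPU training.
* No 3D/conformer information and no memory-efficient attention variants.
* The descriptor list tracks the installed RDKit registry; checkpoints pin
  the names but not the underlying descriptor implementations.
* Scaffold splitting and the kNN probe are exact but quadratic-ish in
  dataset size; fine for thousands of molecules, not millions.
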