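# Methods

This note documents the models, the data handling, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not show.

## Graph representation

Molecules are heavy-atom graphs parsed from SMILES; hydrogens stay
implicit. Every bond is stored as two directed edges at consecutive
positions (bond i occupies slots 2i and 2i+1), which makes reverse-edge
lookup an XOR and lets the same container serve node-centred and
edge-centred message passing.

Node features are fixed-order blocks, total width 40:

| block | encoding | width |
|---|---|---|
| atom type | one-hot over C, N, O, S, F, Cl, Br, I, P, B, Si, Se + "other" | 13 |
| degree | one-hot 0–6, top bucket absorbs overflow | 7 |
| implicit valence | one-hot 0–6 | 7 |
| formal charge | raw integer | 1 |
| radical electrons | raw integer | 1 |
| hybridization | one-hot SP, SP2, SP3, SP3D, SP3D2 | 5 |
| aromaticity | binary | 1 |
| total H count | one-hot 0–4 | 5 |

The element vocabulary is a fixed list of common organic elements with a
catch-all slot: it keeps the feature width constant across datasets.
Charge and radical count stay integers — the smallest encoding consistent
with the feature list. Bond features are a strict one-hot over four
classes (single, double, triple, aromatic); kekulization is not applied,
aromatic bonds are their own class, and any other bond type is a
featurization error. Ionic contacts are not edges: a salt is a
multi-fragment graph whose components exchange no messages (the readout
bridges them additively).

## Architectures

**Initial states.** h_v^(0) is the atom feature vector zero-padded to the
message size D when the feature width is smaller, or linearly projected
when larger. The EMNN uses the raw atom feature vector directly (its state
carrier is the edge).

**SELU-MPNN.** Four per-bond-class message MLPs (one hidden layer of
`msg_hidden_dim`, SELU) map neighbour states to messages; messages sum
over the neighbourhood; a GRU updates the node state. SELU with the
standard self-normalizing constants (α ≈ 1.6733, λ ≈ 1.0507) is used in
every feed-forward stack in place of batch/layer normalization, with
weights initialized N(0, 1/fan_in).

**AMPNN.** Per-bond-class embedding nets f (hidden `msg_hidden_dim`) and
weighting nets g (hidden `att_hidden_dim`) of equal output width D. The
softmax runs along the neighbour axis independently for every output
element, so attention weights per element form a convex combination. An
empty neighbourhood bypasses the softmax and yields a zero message.

**EMNN.** Edge states (width `edge_embedding_size`) start at zero; the
static embedding e' comes from an MLP on the concatenation
(bond one-hot, x_v, x_w) — order-sensitive, so e'_vw ≠ e'_wv in general.
The attention set for edge (v, w) is the states of incoming edges
(k, v), k ≠ w, plus e'_vw itself, so the set is never empty and the
reverse edge never contributes (no backflow — exact, and tested as such).
The f/g attention nets are shared across bond classes: edge identity
already lives in e'. After K rounds, node states are the sum of outgoing
directed-edge states. The EMNN has no separate message-size
hyperparameter; the edge state width *is* the embedding size, because the
attention set mixes edge states and e' and both must share f/g input
width.

**Readout and head.** All three architectures use the gated readout
Σ_v p(h_v^(K)) ⊙ σ(q(h_v^(K), h_v^(0))), p hidden width
`gather_emb_hidden_dim`, q hidden width `gather_att_hidden_dim`, output
width `gather_width`. The output stack has three shrinking hidden layers:
`out_hidden_dim`, then twice scaled by `out_layer_shrinkage` (rounded,
floor 1), SELU between layers, standard inverted dropout `out_dropout_p`
after each hidden activation, final linear width = number of tasks. A
depth of three is a fixed design choice; the shrinkage parameterization
implies at least two and is silent beyond that.

**Weight sharing.** The GRU is shared across all nodes (or edges) and
across the K rounds, following the gated-graph-network lineage.

## Autodiff substrate

The models run on a small tape-based reverse-mode autodiff over float64
NumPy arrays (`molmpnn.autodiff`): affine maps, SELU/sigmoid/tanh,
row gather with scatter-add adjoint, segment-sum with gather adjoint, a
numerically stable segment softmax (per-segment max shift, treated as a
constant — exact for softmax), a stable fused binary cross-entropy with
logits (gradient σ(s) − y), inverted dropout, and Adam. Gradients of all
three full architectures are verified against central finite differences
in the test suite. Batched graphs are disjoint unions with a
molecule-membership index; readout is a segment-sum over molecules, which
makes fragment additivity and permutation invariance exact up to float
reassociation.

## Data handling

**SMD preprocessing.** Structures are replaced by their charge parent —
the uncharged canonical form of the largest organic covalent unit —
via RDKit's standardizer (cleanup, largest organic fragment, uncharge).
Where neutralization is chemically impossible (quaternary nitrogen) the
charge is retained and logged. Rows whose standardization fails are
dropped with a logged count rather than aborting. Missing labels are
whatever reads as an empty cell (or "NA") in the delimited table; they
become an explicit mask.

**Masked losses.** Mean binary cross-entropy (classification, pre-sigmoid
scores) or mean squared error (regression, normalized space) over observed
cells only. Observed cells are selected by index, not multiplied by a 0/1
mask, so appending fully-missing rows leaves the loss bit-for-bit
unchanged and the gradient at missing cells is identically zero. A batch
with no observed cells has loss 0 and warns.

**Normalization.** Per-task mean and sample standard deviation (ddof = 1)
over observed *training* cells only; a constant task is an error naming
the task. Predictions are inverse-transformed before metrics, so reported
regression errors are in original units. Classification tasks are never
normalized.

**Splits.** Random splits permute indices under a fixed seed with
round-to-nearest set sizes. Scaffold splits group by canonical
Bemis-Murcko scaffold (acyclic molecules share the empty scaffold class)
and fill train, then valid, then test greedily with whole groups, largest
group first, ties broken by scaffold string. A group exceeding the train
allocation still goes to train with a warning. Leakage is exactly zero by
construction and asserted in tests.

**Metrics and repeats.** ROC-AUC and PRC-AUC per task over observed cells
(PRC-AUC is average precision — the step-wise integral, not trapezoidal,
because the two differ); RMSE/MAE after inverse normalization. A task
whose observed test labels are single-class is reported NaN and excluded
from the per-dataset mean. The repeat protocol runs three trainings:
random mode uses three split seeds (three memberships); scaffold mode
reuses one membership and varies only the weight seed. Mean and ddof-1
standard deviation are reported over the three repeats.

**Training loop.** Adam at the configured learning rate, no schedule;
batch size 50 and an epoch cap with patience-based early stopping on the
validation metric (defaults 500/20, configurable) — desk-scale choices,
as the optimizer/batch/epoch budget is open configuration. The parameter
snapshot from the best validation epoch supplies the reported test
metrics. Training is deterministic for fixed (config, table, split, seed);
a non-finite loss aborts with diagnostics.

## Hyperparameter optimization

Search domains are fixed per architecture (see the table in
`molmpnn/hyperopt.py`): learning rate continuous on a log scale in
[1e-6, 1e-4]; the remaining dimensions discrete lists; the EMNN domain
omits message size, caps message passes at 8, and tightens the gather
hidden-dim lists. Discrete dimensions are treated as categoricals
(one-hot) in the surrogate; continuous ones are scaled to [0, 1]. The
first five points are a Sobol space-filling design; afterwards a
Gaussian-process surrogate (Matern ν = 2.5 + white noise) drives Expected
Improvement over a random candidate pool, with a soft local penalizer
around already-selected batch points (Lipschitz constant estimated from
pairwise history differences) to spread batch suggestions. AUC metrics
are maximized, error metrics negated internally. Failed objective
evaluations score worst-case-so-far and the search continues; the full
audit trail is retained. The evaluation budget is caller-chosen — there
is no canonical value.

## Synthetic fixtures

The generator assembles molecules from a fragment grammar (aromatic and
saturated rings, short hetero-substituted chains, optional charged salt
pairs), capped at 12 heavy atoms so brute-force oracles stay exhaustive
and fast, deduplicated by canonical SMILES, deterministic per seed. Label
rules are deterministic graph functions: counts (aromatic atoms, heavy
atoms), indicators (ring presence, element presence), a graph-additive
property (fixed per-element contributions plus an aromatic bonus) used
for parameter recovery, and a hashed pseudo-label whose active rate is
controllable — used for census-regime fixtures (such as the 84%-missing
sparse panel emulating extreme multitask sparsity), not for learnability
tests. Missing masks are Bernoulli per task at the requested rate.
Correlated task groups arise by repeating one rule with independent masks.

What passing these tests shows: the architectures, losses, splits and
search behave exactly as specified on graphs whose ground truth is known.
What they do not show: performance on real assay data — fixture molecules
are small, their label rules are noiseless and graph-computable, and
their chemistry is far narrower than a screening collection.

## Problem sizes

The test suite and the acceptance script use 100–200 fixture molecules,
networks with hidden widths 8–32, and ≤ 200 training epochs; these sizes
were chosen so the whole pipeline — including two full parameter-recovery
trainings — completes in well under a minute on one CPU while leaving the
recovery margins wide (RMSE ratio ≈ 0.08 against a 0.2 bound; ROC-AUC
1.0 against a 0.95 bound).

## Known limitations

- No stereochemistry, 3D conformers, or ionic-bond edges in the graph.
- No tautomer canonicalization or salt dictionaries beyond
  largest-organic-fragment logic.
- The softmax attention is O(messages) but the NumPy substrate is
  single-threaded; hundred-thousand-molecule benchmark sets are out of
  desk scope.
- PRC-AUC for extremely few actives is high-variance; single-class test
  tasks are excluded from aggregates rather than patched.
- The hashed pseudo-label rule is deterministic but not learnable by
  design; using it in a training experiment will produce chance-level
  metrics.
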