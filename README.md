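# molmpnn

Message passing neural networks for molecular bioactivity and
physical–chemical property prediction, built for sparse multitask data.

Quantitative structure–activity modelling increasingly replaces engineered
descriptors with representation learning on the molecular graph itself.
This package implements that pipeline end to end for people working on
virtual screening and property prediction: SMILES in, per-task predictions
out, with the data handling that real bioactivity panels need — salts and
charged complexes standardized to their charge parents, unlabelled cells
treated as *missing* rather than imputed as inactive, and scaffold-aware
splitting so test molecules are genuinely novel chemotypes.

## The models

All three architectures follow the message passing scheme over a molecular
graph G = (V, E) with atom features x_v and bond features e_vw, iterating
for K rounds:

    m_v^(t) = Σ_{w ∈ N(v)} M_t(h_v^(t), h_w^(t), e_vw)
    h_v^(t+1) = U_t(h_v^(t), m_v^(t))

followed by a node-order-invariant readout R({h_v^(K)}) and a feed-forward
head. Concretely:

* **SELU-MPNN** — the baseline. One feed-forward message network per bond
  class (single, double, triple, aromatic), messages summed over the
  neighbourhood, a GRU as the update function, and SELU activations
  throughout in place of explicit normalization layers.
* **AMPNN** — replaces the plain sum with elementwise attention. Per-bond-
  class embedding networks f and weighting networks g of equal output
  width; the weights are softmax-normalized *along the neighbour axis*, so
  each element of the message is its own convex combination of neighbour
  embeddings:

      m_v = Σ_w f^(e_vw)(h_w) ⊙ softmax_{w ∈ N(v)} g^(e_vw)(h_w)

* **EMNN** — an edge-memory network. Hidden states live on *directed*
  edges; a static embedding e'_vw = FFNN(e_vw, x_v, x_w) is computed once
  per directed edge, and each round the state of (v, w) attends over the
  states of incoming edges (k, v) with k ≠ w — never its own reverse —
  plus e'_vw. After K rounds edge states collapse onto nodes by summation.
  This one-way flow stops information washing straight back where it came
  from on paths like A–B–C.

All three share the gated (GGNN-style) readout
R = Σ_v p(h_v^(K)) ⊙ σ(q(h_v^(K), h_v^(0))) and a shrinking SELU
feed-forward output stack. Classification heads emit pre-sigmoid scores;
regression targets are standardized per task on training statistics and
predictions mapped back before scoring.

Around the models:

* **SMD preprocessing** (`molmpnn.preprocess`) — charge-parent
  standardization of every structure plus explicit missing-label masks;
  masked binary cross-entropy / squared-error losses guarantee zero
  gradient at unobserved cells. A label census reports actives/inactives/
  missing and the two active-fraction conventions (missing-imputed vs
  observed-only).
* **Splitting & evaluation** (`molmpnn.datasets`, `molmpnn.train`) —
  80/10/10 random or Bemis-Murcko scaffold splits (zero scaffold leakage),
  ROC-AUC / PRC-AUC / RMSE / MAE over observed cells, best-validation-epoch
  model selection, and the three-repeat protocol (three split seeds for
  random splits; one shared split, three weight seeds for scaffold splits).
* **Bayesian optimization** (`molmpnn.hyperopt`) — per-architecture search
  domains, a Gaussian-process surrogate with Expected Improvement, and
  local penalization for diverse batch suggestions.
* **Synthetic fixtures** (`molmpnn.fixtures`) — small molecule sets from a
  fragment grammar with rule-generated labels at controlled sparsity, so
  every stage runs and is testable without external downloads.

The tensor substrate is a compact NumPy reverse-mode autodiff core
(`molmpnn.autodiff`) purpose-built for batched graph operations (segment
gather/scatter, segment softmax, GRU, Adam) — everything runs on one CPU.

## A worked example

`examples/03_train_attention_mpnn.py` trains a small AMPNN on a synthetic
additive-property task (each molecule's label is a fixed sum of per-element
contributions plus an aromatic bonus — exactly representable by a summed
readout):

```
best validation epoch: 114
test RMSE: 0.139 (label std 1.694, ratio 0.082)
```

The test RMSE at 8% of the label standard deviation means the network
recovered the generative rule rather than regressing to the mean. The other
examples cover graph featurization and the directed-edge structure (01),
SMD preprocessing and the label census (02), leakage-free scaffold
splitting (04), and the Bayesian optimizer (05); each prints what it
computes and says what the numbers mean.

## Layout

```
src/molmpnn/     chem_graph, preprocess, datasets, models, train,
                 hyperopt, fixtures, autodiff, cli
examples/        one short narrative script per capability
tests/           pytest suite (unit, property, end-to-end)
docs/methods.md  models, assumptions, numerical choices, limitations
```

A thin `molmpnn` command (`prepare`, `split`, `train`) wraps the common
shell-driven steps; the Python API is the primary interface.
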