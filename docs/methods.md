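# Methods

## Problem and model

Given a perturb-seq screen over K genes, a perturbation condition is a set
c ⊆ {1, …, K} of simultaneously perturbed genes (m = |c|; m = 0 is
control).  The package predicts the post-perturbation expression of a cell
as `ŷ = g(c) + x`, where `x` is a sampled unperturbed control cell and
`g(c) ∈ R^K` is a learned, condition-specific expression shift on the
log-normalized scale.  Predicting the shift rather than the expression
itself factors out cell-to-cell baseline variation and makes the control
distribution an explicit input.

`g(c)` is decoded from the sum of two K × D encodings.

**PertWeight (nonuniform global effects).**  Two K × D_e gene embeddings
(E_w, E_p) are propagated through the GO similarity graph by t-hop
simplified graph convolutions (SGConv: `S^t E T`, one linear projection,
no nonlinearities between hops, S the symmetrically normalized adjacency
with self-loops).  The propagated E_w yields multi-head attention queries
and keys; the propagated E_p yields values, which are masked by the 0/1
indicator vector z_c so only perturbed genes contribute.  Row k of the
attention output is therefore `Σ_{j∈c} W_kj v_j` per head — a learned,
gene-pair-specific weighting of each perturbed gene's effect on each
responding gene.  A second propagated projection P contributes
`Σ_{j∈c} p_j`, a uniform "general effect" of the perturbed set.  Both
parts pass through linear-plus-layer-norm maps (f1, f2) into width D.
Before these output projections the encoder is exactly additive over
disjoint perturbed sets (the masking is linear in z_c); the suite asserts
this at 1e-5.

**PertLocal (local disturbance, nonadditivity).**  A two-row indicator
embedding table is expanded to K × D_e by lookup of z_c and modulated by
the nonadditive bias `1 + β (m − 1) tanh(K_NA z_c)` — a single D_e-vector
broadcast over genes, the only dimensionally consistent reading of the
construction.  The modulation is exactly the identity at m = 1 and at
β = 0, so "NA-bias disabled" is implemented as β = 0 rather than a
separate code path.  The biased embedding is added to a gene base
embedding and propagated by SGConv through the *augmented* GO graph (the
GO graph made fully connected with virtual edges of weight α·min-weight),
then combined as `f3(SGConv(E_g + E'_z)) + f4(E_z)` with
linear-plus-batch-norm maps.

**Decoder.**  `g_k = w_kᵀ f5(h_k^PW + h_k^PL) + b_k` with a shared
linear→ReLU→linear map f5 and per-gene read-out vectors; there is no
cross-gene layer, so each gene's shift depends only on its own encoding
row (asserted in the suite).

## GO graph

Edge weights are the Jaccard similarity of two genes' GO term sets,
|A∩B| / |A∪B|, computed for all pairs.  Each gene marks its k = 20
highest-weight positive edges (ties at the k-th weight broken toward the
smaller partner index); the graph keeps an edge marked by either endpoint
(union symmetrization, the usual kNN-graph convention, which keeps the
graph better connected than intersection).  Every modeled gene must be
annotated; absentees are reported as errors rather than silently isolated.
The augmented graph preserves existing weights bit-exactly and assigns
every missing pair α times the minimum existing weight (α = 0.75), letting
the local encoder learn lightweight rather than exactly-zero interactions
between ontologically unrelated genes.

## Loss and training

The combined loss is an autofocus term `mean |ŷ − y|^(2+γ)` (γ = 1), which
up-weights large errors, plus λ_dir (= 0.1) times a direction term
`mean (sign(y − x̄_ctrl) − sign(ŷ − x̄_ctrl))²` with sign(0) = 0.  The
direction term is piecewise constant in the parameters; it is included in
reported loss values but contributes no gradient — the same effective
behaviour as implementations that differentiate through a hard sign.

Cells are paired with controls once, up front (uniform with replacement,
seeded); control cells themselves are not training targets.  Training is
plain Adam (lr 1e-3, batch 128, 20 epochs) over shuffled mini-batches;
each batch evaluates the forward pass once per unique condition and
gathers per-cell predictions from the condition-level shifts.  The
parameters of the epoch with the best validation combined loss are
returned.  One run seed fans out (via `numpy.random.SeedSequence`) to
pairing, initialization and shuffling sub-seeds, so runs are reproducible
up to floating-point reduction order.

Splits are made at condition granularity — all cells of a condition land
in one partition — and test conditions are labeled "seen s/m" by how many
of their genes are perturbed in the *train* conditions.  `make_split`
partitions uniformly (floor each fraction, remainder to train).
`make_combo_holdout_split` instead holds out two-gene conditions for both
validation and test while keeping all singles in train: checkpoint
selection then tracks combination generalization ("seen 2/2") rather than
the unlearnable effects of never-perturbed genes, which is the relevant
model-selection signal for that task.

## Numerical core

The network, its gradients and Adam run on a small in-package
reverse-mode automatic-differentiation engine over numpy float64 arrays
(`pertattn.autodiff`).  Every operation's gradient is verified against
central finite differences in the test suite.  Softmax detaches its max
shift; layer norm uses ε = 1e-5 on the feature axis.  Batch norm in
f3/f4 normalizes each feature over the gene axis of a condition's K × D
encoding during training (running statistics, momentum 0.1) and uses the
stored running statistics in evaluation, making evaluation forwards
deterministic.  Initialization: embeddings N(0, 1/D_e) (or Gene2Vec-style
rows when an embedding file is given — all three gene embeddings then
start from the same table); projections N(0, 1/fan_in); gains 1, biases 0.
Propagation is dense K × K, appropriate for panels up to a few thousand
genes.

## Evaluation

For each condition the model's mean prediction (shift + control mean) is
compared with the empirical mean over that condition's cells.  DE genes
are the top n = 20 by |mean shift vs control mean| (ties toward smaller
index); the DE ranking is parameter-free and matches the shift-centric
metrics.  Metrics: MSE over DE genes; rel-MSE = 100 × MSE / Ctrl's MSE
(the Ctrl baseline predicts the control mean everywhere and scores exactly
100); Pearson correlation of predicted vs true shift over all genes (0 for
a constant predictor, whose correlation is otherwise undefined; an error
if the true shift is constant); the fraction of DE genes with the wrong
shift sign (sign(0) mismatches any nonzero sign); and the fraction of DE
genes off by more than one sample standard deviation (ddof = 1, hence the
two-cell minimum).  Nonadditive genes (NAG) of a pair c = {i, j} at
threshold η are the top-200 DE genes with |Δ_i,k + Δ_j,k − Δ_c,k| ≥
η |Δ_c,k|, estimated from mean shifts; the additive baseline is
Δ_i + Δ_j.  The residual-matrix analysis tabulates squared errors of
condition-mean predictions over the union of per-condition DE genes and
divides each column by its maximum.

## Synthetic screens

The generator emulates the structure of combinatorial CRISPR screens:
control cells around a baseline μ ~ U(0.5, 5) per gene; single-gene
conditions with sparse shift vectors δ_g (a knockdown-like drop of the
perturbed gene itself plus N(0, effect_scale²) effects on ~15% of genes,
concentrated on the gene's latent module); and two-gene conditions with
Δ_ij = δ_i + δ_j plus, for `interaction_fraction` of pairs, a nonadditive
component on half the union support.  Genes belong to K/n_modules-sized
index blocks ("modules"); the synthetic GO table gives module-mates extra
shared terms, so the Jaccard graph has block structure and perturbation
effects are genuinely localized on it.  Noise is Gaussian on the
log-expression scale; the generator does not model count-level artefacts
(dropout, library size) or any specific public screen, so passing tests
demonstrate correct mechanics and recoverable structure, not performance
on real data.

Reference settings (the package's fixture and the scale used by the
acceptance checks): 60 genes, 6 modules, 120 terms, 30 single and 16
double conditions, 50 cells per condition, 200 controls, effect scale 1,
noise sd 0.1, interaction fraction 0.25 (0.5 for the nonadditivity
study).  Training-based checks use embedding width 32 with all other
hyper-parameters at their defaults, three seeds, median aggregation;
at this scale one training run takes well under a minute on a single CPU.

## Known limitations

* Generalization to conditions whose genes were never perturbed in
  training ("seen 0/1", "seen 0/2") depends entirely on embedding and
  graph structure; on synthetic data with module-local but
  randomly-signed effects this signal is weak, and such conditions are
  near the Ctrl baseline.
* Layer norm inside f1/f2 breaks strict additivity of PertWeight *after*
  projection; additivity is claimed and tested pre-projection only.
* The m = 0 condition is a legal input and yields whatever shift the
  learned biases produce; no zero shift is hard-coded.
* Checkpoints reproduce predictions bit-exactly on the writing platform;
  cross-platform bit-exactness is not promised.
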