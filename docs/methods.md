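# Methods

## Model and assumptions

The pipeline has three stages, all deterministic given their seeds.

**Diffusion states.** Each network is symmetrized (conflicting directed
weights resolved by maximum — a conservative merge of interaction
confidences) before normalisation, since curated interaction networks are
undirected and symmetry makes the column-normalised transition matrix *M*
and its transpose carry the same information. The random walk with restart
is iterated as `S ← (1−α) S Mᵀ + α I` from `S = I`. With a symmetric
adjacency, `Mᵀ = D⁻¹A` is row-stochastic, so each row of `S` remains a
probability distribution at every iteration; this is the orientation under
which the row-vector iteration is a proper, mass-conserving walk.
Zero-degree (isolated) genes get all-zero transition columns; walk mass that
steps onto such a node cannot move on and is redirected wholly to the
restart distribution, which keeps rows exactly stochastic without inventing
a teleportation prior. An isolated source gene's diffusion state is exactly
its restart vector.

**Embedding.** `R = ln(S + 1/n)` (the pseudo-count guarantees finiteness),
then a truncated SVD with `X = U_d Σ_d^{1/2}` node features and
`W = V_d Σ_d^{1/2}` context features. This log/SVD route is the closed-form
production path; the KL divergence between the true diffusion states and the
softmax model `ŝ_ij ∝ exp(x_i·w_j)` is implemented only as a diagnostic
(`kl_objective`) and is never optimised iteratively. Each network is
factorised independently — the per-network SVD is what lets heterogeneous
sources contribute separate feature blocks, in contrast to joint
multi-network factorisations. Sign ambiguity of singular vectors is fixed by
making the largest-magnitude entry of each left vector positive, so
embeddings are bit-reproducible across platforms.

**Cascade forest.** Levels of N forests; per level the N C-dimensional
class-probability vectors are *concatenated* into the N·C augmentation block
(averaging across forests is used only for the level-selection metric and
the final prediction). Level 0 receives a zero block of the same width, so
every level sees a constant feature width of `raw + N·C`. Training class
vectors are assembled from out-of-fold predictions of k-fold CV (default
k = 3, the canonical deep-forest choice) and each forest is then refit on
the full training split for inference. Forests are multi-output decision-
tree ensembles (one probability per label from a single forest, keeping the
N·C accounting exact), not one-vs-rest stacks; half of each level's forests
are completely-random (single random feature per split) for diversity, the
other half standard random forests — the prose of the source method says
only "random forest classifiers" while its architecture figure shows the
two kinds, so the mix is configurable with the half/half default.

**Depth selection.** After each level, micro-F1 of the validation
probabilities binarised at a fixed threshold (default 0.5 — the depth metric
needs *some* deterministic threshold and none is canonical) is recorded;
growth stops when the argmax level (first maximum on ties) is
`early_stopping_rounds` (default 4) levels old, or at the `max_levels = 20`
safety cap. Early stopping is evaluated on a validation split carved from
the training data (default 1/5) — never on test data, which would leak the
test set into model selection.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | restart probability; larger keeps walk mass local |
| d | 100 (300 human-scale) | embedding dimension per network |
| tol, max_iter | 1e-6 (L1), 1000 | RWR convergence (standard practice; exposed in config) |
| N, trees | 8, 500 | forests per level, trees per forest |
| k | 3 | folds for out-of-fold class vectors |
| m | 4 | early-stopping patience in levels |
| t | 0.5 | probability threshold for binary calls |
| folds | 5 | outer cross-validation |

## Evaluation conventions

Micro-F1 pools TP/FP/FN over all gene–label pairs; macro-F1 averages
per-label F1 over labels with at least one positive in the evaluated set
(labels with no positives are skipped rather than scored 0, so trivial
all-negative columns neither reward nor punish). PR curves sweep the
distinct predicted scores plus {0, 1}; precision at zero predicted positives
is defined as 1. AUPR integrates precision over recall by the trapezoid
rule, traversing thresholds from high to low so tied-recall points
contribute their best precision; a step-interpolation oracle bounds the
difference in tests. AUPR is micro-averaged (pooled pairs) only. Genes with
zero labels are excluded from CV folds but still receive predictions.
Embeddings are computed on the full networks before fold splitting: the
diffusion/SVD stage never sees labels, so this is not leakage and mirrors
the embed-then-split ordering of the pipeline.

## Synthetic benchmark

The generator emulates K heterogeneous interaction networks over one gene
index: each gene draws Poisson(2)∧C labels uniformly (every label is
guaranteed one gene); network k is "informative" for a rotating subset of
C/K labels — pairs sharing an informative label connect with probability
p_in = 0.12, all others with p_out = 0.01, with confidences jittered
(N(0.8, 0.05) in-module, N(0.3, 0.05) background, clipped to [0, 1]) to
mimic curated confidence scores. Defaults: 600 genes, 12 labels, 3 networks.
Because the subsets rotate, no single network covers all labels and
integration must win — the benchmark instantiates the premise that
heterogeneous sources carry complementary, context-specific structure.

What it does *not* emulate: scale-free/degree-corrected topology, hub genes,
correlated label hierarchies, evidence-channel semantics, or the ~20%
network-specific gene coverage gaps of real resources. Passing benchmarks
here therefore demonstrates that the pipeline recovers planted modular
signal and that integration aggregates complementary views; it does not
certify performance on real interactomes.

## Experiment scale

Benchmark experiments (`difforest.experiments`) run the cascade at 4 forests
× 50 trees, two levels (patience 1), d = 25, 5-fold CV. The integration and
robustness signals live in the diffusion embeddings, not in ensemble size,
so this desk-scale configuration answers the study questions in minutes on
one CPU; the library defaults above remain the production configuration.
Measured at these conditions (seed 1): integrated AUPR 0.92 vs best single
network 0.58; AUPR spread 0.032 over d ∈ {10, 25, 50} and 0.040 over
α ∈ {0.1, 0.5, 0.9} — these numbers are recomputed, not stored, by
`scripts/acceptance.py`.

## Numerical choices and degenerate inputs

- Duplicate edges within a file merge by max weight; self-loops are allowed.
- A label constant in a training split yields a degenerate single-class
  forest output; its probability is taken as that constant (0 or 1), and a
  warning notes labels with fewer positives than CV folds.
- Closed-form RWR (`rwr_closed_form`) is a test oracle with a size cap
  (default n ≤ 500); with dangling nodes it solves one linear system per
  source because the mass redirect depends on the source.
- Per-level and per-forest seeds derive from the master seed via
  `numpy.random.SeedSequence` spawn keys: reproducible, yet diverse across
  levels and forests.
- Dense n×n diffusion states are used throughout (fine to ~20k genes in
  memory); `svd_embed` uses a full dense SVD for determinism.

## Open design points resolved here

- Genes absent from one network are kept as isolated nodes of a single
  shared index (restart-only diffusion), rather than intersecting gene sets
  across networks — intersection discards exactly the genes integration
  should help.
- "Five trials" in cross-validated reporting is read as 5 folds;
  `cross_validate(n_repeats=...)` offers repeated 5-fold if wanted.
- Multi-grained scanning from the general deep-forest architecture is
  deliberately absent: concatenated embedding features carry no spatial or
  sequential structure to scan.

## Known limitations

Dense diffusion states are O(n²) memory; no directed-network support
(inputs are symmetrized); macro-AUPR is not implemented (micro only); forest
training dominates runtime and parallelises only via `n_jobs` within a
forest.
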