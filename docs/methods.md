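# Methods

This note documents the models, estimators and design choices behind
`fpbench`, and what the synthetic study conditions do and do not establish.

## Molecule ingestion

Raw SMILES are parsed with RDKit. Standardization keeps the largest connected
component by heavy-atom count (salt/solvent stripping), breaking ties by the
lexicographically smallest canonical SMILES, and canonicalizes the survivor.
The length filter (8–140 characters, inclusive) is applied to the
*standardized* string, since filtering follows standardization in the
pipeline. No tautomer or charge normalization is attempted beyond fragment
stripping.

Accepted molecules become graphs: a binary symmetric adjacency `A` (bond
order ignored), the self-loop symmetric normalization

    A_selfloop = A + I
    A_norm     = D^{-1/2} A_selfloop D^{-1/2}

with `D` the diagonal degree matrix of `A_selfloop` (an isolated atom gets
degree 1 from its self-loop, so `A_norm` is always finite), and a 54-column
one-hot atom feature matrix: 38 atom-type slots (37 named elements plus an
unknown slot), 6 degree bins (0–5), 5 formal-charge bins (−2…+2), 4
chirality states (unspecified / CW / CCW / other) and one aromaticity flag.
Row sums are therefore 4 for non-aromatic and 5 for aromatic atoms. The
37-element list covers the common organic/drug-like elements (C, N, O, S,
halogens, P, B, Si, common metals); membership only routes one-hot
assignment and never changes the 54-column layout. Degrees or charges
outside the bins map to the nearest bin with a logged warning.

## Rule-based fingerprints

Morgan (extended-connectivity, 2D circular) fingerprints are folded to 300
or 1024 bits; the radius defaults to 2 (the ECFP4-equivalent community
default — the radius only matters relative to a fixed toolkit, so it is
exposed in the API). Topological path-based fingerprints use RDKit's path
hashing with paths of length 1–7 folded to 1024 bits. Both are binary and
invariant to SMILES atom ordering by canonicalization. A 3D circular
fingerprint slot exists as an adapter (`register_e3fp_backend`); no
conformer backend is shipped, so calling it unregistered raises a
capability error, and the core pipeline never depends on it.

## Graph autoencoder (GAE)

Encoder: seven graph-convolution layers, each a sum aggregation over
`A_norm` followed by ReLU,

    H_{l+1} = ReLU(A_norm H_l W_l),  H_0 = 54-column atom features,

read as per-node propagation (a global pooling readout after each layer
would destroy the per-node embedding matrix the fingerprint construction
needs). The embedding width is fixed at 16: the 64-bit fingerprint is three
pooled blocks of 16 plus 16 singular values, which forces 16. Hidden widths
interpolate geometrically 54→48→40→36→32→24→20→16 and are configurable;
only the depth (7) and the end points are architectural commitments.

Decoder: `sigmoid(dropout_{0.1}(Z Z^T))`, reconstructing `A_norm`. The loss
is elementwise binary cross-entropy with the soft `A_norm` entries as
targets (the literal reading); a binary `A + I` target is available as a
config alternative. Batches pad graphs to the batch-max node count with
zero rows/columns, masked out of the loss, so empty nodes contribute
nothing.

Fingerprints from the embedding `Z` (|V|×16):

* **16 bits** — the singular values of `Z` sorted descending, zero-padded
  when `min(|V|, 16) < 16`. This is the diagonal of Σ from the SVD, in the
  spirit of the Ky Fan k-norm (sum of the k largest singular values). The
  SVD is taken per molecule; a stacked multi-molecule SVD would make
  zero-padding for small molecules meaningless.
* **64 bits** — column-wise mean-, min- and max-pooled `Z` concatenated
  with the 16-bit block, in that order.

Because graph convolution with `A_norm` is permutation-equivariant and
singular values (and column-wise pooling) are invariant to row
permutations, both fingerprints are invariant to atom relabeling; this is
asserted end-to-end in the tests.

## SMILES variational autoencoder (VAE)

The vocabulary is built from the training corpus with a reserved zero-pad
token at index 0 (published corpus-specific counts like 53+1 are not
hard-coded). Inputs are one-hot matrices of fixed length 140. Encoder:
three 1-D convolutions of 9, 9 and 10 filters (kernel sizes 9, 9, 10), each
followed by SELU, then a 196-unit SELU dense layer feeding the posterior
mean and log-variance heads of a 16- or 256-dimensional diagonal Gaussian.
Decoder: the sampled latent vector is repeated at each of the 140 positions
through three GRU layers of hidden width 501 and a softmax readout over the
vocabulary. The loss is `0.5·BCE + 0.5·KL`, with the reconstruction BCE
averaged over all positions × vocabulary entries and the KL divergence from
the standard-normal prior averaged over the batch. Weights start from
Xavier uniform draws.

The fingerprint of a molecule is the **posterior mean** μ, never a sample:
downstream similarity and regression analyses require deterministic
fingerprints. Unknown characters at inference map to the pad slot with a
warning.

### Training and the numerical stack

Both models train with Adam (initial learning rate 1e-3) under a
halving-on-plateau schedule: the rate halves whenever an epoch's mean loss
fails to improve on the best so far, and training halts once the rate
reaches 1e-6 or the loss reaches zero. A k-fold loop (default 5) trains one
weight set throughout, recording a held-out validation loss per fold.
Non-finite losses abort with diagnostics. All randomness flows from one
seeded `numpy` Generator, so training is bitwise reproducible on a single
machine.

The networks run on a small tape-based reverse-mode autodiff engine inside
the package (`fpbench.nn`), written in float64 numpy. The GRU cell is a
single fused tape node with a hand-derived backward pass, which keeps the
140-step decoder graph small; all operator gradients are verified against
central differences in the test suite.

Smoke-scale defaults used by the tests (20 molecules / 5 epochs for the
GAE, 200 SMILES / 3 epochs for the VAE, single fold) were chosen as the
smallest sizes at which the loss trajectory is clearly decreasing; they
demonstrate that the optimization machinery works, not that the learned
fingerprints are chemically meaningful — that would require corpus-scale
training.

## Fingerprint-matrix similarity: HSIC and CKA

Two fingerprint matrices `X` (m×x) and `Y` (m×y) over the same m compounds
are column-centered (binary fingerprints are cast to reals and centered
exactly like continuous ones — the centering treats all types uniformly).
The unnormalized linear-kernel HSIC has two algebraically identical routes,

    HSIC_feature = ||Y^T X||_F^2          (x×y feature similarity)
    HSIC_sample  = trace(X X^T Y Y^T)     (m×m Gram matrices)

and CKA normalizes it to [0, 1]:

    CKA(X, Y) = HSIC(X, Y) / sqrt(HSIC(X, X) · HSIC(Y, Y)).

With the linear kernel this equals the classical RV coefficient, which the
tests use as an independent oracle. The default estimator is the
U-statistic **unbiased** HSIC (Song et al. 2012: zeroed Gram diagonals,
three-term estimator with a `1/(m(m−3))` prefactor, m ≥ 4); it can be
slightly negative for independent data, so CKA clamps a negative numerator
to 0 and raises on non-positive denominators (constant matrices), keeping
the [0, 1] contract while the raw HSIC values stay available in the result
object. The biased (plug-in) estimator is kept for the feature/sample
identity; its mode is chosen by the sample-vs-feature count rule (feature
route when m exceeds both widths — an efficiency rule, since the two routes
agree to rounding). The unbiased estimator has no feature-space shortcut
and always uses Gram matrices.

Pairwise similarity across fingerprint types requires identical compound
sets and row order; the display ordering of the similarity matrix comes
from average-linkage hierarchical clustering of the distance `1 − CKA`.

## Regression benchmark

Raw combination tables may contain biological replicates and both
orientations of a pair. Aggregation canonicalizes the pair key to sorted
compound-id order and averages all rows per (pair, cell line) — the default
collapses (A,B)/(B,A) duplicates, and an augmentation mode that keeps both
orders is available. Featurization concatenates the two drugs'
fingerprints in canonical order with a one-hot cell-line block
(length 2n + n_cells); path-based fingerprints are bit-averaged instead
(length n + n_cells), which makes the drug block manifestly
order-invariant. End-to-end order invariance is asserted in the tests.

Cross-validation: the 90:10 split is a shuffled 10-fold partition; a 60:40
split cannot be realized by 10 disjoint folds, so it is implemented as 10
repeated shuffled 60:40 holdouts — the reading that honors both the fold
count and the test fraction. Repeats reshuffle with seeds derived from the
base seed. The regressor is pluggable behind a fit/predict interface; the
shipped defaults are scikit-learn's histogram gradient-boosted trees and a
ridge baseline, with one model per response score.

Metrics, per (fingerprint × score):

* **PCC** — Pearson correlation per fold; fold values are Fisher
  z-transformed, a Student-t interval (df = folds − 1) is formed on the z
  scale and its endpoints transformed back. The reported mean is the
  back-transformed mean z. A Shapiro–Wilk gate checks normality of the
  fold z values and warns below p = 0.05 without blocking. Fold PCCs of
  ±1 give an infinite z and are reported as degenerate.
* **nRMSE** — RMSE divided by the *population* (n-denominator) standard
  deviation of the pooled test targets, so a constant mean predictor scores
  exactly 1. The 95% interval is a symmetric empirical bootstrap over 1000
  paired resamples (half-width = 97.5th percentile of absolute deviations
  from the point estimate).

## Clustering evaluation

Fingerprint matrices over class-labeled compounds are preprocessed three
ways: column z-scoring (population sd; constant columns dropped with a
warning), z-scoring + PCA keeping the smallest leading set of components
whose cumulative explained variance exceeds 0.95, and z-scoring + PLS with
the one-hot class labels as the multi-response target (K − 1 components by
default, matching the discriminative dimensionality of K classes).

One-versus-all LDA: for each class, a binary (class vs rest) discriminant
axis `w = S_w^{-1}(μ_k − μ_rest)` is fitted, with a small ridge added to a
(near-)singular within-class scatter, and all compounds are projected onto
it. The mean Silhouette coefficient and the variance ratio criterion
(Calinski–Harabasz index) are computed on that 1-D projection with the
binary labels as the two clusters, then averaged over the K classes. This
projection-based reading is the construction consistent with
"one-versus-all", LDA, and a scalar score per fingerprint; computing the
scores on the preprocessed features with LDA as a mere classifier is the
alternative reading and was not adopted. Silhouette uses Euclidean
distance; singleton clusters and coincident points (max(a,b)=0) score 0. A
zero within-cluster scatter makes VRC a +inf sentinel, which tops the
min–max scale.

Across fingerprints, each (regime, metric) column is min–max scaled so its
best entry is 1.0 and its worst 0.0; ranks follow the summed scaled scores
of the plain z-score regime.

## Synthetic data: what it emulates and what it does not

`gen_molecules` assembles SMILES from a fragment grammar: one of ten ring
scaffolds (benzene, pyridine, pyrimidine, furan, thiophene, pyrrole,
cyclohexane, cyclopentane, piperidine, tetrahydropyran) decorated with
acyclic alkyl/ether/amine/carbonyl/halogen/chiral/charged units. Scaffolds
cycle deterministically so all families are populated. About 2% of outputs
are deliberately shorter than 8 characters and 2% longer than 140, and 5%
carry a salt fragment, so the standardization and filter stages are
exercised; roughly 95% of generated molecules survive ingestion. Chiral
units cover the CW and CCW tetrahedral tags; the fourth ("other")
chirality slot cannot be expressed in SMILES and is covered only by the
featurizer's fallback routing.

`gen_screen` plants a linear signal: eight interpretable per-molecule
descriptors (heavy atoms, aromatic atoms, rings, N/O/halogen counts,
charged and chiral atom counts) are z-scored and combined into
order-invariant pair features (sum and absolute difference), weighted by a
random coefficient vector, plus a Gaussian cell-line effect. Noise is
scaled against the *empirical* variance of that structural part so the
planted variance fraction equals ρ by construction, giving a closed-form
prediction ceiling of √ρ for an ideal-descriptor regressor. The five
response scores are affine transforms of the shared latent (CSS-like scale
40 ± 15; synergy-like scales 0 ± 7–10) with half-shared, half-independent
noise so they correlate without asserting any real synergy model. A
configurable fraction of tuples appears as two biological replicates with
small (10% of scale) measurement noise, and pair order is randomized in
the emitted rows to exercise canonicalization. The descriptors driving the
signal are deliberately *not* any shipped fingerprint, so no fingerprint
is trivially favored in recovery benchmarks.

`gen_class_labels` recovers the planted scaffold of each molecule by
substructure match in a fixed priority order, emulating ten level-1
therapeutic classes that correlate with structure.

Passing tests on these conditions show that the estimators, invariances
and recovery machinery behave as derived; they do not show that any
fingerprint predicts real combination synergy — real screens have
dose–response structure, assay noise and chemistry the generator does not
emulate.

## Numerical conventions and limitations

* Everything trains and evaluates in float64; seeds are explicit
  everywhere, and any derived seed stays below 2^31.
* BCE probabilities are clipped at 1e-7 for numerical safety; clipped
  entries contribute no gradient.
* Tie-breaks: fragment selection by (heavy atoms, lexicographic canonical
  SMILES); min–max scaling maps a constant column to 1.
* The benchmark's PCC aggregation level (pooled predictions per fold,
  fold-level values into the Fisher interval) is a documented choice; other
  aggregations would shift CI widths slightly.
* Problem sizes in the test suite (tens of molecules, hundreds–thousands of
  tuples, 1–5 epochs) are the package's desk-scale defaults; all entry
  points accept larger inputs unchanged.
* Transformer-based and pretrained mutual-information graph fingerprints,
  3D conformer fingerprint generation, and computation of synergy scores
  from dose–response matrices are out of scope; synergy scores are treated
  as input columns.
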