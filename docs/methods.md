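# Methods

## Network diffusion

Each similarity network is a nonnegative weighted adjacency A. Transition
probabilities are per-row normalized, B_ij = A_ij / Σ_j' A_ij'. That
formula is undefined for isolated nodes; the default policy replaces a
zero row with the uniform distribution 1/n, which keeps B row-stochastic
and the walk's fixed point well defined (a `self_loop` alternative pins
the walker to the isolated node instead). The restart walk

    s_i^{t+1} = (1 − p_r)·s_i^t·B + p_r·δ_i

is iterated for all sources simultaneously from S = I until the largest
per-row L1 change falls below 1e-6, capped at 1000 iterations (common
network-propagation practice; the contraction factor is 1 − p_r, so at the
default p_r = 0.05 convergence to 1e-6 takes ≈ 270 iterations).
Non-convergence sets a flag and warns rather than aborting. Rows are walk
sources and columns targets throughout; for symmetric networks the choice
is immaterial, but it is fixed once for asymmetric input.

Multiple networks over a shared node set are integrated by running the
walk per network and concatenating the diffusion matrices column-wise into
an n × (m·n) block matrix, followed by one joint SVD embedding; a node
missing from one network enters it as an isolated node under the zero-row
policy.

## Diffusion component analysis

The softmax model ŝ_ij = exp(x_i·w_j)/Σ_j' exp(x_i·w_j') with its
KL-divergence objective is retained only as a small-instance diagnostic
(`kl_objective`); fitting it directly by quasi-Newton iteration is slow
and is superseded by the factorization route: drop the softmax normalizer,
guard the logarithm with the constant pseudo-count Q = 1/n (rows), form
L = log(S + Q) − log(Q), and take the rank-d truncated SVD,
X = U_d Σ_d^{1/2}, W = V_d Σ_d^{1/2}. For fused multi-network input L is
rectangular; all formulas apply unchanged, and Q stays 1/n with n the row
count. Singular vectors are made deterministic by sorting singular values
descending and forcing the largest-magnitude entry of each left singular
vector positive. Full-scale defaults: 600 embedding dimensions for the
gene network branch, 100 for the disease network branch.

## Denoising autoencoder

Feature tables are min-max scaled per feature to [0, 1] (the scaler is
stored with the model; zero-span features map to 0.5, the sigmoid
midpoint). Inputs are corrupted with additive Gaussian noise of standard
deviation 0.2 (masking corruption is available behind a flag), passed
through sigmoid encoder layers (full-scale gene widths 3000-800-300-100;
homolog blocks 200-100), and decoded by a symmetric, untied mirror of the
encoder. Training minimizes mean squared error between the clean scaled
input and the reconstruction — the Gaussian-corruption-compatible choice —
with minibatch Adam (batch 150, 100 epochs, learning rate 1e-3, Adam's
conventional default, as no value is otherwise dictated). All
randomness (init, shuffling, corruption) flows from one seed, so training
is bitwise reproducible on a platform. With linear activation, no noise
and a single code layer the model reduces to a linear autoencoder whose
optimum is the PCA subspace — used as an independent correctness oracle in
the tests.

## PU inductive matrix completion

The objective (README) treats every unknown cell as an α-weighted
negative. α applies per cell, not normalized by |Ω−| (rescaling α is
equivalent); diseases with no known positives still contribute their cells
to Ω−. Each alternating step solves its regularized weighted least-squares
subproblem exactly: on vec(G) the normal matrix is
α·(XᵀX ⊗ VᵀV) + (1 − α)·Σ_{Ω+} kk ᵀ + (λ/2)I with k = x_i ⊗ v_j, i.e. a
Kronecker background term plus |Ω+| rank-one corrections — O(|Ω+|) work
for the sparse part and an (f·k)² dense solve, comfortable at desk scale.
A numerically singular system gets its ridge floor raised with a warning.
No iterative fallback solver is provided: the package targets feature
dimensionalities where the dense solve is exact and fast, which also
guarantees the monotone objective decrease that the tests assert.
Initialization is i.i.d. Gaussian × 0.01 under the config seed (the first
half-sweep re-solves G, so only H's init matters). Stopping: relative
objective decrease below 1e-5 over a sweep, or 50 sweeps. Ranking ties are
broken by ascending gene index.

## Evaluation conventions

Percentile rank of list position p among N candidates is
100·(p − 1)/(N − 1), which reproduces the defining endpoints 0% (top) and
100% (bottom) exactly. The MPR averages per-disease mean percentile ranks
over diseases with at least one hidden gene (a disease with none has no
defined value). When evaluating hidden pairs, a disease's training
positives are excluded from its candidate list so they cannot occupy top
slots (a flag-free behaviour of `predict_rankings(..., exclude=...)`;
passing an empty exclude set gives the literal all-genes ranking).
False positives at threshold r count min(r, candidates) slots per
evaluated disease, i.e. only diseases carrying hidden positives are
scored. The three-fold split randomly partitions known pairs into
near-equal folds, each hidden exactly once; the new-gene / new-disease
protocols hold out the unique positive of every row / column with exactly
one nonzero.

## Synthetic fixtures

The generator emulates the statistical structure the method assumes, not
biology: planted-partition networks (within-module edge probability 0.25,
between 0.02) stand in for interactomes; rank-k_true factor-model tables
plus Gaussian noise (default sd 0.1, small relative to the unit-scale
latent signal) stand in for expression and homolog-phenotype blocks;
positives are the top-density cells of a random rank-k_true bilinear form
on those tables, with 20% withheld as ground truth and everything else
unlabeled — the PU regime. An optional heavy-tailed per-disease tilt
skews positives toward the few-per-disease sparsity of curated catalogs.
The planted model is the same family the completion step fits — a
deliberately favorable test of the *implementation* (can plantable
structure be recovered?), saying nothing about performance on real
biological data, where features and associations are far less aligned.

The standard instance is 300 genes × 120 diseases, two gene networks and
one disease network, k_true = 10, 5% positive density, 20% hidden.
Pipeline dimensions are desk-scale analogues of the full-scale defaults:
gene side 24 network-embedding + 16 autoencoder dims = 40 features
(full scale: 600 + 200 = 800), disease side 16 + 14 = 30 (full scale:
100 + 100 = 200), completion rank 20 (full scale 200), with λ = 0.02,
α = 0.0035 and restart 0.05 unchanged. Network and autoencoder features
live on very different scales, so the concatenated features are
column-standardized before the fit. The random baseline ranks the same
candidate sets (same exclusions) by uniform random scores.

## Known limitations

- The autoencoder trainer is plain numpy minibatch Adam: correct and
  reproducible, but not suited to the full-scale 3000-unit widths on large
  tables.
- Association values are strictly binary; confidence-weighted positives
  are out of scope, as are negative-sampling variants of the PU loss.
- The synthetic generator does not emulate realistic interactome topology
  (degree heavy tails, clustering) beyond modularity, nor realistic
  expression covariance; passing the recovery experiment demonstrates
  implementation correctness, not expected performance on curated data.
- Evaluation assumes each hidden pair's disease has at least two ranked
  candidates; degenerate candidate sets are rejected rather than imputed.
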