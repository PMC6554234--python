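# Methods

## Problem setting

Anticancer peptides (ACPs) are short (typically < 50 residues), often
cationic peptides, usually derived from antimicrobial peptides (AMPs),
that selectively lyse cancer cells. The benchmarks this toolkit targets
are binary: positives are experimentally validated ACPs, negatives are
AMPs without demonstrated anticancer activity. The discriminating signal
known from composition analyses of such benchmarks is largely
*compositional*: residues C, F, G, H, I, N, S and Y tend to be
over-represented among ACPs, while E, L, M, Q, R and W are
over-represented among non-ACP AMPs.

## Feature representation

**Binary profile feature (BPF).** The first `k` N-terminal residues are
one-hot encoded over the alphabetically ordered 20-letter alphabet and
concatenated position-major (all 20 dimensions of position 1, then
position 2, …). Default `k = 7`, giving 140 dimensions. Peptides shorter
than `k` contribute all-zero blocks for the missing positions: an all-zero
block is the natural one-hot of "absent" and preserves the fixed-length
contract. Terminal residues are emphasised deliberately — they matter
for peptide membrane activity.

**Reduced-alphabet k-mer matrix.** The 20 residues are collapsed into 7
groups defined by dipole moment and side-chain volume
(1: A,G,V; 2: I,L,F,P; 3: Y,M,T,S; 4: H,N,Q,W; 5: R,K; 6: D,E; 7: C).
Scanning the reduced sequence left to right with window `k = 3` produces a
binary matrix of shape `7³ × (L−k+1)`: column `j` holds a single 1 in the
row indexing the 3-mer occupying the window that starts at position
`j+1`. Row indexing is the base-7 positional code
`Σ (g_j − 1)·7^(k−j)` (0-based, most-significant digit first) — the
canonical bijection between group tuples and `0 … 7^k − 1`. Sequences
shorter than `k` are a hard error (an empty matrix has no SVD); no silent
padding.

**SVD compression.** The matrix `M = UΣVᵀ` is reduced to the single
vector `u₁·σ₁` — the best rank-1 summary of `M` that lives in the
343-dimensional k-mer space (`strategy="leading"`). A `"sum"` strategy
(`Σᵢ uᵢσᵢ`) is available as an alternative. Sign indeterminacy of
singular vectors is fixed deterministically: the component of largest
absolute value is made non-negative, ties broken by lowest index. An
all-zero matrix (impossible for valid input, reachable through the public
type) maps to the zero vector with a warning.

*Degeneracy caveat.* For most real peptides every reduced 3-mer occurs
once or twice, so the columns of `M` are (near-)orthogonal and the leading
singular value is degenerate (`σ₁ = σ₂ = …`). The leading singular
vector is then not unique as a mathematical object; the implementation is
still exactly reproducible (a fixed LAPACK driver plus the sign rule),
but only the well-defined quantities — `‖u₁σ₁‖₂ = σ₁` and membership of
the column space of `M` — can be pinned by independent oracles. The test
suite asserts exactly those, plus the closed form for non-degenerate
(rank-1) cases; the golden fixture file pins the remaining freedom as a
regression snapshot.

**Conjoining.** The final representation is `[BPF ‖ k-mer/SVD]`,
483 dimensions, BPF block first. Both blocks are recoverable verbatim by
slicing. Encoding is deterministic and label-free, so the whole dataset
is encoded once and reused across cross-validation folds without leakage.

## LSTM classifier

No deep-learning framework is required: the network is implemented in
NumPy. Architecture: one LSTM layer (default 128 hidden units — the
model's only layer-size parameter), dropout (default 0.25) on the final
hidden state, and a 1-unit dense layer with sigmoid activation. The cell
uses the classical gate equations with `z_t = [h_{t−1}, x_t]`:

    f_t = σ(W_f z_t + b_f),  i_t = σ(W_i z_t + b_i),
    C̃_t = tanh(W_c z_t + b_c),  C_t = f_t∗C_{t−1} + i_t∗C̃_t,
    o_t = σ(W_o z_t + b_o),  h_t = o_t ∗ tanh(C_t).

Loss is standard binary cross-entropy
`−[(1−t)·log(1−p) + t·log(p)]`, optimised by Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with backpropagation through time.

Numerical/initialisation choices: Glorot-uniform gate weights over the
concatenated `[h, x]` input, zero biases except the forget-gate bias
initialised to 1 (keeps memory open early in training), probabilities
clipped to `[1e−12, 1−1e−12]` inside the loss, and an explicit abort with
a diagnostic if the loss ever goes non-finite. Dropout is inverted
(scaling at train time) and disabled at prediction, so repeated predict
calls agree bit-exactly; a persisted model (single `.npz` archive holding
weights, config and the feature-length contract) reloads to bit-identical
predictions.

**Tensor layout.** The conjoined vectors are pre-pooled summaries, not a
residue-level time series, so the default layout feeds each vector as a
single timestep of width 483 (`one_step`, shape `(n, 1, 483)`); the LSTM
then acts as one gated cell step. A `per_feature` layout
(`(n, 483, 1)`, 483 timesteps of width 1) is available for
experimentation but trains far slower and is not the default.

**Defaults not fixed by the architecture** — epochs 100, batch size 32,
learning rate 0.001, classification threshold 0.5 — are the conventional
Adam/Keras-era settings for datasets of a few hundred samples; all are
configurable and recorded in every run's config echo. A single seed
drives weight initialisation, dropout masks and batch shuffling, making
cross-validation tables exactly reproducible.

## Evaluation protocol

Stratified 5-fold cross-validation by default (plain random splitting via
`--no-stratify`); stratification is a deliberate stabilising choice for
small benchmarks even where a protocol says only "randomly divide".
Fold sizes differ by at most one. Per fold the model trains on the other
four folds and is scored on the held-out fold; reported values are the
across-fold mean ± sample standard deviation (n−1 denominator).

Metrics from the confusion counts: accuracy, sensitivity, specificity,
precision and MCC, reported as percentages (two decimals in tables, full
precision in JSON). Any metric with a zero denominator is reported as 0
with a logged warning rather than raising — degenerate folds should not
abort a run. ROC curves sweep all score thresholds (ties grouped) and
AUC is the trapezoidal area, which equals the normalised Mann–Whitney U
statistic in the absence of ties; the test suite checks that identity
against an independent rank-statistic computation.

Baselines (SVM with probability estimates, random forest, Gaussian naive
Bayes) are thin adapters over scikit-learn at library defaults, evaluated
on byte-identical fold assignments; the backing estimator's effective
parameters are recorded verbatim in each report because library defaults
drift across versions.

## Synthetic benchmark generator

The generator emulates the *structure* of real ACP benchmarks: two
roughly balanced classes of short peptides (lengths uniform on 10–50)
with a class-differential residue composition. Residues are drawn i.i.d.
within a class from a distribution built by multiplying a uniform base by
an enrichment factor (default 3.0) on the class's enriched residue set
(positives: C,F,G,H,I,N,S,Y; negatives: E,L,M,Q,R,W — the directions
observed in real benchmarks) and renormalising. Duplicates are redrawn
so datasets satisfy the no-duplicate invariant; everything is determined
by one seed.

What it does **not** emulate: positional motifs, hydrophobic moments,
terminal-residue effects, length–class correlations, or sequence
redundancy structure. A green end-to-end test therefore establishes that
the pipeline can learn a compositional signal through the full
encode → train → cross-validate path — it says nothing about performance
on real ACP data.

## External benchmarks (optional, not a gate)

The published ACP740 (376 positives / 364 negatives) and ACP240
benchmarks are hosted in a public repository and are never downloaded
implicitly. Published reference points for the LSTM under 5-fold CV are
accuracy 81.48 % / AUC 0.894 (ACP740) and accuracy 85.42 % / AUC 0.906
(ACP240). The original fold assignments, seeds, epochs, batch size and
learning rate are unpublished, so those numbers cannot be matched
exactly; agreement within roughly ±5 percentage points is the realistic
expectation when running `scripts/benchmark_experiment.py` on the
downloaded files. The gating test suite relies only on property-based
checks and the synthetic benchmark.

## Dataset handling conventions

Non-standard residues (X, B, Z, U, J, O) are a hard error naming the
record, position and character — both encoders are undefined outside the
20-letter alphabet and silent coercion would corrupt features; a
`--skip-invalid` flag drops such records with a warning instead. Exact
duplicate sequences are removed keeping the first occurrence; a sequence
appearing in both classes keeps the positive copy (the experimentally
validated ACP) with a warning, which enforces class disjointness.
Similarity-based redundancy removal (CD-HIT-style 90 % clustering) is
out of scope: inputs are assumed pre-filtered if that matters.

## Known limitations

- The `"leading"` SVD feature is formally non-unique under singular-value
  degeneracy (see above); features are reproducible per platform/BLAS but
  the exact 343 components are an implementation convention, not a
  mathematical invariant.
- The LSTM at the default `one_step` layout is a single gated cell over a
  pre-pooled vector — recurrence contributes nothing beyond the gating
  nonlinearity; this mirrors the pre-pooled-feature design rather than a
  sequence-modelling claim.
- Single LSTM layer only; no stacked/bidirectional variants, attention,
  or hyperparameter search.
- Baselines use whatever defaults the installed scikit-learn ships;
  historical baseline numbers obtained under other library versions are
  not reproducible and are not asserted.
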