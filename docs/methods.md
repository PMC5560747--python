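# Methods

## Model

KronRLS minimizes Σ_i (f(x_i) − y_i)² + λ‖f‖², where each training point
x_i is a compound–protein pair and the pairwise kernel factorizes as
K = K_D ⊗ K_P. By the representer theorem the solution is dual,
(K + λI)α = y with y = vec(Yᵀ) (column-stacking vec; Y has drugs in rows,
so y is drug-major). Training avoids the N × N system (N = n_D·n_P) via the
factor eigendecompositions: with K_D = U_D Σ_D U_Dᵀ and K_P = U_P Σ_P U_Pᵀ,

    C = (U_Pᵀ Yᵀ U_D) ⊘ (σ_P σ_Dᵀ + λ),   α = vec(U_P C U_Dᵀ),

(⊘ entrywise), O(n_D³ + n_P³ + n_D n_P (n_D + n_P)) instead of O(N³). A
query pair is scored as f = k_P (U_P C U_Dᵀ) k_Dᵀ from its kernel vectors
to the training compounds and proteins. `solve_explicit` materializes the
Kronecker system and is retained purely as the small-scale reference; the
equivalence of the two paths (max-abs ≤ 1e−8 on random instances) is the
package's central regression test.

Assumptions: affinity is a smooth function of compound similarity ×
protein similarity; both kernels are PSD; λ > 0. Eigenvalues in
(−1e−8·λ_max, 0) are clipped to zero before inverting; anything lower is an
error, not a repair.

### Missing values

The eigendecomposition shortcut needs a complete Y, so missing cells are
imputed first by the similarity-weighted row average: for a missing (i, j),
the weighted mean of row i's observed values, weighted by the normalized
Smith-Waterman similarity of each observed protein to protein j. Fallback
chain for degenerate cases: weighted row mean → unweighted row mean →
column mean → global observed mean. The original mask is preserved and
imputed cells are excluded from every performance statistic.

## Kernels

All kernel matrices are cosine-normalized, K'(i,j) =
K(i,j)/√(K(i,i)K(j,j)), giving a unit diagonal; a zero self-similarity row
maps to K'(i,i) = 1 with zero off-diagonals. GIP kernels are already
unit-diagonal by construction and are not renormalized.

* **Tanimoto / linear** — S_D(i,j) = N11/(N_i + N_j − N11) on fingerprint
  bits; two all-zero fingerprints score 1 (identity of indiscernibles),
  empty-vs-non-empty scores 0. The kernel is K_D = S_D S_Dᵀ, PSD by
  construction.
* **GIP** — exp(−‖v_i − v_j‖²/2σ²) on affinity profiles (rows for
  compounds, columns for proteins) after imputation. Candidate widths σ are
  the 0.1/0.5/0.9 empirical quantiles (linear interpolation) of the
  off-diagonal pairwise Euclidean profile distances, recomputed from each
  CV fold's own training profiles; quantiles are over distances, not
  squared distances (a config choice — the convention is not forced by the
  math). A zero quantile (duplicate profiles) falls back to the smallest
  positive distance.
* **Smith-Waterman** — local alignment with BLOSUM50 and affine gaps; a gap
  of length k costs open + (k−1)·extend with defaults open = 10,
  extend = 0.5 (the EMBOSS water defaults for BLOSUM50; the gap scheme is a
  package default, exposed in `AlignmentParams`). Normalized score
  SW(i,j)/√(SW(i,i)SW(j,j)); the square matrix feeds the linear kernel
  (KP-SW), and profiles against a larger reference proteome give the
  rectangular SW+ features (KP-SW+). Alignment scoring is delegated to
  Biopython's `PairwiseAligner`; the test suite carries an independent
  Gotoh dynamic program as oracle.
* **Generic string (GS)** — Σ_{l≤L} Σ_{i,j} exp(−(i−j)²/2σ_p²) ·
  exp(−‖ψˡ(s_{i+1..i+l}) − ψˡ(s'_{j+1..j+l})‖²/2σ_c²), with 0-based start
  offsets i, j and ψ the per-residue descriptor (default: the residue's
  BLOSUM50 row over the 20 standard residues, d = 20; replaceable).
  Computed by a diagonal-cumulation recurrence over the position–position
  distance matrix, O(L·|s|·|s'|) after an O(|s|·|s'|·d) setup, and verified
  against naive substring enumeration. Per-pair values are left raw;
  normalization is applied at the matrix level (the alternative —
  normalizing per pair before assembling — is not distinguishable from any
  stated constraint, so the matrix-level choice is documented here).
* **Precomputed similarity matrices** (3D-structure scores etc.) are
  ingested as-is, self-score normalized when square, then passed through
  the linear kernel. The **identity protein kernel** is the fallback when
  no protein features exist; KronRLS then decouples into an independent
  drug-side ridge regression per protein (asserted in tests).
* Residue policy: the 20 standard letters plus optional `X`; `X` scores by
  its substitution-matrix row when present, otherwise 0 in alignments and a
  zero descriptor vector in the GS kernel.

## Cross-validation and leakage control

Scenarios: bioactivity imputation (leave-one-out over observed entries),
new drug (leave-drug-out), new target (leave-target-out; the same driver on
the other axis). Selection is nested: per outer fold, an inner CV of the
same design scores every grid point by RMSE (the selection criterion is
RMSE, not Pearson), ties break toward larger λ, the winner is refit on the
outer-training data. The default λ grid is 13 log-spaced values from 2⁻¹⁵
to 2¹⁰.

Leakage rules, enforced per fold: the held-out entries are masked before
imputation; GIP kernels are rebuilt per fold with the test pair's partner
axis dropped from the profiles (drug-side GIP drops the test protein's
column, protein-side GIP the test drug's row); under LDO/LTO the held-out
unit's kernel row/column is removed entirely and profile-based kernels on
the left-out axis raise a `ScenarioError` (a new compound has no
bioactivity profile to build one from). Black-box sentinel tests perturb a
held-out value and assert the corresponding fold prediction is bit-for-bit
unchanged. Inner LDO folds are ⌈n_train/5⌉ disjoint random 5-compound
folds, seeded per (seed, outer unit) so results do not depend on outer
iteration order; all CV output is reproducible bit-for-bit under a fixed
seed. The new-pair scenario is provided as fold-plan construction only and
is flagged experimental.

Cost note: faithful nested LOO refits the model for every (outer entry ×
inner entry × kernel combination), reusing one eigendecomposition per
fold across all λ values. That is O(N²) fits, so multi-point grids are
exercised on small instances; the 40 × 30 recovery experiment runs LOO
with a single-point grid (λ = 1.0, σ = median-distance quantile) and LDO
with a 5-point λ grid, which completes in seconds.

## Evaluation

Pearson r and RMSE on measured-vs-predicted pK_i; a ROC-AUC sweep that
binarizes measured affinities at a series of interaction thresholds
(positives are pairs with measured ≥ threshold — the boundary is included;
default 11 thresholds spanning pK 6–8, a 21-value step-0.1 sweep is one
flag away), with tie-averaged rank AUC and single-class thresholds skipped
with a warning rather than scored 0.5. `apply_floor` substitutes an assay
floor (e.g. pIC50 4.9 for a 12,500 nM concentration ceiling) for
undetected interactions before scoring. Off-target validation uses the
exact hypergeometric upper tail P(X ≥ hits), computed by log-space
summation of log-gamma binomials; scipy's survival function is the
independent cross-check in tests.

## Synthetic data

The generator emulates a sparse kinase-profiling map: drug and protein
latent factors drawn around cluster centers (defaults: 4 drug / 3 protein
clusters, latent dimension 3, jitter 0.25 around unit-variance centers),
true affinity pK_i = 7 + 1.5·tanh(⟨u_d, v_p⟩) (keeps values in a realistic
[4, 10]-style range; a modeling choice of this package), observation noise
0.3 pK_i units, 20% missing at random, 40 × 30 by default. Fingerprints are
cluster templates (bit density 0.3, 256 bits) with 20% per-bit flips;
sequences are cluster ancestors (length 120) with 8% point mutations. The
flip and jitter rates are calibrated so that structural similarity is
genuinely informative but coarser than bioactivity profiles — the regime
the method targets, where profile kernels dominate in-matrix imputation
while structural kernels carry the new-compound scenario.

What passing the recovery experiment shows — and does not. The generator
matches the method's assumptions by construction (low-rank smooth affinity
surface, side information correlated with it), so recovery there is a
correctness check of the pipeline, not evidence about real chemistry: real
fingerprint–activity relationships are far less regular (activity cliffs),
real missingness is not uniform at random, and assay noise is not
homoscedastic Gaussian. The expected qualitative ordering — imputation-
scenario accuracy above new-drug-scenario accuracy — does reproduce here
and matches what one sees on real kinase maps.

## Known limitations

* Nested LOO with multi-point grids is quadratic in the number of observed
  entries; no hat-matrix shortcut is used because per-fold kernel
  recomputation invalidates it.
* The SW+ reference proteome is user-supplied; tests use a small synthetic
  reference set, not a real proteome.
* Fingerprints are consumed as tables; no structure parsing or fingerprint
  generation.
* Multiple kernel learning and sparse/iterative Kronecker solvers are out
  of scope.
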