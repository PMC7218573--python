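# Methods

## The variance-component model

Each omics layer enters a separate single-random-effect linear mixed
model for the per-animal phenotype y (milk protein yield, kg/day):

    y = X β + u + e,   u ~ N(0, A σ²ₐ),   e ~ N(0, I σ²ₑ)

with fixed effects X = [intercept, parity class contrasts, days-in-milk]
and A = Z Z'/q the relationship matrix of the layer's n×q
column-standardized (zero mean, unit sample sd, n−1 denominator) feature
matrix. Omics-explainability is σ²ₐ/σ²ₚ with σ²ₚ = σ²ₐ + σ²ₑ.

Choices worth stating explicitly:

* **Scaling of A.** Division by the feature count q is adopted (the
  genomic-relationship convention), making trace(A) = n − 1 and σ²ₐ
  directly interpretable on the phenotypic-variance scale. This is the
  single most consequential choice the model description leaves open; it
  is surfaced in the API rather than hidden.
* **σ²ₚ definition.** Model-based (σ²ₐ + σ²ₑ), not the sample variance of
  y; `denominator="sample"` switches to the sample-variance denominator.
* **Days in milk** enters as a continuous linear covariate by default; a
  16-animal design cannot afford a class effect per distinct DIM value.
  `dim_as_class=True` restores the class coding.
* **REML, not ML**, for both estimation and the likelihood-ratio test.
  The LRT of σ²ₐ = 0 uses the boundary mixture ½χ²₀ + ½χ²₁ (a variance is
  tested on the edge of its parameter space); p = 1 exactly when the LRT
  statistic is 0.
* Separate per-layer models; the explainability percentages of different
  layers are not constrained to sum to 100 and no overlap adjustment is
  applied.

### Fitting

A is eigendecomposed once (A = U Λ U'); rotating y and X by U' makes the
covariance diagonal, σ²·diag(h²λᵢ + 1 − h²) with h² = σ²ₐ/σ². β and σ²
are profiled in closed form, leaving a 1-D bounded search for h² on
[10⁻⁶, 1 − 10⁻⁶] (Brent, xatol 10⁻⁸, restarted on three subintervals;
ties resolve toward the smaller h², and h² = 0 — the null — is always a
candidate, so the full fit can never score below the null). The phenotype
is internally rescaled to unit sample sd, which makes the estimates
exactly scale-equivariant: multiplying y by c multiplies both variance
components by c² and leaves the explainability bit-identical.

Degenerate inputs: collinear fixed-effect columns (e.g. a single parity
level) are dropped with a warning; a relationship matrix with a
numerically flat eigenvalue spectrum (e.g. proportional to I) makes the
σ²ₐ/σ²ₑ split unidentifiable — the fit then reports the h² = 0 boundary
with `identifiable=False` instead of an arbitrary interior optimum.

## Association procedures

* **Spearman** correlations use mid-ranks and the two-sided t
  approximation on n − 2 df at every n (the emulated study has n = 16);
  perfectly monotone pairs report the smallest positive double and a
  warning. The matrix form (rank, standardize, cross-product) is used for
  metabotype screens and networks and agrees with the scalar routine to
  10⁻¹².
* **Metabotypes** are metabolites with raw Spearman p < 0.05 against MPY
  (the screening stage is deliberately uncorrected; the FDR correction
  applies to the *next* stage). Sign classes follow the correlation sign.
* **PERMANOVA** regresses Gower-centered Bray-Curtis distances on
  [1, metabotype]: pseudo-F = [tr(HGH)/1] / [tr((I−H)G(I−H))/(n−2)].
  Because G is doubly centered this reduces to a quadratic form in the
  centered covariate (an equivalence asserted by a test against the
  hat-matrix formula). p-values use the add-one permutation estimator,
  permuting covariate entries, 999 permutations by default; a covariate
  explaining *all* dispersion yields pseudo-F = ∞, which the permutation
  test handles naturally. BH FDR across the screened metabotypes at
  q < 0.05 defines microbiome responsiveness.
* **Networks** keep cross-layer edges with |ρ| > 0.5 and p < 0.05,
  emitted in deterministic (source, target) order.

## Differential features

* **Wilcoxon rank-sum**: exact enumeration when both groups have ≤ 10
  observations and no ties, else the normal approximation with tie and
  continuity corrections; feature-wise BH FDR.
* **LEfSe-style score**: stage 1 screens per feature (two groups, so the
  Kruskal-Wallis stage is the rank-sum test); stage 2 fits one
  regularized two-class Fisher discriminant (ridge 10⁻⁶·trace(S_w),
  unit-norm direction w) to the surviving features on the per-million
  scale and scores feature f as log₁₀(1 + |(w_f·Δ_f + Δ_f)/2|), with Δ_f
  the HH−LL mean difference per million. This is a deliberately
  simplified, documented variant — no bootstrap rounds and no
  subclass/one-against-all logic, since the design has exactly two
  classes — so scores are comparable in spirit, not bit-identical, to the
  published LEfSe tool. The threshold 2 is only meaningful on the
  per-million scale, which the implementation enforces.
* **Metabolites**: Welch t-test (the groups have no reason to share a
  variance) + BH FDR, combined with PLS-DA VIP > 1. VIP comes from a
  two-component PLS regression on the ±1 group code
  (VIP_f = √(q Σ_c SS_c w̃²_fc / Σ_c SS_c)); Σ_f VIP² = q holds
  identically and is asserted on every fit. The significance gate follows
  the FDR-adjusted p; `use_fdr=False` restores the raw-p variant.

## Feature retention

Taxa: relative abundance strictly > 0.1% in ≥ 50% of animals of *every*
group. Functions: cpm strictly > 5 in ≥ 50% per group. "At least 50%" is
implemented as fraction ≥ 0.5. Metabolite peaks: present (non-missing) in
≥ 50% of samples, RSD = sd/mean·100 ≤ 30% (sample sd; over QC samples if
given, else all non-missing), spectral similarity ≥ 200, identified.
Missing intensities mean "peak absent"; they are imputed to the column
mean only at z-scoring (becoming 0), after the presence filter has run.
Filtered relative/cpm tables are re-closed so the row-sum invariant
holds; re-closure only increases values, so the filter is idempotent.
Zero-variance columns are dropped with a warning at z-scoring — they
carry no between-animal signal and would make the standardization
undefined.

## The synthetic cohort

The generator emulates the statistical shape of the emulated study, not
its biology:

* **Taxa**: i.i.d. log-normal abundances (log-sd 1.0) closed to relative
  form; a 15-feature dominant block whose log-mean is solved so the
  block's expected share hits a target (default 0.42, the
  Prevotella-like dominance level). No phylogenetic correlation.
* **Functions**: log-normal counts (log-sd 0.8) rescaled to cpm, 500
  features by default. No pathway topology.
* **Metabolomes**: log-normal intensities with biological log-sd 0.25
  (CV ≈ 25%, so most peaks clear the 30% RSD rule, with a realistic
  failing tail), 8% missing cells, and a 5% "junk" fraction of
  low-similarity or unidentified peaks that the quality filter should
  remove. 263 rumen and 177 serum features by default.
* **Phenotype**: mpy = μ + parity effect + slope·DIM + Σ u_layer + e with
  u_layer = Z w, w ~ N(0, σ²_layer/q) per feature — so u_layer has
  exactly the relationship-matrix covariance the model assumes. The
  planted fractions of a fixed total variance (default 1 kg²/day²; mean
  μ = 5 kg/day, shifted up if any mpy ≤ 0) sum with the residual share to
  1 by construction. Milk yield and protein content are derived
  consistently (mpy = yield × content). HH/LL labels are assigned by
  ranking realized MPY (top n_hh animals), mirroring extreme-group
  selection — group labels are consequences, not causes.
* **Planted structure**: group log-fold effects multiply HH animals'
  values (with compositional re-closure); planted metabotypes overwrite
  metabolite columns with exp-transformed Gaussian blends against MPY
  (coupling 0.85, so Spearman |ρ| ≈ 0.8); a linked-cohort generator
  drives taxa, metabolites and MPY from one latent factor for testing the
  composed screen.

Because the generator matches the model's covariance assumptions exactly,
passing recovery tests demonstrate correctness of the estimator and the
composed procedures — they do not demonstrate robustness to the ways real
rumen data violate those assumptions (phylogenetic and co-abundance
correlation, compositional dependence between features, non-log-normal
tails, batch structure).

## Simulation experiment sizes

The validation experiments use sizes chosen for statistical resolution at
interactive runtimes: grid-search cross-checks at n ≤ 12 against a
2,000-point likelihood grid; fraction recovery at n = 300, q = 100
(25 replicates, planted 0.5, tolerance ±0.05 on the mean); LRT size with
1,000 null replicates at n = 60, q = 80; layer-ordering recovery at
n = 800, q = 200 with planted fractions 0.05/0.15/0.25/0.35 — a power
calculation from pilot estimator sds (≈ 0.03, floored by the
√(2/q) sampling noise of the per-layer weight draw) gives ≈ 95% expected
full-ordering recovery at gaps of 0.10; PERMANOVA size with 1,000 null
replicates at 199 permutations. The 16-animal demonstration cohort is the
study-scale condition throughout the drivers and the acceptance script.

## Determinism

Every stochastic routine takes an explicit seed. The pipeline expands one
global seed into per-stage (and per-metabotype) seeds by fixed affine
offsets, so adding a stage or a metabolite never perturbs the randomness
of earlier ones. Two runs with the same configuration produce
byte-identical numeric outputs; the manifest records the seed, every
threshold applied, and a hash of the full configuration.

## Known limitations

* Single random effect only: no joint multi-layer model, no overlap
  adjustment between layers (separately fitted percentages may sum past
  100), no standard errors on explainability (a parametric bootstrap
  would be the natural extension).
* PERMANOVA supports a single continuous covariate, matching the
  screen-then-test design; no additional covariate adjustment.
* The LEfSe-style score is not the published tool; effect sizes agree in
  spirit and threshold semantics, not numerically.
* PCoA clamps negative eigenvalues to zero and excludes them from the
  proportion-explained denominator; no Lingoes/Cailliez correction.
* The generator's independence assumptions are stated above; conclusions
  about real-data behaviour require real data.
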