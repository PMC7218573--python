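# omixplain

How much of a host phenotype does each omics layer explain? `omixplain`
implements the variance-component analysis behind *omics-explainability*
(the multi-omics generalization of "microbiability") together with the
association and differential-abundance procedures that typically surround
it in rumen microbiome studies of dairy cattle.

The motivating setting: mid-lactation cows raised under identical feeding
and management still differ strongly in milk protein yield
(MPY = milk yield × milk protein content, kg/day). Four omics layers are
measured on the same animals — rumen microbial species (compositional
relative abundances), rumen microbial KEGG functions (counts per million),
rumen metabolite intensities, and serum metabolite intensities — and the
question is how much MPY variance each layer carries, and through which
metabolites and taxa.

## The model

For one omics layer with n×q column-standardized feature matrix **Z**, the
layer's relationship matrix is

    A = Z Z' / q        (trace(A) = n − 1)

— the same construction as a genomic relationship matrix, applied to
microbial taxa (**M**), functions (**K**), rumen metabolites (**R**) or
serum metabolites (**S**). The phenotype model is the linear mixed model

    y = μ + parity_j + β·DIM + u + e,
    u ~ N(0, A σ²ₐ),   e ~ N(0, I σ²ₑ)

fitted by REML via a single eigendecomposition of A (rotate y and the
fixed-effect design, profile β and the total variance in closed form, then
a bounded 1-D search over h² = σ²ₐ/(σ²ₐ+σ²ₑ)). The layer's
**omics-explainability** is σ²ₐ/(σ²ₐ+σ²ₑ); its significance is a
likelihood-ratio test of σ²ₐ = 0 against the boundary-corrected
½χ²₀ + ½χ²₁ null. Each layer is fitted in a separate model.

Around the core model the package provides:

* the feature-retention rules of the field (taxa > 0.1% relative abundance
  in ≥ 50% of animals per group; functions > 5 cpm in ≥ 50%; metabolite
  peaks present in ≥ 50% of samples, RSD ≤ 30%, spectral similarity ≥ 200,
  identified);
* Bray-Curtis dissimilarities and PCoA;
* **metabotype screening**: Spearman correlation of each metabolite with
  MPY (raw p < 0.05, signed), then PERMANOVA of each metabotype as a
  continuous covariate on the microbial Bray-Curtis distances with BH FDR
  — metabotypes passing FDR < 0.05 are *microbiome-responsive*;
* differential features: Wilcoxon rank-sum + BH FDR, a documented
  LEfSe-style LDA effect-size score (significant at p < 0.05 and
  LDA score > 2), and Welch t-test + BH FDR combined with PLS-DA VIP > 1
  for metabolites;
* thresholded Spearman correlation networks (|R| > 0.5, p < 0.05);
* a synthetic multi-omics cohort generator with planted ground truth
  (variance fractions, differential features, metabotypes) so every
  procedure can be validated by parameter recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
16-animal cohort (7 high-MPY "HH" vs 9 low-MPY "LL" animals, taxa table
dominated by a Prevotella-like block, 263 rumen and 177 serum metabolite
peaks):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/02_explainability.py      # per-layer variance components
python analysis/03_metabotypes.py         # MPY-associated metabotypes + PERMANOVA
python analysis/04_differential_features.py
python analysis/05_networks.py
```

With the default seed the first two print:

```
  animals: 16 (7 HH / 9 LL)
  MPY (kg/day): mean 4.93, sd 1.01
  dominant genus block share: 45.1%

                  explainability_pct  sigma2_a  sigma2_e  lrt_stat   p_value
taxa                             0.0  0.000000  1.298312  0.000000  1.000000
function                       100.0  1.247393  0.000001  0.599027  0.219475
rumen_metabolome                 0.0  0.000000  1.298312  0.000000  1.000000
serum_metabolome                 0.0  0.000000  1.298312  0.000000  1.000000
```

The boundary estimates (0% / 100%) are the honest behaviour of REML at
n = 16: a cohort this small localizes the variance split very poorly, and
none of the LRTs approaches significance. The estimator itself is sound —
the test suite shows that at n = 300 a planted explainability of 0.5 is
recovered to within ±0.05 on average, and that planted layer *orderings*
are recovered in > 90% of simulated cohorts at n = 800.

Downstream, the same run screens metabotypes and differential features
(`rumen_metabolome: 2 MPY-positive + 4 MPY-negative metabotypes`,
`function LEfSe-style: 27 significant (13 HH-enriched, 14 LL-enriched)`, …)
and exports the taxa-metabolite correlation networks as edge-list TSVs.

The one-shot equivalent is `run_pipeline`:

```python
from omixplain import RunConfig, run_pipeline
out = run_pipeline(RunConfig.from_yaml("run.yaml"))
```

which executes filter → z-score → relationship matrices / Bray-Curtis /
PCoA → explainability → metabotypes → differential features → networks,
writes every table plus a `manifest.json` recording the seed, every
threshold applied and a configuration hash, and is byte-for-byte
reproducible for a fixed config.

## Layout

```
src/omixplain/     the library: tables, io, preprocess, simulate,
                   similarity, varcomp, association, differential, pipeline
analysis/          numbered drivers reproducing the study flow
tests/             pytest suite incl. property-based acceptance checks
docs/methods.md    modelling and design notes
scripts/acceptance.py
```
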