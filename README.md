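# gravesomics

Blood-biomarker discovery for Graves' disease (GD) and Graves' orbitopathy
(GO) from two circulating omics blocks: small-RNA sequencing counts
(miRNA) and label-free mass-spectrometry protein abundances. The package
is aimed at bioinformaticians reproducing or extending this kind of
three-class (healthy control / GD / GO), multi-centre case-control design,
where the question is which circulating molecules separate the groups
robustly enough to be diagnostic or prognostic candidates.

It is organised as an analysis project: every computation lives in the
library under `src/gravesomics/`, and the numbered scripts under
`analysis/` drive the pipeline stage by stage. Because the original
patient-level data are not public, a first-class synthetic-data module
generates datasets with the study's design (13/14/19 subjects across
three centres, ~3000 miRNAs, ~1900 proteins) and a recorded ground truth
of planted differential features, so every downstream claim is testable.

## The methods

**Normalisation and filtering.** miRNA counts are scaled within each
sample to counts-per-million, `CPM_i = X_i / N * 1e6`; only miRNAs with
CPM ≥ 2 in more than two samples are kept. Protein abundances are
natural-log transformed with an explicit zero branch (`f(0) = 0`,
non-detection), filtered to proteins detected in more than two samples,
and median-centred per sample to remove mass-spec loading.

**Differential expression.** Each miRNA is modelled by a negative-binomial
GLM with log link,

    log mu = intercept + status + centre + log(library size),

count variance `mu (1 + phi mu)` with feature-specific dispersion `phi`
estimated by Cox–Reid adjusted profile likelihood. Significance of the
status term is a likelihood-ratio test against the reduced model (df = 2).
Each protein enters a multinomial logistic model of class membership on
centre and the protein value; dropping the protein term gives the LRT.
False discovery is controlled with Storey q-values (Benjamini–Hochberg
available); the discovery threshold is q < 0.05.

**Classification and stability selection.** An L1-penalised multinomial
logistic model (glmnet-style symmetric parameterisation, unpenalised
centre covariates) is fit by partial-Newton coordinate descent:

    (1/N) * NLL(theta) + lambda * sum_j ||theta_j||_1.

The protocol splits off a 1/10 test set, tunes `lambda` by 10-fold
cross-validated multinomial deviance on the remaining 9/10, refits, and
records test accuracy and which features carry nonzero coefficients;
repeated R = 150 times, this yields per-feature selection frequencies.
Three models are run: miRNA only, proteins only, and both blocks combined.

**Biomarker combining.** Five candidate sets — mirDE and protDE (q < 0.05)
plus the top-20 predictors of each model (mirPRD, protPRD, mirprotPRD) —
are merged by

    (mirDE ∩ mirPRD) ∪ (protDE ∩ protPRD) ∪ (mirprotPRD ∩ (mirDE ∪ protDE)).

**Enrichment and power.** Pathways are scored by the upper-tail
hypergeometric probability of the observed overlap between the biomarker
gene list and each gene set. The per-group sample size needed to detect a
fold-change Δ at coverage μ and between-group CV σ is

    n = 2 (z_{1-α/2} + z_β)^2 (1/μ + σ^2) / (ln Δ)^2.

## Worked example

```sh
python analysis/01_simulate.py --seed 1 --n-mirna 600 --n-protein 300
python analysis/02_preprocess.py
python analysis/04_diffexpr.py
python analysis/05_classify.py --reps 40 --seed 7
python analysis/06_combine.py
python analysis/07_enrich_power.py
```

prints, stage by stage:

```
wrote results/sim: 46 samples, 600 miRNAs (library CV 0.281), 300 proteins (loading CV 0.312)
miRNA: kept 440/600 (CPM >= 2 in more than 2 samples); proteins: kept 236/300 (detected (x > 0) in more than 2 samples)
miRNA: 45 of 440 at q<0.05; proteins: 22 of 236
recovery: miRNA 40/48 planted (5 false), protein 16/23 (6 false)
mirna: accuracy 0.95 (sd 0.09) over 40 replicates
protein: accuracy 0.84 (sd 0.15) over 40 replicates
combined: accuracy 0.95 (sd 0.08) over 40 replicates
53 set members across the three terms, 33 unique biomarkers -> results/biomarkers/biomarkers.tsv
top pathway: PW0000 (synthetic target pathway), overlap 12/42, p = 8.81e-09
per-group n for power 0.7/0.8/0.9 at alpha=0.05, mu=10, sigma=0.23, fold-change 2: 4/5/7
```

Reading the numbers: the expression filters keep 440 miRNAs and 236
proteins; the likelihood-ratio tests flag 45 miRNAs and 22 proteins at
q < 0.05, recovering 40 of the 48 detectable planted miRNAs; the
combined-block classifier reaches 95% test accuracy over the resampling
replicates; and the set combiner distils 33 unique biomarker candidates,
each listed with its q-value, selection frequency, provenance and
per-contrast log2 fold-changes. The final line is the closed-form power
calculation: 4–7 subjects per group suffice for a 2-fold change at these
noise levels.

`analysis/03_ordination.py` additionally writes PCoA coordinates and
variance-explained fractions for the miRNA, protein, and combined
distance matrices.

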