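# ssgblup — single-step multi-breed genomic evaluation

`ssgblup` implements a complete single-step GBLUP (ssGBLUP) evaluation
pipeline for a two-breed dairy population of the Alpine/Saanen goat
type, together with the statistical machinery needed to study whether
the two breeds should be evaluated jointly, separately, or as
correlated traits. It is aimed at quantitative geneticists who want a
transparent, fully tested desk-scale implementation of the method
stack used in routine dairy genomic evaluation: relationship matrices,
Henderson's mixed-model equations, AI-REML, and daughter-yield-deviation
cross-validation — exercised end to end on simulated populations with
a known truth.

## The model

All evaluations solve the animal model

    y = Xβ + Zu + Wp + e

where `y` are lactation records weighted by their lactation weights
(`Var(e_i) = σ²_e / w_i`), `β` are fixed effects (herd, parity, breed),
`p ~ N(0, I σ²_p)` are permanent-environment effects of repeated
records, and `u` are breeding values with

    Var(u) = H σ²_u

`H` is the single-step relationship matrix combining the pedigree
numerator relationships `A` with the genomic relationship matrix of
genotyped animals

    G = M M' / (2 Σ_j q_j (1 − q_j)),

scaled for compatibility with `A₂₂` (mean-matching of diagonals and
off-diagonals), blended as `G_b = τ G* + (1 − τ) A₂₂`, and inverted via

    H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A₂₂⁻¹].

Three model variants are supported:

- **multi-breed** — both breeds pooled with one set of genetic
  parameters and pooled allele frequencies;
- **within-breed** — each breed evaluated separately with its own
  parameters and its own allele frequencies;
- **multiple-trait** — the trait in breed A treated as distinct from,
  but genetically correlated with, the same trait in breed S:
  `Var(u) = T ⊗ H` with `T = [[σ²_ua, σ_u_sa], [σ_u_sa, σ²_us]]` and
  across-breed genetic correlation ρ (run at ρ = 0, an estimate, or
  0.99).

Breed-specific genetic parameters and ρ are estimated by AI-REML (with
an EM fallback) on single-record data; prediction quality is assessed
by Pearson correlations between GEBV from truncated data and
daughter yield deviations (DYD) from the full data, regression slopes
of DYD on GEBV (slope < 1 ⇒ over-dispersed GEBV), and PEV-derived
model accuracies of young candidates against the parent-average
baseline `√(¼ rel_sire + ¼ rel_dam)`.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated two-breed population (milk-yield-like parameters: genetic
variances 9962/7278 kg², h² 0.31/0.26, repeatability 0.50, ρ = 0.45):

```bash
python analysis/01_simulate_population.py
python analysis/02_quality_control.py
python analysis/03_relationship_matrices.py
python analysis/04_genetic_parameters.py
python analysis/05_model_comparison.py
python analysis/06_candidate_accuracy.py
```

which prints, among other things:

```
population: 2616 animals, 5832 lactation records, 252 genotyped (144 candidates without progeny)
realized h2: alpine 0.337 (target 0.31), saanen 0.231 (target 0.26)

1901 SNPs validated out of 2000 (MAF > 1% and call rate > 98% in every breed)

validation of GEBV against full-data DYD (r: predictive ability; slope < 1: over-dispersed GEBV):
         model   rho  n_validation_males  pearson_r  slope  slope_se
   multi_breed   NaN                  36      0.669  1.158     0.221
  within_breed   NaN                  36      0.682  1.284     0.236
multiple_trait 0.000                  36      0.672  1.285     0.243
multiple_trait 0.450                  36      0.666  1.265     0.243
multiple_trait 0.990                  36      0.655  1.231     0.244

single-step r = 0.669 vs two-step r = 0.654 on 36 validation sires
```

`04_genetic_parameters.py` prints the AI-REML parameter table for a
first-lactation design with genotyped females (truth in the last
column):

```
               parameter   estimate        se     truth
 genetic_variance_alpine 11231.2215 1445.3014 9962.0000
     heritability_alpine     0.3343    0.0372    0.3100
 genetic_variance_saanen  9123.8666 1184.4643 7278.0000
     heritability_saanen     0.3261    0.0367    0.2600
     genetic_correlation     0.5338    0.1815    0.4500
```

and `06_candidate_accuracy.py` prints a candidate-accuracy table in which every single-step model beats
the parent-average baseline (e.g. multi-breed 0.596 vs 0.558). The
interpretation mirrors routine practice: the three models predict
almost equally well, the single-step evaluation beats the two-step
GBLUP on DYD, and candidate accuracies exceed the pedigree-only
parent average.

A `ssgblup` command-line tool exposes the same stages
(`simulate`, `qc`, `relmat`, `reml`, `evaluate`, `validate`); try
`ssgblup --help`.

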