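# Methods

This note documents the models, the simulator, the numerical choices
and the limitations of `ssgblup`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Evaluation models

All three variants are animal models solved through Henderson's
mixed-model equations (MME),

    [X'R⁻¹X   X'R⁻¹Z          X'R⁻¹W        ] [β]   [X'R⁻¹y]
    [Z'R⁻¹X   Z'R⁻¹Z + G_u⁻¹  Z'R⁻¹W        ] [u] = [Z'R⁻¹y]
    [W'R⁻¹X   W'R⁻¹Z          W'R⁻¹W + P⁻¹  ] [p]   [W'R⁻¹y]

with `R⁻¹ = diag(w_i / σ²_e(breed_i))` (lactation weights `w_i`),
`P⁻¹ = diag(1/σ²_p(breed))` for animals with records, and the genetic
prior depending on the variant:

- multi-breed and within-breed: `G_u⁻¹ = H⁻¹ / σ²_u`;
- multiple-trait: `G_u⁻¹ = T⁻¹ ⊗ H⁻¹` with trait-major equation
  ordering (trait block first, animal within block). Records of a
  breed load only that breed's trait equations; residual and PE
  blocks are breed-diagonal.

Every pedigree animal carries genetic equations whether phenotyped,
genotyped, both or neither; that is the point of the single-step
formulation. Fixed factors are coded as cell means with one reference
level per factor beyond the first (empty levels never enter). The
multiple-trait variant carries separate fixed-effect blocks per
breed.

`|ρ| = 1` makes `T` singular, so a requested correlation is capped at
0.99 — which is also the level at which the multiple-trait model is
expected to approach the multi-breed model (verified as an acceptance
property).

Solvers: dense Cholesky for systems up to ~20k equations; diagonally
preconditioned conjugate gradients (zero start vector, relative
residual < 1e-10 by default) beyond that. Both are deterministic.

PEV are the diagonal entries of the genetic block of the inverted
coefficient matrix; reliability is `1 − PEV_i / (h_ii σ²_u)` clipped
to [0, 1] with `h_ii` the animal's own relationship diagonal
(`diag(G_b)` for genotyped animals, `1 + F` otherwise; a `plain`
mode without `h_ii` is also exposed since the field uses both
conventions), and accuracy is its square root.

## Relationship machinery

- `A` by the tabular method (oracle scale); `F` by exact recursive
  kinship with memoization; `A⁻¹` by Henderson's rules with
  inbreeding, Mendelian-sampling variances `0.5 − 0.25(F_s + F_d)`
  (adjusted for unknown parents). Unknown parents are unrelated,
  non-inbred base animals.
- `A₂₂` by the indirect (triangular-solve) method, exact with
  inbreeding, never forming the full `A`.
- `G` from dosages column-centered by `2q_j`; missing calls are
  filled with `2q_j` so they contribute exactly zero after centering
  (sporadic 0.1% missingness is absorbed, not imputed). Pooled
  frequencies serve the multi-breed and multiple-trait models;
  breed-specific frequencies serve the within-breed model (same
  QC-validated SNP set).
- QC keeps a SNP only if it passes MAF > 1% **and** call rate > 98%
  in **every** breed (strict inequalities, intersection rule).
  Animals are never dropped.
- Compatibility scaling `G* = a + bG` solves the 2×2 system matching
  the means of the diagonal and off-diagonal to those of `A₂₂`
  (two-coefficient mean-matching). An `offset` mode (additive
  constant only, `b = 1`) is provided as the single-constant
  alternative.
- Blending `G_b = τG* + (1 − τ)A₂₂`, default `τ = 0.95`, guarantees
  an invertible genotyped block.
- `H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A₂₂⁻¹]` is kept in structured form
  (sparse `A⁻¹` plus one dense block); an explicit dense `H` with the
  full block formula exists for oracle-scale checks, and the two are
  tested to be mutual inverses.

## REML

Breed genetic variances, the across-breed covariance and per-breed
residual variances are estimated on single-record (first-lactation)
data without the PE term, under `Var(u) = T ⊗ H`.

Algorithms: average-information REML with one EM warm-up step,
step-halving on the AI direction, and an EM fallback when the AI step
fails; or pure EM. The restricted likelihood is evaluated through the
MME identity `−2ℓ = log|C| + log|R| + N log|T| + b log|H| + y'Py`
(`log|H| = Σ log d_i + log|G_b| − log|A₂₂|` comes free from the
structure). EM never decreases ℓ (asserted in tests); AI steps are
only accepted when ℓ does not decrease. Proposals with a
non-positive-definite `T` are rejected by shortening the step rather
than projected, because eigenvalue-clipped near-singular `T` produces
numerically meaningless likelihoods; PSD projection (eigenvalue floor
1e-8) is applied to EM updates and final estimates, which keeps the
reported ρ inside [−1, 1]. Convergence: maximum relative parameter
change below `tol` (default 1e-8; the studies use 1e-4–1e-5, far
below the statistical precision of any parameter). Standard errors
come from the inverse AI matrix at the optimum, with first-order
delta-method SEs for h² and ρ.

The computational core absorbs the equations of every terminal
animal — childless and non-genotyped — analytically: such an animal's
coefficient block couples only to its own parents and its record's
fixed effects, so the absorbed block is block-diagonal with one small
trait-block per animal. What remains is a dense parent-plus-genotyped
system (a few thousand equations for the study sizes here) whose
inverse yields *exactly* the `C⁻¹` traces the AI/EM updates need:
`tr(C^{uu}_{mn} H⁻¹)` is assembled from the kept-by-kept block, the
absorbed diagonal blocks, and the absorbed-by-parent cross terms of
the `H⁻¹` pattern. The absorption path is verified against a dense
no-absorption path to machine precision, and the whole engine against
direct Nelder-Mead maximization of the dense V-based restricted
likelihood.

Identifiability note: with genotyped sires only, the across-breed
correlation is almost unidentified at desk scale, because ρ enters
only through cross-breed relationship entries and the breeds share no
pedigree. The REML study designs therefore include genotyped recorded
females, whose cross-breed genomic relationships carry the
information; this mirrors how genotyped females enter such analyses
in practice.

## Validation layer

- Yield deviations: per record `y − x'β̂ − p̂`, averaged per female
  with her record weights. Genetic effects are *not* removed.
- DYD: `2 · Σ_d w_d (YD_d − 0.5 û_dam) / Σ_d w_d` over a sire's
  phenotyped daughters — the factor 2 and the dam adjustment put DYD
  on the sire breeding-value scale, so the expected regression of DYD
  on an unbiased (G)EBV is 1 (verified by a 200-sire × 100-daughter
  harness). Effective daughter contribution = summed record weights.
- Truncation design: males split by birth year into training and
  validation; validation GEBV come from a re-run on records of
  females born before the cutoff (default: last training year + 3,
  when the youngest training sires' daughters first lactate), DYD
  from the full-data run. Pearson r measures predictive ability;
  the OLS slope of DYD on GEBV measures dispersion (slope < 1 ⇒
  over-dispersed GEBV); slope SEs are classical OLS. Within-breed
  GEBV are centered on the overall mean before pooling breeds
  (per-breed centering is available for breed-wise tables); r and
  slope are invariant to this.
- Two-step comparator: GBLUP on training-sire DYD,
  `dyd = 1μ + u + ε`, `Var(u) = G_b σ²_u`,
  `Var(ε_s) = σ²_ε / edc_s` with
  `σ²_ε = 4(0.75 σ²_u + σ²_p + σ²_e)` by default (daughter-deviation
  variance on the sire scale, dam-error folded into the `0.75 σ²_u`);
  exposed as a parameter.
- Candidate accuracy: mean PEV-derived accuracy over the young
  genotyped males without progeny, paired with the parent-average
  accuracy `√(¼ rel_sire + ¼ rel_dam)` computed from the same run's
  parental reliabilities (unknown parent ⇒ reliability 0).

## Simulator

`simdata` generates the statistical structure the models assume:

- Ancestral allele frequencies uniform on (0.1, 0.9); breed
  frequencies drift apart under the Balding–Nichols model at a chosen
  Fst (default 0.10 for the two related breeds); founder genotypes
  Hardy–Weinberg at breed frequencies; descendants by gene dropping
  at unlinked SNPs.
- Per-SNP effects for the two breed-traits are drawn bivariate normal
  with correlation ρ (default 0.45, the milk-yield end of the
  0.45–0.76 range the multiple-trait analyses produce), then each
  breed's effect vector is rescaled so that the variance of true BVs
  **among that breed's founders** equals the target genetic variance.
  The founder scale matters: σ²_u in the models is a base-population
  variance, and scaling to the whole-population variance instead
  would inflate the effective genetic variance by the mean
  relationship among descendants and mis-calibrate every BLUP
  property by 10–20%.
- Pedigree: sire-centric overlapping generations; each generation a
  fixed number of sires is drawn from the previous generation's
  males and mated to random dams; males are never phenotyped;
  final-generation males are the genotyped selection candidates.
  Genotyped set: all sires, candidates, and optionally a chosen
  number of recorded females.
- Phenotypes: `y = μ_breed + herd + parity + u + p + e` with herd
  effects N(0, herd_sd²), one PE value per female shared by her
  records, and `Var(e) = σ²_e / w`. σ²_p and σ²_e derive from the
  (σ²_u, h², repeatability) triplet exactly as official parameter
  tables are decomposed. First lactations are complete (weight 1.0);
  later records are short (weight 0.5) with probability 0.2 — the
  official weight tables are not public, so these two levels stand in
  for them.
- 0.1% of genotype calls are masked at random; everything is
  reproducible bit-for-bit from one seed.

Default parameters follow the milk-yield regime (genetic variances
9962/7278 kg², h² 0.31/0.26, repeatability 0.50/0.50) with a
2000–5000 SNP panel at desk scale.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: linkage and LD persistence
(SNPs are unlinked), selection-driven allele-frequency change,
crossbred animals, unknown-parent-group structure, heterogeneous herd
sizes and seasonal effects, genotyping error. The models under test
use relationships, not linkage, so these omissions do not touch the
algebra being verified; they do mean that absolute accuracy levels
here cannot be read as forecasts for any real population.

## Calibration studies and problem sizes

The acceptance suite runs each check at a size chosen so the study is
statistically meaningful yet completes quickly on one CPU:

- Exact identities (H collapse to pedigree BLUP, GLS conditional
  mean, mutual inverses, closed-form micro cases) at 30–900
  equations, tolerances 1e-6–1e-8.
- Model equivalences on a ~3100-animal two-breed population: ρ = 0
  reproduces the per-breed runs to 1e-6; ρ = 0.99 with equal breed
  variances correlates > 0.99 with the multi-breed model.
- REML recovery: 10 replicates at 3000 recorded females per breed
  (100 sires × 30 daughters), 300 genotyped sires + 1400 genotyped
  females, 2000 SNPs, truth h² = 0.30/0.25, ρ = 0.5. Estimates are
  checked for 2-SE coverage (breach count held to its binomial 99%
  bound, 4-SE gross-error guard) and mean bias (< 0.05 for h²,
  < 0.10 for ρ).
- BLUP calibration (PEV reliability vs empirical r², dispersion slope
  of true BV on GEBV): 20 replicates of a correctly specified study —
  homogeneous base population (Fst 0, ρ = 1, equal variances),
  offset-only compatibility correction and τ = 1, because
  mean-matching rescaling and blending intentionally shrink the model
  G relative to the gene-dropped truth and would contaminate a
  calibration check. Per-replicate slope noise at ~240 candidates is
  ±0.08–0.10, so the slope is estimated on the pooled
  replicate-centered pairs (n = 4800).
- Direction-of-effect checks (single-step ≥ two-step validation r;
  candidate model accuracy ≥ parent average) over 5 seeds, asserted
  as mean paired difference ≥ −2 SEM.

## Known limitations

- Dense direct solving and inversion bound the practical size to a
  few tens of thousands of equations; no iteration-on-data or APY
  machinery is provided.
- The REML absorption fast path requires terminal animals to be
  non-genotyped; fully genotyped phenotyped populations fall back to
  dense parent-level systems that grow with the genotyped count.
- Two breeds only; the Kronecker machinery is written for the 2×2
  case the comparison needs.
- Reliability approximations (`h_ii` from `diag(G_b)` or `1 + F`)
  ignore the small genomic correction to ungenotyped animals'
  relationship diagonals.
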