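# Methods

This note documents the models, calibration choices, numerical
conventions and known limitations of the package. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Neoantigen definition and its combinatorics

A candidate mutation is a somatic **missense** substitution in a gene
whose protein product has ≥ 8 residues; nonstop mutations are excluded,
and immunoglobulin genes (IGH/IGK/IGL prefixes or an `IG=1` FASTA tag)
can be excluded as a sensitivity analysis, since hypermutated IG loci are
subject to immune tolerance. Coordinates are 1-based with closed
windows. For peptide length k ∈ {8, 9, 10}, the admissible window starts
are `max(1, pos−k+1) … min(pos, len−k+1)`; an interior mutation in a
protein of length ≥ 19 therefore yields exactly 8+9+10 = 27
mutant/wild-type pairs, fewer near termini or in short proteins. Each
mutation is tiled independently against the *unmutated* reference
protein: co-occurring somatic mutations are not composited into the
window. This matches the per-mutation framing of the upstream data model
and keeps pairs well-defined when mutations cluster.

A **neoantigen** is a unique (mutant peptide, HLA allele) combination
within one patient with mutant IC50 < 500 nM and wild-type IC50 > 500 nM,
both strict — a value of exactly 500 nM fails both conditions, the
conservative reading of the threshold convention. Uniqueness is per
patient; sharing across patients is reported, never deduplicated away.
After deduplication a record keeps the IC50 pair of its best-binding
(lowest mutant IC50) instance; this is a reporting convenience and does
not affect counts. The patient's six HLA alleles are reduced to the
unique set before querying: a homozygous allele cannot create a second
distinct peptide:allele combination.

**Expression** is gene-level: a neoantigen is *expressed* iff any of its
source genes has an RNA count ≥ 1; genes absent from the expression table
count as zero. Mutant-allele-specific read support would be the sharper
criterion but is outside this data model (gene-level counts are the only
expression input), so the gene-level rule is used and flagged here.

## The affinity predictor contract

Neural-network binding predictors are external tools; the package defines
only the contract (strictly positive finite IC50 in (0, 50000] nM,
deterministic, unsupported alleles raise an error — they are skipped per
allele and logged, not per patient). The shipped
`SyntheticPSSMPredictor` draws, per allele, a 10×20 position-specific
score matrix from the construction seed, standardizes each positional row
to mean 0/sd 1, scores a k-mer as the row-sum divided by √k (exactly
zero-mean unit-variance for uniformly random peptides, approximately
normal by CLT), and maps the score through a decreasing logistic onto
(0, 50000] nM anchored so that a configurable fraction of random peptides
(default 0.02) falls under 500 nM. The predictor is *structurally*
realistic (deterministic, allele-specific, sensitive to single-residue
changes, calibrated marginal binder rate) but encodes no binding-motif
biology; absolute IC50s are meaningful only relative to the 500 nM rule.
The 50000 nM cap mirrors common predictor output conventions.

## Synthetic cohort model

### Burden

Per-patient missense counts are a rounded (half-up) log-normal with
log-scale parameters from the method of moments:
σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2, calibrated to the printed
cohort moments (mean 63.90, sd 95.88). Zero-count patients are allowed
and retained (they fall in the "low" stratum; log-histograms use
positive counts only, with the number excluded reported).

Total somatic counts use a single deterministic ratio:
`missense_fraction_of_total = 63.90/405.84 ≈ 0.1574`. The two printed
mean/sd pairs have near-identical coefficients of variation
(95.88/63.90 ≈ 608.55/405.84), so one ratio reproduces both moments; the
non-missense remainder is emitted as nonsense/frameshift/silent/nonstop
records (default proportions 0.35/0.35/0.20/0.10, configurable) purely to
exercise the classification filters. Silent records carry alt = ref;
missense records always have alt ≠ ref and a reference residue matching
the emitted proteome.

### Neoantigen yield (parametric mode)

Parametric mode draws each patient's neoantigen count as
Binomial(missense_i, p_i) with p_i ~ Beta(mean 23.52/63.90 ≈ 0.368,
variance 0.01395), and the expressed count by binomial thinning with
probability 9.40/23.52 ≈ 0.400. The Beta variance is a **tuned
constant**, not a biological claim: with n ~ the calibrated log-normal
and Y ~ Bin(n, p), the law of total variance gives
R² ≈ p̄²·Var(n) / [p̄²·Var(n) + E(n)(p̄−p̄²−v) + E(n²)·v] ≈ 0.862 at
v = 0.01395, matching the published regression strength. Mechanistic
mode leaves neoantigen counts emergent from the tiling/binding pipeline;
its absolute level depends on the synthetic predictor's binder rate and
is not calibrated to the printed means.

### Expression, HLA, clinical covariates

Gene expression is zero-inflated negative binomial (zero probability
0.3; NB mean 50, size 2) — the pipeline only uses the ≥ 1 threshold, so
only the zero probability materially matters. HLA genotypes are six
draws with replacement from a 30-allele synthetic pool (12 A, 12 B, 6 C);
homozygosity is possible and intended. Clinical covariates are drawn
independently of burden with plausible myeloma frequencies (ISS stage
0.321/0.342/0.298 with 3.9% missing, high-risk cytogenetics 0.17, age
N(64, 10) clipped to 27–93, elevated LDH 0.20, chr1 amplification 0.30,
bortezomib 0.65, IMID 0.55). Independence of burden from stage follows
the upstream observation that burden does not differ significantly across
stages; the joint distribution beyond that is unspecified there, so
independence is a flagged default, not an asserted fact.

### Survival

PFS is exponential. In **two-group** mode the hazard is inverted from
the group's configured 2-year rate via rate = −ln(S₂ᵧ)/730 (defaults:
0.493 above / 0.726 below the missense-mean threshold); group membership
is the patient's drawn missense count versus the configured threshold, so
burden and outcome are coupled exactly as in the downstream
stratification. OS uses a single cohort-wide rate (default 2-year 0.806).
In **covariate** mode the log hazard is linear in the high-burden
indicator and clinical covariates with user-set coefficients; defaults
put the high-burden hazard ratio at 1.8 with smaller stage/cytogenetic/
LDH/chr1/age effects — documented illustrative values, not estimates.
Administrative censoring at the follow-up horizon (default 1095 days):
event = 0 exactly when the latent time exceeds the horizon, in which case
the recorded time is the horizon itself. 2 years is 730 days exactly.

### Reproducibility

One master seed; the proteome and every patient get independent
`SeedSequence` substreams keyed by purpose and patient index, so the same
config+seed is byte-identical on disk and adding patients never perturbs
earlier ones.

## Survival estimation conventions

Kaplan–Meier, log-rank (hypergeometric variance, χ² with groups−1 df)
and Cox partial likelihood are delegated to lifelines. Ties use the
Efron method — R's `survival` package, the common alternative, defaults
to Efron as well, but the choice is recorded because Breslow is a
frequent default elsewhere. 2-year rates are step-function lookups (last
estimate at or before day 730; beyond the last observed time the last
estimate carries forward with a warning). "High" burden is *strictly*
above the cohort arithmetic mean of raw counts; quartile labels put
boundary ties in the lower quartile. Patients missing a covariate are
dropped listwise from that model only. Welch's t-test compares a
continuous burden between two groups, one-way ANOVA between more; on
exactly identical groups the degenerate 0/0 statistic is reported as
(0, p=1). Nested Cox models are compared by likelihood ratio (clipped at
zero against round-off). No multiple-testing correction is applied
across subgroup analyses, mirroring the upstream reporting convention;
interpret subgroup p-values accordingly. Age subgroups are a median
split, since no age-group definition is given upstream.

## Problem sizes

The test suite runs the generator at the published size (n=664) for
calibration checks, n=2000–5000 for survival-anchor recovery (Monte Carlo
standard error of a 2-year rate ≈ 0.007–0.011, comfortably inside the
±0.02–0.03 check tolerances), 200 replicates at n=500 for Cox CI
coverage, and 10⁵–10⁶ draws for distributional calibration. End-to-end
mechanistic pipeline tests use 20–60 patients with reduced burden so the
full tiling×allele×2 prediction load stays in the tens of thousands of
queries.

## Known limitations

- The synthetic predictor has no binding-motif biology; mechanistic-mode
  neoantigen *levels* are not calibrated, only the parametric-mode model.
- Expression evidence is gene-level, not variant-supporting-read-level.
- Frameshift/indel neoepitopes, proteasomal processing, TAP transport,
  percentile-rank binding modes, MHC class II, clonality weighting and
  TCR recognition are out of scope.
- One protein per gene (no transcript isoforms); "canonical" transcript
  choice is therefore trivial here.
- The covariate-mode hazard coefficients are illustrative defaults;
  multivariate hazard-ratio magnitudes depend on the covariate joint
  distribution and are not reproduction targets.
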