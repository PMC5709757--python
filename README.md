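# neoburden

Somatic mutation burden, MHC class I neoantigen calling, and survival
stratification for multiple myeloma cohorts — with a calibrated
synthetic-cohort simulator so the whole pipeline runs at desk scale
without access-restricted patient data.

## The problem

Multiple myeloma carries a comparatively low somatic mutation burden, and
whether that burden — and the tumor-specific *neoantigens* it creates —
predicts outcome under standard induction therapy is a clinically
relevant question: patients whose tumors present many mutant peptides on
MHC class I are candidates for immunotherapies that current regimens do
not exploit. The package implements the full analysis chain used to ask
that question in a 664-patient newly diagnosed myeloma cohort:

1. **Mutation burden** — per-patient counts of canonical somatic
   mutations from a MAF-like table; missense counts are the headline
   burden metric (log-transformed counts are approximately normal, so the
   cohort mean serves as the high/low threshold).
2. **Peptide tiling** — every somatic missense mutation in a protein of
   ≥ 8 residues (nonstop mutations excluded) is tiled into all 8-, 9- and
   10-mer windows containing the substituted residue: up to
   8 + 9 + 10 = 27 mutant peptides per mutation, each with its
   coordinate-matched wild-type peptide.
3. **Binding and calling** — a predictor assigns each peptide:HLA pair an
   IC50 (nM). A *neoantigen* is any unique (mutant peptide, HLA allele)
   combination per patient with mutant IC50 < 500 nM **and** wild-type
   IC50 > 500 nM (the wild-type condition guards against immune
   tolerance). An *expressed* neoantigen additionally has an RNA-seq
   count ≥ 1 for a source gene.
4. **Survival** — patients are stratified at the cohort mean (or into
   quartiles) of a burden metric; groups are compared with Kaplan–Meier
   curves and 2-year (day-730) rates, log-rank tests, and Cox
   proportional-hazards models (Efron ties), including subgroup analyses
   by ISS stage, cytogenetic risk, treatment, LDH, chromosome 1
   amplification and age, and likelihood-ratio tests of whether burden
   adds predictive benefit beyond established prognostic factors.

The external neural-network affinity predictor is deliberately out of
scope: the package defines a predictor *contract*, ships a deterministic
synthetic PSSM predictor with a calibrated binder rate, and provides a
file-based adapter for affinities computed offline.

## The synthetic cohort

`neoburden.synthetic_cohort` generates a complete cohort bundle
(proteome FASTA, mutation/HLA/expression/clinical TSVs, truth JSON) whose
statistical structure matches the published cohort's printed summaries:

- missense burden ~ rounded log-normal, method-of-moments calibrated to
  mean 63.90, sd 95.88 (total somatic: 405.84, sd 608.55);
- per-patient neoantigen yield ~ Beta with mean 23.52/63.90 and a
  dispersion tuned so the missense→neoantigen regression has R² ≈ 0.862;
- expressed neoantigens by binomial thinning with probability 9.40/23.52;
- exponential PFS/OS inverted from 2-year rates (cohort PFS 0.667,
  OS 0.806; high/low missense strata 0.493/0.726) with administrative
  censoring.

See `docs/methods.md` for the model, its assumptions, and what the
generator deliberately does not emulate.

## Worked example

Simulate a 60-patient cohort and run the full pipeline through the CLI:

```bash
cat > cohort.yaml <<'YAML'
n_patients: 60
seed: 17
missense_mean: 12.0
missense_sd: 9.0
proteome: {n_genes: 60, min_len: 30, max_len: 200}
YAML
neoburden simulate --config cohort.yaml --out sim --mode mechanistic

cat > run.yaml <<'YAML'
proteome: sim/proteome.fasta
mutations: sim/mutations.tsv
hla: sim/hla.tsv
expression: sim/expression.tsv
clinical: sim/clinical.tsv
out_dir: out
seed: 17
YAML
neoburden run-all --config run.yaml
neoburden report --report out/report.json
```

prints

```json
{
  "logrank_p": 0.18903139842623454,
  "missense_mean": 14.2,
  "neoantigen_mean": 17.3,
  "r_squared": 0.8593158129772657,
  "two_year_pfs": {
    "high": 0.4444444444444444,
    "low": 0.6428571428571428
  }
}
```

Reading: the simulated cohort carries 14.2 missense mutations per patient
on average, the emergent neoantigen counts track missense counts tightly
(R² 0.86), and patients above the cohort-mean missense burden have a
lower Kaplan–Meier PFS estimate at day 730 (0.44 vs 0.64) — at n=60 the
log-rank test is, unsurprisingly, not significant (p 0.19). The same
stages are available as library functions (`generate_cohort`,
`select_neoantigen_candidates`, `enumerate_peptide_pairs`,
`call_neoantigens`, `km_estimate`, `cox_fit`, ...) for programmatic use.

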