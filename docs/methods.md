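# Methods

## Estimation model

The estimator treats a sequenced cohort of n diploid individuals as a
random sample of 2n haploid genomes from a population in Hardy–Weinberg
equilibrium at every site. For a gene g, the risk allele frequency is

    q_g = Σ_{v ∈ R_g} AC_v / AN_v

where R_g is the qualifying (risk) variant set and AC/AN are the cohort
alternate-allele count and called-allele number. Allele frequencies are
kept as exact rationals internally, so AF·AN = AC holds as an integer
identity and sums of frequencies do not accumulate rounding error.
Missing genotypes reduce AN; they are never imputed. With Q = 1 − q the
carrier rate is 2Qq and the disease incidence q²; the identity
Q² + 2Qq + q² = 1 is property-tested.

Two risk sets are reported for every disease. The *conservative* set
contains variants classified pathogenic or likely pathogenic; the
*extended* set adds variants of uncertain significance. Benign and likely
benign variants never qualify. Conservative ⊆ extended by construction,
so conservative q, carrier rate and incidence are lower bounds for their
extended counterparts.

Diseases caused by several genes pool q across genes before squaring.
The combined incidence over a disease panel is the sum of per-disease q²;
this treats loci as independent and ignores the (unassessed) possibility
of in-cis variant pairs within a gene, which can only inflate q — the
estimate is an upper bound in that respect, and the per-disease report
keeps individual q values visible so the effect can be bounded.

Phase, X-linked inheritance math, ancestry stratification and Bayesian
shrinkage of allele frequencies are deliberately out of scope.

## Curation funnel

Stage 1 keeps variants that are (i) assigned to an autosomal recessive
panel gene, (ii) rare in the cohort, AF ≤ `af_max` (default 0.05, the
boundary inclusive — a variant at exactly 5% is kept), (iii) exonic or
near-exonic, `exon_distance` ≤ `exon_window` (default 2 bp, the canonical
splice-site positions; "near the exon" has no standard definition and the
window is configurable), and (iv) SNVs or indels changing ≤ 50 bp (the
conventional boundary to structural variation). The filter is idempotent,
order-preserving and a subset operation; `af_max = 0` is accepted and
yields an intentionally empty funnel rather than an error.

Variants are attributed to the panel gene with the nearest exon among
genes whose exon span, padded by 500 bp, contains the variant; the pad
only needs to exceed the exon window and its exact value is immaterial to
the results. Multiallelic records are decomposed to biallelic rows before
counting, and ref/alt pairs are trimmed to parsimonious form (shared
suffix, then shared prefix). True left-alignment against the reference
sequence is not performed; upstream callers emit left-aligned records and
the package does not carry a reference FASTA.

The candidate rule is a two-clause disjunction. Clause 1: the variant is
asserted pathogenic — or likely pathogenic, included by default since
curated cohorts treat ClinVar LP as reportable; a strict-pathogenic switch
exists — in ClinVar, or carried as DM or DM? in HGMD. Clause 2: the
variant is *unreported in both databases* and its severity score strictly
exceeds 7 of 13. Any other assertion (benign, VUS, conflicting, HGMD
"other") makes the variant *reported*, which blocks clause 2: a
database-rejected variant cannot be rescued by predictors. The severity
score counts deleterious calls among the 13 dbNSFP-panel predictors;
missing predictor calls count as non-deleterious votes, which is
conservative toward exclusion and keeps the fixed "7 of 13" denominator.
Binarisation of raw predictor output is outside the core contract — the
evidence sidecar carries categorical D/T/. calls — but a helper maps
dbNSFP letter codes (D/A/H/M deleterious; T/N/P/L/B tolerated) and
thresholds CADD at phred 20.

## ACMG classification engine

Criterion codes are taken as a set (duplicates collapse; strength-modified
codes such as PM3 upgraded to strong are not modelled — published curated
panels list base codes only). Evidence strength is a pure function of the
code prefix. The 2015 combining rules are applied literally:

* Pathogenic: PVS1 with (≥1 PS | ≥2 PM | 1 PM + 1 PP | ≥2 PP); ≥2 PS;
  1 PS with (≥3 PM | 2 PM + ≥2 PP | 1 PM + ≥4 PP).
* Likely pathogenic: PVS1 + 1 PM; 1 PS + 1–2 PM; 1 PS + ≥2 PP; ≥3 PM;
  2 PM + ≥2 PP; 1 PM + ≥4 PP.
* Benign: BA1; ≥2 BS. Likely benign: 1 BS + 1 BP; ≥2 BP.

Any pathogenic-side code together with any benign-side code is treated as
contradictory evidence and yields VUS before rules are evaluated (the
guideline's contradiction clause, applied at the evidence level); a set
firing no rule is also VUS. Two properties are enforced by exhaustive
enumeration against an independent transcription of the rule table: exact
agreement on all criterion sets of size ≤ 4, and monotonicity — adding a
pathogenic-side code never lowers the class, adding a benign-side code
never raises it, with the conflict-VUS respecting rank from both sides.

Published classifications are *audited*, not trusted: the bundled 21-row
novel-variant table re-classifies with 17 rows consistent, while 4 rows
printed "Pathogenic" from {PS1, PM3, PP4} evaluate to likely pathogenic
under the literal rules (1 strong + 1 moderate + 1 supporting) and are
flagged as inconsistent rather than silently matched.

An optional helper derives frequency criteria (BA1 at max external
AF ≥ 0.05; PM2 below 1e-4 or absent everywhere). It is off by default
because the intended workflow assigns criteria manually.

## Uncertainty

An incidence reported as a count c per denominator D (default 100,000)
gets the exact Garwood Poisson interval: lower bound ½·χ²(α/2, 2c), upper
½·χ²(1−α/2, 2c+2), implemented via gamma quantiles (shape c and c+1),
which extends smoothly to the non-integer counts produced by q²·D and
gives a 0 lower bound at c = 0. Exact intervals over-cover by
construction; a seeded simulation (10,000 draws at rates 2, 13 and 94)
confirms coverage ≥ 95%.

Two rates are compared with the exact conditional binomial test: given
K = k_a + k_b total events, k_a is Binomial(K, D_a/(D_a + D_b)) under
equal rates, with the minimum-likelihood two-sided p-value. The test is
symmetric under swapping the rates and conservative (simulated type-I
error below nominal); it is well-defined at the very small counts typical
of rare-disease comparisons, which is why it is the default over the
selectable normal approximation. Non-integer counts are rounded for the
exact test, with a warning.

Per-100,000 values are computed at full precision and rounded half-up to
2 decimals only for reporting (so 4.225 prints as 4.23).

## Synthetic cohorts

The generator emulates exactly what the estimator assumes: for each
planted variant with frequency f, each individual independently draws a
genotype from ((1−f)², 2f(1−f), f²); variants are independent (no linkage
disequilibrium, matching the estimation model's assumption). Gene models
are laid out deterministically with jittered exon (~120–240 bp) and
intron (~1–2 kb) sizes; outputs (VCF 4.2, panel JSON, evidence TSV,
truth JSON) are byte-identical under a fixed seed.

Evidence templates are constructed to be unambiguous under the candidate
rule and the classification engine: `clinvar_pathogenic` and `hgmd_dm`
pass clause 1; `unreported_highscore` passes clause 2 with 9 deleterious
calls; `unreported_lowscore` (4 calls) and `clinvar_benign` fail both
clauses. Criterion sets per true class are {PVS1, PS1} → P,
{PS1, PM3} → LP, {} → VUS, {BS1, BP1} → LB, {BA1} → B, so the engine
recovers the planted class exactly. Per-gene planted frequencies must sum
below 1; sums above 0.5 warn, as they leave the rare-disease regime the
generator is meant to emulate.

What the generator does *not* emulate: sequencing and genotyping error,
missing genotypes, mutation spectra, linkage, population structure, or
disagreement between databases and truth. Passing recovery tests
therefore demonstrate the correctness of the pipeline's accounting and
arithmetic under the model's own assumptions — not robustness of the
estimates to real-data artefacts.

The default study conditions mirror the motivating cohort: 1,495
individuals, per-gene conservative risk frequencies on an even grid over
[0.001, 0.02] split across one pathogenic and one likely-pathogenic
variant, plus one unreported high-score VUS (f = 0.002), one benign
variant (f = 0.01) and one low-score unreported variant (f = 0.001) per
gene.

## Validation study

Since the cohort genotypes behind the published totals are not public,
the headline numbers are validated by parameter recovery rather than
reproduction: 200 seeded replicate cohorts of 1,495 individuals, 24 genes,
full pipeline per replicate (VCF write → ingest → funnel → candidate rule
→ classification → incidence). The per-gene estimate q̂ is a binomial mean
and hence exactly unbiased; the acceptance check requires the mean
relative bias over genes to stay within 2%, comfortably wide relative to
the Monte-Carlo error of the study size. The plug-in incidence q̂² is
biased upward by Var(q̂): its exact expectation q² + q(1−q)/(2n) is the
oracle the replicate means are compared against (within a 5-standard-error
delta-method band). The replicate count and cohort size were fixed with
the study design; 200 replicates run in under a minute on one CPU.

## Degenerate inputs and numerical choices

* q = 0 propagates to zero carrier rate, zero incidence and a (0, upper)
  CI; q outside [0, 1] or summed q > 1 raise errors rather than clamp.
* Empty panels, empty truth specs and empty candidate sets produce empty
  (all-zero) reports, not errors.
* Both-zero rate comparisons return p = 1 with a degenerate flag.
* VCF records with AN = 0 (all genotypes missing) are skipped; symbolic
  and spanning-deletion alleles are skipped.
* Confidence level, allele-frequency bounds and thresholds are validated
  at the interface; error messages name the offending value.
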