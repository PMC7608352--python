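# Methods

## Scope and design

`cnvpheno` implements a complete case-control analysis of a recurrent
heterozygous deletion — by default the 15q11.2 BP1–BP2 locus — in a
biobank-style cohort with coded hospital-episode, operation, self-report and
death records. Because the real cohorts this analysis applies to are
access-controlled, the package pairs the analysis chain with a synthetic
cohort generator that carries ground-truth labels; every downstream stage is
validated against those labels.

## Locus genotyping

Coordinates are 1-based and inclusive (PennCNV convention); the length of
[start, end] is end − start + 1. The default locus is the probe-bounded
interval chr15:22,819,338–23,093,090 (GRCh37; length 273,753 bp) covering
*NIPA1*, *NIPA2*, *CYFIP1*, *TUBGCP5*.

A sample is a carrier when the union of its copy-number-1 segments covers at
least 95 % of that interval. The 95 % rule is applied to the single
probe-bounded interval rather than per gene: the four genes tile the
interval, the published coordinates describe the interval (not per-gene
spans), and a single-interval rule has an unambiguous boundary
(0.95 × 273,753 = 260,065.35, so 260,065 bp of overlap fails and 260,066 bp
passes). Multiple CN = 1 calls are unioned without any gap-merging
heuristic — the simplest reading of "spanned". A CN = 0 call overlapping the
locus is biologically unexpected (no homozygous carriers have been observed
at this locus); it is flagged as an anomaly and the sample is not called a
heterozygous carrier.

Sample QC removes samples with waviness factor strictly outside ±0.03 or
strictly more than 40 genome-wide calls. The boundary values (exactly ±0.03,
exactly 40) are retained: the exclusion rules are strict inequalities, and
the count threshold is deliberately permissive because global CNV burden is
itself associated with congenital cardiovascular malformation.

## Phenotyping cascade

Classification is deterministic given the codebook and invariant to event
order (events are sorted by age, then a tiebreak token). Precedence:

1. **Syndrome exclusion** dominates everything: the case group must be
   non-syndromic.
2. **Congenital-circulatory diagnosis codes** give CASE, except Q21.1,
   which codes both atrial septal defect (ASD, a true malformation) and
   patent foramen ovale (PFO, a normal variant present in up to a quarter of
   the population). Q21.1 evidence is voided when (a) a PFO-specific closure
   operation (K16.5) is present, or (b) a stroke with no atrial-fibrillation
   code at or before it occurs strictly before the earliest Q21.1 — PFO is
   typically found during stroke workup, whereas ASD predisposes to atrial
   fibrillation. A participant whose only evidence was voided Q21.1 is
   excluded from both groups.
3. **Operation codes / self-report**: congenital-heart operations and
   self-reported congenital heart disease give CASE; self-reported heart
   surgery counts only when performed before age 18.
4. **Inferred bicuspid aortic valve (BAV)**: aortic stenosis/insufficiency/
   valve-replacement codes give CASE when first diagnosed before 65 and no
   endocarditis-type exclusion is present; at ≥65 the valve disease is
   presumed degenerative and the participant is excluded from both groups,
   as is anyone with an exclusion diagnosis.
5. **Control exclusions**: remaining acquired-defect codes remove a
   participant from the control group.
6. Otherwise CONTROL.

Tie-breaking: a stroke at the same age as the earliest Q21.1 with no finer
ordering information counts as *prior* — conservative toward exclusion,
since the purpose of the rule is to purge possible PFO from the case group.
"Stroke without atrial fibrillation" means no AF code at or before the
stroke: AF discovered during the stroke workup is exactly the confounder the
rule targets. Age thresholds (<65, <18) are strict and use the earliest
qualifying event. Cause-of-death records carry ICD-10 codes and run through
the same sets, so deceased participants are classified like living ones.

Neuropsychiatric status: a defined subset of mental/behavioural codes
(psychotic, bipolar, intellectual-disability and developmental-disorder
chapters) gives CASE; any *other* mental/behavioural code excludes the
participant from controls. The cognitive analyses additionally drop
participants with any code in the deletion-associated exclusion set,
regardless of CVM status.

The **default codebook is a stand-in** assembled from the public
ICD-10/OPCS-4 chapter structure (Q20–Q28, I35.x, K16.5, I63/I64, I48,
F-chapter subsets). It exercises every cascade branch but is not a curated
clinical code list; studies should supply their own YAML codebook. All
EXCLUDED reasons form a closed enumeration so downstream denominators are
auditable.

## Association statistics

For a 2×2 carrier-by-phenotype table, the package reports the sample odds
ratio, the Woolf confidence interval (log-OR ± 1.96·SE with
SE = √(1/a+1/b+1/c+1/d)) and the Yates continuity-corrected chi-squared
statistic with an upper-tail 1-df p-value. The continuity correction is the
package's deliberate choice for these sparse tables (carrier counts in the
tens against denominators near half a million): on the published counts the
corrected statistic reproduces both printed p-values (0.030 and 0.004),
whereas the uncorrected statistic gives ≈0.020 for the CVM table. A single
zero cell triggers the Haldane–Anscombe correction (+0.5 to every cell,
flagged in the result); a zero margin raises an error. Prevalences and the
test statistic are always computed from uncorrected counts. An exact
conditional-maximum-likelihood interval is available behind a flag
(`ci_method="exact"`); Woolf is the default because it is the standard
reporting convention for biobank-scale 2x2 tables and is what the printed
intervals above correspond to. No multiple-testing adjustment is
applied anywhere in the battery: each outcome is reported as a separate
pre-specified analysis.

Regressions are maximum-likelihood fits with canonical links, always
adjusted for age (years) and sex (0/1) unless sex-stratified:

- reaction time — linear, after a single-pass 5·SD outlier rule (mean and SD
  from the full pre-removal sample; the rule is not iterated, the minimal
  reading since re-iteration is unstated);
- fluid intelligence — Poisson with log link (small non-negative scores);
- numeric memory — logistic on score > 6; pairs-matching — logistic on
  errors > 0 (the raw distribution is zero-inflated);
- highest qualification — multinomial log-linear with a combined "other"
  category as baseline, reporting per-category deletion odds for degree and
  A/AS-level attainment;
- fecundity — Poisson per sex (children fathered for males, live births for
  females) after the 5·SD rule plus hard caps (>8 for males, >7 for
  females), with a pooled deletion×sex Wald interaction test.

Fits that do not converge, or that are degenerate (non-finite estimates, or
for Poisson/logistic an absolute coefficient above 25 or a standard error
above 10³, the signature of separation or an empty outcome group), raise an
explicit fit failure rather than returning silent NaNs.

## Synthetic cohort generator

The generator's defaults encode the cohort conditions the analysis assumes:
deletion prevalence 0.38 %, CVM prevalence 0.59 % with carrier odds ratio
1.73, neuropsychiatric prevalence 0.72 % with odds ratio 1.84, sample-QC
failure rates of 0.06 % (waviness) and 0.29 % (excess CNVs), fecundity means
1.66/1.80 (male carriers/non-carriers) and 1.88/1.82 (female), qualification
shares (other/degree/A-levels) of 0.560/0.328/0.112 for non-carriers and
0.669/0.229/0.102 for carriers, and carrier cognitive shifts of +17.8 ms
reaction time, log(5.40/5.99) fluid-intelligence log-rate, −0.35 log-odds of
a high numeric-memory score and +0.15 log-odds of pairs-matching errors.
Baseline outcome distributions (reaction time ~N(557, 110²) ms, fluid
intelligence ~Poisson(5.99)) match summary statistics typical of a
middle-aged volunteer cohort.

Phenotype risks are **OR-targeted**: given prevalence p, carrier fraction q
and odds ratio R, the non-carrier risk p0 solves
q·p1 + (1−q)·p0 = p with odds(p1) = R·odds(p0) (Brent root-finding), so the
configured OR is the true population parameter and empirical estimates
converge to it as n grows. CVM and neuropsychiatric status are drawn
independently given carrier status: their joint distribution among carriers
is not identified by the summary statistics the generator targets (the
analysis it emulates observed only 2 overlapping individuals).

Event histories realize the labels: each true CVM case draws one of six
code paths (congenital ICD diagnosis, Q21.1-only ASD, congenital-heart
operation, self-reported illness, childhood heart surgery, BAV-pattern code
before 65); each decoy kind receives exactly the pattern the classifier
must exclude (Q21.1+K16.5; stroke-before-Q21.1 without AF; aortic stenosis
at ≥65; valve code plus endocarditis; a syndrome code; an out-of-subset
F-chapter code). Controls receive no classifying codes; a configurable
fraction of all participants receives a benign non-classifying code so that
classification is tested against irrelevant noise. Event ages are integers
consistent with year of birth, with a fractional tiebreak ordering same-age
events. Carriers receive a single CN = 1 call over the locus with boundary
jitter validated against the 95 % rule (worst-case inward jitter from both
ends must not push coverage below threshold); no CN = 0 call is ever placed
at the locus. Background CNV calls (Poisson, mean 6 per clean sample; 41+
for designated excess-CNV failures) are placed on autosomes other than
chromosome 15 so that only designated carriers intersect the locus.

Randomness comes from a single seeded numpy Generator with vectorized draws
in fixed participant order, so output is byte-identical across runs with the
same seed.

What the generator does **not** emulate: array intensities or probe-level
data, imprinting/parent-of-origin effects, missing outcome data, calendar
dates (only age-at-event), correlated comorbidity structure, or carrier/
phenotype misclassification at the CNV-calling step. Passing tests therefore
demonstrate that the pipeline's logic is correct and its estimators recover
known parameters — not that the stand-in codebook or the generator's decoy
mix matches any real cohort's coding practice.

## Problem sizes used in the checks

End-to-end recovery runs 20 simulated cohorts of n = 200,000 at the default
conditions and requires the Woolf CI to cover the configured OR in ≥18/20
(the 90 % criterion at 20 seeds) and phenotype/carrier recovery to be exact.
Regression recovery uses one cohort of n = 100,000 (all families within
3 SE of generator settings); the null fecundity-interaction check uses 200
replicates of n = 3,000 with a Kolmogorov–Smirnov uniformity test. Woolf CI
coverage is verified over 2,000 simulated tables (±2 % of nominal).

## Known limitations

- The default codebook is structural, not clinical; real studies must
  supply curated code lists, including the supplementary-table-level detail
  (e.g. the full self-report code vocabulary) this package cannot ship.
- The <65 age rule is applied uniformly to hospital-coded and self-reported
  BAV-pattern evidence, using age at the earliest qualifying event.
- The attainment percentages are reported at 1 dp from the computed
  fractions; a frequency table of (414, 185, 1209) gives a carrier degree
  share of 22.9 % (414/1,808).
- No GP/primary-care record handling, no NLP phenotyping, no duplication
  (CN ≥ 3) genotyping at the locus, no GRCh38 liftover.
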