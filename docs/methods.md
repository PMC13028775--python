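# Methods

## Variant panel and diplotype model

The panel covers five loci in three statin-disposition genes:

| key            | gene    | rsID      | role |
|----------------|---------|-----------|------|
| `rs4149056`    | SLCO1B1 | rs4149056 | c.521T>C, defines \*5/\*15 reduced-function haplotypes |
| `rs2306283`    | SLCO1B1 | rs2306283 | c.388A>G, distinguishes \*1/\*5 from \*37/\*15 |
| `rs2231142`    | ABCG2   | rs2231142 | c.421C>A, reduced BCRP efflux |
| `cyp2c9_star2` | CYP2C9  | rs1799853 | reduced-function \*2 |
| `cyp2c9_star3` | CYP2C9  | rs4986893 (configurable) | reduced-function \*3 |

The \*3 locus is keyed by name rather than rsID because sources disagree on
the rsID (the conventional CYP2C9\*3 identifier is rs1057910, while
rs4986893 conventionally labels CYP2C19\*3); the VCF reader accepts a
configurable rsID plus a chrom:pos:ref:alt fallback, and the package takes
no position on which assay was used upstream.

SLCO1B1 haplotypes are the four combinations of the 388/521 alleles
(\*1 = A‑T, \*37 = G‑T, \*5 = A‑C, \*15 = G‑C). From unphased dosages the
caller enumerates every consistent unordered haplotype pair. Because both
521C-bearing haplotypes are reduced-function, the function phenotype is a
closed form of the 521 dosage alone — 0 copies: normal, 1: decreased, 2:
poor — and is therefore invariant to phase; the exhaustive 9-combination
check in the test suite proves this equals the diplotype-group definition.
Phase ambiguity is reported (e.g. `*1/*15|*37/*5`) but never needs
resolution for scoring.

**Burden score.** Two schemes are implemented because the score has two
printed definitions that disagree for the decreased phenotype:
`text_ordinal` (normal 0 / decreased 1 / poor 2) and `table8_weighted`
(normal 0 / decreased or poor 2). The weighted scheme is the default, being
presented as the score's definition; the dichotomisation (low 0–1, high 2–4)
is scheme-dependent exactly when a subject's only component is a decreased
SLCO1B1 phenotype, so reports always carry the scheme. ABCG2 and CYP2C9 are
dominant carrier flags (variant homozygotes are rare; CYP2C9 contributes at
most 1 even when \*2 and \*3 are both present). Missing genotypes exclude a
subject from scored analyses with a logged, manifest-visible reason; no
imputation is performed because none is described for the emulated analysis.

## Regimen course

Intensity classification uses the ACC/AHA dose bands with printed ranges
treated as closed intervals; doses covered by no band (e.g. atorvastatin
30 mg) are `unclassifiable`, skipped for transition detection but still
counted as switches. The three-level modification outcome is fixed by the
*first* transition between classified intensity levels within follow-up, so
the class and the time-to-event refer to the same transition; later
reversals do not reclassify. Same-intensity drug or dose changes are
`no_change` for the three-level outcome but increment `switch_count`, which
feeds the behavioural intolerance clause. Ties in fill dates keep input
order (stable sort). MPR is the simple sum of days supplied (truncated at
the follow-up boundary) over follow-up days, capped at 1.0, with the 0.80
threshold inclusive; overlapping fills are deliberately not de-duplicated,
matching the plain formula.

## Outcome rules

CK uses sex-specific ULNs (120 IU/L women, 180 IU/L men); `ck_elevated`
(≥1×ULN) is reported separately from the 3×ULN intolerance criterion. The
intolerance rule's default reading attaches the 3×CK requirement to
"myopathy or de-escalation" while ">3 statin switches" stands alone as a
behavioural route requiring no CK; a `strict` variant requiring 3×CK for
all sub-clauses is available because the source sentence is grammatically
ambiguous. Missing CK or sex degrades the biochemical clause to false with
a log entry. Myopathy and liver injury are consumed as EHR-style diagnosis
flags — no numeric liver-injury threshold is defined upstream, so none is
invented; ALT/AST are descriptive. The composite outcome is the OR of
myopathy, liver injury and non-adherence.

## Association layer

All models are complete-case and carry `n_used`. Estimates are OR
(logistic), RRR (multinomial, reference `no_change`) and HR (Cox, Efron
ties), with 95% Wald CIs symmetric on the log scale. The 2×2 contingency OR
applies the Haldane–Anscombe 0.5 correction on zero cells, flagged.
Perfectly collinear design columns are dropped greedily by rank with an
explicit `dropped:` flag; separation is flagged (`separation`, infinite
upper bound) rather than penalised. χ² tests are computed without
continuity correction. No multiple-testing correction is applied, matching
the emulated analysis; the descriptive report carries the number of tests
run. The Cox fit accepts `strata=` for stratum-specific baseline hazards;
the pipeline stratifies on baseline intensity because intensity mechanically
constrains which transitions are possible (a high-intensity starter cannot
escalate), which otherwise produces separation-prone dummies.

## Synthetic cohort generator

The generator's defaults are the emulated study conditions: n = 911,
12-month follow-up, statin mix dominated by atorvastatin (61.4%) and
rosuvastatin (33.7%), intensity mix 1.6/44.6/53.8% (low/moderate/high),
baseline rates — myopathy 14.5%, liver injury 2.5%, non-adherence 29.5%,
escalation 10.2%, de-escalation 11.4% — and the reference cohort's adjusted
effect estimates as default truth (intolerance OR 1.14, de-escalation RRR
1.18, escalation RRR 0.93, regimen-change HR 1.02, myopathy→de-escalation
RRR 1.91). The default rs4149056 frequency (0.1936) is back-derived from
the phenotype marginals (p(T/T) = 0.6502) so the default cohort reproduces
the published phenotype mix; the population maximum for this ancestry
group (0.2322) is an equally valid configuration. The rs2306283, rs2231142
and CYP2C9 frequencies (0.485, 0.0623, 0.110/0.047) are likewise
back-derived from printed genotype marginals (the CYP2C9 pair solves
1−[(1−p₂)(1−p₃)]² = 0.2801). A baseline intolerance-designation rate of
0.10 is the one rate with no printed anchor; it was chosen once as a
plausible clinical prevalence and is configuration, not a claim.

**Genotypes** are drawn independently per locus under Hardy–Weinberg
proportions (loci lie on chromosomes 12, 4 and 10; no LD is modelled, in
line with the score's independence assumption). The SLCO1B1 pair is drawn
as phased haplotypes so a truth diplotype exists, then emitted unphased to
exercise ambiguity handling.

**Regimen modification** is generated so that each configured effect is
recoverable by the estimator that targets it:

* class odds follow a multinomial logit with intercepts calibrated to the
  baseline escalation/de-escalation rates (divided by the feasibility mass,
  i.e. the probability that a drawn transition is attainable from the
  starting drug/intensity, so realised rates track the configured ones);
  log-RRR coefficients act on high burden and latent myopathy;
* feasibility (a high starter cannot escalate; a low starter cannot
  de-escalate) enters the subject's own odds. It is independent of burden,
  so it cancels out of the marginal RRRs;
* the no-change probability is then tilted as S = S_base^(HR^high): within
  each baseline-intensity stratum the hazard of any change is exactly
  proportional between burden groups (exponential, censored at follow-up),
  so an intensity-stratified Cox fit recovers the configured HR; change
  times are truncated-exponential, realised at the next ~30-day fill
  (±3-day jitter breaks ties).

**Adherence.** Designated non-adherent subjects (Bernoulli at the
configured rate) keep a random subset of fills targeting MPR ∈ [0.30,
0.75]; adherent subjects keep MPR ≥ 0.85. The first fill, and the first
post-change fill, are always kept so the index date and the transition stay
observable.

**Intolerance** is designated at a baseline rate tilted by the configured
OR on high burden, then *realised from observables*: designated subjects
receive a CK draw at 3–6×ULN, and when the biochemical clause cannot fire
(CK series missing, or neither myopathy nor a realised de-escalation) they
instead receive alternating same-intensity drug/dose fills producing >3
switches. The rule-based phenotyper therefore re-derives every designation
exactly (verified in tests); a small background of accidental
rule-positives (~0.3%) slightly attenuates fitted ORs, well inside the
recovery tolerances. Myopathy and liver-injury flags are Bernoulli at their
baseline rates with the same odds tilt on high burden. CK is lognormal per
sex (medians 100/150 IU/L, σ = 0.5 — below the 120/180 ULNs); ALT/AST are
lognormal around 19/17 U/L. Missingness (defaults: CK 30%, ALT/AST 10%) is
applied last.

**Reproducibility.** One pseudo-random stream per component (genotypes,
latent designations, dispensing, labs) is split from the master seed via
`SeedSequence.spawn`, so identical configs give byte-identical cohorts and
extending one component does not perturb the others. Latent designations
are regenerated deterministically by every stage that needs them, so stages
compose without hidden state.

## What the generator does and does not emulate

It reproduces the statistical skeleton the analysis assumes: HWE genotypes
at configurable frequencies, a fill calendar with adherence gaps,
feasibility-constrained intensity transitions with configurable
OR/RRR/HR effects, lognormal biomarkers with designated exceedances, and
EHR-style diagnosis flags. It does **not** emulate LD between loci, LDL
response to treatment, dose-titration feedback from lab values,
drug–drug-interaction pharmacokinetics, informative missingness, or
correlated comorbidity structure — demographics and comorbidities are
outcome-independent noise. Passing recovery tests therefore show that the
estimators are unbiased under the generator's assumptions, not that those
assumptions hold in any real cohort. Behavioural-route realisation of
intolerance assumes ≥5 fills fit in the follow-up window; with follow-up
much shorter than the default 12 months the designation may under-realise.

## Numerical choices

* Wald inference everywhere (z on the log scale); MNLogit maximum 500
  Newton iterations, Logit 200; a Wald SE above 50 is reported as
  separation with an infinite upper CI bound and NaN p.
* Dose-band membership is closed-interval; intensity ties never occur
  because bands do not overlap.
* MPR uses exact day arithmetic; the 0.80 adherence threshold is inclusive.
* The 2×2 OR orientation is (reference row first, event column second);
  reversing the exposure coding inverts every ratio exactly (tested to
  1e-9 on the log scale).
* Subject order never affects any result (mergesort throughout).

## Known limitations

* The score's two printed definitions disagree for decreased-function
  subjects; results dichotomised under different schemes are not
  comparable. The scheme is therefore a mandatory, recorded parameter.
* Printed summary counts in the emulated cohort are internally inconsistent
  in places (e.g. a row percentage disagreeing with its own counts by
  0.13 points); the package always reports count-derived values.
* High-intensity simvastatin/pravastatin/fluvastatin doses do not exist in
  the dose-band table, so users starting on those drugs can only reach high
  intensity through a statin switch; the generator routes such escalations
  to atorvastatin 40 mg.
* The fitted cohort-level estimates of any real dataset depend on EHR
  phenotyping quality (diagnosis flags are taken at face value); the
  package adds no adjudication layer.
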