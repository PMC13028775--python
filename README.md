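# statin-pgx

Cumulative pharmacogenetic (PGx) burden scoring and statin regimen-modification
analysis from pharmacy dispensing records.

## The problem

Statins are first-line therapy for atherosclerotic cardiovascular disease, but a
substantial fraction of patients modifies or abandons therapy within a year,
often because of statin-associated muscle symptoms. Three pharmacokinetic genes
carry most of the known genetic signal for statin exposure: *SLCO1B1* (hepatic
uptake via OATP1B1), *ABCG2* (efflux via BCRP) and *CYP2C9* (metabolic
clearance). Single variants rarely explain clinical intolerance, which
motivates a **cumulative PGx burden score** combining them, and the question
this package operationalises: does higher burden shift real-world statin
regimen modification (dose escalation vs de-escalation), intolerance, adverse
outcomes, and treatment persistence?

`statin-pgx` is aimed at pharmacoepidemiologists who want a tested, reusable
implementation of this analysis — from raw genotypes and dispensing records to
effect estimates — plus a seeded synthetic-cohort generator so the entire
pipeline is testable (and its parameter recovery verifiable) without any
patient data.

## The score and the outcome definitions

For subject *i* with SLCO1B1 function phenotype *f(i)* (normal / decreased /
poor, derived from the diplotype over \*1, \*37, \*5, \*15 defined by
c.388A>G and c.521T>C):

```
burden(i) = S(f(i)) + 1[ABCG2 421C>A carrier] + 1[CYP2C9 *2 or *3 carrier]
```

with `S = {normal: 0, decreased: 2, poor: 2}` under the default weighted
scheme (an ordinal `{0, 1, 2}` scheme is also implemented); scores 0–1 are
**low burden**, 2–4 **high burden**. Every haplotype carrying 521C is
reduced-function, so the phenotype depends only on the 521 dosage and is
phase-ambiguity-proof — the candidate diplotype set is still reported.

Dispensing records become an intensity-labelled trajectory via the ACC/AHA
low/moderate/high dose bands; the first intensity transition within follow-up
defines escalation/de-escalation (otherwise no change, censored), MPR =
days-supplied/follow-up days with MPR ≥ 0.80 defining adherence, intolerance
combines a 3×ULN creatine-kinase elevation (sex-specific ULN 120/180 IU/L)
with myopathy or de-escalation, or >3 statin switches, and the composite
adverse outcome is myopathy ∨ liver injury ∨ non-adherence. Associations are
reported as OR (logistic), RRR (multinomial vs no-change) and HR (Cox, with
Kaplan–Meier curves and log-rank test), all with 95% Wald CIs.

## Worked example

```python
import statin_pgx as sp

profile = sp.build_profile("double_het", {
    "rs4149056": 1, "rs2306283": 1, "rs2231142": 0,
    "cyp2c9_star2": 0, "cyp2c9_star3": 0,
})
print(profile.slco1b1, profile.slco1b1.phenotype,
      profile.burden_score, profile.burden_category)
# *1/*15|*37/*5 decreased 2 high
```

End-to-end recovery of a configured effect (`examples/04_outcomes_and_association.py`,
n = 5000, de-escalation RRR for high burden set to 2.0, all other effects null):

```
OR intolerance ~ high burden            0.91  (95% CI 0.75-1.10, p=0.324, n=5000)
RRR escalation_vs_no_change ~ high burden  1.11  (95% CI 0.90-1.36, p=0.331, n=5000)
RRR de_escalation_vs_no_change ~ high burden  1.97  (95% CI 1.67-2.31, p=0.000, n=5000)
HR time-to-regimen-change               1.47  (95% CI 1.31-1.65, p=0.000, n=5000)
KM persistence at 12 months: low=0.799 high=0.715
```

The fitted de-escalation RRR (1.97) recovers the configured 2.0 from
observables alone; the null effects stay near 1; and persistence is lower in
the high-burden group exactly as a de-escalation excess implies.

Each script in `examples/` demonstrates one capability (scoring, course
derivation, simulation, association fitting, the orchestrated pipeline). A
thin CLI wraps the pipeline:

```bash
statin-pgx run --seed 1 --scheme table8_weighted --out runs/demo
statin-pgx simulate --n 911 --seed 1 --out cohort/
```

Every run writes a manifest (config hash, seed, per-stage row counts, every
exclusion with its reason) so attrition is always explicit.

## Layout

```
src/statin_pgx/
  genotyping.py   # diplotypes, carrier codes, burden score (both schemes)
  regimen.py      # intensity bands, course derivation, MPR
  outcomes.py     # CK/intolerance/composite rules
  association.py  # contingency OR, logistic/multinomial/Cox, KM, descriptives
  simulate.py     # seeded synthetic-cohort generator (HWE genotypes, fills, labs)
  pipeline.py     # orchestration + manifest
  io.py           # minimal VCF 4.2, CSV dialects, truth JSON
  cli.py          # thin click wrapper
docs/methods.md   # model, generator design, numerical choices, limitations
```
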