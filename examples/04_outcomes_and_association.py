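"""End-to-end association analysis on a simulated cohort.

Simulates n=5000 subjects with a configured de-escalation RRR of 2.0 for
high PGx burden (other effects null), derives courses and outcome flags,
and fits the full association layer — showing the configured effect being
recovered from the observable data alone.
"""

import statin_pgx as sp

effects = {
    "or_intolerance_high_burden": 1.0,
    "rrr_deescalation_high_burden": 2.0,
    "rrr_escalation_high_burden": 1.0,
    "hr_regimen_change_high_burden": 1.0,
    "rrr_deescalation_myopathy": 1.0,
}
cfg = sp.SimConfig(n_subjects=5000, seed=11, effect_sizes=effects)
cohort = sp.simulate_cohort(cfg)

courses = sp.derive_courses(cohort.dispensings, cfg.followup_days)
flags = sp.phenotype_cohort(cohort.clinical, cohort.labs, courses)
profiles = sp.score_cohort(cohort.genotypes)
ds = (profiles[["subject_id", "burden_category"]]
      .assign(high_burden=lambda d: d["burden_category"] == "high")
      .merge(courses, on="subject_id").merge(flags, on="subject_id"))


def show(tag, r):
    print(f"{tag:<38} {r.estimate:5.2f}  (95% CI {r.ci_low:.2f}-{r.ci_high:.2f}, "
          f"p={r.p_value:.3f}, n={r.n_used})")


logit, _ = sp.fit_logistic(ds, "intolerance", "high_burden")
show("OR intolerance ~ high burden", logit)

for r in sp.fit_multinomial(ds, "modification", "high_burden"):
    show(f"RRR {r.contrast} ~ high burden", r)

cox, km, logrank_p = sp.fit_persistence_cox(ds, strata=["baseline_intensity"])
show("HR time-to-regimen-change", cox)
print(f"log-rank p = {logrank_p:.3f}")
print(f"KM persistence at 12 months: "
      f"low={sp.km_survival_at(km['low'], 365):.3f} "
      f"high={sp.km_survival_at(km['high'], 365):.3f}")

print()
print("The de-escalation RRR CI should cover the configured 2.0; the")
print("intolerance OR and escalation RRR stay near their null value of 1,")
print("and the high-burden persistence curve sits below the low-burden one")
print("exactly as a de-escalation excess (with no escalation deficit) implies.")
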