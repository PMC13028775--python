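"""Summary counts from the reference coronary-artery-disease statin cohort.

These printed cohort-level counts serve two purposes: worked-example inputs
for the contingency and descriptive operations, and emulation targets for
the synthetic generator's default configuration.  They are counts, not
patient data.
"""

REFERENCE_COHORT = {
    "n_total": 911,
    # three-level regimen-modification outcome
    "regimen_groups": {"escalation": 93, "de_escalation": 104, "no_change": 714},
    # composite adverse outcome by burden category: {category: (no, yes)}
    "composite_by_burden": {"low": (348, 239), "high": (187, 138)},
    # SLCO1B1 function phenotypes among subjects with a called diplotype
    "slco1b1_phenotypes": {"normal": 578, "decreased": 272, "poor": 39},
    "statin_counts": {
        "atorvastatin": 559, "rosuvastatin": 307, "pravastatin": 22,
        "simvastatin": 20, "fluvastatin": 3,
    },
    "intensity_counts": {"low": 15, "moderate": 406, "high": 490},
    "outcome_counts": {"myopathy": 132, "liver_injury": 23, "nonadherence": 269},
}
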