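"""Call SLCO1B1 diplotypes and the cumulative PGx burden score.

Three illustrative subjects: a reference-genotype subject, a 388/521 double
heterozygote (whose two possible phasings share one function class), and a
maximally burdened subject.
"""

import statin_pgx as sp

subjects = {
    "reference": {"rs4149056": 0, "rs2306283": 0, "rs2231142": 0,
                  "cyp2c9_star2": 0, "cyp2c9_star3": 0},
    "double_het": {"rs4149056": 1, "rs2306283": 1, "rs2231142": 0,
                   "cyp2c9_star2": 0, "cyp2c9_star3": 0},
    "max_burden": {"rs4149056": 2, "rs2306283": 2, "rs2231142": 1,
                   "cyp2c9_star2": 1, "cyp2c9_star3": 0},
}

for name, dosage in subjects.items():
    for scheme in ("table8_weighted", "text_ordinal"):
        p = sp.build_profile(name, dosage, scheme=scheme)
        print(f"{name:>10} [{scheme:>15}] diplotype(s)={str(p.slco1b1):<14} "
              f"phenotype={p.slco1b1.phenotype:<9} score={p.burden_score} "
              f"category={p.burden_category}")

print()
print("The double heterozygote is *1/*15 or *37/*5 depending on phase; both")
print("haplotype pairs carry one 521C allele, so the function class (and the")
print("score) is phase-independent.  Under the weighted scheme any reduced-")
print("function phenotype scores 2, pushing a lone 'decreased' into the high-")
print("burden category; the ordinal scheme keeps it low-burden.")
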