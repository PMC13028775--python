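"""SLCO1B1 diplotype calling, carrier coding, and the cumulative PGx burden score.

The pharmacogene panel covers three genes governing statin disposition:

* **SLCO1B1** (hepatic uptake transporter OATP1B1), modelled through a
  diplotype over four haplotypes defined by two common coding SNPs,
  c.388A>G (rs2306283) and c.521T>C (rs4149056).  Every haplotype carrying
  the 521C allele (*5, *15) has reduced transporter function, so the CPIC-style
  function phenotype (normal / decreased / poor) depends only on the number
  of 521C alleles carried — a fact this module exploits to call phenotypes
  from unphased genotypes without ambiguity.
* **ABCG2** (efflux transporter BCRP), c.421C>A (rs2231142), coded under a
  dominant carrier model because variant homozygotes are rare.
* **CYP2C9**, reduced-function alleles *2 and *3, likewise collapsed into a
  single gene-level dominant carrier flag.

The cumulative PGx burden score is the sum of an SLCO1B1 phenotype component
and the two carrier flags.  Two scoring schemes are implemented:

* ``text_ordinal`` — normal 0, decreased 1, poor 2;
* ``table8_weighted`` (default) — normal 0, decreased or poor 2, i.e. any
  reduced-function SLCO1B1 phenotype receives the full gene weight.

The score ranges 0–4 and is dichotomised as *low* (0–1) vs *high* (2–4).
Note the dichotomisation is scheme-dependent for subjects whose only risk
component is a decreased-function SLCO1B1 phenotype (score 1 vs 2).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Variant panel

SLCO1B1_521 = "rs4149056"
SLCO1B1_388 = "rs2306283"
ABCG2_421 = "rs2231142"
CYP2C9_STAR2 = "cyp2c9_star2"
CYP2C9_STAR3 = "cyp2c9_star3"


@dataclass(frozen=True)
class VariantDef:
    key: str
    gene: str
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def coord_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


#: The five-locus panel.  The CYP2C9*3 rsID is configurable at I/O time (see
#: :mod:`statin_pgx.io`); the dosage keys used throughout the package are the
#: ``key`` fields below.
PANEL: dict[str, VariantDef] = {
    SLCO1B1_521: VariantDef(SLCO1B1_521, "SLCO1B1", "rs4149056", "12", 21331549, "T", "C"),
    SLCO1B1_388: VariantDef(SLCO1B1_388, "SLCO1B1", "rs2306283", "12", 21329738, "A", "G"),
    ABCG2_421: VariantDef(ABCG2_421, "ABCG2", "rs2231142", "4", 89052323, "G", "T"),
    CYP2C9_STAR2: VariantDef(CYP2C9_STAR2, "CYP2C9", "rs1799853", "10", 96702047, "C", "T"),
    CYP2C9_STAR3: VariantDef(CYP2C9_STAR3, "CYP2C9", "rs4986893", "10", 96540410, "A", "C"),
}

PANEL_VARIANTS: tuple[str, ...] = tuple(PANEL)

SCHEMES = ("text_ordinal", "table8_weighted")
DEFAULT_SCHEME = "table8_weighted"

#: SLCO1B1 phenotype points per scheme.
PHENOTYPE_POINTS: dict[str, dict[str, int]] = {
    "text_ordinal": {"normal": 0, "decreased": 1, "poor": 2},
    "table8_weighted": {"normal": 0, "decreased": 2, "poor": 2},
}

#: Function phenotype implied by the c.521T>C dosage (count of C alleles).
PHENOTYPE_BY_521: dict[int, str] = {0: "normal", 1: "decreased", 2: "poor"}

# Haplotypes as (388G allele, 521C allele) bit pairs.
_HAP_NAME = {(0, 0): "*1", (1, 0): "*37", (0, 1): "*5", (1, 1): "*15"}
_HAP_BITS = {v: k for k, v in _HAP_NAME.items()}
_STAR_ORDER = ("*1", "*37", "*5", "*15")


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return bool(math.isnan(float(x)))
    except (TypeError, ValueError):
        return False


def _check_dosage(x, what: str) -> int:
    xi = int(x)
    if xi != x or xi not in (0, 1, 2):
        raise ValueError(f"{what} dosage must be 0, 1, 2 or missing; got {x!r}")
    return xi


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GenotypeRecord:
    """Allele dosages at the five panel variants for one subject.

    ``dosage`` maps panel variant keys to the count of minor/variant alleles
    (0, 1, 2) or ``None`` for missing.
    """

    subject_id: str
    dosage: Mapping[str, Optional[int]]


@dataclass(frozen=True)
class SlcoDiplotype:
    """All star-allele diplotypes consistent with the observed dosages.

    With unphased data a 388/521 double heterozygote is compatible with two
    phasings (*1/*15 and *37/*5); both fall in the same function class, so
    ``phenotype`` is always well defined when the dosages are.
    """

    candidate_diplotypes: frozenset
    phenotype: str  # normal | decreased | poor | unknown
    phased: bool = False

    def __str__(self) -> str:  # e.g. "*1/*15|*37/*5"
        def key(pair):
            return tuple(_STAR_ORDER.index(h) for h in pair)

        return "|".join("/".join(p) for p in sorted(self.candidate_diplotypes, key=key))


@dataclass(frozen=True)
class PgxProfile:
    subject_id: str
    slco1b1: SlcoDiplotype
    slco1b1_points: Optional[int]
    abcg2_carrier: Optional[int]
    cyp2c9_carrier: Optional[int]
    burden_score: Optional[int]
    burden_category: str  # low | high | unscored
    scheme: str

    @property
    def scored(self) -> bool:
        return self.burden_score is not None


# ---------------------------------------------------------------------------
# Operations


def call_slco1b1_diplotype(
    d521, d388, phased_haplotypes: Optional[Sequence[str]] = None
) -> SlcoDiplotype:
    """Call the SLCO1B1 diplotype set and function phenotype.

    Parameters
    ----------
    d521, d388
        Variant-allele dosages at c.521T>C and c.388A>G (0, 1, 2, or missing).
    phased_haplotypes
        Optional pair of star-allele names (e.g. ``("*1", "*15")``) when phase
        is known; the candidate set is then a singleton.  Must be consistent
        with the dosages.
    """
    if _is_missing(d521) or _is_missing(d388):
        return SlcoDiplotype(frozenset(), "unknown", phased=False)
    c = _check_dosage(d521, "c.521T>C")
    g = _check_dosage(d388, "c.388A>G")

    if phased_haplotypes is not None:
        h1, h2 = phased_haplotypes
        bits = (_HAP_BITS[h1], _HAP_BITS[h2])
        if bits[0][1] + bits[1][1] != c or bits[0][0] + bits[1][0] != g:
            raise ValueError(
                f"phased haplotypes {h1}/{h2} inconsistent with dosages "
                f"d521={c}, d388={g}"
            )
        pair = tuple(sorted((h1, h2), key=_STAR_ORDER.index))
        return SlcoDiplotype(frozenset({pair}), PHENOTYPE_BY_521[c], phased=True)

    candidates = set()
    for b1, b2 in itertools.combinations_with_replacement(_HAP_BITS.values(), 2):
        if b1[1] + b2[1] == c and b1[0] + b2[0] == g:
            pair = tuple(sorted((_HAP_NAME[b1], _HAP_NAME[b2]), key=_STAR_ORDER.index))
            candidates.add(pair)
    assert candidates, "every valid dosage pair admits at least one diplotype"
    return SlcoDiplotype(frozenset(candidates), PHENOTYPE_BY_521[c], phased=False)


def phenotype_points(slco, scheme: str = DEFAULT_SCHEME) -> Optional[int]:
    """SLCO1B1 burden-score component for a phenotype (or SlcoDiplotype).

    Returns ``None`` for an unknown phenotype (the subject is then excluded
    from scoring, with a log entry, rather than imputed).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scoring scheme {scheme!r}; expected one of {SCHEMES}")
    phenotype = slco.phenotype if isinstance(slco, SlcoDiplotype) else slco
    if phenotype == "unknown":
        return None
    return PHENOTYPE_POINTS[scheme][phenotype]


def carrier_code(dosage) -> Optional[int]:
    """Dominant-model carrier flag: 0 for non-carriers, 1 for any variant allele."""
    if _is_missing(dosage):
        return None
    return 1 if _check_dosage(dosage, "carrier") > 0 else 0


def burden_score(
    slco1b1_points: Optional[int],
    abcg2_carrier: Optional[int],
    cyp2c9_carrier: Optional[int],
) -> tuple[Optional[int], str]:
    """Sum the three components; category low iff score <= 1, else high.

    Any unknown component leaves the profile unscored.
    """
    if slco1b1_points is None or abcg2_carrier is None or cyp2c9_carrier is None:
        return None, "unscored"
    score = int(slco1b1_points) + int(abcg2_carrier) + int(cyp2c9_carrier)
    return score, ("low" if score <= 1 else "high")


def build_profile(
    subject_id: str,
    dosage: Mapping[str, Optional[int]],
    scheme: str = DEFAULT_SCHEME,
    phased_haplotypes: Optional[Sequence[str]] = None,
) -> PgxProfile:
    """Assemble the full PgxProfile for one subject from panel dosages."""
    slco = call_slco1b1_diplotype(
        dosage.get(SLCO1B1_521), dosage.get(SLCO1B1_388), phased_haplotypes
    )
    pts = phenotype_points(slco, scheme)
    abcg2 = carrier_code(dosage.get(ABCG2_421))
    d2, d3 = dosage.get(CYP2C9_STAR2), dosage.get(CYP2C9_STAR3)
    # gene-level carrier: a single observed variant allele suffices even if the
    # other CYP2C9 locus is missing; both observed reference is required for 0.
    c2, c3 = carrier_code(d2), carrier_code(d3)
    if c2 == 1 or c3 == 1:
        cyp = 1
    elif c2 == 0 and c3 == 0:
        cyp = 0
    else:
        cyp = None
    score, category = burden_score(pts, abcg2, cyp)
    if score is None:
        log.info("subject %s excluded from scoring (missing genotype component)", subject_id)
    return PgxProfile(subject_id, slco, pts, abcg2, cyp, score, category, scheme)


def profile_from_record(record: GenotypeRecord, scheme: str = DEFAULT_SCHEME) -> PgxProfile:
    return build_profile(record.subject_id, record.dosage, scheme)


# ---------------------------------------------------------------------------
# Cohort-level (vectorised) scoring


def _diplotype_string_table() -> dict[tuple[int, int], str]:
    return {
        (c, g): str(call_slco1b1_diplotype(c, g))
        for c in (0, 1, 2)
        for g in (0, 1, 2)
    }


_DIPLO_STR = _diplotype_string_table()


def score_cohort(genotypes: pd.DataFrame, scheme: str = DEFAULT_SCHEME) -> pd.DataFrame:
    """Score every subject in a wide genotype table.

    Parameters
    ----------
    genotypes
        One row per subject with a ``subject_id`` column and one dosage column
        per panel variant key (NaN = missing).
    scheme
        Burden-score scheme (``table8_weighted`` default).

    Returns
    -------
    DataFrame with diplotype string, phenotype, component points, score,
    category, a ``scored`` flag and an ``exclusion_reason`` for unscored rows.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scoring scheme {scheme!r}; expected one of {SCHEMES}")
    missing_cols = [v for v in PANEL_VARIANTS if v not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks panel variant column(s): {missing_cols}")

    d521 = genotypes[SLCO1B1_521].to_numpy(dtype=float)
    d388 = genotypes[SLCO1B1_388].to_numpy(dtype=float)
    dabc = genotypes[ABCG2_421].to_numpy(dtype=float)
    d2 = genotypes[CYP2C9_STAR2].to_numpy(dtype=float)
    d3 = genotypes[CYP2C9_STAR3].to_numpy(dtype=float)
    for name, arr in ((SLCO1B1_521, d521), (SLCO1B1_388, d388), (ABCG2_421, dabc),
                      (CYP2C9_STAR2, d2), (CYP2C9_STAR3, d3)):
        bad = ~np.isnan(arr) & ~np.isin(arr, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError(f"invalid dosage values at {name}: {np.unique(arr[bad])}")

    slco_known = ~np.isnan(d521) & ~np.isnan(d388)
    phen = np.full(len(d521), "unknown", dtype=object)
    names = np.array(["normal", "decreased", "poor"], dtype=object)
    phen[slco_known] = names[d521[slco_known].astype(int)]

    pts_map = PHENOTYPE_POINTS[scheme]
    pts = np.where(
        slco_known,
        np.where(d521 == 0, pts_map["normal"],
                 np.where(d521 == 1, pts_map["decreased"], pts_map["poor"])),
        np.nan,
    )
    abcg2 = np.where(np.isnan(dabc), np.nan, (dabc > 0).astype(float))
    any_cyp = (d2 > 0) | (d3 > 0)  # NaN comparisons are False
    both_ref = (d2 == 0) & (d3 == 0)
    cyp = np.where(any_cyp, 1.0, np.where(both_ref, 0.0, np.nan))

    score = pts + abcg2 + cyp
    scored = ~np.isnan(score)
    category = np.where(scored, np.where(score <= 1, "low", "high"), "unscored")

    diplo = np.array([
        _DIPLO_STR[(int(c), int(g))] if ok else ""
        for c, g, ok in zip(d521, d388, slco_known)
    ], dtype=object)

    reasons = np.full(len(score), "", dtype=object)
    reasons[~slco_known] = "missing SLCO1B1 genotype"
    reasons[slco_known & np.isnan(abcg2)] = "missing ABCG2 genotype"
    reasons[slco_known & ~np.isnan(abcg2) & np.isnan(cyp)] = "missing CYP2C9 genotype"

    n_excl = int((~scored).sum())
    if n_excl:
        log.info("%d subject(s) excluded from burden scoring (missing genotypes)", n_excl)

    return pd.DataFrame({
        "subject_id": genotypes["subject_id"].to_numpy(),
        "diplotypes": diplo,
        "phenotype": phen,
        "slco1b1_points": pts,
        "abcg2_carrier": abcg2,
        "cyp2c9_carrier": cyp,
        "burden_score": score,
        "burden_category": category,
        "scored": scored,
        "exclusion_reason": reasons,
        "scheme": scheme,
    })


def records_to_frame(records: Sequence[GenotypeRecord]) -> pd.DataFrame:
    """Convert GenotypeRecord dataclasses to the wide genotype table."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        for v in PANEL_VARIANTS:
            d = r.dosage.get(v)
            row[v] = np.nan if d is None else d
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *PANEL_VARIANTS])


def frame_to_records(genotypes: pd.DataFrame) -> list[GenotypeRecord]:
    recs = []
    for row in genotypes.itertuples(index=False):
        d = {}
        for v in PANEL_VARIANTS:
            x = getattr(row, v)
            d[v] = None if _is_missing(x) else int(x)
        recs.append(GenotypeRecord(str(row.subject_id), d))
    return recs
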