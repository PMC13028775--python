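"""Rule-based adverse-outcome phenotyping for statin users.

Definitions applied per subject:

* **CK elevation** — any creatine-kinase value at or above the sex-specific
  upper limit of normal (ULN): 120 IU/L for women, 180 IU/L for men.
* **Statin intolerance** (``rule="default"``) — a biochemical clause,
  max CK >= 3×ULN *and* (myopathy diagnosis *or* regimen de-escalation),
  **or** a behavioural clause, more than 3 drug-or-dose switches, which does
  not require any CK measurement.  Under ``rule="strict"`` the 3×CK elevation
  is required for all three sub-clauses (myopathy, de-escalation, or >3
  switches).
* **Myopathy / liver injury** — consumed as EHR-style diagnosis flags; no
  numeric liver threshold is applied (ALT/AST are descriptive only).
* **Non-adherence** — MPR < 0.80 from the regimen course.
* **Composite adverse outcome** — myopathy OR liver injury OR non-adherence.

Missing inputs degrade gracefully: an empty CK series or unknown sex makes
the biochemical clause false (logged), never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regimen import RegimenCourse

log = logging.getLogger(__name__)

INTOLERANCE_RULES = ("default", "strict")

#: Sex-specific CK upper limits of normal, IU/L.
CK_ULN = {"female": 120.0, "male": 180.0}


@dataclass(frozen=True)
class LabSeries:
    """Dated laboratory values for one subject (values in IU/L or U/L)."""

    subject_id: str
    sex: Optional[str]  # "male" | "female" | None
    ck_values: Sequence[float] = ()
    alt_values: Sequence[float] = ()
    ast_values: Sequence[float] = ()


@dataclass(frozen=True)
class OutcomeFlags:
    subject_id: str
    ck_elevated: bool
    ck_evaluable: bool
    intolerance: bool
    myopathy: bool
    liver_injury: bool
    nonadherent: bool
    composite: bool


def ck_uln(sex: Optional[str]) -> Optional[float]:
    """Sex-specific CK upper limit of normal; None when sex is missing."""
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        log.info("missing sex: CK rules unevaluable")
        return None
    try:
        return CK_ULN[str(sex).lower()]
    except KeyError:
        raise ValueError(f"sex must be 'male' or 'female'; got {sex!r}") from None


def ck_elevated_flag(labs: LabSeries) -> tuple[bool, bool]:
    """(elevated, evaluable): any CK >= 1×ULN; unevaluable without sex or CK."""
    uln = ck_uln(labs.sex)
    values = [v for v in labs.ck_values if not (v is None or np.isnan(v))]
    if uln is None or not values:
        return False, False
    return max(values) >= uln, True


def intolerance_flag(
    labs: LabSeries, course: RegimenCourse, myopathy: bool, rule: str = "default"
) -> bool:
    """Statin-intolerance rule (see module docstring for the two readings)."""
    if rule not in INTOLERANCE_RULES:
        raise ValueError(f"unknown intolerance rule {rule!r}; expected {INTOLERANCE_RULES}")
    uln = ck_uln(labs.sex)
    values = [v for v in labs.ck_values if not (v is None or np.isnan(v))]
    ck3 = bool(values) and uln is not None and max(values) >= 3.0 * uln
    if not values:
        log.info("subject %s: no CK values; biochemical clause false", labs.subject_id)
    clinical = bool(myopathy) or course.modification == "de_escalation"
    many_switches = course.switch_count > 3
    if rule == "strict":
        return ck3 and (clinical or many_switches)
    return (ck3 and clinical) or many_switches


def composite_flag(myopathy: bool, liver_injury: bool, nonadherent: bool) -> bool:
    """Composite adverse outcome: any of the three component events."""
    return bool(myopathy) or bool(liver_injury) or bool(nonadherent)


def phenotype_cohort(
    clinical: pd.DataFrame,
    labs: pd.DataFrame,
    courses: pd.DataFrame,
    rule: str = "default",
) -> pd.DataFrame:
    """Apply all outcome rules across a cohort.

    Parameters
    ----------
    clinical
        One row per subject: subject_id, sex, myopathy_dx, liver_injury.
    labs
        Long table: subject_id, day, analyte ('ck'|'alt'|'ast'), value.
    courses
        Output of :func:`statin_pgx.regimen.derive_courses`.
    rule
        Intolerance rule variant, ``"default"`` or ``"strict"``.

    Returns
    -------
    One row per subject in ``clinical`` with all outcome flags.
    """
    if rule not in INTOLERANCE_RULES:
        raise ValueError(f"unknown intolerance rule {rule!r}; expected {INTOLERANCE_RULES}")
    df = clinical[["subject_id", "sex", "myopathy_dx", "liver_injury"]].copy()

    ck = labs[labs["analyte"] == "ck"]
    max_ck = ck.groupby("subject_id")["value"].max()
    df = df.merge(max_ck.rename("max_ck"), on="subject_id", how="left")
    df = df.merge(
        courses[["subject_id", "modification", "switch_count", "adherent"]],
        on="subject_id", how="left",
    )
    df["switch_count"] = df["switch_count"].fillna(0).astype(int)
    df["modification"] = df["modification"].fillna("no_change")
    df["adherent"] = df["adherent"].fillna(False)

    uln = df["sex"].map(CK_ULN)
    evaluable = uln.notna() & df["max_ck"].notna()
    n_uneval = int((~evaluable).sum())
    if n_uneval:
        log.info("%d subject(s) with unevaluable CK rules (missing sex or CK)", n_uneval)
    ck1 = evaluable & (df["max_ck"] >= uln)
    ck3 = evaluable & (df["max_ck"] >= 3.0 * uln)
    clinical_clause = df["myopathy_dx"].astype(bool) | (df["modification"] == "de_escalation")
    many_switches = df["switch_count"] > 3
    if rule == "strict":
        intol = ck3 & (clinical_clause | many_switches)
    else:
        intol = (ck3 & clinical_clause) | many_switches

    out = pd.DataFrame({
        "subject_id": df["subject_id"],
        "ck_elevated": ck1.fillna(False),
        "ck_evaluable": evaluable,
        "intolerance": intol.fillna(False),
        "myopathy": df["myopathy_dx"].astype(bool),
        "liver_injury": df["liver_injury"].astype(bool),
        "nonadherent": ~df["adherent"].astype(bool),
    })
    out["composite"] = out["myopathy"] | out["liver_injury"] | out["nonadherent"]
    return out
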