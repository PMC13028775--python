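"""Statin intensity classification, regimen-course derivation, and MPR adherence.

A subject's pharmacy dispensing history is reduced to:

* an intensity-labelled trajectory, using the ACC/AHA low/moderate/high
  statin-intensity dose bands (printed ranges treated as closed intervals;
  doses outside every band are ``unclassifiable``);
* a three-level regimen-modification outcome — *escalation* / *de_escalation*
  / *no_change* — defined by the **first** transition between classified
  intensity levels within follow-up (the time-to-event analysis refers to the
  same transition);
* ``switch_count``: the number of any drug-or-dose changes between
  consecutive fills, regardless of intensity (consumed by the behavioural
  arm of the statin-intolerance rule);
* the medication possession ratio, MPR = days supplied within follow-up /
  follow-up days, capped at 1.0, with MPR >= 0.80 defining adherence.

Same-intensity drug or dose switches map to ``no_change`` for the three-level
outcome but do increment ``switch_count``.  Subjects with no intensity
transition are censored at ``followup_days``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LEVELS = ("low", "moderate", "high")
_LEVEL_CODE = {lv: i for i, lv in enumerate(LEVELS)}
UNCLASSIFIABLE = "unclassifiable"

MODIFICATION_CLASSES = ("escalation", "de_escalation", "no_change")

#: ACC/AHA intensity dose bands (mg/day), closed intervals.
INTENSITY_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "atorvastatin": {"moderate": (10, 20), "high": (40, 80)},
    "rosuvastatin": {"moderate": (5, 10), "high": (20, 40)},
    "simvastatin": {"low": (10, 10), "moderate": (20, 40)},
    "pravastatin": {"low": (10, 20), "moderate": (40, 80)},
    "fluvastatin": {"low": (20, 40), "moderate": (80, 80)},
}

STATINS = tuple(INTENSITY_TABLE)


def available_levels(drug: str) -> tuple[str, ...]:
    """Intensity levels attainable with the given statin."""
    if drug not in INTENSITY_TABLE:
        raise ValueError(f"unknown statin: {drug!r}")
    return tuple(lv for lv in LEVELS if lv in INTENSITY_TABLE[drug])


def classify_intensity(drug: str, dose_mg: float) -> str:
    """Map a (drug, dose) pair to low/moderate/high or ``unclassifiable``."""
    if drug not in INTENSITY_TABLE:
        raise ValueError(f"unknown statin: {drug!r}")
    if not dose_mg > 0:
        raise ValueError(f"dose must be positive; got {dose_mg!r}")
    for level, (lo, hi) in INTENSITY_TABLE[drug].items():
        if lo <= dose_mg <= hi:
            return level
    return UNCLASSIFIABLE


@dataclass(frozen=True)
class DispensingEvent:
    subject_id: str
    date: int  # day index from index date (first fill), or raw day
    drug: str
    dose_mg: float
    days_supplied: int


@dataclass(frozen=True)
class RegimenCourse:
    subject_id: str
    trajectory: tuple  # (day, drug, dose_mg, intensity) tuples, sorted
    modification: str
    switch_count: int
    time_to_first_change: int  # censored at followup_days when no transition
    event: bool  # True iff an intensity transition was observed
    mpr: float
    adherent: bool
    baseline_intensity: str = UNCLASSIFIABLE


EventsLike = Union[Sequence[DispensingEvent], pd.DataFrame]


def _as_tuples(events: EventsLike):
    if isinstance(events, pd.DataFrame):
        it = zip(events["subject_id"], events["date"], events["drug"],
                 events["dose_mg"], events["days_supplied"])
        return [(str(s), int(d), str(g), float(m), int(ds)) for s, d, g, m, ds in it]
    return [(str(e.subject_id), int(e.date), str(e.drug), float(e.dose_mg),
             int(e.days_supplied)) for e in events]


def compute_mpr(events: EventsLike, followup_days: int) -> tuple[float, bool]:
    """Medication possession ratio and the >=0.80 adherence flag.

    Days supplied are truncated at the end of follow-up and summed without
    overlap de-duplication (simple MPR, matching the stated formula); the
    ratio is capped at 1.0.  No events gives MPR 0 / non-adherent.
    """
    if followup_days <= 0:
        raise ValueError("followup_days must be positive")
    rows = _as_tuples(events)
    if not rows:
        return 0.0, False
    t0 = min(r[1] for r in rows)
    total = 0.0
    for _, date, _, _, days in rows:
        t = date - t0
        if t < followup_days:
            total += min(days, followup_days - t)
    mpr = min(total / followup_days, 1.0)
    return mpr, mpr >= 0.80


def derive_course(events: EventsLike, followup_days: int) -> RegimenCourse:
    """Derive the regimen course for a single subject.

    The first event defines the index date (day 0); events beyond follow-up
    are ignored with a log entry.  Unclassifiable intensities are skipped for
    transition detection but still count as switches when drug/dose differ.
    """
    rows = sorted(_as_tuples(events), key=lambda r: r[1])
    if not rows:
        raise ValueError("cannot derive a regimen course from an empty event list")
    subject = rows[0][0]
    t0 = rows[0][1]
    kept = [(d - t0, drug, dose) for _, d, drug, dose, _ in rows if d - t0 < followup_days]
    n_beyond = len(rows) - len(kept)
    if n_beyond:
        log.info("subject %s: %d event(s) beyond follow-up window ignored", subject, n_beyond)

    trajectory = tuple((t, drug, dose, classify_intensity(drug, dose)) for t, drug, dose in kept)

    switch_count = 0
    modification = "no_change"
    time_to_change = followup_days
    event = False
    prev_drug_dose = None
    prev_level: Optional[int] = None
    for t, drug, dose, intensity in trajectory:
        if prev_drug_dose is not None and (drug, dose) != prev_drug_dose:
            switch_count += 1
        prev_drug_dose = (drug, dose)
        if intensity == UNCLASSIFIABLE:
            continue
        code = _LEVEL_CODE[intensity]
        if prev_level is not None and code != prev_level and not event:
            modification = "escalation" if code > prev_level else "de_escalation"
            time_to_change = t
            event = True
        prev_level = code

    baseline = next((iv for *_, iv in trajectory if iv != UNCLASSIFIABLE), UNCLASSIFIABLE)
    mpr, adherent = compute_mpr(events, followup_days)
    return RegimenCourse(subject, trajectory, modification, switch_count,
                         time_to_change, event, mpr, adherent, baseline)


def derive_courses(events: pd.DataFrame, followup_days: int) -> pd.DataFrame:
    """Vectorised cohort version of :func:`derive_course`.

    Parameters
    ----------
    events
        Dispensing table with columns subject_id, date (day index), drug,
        dose_mg, days_supplied; multiple subjects allowed.

    Returns
    -------
    One row per subject: modification, switch_count, time_to_first_change,
    event, mpr, adherent, baseline_intensity.
    """
    if followup_days <= 0:
        raise ValueError("followup_days must be positive")
    if events.empty:
        raise ValueError("cannot derive regimen courses from an empty event table")

    df = events[["subject_id", "date", "drug", "dose_mg", "days_supplied"]].copy()
    df = df.sort_values(["subject_id", "date"], kind="mergesort").reset_index(drop=True)
    df["t"] = df["date"] - df.groupby("subject_id")["date"].transform("min")

    # intensity lookup on unique (drug, dose) pairs
    pairs = df[["drug", "dose_mg"]].drop_duplicates()
    pairs["intensity"] = [classify_intensity(d, m) for d, m in
                          zip(pairs["drug"], pairs["dose_mg"])]
    df = df.merge(pairs, on=["drug", "dose_mg"], how="left")

    all_subjects = df["subject_id"].drop_duplicates()

    n_beyond = int((df["t"] >= followup_days).sum())
    if n_beyond:
        log.info("%d event(s) beyond follow-up window ignored", n_beyond)
    # MPR on truncated supply
    df["supply_trunc"] = np.where(
        df["t"] < followup_days,
        np.minimum(df["days_supplied"], followup_days - df["t"]),
        0,
    )
    mpr = (df.groupby("subject_id")["supply_trunc"].sum() / followup_days).clip(upper=1.0)

    df = df[df["t"] < followup_days]
    grp = df.groupby("subject_id", sort=False)

    switch = (
        (df["drug"] != grp["drug"].shift(1)) | (df["dose_mg"] != grp["dose_mg"].shift(1))
    ) & grp.cumcount().gt(0)
    switch_count = switch.groupby(df["subject_id"]).sum()

    lv = df["intensity"].map(_LEVEL_CODE)  # NaN for unclassifiable
    prev_lv = lv.groupby(df["subject_id"]).shift(1).groupby(df["subject_id"]).ffill()
    transition = lv.notna() & prev_lv.notna() & (lv != prev_lv)
    tr = df.loc[transition, ["subject_id", "t"]].copy()
    tr["direction"] = np.where(lv[transition] > prev_lv[transition],
                               "escalation", "de_escalation")
    first = tr.groupby("subject_id", sort=False).first()

    baseline = df.loc[lv.notna(), ["subject_id", "intensity"]].groupby(
        "subject_id", sort=False).first()["intensity"]

    out = pd.DataFrame(index=pd.Index(all_subjects, name="subject_id"))
    out["modification"] = first["direction"].reindex(out.index).fillna("no_change")
    out["event"] = first["direction"].reindex(out.index).notna()
    out["time_to_first_change"] = (
        first["t"].reindex(out.index).fillna(followup_days).astype(int)
    )
    out["switch_count"] = switch_count.reindex(out.index).fillna(0).astype(int)
    out["mpr"] = mpr.reindex(out.index).fillna(0.0)
    out["adherent"] = out["mpr"] >= 0.80
    out["baseline_intensity"] = baseline.reindex(out.index).fillna(UNCLASSIFIABLE)
    return out.reset_index()
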