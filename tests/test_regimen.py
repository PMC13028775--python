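"""Intensity classification, course derivation and MPR adherence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import statin_pgx as sp
from statin_pgx.regimen import UNCLASSIFIABLE, classify_intensity


@pytest.mark.parametrize(
    "drug,dose,expected",
    [
        ("atorvastatin", 40, "high"),
        ("atorvastatin", 80, "high"),
        ("atorvastatin", 10, "moderate"),
        ("atorvastatin", 20, "moderate"),     # bounds inclusive
        ("rosuvastatin", 5, "moderate"),
        ("rosuvastatin", 20, "high"),
        ("simvastatin", 10, "low"),
        ("simvastatin", 40, "moderate"),
        ("pravastatin", 15, "low"),
        ("pravastatin", 40, "moderate"),
        ("fluvastatin", 80, "moderate"),
        ("fluvastatin", 20, "low"),
        ("atorvastatin", 5, UNCLASSIFIABLE),  # below every band
        ("atorvastatin", 30, UNCLASSIFIABLE), # between bands
        ("simvastatin", 80, UNCLASSIFIABLE),  # above every band
    ],
)
def test_classify_intensity_bands(drug, dose, expected):
    assert classify_intensity(drug, dose) == expected


def test_classify_intensity_unknown_drug_named():
    with pytest.raises(ValueError, match="lovastatin"):
        classify_intensity("lovastatin", 20)


def test_classify_intensity_nonpositive_dose():
    with pytest.raises(ValueError, match="positive"):
        classify_intensity("atorvastatin", 0)


def _events(rows):
    return [sp.DispensingEvent("s1", d, drug, dose, supply)
            for d, drug, dose, supply in rows]


def test_escalation_first_transition():
    ev = _events([(0, "atorvastatin", 20, 30), (90, "atorvastatin", 40, 30)])
    course = sp.derive_course(ev, 365)
    assert course.modification == "escalation"
    assert course.time_to_first_change == 90
    assert course.event
    assert course.switch_count == 1
    assert course.baseline_intensity == "moderate"


def test_constant_regimen_censored():
    ev = _events([(0, "atorvastatin", 20, 30), (60, "atorvastatin", 20, 30)])
    course = sp.derive_course(ev, 365)
    assert course.modification == "no_change"
    assert not course.event
    assert course.time_to_first_change == 365
    assert course.switch_count == 0


def test_same_intensity_switch_is_no_change_but_counts():
    ev = _events([(0, "atorvastatin", 20, 30), (30, "rosuvastatin", 10, 30)])
    course = sp.derive_course(ev, 365)
    assert course.modification == "no_change"
    assert course.switch_count == 1


def test_first_transition_fixes_class_despite_reversal():
    ev = _events([
        (0, "atorvastatin", 20, 30),
        (60, "atorvastatin", 40, 30),
        (120, "atorvastatin", 20, 30),
    ])
    course = sp.derive_course(ev, 365)
    assert course.modification == "escalation"
    assert course.time_to_first_change == 60


def test_label_symmetry_under_reversal():
    """Reversing a two-step escalation trajectory yields de-escalation."""
    up = _events([(0, "atorvastatin", 20, 30), (90, "atorvastatin", 40, 30)])
    down = _events([(0, "atorvastatin", 40, 30), (90, "atorvastatin", 20, 30)])
    assert sp.derive_course(up, 365).modification == "escalation"
    assert sp.derive_course(down, 365).modification == "de_escalation"


def test_unclassifiable_skipped_for_transitions():
    ev = _events([
        (0, "atorvastatin", 20, 30),
        (30, "atorvastatin", 30, 30),   # unclassifiable, still a switch
        (60, "atorvastatin", 40, 30),
    ])
    course = sp.derive_course(ev, 365)
    assert course.modification == "escalation"
    assert course.time_to_first_change == 60
    assert course.switch_count == 2


def test_empty_events_raise():
    with pytest.raises(ValueError, match="empty"):
        sp.derive_course([], 365)


def test_events_beyond_followup_ignored():
    ev = _events([(0, "atorvastatin", 20, 30), (400, "atorvastatin", 40, 30)])
    course = sp.derive_course(ev, 365)
    assert course.modification == "no_change"


@pytest.mark.parametrize(
    "supplied,followup,mpr,adherent",
    [
        (292, 365, 292 / 365, True),   # exactly the 0.80 boundary
        (365, 365, 1.0, True),
        (180, 365, 180 / 365, False),
        (400, 365, 1.0, True),         # capped
    ],
)
def test_mpr_arithmetic(supplied, followup, mpr, adherent):
    ev = _events([(0, "atorvastatin", 20, supplied)])
    got_mpr, got_adherent = sp.compute_mpr(ev, followup)
    assert got_mpr == pytest.approx(mpr)
    assert got_adherent is adherent


def test_mpr_truncates_supply_at_followup_end():
    ev = _events([(0, "atorvastatin", 20, 30), (350, "atorvastatin", 20, 30)])
    mpr, _ = sp.compute_mpr(ev, 365)
    assert mpr == pytest.approx((30 + 15) / 365)


def test_mpr_no_events():
    assert sp.compute_mpr([], 365) == (0.0, False)


# --------------------------------------------------------------------------
# brute-force oracle for random trajectories

_DOSES = [5, 10, 20, 30, 40, 80]
_DRUGS = list(sp.INTENSITY_TABLE)

trajectory_strategy = st.lists(
    st.tuples(st.integers(0, 400), st.sampled_from(_DRUGS), st.sampled_from(_DOSES)),
    min_size=1, max_size=6,
)


def _oracle(rows, followup):
    """Independent scan over consecutive classified-intensity pairs.

    Same-day fills keep their input order (stable date sort), matching the
    course derivation's tie-break.
    """
    rows = sorted(rows, key=lambda r: r[0])
    t0 = rows[0][0]
    rows = [(t - t0, drug, dose) for t, drug, dose in rows if t - t0 < followup]
    order = {"low": 0, "moderate": 1, "high": 2}
    switches = sum(
        1 for prev, cur in zip(rows, rows[1:]) if (prev[1], prev[2]) != (cur[1], cur[2])
    )
    classified = [
        (t, order[classify_intensity(drug, dose)])
        for t, drug, dose in rows
        if classify_intensity(drug, dose) != UNCLASSIFIABLE
    ]
    for (t1, l1), (t2, l2) in zip(classified, classified[1:]):
        if l1 != l2:
            cls = "escalation" if l2 > l1 else "de_escalation"
            return cls, t2, True, switches
    return "no_change", followup, False, switches


@given(trajectory_strategy)
def test_derive_course_matches_bruteforce(rows):
    followup = 365
    ev = _events([(t, drug, dose, 30) for t, drug, dose in rows])
    course = sp.derive_course(ev, followup)
    cls, t, event, switches = _oracle([(t, d, m) for t, d, m in rows], followup)
    assert course.modification == cls
    assert course.time_to_first_change == t
    assert course.event is event
    assert course.switch_count == switches


@given(st.lists(trajectory_strategy, min_size=1, max_size=8))
def test_cohort_derivation_matches_per_subject(trajectories):
    """Vectorised cohort path equals the single-subject path, and every
    subject gets exactly one modification class (partition invariant)."""
    frames = []
    for i, rows in enumerate(trajectories):
        frames.append(pd.DataFrame({
            "subject_id": f"P{i}",
            "date": [r[0] for r in rows],
            "drug": [r[1] for r in rows],
            "dose_mg": [r[2] for r in rows],
            "days_supplied": 30,
        }))
    events = pd.concat(frames, ignore_index=True)
    cohort = sp.derive_courses(events, 365).set_index("subject_id")
    assert len(cohort) == len(trajectories)
    assert cohort["modification"].isin(
        ["escalation", "de_escalation", "no_change"]).all()
    for i, rows in enumerate(trajectories):
        single = sp.derive_course(
            _events([(t, d, m, 30) for t, d, m in rows]), 365)
        row = cohort.loc[f"P{i}"]
        assert row["modification"] == single.modification
        assert row["time_to_first_change"] == single.time_to_first_change
        assert row["switch_count"] == single.switch_count
        assert row["mpr"] == pytest.approx(single.mpr)
        assert bool(row["adherent"]) == single.adherent


@given(st.integers(1, 12), st.integers(10, 60))
def test_mpr_monotone_in_supply(n_fills, supply):
    """MPR is non-decreasing in days supplied and bounded in [0, 1]."""
    ev1 = _events([(30 * i, "atorvastatin", 20, supply) for i in range(n_fills)])
    ev2 = _events([(30 * i, "atorvastatin", 20, supply + 5) for i in range(n_fills)])
    m1, _ = sp.compute_mpr(ev1, 365)
    m2, _ = sp.compute_mpr(ev2, 365)
    assert 0.0 <= m1 <= m2 <= 1.0
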