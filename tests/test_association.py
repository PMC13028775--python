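"""Contingency OR, regression layers, KM closed forms and calibration."""

import math

import numpy as np
import pandas as pd
import pytest

import statin_pgx as sp
from statin_pgx.datasets import REFERENCE_COHORT


def _expand_2x2(table):
    """Rows of individual subjects from [[no_ref, yes_ref], [no_exp, yes_exp]]."""
    rows = []
    for exposed, (no, yes) in enumerate(table):
        rows += [{"exposed": bool(exposed), "y": False}] * no
        rows += [{"exposed": bool(exposed), "y": True}] * yes
    return pd.DataFrame(rows)


class TestContingencyOR:
    def test_reference_counts_arithmetic(self):
        """(no,yes|low,high)=(348,239|187,138): OR=(138*348)/(187*239)."""
        low = REFERENCE_COHORT["composite_by_burden"]["low"]
        high = REFERENCE_COHORT["composite_by_burden"]["high"]
        res = sp.contingency_or([low, high])
        expected = (138 * 348) / (187 * 239)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.estimate == pytest.approx(1.074, abs=1e-3)
        assert res.ci_low < res.estimate < res.ci_high

    def test_symmetric_table_is_null(self):
        res = sp.contingency_or([[10, 10], [10, 10]])
        assert res.estimate == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = sp.contingency_or([[0, 5], [5, 5]])
        # hand formula after +0.5 on every cell
        expected = (5.5 * 0.5) / (5.5 * 5.5)
        assert res.estimate == pytest.approx(expected)
        assert "haldane_anscombe_0.5" in res.flags
        assert math.isfinite(res.estimate)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            sp.contingency_or([[1, 2, 3], [4, 5, 6]])

    def test_ci_symmetric_on_log_scale(self):
        res = sp.contingency_or([[30, 20], [25, 40]])
        assert (math.log(res.estimate) - math.log(res.ci_low)
                ) == pytest.approx(math.log(res.ci_high) - math.log(res.estimate))


class TestLogistic:
    def test_unadjusted_logistic_equals_contingency_or(self):
        """Saturated logistic reproduces the 2x2 odds ratio to 1e-6."""
        table = [[348, 239], [187, 138]]
        data = _expand_2x2(table)
        fit, _ = sp.fit_logistic(data, "y", "exposed")
        assert fit.estimate == pytest.approx(sp.contingency_or(table).estimate,
                                             rel=1e-6)

    def test_degenerate_outcome_raises(self):
        data = pd.DataFrame({"y": [False] * 20, "exposed": [True, False] * 10})
        with pytest.raises(ValueError, match="degenerate"):
            sp.fit_logistic(data, "y", "exposed")

    def test_reference_inversion_reciprocal(self):
        data = _expand_2x2([[50, 30], [40, 45]])
        fwd, _ = sp.fit_logistic(data, "y", "exposed")
        data["flipped"] = ~data["exposed"]
        rev, _ = sp.fit_logistic(data, "y", "flipped")
        assert math.log(fwd.estimate) == pytest.approx(-math.log(rev.estimate),
                                                       abs=1e-9)

    def test_collinear_covariate_dropped_with_report(self):
        data = _expand_2x2([[50, 30], [40, 45]])
        data["dup"] = data["exposed"]
        fit, _ = sp.fit_logistic(data, "y", "exposed", covariates=["dup"])
        assert any(f.startswith("dropped:") for f in fit.flags)


class TestMultinomial:
    def test_two_class_collapse_equals_binary_logistic(self):
        """With one contrast empty the RRR equals a binary logistic OR."""
        rng = np.random.default_rng(7)
        n = 800
        x = rng.random(n) < 0.4
        p = 0.15 + 0.15 * x
        y = np.where(rng.random(n) < p, "de_escalation", "no_change")
        data = pd.DataFrame({"modification": y, "exposed": x})
        mn = sp.fit_multinomial(data, "modification", "exposed",
                                classes=("no_change", "de_escalation"))
        de = [r for r in mn if r.contrast == "de_escalation_vs_no_change"][0]
        binary = data.assign(y=data["modification"] == "de_escalation")
        logit, _ = sp.fit_logistic(binary, "y", "exposed")
        assert de.estimate == pytest.approx(logit.estimate, rel=1e-6)
        assert de.p_value == pytest.approx(logit.p_value, rel=1e-4)

    def test_empty_class_raises_with_name(self):
        data = pd.DataFrame({
            "modification": ["no_change", "escalation"] * 10,
            "exposed": [True, False] * 10,
        })
        with pytest.raises(ValueError, match="de_escalation"):
            sp.fit_multinomial(data, "modification", "exposed")

    def test_separation_flagged_not_penalised(self):
        """A deterministic predictor diverges and is flagged, never shrunk."""
        rng = np.random.default_rng(3)
        n = 400
        myo = rng.random(n) < 0.25
        cls = np.where(myo & (rng.random(n) < 0.6), "de_escalation", "no_change")
        cls[rng.integers(0, n, 30)] = "escalation"
        cls = np.where(~myo & (cls == "de_escalation"), "no_change", cls)
        data = pd.DataFrame({"modification": cls, "myopathy": myo})
        mn = sp.fit_multinomial(data, "modification", "myopathy")
        de = [r for r in mn if r.contrast == "de_escalation_vs_no_change"
              and r.term == "myopathy"][0]
        assert ("separation" in de.flags) or de.estimate > 50


class TestCoxKM:
    def test_km_closed_form_uncensored(self):
        """With every censoring time at follow-up end, KM survival at the
        last event time equals 1 - changed/n exactly."""
        rng = np.random.default_rng(1)
        n = 500
        changed = rng.random(n) < 0.3
        times = np.where(changed, rng.integers(10, 300, n), 365)
        data = pd.DataFrame({
            "time_to_first_change": times, "event": changed,
            "high_burden": rng.random(n) < 0.5,
        })
        res, km, p = sp.fit_persistence_cox(data)
        full = pd.concat(km.values())
        for grp in ("low", "high"):
            sub = data[(data.high_burden) == (grp == "high")]
            expected = 1.0 - sub.event.mean()
            observed = sp.km_survival_at(km[grp], 365)
            assert observed == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_null(self):
        """Duplicating each subject into both groups gives log-rank p=1 and
        an HR confidence interval containing 1."""
        rng = np.random.default_rng(2)
        n = 300
        times = rng.integers(10, 365, n)
        event = rng.random(n) < 0.4
        base = pd.DataFrame({"time_to_first_change": times, "event": event})
        data = pd.concat([base.assign(high_burden=False),
                          base.assign(high_burden=True)], ignore_index=True)
        res, km, p = sp.fit_persistence_cox(data)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_no_events_raises(self):
        data = pd.DataFrame({
            "time_to_first_change": [365] * 10, "event": [False] * 10,
            "high_burden": [True, False] * 5,
        })
        with pytest.raises(ValueError, match="no events"):
            sp.fit_persistence_cox(data)

    def test_reference_inversion_reciprocal(self):
        rng = np.random.default_rng(4)
        n = 800
        g = rng.random(n) < 0.5
        lam = np.where(g, 2.0, 1.0) / 365.0
        t = rng.exponential(1 / lam)
        event = t < 365
        data = pd.DataFrame({"time_to_first_change": np.minimum(t, 365),
                             "event": event, "high_burden": g})
        fwd, _, _ = sp.fit_persistence_cox(data)
        data["flipped"] = ~data["high_burden"]
        rev, _, _ = sp.fit_persistence_cox(data, exposure="flipped")
        assert math.log(fwd.estimate) == pytest.approx(-math.log(rev.estimate),
                                                       abs=1e-6)


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        base = pd.DataFrame({
            "age": np.tile(np.arange(30.0, 60.0), 1),
            "sex": ["male", "female"] * 15,
        })
        data = pd.concat(
            [base.assign(grp=g) for g in ("escalation", "de_escalation", "no_change")],
            ignore_index=True,
        )
        out = sp.group_comparison_table(
            data, "grp", variables={"age": "normal", "sex": "categorical"})
        assert out["p_value"].tolist() == pytest.approx([1.0, 1.0])

    def test_reference_percentages(self):
        """239 of 587 low-burden subjects with the composite = 40.72%."""
        low = REFERENCE_COHORT["composite_by_burden"]["low"]
        high = REFERENCE_COHORT["composite_by_burden"]["high"]
        from statin_pgx.association import row_percent

        tab = pd.DataFrame([low, high], index=["low", "high"],
                           columns=["no", "yes"])
        pct = row_percent(tab)
        assert pct.loc["low", "yes"] == pytest.approx(40.72, abs=0.005)

    def test_kruskal_null_uniform(self):
        """KW p-values on groups from one distribution are ~uniform."""
        from scipy import stats

        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            data = pd.DataFrame({
                "v": rng.normal(size=150),
                "grp": rng.choice(["a", "b", "c"], size=150),
            })
            out = sp.group_comparison_table(data, "grp", variables={"v": "skewed"})
            ps.append(out["p_value"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
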