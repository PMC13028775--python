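"""Statistical layer: contingency OR, logistic / multinomial / Cox models,
Kaplan–Meier persistence curves, and descriptive group-comparison tables.

Conventions shared by every model:

* complete-case analysis per model (rows with missing covariates dropped;
  each result carries ``n_used``);
* effect estimates reported as OR (logistic), RRR (multinomial contrast vs
  the ``no_change`` reference), or HR (Cox, Efron ties), with 95% Wald
  confidence intervals symmetric on the log scale;
* perfectly collinear covariates are dropped with an explicit report, never
  silently; separation is flagged, never penalised away;
* no multiple-testing correction is applied — the descriptive report carries
  the number of tests run as context.

The estimation itself is delegated to statsmodels (Logit, MNLogit),
lifelines (CoxPHFitter, KaplanMeierFitter, logrank_test) and scipy.stats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

log = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

#: threshold on a Wald SE beyond which a contrast is flagged as separated
_SEPARATION_SE = 50.0


@dataclass(frozen=True)
class AssocResult:
    """One effect estimate on the ratio scale (OR / RRR / HR)."""

    measure: str          # "OR" | "RRR" | "HR"
    term: str             # predictor name
    contrast: str         # outcome (or outcome level vs reference)
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model: str
    flags: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["flags"] = list(self.flags)
        return d


def _from_log(measure, term, contrast, beta, se, n_used, model, flags=()):
    if not np.isfinite(se) or se > _SEPARATION_SE:
        flags = tuple(flags) + ("separation",)
        return AssocResult(measure, term, contrast, float(np.exp(beta)),
                           0.0, float("inf"), float("nan"), n_used, model, flags)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssocResult(
        measure, term, contrast, float(np.exp(beta)),
        float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)),
        float(p), n_used, model, tuple(flags),
    )


# ---------------------------------------------------------------------------
# 2x2 contingency analysis


def contingency_or(table) -> AssocResult:
    """Odds ratio from a 2×2 table with Wald CI on the log scale.

    ``table`` is [[no_ref, yes_ref], [no_exposed, yes_exposed]] — the first
    row is the reference (e.g. low burden), columns are event no/yes.  A zero
    cell triggers the Haldane–Anscombe 0.5 correction, flagged in the result.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("contingency_or expects a 2x2 table of nonnegative counts")
    flags = ()
    if (t == 0).any():
        t = t + 0.5
        flags = ("haldane_anscombe_0.5",)
    (a, b), (c, d) = t  # a=no_ref, b=yes_ref, c=no_exposed, d=yes_exposed
    beta = math.log((d * a) / (c * b))
    se = math.sqrt((1.0 / t).sum())
    return _from_log("OR", "exposed_vs_reference", "event", beta, se,
                     int(np.asarray(table).sum()), "contingency_2x2", flags)


def two_by_two(data: pd.DataFrame, row: str, col: str,
               row_order=None, col_order=None) -> pd.DataFrame:
    """Counts cross-tab with the row/col orders the OR orientation expects."""
    tab = pd.crosstab(data[row], data[col])
    if row_order is not None:
        tab = tab.reindex(index=row_order, fill_value=0)
    if col_order is not None:
        tab = tab.reindex(columns=col_order, fill_value=0)
    return tab


def row_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise percentages of a counts table."""
    return table.div(table.sum(axis=1), axis=0) * 100.0


# ---------------------------------------------------------------------------
# Design-matrix helpers


def _design(data: pd.DataFrame, exposure: str, covariates: Sequence[str]):
    """Complete-case design matrix; categoricals dummy-coded (first = ref)."""
    cols = [exposure, *covariates]
    df = data[cols].copy()
    n_before = len(df)
    df = df.dropna()
    X = pd.DataFrame(index=df.index)
    for c in cols:
        s = df[c]
        if s.dtype == bool:
            X[c] = s.astype(float)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[c] = s.astype(float)
    X.insert(0, "const", 1.0)
    return X, df.index, n_before - len(df)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that do not increase the design rank."""
    cols = list(X.columns)
    keep: list[str] = []
    dropped: list[str] = []
    mat = np.empty((len(X), 0))
    rank = 0
    for c in cols:
        cand = np.column_stack([mat, X[c].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(c)
            mat, rank = cand, r
        else:
            dropped.append(c)
    if dropped:
        log.info("collinear column(s) omitted from the model: %s", dropped)
    return X[keep], dropped


# ---------------------------------------------------------------------------
# Logistic model (statin intolerance etc.)


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    measure: str = "OR",
    model_name: Optional[str] = None,
) -> tuple[AssocResult, list[AssocResult]]:
    """Binary logistic regression; returns (exposure result, all terms).

    The outcome must have both classes present; perfectly collinear
    covariates are dropped with a report and a ``dropped:`` flag.
    """
    y = data[outcome]
    X, idx, _ = _design(data, exposure, covariates)
    y = y.loc[idx].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"degenerate outcome: {outcome!r} has a single class")
    X, dropped = _drop_collinear(X)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    name = model_name or f"logistic:{outcome}"
    flags = tuple(f"dropped:{c}" for c in dropped)
    results = [
        _from_log(measure, term, outcome, res.params[term], res.bse[term],
                  int(res.nobs), name, flags)
        for term in X.columns if term != "const"
    ]
    main = next(r for r in results if r.term.startswith(exposure))
    return main, results


# ---------------------------------------------------------------------------
# Multinomial model (regimen modification)


def fit_multinomial(
    data: pd.DataFrame,
    outcome: str = "modification",
    exposure: str = "high_burden",
    covariates: Sequence[str] = (),
    reference: str = "no_change",
    classes: Sequence[str] = ("no_change", "escalation", "de_escalation"),
) -> list[AssocResult]:
    """Multinomial logit: RRR per predictor for each class vs the reference."""
    present = set(data[outcome].dropna().unique())
    for c in classes:
        if c not in present:
            raise ValueError(f"outcome class {c!r} absent from the data")
    order = [reference, *[c for c in classes if c != reference]]
    X, idx, _ = _design(data, exposure, covariates)
    codes = data.loc[idx, outcome].map({c: i for i, c in enumerate(order)})
    X, dropped = _drop_collinear(X)
    res = sm.MNLogit(codes.astype(int), X).fit(disp=0, maxiter=500)
    flags = tuple(f"dropped:{c}" for c in dropped)
    name = f"multinomial:{outcome}"
    out: list[AssocResult] = []
    for j, cls in enumerate(order[1:]):
        for term in X.columns:
            if term == "const":
                continue
            beta = res.params.loc[term].iloc[j]
            se = res.bse.loc[term].iloc[j]
            out.append(_from_log("RRR", term, f"{cls}_vs_{reference}",
                                 beta, se, int(res.nobs), name, flags))
    return out


# ---------------------------------------------------------------------------
# Cox / Kaplan-Meier persistence analysis


def fit_persistence_cox(
    data: pd.DataFrame,
    duration: str = "time_to_first_change",
    event: str = "event",
    exposure: str = "high_burden",
    covariates: Sequence[str] = (),
    strata: Sequence[str] = (),
) -> tuple[AssocResult, dict[str, pd.DataFrame], float]:
    """Cox PH (Efron ties) for time to first regimen change, with KM curves.

    Returns (HR result for the exposure, per-group KM survival curves,
    log-rank p-value).  Groups are the two levels of the boolean/binary
    exposure.  ``strata`` columns get stratum-specific baseline hazards
    (e.g. baseline statin intensity, whose rare levels would otherwise
    separate).  Raises if no events are observed.
    """
    cols = [duration, event, exposure, *covariates, *strata]
    df = data[cols].dropna().copy()
    df[exposure] = df[exposure].astype(float)
    if df[event].sum() == 0:
        raise ValueError("no events observed: hazard ratio undefined")
    for c in covariates:
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(df[c], prefix=c, drop_first=True, dtype=float)
            df = pd.concat([df.drop(columns=[c]), dummies], axis=1)
        elif df[c].dtype == bool:
            df[c] = df[c].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration, event_col=event,
            strata=list(strata) or None)
    beta = cph.params_[exposure]
    se = cph.standard_errors_[exposure]
    main = _from_log("HR", exposure, "regimen_change", beta, se,
                     len(df), "cox_ph")

    km: dict[str, pd.DataFrame] = {}
    for label, sub in df.groupby(df[exposure] > 0):
        fitter = KaplanMeierFitter(label="high" if label else "low")
        fitter.fit(sub[duration], event_observed=sub[event])
        km["high" if label else "low"] = fitter.survival_function_

    lr = multivariate_logrank_test(df[duration], (df[exposure] > 0), df[event])
    return main, km, float(lr.p_value)


def km_survival_at(km_curve: pd.DataFrame, t: float) -> float:
    """Step-function KM survival probability at time t."""
    s = km_curve.iloc[:, 0]
    eligible = s[s.index <= t]
    return float(eligible.iloc[-1]) if len(eligible) else 1.0


# ---------------------------------------------------------------------------
# Descriptive group comparisons


def group_comparison_table(
    data: pd.DataFrame,
    group: str,
    variables: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Per-group descriptive summaries with the appropriate global test.

    ``variables`` maps column name → kind: ``"normal"`` (mean±SD, one-way
    ANOVA), ``"skewed"`` (median [IQR], Kruskal–Wallis) or ``"categorical"``
    (n (%), χ² without continuity correction).  Groups with no observations
    are omitted with a note.  Degenerate inputs (all groups identical)
    report p = 1.
    """
    if variables is None:
        raise ValueError("variables mapping is required")
    groups = [g for g in data[group].dropna().unique()]
    rows = []
    for var, kind in variables.items():
        samples, labels = [], []
        for g in groups:
            s = data.loc[data[group] == g, var].dropna()
            if len(s) == 0:
                log.info("group %r omitted for %r (no observations)", g, var)
                continue
            samples.append(s)
            labels.append(g)
        summary = {}
        if kind == "categorical":
            tab = pd.crosstab(data.loc[data[group].isin(labels), group], data[var])
            for g in labels:
                counts = tab.loc[g]
                n_g = counts.sum()
                summary[g] = "; ".join(
                    f"{lvl}: {c} ({100 * c / n_g:.2f}%)" for lvl, c in counts.items()
                )
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                p = float("nan")
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
                p = 1.0 if chi2 == 0 else float(p)
        elif kind == "normal":
            for g, s in zip(labels, samples):
                summary[g] = f"{s.mean():.2f} ± {s.std(ddof=1):.2f}"
            p = _safe_p(stats.f_oneway, samples)
        elif kind == "skewed":
            for g, s in zip(labels, samples):
                q1, q3 = s.quantile([0.25, 0.75])
                summary[g] = f"{s.median():.2f} ({q1:.2f}-{q3:.2f})"
            p = _safe_p(stats.kruskal, samples)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append({"variable": var, "kind": kind, **summary, "p_value": p})
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out


def _safe_p(test, samples) -> float:
    if len(samples) < 2:
        return float("nan")
    pooled = pd.concat(samples)
    if pooled.nunique() == 1:
        return 1.0  # no variation anywhere: no evidence against equality
    try:
        return float(test(*samples).pvalue)
    except ValueError:
        return 1.0
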