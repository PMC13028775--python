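"""Seeded synthetic-cohort generator for the statin PGx pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage (diplotype calling, regimen-course derivation,
outcome phenotyping, association models) can be exercised — and its
parameter recovery tested — without any patient data.

Structure of one simulated cohort:

* **Genotypes** — five pharmacogene variants drawn independently per locus
  under Hardy–Weinberg proportions at configurable frequencies.  The two
  SLCO1B1 SNPs are generated as phased haplotypes internally (so a truth
  diplotype exists) but emitted unphased, exercising the caller's phase
  ambiguity handling.  Loci are unlinked (they lie on chromosomes 12, 4, 10).
* **Dispensing records** — a 12-month (configurable) course of ~30-day fills.
  The three-level regimen-modification outcome is drawn from a multinomial
  logit whose intercepts reproduce the configured baseline escalation /
  de-escalation rates and whose log-RRR coefficients act on the subject's
  latent high-burden category and latent myopathy.  The no-change
  probability is then tilted as S = S_base**(HR**high) so that the hazard of
  any regimen change is exactly proportional between burden groups
  (exponential, censored at follow-up) and a Cox fit recovers the configured
  HR.  Change times are truncated-exponential, realised at the next fill.
* **Adherence** — designated non-adherent subjects (at the configured rate)
  skip fills to land at an MPR of ~0.30–0.75; adherent subjects keep an MPR
  above 0.85.
* **Labs and outcomes** — CK is lognormal per sex; subjects designated
  intolerant (baseline rate tilted by the configured odds ratio on high
  burden) receive a CK draw at 3–6×ULN, and — when neither myopathy nor a
  realised de-escalation provides the accompanying clinical clause — a run
  of >3 same-intensity drug/dose switches, so the intolerance rule
  re-derives the designation from observables.  Myopathy and liver-injury
  diagnosis flags are Bernoulli at their baseline rates with the same odds
  tilt on high burden.  Lab missingness is applied last.

Reproducibility: one pseudo-random stream per component (genotypes, latent
assignments, dispensing, labs), split from the master seed, so identical
configs give identical cohorts and adding draws to one component does not
perturb the others.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import genotyping as gt
from . import regimen as rg

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a SimConfig (or pipeline config) fails validation."""


# ---------------------------------------------------------------------------
# Default study conditions (the cohort the generator emulates)

#: rs4149056 frequency back-derived from the reference cohort's phenotype
#: marginals (p(TT) = 0.6502); the population maximum reported for this
#: ancestry group is 0.2322 and remains a valid configuration.
DEFAULT_ALLELE_FREQS: dict[str, float] = {
    gt.SLCO1B1_521: 0.1936,
    gt.SLCO1B1_388: 0.4850,
    gt.ABCG2_421: 0.0623,
    gt.CYP2C9_STAR2: 0.1100,
    gt.CYP2C9_STAR3: 0.0470,
}

DEFAULT_STATIN_MIX: dict[str, float] = {
    "atorvastatin": 559 / 911,
    "rosuvastatin": 307 / 911,
    "pravastatin": 22 / 911,
    "simvastatin": 20 / 911,
    "fluvastatin": 3 / 911,
}

DEFAULT_INTENSITY_MIX: dict[str, float] = {
    "low": 15 / 911,
    "moderate": 406 / 911,
    "high": 490 / 911,
}

#: Adjusted effect estimates of the reference cohort, used as default truth.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "or_intolerance_high_burden": 1.14,
    "rrr_deescalation_high_burden": 1.18,
    "rrr_escalation_high_burden": 0.93,
    "hr_regimen_change_high_burden": 1.02,
    "rrr_deescalation_myopathy": 1.91,
}

DEFAULT_BASELINE_RATES: dict[str, float] = {
    "myopathy": 132 / 911,
    "liver_injury": 23 / 911,
    "nonadherence": 269 / 911,
    "escalation": 93 / 911,
    "deescalation": 104 / 911,
    "intolerance": 0.10,
}

#: Per-sex (mu, sigma) of log CK in IU/L: medians ~100 (women) / ~150 (men),
#: below the respective ULNs of 120 and 180.
DEFAULT_CK_LOGNORMAL: dict[str, tuple[float, float]] = {
    "female": (math.log(100.0), 0.5),
    "male": (math.log(150.0), 0.5),
}

DEFAULT_MISSINGNESS: dict[str, float] = {"ck": 0.30, "alt": 0.10, "ast": 0.10}

# Demographic emulation constants (descriptive only; independent of outcomes).
_P_MALE = 657 / 911
_AGE_MEAN, _AGE_SD = 60.33, 10.71
_P_DIABETES = 715 / 911
_P_SMOKER = 0.2549
_LDL_MEAN, _LDL_SD = 2.48, 0.99
_P_INHIBITOR = 0.1679

_FILL_CYCLE = 30  # days per fill

# canonical starting dose per (drug, level) and a same-level alternate
# regimen used to realise behavioural (>3 switches) intolerance
_CANONICAL_DOSE: dict[tuple[str, str], float] = {
    ("atorvastatin", "moderate"): 20, ("atorvastatin", "high"): 40,
    ("rosuvastatin", "moderate"): 10, ("rosuvastatin", "high"): 20,
    ("simvastatin", "low"): 10, ("simvastatin", "moderate"): 20,
    ("pravastatin", "low"): 20, ("pravastatin", "moderate"): 40,
    ("fluvastatin", "low"): 40, ("fluvastatin", "moderate"): 80,
}
_ALT_REGIMEN: dict[tuple[str, str], tuple[str, float]] = {
    ("atorvastatin", "moderate"): ("atorvastatin", 10),
    ("atorvastatin", "high"): ("atorvastatin", 80),
    ("rosuvastatin", "moderate"): ("rosuvastatin", 5),
    ("rosuvastatin", "high"): ("rosuvastatin", 40),
    ("simvastatin", "low"): ("pravastatin", 10),
    ("simvastatin", "moderate"): ("simvastatin", 40),
    ("pravastatin", "low"): ("pravastatin", 10),
    ("pravastatin", "moderate"): ("pravastatin", 80),
    ("fluvastatin", "low"): ("fluvastatin", 20),
    ("fluvastatin", "moderate"): ("atorvastatin", 10),
}
# drug used when the current drug lacks the target intensity level
_FALLBACK_DRUG = {"low": "simvastatin", "moderate": "atorvastatin", "high": "atorvastatin"}


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_subjects: int = 911
    seed: int = 0
    allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    statin_mix: dict = field(default_factory=lambda: dict(DEFAULT_STATIN_MIX))
    intensity_mix: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_MIX))
    followup_days: int = 365
    effect_sizes: dict = field(default_factory=dict)
    baseline_rates: dict = field(default_factory=dict)
    ck_lognormal_params: dict = field(default_factory=lambda: dict(DEFAULT_CK_LOGNORMAL))
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    scheme: str = gt.DEFAULT_SCHEME

    def __post_init__(self):
        self.effect_sizes = {**DEFAULT_EFFECT_SIZES, **self.effect_sizes}
        self.baseline_rates = {**DEFAULT_BASELINE_RATES, **self.baseline_rates}
        self.validate()

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be positive")
        for v in gt.PANEL_VARIANTS:
            if v not in self.allele_freqs:
                raise ConfigError(f"allele_freqs missing panel variant {v!r}")
        for name, p in {**self.allele_freqs, **self.baseline_rates,
                        **self.missingness}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name!r}={p} outside [0, 1]")
        for mix_name, mix in (("statin_mix", self.statin_mix),
                              ("intensity_mix", self.intensity_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{mix_name} must sum to 1 (got {sum(mix.values())})")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{mix_name} has negative probabilities")
        for drug in self.statin_mix:
            if drug not in rg.INTENSITY_TABLE:
                raise ConfigError(f"unknown statin in statin_mix: {drug!r}")
        for name, e in self.effect_sizes.items():
            if not e > 0:
                raise ConfigError(f"effect size {name!r} must be positive (got {e})")
        p_es = self.baseline_rates["escalation"]
        p_de = self.baseline_rates["deescalation"]
        if p_es + p_de >= 1.0:
            raise ConfigError("escalation + deescalation baseline rates must be < 1")
        if self.scheme not in gt.SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """All components of one simulated cohort, keyed by subject_id."""

    config: SimConfig
    genotypes: pd.DataFrame     # subject_id + five unphased dosage columns
    dispensings: pd.DataFrame   # subject_id, date, drug, dose_mg, days_supplied
    clinical: pd.DataFrame      # demographics + EHR-style diagnosis flags
    labs: pd.DataFrame          # long: subject_id, day, analyte, value
    truth: pd.DataFrame         # latent labels consistent with the observables


# ---------------------------------------------------------------------------
# Random streams


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("genotypes", "latent", "dispensing", "labs")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _subject_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"S{i + 1:0{width}d}" for i in range(n)], dtype=object)


# ---------------------------------------------------------------------------
# Genotypes


def _simulate_genotypes_full(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = _rngs(config.seed)["genotypes"]
    n = config.n_subjects
    f = config.allele_freqs

    # SLCO1B1: phased haplotypes (388G bit, 521C bit) per chromosome
    g_bits = rng.random((n, 2)) < f[gt.SLCO1B1_388]
    c_bits = rng.random((n, 2)) < f[gt.SLCO1B1_521]
    d388 = g_bits.sum(axis=1)
    d521 = c_bits.sum(axis=1)
    hap_names = np.array([
        "/".join(sorted(
            (gt._HAP_NAME[(int(g1), int(c1))], gt._HAP_NAME[(int(g2), int(c2))]),
            key=gt._STAR_ORDER.index,
        ))
        for (g1, g2), (c1, c2) in zip(g_bits, c_bits)
    ], dtype=object)

    public = pd.DataFrame({"subject_id": _subject_ids(n)})
    public[gt.SLCO1B1_521] = d521
    public[gt.SLCO1B1_388] = d388
    for key in (gt.ABCG2_421, gt.CYP2C9_STAR2, gt.CYP2C9_STAR3):
        public[key] = rng.binomial(2, f[key], size=n)

    haps = pd.DataFrame({"subject_id": public["subject_id"],
                         "slco1b1_diplotype_true": hap_names})
    return public, haps


def simulate_genotypes(config: SimConfig) -> pd.DataFrame:
    """Draw unphased panel genotypes under per-locus Hardy–Weinberg proportions."""
    public, _ = _simulate_genotypes_full(config)
    return public


# ---------------------------------------------------------------------------
# Latent assignments (shared stream; regenerated identically by every stage)


def _latents(config: SimConfig, genotypes: pd.DataFrame) -> pd.DataFrame:
    rng = _rngs(config.seed)["latent"]
    n = len(genotypes)
    scored = gt.score_cohort(genotypes, scheme=config.scheme)
    high = (scored["burden_category"] == "high").to_numpy()

    u_myo = rng.random(n)
    u_int = rng.random(n)
    u_non = rng.random(n)
    u_ckm = rng.random(n)

    eff = config.effect_sizes
    base = config.baseline_rates
    log_or = math.log(eff["or_intolerance_high_burden"])

    def tilted(p0: float) -> np.ndarray:
        if p0 <= 0.0:
            return np.zeros(n)
        if p0 >= 1.0:
            return np.ones(n)
        return expit(logit(p0) + log_or * high)

    out = pd.DataFrame({
        "subject_id": genotypes["subject_id"].to_numpy(),
        "high_burden": high,
        "burden_score": scored["burden_score"].to_numpy(),
        "burden_category": scored["burden_category"].to_numpy(),
        "latent_myopathy": u_myo < tilted(base["myopathy"]),
        "designated_intolerant": u_int < tilted(base["intolerance"]),
        "designated_nonadherent": u_non < base["nonadherence"],
        "ck_series_missing": u_ckm < config.missingness.get("ck", 0.0),
    })
    return out


# ---------------------------------------------------------------------------
# Dispensing


def _drug_tables(config: SimConfig):
    """Per-drug canonical/alternate regimen arrays indexed (drug, level)."""
    drugs = list(config.statin_mix)
    nd = len(drugs)
    didx = {d: i for i, d in enumerate(drugs)}
    canon = np.full((nd, 3), np.nan)
    alt_drug = np.full((nd, 3), -1, dtype=int)
    alt_dose = np.full((nd, 3), np.nan)
    has_level = np.zeros((nd, 3), dtype=bool)
    for d in drugs:
        for lv in rg.available_levels(d):
            j = rg._LEVEL_CODE[lv]
            has_level[didx[d], j] = True
            canon[didx[d], j] = _CANONICAL_DOSE[(d, lv)]
            ad, adose = _ALT_REGIMEN[(d, lv)]
            if ad not in didx:  # alternate drug outside the configured mix
                ad, adose = d, _CANONICAL_DOSE[(d, lv)]
            alt_drug[didx[d], j] = didx[ad]
            alt_dose[didx[d], j] = adose
    fallback = np.array(
        [didx.get(_FALLBACK_DRUG[lv], -1) for lv in rg.LEVELS], dtype=int
    )
    return drugs, canon, alt_drug, alt_dose, has_level, fallback


def simulate_dispensing(config: SimConfig, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Generate per-subject fill sequences realising the configured effects.

    Returns the dispensing event table (one row per fill): subject_id,
    date (day index from first fill), drug, dose_mg, days_supplied.
    """
    if len(genotypes) == 0:
        raise ValueError("genotypes must be nonempty")
    rng = _rngs(config.seed)["dispensing"]
    lat = _latents(config, genotypes)
    n = len(genotypes)
    F = config.followup_days
    cycle = _FILL_CYCLE
    K = max(1, int(np.ceil(F / cycle)))
    fill_base = np.arange(K) * cycle

    drugs, canon, alt_drug, alt_dose, has_level, fallback = _drug_tables(config)
    p_drug = np.array([config.statin_mix[d] for d in drugs])
    p_drug = p_drug / p_drug.sum()

    drug0 = rng.choice(len(drugs), size=n, p=p_drug)

    # initial intensity: configured mix restricted to the drug's attainable levels
    mix = np.array([config.intensity_mix.get(lv, 0.0) for lv in rg.LEVELS])
    per_drug = np.where(has_level, mix[None, :], 0.0)
    rowsum = per_drug.sum(axis=1, keepdims=True)
    uniform = has_level / np.maximum(has_level.sum(axis=1, keepdims=True), 1)
    per_drug = np.where(rowsum > 0, per_drug / np.maximum(rowsum, 1e-300), uniform)
    cum = np.cumsum(per_drug, axis=1)
    u_lvl = rng.random(n)
    lvl0 = (u_lvl[:, None] > cum[drug0]).sum(axis=1)
    dose0 = canon[drug0, lvl0]

    # --- regimen modification: multinomial logit + proportional-hazard tilt
    eff, base = config.effect_sizes, config.baseline_rates
    high = lat["high_burden"].to_numpy()
    myo = lat["latent_myopathy"].to_numpy()
    p_es, p_de = base["escalation"], base["deescalation"]
    p_nc = 1.0 - p_es - p_de

    # feasibility mass: a drawn escalation (de-escalation) is only realisable
    # when a higher (lower) intensity level exists for some configured drug.
    # Dividing the intercept odds by this mass pre-compensates the thinning so
    # realised class rates track the configured baselines; the mass does not
    # depend on burden, so configured RRR/HR effects are unaffected.
    def _feasible(direction: int) -> np.ndarray:
        ok = np.zeros_like(has_level)
        for d in range(has_level.shape[0]):
            for l in range(3):
                t = l + direction
                if not 0 <= t <= 2:
                    continue
                fb = fallback[t]
                ok[d, l] = has_level[d, t] or (fb >= 0 and has_level[fb, t])
        return ok

    feas_es_mat = _feasible(+1)
    feas_de_mat = _feasible(-1)
    start_prob = p_drug[:, None] * per_drug  # joint (drug, level) start probs
    q_es = float((start_prob * feas_es_mat).sum())
    q_de = float((start_prob * feas_de_mat).sum())
    if p_es > 0 and q_es <= 0:
        log.warning("escalation baseline %.3f unrealisable under this mix", p_es)
    if p_de > 0 and q_de <= 0:
        log.warning("de-escalation baseline %.3f unrealisable under this mix", p_de)
    w_es0 = (p_es / p_nc) / q_es if q_es > 0 else 0.0
    w_de0 = (p_de / p_nc) / q_de if q_de > 0 else 0.0
    w_es = w_es0 * eff["rrr_escalation_high_burden"] ** high
    w_de = (w_de0 * eff["rrr_deescalation_high_burden"] ** high
            * eff["rrr_deescalation_myopathy"] ** myo)
    # feasibility enters the subject's own odds (a frailty shared by both
    # burden groups): within each baseline-intensity stratum the change
    # hazard is exactly proportional between burden groups, and the
    # stratum mass is burden-independent, so RRRs stay exact marginally and
    # the HR is recovered by an intensity-adjusted Cox fit.
    a_es = w_es * feas_es_mat[drug0, lvl0]
    a_de = w_de * feas_de_mat[drug0, lvl0]
    s_base = 1.0 / (1.0 + a_es + a_de)
    hr = eff["hr_regimen_change_high_burden"]
    surv = s_base ** np.where(high, hr, 1.0)
    lam = -np.log(np.maximum(surv, 1e-300)) / F

    u_event = rng.random(n)
    u_type = rng.random(n)
    u_time = rng.random(n)

    event_drawn = u_event < (1.0 - surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(
            lam > 0,
            -np.log1p(-u_time * (1.0 - np.exp(-lam * F))) / np.maximum(lam, 1e-300),
            np.inf,
        )
    change_fill = np.clip(np.ceil(T / cycle), 1, None)
    change_fill = np.where(np.isfinite(change_fill), change_fill, K).astype(int)
    observable = change_fill <= K - 1

    asum = a_es + a_de
    cond_de = np.divide(a_de, asum, out=np.zeros(n), where=asum > 0)
    want_de = u_type < cond_de
    target = np.clip(lvl0 + np.where(want_de, -1, 1), 0, 2)
    same_ok = has_level[drug0, target]
    post_drug = np.where(same_ok, drug0, fallback[target])
    post_drug = np.where(post_drug >= 0, post_drug, drug0)
    post_dose = canon[post_drug, target]

    event = event_drawn & observable
    cls = np.where(event, np.where(want_de, "de_escalation", "escalation"), "no_change")

    # --- fill calendar with small jitter (breaks event-time ties)
    jitter = rng.integers(-3, 4, size=(n, K))
    jitter[:, 0] = 0
    days = np.clip(fill_base[None, :] + jitter, 0, F - 1)

    # --- which fills are kept (adherence), which must be kept
    nonadh = lat["designated_nonadherent"].to_numpy()
    m_target = rng.uniform(0.30, 0.75, size=n)
    k_non = np.clip(np.rint(m_target * F / cycle).astype(int), 1, K)
    min_keep_adh = min(K, int(np.ceil(0.85 * F / cycle)))
    d_max = K - min_keep_adh
    drop_adh = rng.integers(0, d_max + 1, size=n) if d_max > 0 else np.zeros(n, dtype=int)
    k_eff = np.where(nonadh, k_non, K - drop_adh)

    # behavioural intolerance route: taken whenever the biochemical clause
    # cannot realise the designation (no observed CK, or neither myopathy nor
    # a realised de-escalation); needs >3 switches, hence >=5 kept fills
    intol = lat["designated_intolerant"].to_numpy()
    ck_obs = ~lat["ck_series_missing"].to_numpy()
    behav = intol & ~(ck_obs & (myo | (cls == "de_escalation")))
    k_cap = max(1, int(0.79 * F / cycle))
    k_eff = np.where(behav, np.maximum(k_eff, min(5, k_cap)), k_eff)
    k_eff = np.where(event, np.maximum(k_eff, 2), k_eff)

    pr = rng.random((n, K))
    pr[:, 0] = -1.0
    rows_ev = np.nonzero(event)[0]
    pr[rows_ev, change_fill[rows_ev]] = -1.0
    rank = np.argsort(np.argsort(pr, axis=1), axis=1)
    keep = rank < k_eff[:, None]

    # --- regimen per fill
    post_mask = (np.arange(K)[None, :] >= change_fill[:, None]) & event[:, None]
    drug_f = np.where(post_mask, post_drug[:, None], drug0[:, None])
    lvl_f = np.where(post_mask, target[:, None], lvl0[:, None])
    dose_f = np.where(post_mask, post_dose[:, None], dose0[:, None])

    csum = np.cumsum(keep, axis=1)
    alt_pos = keep & behav[:, None] & (csum % 2 == 0)
    drug_f = np.where(alt_pos, alt_drug[drug_f, lvl_f], drug_f)
    dose_f = np.where(alt_pos, alt_dose[drug_f, lvl_f], dose_f)
    # note: alt lookup uses the (possibly alternated) drug at the same level —
    # both orders give a same-level regimen differing from the canonical one

    subj = lat["subject_id"].to_numpy()
    ridx, cidx = np.nonzero(keep)
    drug_names = np.array(drugs, dtype=object)
    events = pd.DataFrame({
        "subject_id": subj[ridx],
        "date": days[ridx, cidx],
        "drug": drug_names[drug_f[ridx, cidx]],
        "dose_mg": dose_f[ridx, cidx],
        "days_supplied": cycle,
    })
    return events


# ---------------------------------------------------------------------------
# Labs, clinical table, truth


def simulate_labs_outcomes(
    config: SimConfig, genotypes: pd.DataFrame, dispensings: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the clinical table, the long lab table, and the truth labels."""
    rng = _rngs(config.seed)["labs"]
    lat = _latents(config, genotypes)
    n = len(genotypes)
    F = config.followup_days
    subj = lat["subject_id"].to_numpy()

    sex = np.where(rng.random(n) < _P_MALE, "male", "female")
    age = rng.normal(_AGE_MEAN, _AGE_SD, n).round(1)
    diabetes = rng.random(n) < _P_DIABETES
    smoker = rng.random(n) < _P_SMOKER
    ldl = np.clip(rng.normal(_LDL_MEAN, _LDL_SD, n), 0.3, None).round(2)
    inhibitor = rng.random(n) < _P_INHIBITOR

    mu_m, sg_m = config.ck_lognormal_params["male"]
    mu_f, sg_f = config.ck_lognormal_params["female"]
    mu = np.where(sex == "male", mu_m, mu_f)
    sg = np.where(sex == "male", sg_m, sg_f)

    ck_days = np.sort(rng.integers(0, F, size=(n, 3)), axis=1)
    ck = np.exp(mu[:, None] + sg[:, None] * rng.standard_normal((n, 3)))
    uln = np.where(sex == "male", 180.0, 120.0)
    mult = rng.uniform(3.0, 6.0, n)
    intol = lat["designated_intolerant"].to_numpy()
    ck[intol, 2] = (uln * mult)[intol]
    ck = ck.round(1)

    alt_days = np.sort(rng.integers(0, F, size=(n, 2)), axis=1)
    alt_vals = np.exp(math.log(19.0) + 0.35 * rng.standard_normal((n, 2))).round(1)
    ast_days = np.sort(rng.integers(0, F, size=(n, 2)), axis=1)
    ast_vals = np.exp(math.log(17.0) + 0.35 * rng.standard_normal((n, 2))).round(1)
    miss_alt = rng.random(n) < config.missingness.get("alt", 0.0)
    miss_ast = rng.random(n) < config.missingness.get("ast", 0.0)

    eff = config.effect_sizes
    p_liv = config.baseline_rates["liver_injury"]
    high = lat["high_burden"].to_numpy()
    if 0.0 < p_liv < 1.0:
        p_liver = expit(logit(p_liv) + math.log(eff["or_intolerance_high_burden"]) * high)
    else:
        p_liver = np.full(n, float(p_liv))
    liver = rng.random(n) < p_liver

    clinical = pd.DataFrame({
        "subject_id": subj, "sex": sex, "age": age, "diabetes": diabetes,
        "smoker": smoker, "ldl": ldl, "inhibitor": inhibitor,
        "myopathy_dx": lat["latent_myopathy"].to_numpy(), "liver_injury": liver,
    })

    miss_ck = lat["ck_series_missing"].to_numpy()
    parts = []
    for analyte, days_a, vals_a, missing in (
        ("ck", ck_days, ck, miss_ck),
        ("alt", alt_days, alt_vals, miss_alt),
        ("ast", ast_days, ast_vals, miss_ast),
    ):
        kk = days_a.shape[1]
        keep_rows = np.repeat(~missing, kk)
        parts.append(pd.DataFrame({
            "subject_id": np.repeat(subj, kk)[keep_rows],
            "day": days_a.ravel()[keep_rows],
            "analyte": analyte,
            "value": vals_a.ravel()[keep_rows],
        }))
    labs = pd.concat(parts, ignore_index=True)

    courses = rg.derive_courses(dispensings, F)
    truth = lat.merge(
        courses[["subject_id", "modification", "time_to_first_change", "event",
                 "mpr", "adherent"]],
        on="subject_id", how="left",
    )
    return clinical, labs, truth


# ---------------------------------------------------------------------------
# Whole cohort


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (deterministic under a fixed config)."""
    genotypes, haps = _simulate_genotypes_full(config)
    dispensings = simulate_dispensing(config, genotypes)
    clinical, labs, truth = simulate_labs_outcomes(config, genotypes, dispensings)
    truth = truth.merge(haps, on="subject_id", how="left")
    return SyntheticCohort(config, genotypes, dispensings, clinical, labs, truth)
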