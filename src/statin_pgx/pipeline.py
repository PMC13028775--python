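"""End-to-end orchestration: simulate/load → score → course → outcomes → models.

The pipeline consumes either a simulation block (a ``SimConfig``) or paths to
genotype/dispensing/clinical/lab files, runs every stage in order, and writes
a versioned run manifest recording the configuration hash, the seed, row
counts per stage and every exclusion with its reason — no subject is dropped
silently (the attrition between 'genotyped' and 'scored' is explicit).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import genotyping as gt
from . import io as pio
from . import outcomes as oc
from . import regimen as rg
from .simulate import ConfigError, SimConfig, simulate_cohort

log = logging.getLogger(__name__)

#: adjusted-model covariates (demographics + clinical, as in the reference analysis)
DEFAULT_COVARIATES = ("age", "sex", "ldl", "diabetes", "baseline_intensity", "inhibitor")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, subject_ids=()):
        self.stage = stage
        self.subject_ids = tuple(subject_ids)
        extra = f" (subjects: {', '.join(map(str, subject_ids[:10]))})" if subject_ids else ""
        super().__init__(f"stage {stage!r} failed: {message}{extra}")


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of ``simulate`` or ``paths``."""

    simulate: Optional[SimConfig] = None
    paths: Optional[dict] = None  # genotypes (vcf/csv), dispensing, clinical, labs
    scheme: str = gt.DEFAULT_SCHEME
    followup_days: int = 365
    intolerance_rule: str = "default"
    seed: int = 0
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.paths is None):
            raise ConfigError(
                "config must contain exactly one of a 'simulate' block or input 'paths'"
            )
        if self.scheme not in gt.SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.intolerance_rule not in oc.INTOLERANCE_RULES:
            raise ConfigError(f"unknown intolerance rule {self.intolerance_rule!r}")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be positive")
        if self.simulate is not None:
            # pipeline-level seed/scheme/followup govern the simulation too
            self.simulate.seed = self.seed
            self.simulate.scheme = self.scheme
            self.simulate.followup_days = self.followup_days

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = SimConfig(**sim)
        return cls(simulate=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage helpers


def _load_inputs(config: PipelineConfig):
    p = config.paths
    geno_path = str(p["genotypes"])
    if geno_path.endswith(".vcf"):
        genotypes = pio.read_genotype_vcf(geno_path,
                                          star3_rsid=p.get("star3_rsid", "rs4986893"))
    else:
        genotypes = pio.read_genotype_csv(geno_path)
    dispensings = pio.read_dispensing_csv(p["dispensing"])
    clinical = pio.read_clinical_csv(p["clinical"])
    labs = pio.read_labs_csv(p["labs"])
    return genotypes, dispensings, clinical, labs, None


def assemble_dataset(
    profiles: pd.DataFrame,
    courses: pd.DataFrame,
    flags: pd.DataFrame,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Merge scored subjects into the one-row-per-subject analysis table."""
    scored = profiles[profiles["scored"]]
    df = scored[["subject_id", "burden_score", "burden_category"]].copy()
    df["high_burden"] = df["burden_category"] == "high"
    df = df.merge(courses, on="subject_id", how="inner")
    df = df.merge(flags.drop(columns=["myopathy", "liver_injury"]),
                  on="subject_id", how="left")
    df = df.merge(
        clinical[["subject_id", "sex", "age", "diabetes", "ldl", "inhibitor",
                  "myopathy_dx", "liver_injury"]],
        on="subject_id", how="left",
    )
    df = df.rename(columns={"myopathy_dx": "myopathy"})
    df["composite"] = df["myopathy"] | df["liver_injury"] | df["nonadherent"]
    return df


def run_associations(dataset: pd.DataFrame,
                     covariates=DEFAULT_COVARIATES) -> tuple[dict, dict]:
    """Fit the full association layer on an assembled dataset.

    Returns (results dict of AssocResult dicts, KM curves per burden group).
    Categorical covariates with an empty outcome×level cell are omitted with
    a report, mirroring a collinearity omission.
    """
    results: dict = {"n_tests_run": 0}

    tab = assoc.two_by_two(dataset, "burden_category", "composite",
                           row_order=["low", "high"], col_order=[False, True])
    results["composite_contingency"] = {
        "table": tab.to_numpy().tolist(),
        "row_percent": assoc.row_percent(tab).to_numpy().round(2).tolist(),
        "or": assoc.contingency_or(tab.to_numpy()).to_dict(),
    }

    covs = [c for c in covariates if c in dataset.columns]
    usable, omitted = [], []
    for c in covs:
        s = dataset[c].dropna()
        if s.dtype == object or s.dtype == bool or isinstance(s.dtype, pd.CategoricalDtype):
            ct = pd.crosstab(dataset["modification"], dataset[c])
            if (ct == 0).any().any():
                omitted.append(c)
                continue
        usable.append(c)
    if omitted:
        log.info("covariate(s) omitted (empty outcome cell / collinearity): %s", omitted)
    results["omitted_covariates"] = omitted

    main, _ = assoc.fit_logistic(dataset, "intolerance", "high_burden",
                                 covariates=usable, model_name="logistic:intolerance")
    results["intolerance_logistic"] = main.to_dict()

    mn = assoc.fit_multinomial(dataset, "modification", "high_burden",
                               covariates=[*usable, "myopathy"])
    results["modification_multinomial"] = [r.to_dict() for r in mn]

    cox, km, logrank_p = assoc.fit_persistence_cox(
        dataset, strata=("baseline_intensity",)
    )
    results["persistence_cox"] = cox.to_dict()
    results["logrank_p"] = logrank_p

    desc = assoc.group_comparison_table(
        dataset, "modification",
        variables={"age": "normal", "ldl": "normal", "mpr": "skewed",
                   "sex": "categorical", "diabetes": "categorical",
                   "myopathy": "categorical"},
    )
    results["group_comparison"] = desc.to_dict(orient="records")
    results["n_tests_run"] = (
        1 + 1 + len(mn) + 1 + desc.attrs.get("n_tests", 0)
    )
    return results, km


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and optionally write) the run manifest."""
    logging.basicConfig(level=config.log_level)

    stage = "inputs"
    try:
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            genotypes, dispensings = cohort.genotypes, cohort.dispensings
            clinical, labs = cohort.clinical, cohort.labs
            truth = cohort.truth
        else:
            genotypes, dispensings, clinical, labs, truth = _load_inputs(config)
    except (KeyError, FileNotFoundError, ValueError) as e:
        raise PipelineError(stage, str(e)) from e

    stage = "genotyping"
    try:
        profiles = gt.score_cohort(genotypes, scheme=config.scheme)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e
    excluded = profiles.loc[~profiles["scored"], ["subject_id", "exclusion_reason"]]

    stage = "regimen_course"
    try:
        courses = rg.derive_courses(dispensings, config.followup_days)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "outcome_phenotyping"
    try:
        flags = oc.phenotype_cohort(clinical, labs, courses,
                                    rule=config.intolerance_rule)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "association"
    try:
        dataset = assemble_dataset(profiles, courses, flags, clinical)
        results, km = run_associations(dataset)
    except ValueError as e:
        raise PipelineError(stage, str(e)) from e

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "scheme": config.scheme,
        "intolerance_rule": config.intolerance_rule,
        "followup_days": config.followup_days,
        "counts": {
            "genotyped": int(len(genotypes)),
            "scored": int(profiles["scored"].sum()),
            "excluded_unscored": int(len(excluded)),
            "exclusions": excluded.to_dict(orient="records"),
            "dispensing_events": int(len(dispensings)),
            "courses": int(len(courses)),
            "analysis_rows": int(len(dataset)),
            "modification": dataset["modification"].value_counts().to_dict(),
            "outcomes": {
                k: int(dataset[k].sum())
                for k in ("myopathy", "liver_injury", "nonadherent",
                          "intolerance", "composite")
            },
        },
        "results": results,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(out / "profiles.csv", index=False)
        courses.to_csv(out / "courses.csv", index=False)
        flags.to_csv(out / "outcomes.csv", index=False)
        dataset.to_csv(out / "dataset.csv", index=False)
        km_rows = []
        for grp, curve in km.items():
            c = curve.reset_index()
            c.columns = ["time", "survival"]
            c["burden_group"] = grp
            km_rows.append(c)
        pd.concat(km_rows, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
        if config.simulate is not None:
            pio.write_genotype_vcf(genotypes, out / "genotypes.vcf")
            pio.write_dispensing_csv(dispensings, out / "dispensing.csv")
            pio.write_clinical_csv(clinical, out / "clinical.csv")
            pio.write_labs_csv(labs, out / "labs.csv")
            pio.write_truth_json(truth, config.simulate.to_dict(), out / "truth.json")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=pio._json_default)
        )

    return manifest
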