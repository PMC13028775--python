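"""Readers and writers for the pipeline's plain-text interchange formats.

* genotypes: minimal VCF 4.2 (GT-only, unphased ``/`` separator) or a long
  genotype CSV (subject_id, variant_id, dosage);
* dispensing / clinical / lab tables: CSV with ISO-8601 dates (readers also
  accept integer day indices);
* truth labels: JSON.

VCF parsing goes through cyvcf2; variants are matched to the panel by rsID
first (the CYP2C9*3 rsID is configurable) with a chrom:pos:ref:alt fallback.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import genotyping as gt

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_DATE_ORIGIN = "2020-01-01"


# ---------------------------------------------------------------------------
# Genotypes


def write_genotype_vcf(genotypes: pd.DataFrame, path: PathLike) -> None:
    """Write the wide genotype table as a minimal GT-only VCF 4.2."""
    subjects = genotypes["subject_id"].astype(str).tolist()
    variants = sorted(gt.PANEL.values(), key=lambda v: (v.chrom, v.pos))
    lines = ["##fileformat=VCFv4.2", "##source=statin_pgx"]
    for chrom in sorted({v.chrom for v in variants}, key=int):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for v in variants:
        dosages = genotypes[v.key]
        calls = "\t".join(
            "./." if pd.isna(d) else gt_strings[int(d)] for d in dosages
        )
        lines.append(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{calls}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_vcf(path: PathLike, star3_rsid: str = "rs4986893") -> pd.DataFrame:
    """Read panel genotypes from a VCF into the wide dosage table.

    Variants are matched by rsID (``star3_rsid`` configures which rsID is
    accepted for the CYP2C9*3 locus), falling back to chrom:pos:ref:alt.
    Unmatched variants are skipped with a log entry; missing calls are NaN.
    """
    from cyvcf2 import VCF

    by_rsid = {v.rsid: v.key for v in gt.PANEL.values()}
    by_rsid[star3_rsid] = gt.CYP2C9_STAR3
    by_coord = {v.coord_key: v.key for v in gt.PANEL.values()}

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        alt = variant.ALT[0] if variant.ALT else "."
        key = by_rsid.get(variant.ID) or by_coord.get(
            f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
        )
        if key is None:
            log.info("skipping non-panel variant %s at %s:%s",
                     variant.ID, variant.CHROM, variant.POS)
            continue
        dosages = np.full(len(subjects), np.nan)
        for i, call in enumerate(variant.genotypes):
            alleles = [a for a in call[:-1] if a >= 0]
            if len(alleles) == 2:
                dosages[i] = sum(1 for a in alleles if a > 0)
        data[key] = dosages
    vcf.close()

    out = pd.DataFrame({"subject_id": subjects})
    for key in gt.PANEL_VARIANTS:
        out[key] = data.get(key, np.full(len(subjects), np.nan))
    return out


def write_genotype_csv(genotypes: pd.DataFrame, path: PathLike) -> None:
    """Write genotypes as a long CSV: subject_id, variant_id, dosage."""
    long = genotypes.melt(id_vars="subject_id", value_vars=list(gt.PANEL_VARIANTS),
                          var_name="variant_id", value_name="dosage")
    long.to_csv(path, index=False)


def read_genotype_csv(path: PathLike) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index="subject_id", columns="variant_id", values="dosage")
    wide = wide.reindex(columns=list(gt.PANEL_VARIANTS)).reset_index()
    wide.columns.name = None
    wide["subject_id"] = wide["subject_id"].astype(str)
    return wide


# ---------------------------------------------------------------------------
# Dispensing / clinical / labs


def write_dispensing_csv(events: pd.DataFrame, path: PathLike,
                         origin: str = _DATE_ORIGIN) -> None:
    """Write dispensing events with ISO-8601 dates (day index + origin)."""
    out = events.copy()
    out["date"] = (pd.Timestamp(origin) + pd.to_timedelta(out["date"], unit="D")
                   ).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _coerce_days(series: pd.Series) -> pd.Series:
    """Accept integer day indices or ISO dates; rebase dates per subject later."""
    try:
        return series.astype(int)
    except (ValueError, TypeError):
        dates = pd.to_datetime(series, format="ISO8601")
        return (dates - dates.min()).dt.days.astype(int)


def read_dispensing_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    df["date"] = _coerce_days(df["date"])
    df["drug"] = df["drug"].str.lower()
    return df


def write_clinical_csv(clinical: pd.DataFrame, path: PathLike) -> None:
    clinical.to_csv(path, index=False)


def read_clinical_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_labs_csv(labs: pd.DataFrame, path: PathLike,
                   origin: str = _DATE_ORIGIN) -> None:
    out = labs.copy()
    out["day"] = (pd.Timestamp(origin) + pd.to_timedelta(out["day"], unit="D")
                  ).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_labs_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    df["day"] = _coerce_days(df["day"])
    return df


# ---------------------------------------------------------------------------
# Truth / JSON


def write_truth_json(truth: pd.DataFrame, config_dict: dict, path: PathLike) -> None:
    """Latent truth labels plus the generating configuration, for harnesses."""
    payload = {
        "config": config_dict,
        "subjects": truth.replace({np.nan: None}).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
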