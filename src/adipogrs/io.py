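"""Readers and writers: genotype TSV / minimal VCF, cohort CSV, run config."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .simulate import canonical_genotype

__all__ = [
    "MISSING_TOKEN",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_cohort",
    "write_cohort",
    "RunConfig",
]

MISSING_TOKEN = "NA"

_MANDATORY_COHORT_COLS = [
    "subject_id",
    "sex",
    "age",
    "adherence",
    "weight",
    "height",
    "baseline_wc",
    "baseline_tfat",
    "mets",
    "energy",
]


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    """Subjects × rsIDs TSV with canonical calls ('AG'); missing as 'NA'."""
    out = genotypes.fillna(MISSING_TOKEN)
    out.to_csv(path, sep="\t", index_label="subject_id")


def _read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in df.columns:
        raise DataError("genotype TSV must have a subject_id column")
    df = df.set_index("subject_id")
    for col in df.columns:
        alleles: set[str] = set()
        vals = []
        for i, raw in enumerate(df[col].tolist(), start=2):  # header is line 1
            if raw is None or raw != raw or raw in (MISSING_TOKEN, "", "./."):
                vals.append(np.nan)
                continue
            call = str(raw).strip()
            if len(call) != 2 or not set(call) <= set("ACGT"):
                raise DataError(f"{col}: malformed call {call!r} at line {i}")
            vals.append(canonical_genotype(*call))
            alleles |= set(call)
        if len(alleles) > 2:
            raise DataError(f"locus {col} is not biallelic: alleles {sorted(alleles)}")
        df[col] = vals
    return df


def _locus_alleles(calls: pd.Series, rsid: str) -> tuple[str, str]:
    """(REF, ALT) = (major, minor) allele by count; ties break alphabetically."""
    counts: dict[str, int] = {}
    for g in calls.dropna():
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) > 2:
        raise DataError(f"locus {rsid} is not biallelic: alleles {alleles}")
    if len(alleles) == 1:  # monomorphic: invent an ALT for a valid record
        alleles.append(next(a for a in "ACGT" if a != alleles[0]))
    return alleles[0], alleles[1]


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2 (GT only), calls 0/1-coded against declared REF/ALT."""
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in samples),
    ]
    for pos, rsid in enumerate(genotypes.columns, start=1):
        calls = genotypes[rsid]
        ref, alt = _locus_alleles(calls, rsid)
        gts = []
        for g in calls:
            if g is None or g != g:
                gts.append("./.")
            else:
                gts.append("/".join(sorted("0" if a == ref else "1" for a in g)))
        lines.append(
            f"1\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_genotypes_vcf(path) -> pd.DataFrame:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    cols: dict[str, list] = {}
    order: list[str] = []
    for rec in vf:
        alleles = (rec.ref, rec.alts[0] if rec.alts else None)
        calls = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                calls.append(np.nan)
            else:
                pair = [alleles[a] for a in gt]
                calls.append(canonical_genotype(*pair))
        cols[rec.id] = calls
        order.append(rec.id)
    vf.close()
    df = pd.DataFrame(cols, index=pd.Index(samples, name="subject_id"))
    return df[order]


def read_genotypes(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a genotype matrix from TSV or VCF v4.2 (auto by extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise DataError(f"unknown genotype dialect {dialect!r}")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="subject_id")


def read_cohort(path) -> pd.DataFrame:
    """Cohort CSV → typed, validated table indexed by subject_id.

    Mandatory columns: sex (0 male / 1 female), age (years), adherence (0–3),
    weight (kg), height (m), baseline_wc (cm), baseline_tfat (%), mets, energy
    (kcal/day).  Optional: arm, tg, glucose, WCR (cm), TFATL (%).
    """
    df = pd.read_csv(path)
    for col in _MANDATORY_COHORT_COLS:
        if col not in df.columns:
            raise DataError(f"cohort file missing mandatory column {col!r}")
    df = df.set_index("subject_id")
    numeric = [c for c in df.columns if c != "arm"]
    df[numeric] = df[numeric].apply(pd.to_numeric)
    problems = []
    if (df["age"] <= 0).any():
        problems.append("age must be positive")
    if (df["baseline_wc"] <= 0).any():
        problems.append("baseline_wc must be positive")
    if ((df["baseline_tfat"] < 0) | (df["baseline_tfat"] > 100)).any():
        problems.append("baseline_tfat must be within [0, 100]")
    if not df["adherence"].isin([0, 1, 2, 3]).all():
        problems.append("adherence must be in {0,1,2,3}")
    if not df["sex"].isin([0, 1]).all():
        problems.append("sex must be 0/1")
    if df.index.duplicated().any():
        problems.append("duplicate subject_id")
    if problems:
        raise DataError("cohort validation failed: " + "; ".join(problems))
    return df


@dataclass
class RunConfig:
    """End-to-end run settings (thresholds, selector, paths, seed)."""

    genotypes: str | None = None
    cohort: str | None = None
    out_dir: str = "."
    simulate: bool = True
    n_subjects: int = 232
    n_loci: int = 95
    arms: tuple = ("MHP", "LF")
    outcomes: tuple = ("WCR", "TFATL")
    anova_p: float = 0.10
    confirm_p: float = 0.10
    min_prevalence: float = 0.10
    entry_p: float = 0.05
    keep_fraction: float = 0.6
    B: int = 200
    seed: int = 0
    selector: str = "best_subset"
    weights: str = "joint"
    naive_validation: bool = False

    def __post_init__(self) -> None:
        for name in ("anova_p", "confirm_p", "min_prevalence", "entry_p", "keep_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        for name in ("genotypes", "cohort"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for k in ("arms", "outcomes"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"], d["outcomes"] = list(self.arms), list(self.outcomes)
        return d
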