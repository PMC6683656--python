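"""Packaged reference tables from the motivating dietary-intervention study.

The study randomized overweight/obese adults to one of two 16-week hypocaloric
diets — moderately high-protein (MHP) or low-fat (LF) — and screened 95 SNPs
for association with two adiposity responses: waist-circumference reduction
(WCR, cm) and total body-fat loss (TFATL, %).  These loaders expose the
published per-locus genotype codifications (group sizes, means ± SD, p-values),
the best regression models (coefficients and squared partial correlations),
baseline cohort characteristics, outcome changes, and score metadata (locus
counts, score ranges, optimism-corrected adjusted R²).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reported_codifications",
    "load_reported_best_models",
    "load_reported_baseline",
    "load_reported_outcomes",
    "load_reported_score_meta",
    "distinct_snp_counts",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("adipogrs.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_reported_codifications(outcome: str = "both") -> pd.DataFrame:
    """Published genotype codifications for ``outcome`` in {WCR, TFATL, both}.

    One row per SNP × arm: low/high-risk genotype sets (``+``-joined), group
    sizes, group means ± SD of the signed outcome change, and the reported
    two-group p-value.
    """
    outcome = outcome.upper()
    if outcome == "WCR":
        df = _read("reported_codifications_wcr.tsv")
        df["outcome"] = "WCR"
    elif outcome == "TFATL":
        df = _read("reported_codifications_tfatl.tsv")
        df["outcome"] = "TFATL"
    elif outcome == "BOTH":
        a = load_reported_codifications("WCR")
        b = load_reported_codifications("TFATL")
        df = pd.concat([a, b], ignore_index=True)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return df


def load_reported_best_models() -> pd.DataFrame:
    """Published best-model coefficients and PC² per outcome × arm."""
    return _read("reported_best_models.tsv")


def load_reported_baseline() -> pd.DataFrame:
    """Published baseline characteristics per arm (mean ± SD, pooled-t p)."""
    return _read("reported_baseline.tsv")


def load_reported_outcomes() -> pd.DataFrame:
    """Published end-of-trial changes per arm (mean ± SEM, p)."""
    return _read("reported_outcomes.tsv")


def load_reported_score_meta() -> pd.DataFrame:
    """Published per-score locus counts, score ranges, corrected adj. R²."""
    return _read("reported_score_meta.tsv")


def distinct_snp_counts() -> dict:
    """SNP counts as published vs. as the distinct union of the tables.

    The study text reports 26 SNPs (9 for WCR + 17 for TFATL) counting a locus
    once per outcome; the distinct union of rsIDs across both codification
    tables is smaller because some loci are associated with both outcomes.
    Both counts are reported rather than guessing which was intended.
    """
    both = load_reported_codifications("both")
    wcr = both.loc[both.outcome == "WCR", "snp"]
    tf = both.loc[both.outcome == "TFATL", "snp"]
    return {
        "wcr_snp_arm_rows": int(wcr.nunique()),
        "tfatl_snp_arm_rows": int(tf.nunique()),
        "as_published_total": int(wcr.nunique() + tf.nunique()),
        "distinct_union": int(both["snp"].nunique()),
    }
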