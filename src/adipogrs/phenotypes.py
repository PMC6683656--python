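"""Derived phenotypes and baseline summary reporting."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codify import pooled_t_from_stats
from .errors import DataError

__all__ = ["derive_phenotypes", "bmi", "tyg_index", "baseline_summary"]

#: variables summarized per arm when present
SUMMARY_VARS = [
    "age",
    "weight",
    "bmi",
    "baseline_tfat",
    "baseline_wc",
    "glucose",
    "tg",
    "tyg",
    "energy",
    "mets",
    "WCR",
    "TFATL",
]


def bmi(weight_kg, height_m):
    """Body mass index, weight (kg) over squared height (m²)."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if (w <= 0).any() or (h <= 0).any():
        raise DataError("weight and height must be positive")
    return w / h**2


def tyg_index(tg_mgdl, glucose_mgdl):
    """Triglyceride-glucose index, ln(TG × glucose / 2), both in mg/dl.

    Implemented exactly as defined.  Note the published baseline values of the
    emulated trial (≈ 4.5) are inconsistent with this natural-log formula,
    which yields ≈ 8.5 at the published TG/glucose means (they instead match a
    base-10 logarithm); the formula is kept as defined and the discrepancy is
    documented in the methods note.
    """
    tg = np.asarray(tg_mgdl, dtype=float)
    gl = np.asarray(glucose_mgdl, dtype=float)
    if (tg <= 0).any() or (gl <= 0).any():
        raise DataError("TG and glucose must be positive")
    return np.log(tg * gl / 2.0)


def derive_phenotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``bmi`` and (when TG/glucose present) ``tyg`` added."""
    out = cohort.copy()
    out["bmi"] = bmi(out["weight"], out["height"])
    if {"tg", "glucose"}.issubset(out.columns):
        out["tyg"] = tyg_index(out["tg"], out["glucose"])
    return out


def baseline_summary(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-arm mean ± SD table with pooled-t p-values, one row per variable.

    Requires both arms present.  Variables with zero variance in both arms get
    a NaN p-value.  The first row reports per-arm counts.
    """
    if "arm" not in cohort.columns:
        raise DataError("arm column missing")
    arms = sorted(cohort["arm"].unique().tolist())
    if len(arms) != 2:
        raise DataError(f"baseline_summary needs exactly two arms, got {arms}")
    a1, a2 = ("MHP", "LF") if set(arms) == {"MHP", "LF"} else arms
    g1 = cohort.loc[cohort["arm"] == a1]
    g2 = cohort.loc[cohort["arm"] == a2]
    variables = variables or [v for v in SUMMARY_VARS if v in cohort.columns]
    rows = [
        {
            "variable": "n",
            f"{a1}_mean": float(len(g1)),
            f"{a1}_sd": np.nan,
            f"{a2}_mean": float(len(g2)),
            f"{a2}_sd": np.nan,
            "p_value": np.nan,
        }
    ]
    for v in variables:
        x1 = g1[v].dropna().to_numpy(dtype=float)
        x2 = g2[v].dropna().to_numpy(dtype=float)
        m1, s1 = x1.mean(), x1.std(ddof=1)
        m2, s2 = x2.mean(), x2.std(ddof=1)
        if s1 == 0 and s2 == 0:
            p = np.nan
        else:
            _, p = pooled_t_from_stats(len(x1), m1, s1, len(x2), m2, s2)
        rows.append(
            {
                "variable": v,
                f"{a1}_mean": m1,
                f"{a1}_sd": s1,
                f"{a2}_mean": m2,
                f"{a2}_sd": s2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
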