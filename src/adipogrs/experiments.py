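"""Reproduction experiments at study conditions.

Each function here re-runs a defined piece of the pipeline on synthetic data
generated from the published tables (group sizes, means, SDs, model
coefficients) and returns the measured quantities: parameter recovery of the
codification stage, corrected-adjusted-R² behaviour of GRS vs single-SNP
models, the pure-noise overfitting demonstration, and the operating
characteristics of the screening and diagnostic tests under their nulls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import fixtures
from .codify import GenotypeRiskCodifier, SnpCodification
from .grs import GeneticRiskScorer
from .modeling import BestSubsetSelector, ModelSpec, build_design, fit_linear, select_stepwise
from .pipeline import candidate_terms
from .simulate import (
    apply_adherence_filter,
    canonical_genotype,
    simulate_cohort,
    simulate_genotypes,
    simulate_locus_from_groups,
    study_config,
    Locus,
    SimConfig,
)
from .phenotypes import derive_phenotypes
from .validation import optimism_validate

__all__ = [
    "recover_low_risk_mean",
    "published_panel_scores",
    "grs_vs_single_snp",
    "overfitting_null",
    "null_panel_selection_rate",
    "stepwise_null_inclusion",
    "bp_null_rate",
    "bsm_null_inclusion",
]


def _expand(gstr: str) -> frozenset:
    return frozenset(canonical_genotype(*g.strip()) for g in str(gstr).split("+"))


def recover_low_risk_mean(
    rsid: str,
    arm: str,
    outcome: str = "WCR",
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the codification stage for one published locus.

    For each replicate, an arm-sized cohort is simulated from the locus'
    published generating parameters (fixed group sizes, Gaussian outcomes),
    codification is run, and the sample mean of the group it labels low-risk
    is recorded; replicates where no labeling is possible are skipped and
    counted.  Returns the replicate average, its Monte-Carlo SE, and the
    published target mean.
    """
    cod = fixtures.load_reported_codifications(outcome)
    row = cod[(cod.snp == rsid) & (cod.arm == arm)].iloc[0]
    rng = np.random.default_rng(seed)
    means = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            G, y = simulate_locus_from_groups(row, rng)
            rec = GenotypeRiskCodifier(arm=arm, outcome=outcome).fit(G, y).codifications_[0]
            if rec.low_risk_genotypes:
                means.append(float(y[G[rsid].isin(rec.low_risk_genotypes)].mean()))
    means = np.asarray(means)
    return {
        "value": float(means.mean()),
        "mc_se": float(means.std(ddof=1) / np.sqrt(len(means))),
        "n": n_replicates,
        "n_labeled": int(len(means)),
        "target": float(row.mean_low),
    }


def published_panel_scores(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    arm: str,
    outcome: str,
    weights: str = "joint",
):
    """Indicators and GRS for the *published* codification panel of arm×outcome.

    Uses the printed low/high-risk genotype sets as the selected panel (the
    panel the published models were built on) rather than re-screening, so the
    modeling stage can be exercised without the selection-power confound.
    Returns ``(scores, snp_list)`` where scores holds ugrs, wgrs and the
    per-SNP indicators for the arm subset.
    """
    cod = fixtures.load_reported_codifications(outcome)
    cod = cod[cod.arm == arm]
    sub = cohort.loc[cohort["arm"] == arm]
    recs = [
        SnpCodification(
            snp=row.snp,
            arm=arm,
            outcome=outcome,
            low_risk_genotypes=_expand(row.low_genotypes),
            high_risk_genotypes=_expand(row.high_genotypes),
            status="selected",
        )
        for _, row in cod.iterrows()
    ]
    I = pd.DataFrame(
        {r.snp: r.indicator(genotypes.loc[sub.index, r.snp]) for r in recs},
        index=sub.index,
    )
    scorer = GeneticRiskScorer(weights=weights, missing="impute").fit(I, sub[outcome])
    scores = pd.concat([scorer.transform(I), I], axis=1)
    return scores, [r.snp for r in recs]


def grs_vs_single_snp(
    outcome: str = "WCR",
    arm: str = "MHP",
    n_seeds: int = 5,
    B: int = 200,
    seed: int = 1,
) -> pd.DataFrame:
    """Corrected adj. R² of GRS models vs single-SNP models at study scale.

    Per seed: simulate a full study cohort, score the published panel, then
    build and internally validate (honest bootstrap, best-subset search) one
    candidate model per gene term (uGRS, wGRS, each single SNP).  Returns one
    row per seed with the best corrected adj. R² among GRS models and among
    single-SNP models.
    """
    rows = []
    for s in range(n_seeds):
        cohort, genotypes = simulate_cohort(study_config(seed=seed + s))
        cohort, genotypes = apply_adherence_filter(cohort, genotypes)
        cohort = derive_phenotypes(cohort)
        scores, snps = published_panel_scores(cohort, genotypes, arm, outcome)
        sub = cohort.loc[cohort["arm"] == arm]
        corrected = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for gene in ["ugrs", "wgrs", *snps]:
                spec = ModelSpec(outcome, arm, tuple(candidate_terms(outcome, gene)))
                X, y = build_design(sub, scores, spec)
                rep = optimism_validate(
                    lambda Xb, yb: BestSubsetSelector().fit(Xb, yb).model_,
                    X.drop(columns="const"),
                    y,
                    B=B,
                    seed=seed + s,
                )
                corrected[gene] = rep.corrected_adj_r2
        rows.append(
            {
                "seed": seed + s,
                "corrected_grs": max(corrected["ugrs"], corrected["wgrs"]),
                "corrected_ugrs": corrected["ugrs"],
                "corrected_wgrs": corrected["wgrs"],
                "corrected_best_snp": max(corrected[s_] for s_ in snps),
            }
        )
    return pd.DataFrame(rows)


def _stepwise_builder(entry_p: float = 0.05):
    from .modeling import _refit

    def build(X, y):
        Xc = X.copy()
        if "const" not in Xc.columns:
            Xc.insert(0, "const", 1.0)
        y = pd.Series(np.asarray(y, dtype=float), index=Xc.index)
        terms = select_stepwise(Xc, y, entry_p=entry_p, hierarchy=False)
        return _refit(Xc, y, terms)

    return build


def overfitting_null(
    n: int = 50,
    p: int = 10,
    n_seeds: int = 50,
    B: int = 200,
    entry_p: float = 0.05,
    seed: int = 0,
) -> dict:
    """Pure-noise overfitting demonstration with stepwise selection.

    Response and all candidates are independent noise; selection is repeated
    inside every bootstrap resample.  Returns the seed-averaged apparent and
    optimism-corrected adjusted R² (apparent inflated by selection; corrected
    should sit near zero).  Intercept-only winners have apparent adj. R² 0.
    """
    master = np.random.default_rng(seed)
    apparents, correcteds = [], []
    build = _stepwise_builder(entry_p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_seeds):
            s = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(s)
            X = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
            )
            y = rng.normal(size=n)
            rep = optimism_validate(build, X, y, B=B, seed=s)
            apparents.append(rep.apparent_adj_r2)
            correcteds.append(rep.corrected_adj_r2)
    return {
        "mean_apparent": float(np.mean(apparents)),
        "mean_corrected": float(np.mean(correcteds)),
        "apparent": apparents,
        "corrected": correcteds,
    }


def null_panel_selection_rate(
    n_snps: int = 95,
    n_seeds: int = 200,
    n_subjects: int = 100,
    seed: int = 0,
) -> dict:
    """Null operating characteristics of the codification over a SNP panel.

    Genotypes under HWE (MAF uniform on 0.1–0.5), outcome independent noise.
    Returns the ANOVA-screen pass rate (calibrated at the marginal 0.10 gate),
    the full selection rate (strictly smaller: the partition and prevalence
    requirements remove part of the screen's false positives), the per-reason
    exclusion counts, and the Monte-Carlo SE of the rates.
    """
    master = np.random.default_rng(seed)
    mafs = master.uniform(0.1, 0.5, n_snps)
    loci = [Locus(f"rs{j:05d}", ("A", "G"), float(m)) for j, m in enumerate(mafs)]
    cfg = SimConfig(n_subjects=n_subjects, loci=loci, seed=0)
    n_selected = 0
    n_screen = 0
    reasons: dict[str, int] = {}
    total = n_snps * n_seeds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_seeds):
            rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
            G = simulate_genotypes(cfg, rng)
            y = pd.Series(rng.normal(0, 1, n_subjects), index=G.index)
            cod = GenotypeRiskCodifier(arm="", outcome="y").fit(G, y)
            n_selected += len(cod.selected_loci_)
            for r in cod.codifications_:
                if np.isfinite(r.anova_p) and r.anova_p < 0.10:
                    n_screen += 1
                key = r.status if r.selected else r.reason
                reasons[key] = reasons.get(key, 0) + 1
    screen = n_screen / total
    selected = n_selected / total
    return {
        "screen_rate": screen,
        "selected_rate": selected,
        "screen_mc_se": float(np.sqrt(screen * (1 - screen) / total)),
        "n_tests": total,
        "reasons": reasons,
    }


def stepwise_null_inclusion(
    n_seeds: int = 200,
    n: int = 100,
    p: int = 8,
    entry_p: float = 0.05,
    seed: int = 5,
) -> dict:
    """Per-term inclusion rate of bidirectional stepwise under pure noise.

    This is the calibration of the selection engine the bootstrap-stepwise
    method resamples: on independent null data each candidate should enter at
    roughly its entry level.  (On bootstrap *resamples* the rate is inflated
    by duplicate observations — see :func:`bsm_null_inclusion`.)  Returns the
    seed-averaged per-term rate and its across-seed Monte-Carlo SE.
    """
    master = np.random.default_rng(seed)
    rates = []
    for _ in range(n_seeds):
        rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
        X.insert(0, "const", 1.0)
        y = rng.normal(size=n)
        sel = select_stepwise(X, y, entry_p=entry_p, hierarchy=False)
        rates.append(len(sel) / p)
    rates = np.asarray(rates)
    return {
        "mean": float(rates.mean()),
        "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates))),
        "n_seeds": n_seeds,
    }


def bp_null_rate(n_seeds: int = 200, n: int = 200, seed: int = 0) -> float:
    """Breusch–Pagan rejection rate under homoscedastic normal errors."""
    from .modeling import diagnostics

    master = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_seeds):
        rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = X["a"] + rng.normal(size=n)
        Xc = X.copy()
        Xc.insert(0, "const", 1.0)
        model = fit_linear(Xc, y)
        if diagnostics(model, Xc)["bp_p"] < 0.05:
            rejections += 1
    return rejections / n_seeds


def bsm_null_inclusion(
    n_seeds: int = 200,
    B: int = 50,
    n: int = 100,
    p: int = 8,
    entry_p: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean per-term bootstrap-stepwise inclusion frequency under pure noise."""
    from .modeling import select_bootstrap_stepwise

    master = np.random.default_rng(seed)
    freqs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_seeds):
            s = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(s)
            X = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
            )
            X.insert(0, "const", 1.0)
            y = rng.normal(size=n)
            _, _, freq = select_bootstrap_stepwise(
                X, y, B=B, entry_p=entry_p, seed=s, hierarchy=False
            )
            freqs.append(freq.mean())
    return float(np.mean(freqs))
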