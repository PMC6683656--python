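"""End-to-end orchestration: simulate → filter → codify → score → model → validate."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codify import GenotypeRiskCodifier
from .errors import DataError
from .grs import GeneticRiskScorer
from .io import RunConfig, read_cohort, read_genotypes, write_cohort, write_genotypes_tsv
from .modeling import (
    BestSubsetSelector,
    BootstrapStepwiseSelector,
    LarsSelector,
    ModelSpec,
    build_design,
    diagnostics,
    fit_linear,
)
from .phenotypes import baseline_summary, derive_phenotypes
from .simulate import apply_adherence_filter, simulate_cohort, study_config
from .validation import ValidationReport, model_tournament, optimism_validate

log = logging.getLogger("adipogrs")

__all__ = ["run_pipeline", "candidate_terms", "interaction_slopes"]

#: conventional (non-genetic) candidate predictors per outcome
CONVENTIONAL = {
    "WCR": ["age", "sex", "baseline_wc", "mets", "energy100"],
    "TFATL": ["age", "sex", "baseline_tfat", "mets", "energy100"],
}
#: exposures crossed with the gene term in the candidate set
INTERACTION_EXPOSURES = {
    "WCR": ["mets", "energy100", "baseline_wc"],
    "TFATL": ["mets", "energy100", "baseline_tfat"],
}


def candidate_terms(outcome: str, gene_term: str) -> list[str]:
    """Candidate predictor list for one gene term: conventional main effects,
    the gene main effect, and gene × exposure products."""
    conv = CONVENTIONAL[outcome]
    inter = [f"{gene_term}:{e}" for e in INTERACTION_EXPOSURES[outcome]]
    return conv + [gene_term] + inter


def _make_selector(config: RunConfig, seed: int):
    if config.selector == "lars":
        return LarsSelector()
    if config.selector == "best_subset":
        return BestSubsetSelector()
    if config.selector == "bootstrap_stepwise":
        return BootstrapStepwiseSelector(
            B=max(50, config.B // 4),
            entry_p=config.entry_p,
            keep_fraction=config.keep_fraction,
            random_state=seed,
        )
    raise DataError(f"unknown selector {config.selector!r}")


def _builder(selector_factory):
    def build(X, y):
        sel = selector_factory()
        sel.fit(X, y)
        return sel.model_
    return build


def analyze_arm_outcome(
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame,
    arm: str,
    outcome: str,
    config: RunConfig,
    seed: int,
) -> dict:
    """Codify → score → fit and validate candidate models for one arm × outcome.

    Candidates: one model per selected single SNP, one uGRS model, one wGRS
    model; each candidate's terms are searched by the configured selector and
    internally validated with the bootstrap optimism correction (selection
    repeated inside every resample unless ``config.naive_validation``).
    """
    sub = cohort.loc[cohort["arm"] == arm]
    G = genotypes.loc[sub.index]
    codifier = GenotypeRiskCodifier(
        anova_p=config.anova_p,
        confirm_p=config.confirm_p,
        min_prevalence=config.min_prevalence,
        arm=arm,
        outcome=outcome,
    )
    codifier.fit(G, sub[outcome])
    result = {
        "arm": arm,
        "outcome": outcome,
        "codifications": codifier.codifications_,
        "selected_loci": codifier.selected_loci_,
    }
    if not codifier.selected_loci_:
        log.warning("%s/%s: no SNP survived codification", outcome, arm)
        result.update(scores=None, candidates=[], winner=None)
        return result

    indicators = codifier.transform(G)
    scorer = GeneticRiskScorer(weights=config.weights).fit(indicators, sub[outcome])
    scores = scorer.transform(indicators)
    scores = pd.concat([scores, indicators], axis=1)
    result["weights"] = scorer.weights_
    result["scores"] = scores

    rng = np.random.default_rng(seed)
    candidates = []
    gene_terms = ["ugrs", "wgrs"] + list(indicators.columns)
    for gene in gene_terms:
        spec = ModelSpec(outcome, arm, tuple(candidate_terms(outcome, gene)))
        X, y = build_design(sub, scores, spec)
        vseed = int(rng.integers(0, 2**31 - 1))
        report = optimism_validate(
            _builder(lambda vs=vseed: _make_selector(config, vs)),
            X.drop(columns="const"),
            y,
            B=config.B,
            seed=vseed,
            naive=config.naive_validation,
            selector_name=config.selector,
        )
        candidates.append(
            {"gene_term": gene, "spec": spec, "report": report, "design": (X, y)}
        )
    result["candidates"] = candidates
    winner = model_tournament([(c["gene_term"], c["report"]) for c in candidates])
    win = next(c for c in candidates if c["gene_term"] == winner[0])
    X, y = win["design"]
    final = fit_linear(X[["const", *winner[1].terms]], y)
    result["winner"] = {
        "gene_term": winner[0],
        "report": winner[1],
        "model": final,
        "diagnostics": diagnostics(final, X),
    }
    return result


def interaction_slopes(
    model, X: pd.DataFrame, gene_term: str, exposure: str, gene_values=(0, 3)
) -> pd.DataFrame:
    """Fitted outcome-vs-exposure slope at chosen gene-score values.

    For a model with terms {gene, exposure, gene:exposure}, the slope of the
    outcome against the exposure at gene score g is
    coef(exposure) + g·coef(gene:exposure) — the tabular counterpart of the
    usual interaction plot.
    """
    b_exp = float(model.params.get(exposure, 0.0))
    b_int = float(model.params.get(f"{gene_term}:{exposure}", 0.0))
    rows = [
        {"gene_term": gene_term, "value": g, "slope": b_exp + g * b_int}
        for g in gene_values
    ]
    return pd.DataFrame(rows)


def _codification_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        low = "+".join(sorted(r.low_risk_genotypes))
        high = "+".join(sorted(r.high_risk_genotypes))
        stats = r.group_stats or {}
        lo = stats.get("low", (np.nan, np.nan, np.nan))
        hi = stats.get("high", (np.nan, np.nan, np.nan))
        rows.append(
            {
                "snp": r.snp,
                "arm": r.arm,
                "outcome": r.outcome,
                "low_genotypes": low,
                "high_genotypes": high,
                "n_low": lo[0],
                "n_high": hi[0],
                "mean_low": lo[1],
                "sd_low": lo[2],
                "mean_high": hi[1],
                "sd_high": hi[2],
                "anova_p": r.anova_p,
                "dichotomy_p": r.dichotomy_p,
                "status": r.status,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; write stage outputs under ``config.out_dir``.

    Returns a dict with the cohort, genotype matrix, per-arm×outcome analysis
    results and the four tournament winners.  Byte-identical outputs under a
    fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        sim = study_config(
            seed=config.seed, n_loci=config.n_loci, n_subjects=config.n_subjects
        )
        cohort, genotypes = simulate_cohort(sim)
        cohort = derive_phenotypes(cohort)
    else:
        cohort = read_cohort(config.cohort)
        genotypes = read_genotypes(config.genotypes)
        cohort = derive_phenotypes(cohort)

    cohort, genotypes = apply_adherence_filter(cohort, genotypes)
    n_removed = cohort.attrs.get("n_removed", 0)
    log.info("adherence filter removed %d subject(s)", n_removed)

    write_cohort(cohort, out / "cohort.csv")
    write_genotypes_tsv(genotypes, out / "genotypes.tsv")
    baseline_summary(cohort).to_csv(out / "baseline_summary.tsv", sep="\t", index=False)

    rng = np.random.default_rng(config.seed)
    results = {}
    winners = {}
    for outcome in config.outcomes:
        for arm in config.arms:
            seed = int(rng.integers(0, 2**31 - 1))
            res = analyze_arm_outcome(cohort, genotypes, arm, outcome, config, seed)
            key = f"{outcome}-{arm}"
            results[key] = res
            _codification_frame(res["codifications"]).to_csv(
                out / f"codification_{key}.tsv", sep="\t", index=False
            )
            if res.get("scores") is not None:
                res["scores"][["ugrs", "wgrs"]].to_csv(out / f"scores_{key}.csv")
            if res["winner"] is not None:
                winners[key] = res["winner"]
                _write_model_json(out / f"model_{key}.json", res, key)

    run_log = {
        "version": __version__,
        "config": config.to_dict(),
        "n_removed_adherence": int(n_removed),
        "winners": {
            k: {
                "gene_term": w["gene_term"],
                "terms": list(w["report"].terms),
                "corrected_adj_r2": w["report"].corrected_adj_r2,
            }
            for k, w in winners.items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return {"cohort": cohort, "genotypes": genotypes, "results": results, "winners": winners}


def _write_model_json(path: Path, res: dict, key: str) -> None:
    w = res["winner"]
    model = w["model"]
    report: ValidationReport = w["report"]
    payload = {
        "key": key,
        "gene_term": w["gene_term"],
        "coefficients": {k: float(v) for k, v in model.params.items()},
        "pc2": report.pc2,
        "n": model.nobs,
        "r2": model.rsquared,
        "adj_r2": model.rsquared_adj,
        "validation": report.to_dict(),
        "diagnostics": {
            "bp_p": w["diagnostics"]["bp_p"],
            "vif": w["diagnostics"]["vif"],
            "flagged": w["diagnostics"]["flagged"],
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
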