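"""Multiple linear regression with three model-search strategies.

Models predict a signed adiposity change (WCR or TFATL) within one diet arm
from genetic terms (single-SNP indicators, uGRS, wGRS), phenotypic terms (age,
sex, baseline WC or TFAT), environmental exposures (METs, energy intake per
100 kcal) and gene × environment products (raw-scale, no centering).  Search
strategies: least-angle regression truncated by Mallows' Cp, exhaustive
best-subset by adjusted R² (or BIC), and bootstrapped bidirectional stepwise
selection with an inclusion-frequency keep rule.  Hierarchy is enforced by
default: an interaction term g:e may be selected only when the gene main
effect g is in the model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lars_path
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import DataError

__all__ = [
    "ModelSpec",
    "FittedModel",
    "build_design",
    "fit_linear",
    "select_lars",
    "select_best_subset",
    "select_stepwise",
    "select_bootstrap_stepwise",
    "diagnostics",
    "LarsSelector",
    "BestSubsetSelector",
    "BootstrapStepwiseSelector",
]

#: cohort/score variables a model term may reference, and the gene terms that
#: may anchor an interaction
GENE_TERMS = ("ugrs", "wgrs")
EXPOSURE_TERMS = ("mets", "energy100", "baseline_wc", "baseline_tfat", "age", "sex")


@dataclass(frozen=True)
class ModelSpec:
    """A model skeleton: outcome, arm, and ordered predictor terms.

    Interaction terms are written ``gene:exposure`` (e.g. ``ugrs:mets``) and
    must pair a gene term (uGRS, wGRS or a SNP indicator) with a phenotype or
    exposure.  Duplicate terms are rejected.
    """

    outcome: str
    arm: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise DataError(f"duplicate terms in spec: {self.terms}")
        for t in self.terms:
            if ":" in t:
                g, e = t.split(":", 1)
                if not _is_gene_term(g) or e not in EXPOSURE_TERMS:
                    raise DataError(
                        f"interaction {t!r} must pair a gene term with one of "
                        f"{EXPOSURE_TERMS}"
                    )


def _is_gene_term(t: str) -> bool:
    return t in GENE_TERMS or t.startswith("rs") or t.startswith("snp_")


@dataclass
class FittedModel:
    """OLS fit summary: coefficients, classical SEs, t statistics, R²."""

    terms: tuple[str, ...]  # non-intercept design columns, in order
    params: pd.Series  # includes 'const'
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    nobs: int
    df_resid: int
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        M = np.column_stack(
            [np.ones(len(X))] + [X[t].to_numpy(dtype=float) for t in self.terms]
        )
        order = ["const", *self.terms]
        return M @ self.params.reindex(order).to_numpy()


@dataclass
class _Ols:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    adj_r2: float
    df_resid: int
    resid: np.ndarray


def _ols(X: np.ndarray, y: np.ndarray) -> _Ols:
    """Lean OLS on a design that already includes the intercept column."""
    n, k = X.shape
    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - k
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    rinv = np.linalg.inv(r)
    sigma2 = ss_res / df if df > 0 else np.nan
    se = np.sqrt(np.maximum((rinv @ rinv.T).diagonal() * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df) if df > 0 else np.full(k, np.nan)
    return _Ols(beta, se, t, p, r2, adj, df, resid)


def build_design(
    cohort: pd.DataFrame,
    scores: pd.DataFrame | None,
    spec: ModelSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the design matrix and response for a model spec.

    Columns: intercept, main effects (energy rescaled to 100-kcal units),
    interactions as raw elementwise products.  Rows with any missing value are
    dropped (count logged via a warning).
    """
    if not spec.terms:
        raise DataError("empty model spec")
    sub = cohort
    if spec.arm and "arm" in cohort.columns:
        sub = cohort.loc[cohort["arm"] == spec.arm]
    if spec.outcome not in sub.columns:
        raise DataError(f"outcome column {spec.outcome!r} missing")

    def resolve(term: str) -> pd.Series:
        if term == "energy100":
            return sub["energy"] / 100.0
        if term in sub.columns:
            return sub[term].astype(float)
        if scores is not None and term in scores.columns:
            return scores.loc[sub.index, term].astype(float)
        raise DataError(f"term {term!r} not found in cohort or scores")

    cols = {}
    for t in spec.terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols[t] = resolve(a) * resolve(b)
        else:
            cols[t] = resolve(t)
    X = pd.DataFrame(cols, index=sub.index)
    y = sub[spec.outcome].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"build_design: dropped {dropped} row(s) with missing values")
    X = X.loc[ok]
    X.insert(0, "const", 1.0)
    return X, y.loc[ok]


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = []
        for j in range(M.shape[1]):
            sub = np.delete(M, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(M):
                bad.append(X.columns[j])
        raise DataError(f"design is rank deficient; dependent columns: {bad}")


def fit_linear(X: pd.DataFrame, y) -> FittedModel:
    """OLS fit of a design (with 'const' column) via statsmodels."""
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if len(X) <= X.shape[1]:
        raise DataError("need n > number of columns")
    _check_rank(X)
    res = sm.OLS(y.to_numpy(), X.to_numpy(dtype=float)).fit()
    names = list(X.columns)
    terms = tuple(c for c in names if c != "const")
    return FittedModel(
        terms=terms,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        nobs=int(res.nobs),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
    )


def _refit(X: pd.DataFrame, y: pd.Series, terms: Sequence[str]) -> FittedModel:
    cols = ["const", *terms]
    return fit_linear(X[cols], y)


def _candidate_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c != "const"]


def _enforce_hierarchy(terms: list[str]) -> list[str]:
    out = list(terms)
    for t in terms:
        if ":" in t:
            g = t.split(":", 1)[0]
            if g not in out:
                out.insert(out.index(t), g)
    return out


def _hierarchy_ok(subset: Sequence[str]) -> bool:
    s = set(subset)
    return all(t.split(":", 1)[0] in s for t in s if ":" in t)


def select_lars(
    X: pd.DataFrame, y, stop_rule: str = "cp", hierarchy: bool = True
) -> tuple[list[str], FittedModel]:
    """Least-angle regression on standardized candidates, truncated by Cp.

    The LAR entry path is computed on standardized columns; the active set
    minimizing Mallows' Cp (σ² from the full OLS fit) is kept and refit by
    OLS on the raw scale.
    """
    cands = _candidate_columns(X)
    if not cands:
        raise DataError("no candidate columns")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    M = X[cands].to_numpy(dtype=float)
    Ms = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    ys = y.to_numpy() - y.mean()
    alphas, _, coefs = lars_path(Ms, ys, method="lar")
    full = _ols(np.column_stack([np.ones(len(y)), M]), y.to_numpy())
    sigma2 = float(full.resid @ full.resid) / max(full.df_resid, 1)
    n = len(y)
    best_terms, best_cp = [], np.inf
    for step in range(coefs.shape[1]):
        active = [cands[j] for j in np.flatnonzero(coefs[:, step])]
        k = len(active) + 1
        fit = _ols(
            np.column_stack([np.ones(n), X[active].to_numpy(float)]), y.to_numpy()
        )
        ss_res = float(fit.resid @ fit.resid)
        cp = ss_res / sigma2 - n + 2 * k
        if cp < best_cp - 1e-12:
            best_cp, best_terms = cp, active
    if hierarchy:
        best_terms = _enforce_hierarchy(best_terms)
    if not best_terms:  # Cp minimum at the null model: keep first entrant
        j = int(np.flatnonzero(coefs[:, 1])[0]) if coefs.shape[1] > 1 else 0
        best_terms = [cands[j]]
    return best_terms, _refit(X, y, best_terms)


def select_best_subset(
    X: pd.DataFrame,
    y,
    criterion: str = "adj_r2",
    max_p: int = 20,
    hierarchy: bool = True,
) -> tuple[list[str], FittedModel]:
    """Exhaustive best-subset search over all 2^p candidate subsets.

    ``criterion='adj_r2'`` maximizes adjusted R²; ``'bic'`` minimizes BIC.
    Refuses more than ``max_p`` candidates (use LARS or bootstrap stepwise
    instead).  Ties break toward fewer terms, then lexicographic term order.
    """
    cands = _candidate_columns(X)
    p = len(cands)
    if p > max_p:
        raise DataError(
            f"{p} candidates exceed the exhaustive guard ({max_p}); "
            "use select_lars or select_bootstrap_stepwise"
        )
    if criterion not in ("adj_r2", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    yv = y.to_numpy()
    n = len(yv)
    # sufficient statistics: RSS of any subset needs only the Gram blocks
    Z = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in cands])
    G = Z.T @ Z
    g = Z.T @ yv
    yy = float(yv @ yv)
    ss_tot = yy - n * float(yv.mean()) ** 2

    def score(ix: tuple[int, ...]) -> float:
        sel = (0, *ix)
        try:
            beta = np.linalg.solve(G[np.ix_(sel, sel)], g[list(sel)])
        except np.linalg.LinAlgError:
            return np.inf
        ss_res = max(yy - float(g[list(sel)] @ beta), 0.0)
        k = len(ix)
        if criterion == "adj_r2":
            df = n - k - 1
            if df <= 0 or ss_tot <= 0:
                return np.inf
            return (ss_res / df) / (ss_tot / (n - 1)) - 1.0  # = -adj R²
        return n * np.log(max(ss_res, 1e-300) / n) + (k + 1) * np.log(n)

    best, best_key = (), None
    for r in range(p + 1):
        for subset in itertools.combinations(range(1, p + 1), r):
            names = tuple(cands[j - 1] for j in subset)
            if hierarchy and not _hierarchy_ok(names):
                continue
            key = (round(score(subset), 12), len(subset), names)
            if best_key is None or key < best_key:
                best_key, best = key, names
    terms = list(best)
    return terms, _refit(X, y, terms)


def select_stepwise(
    X: pd.DataFrame,
    y,
    entry_p: float = 0.05,
    stay_p: float | None = None,
    hierarchy: bool = True,
    max_steps: int = 100,
) -> list[str]:
    """Bidirectional p-value stepwise selection (entry/stay at ``entry_p``)."""
    stay_p = entry_p if stay_p is None else stay_p
    cands = _candidate_columns(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    cols = {c: X[c].to_numpy(dtype=float) for c in cands}
    ones = np.ones(n)
    current: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward: best admissible candidate
        best_c, best_p = None, entry_p
        in_set = set(current)
        for c in cands:
            if c in in_set:
                continue
            if hierarchy and ":" in c and c.split(":", 1)[0] not in in_set:
                continue
            M = np.column_stack([ones] + [cols[t] for t in current] + [cols[c]])
            if np.linalg.matrix_rank(M) < M.shape[1] or n <= M.shape[1]:
                continue
            fit = _ols(M, yv)
            pc = fit.p[-1]
            if pc < best_p:
                best_p, best_c = pc, c
        if best_c is not None:
            current.append(best_c)
            changed = True
        # backward: drop the worst removable term
        while current:
            M = np.column_stack([ones] + [cols[t] for t in current])
            fit = _ols(M, yv)
            pvals = fit.p[1:]
            locked = set()
            if hierarchy:
                locked = {t.split(":", 1)[0] for t in current if ":" in t}
            removable = [
                (pv, t)
                for pv, t in zip(pvals, current)
                if t not in locked and pv > stay_p
            ]
            if not removable:
                break
            _, worst = max(removable)
            current.remove(worst)
            changed = True
        if not changed:
            break
    return current


def select_bootstrap_stepwise(
    X: pd.DataFrame,
    y,
    B: int = 100,
    entry_p: float = 0.05,
    keep_fraction: float = 0.6,
    seed: int | np.random.Generator = 0,
    hierarchy: bool = True,
) -> tuple[list[str], FittedModel, pd.Series]:
    """Bootstrapped stepwise: keep terms selected in ≥ ``keep_fraction`` of
    ``B`` resamples; refit the kept terms by OLS on the original data.

    Returns ``(terms, fit, inclusion_frequencies)``.  Degenerate resamples
    (constant response) are redrawn and counted in a warning.
    """
    if B < 50:
        raise DataError("B must be >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    n = len(y)
    counts = pd.Series(0.0, index=_candidate_columns(X))
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        yb = y.to_numpy()[idx]
        if np.ptp(yb) == 0:
            redrawn += 1
            if redrawn > 10 * B:
                raise DataError("bootstrap resampling keeps degenerating")
            continue
        Xb = X.iloc[idx].reset_index(drop=True)
        sel = select_stepwise(Xb, yb, entry_p=entry_p, hierarchy=hierarchy)
        counts[sel] += 1.0
        b += 1
    if redrawn:
        warnings.warn(f"bootstrap stepwise: redrew {redrawn} degenerate resample(s)")
    freq = counts / B
    terms = [c for c in counts.index if freq[c] >= keep_fraction]
    if hierarchy:
        terms = _enforce_hierarchy(terms)
    if terms:
        fit = _refit(X, y, terms)
    else:
        fit = fit_linear(X[["const"]], y)
    return terms, fit, freq


def diagnostics(model: FittedModel, X: pd.DataFrame) -> dict:
    """Residual homoscedasticity (Breusch–Pagan) and multicollinearity (VIF).

    Flags the model when BP p < 0.05 or any VIF > 10.  Duplicated or perfectly
    collinear predictors get infinite VIF.
    """
    cols = ["const", *model.terms]
    M = X[cols].to_numpy(dtype=float)
    bp_p = float(het_breuschpagan(model.resid, M)[1]) if model.terms else np.nan
    vifs = {}
    for j, t in enumerate(model.terms, start=1):
        others = np.delete(M, j, axis=1)
        xj = M[:, j]
        fit = _ols(others, xj)
        r2 = fit.r2
        vifs[t] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    flagged = (np.isfinite(bp_p) and bp_p < 0.05) or any(
        v > 10 for v in vifs.values()
    )
    return {"bp_p": bp_p, "vif": vifs, "flagged": bool(flagged)}


# ---------------------------------------------------------------------------
# estimator front-ends


class _SelectorBase(BaseEstimator, RegressorMixin):
    """Shared fit/predict plumbing for the three search strategies."""

    def fit(self, X: pd.DataFrame, y):
        X = self._with_const(X)
        self.selected_terms_, self.model_ = self._select(X, y)
        self.n_features_in_ = X.shape[1] - 1
        return self

    @staticmethod
    def _with_const(X: pd.DataFrame) -> pd.DataFrame:
        if "const" not in X.columns:
            X = X.copy()
            X.insert(0, "const", 1.0)
        return X

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")
        return self.model_.predict(X)

    @property
    def rsquared_adj_(self) -> float:
        return self.model_.rsquared_adj


class LarsSelector(_SelectorBase):
    """Least-angle regression selector: LAR path, Mallows-Cp stop, OLS refit."""

    def __init__(self, stop_rule: str = "cp", hierarchy: bool = True):
        self.stop_rule = stop_rule
        self.hierarchy = hierarchy

    def _select(self, X, y):
        return select_lars(X, y, stop_rule=self.stop_rule, hierarchy=self.hierarchy)


class BestSubsetSelector(_SelectorBase):
    """Exhaustive best-subset selector (adjusted R² or BIC), p ≤ 20."""

    def __init__(
        self, criterion: str = "adj_r2", max_p: int = 20, hierarchy: bool = True
    ):
        self.criterion = criterion
        self.max_p = max_p
        self.hierarchy = hierarchy

    def _select(self, X, y):
        return select_best_subset(
            X, y, criterion=self.criterion, max_p=self.max_p, hierarchy=self.hierarchy
        )


class BootstrapStepwiseSelector(_SelectorBase):
    """Bootstrapped bidirectional stepwise with an inclusion-frequency rule."""

    def __init__(
        self,
        B: int = 100,
        entry_p: float = 0.05,
        keep_fraction: float = 0.6,
        random_state: int = 0,
        hierarchy: bool = True,
    ):
        self.B = B
        self.entry_p = entry_p
        self.keep_fraction = keep_fraction
        self.random_state = random_state
        self.hierarchy = hierarchy

    def _select(self, X, y):
        terms, fit, freq = select_bootstrap_stepwise(
            X,
            y,
            B=self.B,
            entry_p=self.entry_p,
            keep_fraction=self.keep_fraction,
            seed=self.random_state,
            hierarchy=self.hierarchy,
        )
        self.inclusion_frequencies_ = freq
        return terms, fit
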