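"""Unweighted and weighted genetic risk scores (uGRS / wGRS).

Given the binary high-risk indicator matrix of the selected loci, the uGRS of
a subject is the plain count of high-risk genotypes, so one unit corresponds
to one additional risk genotype.  The wGRS weights each indicator by a
per-locus effect size β_j in outcome units (cm for WCR, % for TFATL) and sums
the products:  wGRS = Σ_j β_j · I_j.

β_j is estimated by joint multivariable OLS of the signed outcome change on
all selected indicators (default) — the only scheme that can produce the
negative weights a below-zero wGRS lower bound implies — or, optionally, by
per-locus group-mean differences (``weights='univariate'``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError

__all__ = [
    "compute_ugrs",
    "estimate_weights",
    "compute_wgrs",
    "GeneticRiskScorer",
]


def _as_indicator_frame(indicators) -> pd.DataFrame:
    I = pd.DataFrame(indicators).astype(float)
    vals = I.to_numpy()
    ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
    if not ok.all():
        raise DataError("indicators must be 0/1 (or NaN for missing)")
    return I


def compute_ugrs(indicators) -> pd.Series:
    """Unweighted GRS: integer count of high-risk genotypes per subject.

    Rows with any missing indicator yield NaN (the subject cannot be scored).
    """
    I = _as_indicator_frame(indicators)
    s = I.sum(axis=1, skipna=False)
    return s.rename("ugrs")


def estimate_weights(outcome, indicators, method: str = "joint") -> pd.Series:
    """Per-locus β (outcome units) for the wGRS.

    ``joint``: coefficients of the multivariable OLS of the signed outcome on
    all indicators plus an intercept.  ``univariate``: per-locus difference of
    group means (high − low).  Subjects with missing indicators or outcome are
    dropped from estimation.
    """
    I = _as_indicator_frame(indicators)
    y = pd.Series(np.asarray(outcome, dtype=float), index=I.index)
    ok = I.notna().all(axis=1) & y.notna()
    Iv, yv = I.loc[ok], y.loc[ok]
    if Iv.shape[0] <= Iv.shape[1] + 1:
        raise DataError("need n > number of loci + 1 to estimate weights")
    if method == "univariate":
        betas = {}
        for c in Iv.columns:
            hi, lo = yv[Iv[c] == 1.0], yv[Iv[c] == 0.0]
            if hi.empty or lo.empty:
                raise DataError(f"locus {c}: a risk group is empty")
            betas[c] = hi.mean() - lo.mean()
        return pd.Series(betas, name="beta")
    if method != "joint":
        raise ValueError(f"unknown weighting scheme {method!r}")
    X = np.column_stack([np.ones(len(Iv)), Iv.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(Iv)
        raise DataError(f"rank-deficient indicator matrix; check loci {collinear}")
    beta, *_ = np.linalg.lstsq(X, yv.to_numpy(), rcond=None)
    return pd.Series(beta[1:], index=Iv.columns, name="beta")


def _collinear_columns(I: pd.DataFrame) -> list[str]:
    cols = list(I.columns)
    bad = []
    X = I.to_numpy()
    base_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(I)), X]))
    for j, c in enumerate(cols):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(I)), sub])) == base_rank:
            bad.append(c)
    return bad


def compute_wgrs(indicators, weights: pd.Series) -> pd.Series:
    """Weighted GRS: Σ β_j · I_j per subject (NaN when any indicator missing)."""
    I = _as_indicator_frame(indicators)
    w = pd.Series(weights, dtype=float)
    if set(I.columns) != set(w.index):
        raise DataError(
            f"locus mismatch between indicators {list(I.columns)} and "
            f"weights {list(w.index)}"
        )
    return (I * w.reindex(I.columns)).sum(axis=1, skipna=False).rename("wgrs")


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Fit per-locus wGRS weights and emit per-subject uGRS/wGRS columns.

    ``fit(I, y)`` estimates the weights on the indicator matrix ``I`` (the
    output of :class:`~adipogrs.codify.GenotypeRiskCodifier.transform`) and the
    signed outcome ``y``; ``transform(I)`` returns a frame with ``ugrs`` and
    ``wgrs`` columns.  Weights are estimated on the same arm/outcome data
    being scored — the in-sample reuse that the downstream bootstrap optimism
    correction accounts for.

    Parameters
    ----------
    weights : {'joint', 'univariate'}
        β estimation scheme (see :func:`estimate_weights`).
    missing : {'drop', 'impute'}
        Subjects with a missing indicator get NaN scores ('drop', default) or
        have the missing indicator replaced by its locus mean ('impute').
    """

    def __init__(self, weights: str = "joint", missing: str = "drop"):
        self.weights = weights
        self.missing = missing

    def fit(self, X, y):
        I = _as_indicator_frame(X)
        self.weights_ = estimate_weights(y, I, method=self.weights)
        self.loci_ = list(I.columns)
        self.indicator_means_ = I.mean()
        self.n_features_in_ = I.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            raise RuntimeError("GeneticRiskScorer is not fitted")
        I = _as_indicator_frame(X)[self.loci_]
        if self.missing == "impute":
            # mean-imputed indicators are fractional, so sum directly
            I = I.fillna(self.indicator_means_)
            ugrs = I.sum(axis=1, skipna=False).rename("ugrs")
            wgrs = (I * self.weights_.reindex(self.loci_)).sum(
                axis=1, skipna=False
            ).rename("wgrs")
            return pd.DataFrame({"ugrs": ugrs, "wgrs": wgrs}, index=I.index)
        return pd.DataFrame(
            {"ugrs": compute_ugrs(I), "wgrs": compute_wgrs(I, self.weights_)},
            index=I.index,
        )
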