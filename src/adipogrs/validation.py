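"""Internal validation: bootstrap optimism correction, PC², model tournament.

The optimism correction follows Harrell's bootstrap algorithm: the *entire*
model-building process (variable selection included) is re-run on each of B
bootstrap resamples; the optimism of a resample is the drop in adjusted R²
when the resample's model is applied back to the original data, and the
corrected value is the apparent adjusted R² minus the mean optimism.  The
individual contribution of each predictor is its squared partial correlation
PC² = t² / (t² + residual df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .modeling import FittedModel

__all__ = [
    "ValidationReport",
    "adjusted_r2",
    "optimism_validate",
    "partial_contributions",
    "model_tournament",
]


@dataclass
class ValidationReport:
    """Apparent vs optimism-corrected adjusted R² plus per-predictor PC²."""

    apparent_adj_r2: float
    optimism: float
    corrected_adj_r2: float
    B: int
    pc2: dict = field(default_factory=dict)
    selector: str = ""
    seed: int | None = None
    terms: tuple = ()
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "apparent_adj_r2": self.apparent_adj_r2,
            "optimism": self.optimism,
            "corrected_adj_r2": self.corrected_adj_r2,
            "B": self.B,
            "pc2": dict(self.pc2),
            "selector": self.selector,
            "seed": self.seed,
            "terms": list(self.terms),
            "n_redrawn": self.n_redrawn,
        }


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) for p predictors."""
    if not 0.0 <= r2 <= 1.0:
        raise DataError(f"r2 must be in [0, 1], got {r2}")
    if n <= p + 1:
        raise DataError(f"need n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _adj_r2_of_predictions(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n = len(y)
    # out-of-fit R² can be negative; apply the same (n,p) adjustment either way
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def optimism_validate(
    builder: Callable[[pd.DataFrame, pd.Series], FittedModel],
    X: pd.DataFrame,
    y,
    B: int = 500,
    seed: int | np.random.Generator = 0,
    naive: bool = False,
    selector_name: str = "",
) -> ValidationReport:
    """Harrell bootstrap optimism correction of the adjusted R².

    ``builder(X, y)`` must run the full model-building process — selection and
    fit — and return a :class:`FittedModel`.  For b = 1..B the process is
    re-run on a with-replacement resample; optimism_b = adj R²(boot model on
    boot data) − adj R²(boot model applied to the original data).  With
    ``naive=True`` the apparent model's *terms* are frozen and only refit on
    each resample (selection not repeated), for comparison.

    Resamples on which building fails (degenerate data, selection error) are
    redrawn and counted.
    """
    if B < 100:
        raise DataError("B must be >= 100 for reported results")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    apparent_model = builder(X, y)
    apparent = apparent_model.rsquared_adj

    if naive:
        frozen = list(apparent_model.terms)
        from .modeling import _refit  # fixed-terms refit

        def build(Xb, yb):
            return _refit(Xb, yb, frozen)
    else:
        build = builder

    n = len(y)
    yv = y.to_numpy()
    optimisms = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        yb = yv[idx]
        if np.ptp(yb) == 0:
            redrawn += 1
            continue
        Xb = X.iloc[idx].reset_index(drop=True)
        try:
            mb = build(Xb, pd.Series(yb))
        except (DataError, np.linalg.LinAlgError):
            redrawn += 1
            if redrawn > 10 * B:
                raise DataError("model building keeps failing on resamples")
            continue
        p = len(mb.terms)
        yhat = mb.predict(X)
        test_adj = _adj_r2_of_predictions(yv, yhat, p)
        optimisms[b] = mb.rsquared_adj - test_adj
        b += 1
    if redrawn:
        warnings.warn(f"optimism_validate: redrew {redrawn} resample(s)")
    optimism = float(optimisms.mean())
    return ValidationReport(
        apparent_adj_r2=float(apparent),
        optimism=optimism,
        corrected_adj_r2=float(apparent - optimism),
        B=B,
        pc2=partial_contributions(apparent_model),
        selector=selector_name,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        terms=tuple(apparent_model.terms),
        n_redrawn=redrawn,
    )


def partial_contributions(model: FittedModel) -> dict:
    """Squared partial correlation PC² = t²/(t² + df_resid) per predictor."""
    out = {}
    for t in model.terms:
        tv = float(model.tvalues[t])
        out[t] = tv**2 / (tv**2 + model.df_resid)
    return out


def model_tournament(candidates: Sequence[tuple]) -> tuple:
    """Pick the candidate with the highest optimism-corrected adjusted R².

    ``candidates`` is a sequence of ``(label_or_spec, ValidationReport)``.
    Ties break toward fewer terms, then lexicographic term order.
    """
    if not candidates:
        raise DataError("model_tournament needs at least one candidate")
    def key(item):
        _, report = item
        return (
            -report.corrected_adj_r2,
            len(report.terms),
            tuple(sorted(report.terms)),
        )
    return min(candidates, key=key)
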