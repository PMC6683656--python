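"""Per-SNP genotype risk codification.

For one diet arm and one signed outcome change (WCR in cm or TFATL in %,
negative = reduction), each biallelic SNP is screened and dichotomized:

1. one-way ANOVA across genotype groups (entry gate P < 0.10 by default —
   "statistically or marginally associated");
2. pairwise post hoc tests — Bonferroni-adjusted pooled t when group variances
   are homogeneous by Levene's test, Dunnett-T3-style Welch t otherwise —
   merging genotypes with similar effects (P > 0.05) into a single category;
3. a pooled two-sample t-test confirming the low-risk vs high-risk dichotomy
   (kept when P < 0.10, strict);
4. a prevalence filter excluding SNPs where either risk group holds < 10 % of
   the arm.

The *low-risk* group is the one with the better response, i.e. the more
negative mean change; *high-risk* genotypes are coded 1 in downstream scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError

__all__ = [
    "SnpCodification",
    "ks_normality",
    "anova_screen",
    "posthoc_partition",
    "dichotomy_test",
    "pooled_t_from_stats",
    "prevalence_check",
    "codify_panel",
    "GenotypeRiskCodifier",
]


@dataclass
class SnpCodification:
    """Screening record for one SNP × arm × outcome."""

    snp: str
    arm: str
    outcome: str
    low_risk_genotypes: frozenset = frozenset()
    high_risk_genotypes: frozenset = frozenset()
    group_stats: dict = field(default_factory=dict)  # 'low'/'high' -> (n, mean, sd)
    genotype_stats: dict = field(default_factory=dict)  # genotype -> (n, mean, sd)
    anova_f: float = float("nan")
    anova_p: float = float("nan")
    posthoc_pairs: dict = field(default_factory=dict)  # (g1, g2) -> adjusted p
    posthoc_method: str = ""
    dichotomy_p: float = float("nan")
    status: str = "excluded"
    reason: str = ""

    @property
    def selected(self) -> bool:
        return self.status == "selected"

    def indicator(self, genotypes: pd.Series) -> pd.Series:
        """0/1 high-risk indicator per subject; NaN for missing/unseen calls."""
        seen = self.low_risk_genotypes | self.high_risk_genotypes

        def code(g):
            if g is None or g != g or g not in seen:
                return np.nan
            return 1.0 if g in self.high_risk_genotypes else 0.0

        return genotypes.map(code).astype(float)


def ks_normality(values) -> float:
    """Kolmogorov–Smirnov composite-normality p-value (Lilliefors correction).

    The null is that the data are normal with unknown mean and variance;
    callers treat P > 0.05 as consistent with normality.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise DegenerateInputError("ks_normality needs >= 8 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("ks_normality: constant vector")
    _, p = lilliefors(x, dist="norm")
    return float(p)


def anova_screen(groups: Sequence) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over genotype groups -> (F, p).

    Groups with fewer than 2 observations are dropped with a warning.  With
    fewer than 2 usable groups the screen cannot run.  Zero within-group
    variance with distinct group means is reported as (inf, 0.0).
    """
    usable = [np.asarray(g, dtype=float) for g in groups]
    usable = [g[~np.isnan(g)] for g in usable]
    dropped = [g for g in usable if g.size < 2]
    if dropped:
        warnings.warn(f"anova_screen: dropped {len(dropped)} group(s) with n < 2")
    usable = [g for g in usable if g.size >= 2]
    if len(usable) < 2:
        raise DegenerateInputError("anova_screen needs >= 2 groups with n >= 2")
    allv = np.concatenate(usable)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in usable)
    if np.ptp(allv) == 0:
        raise DegenerateInputError("anova_screen: all values identical")
    if ssw == 0:
        return float("inf"), 0.0
    f, p = stats.f_oneway(*usable)
    return float(f), float(p)


def _pairwise_p(
    g1: np.ndarray, g2: np.ndarray, n_pairs: int, welch: bool
) -> float:
    """Adjusted pairwise p: Bonferroni pooled t, or Welch t with a
    Šidák-style studentized-maximum-modulus bound (Dunnett-T3 flavour)."""
    if welch:
        t, p = stats.ttest_ind(g1, g2, equal_var=False)
        return float(min(1.0, 1.0 - (1.0 - p) ** n_pairs)) if n_pairs > 1 else float(p)
    _, p = stats.ttest_ind(g1, g2, equal_var=True)
    return float(min(1.0, p * n_pairs))


def posthoc_partition(
    groups: Mapping[str, Sequence], levene_p: float = 0.05, sim_p: float = 0.05
):
    """Cluster genotype groups into a (low-risk, high-risk) two-block partition.

    Pairwise post hoc p-values use Bonferroni-adjusted pooled t-tests when
    Levene's test accepts variance homogeneity (P >= ``levene_p``) and
    Welch-based Dunnett-T3-style tests otherwise.  With three or more groups,
    genotypes whose pairwise p > ``sim_p`` are merged:

    - exactly two similarity components -> that partition;
    - all genotypes mutually similar -> no partition (``None``);
    - no mergeable pair, or an ambiguous chain -> split the genotypes sorted
      by mean at the largest adjacent-mean gap.

    With exactly two genotype groups there is nothing to merge; the partition
    is the two singletons, and whether the dichotomy holds up is the business
    of the downstream confirmation t-test (several published codifications
    with only two observed genotypes carry confirmation p-values above 0.05,
    so the partition stage cannot itself be requiring pairwise p < 0.05).

    Returns ``(low_set, high_set, pair_p, method)`` or ``None``; the block
    with the more negative mean (greater reduction) is low-risk.
    """
    keys = [k for k in groups if len(np.asarray(groups[k], float)) >= 2]
    arrs = {k: np.asarray(groups[k], dtype=float) for k in keys}
    if len(keys) < 2:
        return None
    if len(keys) == 2:
        # nothing to merge with two genotypes: the partition is the two
        # singletons and its confirmation is the downstream dichotomy t-test
        welch = stats.levene(*arrs.values(), center="median")[1] < levene_p
        method = "dunnett_t3" if welch else "bonferroni"
        a, b = keys
        pair_p = {(a, b): _pairwise_p(arrs[a], arrs[b], 1, welch)}
        blocks = [{a}, {b}]
    else:
        welch = stats.levene(*arrs.values(), center="median")[1] < levene_p
        method = "dunnett_t3" if welch else "bonferroni"
        pairs = list(combinations(keys, 2))
        pair_p = {
            (a, b): _pairwise_p(arrs[a], arrs[b], len(pairs), welch)
            for a, b in pairs
        }
        # similarity graph: edge where the post hoc test does not separate
        parent = {k: k for k in keys}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_edges = 0
        for (a, b), p in pair_p.items():
            if p > sim_p:
                n_edges += 1
                parent[find(a)] = find(b)
        comps: dict[str, set] = {}
        for k in keys:
            comps.setdefault(find(k), set()).add(k)
        blocks = list(comps.values())
        n_pairs_similar = sum(1 for p in pair_p.values() if p > sim_p)
        if len(blocks) == 1 and n_pairs_similar == len(pair_p):
            return None  # all genotypes mutually similar
        if len(blocks) != 2:
            # no mergeable pair, or an ambiguous similarity chain: dichotomize
            # at the largest gap between mean-sorted genotypes
            blocks = _gap_split(arrs)
    means = [np.mean(np.concatenate([arrs[k] for k in blk])) for blk in blocks]
    low_i = int(np.argmin(means))  # more negative change = better response
    low = frozenset(blocks[low_i])
    high = frozenset(blocks[1 - low_i])
    return low, high, pair_p, method


def _gap_split(arrs: Mapping[str, np.ndarray]) -> list[set]:
    """Dichotomize groups sorted by mean at the largest adjacent gap."""
    order = sorted(arrs, key=lambda k: arrs[k].mean())
    means = [arrs[k].mean() for k in order]
    gaps = np.diff(means)
    cut = int(np.argmax(gaps)) + 1
    return [set(order[:cut]), set(order[cut:])]


def dichotomy_test(low, high) -> float:
    """Two-sided pooled-variance t-test p for the low vs high risk groups."""
    a = np.asarray(low, dtype=float)
    b = np.asarray(high, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("dichotomy_test needs >= 2 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p)


def pooled_t_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Pooled two-sample t and two-sided p from sufficient statistics."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def prevalence_check(n_low: int, n_high: int, arm_n: int, threshold: float = 0.10) -> bool:
    """True iff both risk groups hold at least ``threshold`` of the arm.

    The exclusion rule is strict (< 10 % excluded), so exactly 10 % passes.
    """
    return min(n_low, n_high) / arm_n >= threshold


def _stats(x: np.ndarray) -> tuple[int, float, float]:
    return int(x.size), float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def codify_panel(
    genotypes: pd.DataFrame,
    cohort: pd.DataFrame,
    arm: str,
    outcome: str,
    anova_p: float = 0.10,
    confirm_p: float = 0.10,
    min_prevalence: float = 0.10,
    levene_p: float = 0.05,
    fdr: bool = False,
    check_normality: bool = True,
) -> list[SnpCodification]:
    """Screen every SNP of ``genotypes`` for ``outcome`` within ``arm``.

    ``cohort`` must carry ``arm`` and the signed outcome column.  Emits one
    :class:`SnpCodification` per SNP with all intermediate statistics; records
    with ``status == 'selected'`` form the panel used by the risk scores.
    """
    sub = cohort.loc[cohort["arm"] == arm] if "arm" in cohort.columns else cohort
    if sub.empty:
        raise DegenerateInputError(f"no subjects in arm {arm!r}")
    y = sub[outcome]
    if check_normality:
        try:
            p_norm = ks_normality(y)
            if p_norm <= 0.05:
                warnings.warn(
                    f"{outcome}/{arm}: normality screen P = {p_norm:.3g} <= 0.05"
                )
        except DegenerateInputError:
            pass
    G = genotypes.loc[sub.index]
    records = [
        _codify_snp(
            G[snp], y, snp, arm, outcome, anova_p, confirm_p, min_prevalence, levene_p
        )
        for snp in G.columns
    ]
    if fdr:
        cand = [r for r in records if np.isfinite(r.dichotomy_p)]
        if cand:
            adj = multipletests([r.dichotomy_p for r in cand], method="fdr_bh")[1]
            for r, q in zip(cand, adj):
                if r.status == "selected" and q >= confirm_p:
                    r.status, r.reason = "excluded", "ttest_fail"
    return records


def _codify_snp(
    calls: pd.Series,
    y: pd.Series,
    snp: str,
    arm: str,
    outcome: str,
    anova_p: float,
    confirm_p: float,
    min_prevalence: float,
    levene_p: float,
) -> SnpCodification:
    rec = SnpCodification(snp=snp, arm=arm, outcome=outcome)
    ok = calls.notna() & y.notna()
    groups = {
        str(g): y[ok][calls[ok] == g].to_numpy(dtype=float)
        for g in sorted(calls[ok].dropna().unique())
    }
    rec.genotype_stats = {g: _stats(v) for g, v in groups.items() if v.size > 0}
    try:
        rec.anova_f, rec.anova_p = anova_screen(list(groups.values()))
    except DegenerateInputError:
        rec.reason = "anova_fail"
        return rec
    # the partition (labeling) is computed for every screenable SNP; the gates
    # below decide selection status, not the labels
    part = posthoc_partition(groups, levene_p=levene_p)
    if part is not None:
        low, high, rec.posthoc_pairs, rec.posthoc_method = part
        rec.low_risk_genotypes, rec.high_risk_genotypes = low, high
        lv = np.concatenate([groups[g] for g in low])
        hv = np.concatenate([groups[g] for g in high])
        rec.group_stats = {"low": _stats(lv), "high": _stats(hv)}
        try:
            rec.dichotomy_p = dichotomy_test(lv, hv)
        except DegenerateInputError:
            pass
    if not rec.anova_p < anova_p:
        rec.reason = "anova_fail"
        return rec
    if part is None:
        rec.reason = "no_partition"
        return rec
    if not rec.dichotomy_p < confirm_p:
        rec.reason = "ttest_fail"
        return rec
    arm_n = int(ok.sum())
    if not prevalence_check(lv.size, hv.size, arm_n, min_prevalence):
        rec.reason = "low_prevalence"
        return rec
    rec.status = "selected"
    return rec


class GenotypeRiskCodifier(BaseEstimator, TransformerMixin):
    """Learn per-SNP low/high-risk genotype partitions; emit 0/1 indicators.

    ``fit(G, y)`` screens every column of the genotype matrix ``G`` (canonical
    allele-pair strings) against the signed outcome ``y`` using the
    ANOVA → post hoc clustering → t-test confirmation → prevalence pipeline;
    ``transform(G)`` returns a subjects × selected-loci indicator frame
    (1 = high-risk genotype, NaN = missing call).

    Parameters
    ----------
    anova_p, confirm_p : float
        Entry and confirmation gates (strict '<'), both 0.10 by default.
    min_prevalence : float
        Minimum risk-group share of the arm, 0.10 (inclusive).
    levene_p : float
        Variance-homogeneity gate choosing Bonferroni vs Dunnett-T3 post hoc.
    fdr : bool
        Optional Benjamini–Hochberg correction of the confirmation p-values
        across the panel (off by default, matching the original procedure).
    """

    def __init__(
        self,
        anova_p: float = 0.10,
        confirm_p: float = 0.10,
        min_prevalence: float = 0.10,
        levene_p: float = 0.05,
        fdr: bool = False,
        arm: str = "",
        outcome: str = "outcome",
    ):
        self.anova_p = anova_p
        self.confirm_p = confirm_p
        self.min_prevalence = min_prevalence
        self.levene_p = levene_p
        self.fdr = fdr
        self.arm = arm
        self.outcome = outcome

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name=self.outcome)
        cohort = y.to_frame()
        cohort["arm"] = self.arm
        self.codifications_ = codify_panel(
            X,
            cohort,
            self.arm,
            self.outcome,
            anova_p=self.anova_p,
            confirm_p=self.confirm_p,
            min_prevalence=self.min_prevalence,
            levene_p=self.levene_p,
            fdr=self.fdr,
            check_normality=False,
        )
        self.selected_ = [r for r in self.codifications_ if r.selected]
        self.selected_loci_ = [r.snp for r in self.selected_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "codifications_"):
            raise RuntimeError("GenotypeRiskCodifier is not fitted")
        return pd.DataFrame(
            {r.snp: r.indicator(X[r.snp]) for r in self.selected_},
            index=X.index,
        )
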