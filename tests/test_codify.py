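"""Codification stage: normality screen, ANOVA, post hoc partition, t gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipogrs.codify import (
    GenotypeRiskCodifier,
    anova_screen,
    codify_panel,
    dichotomy_test,
    ks_normality,
    pooled_t_from_stats,
    posthoc_partition,
    prevalence_check,
)
from adipogrs.errors import DegenerateInputError


class TestKsNormality:
    def test_gaussian_samples_rarely_rejected(self):
        rng = np.random.default_rng(0)
        hits = sum(ks_normality(rng.normal(size=500)) > 0.05 for _ in range(100))
        assert hits >= 90

    def test_exponential_samples_mostly_rejected(self):
        rng = np.random.default_rng(1)
        hits = sum(
            ks_normality(rng.exponential(size=500)) < 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks_normality(np.ones(20))

    def test_too_few_observations_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([1.0, 2.0, 3.0])


class TestAnovaScreen:
    def test_hand_computed_f(self):
        # SSB = 18 on 2 df, SSW = 6 on 6 df -> F = 9
        f, p = anova_screen([[0, 1, -1], [0, 1, -1], [3, 4, 2]])
        assert f == pytest.approx(9.0, abs=1e-12)
        assert 0 < p < 0.05

    def test_null_f_near_one_p_uniform(self):
        rng = np.random.default_rng(2)
        fs, ps = [], []
        for _ in range(300):
            f, p = anova_screen([rng.normal(size=20) for _ in range(3)])
            fs.append(f)
            ps.append(p)
        assert 0.8 < np.mean(fs) < 1.3
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_within_variance_flagged_extreme(self):
        f, p = anova_screen([[1, 1], [2, 2], [3, 3]])
        assert np.isinf(f) and p == 0.0

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateInputError):
            anova_screen([[1, 1], [1, 1]])

    def test_fewer_than_two_usable_groups(self):
        with pytest.raises(DegenerateInputError):
            anova_screen([[1.0], [2.0, 3.0]])


class TestPosthocPartition:
    def test_two_similar_one_distinct(self, rng):
        groups = {
            "AA": rng.normal(-9.8, 1.0, 40),
            "AG": rng.normal(-9.7, 1.0, 40),
            "GG": rng.normal(-8.0, 1.0, 40),
        }
        low, high, pairs, method = posthoc_partition(groups)
        assert low == frozenset({"AA", "AG"})
        assert high == frozenset({"GG"})

    def test_clustering_by_effect_not_allele_dosage(self, rng):
        # both homozygotes respond alike, the heterozygote differs
        groups = {
            "GG": rng.normal(-9.7, 1.0, 35),
            "AA": rng.normal(-9.7, 1.0, 26),
            "GA": rng.normal(-7.4, 1.0, 35),
        }
        low, high, *_ = posthoc_partition(groups)
        assert low == frozenset({"GG", "AA"})
        assert high == frozenset({"GA"})

    def test_all_similar_no_partition(self, rng):
        groups = {g: rng.normal(0.0, 1.0, 30) for g in ("AA", "AG", "GG")}
        assert posthoc_partition(groups) is None

    def test_two_group_partition_needs_no_posthoc_significance(self, rng):
        # two observed genotypes: partition exists even at marginal separation
        groups = {"AA": rng.normal(0.0, 1.0, 40), "GA": rng.normal(0.5, 1.0, 12)}
        part = posthoc_partition(groups)
        assert part is not None
        low, high, *_ = part
        assert low | high == frozenset({"AA", "GA"})

    @given(shift=st.floats(-50, 50), scale=st.sampled_from([1.0, 3.5]))
    @settings(max_examples=25, deadline=None)
    def test_partition_invariant_to_location_shift(self, shift, scale):
        rng = np.random.default_rng(99)
        base = {
            "AA": rng.normal(-9.5, scale, 40),
            "AG": rng.normal(-9.4, scale, 40),
            "GG": rng.normal(-7.2, scale, 30),
        }
        ref = posthoc_partition(base)
        shifted = {k: v + shift for k, v in base.items()}
        out = posthoc_partition(shifted)
        assert (ref is None) == (out is None)
        if ref is not None:
            assert ref[0] == out[0] and ref[1] == out[1]

    def test_partition_invariant_to_genotype_relabeling(self, rng):
        base = {
            "AA": rng.normal(-9.5, 1.0, 40),
            "AG": rng.normal(-9.4, 1.0, 40),
            "GG": rng.normal(-7.2, 1.0, 30),
        }
        mapping = {"AA": "TT", "AG": "CT", "GG": "CC"}
        relabeled = {mapping[k]: v for k, v in base.items()}
        low1, high1, *_ = posthoc_partition(base)
        low2, high2, *_ = posthoc_partition(relabeled)
        assert {mapping[g] for g in low1} == set(low2)
        assert {mapping[g] for g in high1} == set(high2)


class TestDichotomyTest:
    def test_identical_groups_p_one(self):
        assert dichotomy_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_published_summary_statistics_reproduced(self):
        # group sizes 80/16, means -9.4/-6.1, SDs 4.5/3.2 -> pooled t on 94 df
        t, p = pooled_t_from_stats(80, -9.4, 4.5, 16, -6.1, 3.2)
        assert t == pytest.approx(-2.790, abs=0.005)
        assert 0.005 < p < 0.008  # printed as 0.007 after rounding

    def test_pooled_t_raw_equals_sufficient_statistics(self, rng):
        for _ in range(10):
            a = rng.normal(0, 2, 25)
            b = rng.normal(1, 3, 40)
            from scipy.stats import ttest_ind

            t_raw, _ = ttest_ind(a, b, equal_var=True)
            t_stats, _ = pooled_t_from_stats(
                len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
            )
            assert t_raw == pytest.approx(t_stats, abs=1e-10)

    def test_group_too_small_rejected(self):
        with pytest.raises(DegenerateInputError):
            dichotomy_test([1.0], [1, 2, 3])


@pytest.mark.parametrize(
    "n_low, n_high, arm_n, expected",
    [
        (9, 87, 96, False),  # 9.4% -> excluded (strict < 10%)
        (10, 90, 100, True),  # exactly 10% -> retained
        (16, 80, 96, True),  # the retained published split
    ],
)
def test_prevalence_threshold_is_inclusive(n_low, n_high, arm_n, expected):
    assert prevalence_check(n_low, n_high, arm_n) is expected


class TestCodifyPanel:
    def test_empty_panel_empty_result(self, rng):
        cohort = pd.DataFrame(
            {"arm": ["MHP"] * 10, "WCR": rng.normal(size=10)},
            index=pd.RangeIndex(10),
        )
        G = pd.DataFrame(index=cohort.index)
        assert codify_panel(G, cohort, "MHP", "WCR", check_normality=False) == []

    def test_selected_snp_low_risk_has_better_response(self, rng):
        idx = pd.RangeIndex(120)
        calls = rng.choice(["AA", "AG", "GG"], size=120, p=[0.45, 0.4, 0.15])
        y = rng.normal(-9, 2, 120) - 3.0 * (calls == "AA")
        cohort = pd.DataFrame({"arm": "MHP", "WCR": y}, index=idx)
        G = pd.DataFrame({"rs1": calls}, index=idx)
        recs = codify_panel(G, cohort, "MHP", "WCR", check_normality=False)
        rec = recs[0]
        assert rec.selected
        # more negative signed change = larger reduction = low risk
        assert rec.group_stats["low"][1] <= rec.group_stats["high"][1]
        assert rec.low_risk_genotypes | rec.high_risk_genotypes == frozenset(
            {"AA", "AG", "GG"}
        )

    def test_codifier_transform_indicators(self, rng):
        idx = pd.RangeIndex(150)
        calls = rng.choice(["CC", "CT", "TT"], size=150, p=[0.5, 0.35, 0.15])
        y = rng.normal(0, 1, 150) + 2.0 * (calls == "CT") + 2.0 * (calls == "TT")
        G = pd.DataFrame({"rs9": calls}, index=idx)
        cod = GenotypeRiskCodifier(arm="LF", outcome="WCR").fit(G, pd.Series(y, idx))
        assert cod.selected_loci_ == ["rs9"]
        ind = cod.transform(G)["rs9"]
        rec = cod.selected_[0]
        assert set(ind.dropna().unique()) <= {0.0, 1.0}
        assert (ind[G["rs9"].isin(rec.high_risk_genotypes)] == 1.0).all()

    def test_unseen_genotype_maps_to_missing(self, rng):
        idx = pd.RangeIndex(100)
        calls = rng.choice(["AA", "AG"], size=100)
        y = rng.normal(0, 1, 100) + 2.5 * (calls == "AG")
        G = pd.DataFrame({"rs1": calls}, index=idx)
        cod = GenotypeRiskCodifier(arm="", outcome="y").fit(G, pd.Series(y, idx))
        G2 = G.copy()
        G2.iloc[0, 0] = "GG"  # never observed during fit
        assert np.isnan(cod.transform(G2)["rs1"].iloc[0])
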