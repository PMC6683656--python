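# Methods

## Scope and data model

The package re-implements, as a tested pipeline, a genetics-by-lifestyle
analysis of a two-arm hypocaloric-diet trial: per-SNP genotype risk
codification, unweighted/weighted genetic risk scores, gene–environment
interaction regression with three model-search strategies, and bootstrap
optimism-corrected internal validation. Because the original cohort is not
public, every quantitative behaviour is exercised on synthetic cohorts whose
generating parameters come from the published summary tables (group sizes,
means ± SD, regression coefficients), which the package carries as
machine-readable fixtures.

Two signed outcomes are modeled: waist-circumference change (WCR, cm) and
total body-fat change (TFATL, %), negative = reduction. "Low risk" always
denotes the genotype group with the more negative mean change (better
response); internal comparisons therefore use reduction = −Δ, while all
stored and reported values keep the signed convention of the source tables.

## Synthetic cohort generator

`SimConfig`/`simulate_cohort` draw, per subject: sex (70 % female — typical of
volunteer weight-loss trials; the source reports no split), age ~ N(47, 10²)
clipped to 21–67, BMI ~ N(31.7, 3.4²) clipped to 25–40, height ~ N(1.66,
0.08²), WC = 54.5 + 1.5·BMI + N(0, 5²), TFAT with a +8 point female offset,
METs and triglycerides log-normal, energy ~ N(2980, 900²) kcal/day — all
matched to the published baseline means/SDs. Adherence scores {0,1,2,3} have
probabilities (31/232, 67/232, 67/232, 67/232) so the expected score-0
exclusion count equals the published 31 of 232 completers; `apply_adherence_filter`
removes score 0 and is idempotent.

Arms are assigned by stratified permuted blocks of size 2 within sex ×
age-group (<45/≥45 y) × BMI-class (25–29.9/≥30) strata, so within-stratum
counts differ by ≤ 1. The original trial's randomization algorithm is not
described beyond its strata; permuted blocks are the standard realization.

Genotypes are two independent allele draws per locus (Hardy–Weinberg
proportions) stored as canonical unordered pairs ("AG", never "GA");
missingness is injectable (default 0). Outcomes follow the additive model

    y = arm mean + Σ_j β_j·I_j + Σ_k γ_k·I_k·(x_k − ref_k)
        + Σ_m δ_m·(c_m − ref_m) + N(0, σ²).

`study_config()` parameterizes this from the fixtures: per-locus effects β_j
equal the published high-minus-low group-mean differences; risk genotype sets
are the published ones; per-locus MAFs are solved from the published group
sizes under HWE (a lone heterozygote group of prevalence v gives 2pq = v, a
lone homozygote group gives allele frequency √v); covariate and interaction
coefficients come from the published best models, with covariates centered at
their generating means (the `ref` terms) so that arm means stay at the
published outcome changes; residual SDs default to the published
within-genotype-group SDs (4.3 cm WCR, 2.7 % TFATL). Filler loci (MAF uniform
0.05–0.5) pad the panel to 95.

`simulate_locus_from_groups` generates single-locus arm cohorts directly from
a codification row: group sizes fixed exactly, Gaussian outcomes within
group, and merged genotype sides (e.g. "CC+TT") split between constituent
genotypes in proportion to their HWE frequencies (even split when no MAF is
identifiable).

What the generator does *not* emulate: dropout dynamics, intake trajectories,
linkage disequilibrium between loci, genotyping error, non-Gaussian outcome
tails, or blood-marker changes beyond baseline TG/glucose. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generating model, not robustness to those real-data features.

## Codification

Per SNP × arm × outcome: (1) one-way ANOVA across genotype groups, entry gate
P < 0.10 (the screening language "statistically or marginally associated"
names no number; 0.10 matches the confirmation gate and is
config-overridable); groups with n < 2 are dropped with a warning. (2) Post
hoc clustering: Levene's test (median-centered) at P < 0.05 chooses between
Bonferroni-adjusted pooled-t pairwise tests (homogeneous variances) and
Welch-based Dunnett-T3-style tests, whose studentized-maximum-modulus tail is
approximated by a Šidák bound, 1 − (2F_t(|t|; ν_Welch) − 1)^m — conservative,
and exact quantiles are not available in the scientific Python stack.
Genotype pairs with adjusted p > 0.05 are merged. Exactly two similarity
components give the partition; all-similar gives none; no mergeable pair or
an ambiguous chain is dichotomized at the largest adjacent gap of the
mean-sorted genotypes. With only two observed genotypes the partition is the
two singletons with *no* significance requirement: several published
codifications with two observed genotypes carry confirmation p-values above
0.05, so the partition stage cannot itself gate at 0.05 — the dichotomy is
confirmed by step 3. The partition is computed for every screenable SNP; the
gates set selection status, not labels. (3) Pooled two-sample t-test on the
two blocks, kept when P < 0.10 (strict, as printed). (4) Prevalence: both
blocks must hold ≥ 10 % of the arm (strictly-less-than-10 % excluded, so
exactly 10 % passes). No multiple-testing correction across the panel is
applied by default (matching the original procedure); a Benjamini–Hochberg
flag exists. The normality screen (Lilliefors-corrected KS) warns rather than
aborts.

Null operating characteristics (measured by `experiments.null_panel_selection_rate`,
200 seeds × 95 null SNPs): the ANOVA screen passes 9.96 % ≈ its nominal 10 %;
the full codification selects ≈ 3.7 %, because the partition requirement
(all-similar → none) and the prevalence filter remove roughly two-thirds of
screen false-positives. The procedure is thus conservative under the null,
never anti-conservative.

## Risk scores

uGRS is the integer count of high-risk genotypes. wGRS weights are, by
default, the coefficients of the *joint* multivariable OLS of the signed
outcome on all selected indicators: only joint estimation can produce the
negative weights that a below-zero wGRS lower bound implies; per-locus
group-mean differences are available as `weights="univariate"`. Weights are
estimated on the same arm/outcome being scored — exactly the in-sample reuse
the optimism correction later accounts for. Subjects with a missing indicator
get missing scores by default; mean-imputation of the indicator is a flag
(scores then fractional). The attainable score ranges are [0, L] for uGRS and
[Σ min(β_j,0), Σ max(β_j,0)] for wGRS; the published wGRS ranges themselves
depend on the original fitted weights, which the source tables do not print,
and are therefore not reproducible — the package verifies the range identity
and the published locus counts (6, 3, 11, 7) instead.

## Modeling and selection

Designs are raw-scale: energy enters per 100 kcal, sex is coded 0 male / 1
female, interactions are uncentered elementwise products (the published
coefficients are raw-scale). Hierarchy is enforced by default: an interaction
g:e can be selected only with its gene main effect g present (overridable).
`fit_linear` delegates to statsmodels OLS; a small QR-based OLS (`modeling._ols`)
serves the selection/bootstrap inner loops for speed and is cross-checked
against statsmodels and a normal-equations oracle at 1e-8. Best-subset
enumeration scores subsets from Gram-matrix sufficient statistics (identical
results to per-subset OLS, ~10× faster) and refuses p > 20. LARS uses
sklearn's `lars_path` on standardized candidates with a Mallows-Cp stop (σ²
from the full OLS) and an OLS refit. Bootstrap stepwise runs p-value-based
bidirectional stepwise (entry/stay 0.05) on each of B ≥ 50 resamples and
keeps terms selected in ≥ 60 % of them; degenerate resamples are redrawn and
logged. The stepwise engine's per-term null inclusion on independent data is
≈ its entry level (measured 0.044 at α = 0.05 over 200 seeds); on bootstrap
*resamples* the rate is inflated (measured ≈ 0.17) because duplicated
observations shrink apparent residual variance — this inflation is intrinsic
to resampled p-value selection and is exactly why the keep-fraction rule
exists. Diagnostics: Breusch–Pagan on the model's own design (null size
measured 6 % at n = 200) and VIFs (flag > 10, infinite for perfect
collinearity).

## Validation

`optimism_validate` implements Harrell's bootstrap: the full model-building
closure (selection included) is re-run on every resample; optimism_b = adj.
R²(resample model on resample) − adj. R²(resample model applied to the
original data); corrected = apparent − mean optimism. The correction operates
on adjusted R² (the reported scale). Selection-inside-the-loop is the default
("honest"); `naive=True` freezes the apparent model's terms for comparison.
B defaults to 500 in the library and 200 in the packaged experiments; a
single master seed spawns per-replicate substreams. Under pure noise with
stepwise selection (n = 50, p = 10, B = 200, 50 seeds) the apparent adj. R²
averages ≈ 0.04 while the corrected value averages ≈ −0.21: the correction
fully absorbs the selection optimism and, like Harrell's estimator generally,
over-corrects under aggressive selection on small samples — corrected values
near or below zero should be read as "no validated signal". PC² uses
t²/(t² + residual df), equal to the squared partial correlation
(residualization identity verified at 1e-8). The tournament maximizes
corrected adj. R², breaking ties toward fewer terms, then lexicographic term
order.

At study scale (synthetic WCR-MHP cohorts from the published effect sizes,
published codification panel, honest best-subset validation at B = 200), the
corrected adj. R² of GRS models averages ≈ 0.19 across seeds — inside the
0.15–0.45 band of the published per-outcome values — and exceeds the best
single-SNP model in every measured seed.

## Parameter recovery and its limits

`experiments.recover_low_risk_mean` re-derives a published low-risk group
mean by simulating 200 arm-sized replicates from a locus' generating
parameters and averaging the mean outcome of the group the codification
labels low-risk. For rs3813929/MHP the recovery is unbiased (−9.44 vs −9.4
cm; every replicate labelable because the rare TT homozygote drops out and
the two-group partition always exists). For rs11091046/LF about a quarter of
replicates produce no labeling (the all-genotypes-similar rule plus the
ANOVA gate at the printed effect size), and conditioning on labeling biases
the recovered mean to ≈ −12.0 vs −11.6 cm (≈ 3.6 %). This selection
conditioning is a property of the estimand itself — any pipeline that only
labels significantly-separated groups shows it — and is documented rather
than patched; the corresponding strict 2-Monte-Carlo-SE test is expected to
fail for this locus.

## Numerical and interface choices

Thresholds are strict inequalities as printed. Genotype strings are
alphabetically sorted allele pairs; ties in VCF REF/ALT assignment break
alphabetically after allele counts. The TyG index is implemented exactly as
defined, ln(TG × glucose / 2); note the published baseline TyG values (~4.5)
match a base-10 logarithm of the same argument (~8.5 natural-log at the
published TG/glucose means) — the fixture stores the printed values verbatim
and the formula is kept as defined. The published SNP counts are reported
both ways: 26 as published (9 WCR + 17 TFATL, counting per outcome) and 22
distinct rsIDs (four loci associate with both outcomes). Experiment problem
sizes (200 replicates, 200 seeds, B = 200, 5-seed study-scale runs) are the
package's reporting defaults and are parameters of every experiment function.

## Known limitations

- No linkage disequilibrium, imputation, haplotypes, or allele-dosage (0/1/2)
  scores; the codification is strictly genotype-dichotomy based.
- OLS only (no GLM/mixed models); classical SEs.
- The Dunnett-T3 tail is a Šidák approximation (conservative).
- Harrell correction over-corrects under aggressive selection at small n.
- Synthetic validation only: the original cohort is unavailable, so published
  headline values are bracketed by bands, not reproduced point-wise.
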