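"""Synthetic two-arm diet-intervention cohorts with genotype effects.

Emulates the data structure of a 16-week hypocaloric-diet trial: subjects are
randomized to a moderately high-protein (MHP) or low-fat (LF) arm by stratified
block randomization (sex × age group × BMI class), genotyped at biallelic SNPs
drawn under Hardy–Weinberg proportions, and followed to two signed adiposity
changes — waist-circumference reduction (WCR, cm) and total body-fat loss
(TFATL, %), negative = reduction.  Outcomes are generated additively:

    y = arm mean + Σ_j β_j·I_j + Σ_k γ_k·I_k·(x_k − ref_k)
        + Σ_m δ_m·(c_m − ref_m) + ε,   ε ~ N(0, σ²)

where I_j indicates carrying the high-risk genotype at locus j, x_k is an
environmental exposure (METs, energy intake, baseline adiposity), and c_m a
conventional covariate.  Reference points default to 0, i.e. raw-scale terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from . import fixtures

__all__ = [
    "Locus",
    "Effect",
    "Interaction",
    "SimConfig",
    "canonical_genotype",
    "simulate_genotypes",
    "simulate_baseline",
    "assign_arms",
    "simulate_outcomes",
    "apply_adherence_filter",
    "simulate_cohort",
    "simulate_locus_from_groups",
    "locus_from_codification_row",
    "study_config",
]

OUTCOMES = ("WCR", "TFATL")
ARMS = ("MHP", "LF")

#: per-arm SNP counts of the emulated trial after adherence filtering
STUDY_ARM_N = {"MHP": 96, "LF": 105}


def canonical_genotype(a1: str, a2: str) -> str:
    """Unordered allele pair as a canonical 2-character string ('GA' -> 'AG')."""
    return "".join(sorted((a1, a2)))


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: rsID, (major, minor) alleles, minor-allele frequency."""

    rsid: str
    alleles: tuple[str, str]
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ConfigurationError(
                f"{self.rsid}: maf must be in [0, 1], got {self.maf}"
            )
        if len(set(self.alleles)) != 2:
            raise ConfigurationError(f"{self.rsid}: two distinct alleles required")

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """(major hom, het, minor hom) canonical genotype strings."""
        a, b = self.alleles
        return (
            canonical_genotype(a, a),
            canonical_genotype(a, b),
            canonical_genotype(b, b),
        )


@dataclass(frozen=True)
class Effect:
    """Additive shift ``beta`` on a signed outcome for high-risk carriers."""

    locus: str
    outcome: str
    risk_genotypes: frozenset
    beta: float
    arm: str | None = None  # None = both arms


@dataclass(frozen=True)
class Interaction:
    """Gene × exposure product term: beta · I(high risk) · (exposure − ref)."""

    locus: str
    outcome: str
    risk_genotypes: frozenset
    exposure: str
    beta: float
    arm: str | None = None


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the study conditions of the emulated trial: 232
    completers of whom an expected 31 show poor adherence (score 0) and are
    excluded, leaving ~201 analyzable subjects split ~1:1 over the two arms;
    95 biallelic loci; residual SDs equal to the published within-genotype-group
    SDs (4.3 cm for WCR, 2.7 % for TFATL).
    """

    n_subjects: int = 232
    loci: Sequence[Locus] = field(default_factory=list)
    arm_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("WCR", "MHP"): -8.9,
            ("WCR", "LF"): -9.7,
            ("TFATL", "MHP"): -4.4,
            ("TFATL", "LF"): -4.3,
        }
    )
    effects: Sequence[Effect] = field(default_factory=list)
    interactions: Sequence[Interaction] = field(default_factory=list)
    covariate_effects: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict
    )
    covariate_refs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"WCR": 4.3, "TFATL": 2.7}
    )
    adherence_probs: tuple[float, float, float, float] = (
        31 / 232,
        67 / 232,
        67 / 232,
        67 / 232,
    )
    missing_rate: float = 0.0
    female_fraction: float = 0.7
    age_cut: float = 45.0
    bmi_obese_cut: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if abs(sum(self.adherence_probs) - 1.0) > 1e-9:
            raise ConfigurationError("adherence_probs must sum to 1")
        if any(p < 0 for p in self.adherence_probs):
            raise ConfigurationError("adherence_probs must be non-negative")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        known = {loc.rsid for loc in self.loci}
        for eff in list(self.effects) + list(self.interactions):
            if eff.locus not in known:
                raise ConfigurationError(f"effect refers to unknown locus {eff.locus}")
            if eff.outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {eff.outcome}")

    def locus_map(self) -> dict[str, Locus]:
        return {loc.rsid: loc for loc in self.loci}


def _subject_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="subject_id")


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a subjects × loci genotype matrix under Hardy–Weinberg proportions.

    Each genotype is two independent allele draws at the locus MAF; calls are
    canonical unordered pairs ('AG', never 'GA').  Missing calls (NaN) are
    injected at ``config.missing_rate``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    idx = _subject_ids(n)
    cols = {}
    for loc in config.loci:
        major, minor = loc.alleles
        draws = rng.random((n, 2)) < loc.maf  # True = minor allele
        counts = draws.sum(axis=1)
        geno = np.array(
            [
                canonical_genotype(major, major),
                canonical_genotype(major, minor),
                canonical_genotype(minor, minor),
            ],
            dtype=object,
        )[counts]
        cols[loc.rsid] = geno
    df = pd.DataFrame(cols, index=idx, dtype=object)
    if config.missing_rate > 0 and len(config.loci) > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df = df.mask(mask)
    return df


def simulate_baseline(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate baseline demographics, anthropometry and lifestyle exposures.

    Marginal distributions are matched to the published baseline means/SDs of
    the emulated trial (BMI ~ 31.7 ± 3.4 clipped to 25–40, WC tracking BMI,
    METs and triglycerides log-normal, energy ~ 2980 ± 900 kcal/day).
    Adherence scores 0–3 are drawn from ``config.adherence_probs``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    age = np.clip(rng.normal(47.0, 10.0, n), 21.0, 67.0)
    height = np.clip(rng.normal(1.66, 0.08, n), 1.45, 1.95)
    bmi = np.clip(rng.normal(31.7, 3.4, n), 25.0, 40.0)
    weight = bmi * height**2
    wc = 54.5 + 1.5 * bmi + rng.normal(0.0, 5.0, n)
    tfat = np.clip(36.0 - 8.0 * (1 - sex) + 0.5 * (bmi - 31.7) + rng.normal(0, 4.0, n), 15, 60)
    # log-normal moments matched to mean 24.2, SD 19.1 (METs)
    mets = rng.lognormal(mean=2.935, sigma=0.698, size=n)
    energy = np.clip(rng.normal(2980.0, 900.0, n), 1200.0, None)
    tg = rng.lognormal(mean=4.497, sigma=0.506, size=n)
    glucose = np.clip(rng.normal(95.6, 10.3, n), 60.0, None)
    adherence = rng.choice(4, size=n, p=np.asarray(config.adherence_probs))
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "weight": weight,
            "height": height,
            "bmi": bmi,
            "baseline_wc": wc,
            "baseline_tfat": tfat,
            "mets": mets,
            "energy": energy,
            "tg": tg,
            "glucose": glucose,
            "adherence": adherence,
        },
        index=_subject_ids(n),
    )


def assign_arms(
    cohort: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    age_cut: float = 45.0,
    bmi_obese_cut: float = 30.0,
) -> pd.DataFrame:
    """Stratified block randomization to the MHP and LF arms.

    Strata are sex × age group (< / ≥ ``age_cut`` years) × BMI class
    (overweight / obese at ``bmi_obese_cut``).  Within each stratum subjects
    are shuffled and assigned in permuted blocks of two, so arm counts within
    any stratum differ by at most one.  Returns a copy with an ``arm`` column.
    """
    for col in ("sex", "age"):
        if col not in cohort.columns:
            raise DataError(f"stratification variable {col!r} missing")
    if "bmi" not in cohort.columns:
        if {"weight", "height"}.issubset(cohort.columns):
            cohort = cohort.assign(bmi=cohort["weight"] / cohort["height"] ** 2)
        else:
            raise DataError("stratification variable 'bmi' missing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    out["arm"] = ""
    strata = (
        out["sex"].astype(int).astype(str)
        + "|"
        + (out["age"] >= age_cut).astype(str)
        + "|"
        + (out["bmi"] >= bmi_obese_cut).astype(str)
    )
    # iterate strata in sorted order so the assignment is seed-stable
    for _, members in sorted(strata.groupby(strata).groups.items()):
        order = np.asarray(members)[rng.permutation(len(members))]
        arms = []
        for b in range(0, len(order), 2):
            block = ["MHP", "LF"]
            rng.shuffle(block)
            arms.extend(block[: len(order) - b])
        out.loc[order, "arm"] = arms
    return out


def _indicator(genotypes: pd.Series, risk: frozenset) -> np.ndarray:
    """1.0 where the call is in the high-risk set, NaN where missing."""
    vals = genotypes.to_numpy(dtype=object)
    out = np.array([np.nan if g is None or g != g else float(g in risk) for g in vals])
    return out


def simulate_outcomes(
    genotypes: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill signed outcome changes WCR (cm) and TFATL (%) per the linear model.

    Missing genotype calls contribute their locus' expected indicator value
    (high-risk prevalence under HWE) so outcome generation never propagates
    NaN; downstream analysis still sees the missing call itself.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if "arm" not in cohort.columns or (cohort["arm"] == "").any():
        raise DataError("arms must be assigned before simulating outcomes")
    known = set(genotypes.columns)
    lmap = config.locus_map()
    out = cohort.copy()
    refs = config.covariate_refs
    for outcome in OUTCOMES:
        y = np.zeros(len(cohort))
        for arm in ARMS:
            in_arm = (cohort["arm"] == arm).to_numpy()
            y[in_arm] += config.arm_means.get((outcome, arm), 0.0)
            for var, coef in config.covariate_effects.get((outcome, arm), {}).items():
                x = cohort[var].to_numpy(dtype=float) - refs.get(var, 0.0)
                y[in_arm] += coef * x[in_arm]
        for eff in config.effects:
            if eff.outcome != outcome:
                continue
            if eff.locus not in known:
                raise ConfigurationError(f"effect on unknown locus {eff.locus}")
            ind = _indicator(genotypes[eff.locus], eff.risk_genotypes)
            if np.isnan(ind).any():
                ind = np.where(np.isnan(ind), _expected_indicator(lmap[eff.locus], eff.risk_genotypes), ind)
            rows = np.ones(len(cohort), bool) if eff.arm is None else (cohort["arm"] == eff.arm).to_numpy()
            y[rows] += eff.beta * ind[rows]
        for ia in config.interactions:
            if ia.outcome != outcome:
                continue
            if ia.locus not in known:
                raise ConfigurationError(f"interaction on unknown locus {ia.locus}")
            ind = _indicator(genotypes[ia.locus], ia.risk_genotypes)
            if np.isnan(ind).any():
                ind = np.where(np.isnan(ind), _expected_indicator(lmap[ia.locus], ia.risk_genotypes), ind)
            x = cohort[ia.exposure].to_numpy(dtype=float) - refs.get(ia.exposure, 0.0)
            rows = np.ones(len(cohort), bool) if ia.arm is None else (cohort["arm"] == ia.arm).to_numpy()
            y[rows] += ia.beta * (ind * x)[rows]
        sd = config.noise_sd.get(outcome, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, len(cohort))
        out[outcome] = y
    return out


def _expected_indicator(locus: Locus, risk: frozenset) -> float:
    """High-risk prevalence under HWE at the locus MAF."""
    q = locus.maf
    p = 1 - q
    hom_major, het, hom_minor = locus.genotypes
    prev = 0.0
    for g, f in ((hom_major, p * p), (het, 2 * p * q), (hom_minor, q * q)):
        if g in risk:
            prev += f
    return prev


def apply_adherence_filter(
    cohort: pd.DataFrame, genotypes: pd.DataFrame | None = None
):
    """Drop subjects with adherence score 0 (failure to follow the diet).

    Returns the filtered cohort (and genotype matrix, when given) with the
    removal count stored in ``.attrs['n_removed']``.  Idempotent.
    """
    if "adherence" not in cohort.columns:
        raise DataError("adherence column missing")
    scores = cohort["adherence"]
    if not scores.isin([0, 1, 2, 3]).all():
        bad = sorted(scores[~scores.isin([0, 1, 2, 3])].unique().tolist())
        raise DataError(f"adherence scores outside {{0,1,2,3}}: {bad}")
    keep = scores >= 1
    filtered = cohort.loc[keep].copy()
    filtered.attrs["n_removed"] = int((~keep).sum())
    if genotypes is not None:
        g = genotypes.loc[filtered.index].copy()
        return filtered, g
    return filtered


def simulate_cohort(config: SimConfig):
    """End-to-end draw: baseline → arms → genotypes → outcomes.

    Returns ``(cohort, genotypes)`` for all completers (adherence 0 subjects
    included; apply :func:`apply_adherence_filter` before analysis).
    Bit-identical under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_baseline(config, rng)
    cohort = assign_arms(cohort, rng, config.age_cut, config.bmi_obese_cut)
    genotypes = simulate_genotypes(config, rng)
    cohort = simulate_outcomes(genotypes, cohort, config, rng)
    return cohort, genotypes


# ---------------------------------------------------------------------------
# generation from published per-locus group parameters


def _split_counts(n: int, k: int) -> list[int]:
    """Split n as evenly as possible into k parts (first parts get the rest)."""
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _proportional_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(weights) parts."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return _split_counts(n, len(w))
    exact = n * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    for j in np.argsort(-(exact - counts))[:rem]:
        counts[j] += 1
    return counts.tolist()


def simulate_locus_from_groups(
    row: Mapping, rng: np.random.Generator | int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate one locus from published two-group summary parameters.

    ``row`` must carry ``low_genotypes``/``high_genotypes`` ('+'-joined sets),
    group sizes ``n_low``/``n_high`` and per-group outcome ``mean``/``sd``.
    Group sizes are fixed exactly; a merged genotype set is split between its
    constituent genotypes in proportion to their Hardy–Weinberg frequencies at
    the MAF the row's group sizes imply (as even as possible when no MAF is
    identifiable); outcomes are Gaussian within group.  Returns a one-column
    genotype matrix and the outcome vector.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rsid = row.get("snp", "rs0")
    try:
        loc = locus_from_codification_row(row)
        p, q = 1.0 - loc.maf, loc.maf
        hom_major, het, hom_minor = loc.genotypes
        hwe = {hom_major: p * p, het: 2 * p * q, hom_minor: q * q}
    except DataError:
        hwe = None
    genos, ys = [], []
    for side in ("low", "high"):
        gset = [canonical_genotype(*g.strip()) for g in str(row[f"{side}_genotypes"]).split("+")]
        n = int(row[f"n_{side}"])
        if len(gset) == 1 or hwe is None:
            counts = _split_counts(n, len(gset))
        else:
            counts = _proportional_counts(n, [hwe.get(g, 0.0) for g in gset])
        for g, cnt in zip(gset, counts):
            genos.extend([g] * cnt)
        ys.append(rng.normal(float(row[f"mean_{side}"]), float(row[f"sd_{side}"]), n))
    y = np.concatenate(ys)
    idx = _subject_ids(len(genos))
    order = rng.permutation(len(genos))
    G = pd.DataFrame({rsid: np.asarray(genos, dtype=object)[order]}, index=idx)
    return G, pd.Series(y[order], index=idx, name="outcome")


def locus_from_codification_row(row: Mapping, arm_n: int | None = None) -> Locus:
    """Infer a biallelic locus (alleles + HWE MAF) from a codification row.

    The side of the dichotomy holding a single genotype pins the allele
    frequency: a lone heterozygote group of prevalence v gives 2pq = v; a lone
    homozygote group gives (allele freq)² = v.
    """
    low = [g.strip() for g in str(row["low_genotypes"]).split("+")]
    high = [g.strip() for g in str(row["high_genotypes"]).split("+")]
    alleles = sorted({a for g in low + high for a in g})
    if len(alleles) != 2:
        raise DataError(f"{row.get('snp')}: expected 2 alleles, got {alleles}")
    n_low, n_high = int(row["n_low"]), int(row["n_high"])
    total = arm_n or (n_low + n_high)
    single = None
    for gset, n in ((high, n_high), (low, n_low)):
        if len(gset) == 1:
            single = (gset[0], n / total)
    if single is None:
        raise DataError(f"{row.get('snp')}: no single-genotype side")
    g, prev = single
    prev = min(prev, 0.999)
    if g[0] != g[1]:
        # lone heterozygote group: 2pq = prev; which allele is minor is not
        # identifiable, take the alphabetically later one
        q = (1.0 - math.sqrt(max(1.0 - 2.0 * prev, 0.0))) / 2.0
        return Locus(row["snp"], (alleles[0], alleles[1]), q)
    # lone homozygote group: freq(allele)² = prev
    fa = math.sqrt(prev)
    other = next(a for a in alleles if a != g[0])
    if fa <= 0.5:
        return Locus(row["snp"], (other, g[0]), fa)
    return Locus(row["snp"], (g[0], other), 1.0 - fa)


def study_config(seed: int = 0, n_loci: int = 95, n_subjects: int = 232) -> SimConfig:
    """SimConfig parameterized to the emulated trial's published tables.

    Loci with real effects come from the published codifications (alleles and
    HWE MAFs inferred from the printed group sizes; effect sizes equal the
    printed high-minus-low group-mean differences).  Filler loci (MAF uniform
    on 0.05–0.5) pad the panel to ``n_loci``.  Covariate and gene×environment
    coefficients come from the published best models; covariates enter
    centered at their generating means so arm means stay at the printed
    values.  Residual SDs are the published within-group SDs.
    """
    cod = fixtures.load_reported_codifications("both")
    models = fixtures.load_reported_best_models()

    loci: dict[str, Locus] = {}
    for _, row in cod.iterrows():
        if row["snp"] not in loci:
            loci[row["snp"]] = locus_from_codification_row(
                row, STUDY_ARM_N[row["arm"]]
            )
    rng = np.random.default_rng(seed + 7919)  # panel layout stream
    bases = "ACGT"
    i = 1
    while len(loci) < n_loci:
        rsid = f"rs90{i:04d}"
        i += 1
        if rsid in loci:
            continue
        a, b = rng.choice(list(bases), size=2, replace=False)
        loci[rsid] = Locus(rsid, (str(a), str(b)), float(rng.uniform(0.05, 0.5)))

    def expand(gstr: str) -> frozenset:
        return frozenset(canonical_genotype(*g.strip()) for g in str(gstr).split("+"))

    effects = []
    diff: dict[tuple[str, str, str], float] = {}
    risk_sets: dict[tuple[str, str, str], frozenset] = {}
    for _, row in cod.iterrows():
        key = (row["snp"], row["outcome"], row["arm"])
        d = float(row["mean_high"]) - float(row["mean_low"])
        risk = expand(row["high_genotypes"])
        effects.append(
            Effect(row["snp"], row["outcome"], risk, d, arm=row["arm"])
        )
        diff[key] = d
        risk_sets[key] = risk

    covariate_effects: dict[tuple[str, str], dict[str, float]] = {}
    interactions: list[Interaction] = []
    covariates = {"age", "sex", "baseline_wc", "baseline_tfat", "mets", "energy100"}
    for _, row in models.iterrows():
        term, outcome, arm = row["term"], row["outcome"], row["arm"]
        coef = float(row["coefficient"])
        if term in covariates:
            var = "energy" if term == "energy100" else term
            c = coef / 100.0 if term == "energy100" else coef
            covariate_effects.setdefault((outcome, arm), {})[var] = c
        elif ":" in term:
            gene, expo = term.split(":")
            var = "energy" if expo == "energy100" else expo
            scale = 1.0 / 100.0 if expo == "energy100" else 1.0
            sel = [k for k in diff if k[1] == outcome and k[2] == arm]
            for snp, _, _ in sel:
                key = (snp, outcome, arm)
                w = 1.0 if gene == "ugrs" else diff[key]
                interactions.append(
                    Interaction(
                        snp, outcome, risk_sets[key], var, coef * scale * w, arm=arm
                    )
                )
    # center covariates/exposures at their generating means so the printed arm
    # means are preserved
    refs = {
        "age": 47.0,
        "sex": 0.7,
        "baseline_wc": 102.0,
        "baseline_tfat": 41.9,
        "mets": 24.2,
        "energy": 2980.0,
    }
    # offset arm means by the expected genetic contribution so realized means
    # track the printed outcome changes
    arm_means = {
        ("WCR", "MHP"): -8.9,
        ("WCR", "LF"): -9.7,
        ("TFATL", "MHP"): -4.4,
        ("TFATL", "LF"): -4.3,
    }
    adj = dict(arm_means)
    for eff in effects:
        loc = loci[eff.locus]
        prev = _expected_indicator(loc, eff.risk_genotypes)
        adj[(eff.outcome, eff.arm)] -= eff.beta * prev

    return SimConfig(
        n_subjects=n_subjects,
        loci=list(loci.values()),
        arm_means=adj,
        effects=effects,
        interactions=interactions,
        covariate_effects=covariate_effects,
        covariate_refs=refs,
        seed=seed,
    )
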