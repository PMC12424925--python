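"""Synthetic cohort generation and phenotype preprocessing.

Generates a desk-scale stand-in for a biobank cohort: unlinked biallelic SNP
genotypes, sex, baseline ages on [40, 79], quantitative traits with a chosen
per-age-bin heritability profile, up to three longitudinal visits with
measurement error, medication-use flags, and disease age-at-first-diagnosis
produced by a liability-threshold process.  Also implements the phenotype
preprocessing rules applied to real data: additive medication corrections and
age-matched inverse-probability resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientVisitsError,
    MatchingInfeasibleError,
    ParameterError,
)
from .liability import LiabilityState, threshold_onsets

__all__ = [
    "GenotypeMatrix",
    "CohortTable",
    "MedicationRule",
    "TraitSpec",
    "DiseaseSpec",
    "CohortConfig",
    "DEFAULT_MEDICATION_RULES",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_longitudinal_liability",
    "apply_medication_correction",
    "age_matched_resample",
]


@dataclass
class GenotypeMatrix:
    """Additive dosages (n_individuals x n_snps) with per-SNP allele frequencies."""

    dosages: np.ndarray
    allele_freqs: np.ndarray
    snp_ids: list
    individual_ids: list

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise ConfigurationError("genotype dimensions inconsistent with id lists")
        if len(self.allele_freqs) != m:
            raise ConfigurationError("allele_freqs length != n_snps")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Dosages standardized per SNP by empirical mean and s.d."""
        X = self.dosages.astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ParameterError("monomorphic SNP in standardization; filter first")
        return (X - mu) / sd


@dataclass
class CohortTable:
    """One row per individual plus long-format visit and diagnosis tables.

    individuals: id, sex (0/1), baseline_age, censor_age, medication flags.
    visits: id, visit (1-based), age, trait, value.
    diagnoses: id, disease, age_at_diagnosis (only diagnosed individuals appear).
    """

    individuals: pd.DataFrame
    visits: pd.DataFrame
    diagnoses: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.visits):
            ages = self.visits.pivot_table(index="id", columns="visit", values="age")
            if ages.shape[1] > 1:
                diffs = ages.diff(axis=1).to_numpy()[:, 1:]
                if np.nanmin(diffs) <= 0:
                    raise ConfigurationError(
                        "visit ages must be strictly increasing per individual"
                    )
        if len(self.diagnoses):
            merged = self.diagnoses.merge(
                self.individuals[["id", "censor_age"]], on="id", how="left"
            )
            if (merged["age_at_diagnosis"] > merged["censor_age"]).any():
                raise ConfigurationError("diagnosis after censoring age")

    def trait_at_visit(self, trait: str, visit: int = 1) -> pd.Series:
        """Trait values at one visit, indexed by individual id (cohort order)."""
        sub = self.visits[(self.visits["trait"] == trait) & (self.visits["visit"] == visit)]
        s = sub.set_index("id")["value"]
        return s.reindex(self.individuals["id"]).rename(trait)


@dataclass
class MedicationRule:
    """Additive phenotype correction applied to flagged individuals.

    ``unit_mode='sd'`` corrections add ``correction`` times the trait's
    standard deviation computed in the entire population; ``'absolute'``
    corrections add the raw amount in trait units.
    """

    trait: str
    flag: str
    correction: float
    unit_mode: str = "absolute"

    def __post_init__(self):
        if self.unit_mode not in ("absolute", "sd"):
            raise ConfigurationError(f"unit_mode must be 'absolute' or 'sd', got {self.unit_mode!r}")


# The blood-biochemistry corrections used for medicated individuals: lipid
# lowering drugs for cholesterol/LDL (+1 s.d.) and triglycerides (+0.5 s.d.),
# antihypertensives for blood pressure (+15 / +10 mm Hg), and diabetic
# medication for HbA1c (+10.929; insulin +1.3 x 10.929).
DEFAULT_MEDICATION_RULES = [
    MedicationRule("cholesterol", "lipid_lowering", 1.0, "sd"),
    MedicationRule("ldl", "lipid_lowering", 1.0, "sd"),
    MedicationRule("triglycerides", "lipid_lowering", 0.5, "sd"),
    MedicationRule("sbp", "hypertension_med", 15.0, "absolute"),
    MedicationRule("dbp", "hypertension_med", 10.0, "absolute"),
    MedicationRule("hba1c", "noninsulin_diabetic_med", 10.929, "absolute"),
    MedicationRule("hba1c", "insulin_med", 1.3 * 10.929, "absolute"),
]


@dataclass
class TraitSpec:
    """A quantitative trait's generative parameters.

    ``h2`` is the baseline-bin heritability; ``ea_increment_var`` is the
    per-age-bin environmental increment variance (0 for a constant-h2 trait);
    ``measurement_error_var`` is the iid visit-level noise variance;
    ``age_slope`` shifts the mean per age bin.
    """

    name: str
    h2: float = 0.0
    ea_increment_var: float = 0.0
    measurement_error_var: float = 0.0
    age_slope: float = 0.0
    loads_on: str | None = None  # disease name; trait becomes a noisy view of its liability
    loading: float = 0.6  # correlation with that liability (only with loads_on)

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"trait {self.name}: h2 must be in [0,1]")
        if self.ea_increment_var < 0 or self.measurement_error_var < 0:
            raise ConfigurationError(f"trait {self.name}: variances must be >= 0")
        if self.loads_on is not None and not 0.0 < abs(self.loading) <= 1.0:
            raise ConfigurationError(f"trait {self.name}: |loading| must be in (0,1]")


@dataclass
class DiseaseSpec:
    """A disease's liability-threshold parameters (per-bin prevalence ``bin_fraction``)."""

    name: str
    h2: float
    bin_fraction: float = 0.02
    ea_increment_var: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError(f"disease {self.name}: h2 must be in [0,1]")
        if not 0.0 < self.bin_fraction < 1.0:
            raise ConfigurationError(f"disease {self.name}: bin_fraction must be in (0,1)")


@dataclass
class CohortConfig:
    traits: list = field(default_factory=list)
    diseases: list = field(default_factory=list)
    visit_offsets: tuple = (0.0,)
    age_range: tuple = (40.0, 79.0)
    n_age_bins: int = 5
    medication_flags: dict = field(default_factory=dict)  # flag -> prevalence
    censor_age_range: tuple = (60.0, 85.0)

    def __post_init__(self):
        if not 1 <= len(self.visit_offsets) <= 3:
            raise ConfigurationError("visit schedule must have 1-3 visits")
        if list(self.visit_offsets) != sorted(set(self.visit_offsets)):
            raise ConfigurationError("visit offsets must be strictly increasing")


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Unlinked biallelic SNPs: dosage ~ Binomial(2, p), p ~ Uniform(maf_range)."""
    if n_individuals < 2 or n_snps < 1:
        raise ParameterError("need >= 2 individuals and >= 1 SNP")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError(f"maf_range must be within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, n_snps)
    dosages = rng.binomial(2, p, size=(n_individuals, n_snps)).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        allele_freqs=p,
        snp_ids=[f"snp{j}" for j in range(n_snps)],
        individual_ids=[f"ind{i}" for i in range(n_individuals)],
    )


def _age_bin_index(ages: np.ndarray, age_range: tuple, n_bins: int) -> np.ndarray:
    """Equal-width age bins over the configured range, 1-based."""
    lo, hi = age_range
    k = np.floor((ages - lo) / (hi - lo) * n_bins).astype(int) + 1
    return np.clip(k, 1, n_bins)


def simulate_cohort(
    genotypes: GenotypeMatrix,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[CohortTable, dict]:
    """Generate a full cohort table plus the latent liability state per trait/disease.

    For each trait, G = standardized dosages @ effects with effect variance
    h2/m (so var(G) = h2 in expectation), E ~ N(0, 1-h2) independent, and the
    liability at the individual's baseline age bin adds cumulative per-bin EA
    increments.  Observed visit values add iid measurement noise.  Disease
    onsets come from the liability-threshold engine applied to a genotype-based
    liability; onset ages are placed uniformly within the onset bin's age
    interval and recorded only when they precede the censoring age.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n
    m = genotypes.m
    Z = genotypes.standardized()

    sex = rng.integers(0, 2, n)
    lo, hi = config.age_range
    baseline_age = rng.uniform(lo, hi, n)
    bin_idx = _age_bin_index(baseline_age, config.age_range, config.n_age_bins)
    censor_age = rng.uniform(*config.censor_age_range, n)
    censor_age = np.maximum(censor_age, baseline_age)  # followed at least to baseline

    individuals = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "sex": sex,
            "baseline_age": baseline_age,
            "censor_age": censor_age,
        }
    )
    for flag, prev in config.medication_flags.items():
        individuals[flag] = rng.binomial(1, prev, n)

    states: dict[str, LiabilityState] = {}
    n_bins = config.n_age_bins

    diag_rows = []
    bin_edges = np.linspace(lo, hi + 1.0, n_bins + 1)  # onset ages can run past the oldest baseline
    for spec in config.diseases:
        beta = rng.normal(0.0, np.sqrt(spec.h2 / m), m)
        G = Z @ beta
        E = rng.normal(0.0, np.sqrt(1.0 - spec.h2), n)
        increments = np.zeros((n, n_bins))
        if spec.ea_increment_var > 0 and n_bins > 1:
            increments[:, 1:] = rng.normal(0.0, np.sqrt(spec.ea_increment_var), (n, n_bins - 1))
        state, _ = threshold_onsets(G, E, increments, spec.bin_fraction, rng)
        states[spec.name] = state
        diagnosed = np.flatnonzero(state.onset_bin > 0)
        onset_bins = state.onset_bin[diagnosed]
        onset_age = rng.uniform(bin_edges[onset_bins - 1], bin_edges[onset_bins])
        observed = onset_age <= censor_age[diagnosed]
        diag_rows.append(
            pd.DataFrame(
                {
                    "id": np.asarray(genotypes.individual_ids)[diagnosed[observed]],
                    "disease": spec.name,
                    "age_at_diagnosis": onset_age[observed],
                }
            )
        )

    visit_rows = []
    for spec in config.traits:
        if spec.loads_on is not None:
            if spec.loads_on not in states:
                raise ConfigurationError(
                    f"trait {spec.name} loads on unknown disease {spec.loads_on!r}"
                )
            src = states[spec.loads_on]
            base = src.liability_at_bin[np.arange(n), bin_idx - 1]
            base = (base - base.mean()) / base.std(ddof=1)
            G = spec.loading * src.G
            E = spec.loading * base - G  # residual non-genetic part of the loaded view
            resid_sd = np.sqrt(max(0.0, 1.0 - spec.loading**2))
            extra = rng.normal(0.0, resid_sd, n) if resid_sd > 0 else np.zeros(n)
            E = E + extra
            increments = np.zeros((n, n_bins))
        else:
            beta = rng.normal(0.0, np.sqrt(spec.h2 / m), m)
            G = Z @ beta
            E = rng.normal(0.0, np.sqrt(1.0 - spec.h2), n)
            increments = np.zeros((n, n_bins))
            if spec.ea_increment_var > 0 and n_bins > 1:
                increments[:, 1:] = rng.normal(
                    0.0, np.sqrt(spec.ea_increment_var), (n, n_bins - 1)
                )
        cum = np.cumsum(increments, axis=1)
        liability_at_bin = (G + E)[:, None] + cum
        liability = liability_at_bin[np.arange(n), bin_idx - 1] + spec.age_slope * (bin_idx - 1)
        states[spec.name] = LiabilityState(
            G=G,
            E0=E,
            ea_increments=increments,
            liability_at_bin=liability_at_bin,
            onset_bin=np.zeros(n, dtype=int),
        )
        for v, off in enumerate(config.visit_offsets, start=1):
            noise = (
                rng.normal(0.0, np.sqrt(spec.measurement_error_var), n)
                if spec.measurement_error_var > 0
                else np.zeros(n)
            )
            visit_rows.append(
                pd.DataFrame(
                    {
                        "id": genotypes.individual_ids,
                        "visit": v,
                        "age": baseline_age + off,
                        "trait": spec.name,
                        "value": liability + noise,
                    }
                )
            )

    visits = (
        pd.concat(visit_rows, ignore_index=True)
        if visit_rows
        else pd.DataFrame(columns=["id", "visit", "age", "trait", "value"])
    )
    diagnoses = (
        pd.concat(diag_rows, ignore_index=True)
        if diag_rows
        else pd.DataFrame(columns=["id", "disease", "age_at_diagnosis"])
    )
    return CohortTable(individuals=individuals, visits=visits, diagnoses=diagnoses), states


def simulate_longitudinal_liability(
    n: int,
    process: str = "stationary_decay",
    decay_rate: float = 0.02,
    visit_ages: tuple = (45.0, 50.0, 55.0),
    measurement_error_var: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Visit-level liability trajectories for the longitudinal denoising analysis.

    ``stationary_decay``: liability is a stationary AR process with unit
    variance and corr(l_t, l_{t+d}) = exp(-decay_rate * d).  ``wiener``:
    liability starts N(0, 1) and gains independent N(0, decay_rate * d)
    increments, so variance grows linearly (decay_rate doubles as the per-year
    increment variance).  Observed value = liability + iid measurement noise.

    Returns a long table (id, visit, age, value, liability).
    """
    if process not in ("stationary_decay", "wiener"):
        raise ParameterError(f"unknown process {process!r}")
    if decay_rate < 0:
        raise ParameterError("decay_rate must be >= 0")
    if len(visit_ages) < 2:
        raise InsufficientVisitsError("need >= 2 visit ages")
    if list(visit_ages) != sorted(set(visit_ages)):
        raise ParameterError("visit ages must be strictly increasing")
    rng = np.random.default_rng(seed)
    ages = np.asarray(visit_ages, dtype=float)
    liab = np.empty((n, len(ages)))
    liab[:, 0] = rng.normal(0.0, 1.0, n)
    for j in range(1, len(ages)):
        d = ages[j] - ages[j - 1]
        if process == "stationary_decay":
            rho = np.exp(-decay_rate * d)
            liab[:, j] = rho * liab[:, j - 1] + rng.normal(0.0, np.sqrt(1.0 - rho**2), n)
        else:
            liab[:, j] = liab[:, j - 1] + rng.normal(0.0, np.sqrt(decay_rate * d), n)
    noise = (
        rng.normal(0.0, np.sqrt(measurement_error_var), liab.shape)
        if measurement_error_var > 0
        else np.zeros_like(liab)
    )
    rows = []
    for j, age in enumerate(ages):
        rows.append(
            pd.DataFrame(
                {
                    "id": [f"ind{i}" for i in range(n)],
                    "visit": j + 1,
                    "age": age,
                    "value": liab[:, j] + noise[:, j],
                    "liability": liab[:, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def apply_medication_correction(
    cohort: CohortTable, rules: list[MedicationRule]
) -> CohortTable:
    """Apply additive medication corrections, keeping both columns.

    For each rule, flagged individuals' values of ``rule.trait`` are shifted by
    the correction (sd-mode: correction x whole-population s.d. of the trait)
    and stored under ``<trait>_corrected``; the uncorrected trait is retained.
    Rules sharing a trait accumulate on the same corrected column.
    """
    individuals = cohort.individuals
    visits = cohort.visits.copy()
    present_traits = set(visits["trait"].unique())
    for rule in rules:
        if rule.flag not in individuals.columns:
            raise ConfigurationError(f"unknown medication flag {rule.flag!r}")
        if rule.trait not in present_traits:
            raise ConfigurationError(f"unknown trait {rule.trait!r}")

    corrected = {}
    for rule in rules:
        name = f"{rule.trait}_corrected"
        if name not in corrected:
            block = visits[visits["trait"] == rule.trait].copy()
            block["trait"] = name
            corrected[name] = block
        block = corrected[name]
        pop_sd = float(visits.loc[visits["trait"] == rule.trait, "value"].std(ddof=1))
        amount = rule.correction * pop_sd if rule.unit_mode == "sd" else rule.correction
        flags = individuals.set_index("id")[rule.flag]
        flagged = block["id"].map(flags).to_numpy().astype(bool)
        block.loc[flagged, "value"] += amount

    visits = pd.concat([visits] + list(corrected.values()), ignore_index=True)
    return CohortTable(
        individuals=individuals, visits=visits, diagnoses=cohort.diagnoses
    )


def age_matched_resample(
    ages: np.ndarray,
    group_label: np.ndarray,
    n_per_group: int,
    seed: int | np.random.Generator = 0,
    n_age_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two age-matched samples by inverse-probability stratified sampling.

    Ages are binned on a shared histogram; the common target age distribution
    is proportional to the per-bin minimum availability across the two groups
    (the feasible distribution closest to each group's own, with each
    individual's inclusion probability proportional to target density over
    group density).  The same per-bin counts are drawn uniformly without
    replacement from both groups, so the two samples have matched age
    distributions by construction.  Returns reproducible index arrays.
    """
    ages = np.asarray(ages, dtype=float)
    group_label = np.asarray(group_label).astype(bool)
    idx0 = np.flatnonzero(~group_label)
    idx1 = np.flatnonzero(group_label)
    if len(idx0) == 0 or len(idx1) == 0:
        raise MatchingInfeasibleError("both groups must be non-empty")
    if n_per_group > min(len(idx0), len(idx1)):
        raise MatchingInfeasibleError("n_per_group exceeds a group size")
    edges = np.histogram_bin_edges(ages, bins=n_age_bins)
    c0, _ = np.histogram(ages[idx0], bins=edges)
    c1, _ = np.histogram(ages[idx1], bins=edges)
    avail = np.minimum(c0, c1)
    if not avail.any():
        raise MatchingInfeasibleError("group age supports are disjoint")
    if avail.sum() < n_per_group:
        raise MatchingInfeasibleError(
            f"only {avail.sum()} age-matched individuals available per group"
        )
    # largest-remainder allocation of per-bin counts toward the target
    exact = n_per_group * avail / avail.sum()
    take = np.minimum(np.floor(exact).astype(int), avail)
    short = n_per_group - take.sum()
    if short > 0:
        room = avail - take
        order = np.argsort(-(exact - np.floor(exact)))
        for b in order:
            if short == 0:
                break
            add = min(short, room[b])
            take[b] += add
            short -= add
    rng = np.random.default_rng(seed)
    out = []
    for idx in (idx0, idx1):
        b = np.clip(np.digitize(ages[idx], edges) - 1, 0, len(avail) - 1)
        chosen = []
        for j in np.flatnonzero(take):
            members = idx[b == j]
            chosen.append(rng.choice(members, size=take[j], replace=False))
        out.append(np.concatenate(chosen))
    return out[0], out[1]
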