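"""Haseman-Elston variance-component estimation per age bin.

Desk-scale substitutes for mixed-model REML heritability and summary-statistic
genetic correlation: a GRM from standardized genotypes, Haseman-Elston (HE)
regression of phenotype cross-products on relatedness for within-bin h2, and
cross-sample HE between disjoint age bins for the genetic correlation.
Standard errors come from a delete-one-block jackknife over individuals.
Estimates are deliberately never truncated to [0, 1] (or [-1, 1]); truncation
would bias downstream trend fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, GenotypeMatrix
from .errors import DegenerateInputError, ParameterError, UndefinedEstimateError
from .series import MetricSeries

__all__ = [
    "GRM",
    "HeritabilityEstimate",
    "GeneticCorrelationEstimate",
    "compute_grm",
    "he_heritability",
    "he_genetic_correlation",
    "per_bin_estimates",
]


@dataclass
class GRM:
    """Genetic relationship matrix (1/m) * Z Z' from per-SNP standardized dosages."""

    values: np.ndarray
    n_snps_used: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "GRM":
        return GRM(values=self.values[np.ix_(idx, idx)], n_snps_used=self.n_snps_used)


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    median_age: float = np.nan
    n: int = 0


@dataclass
class GeneticCorrelationEstimate:
    rg: float
    se: float
    bin_pair: tuple = (0, 0)
    age_gap: float = np.nan


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """GRM from empirically standardized dosages; monomorphic SNPs are dropped."""
    if genotypes.n < 2 or genotypes.m < 1:
        raise ParameterError("need >= 2 individuals and >= 1 SNP")
    X = genotypes.dosages.astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} monomorphic SNPs from the GRM")
    if not keep.any():
        raise ParameterError("all SNPs monomorphic")
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    m = Z.shape[1]
    return GRM(values=(Z @ Z.T) / m, n_snps_used=m)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.ones((len(y), 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if not np.any(np.all(C == C[0, :], axis=0) & (C[0, :] != 0)):
            C = np.column_stack([np.ones(len(y)), C])
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


def _block_slices(n: int, n_blocks: int) -> list[np.ndarray]:
    n_blocks = max(1, min(n_blocks, n))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    return [np.arange(bounds[b], bounds[b + 1]) for b in range(n_blocks)]


def _pair_regression_sums(Gm: np.ndarray, P: np.ndarray):
    """Sufficient statistics for the off-diagonal pair regression and its jackknife.

    Gm and P must have zeroed diagonals.  Returns total sums over i<j pairs and
    per-individual row sums for each of x, y, xy, xx.
    """
    GP = Gm * P
    GG = Gm * Gm
    rows = {
        "x": Gm.sum(axis=1),
        "y": P.sum(axis=1),
        "xy": GP.sum(axis=1),
        "xx": GG.sum(axis=1),
    }
    totals = {k: v.sum() / 2.0 for k, v in rows.items()}
    return totals, rows


def _slope(n_pairs: float, Sx: float, Sy: float, Sxy: float, Sxx: float) -> float:
    denom = n_pairs * Sxx - Sx * Sx
    if denom == 0:
        raise DegenerateInputError("no variation in relatedness among pairs")
    return (n_pairs * Sxy - Sx * Sy) / denom


def he_heritability(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM,
    n_jackknife_blocks: int = 100,
    median_age: float = np.nan,
) -> HeritabilityEstimate:
    """HE regression heritability with delete-one-block jackknife s.e.

    The phenotype is residualized on the covariates (an intercept is added if
    absent) and standardized; products y_i * y_j over all i<j pairs are
    regressed (with intercept) on off-diagonal GRM entries.  The slope is the
    h2 estimate.  Jackknife blocks are contiguous ranges of individuals; each
    pseudo-estimate drops every pair touching the block.
    """
    y = np.asarray(phenotype, dtype=float)
    n = grm.n
    if len(y) != n:
        raise ParameterError("phenotype length != GRM dimension")
    resid = _residualize(y, covariates)
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise DegenerateInputError("phenotype constant after covariate adjustment")
    yz = resid / sd

    Gm = grm.values.copy()
    np.fill_diagonal(Gm, 0.0)
    P = np.outer(yz, yz)
    np.fill_diagonal(P, 0.0)
    totals, rows = _pair_regression_sums(Gm, P)
    n_pairs = n * (n - 1) / 2.0
    h2 = _slope(n_pairs, totals["x"], totals["y"], totals["xy"], totals["xx"])

    blocks = _block_slices(n, n_jackknife_blocks)
    pseudo = []
    for I in blocks:
        k = len(I)
        sub_g = Gm[np.ix_(I, I)]
        sub_p = P[np.ix_(I, I)]
        within = {
            "x": sub_g.sum() / 2.0,
            "y": sub_p.sum() / 2.0,
            "xy": (sub_g * sub_p).sum() / 2.0,
            "xx": (sub_g * sub_g).sum() / 2.0,
        }
        comp = {
            key: totals[key] - (rows[key][I].sum() - within[key])
            for key in totals
        }
        n_c = (n - k) * (n - k - 1) / 2.0
        pseudo.append(_slope(n_c, comp["x"], comp["y"], comp["xy"], comp["xx"]))
    pseudo = np.asarray(pseudo)
    B = len(pseudo)
    se = np.sqrt((B - 1) / B * ((pseudo - pseudo.mean()) ** 2).sum())
    return HeritabilityEstimate(h2=float(h2), se=float(se), median_age=median_age, n=n)


def he_genetic_correlation(
    pheno_a: np.ndarray,
    pheno_b: np.ndarray,
    grm_cross: np.ndarray,
    h2_a: float,
    h2_b: float,
    n_jackknife_blocks: int = 100,
    covariates_a: np.ndarray | None = None,
    covariates_b: np.ndarray | None = None,
    bin_pair: tuple = (0, 0),
    age_gap: float = np.nan,
) -> GeneticCorrelationEstimate:
    """Cross-sample HE genetic correlation between two disjoint samples.

    Products y_a,i * y_b,j are regressed on cross-GRM entries over all
    n_a x n_b pairs; the slope estimates the genetic covariance, divided by
    sqrt(h2_a * h2_b).  Because the samples are disjoint there is no shared
    environmental term, so the regression intercept absorbs nothing genetic —
    the analogue of a zero sample-overlap covariance intercept.  The jackknife
    deletes aligned contiguous blocks from both samples; the h2 denominators
    are held at their point estimates, so the s.e. reflects numerator noise.
    """
    if h2_a <= 0 or h2_b <= 0:
        raise UndefinedEstimateError(
            f"genetic correlation undefined for non-positive h2 ({h2_a:.3f}, {h2_b:.3f})"
        )
    ya = _residualize(np.asarray(pheno_a, float), covariates_a)
    yb = _residualize(np.asarray(pheno_b, float), covariates_b)
    sa, sb = ya.std(ddof=1), yb.std(ddof=1)
    if sa < 1e-12 or sb < 1e-12:
        raise DegenerateInputError("constant phenotype after adjustment")
    ya, yb = ya / sa, yb / sb
    K = np.asarray(grm_cross, dtype=float)
    na, nb = K.shape
    if len(ya) != na or len(yb) != nb:
        raise ParameterError("phenotype lengths inconsistent with cross-GRM block")

    P = np.outer(ya, yb)
    KP = K * P
    KK = K * K
    tot = {
        "x": K.sum(),
        "y": P.sum(),
        "xy": KP.sum(),
        "xx": KK.sum(),
    }
    n_pairs = na * nb
    cov = _slope(n_pairs, tot["x"], tot["y"], tot["xy"], tot["xx"])
    rg = cov / np.sqrt(h2_a * h2_b)

    blocks_a = _block_slices(na, n_jackknife_blocks)
    blocks_b = _block_slices(nb, len(blocks_a))
    pseudo = []
    for Ia, Ib in zip(blocks_a, blocks_b):
        comp = {}
        for key, M in (("x", K), ("y", P), ("xy", KP), ("xx", KK)):
            comp[key] = (
                tot[key]
                - M[Ia, :].sum()
                - M[:, Ib].sum()
                + M[np.ix_(Ia, Ib)].sum()
            )
        n_c = (na - len(Ia)) * (nb - len(Ib))
        pseudo.append(_slope(n_c, comp["x"], comp["y"], comp["xy"], comp["xx"]))
    pseudo = np.asarray(pseudo) / np.sqrt(h2_a * h2_b)
    B = len(pseudo)
    se = np.sqrt((B - 1) / B * ((pseudo - pseudo.mean()) ** 2).sum())
    return GeneticCorrelationEstimate(
        rg=float(rg), se=float(se), bin_pair=bin_pair, age_gap=age_gap
    )


def per_bin_estimates(
    cohort: CohortTable,
    trait: str,
    grm: GRM,
    n_bins: int = 5,
    n_jackknife_blocks: int = 100,
    min_bin_n: int = 50,
) -> tuple[MetricSeries, pd.DataFrame]:
    """Per-age-bin HE heritability with sex and within-bin age as covariates.

    Bins are baseline-age quintiles of the analysis sample.  Returns the h2
    MetricSeries plus a per-bin, per-sex phenotypic variance table (columns
    bin, sex, var_p, median_age, n) used for the genetic/environmental variance
    decomposition.  Bins smaller than ``min_bin_n`` are skipped with a warning.
    """
    ind = cohort.individuals
    y_all = cohort.trait_at_visit(trait, visit=1).to_numpy()
    if len(ind) != grm.n:
        raise ParameterError("cohort size != GRM dimension")
    bins = pd.qcut(ind["baseline_age"], n_bins, labels=False) + 1
    values, ses, ages, ns = [], [], [], []
    var_rows = []
    for k in range(1, n_bins + 1):
        idx = np.flatnonzero((bins == k) & ~np.isnan(y_all))
        if len(idx) < min_bin_n:
            warnings.warn(f"bin {k} has n={len(idx)} < {min_bin_n}; skipped")
            continue
        y = y_all[idx]
        med_age = float(ind["baseline_age"].iloc[idx].median())
        C = np.column_stack(
            [ind["sex"].iloc[idx].to_numpy(), ind["baseline_age"].iloc[idx].to_numpy()]
        )
        est = he_heritability(
            y, C, grm.subset(idx), n_jackknife_blocks=n_jackknife_blocks, median_age=med_age
        )
        values.append(est.h2)
        ses.append(est.se)
        ages.append(med_age)
        ns.append(len(idx))
        for sex_val in (0, 1):
            sub = idx[ind["sex"].iloc[idx].to_numpy() == sex_val]
            if len(sub) >= 2:
                var_rows.append(
                    {
                        "bin": k,
                        "sex": sex_val,
                        "var_p": float(np.var(y_all[sub], ddof=1)),
                        "median_age": float(ind["baseline_age"].iloc[sub].median()),
                        "n": len(sub),
                    }
                )
        var_rows.append(
            {
                "bin": k,
                "sex": -1,  # pooled
                "var_p": float(np.var(y, ddof=1)),
                "median_age": med_age,
                "n": len(idx),
            }
        )
    series = MetricSeries(
        metric="h2",
        values=np.array(values),
        ses=np.array(ses),
        median_ages=np.array(ages),
        ns=np.array(ns),
        label=trait,
    )
    return series, pd.DataFrame(var_rows)
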