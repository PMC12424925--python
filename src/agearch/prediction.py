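"""Predictors, case-control designs, and age-dependent accuracy metrics.

Builds the scores used across the analysis — calibrated liability predictors
at a target liability-scale R2, rank-normalized quantitative risk scores
(QRS), LASSO-estimated disease liability — together with incident/prevalent
case-control set construction, observed-scale R2, regression association
metrics (AUC, logOR, linear effect, logHR), the observed-to-liability-scale
R2 transformation under ascertainment, and the noise-matched QRS Monte-Carlo
pipeline that predicts the expected age profile of PRS accuracy under the
liability-threshold model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    EmptySetError,
    ParameterError,
    UndefinedEstimateError,
)
from .liability import CaseControlSet
from .series import MetricSeries

__all__ = [
    "Score",
    "AccuracyEstimate",
    "calibrate_predictor",
    "rank_normal",
    "fit_estimated_liability",
    "incident_case_sets",
    "prevalent_case_sets",
    "observed_r2",
    "association_metrics",
    "liability_r2_transform",
    "inverse_liability_r2_transform",
    "liability_scale_correlation",
    "qrs_pipeline",
    "QRSResult",
]


@dataclass
class Score:
    """A per-individual predictor, standardized to mean 0, s.d. 1 over the population."""

    values: np.ndarray
    kind: str = "prs_like"  # prs_like | qrs | estimated_liability | single_trait | combined
    name: str = ""
    target_r2_liab: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("score values must be finite")


@dataclass
class AccuracyEstimate:
    metric: str  # r2_obs | auc | log_or | linear_effect | log_hr | r2_liab
    value: float
    se: float = np.nan
    bin: int | None = None  # None = whole population
    K: float = np.nan
    P: float = np.nan
    converged: bool = True


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd < 1e-12:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return y - y.mean()
    C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


def calibrate_predictor(
    liability: np.ndarray,
    target_r2_liab: float,
    seed: int | np.random.Generator = 0,
) -> Score:
    """A predictor with a chosen squared correlation to the liability.

    score = liability + N(0, var(L) * (1 - t) / t) noise, then standardized;
    the realized squared correlation with liability is t in expectation.  The
    tiers used in simulation experiments are t = 0.99 (near-perfect), 0.5
    (strong), 0.2 (clinical-score-like) and 0.05 (PRS-like).
    """
    if not 0.0 < target_r2_liab <= 1.0:
        raise ParameterError("target_r2_liab must be in (0, 1]")
    L = np.asarray(liability, dtype=float)
    rng = np.random.default_rng(seed)
    var_l = L.var(ddof=1)
    noise_var = var_l * (1.0 - target_r2_liab) / target_r2_liab
    noise = rng.normal(0.0, np.sqrt(noise_var), len(L)) if noise_var > 0 else 0.0
    return Score(
        values=_standardize(L + noise),
        kind="prs_like",
        target_r2_liab=target_r2_liab,
    )


def rank_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset (ties -> average rank)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateInputError("rank-normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def _lasso_cv_curve(X, y, alphas, folds):
    """Mean CV MSE and its fold-to-fold s.e. along a shared alpha path."""
    from sklearn.linear_model import lasso_path

    fold_mse = np.empty((len(folds), len(alphas)))
    for f, (tr, te) in enumerate(folds):
        _, coefs, _ = lasso_path(X[tr], y[tr], alphas=alphas)
        mu = y[tr].mean()
        icept = mu - X[tr].mean(axis=0) @ coefs
        pred = X[te] @ coefs + icept
        fold_mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    cvm = fold_mse.mean(axis=0)
    cvse = fold_mse.std(axis=0, ddof=1) / np.sqrt(len(folds))
    return cvm, cvse


def fit_estimated_liability(
    quant_traits: np.ndarray,
    disease_status: np.ndarray,
    n_folds: int = 10,
    rule: str = "2se",
    seed: int = 0,
    n_alphas: int = 60,
) -> tuple[Score, np.ndarray]:
    """LASSO linear estimated disease liability from quantitative traits.

    A linear (not logistic) L1 model of case status — the liability-threshold
    view treats the binary outcome as a thresholded latent variable, so the
    linear fit targets the liability itself.  The penalty is chosen by k-fold
    CV with the 1se rule (largest penalty within one CV s.e. of the minimum)
    or the stronger 2se analogue.  Out-of-fold predictions are returned as the
    estimated liability; coefficients come from a final full-data fit at the
    chosen penalty.  Age is deliberately not a covariate, so the prediction
    approximates liability at the measurement age.
    """
    from sklearn.linear_model import Lasso, lasso_path
    from sklearn.model_selection import StratifiedKFold

    if rule not in ("1se", "2se"):
        raise ParameterError("rule must be '1se' or '2se'")
    X = np.asarray(quant_traits, dtype=float)
    y = np.asarray(disease_status, dtype=float)
    n_cases = int(y.sum())
    if n_cases < n_folds:
        raise ParameterError(f"{n_cases} cases < {n_folds} folds")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)

    alphas, _, _ = lasso_path(Xs, y, alphas=n_alphas)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y))
    cvm, cvse = _lasso_cv_curve(Xs, y, alphas, folds)
    i_min = int(np.argmin(cvm))
    k_se = 1.0 if rule == "1se" else 2.0
    ok = cvm <= cvm[i_min] + k_se * cvse[i_min]
    alpha = float(alphas[ok].max())  # alphas decreasing; largest admissible penalty

    oof = np.empty(len(y))
    for tr, te in folds:
        model = Lasso(alpha=alpha, max_iter=5000)
        model.fit(Xs[tr], y[tr])
        oof[te] = model.predict(Xs[te])
    final = Lasso(alpha=alpha, max_iter=5000)
    final.fit(Xs, y)
    score = Score(values=oof, kind="estimated_liability")
    return score, final.coef_


def _diag_frame(cohort, disease: str):
    ind = cohort.individuals
    d = cohort.diagnoses
    sub = d[d["disease"] == disease].groupby("id")["age_at_diagnosis"].min()
    df = ind[["id", "censor_age"]].copy()
    df["diag_age"] = df["id"].map(sub)
    df["row"] = np.arange(len(df))
    return df


def incident_case_sets(
    cohort,
    disease: str,
    n_bins: int = 5,
    seed: int | np.random.Generator = 0,
    include_lost_to_followup: bool = True,
) -> list[CaseControlSet]:
    """Interval-censored incident case-control sets by diagnosis-age quintile.

    Cases are split into ``n_bins`` quantile intervals of first-diagnosis age.
    Within each interval, cases are those diagnosed inside it; controls are
    undiagnosed individuals followed to the end of the interval (optionally
    also those lost to follow-up inside it).  Anyone diagnosed before the
    interval is excluded entirely.  Controls are down-sampled to 1:1.
    Returns row-index-based CaseControlSets with the interval attached.
    """
    df = _diag_frame(cohort, disease)
    diag = df["diag_age"]
    case_ages = diag.dropna().to_numpy()
    if len(case_ages) < n_bins:
        raise EmptySetError(f"only {len(case_ages)} cases of {disease}")
    edges = np.quantile(case_ages, np.linspace(0, 1, n_bins + 1))
    rng = np.random.default_rng(seed)
    sets = []
    for k in range(1, n_bins + 1):
        lo, hi = edges[k - 1], edges[k]
        in_interval = (diag > lo) & (diag <= hi)
        if k == 1:
            in_interval |= diag == lo
        cases = df.loc[in_interval.fillna(False), "row"].to_numpy()
        healthy = diag.isna() | (diag > hi)
        followed = df["censor_age"] >= hi
        eligible_ctrl = diag.isna() & followed
        if include_lost_to_followup:
            lost = diag.isna() & (df["censor_age"] > lo) & (df["censor_age"] < hi)
            eligible_ctrl |= lost
        # never use anyone diagnosed at any time as a control; individuals
        # diagnosed after the interval remained healthy through it
        eligible_ctrl |= (diag > hi).fillna(False) & followed
        pool = df.loc[eligible_ctrl, "row"].to_numpy()
        if len(cases) == 0:
            raise EmptySetError(f"no incident cases in interval {k}")
        if len(pool) < len(cases):
            raise EmptySetError(f"control pool smaller than cases in interval {k}")
        K = len(cases) / (len(cases) + len(pool))
        controls = rng.choice(pool, size=len(cases), replace=False)
        sets.append(
            CaseControlSet(
                case_ids=cases,
                control_ids=controls,
                bin=k,
                design="incident",
                K=K,
                interval=(float(lo), float(hi)),
            )
        )
    return sets


def prevalent_case_sets(
    cohort,
    disease: str,
    baseline_ages: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> list[CaseControlSet]:
    """Prevalent case-control sets at fixed baseline age points.

    ``baseline_ages`` are conventionally the five median case ages of the
    incident intervals.  At each age point, eligible individuals are those
    followed past it; cases have a diagnosis before it; controls are sampled
    1:1 from undiagnosed-by-then eligibles.
    """
    df = _diag_frame(cohort, disease)
    rng = np.random.default_rng(seed)
    sets = []
    for k, age in enumerate(np.asarray(baseline_ages, dtype=float), start=1):
        eligible = df["censor_age"] >= age
        is_case = (df["diag_age"] < age).fillna(False) & eligible
        is_ctrl = (df["diag_age"].isna() | (df["diag_age"] >= age)) & eligible
        cases = df.loc[is_case, "row"].to_numpy()
        pool = df.loc[is_ctrl, "row"].to_numpy()
        if len(cases) == 0:
            raise EmptySetError(f"no prevalent cases before age {age:.1f}")
        if len(pool) < len(cases):
            raise EmptySetError(f"control pool smaller than cases at age {age:.1f}")
        K = len(cases) / (len(cases) + len(pool))
        controls = rng.choice(pool, size=len(cases), replace=False)
        sets.append(
            CaseControlSet(
                case_ids=cases,
                control_ids=controls,
                bin=k,
                design="prevalent",
                K=K,
                baseline_age=float(age),
            )
        )
    return sets


def observed_r2(
    score: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Observed-scale R2: residualize the outcome on covariates, square the
    Pearson correlation of the residual with the score."""
    s = np.asarray(score, dtype=float)
    if s.std() < 1e-12:
        raise DegenerateInputError("constant score")
    resid = _residualize(np.asarray(outcome, dtype=float), covariates)
    if resid.std() < 1e-12:
        raise DegenerateInputError("outcome constant after covariate adjustment")
    r = np.corrcoef(resid, s)[0, 1]
    return float(r * r)


def association_metrics(
    score: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None,
    metric: str,
    durations: np.ndarray | None = None,
    events: np.ndarray | None = None,
) -> AccuracyEstimate:
    """One association metric of a standardized score with a binary outcome.

    auc: Mann-Whitney probability (no covariate adjustment), Hanley-McNeil
    s.e.; log_or: logistic coefficient; linear_effect: OLS coefficient;
    log_hr: Cox proportional-hazards coefficient (needs durations + events).
    Covariates enter the regression models alongside the score.
    """
    s = _standardize(score)
    y = np.asarray(outcome, dtype=float)
    if metric == "auc":
        n1, n0 = int(y.sum()), int((1 - y).sum())
        if n1 == 0 or n0 == 0:
            raise DegenerateInputError("AUC needs both classes")
        u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        auc = float(u / (n1 * n0))
        q1, q2 = auc / (2 - auc), 2 * auc**2 / (1 + auc)
        se = np.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0)
        )
        return AccuracyEstimate(metric="auc", value=auc, se=float(se))
    X = s[:, None] if covariates is None else np.column_stack([s, covariates])
    if metric == "log_or":
        import statsmodels.api as sm

        model = sm.Logit(y, sm.add_constant(X))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=False, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                return AccuracyEstimate(metric="log_or", value=np.nan, converged=False)
            return AccuracyEstimate(
                metric="log_or", value=float(res.params[1]), se=float(res.bse[1])
            )
        except Exception:
            return AccuracyEstimate(metric="log_or", value=np.nan, converged=False)
    if metric == "linear_effect":
        import statsmodels.api as sm

        res = sm.OLS(y, sm.add_constant(X)).fit()
        return AccuracyEstimate(
            metric="linear_effect", value=float(res.params[1]), se=float(res.bse[1])
        )
    if metric == "log_hr":
        if durations is None or events is None:
            raise ParameterError("log_hr requires durations and events")
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"duration": durations, "event": events, "score": s})
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != len(s):
                C = C.T
            for j in range(C.shape[1]):
                df[f"c{j}"] = C[:, j]
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="duration", event_col="event")
            return AccuracyEstimate(
                metric="log_hr",
                value=float(cph.params_["score"]),
                se=float(cph.standard_errors_["score"]),
            )
        except Exception:
            return AccuracyEstimate(metric="log_hr", value=np.nan, converged=False)
    raise ParameterError(f"unknown metric {metric!r}")


def liability_r2_transform(r2_obs: float, K: float, P: float) -> float:
    """Observed-scale R2 to liability-scale R2 under case-control ascertainment.

    Lee et al. (2012) ascertainment-corrected transformation: with threshold
    t = Phi^-1(1 - K), z = phi(t), mean case liability m = z / K,
    C = K(1-K)/z^2 * K(1-K)/(P(1-P)) and
    theta = m * (P-K)/(1-K) * (m * (P-K)/(1-K) - t),
    R2_liab = C * R2_obs / (1 + C * theta * R2_obs).
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ParameterError("K and P must be in (0, 1)")
    if r2_obs < 0:
        raise ParameterError("r2_obs must be >= 0")
    t = stats.norm.ppf(1 - K)
    z = stats.norm.pdf(t)
    m = z / K
    C = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    return float(C * r2_obs / (1 + C * theta * r2_obs))


def inverse_liability_r2_transform(r2_liab: float, K: float, P: float) -> float:
    """Observed-scale R2 that maps to ``r2_liab`` under the Lee transformation."""
    if not (0 < K < 1 and 0 < P < 1):
        raise ParameterError("K and P must be in (0, 1)")
    t = stats.norm.ppf(1 - K)
    z = stats.norm.pdf(t)
    m = z / K
    C = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    denom = C * (1 - theta * r2_liab)
    if denom <= 0:
        raise UndefinedEstimateError("r2_liab outside the transform's range")
    return float(r2_liab / denom)


def liability_scale_correlation(
    quant: np.ndarray, binary: np.ndarray, K: float | None = None
) -> float:
    """Point-biserial correlation mapped to the liability scale.

    Used as the screen for selecting the quantitative traits most relevant to
    each disease.  In an unascertained sample (P = K) the Lee transformation
    reduces to r_liab = r_obs * sqrt(K(1-K)) / z.
    """
    y = np.asarray(binary, dtype=float)
    x = np.asarray(quant, dtype=float)
    if y.std() < 1e-12 or x.std() < 1e-12:
        raise DegenerateInputError("constant input")
    P = y.mean()
    if K is None:
        K = P
    r = np.corrcoef(x, y)[0, 1]
    r2_liab = liability_r2_transform(r * r, K, P)
    return float(np.sign(r) * np.sqrt(r2_liab))


@dataclass
class QRSResult:
    """Output bundle of the noise-matched QRS Monte-Carlo pipeline."""

    qrs_series: MetricSeries  # per-bin incident R2_obs of the noise-matched QRS (MC mean, sd)
    prs_series: MetricSeries  # per-bin incident R2_obs of the PRS
    r2liab_prs: float
    r2liab_qrs_raw: float
    r2liab_qrs_matched: float
    noise_var: float
    n_mc: int
    case_sets: list = field(default_factory=list, repr=False)


def _match_noise_var(q_resid: np.ndarray, r2_obs_now: float, r2_obs_target: float) -> float:
    """Noise variance that attenuates the QRS observed R2 to the target.

    corr^2(Q + eps, y) = corr^2(Q, y) * var(Q) / (var(Q) + var(eps)).
    """
    if r2_obs_target >= r2_obs_now:
        warnings.warn("QRS R2 already at or below the PRS target; adding no noise")
        return 0.0
    return float(q_resid.var(ddof=1) * (r2_obs_now / r2_obs_target - 1.0))


def qrs_pipeline(
    qrs_raw: np.ndarray,
    prs: np.ndarray,
    cohort,
    disease: str,
    qrs_covariates: np.ndarray | None,
    prs_covariates: np.ndarray | None,
    n_mc: int = 50,
    n_bins: int = 5,
    seed: int = 0,
) -> QRSResult:
    """Expected age profile of PRS accuracy under the liability-threshold model.

    Six steps: (1) rank-normalize the raw QRS (an estimated liability);
    (2) residualize QRS on age + sex and the standardized PRS on sex (+ PCs);
    (3) compute each score's whole-population liability-scale R2 against
    case status (union of prevalent and incident cases); (4) add Gaussian
    noise to the QRS so its liability-scale R2 matches the PRS's; (5) compute
    the noise-matched QRS's observed R2 per incident age bin using the same
    case-control sets as the PRS; (6) repeat the noise draw and control
    sampling ``n_mc`` times, reporting the mean and s.d. per bin.
    """
    rng = np.random.default_rng(seed)
    q = rank_normal(np.asarray(qrs_raw, dtype=float))
    q_resid = _residualize(q, qrs_covariates)
    p_resid = _residualize(_standardize(np.asarray(prs, dtype=float)), prs_covariates)

    df = _diag_frame(cohort, disease)
    status = (~df["diag_age"].isna()).to_numpy().astype(float)
    K = status.mean()
    if not 0 < K < 1:
        raise EmptySetError(f"disease {disease} has no cases or no controls")
    r2o_q = observed_r2(q_resid, status)
    r2o_p = observed_r2(p_resid, status)
    r2l_q = liability_r2_transform(r2o_q, K, K)
    r2l_p = liability_r2_transform(r2o_p, K, K)
    target_r2o = inverse_liability_r2_transform(r2l_p, K, K)
    noise_var = _match_noise_var(q_resid, r2o_q, target_r2o)

    base_sets = incident_case_sets(
        cohort, disease, n_bins=n_bins, seed=rng.integers(2**31)
    )
    diag_ages = df["diag_age"].to_numpy()
    bin_ages = [float(np.median(diag_ages[cc.case_ids.astype(int)])) for cc in base_sets]
    bin_ns = [len(cc.ids()) for cc in base_sets]

    mc_q = np.empty((n_mc, n_bins))
    mc_p = np.empty((n_mc, n_bins))
    for r in range(n_mc):
        eps = rng.normal(0.0, np.sqrt(noise_var), len(q_resid)) if noise_var > 0 else 0.0
        q_mc = q_resid + eps
        sets = incident_case_sets(cohort, disease, n_bins=n_bins, seed=rng.integers(2**31))
        for j, cc in enumerate(sets):
            rows = cc.ids().astype(int)
            qcov = None if qrs_covariates is None else np.asarray(qrs_covariates)[rows]
            pcov = None if prs_covariates is None else np.asarray(prs_covariates)[rows]
            mc_q[r, j] = observed_r2(q_mc[rows], cc.outcome(), qcov)
            mc_p[r, j] = observed_r2(p_resid[rows], cc.outcome(), pcov)

    matched_draws = [
        liability_r2_transform(
            observed_r2(
                q_resid
                + (rng.normal(0, np.sqrt(noise_var), len(q_resid)) if noise_var > 0 else 0.0),
                status,
            ),
            K,
            K,
        )
        for _ in range(10)
    ]
    matched_r2l = float(np.mean(matched_draws))
    qrs_series = MetricSeries(
        metric="r2_obs",
        values=mc_q.mean(axis=0),
        ses=mc_q.std(axis=0, ddof=1),
        median_ages=np.array(bin_ages),
        ns=np.array(bin_ns),
        label=f"{disease}:qrs",
    )
    prs_series = MetricSeries(
        metric="r2_obs",
        values=mc_p.mean(axis=0),
        ses=mc_p.std(axis=0, ddof=1),
        median_ages=np.array(bin_ages),
        ns=np.array(bin_ns),
        label=f"{disease}:prs",
    )
    return QRSResult(
        qrs_series=qrs_series,
        prs_series=prs_series,
        r2liab_prs=r2l_p,
        r2liab_qrs_raw=r2l_q,
        r2liab_qrs_matched=matched_r2l,
        noise_var=noise_var,
        n_mc=n_mc,
        case_sets=base_sets,
    )
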