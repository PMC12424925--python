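"""End-to-end orchestration: simulate -> estimate -> correlate -> predict -> trends.

A single RunConfig drives every stage with derived, logged seeds; all
interchange tables are written to the output directory, so each reported
number is traceable to a file on disk.  Stage failures abort with the stage
name attached.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as co
from . import correlations as corr
from . import heritability as her
from . import prediction as pred
from . import trends as tr
from .errors import AgearchError, ConfigurationError
from .io import write_table

__all__ = ["RunConfig", "run_pipeline", "StageError"]

log = logging.getLogger("agearch")


class StageError(AgearchError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    seed: int = 0
    n_individuals: int = 4000
    n_snps: int = 1000
    maf_range: tuple = (0.05, 0.5)
    traits: list = field(
        default_factory=lambda: [
            {"name": "trait_ea", "h2": 0.5, "ea_increment_var": 0.05,
             "measurement_error_var": 0.2},
            {"name": "trait_flat", "h2": 0.5},
            {"name": "marker_1", "loads_on": "disease_a", "loading": 0.5,
             "measurement_error_var": 0.1},
            {"name": "marker_2", "loads_on": "disease_a", "loading": 0.4,
             "measurement_error_var": 0.1},
        ]
    )
    diseases: list = field(
        default_factory=lambda: [{"name": "disease_a", "h2": 0.3, "bin_fraction": 0.03}]
    )
    visit_offsets: tuple = (0.0, 5.0, 10.0)
    n_age_bins: int = 5
    n_jackknife_blocks: int = 50
    n_bootstrap: int = 200
    n_mc_trend: int = 1000
    n_mc_qrs: int = 20
    prs_target_r2_liab: float = 0.05
    output_dir: str = "results/pipeline"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["visit_offsets"] = list(self.visit_offsets)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "visit_offsets" in d:
            d["visit_offsets"] = tuple(d["visit_offsets"])
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raised with stage label
                raise StageError(name, e) from e
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the result tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    seeds = {s: int(root.integers(2**31)) for s in
             ("genotypes", "cohort", "longitudinal", "prs", "qrs", "trend")}
    log.info("derived stage seeds: %s", seeds)
    results: dict = {}

    @_stage("simulate")
    def simulate():
        geno = co.simulate_genotypes(
            config.n_individuals, config.n_snps, config.maf_range, seeds["genotypes"]
        )
        cfg = co.CohortConfig(
            traits=[co.TraitSpec(**t) for t in config.traits],
            diseases=[co.DiseaseSpec(**d) for d in config.diseases],
            visit_offsets=tuple(config.visit_offsets),
            n_age_bins=config.n_age_bins,
        )
        table, states = co.simulate_cohort(geno, cfg, seeds["cohort"])
        write_table(table.individuals, out / "individuals.tsv", "individuals")
        write_table(table.visits, out / "visits.tsv", "visits")
        write_table(table.diagnoses, out / "diagnoses.tsv", "diagnoses")
        return geno, cfg, table, states

    geno, cfg, table, states = simulate()

    @_stage("estimate")
    def estimate():
        grm = her.compute_grm(geno)
        frames = []
        series_by_trait = {}
        for spec in cfg.traits:
            series, _ = her.per_bin_estimates(
                table, spec.name, grm, n_bins=config.n_age_bins,
                n_jackknife_blocks=config.n_jackknife_blocks,
            )
            series_by_trait[spec.name] = series
            frames.append(series.to_frame())
        est = pd.concat(frames, ignore_index=True)
        write_table(est, out / "estimates.tsv", "estimates")
        return grm, series_by_trait

    grm, h2_series = estimate()

    @_stage("correlate")
    def correlate():
        rows = []
        visits = co.simulate_longitudinal_liability(
            config.n_individuals, "stationary_decay", 0.02,
            visit_ages=(45.0, 50.0, 55.0),
            measurement_error_var=0.3, seed=seeds["longitudinal"],
        )
        ce = corr.denoised_phenotypic_correlation(
            visits, n_bootstrap=config.n_bootstrap, seed=seeds["longitudinal"]
        )
        z, p1, _ = corr.test_corr_lt_1((ce.rho_10yr, ce.se))
        rows.append(
            {"trait": "longitudinal_demo", "kind": ce.kind, "rho_raw": ce.rho_raw,
             "age_gap": ce.age_gap, "rho_10yr": ce.rho_10yr, "se": ce.se,
             "z": z, "p": p1}
        )
        df = pd.DataFrame(rows)
        write_table(df, out / "correlations.tsv", "correlations")
        return df

    results["correlations"] = correlate()

    @_stage("predict")
    def predict():
        rows, trend_rows = [], []
        for spec in cfg.diseases:
            state = states[spec.name]
            prs = pred.calibrate_predictor(
                state.G, config.prs_target_r2_liab, seeds["prs"]
            )
            trait_names = [t.name for t in cfg.traits]
            X = np.column_stack(
                [table.trait_at_visit(t, 1).to_numpy() for t in trait_names]
            )
            status = table.individuals["id"].isin(
                table.diagnoses.loc[table.diagnoses["disease"] == spec.name, "id"]
            ).to_numpy().astype(float)
            if status.sum() < 10:
                log.warning("disease %s has too few observed cases; skipped", spec.name)
                continue
            est_liab, _ = pred.fit_estimated_liability(
                X, status, n_folds=5, rule="2se", seed=seeds["qrs"]
            )
            sexage = np.column_stack(
                [table.individuals["sex"], table.individuals["baseline_age"]]
            )
            res = pred.qrs_pipeline(
                est_liab.values, prs.values, table, spec.name,
                qrs_covariates=sexage,
                prs_covariates=table.individuals[["sex"]].to_numpy(),
                n_mc=config.n_mc_qrs, n_bins=config.n_age_bins, seed=seeds["qrs"],
            )
            results[f"qrs:{spec.name}"] = res
            for s in (res.qrs_series, res.prs_series):
                for j in range(len(s)):
                    rows.append(
                        {"trait": s.label, "bin": j + 1,
                         "median_age": s.median_ages[j], "n": s.ns[j],
                         "estimate": s.values[j], "se": s.ses[j], "metric": s.metric}
                    )
        df = pd.DataFrame(rows)
        if len(df):
            write_table(df, out / "prediction_estimates.tsv", "estimates")
        return df

    results["prediction"] = predict()

    @_stage("trends")
    def trend_stage():
        rows = []
        for name, series in h2_series.items():
            t = tr.fit_metric_trend(series, n_mc=config.n_mc_trend, seed=seeds["trend"])
            pop = float(series.values.mean())
            rel, rel_se = (np.nan, np.nan)
            if pop != 0:
                rel, rel_se = tr.relative_10yr_change(t, pop)
            rows.append(
                {"label": name, "metric": "h2", "slope": t.slope,
                 "slope_se": t.slope_se, "rel_change_10yr": rel,
                 "rel_change_se": rel_se, "lrt_p": t.lrt_p}
            )
        for key, res in list(results.items()):
            if not key.startswith("qrs:"):
                continue
            for s in (res.qrs_series, res.prs_series):
                t = tr.fit_metric_trend(s, n_mc=config.n_mc_trend, seed=seeds["trend"])
                pop = float(s.values.mean())
                rel, rel_se = tr.relative_10yr_change(t, pop) if pop else (np.nan, np.nan)
                rows.append(
                    {"label": s.label, "metric": s.metric, "slope": t.slope,
                     "slope_se": t.slope_se, "rel_change_10yr": rel,
                     "rel_change_se": rel_se, "lrt_p": t.lrt_p}
                )
        df = pd.DataFrame(rows)
        write_table(df, out / "trends.tsv", "trends")
        return df

    results["trends"] = trend_stage()

    @_stage("attribute")
    def attribute():
        trends_df = results["trends"]
        rows = []
        for spec in cfg.diseases:
            ql = f"{spec.name}:qrs"
            pl = f"{spec.name}:prs"
            have = set(trends_df["label"])
            if not {ql, pl} <= have:
                continue
            q = trends_df[trends_df["label"] == ql].iloc[0]
            p = trends_df[trends_df["label"] == pl].iloc[0]
            tau = tr.tau_explained([q["rel_change_10yr"]], [p["rel_change_10yr"]])
            z, pv = tr.slope_difference_test(
                q["rel_change_10yr"], p["rel_change_10yr"],
                q["rel_change_se"], p["rel_change_se"],
            )
            comb, _ = tr.combined_expected_change(
                q["rel_change_10yr"], 0.0, q["rel_change_se"], 0.0, seed=seeds["trend"]
            )
            rows.append(
                {"disease": spec.name, "delta_qrs": q["rel_change_10yr"],
                 "delta_prs": p["rel_change_10yr"], "delta_h2": 0.0,
                 "expected_combined": comb, "z": z, "p": pv, "tau": tau}
            )
        df = pd.DataFrame(rows)
        if len(df):
            write_table(df, out / "attribution.tsv", "attribution")
        return df

    results["attribution"] = attribute()
    return results
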