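"""Simulate the synthetic study cohort and summarize its structure.

Generates unlinked SNP genotypes and a biobank-style cohort: an
exposure-accumulation (EA) quantitative trait, a constant-heritability
control trait, four biomarkers that load on a liability-threshold disease,
and the disease's age-at-first-diagnosis records.  Writes the small cohort
summary tables under results/cohort/.  Downstream scripts regenerate the
same cohort from the shared seed rather than reading multi-megabyte dosage
files back in.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import COHORT_SEED, RESULTS, build_cohort  # noqa: E402

import pandas as pd  # noqa: E402


def main():
    geno, table, states, cfg = build_cohort()
    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    # compact per-age-bin summary (full per-individual tables are regenerated
    # from the seed by any downstream consumer; no need to persist megabytes)
    ind = table.individuals.copy()
    ind["age_bin"] = pd.qcut(ind["baseline_age"], 5, labels=False) + 1
    diag_ids = set(table.diagnoses["id"])
    ind["diagnosed"] = ind["id"].isin(diag_ids)
    summary = (
        ind.groupby("age_bin")
        .agg(n=("id", "size"), median_age=("baseline_age", "median"),
             frac_male=("sex", "mean"), prevalence=("diagnosed", "mean"))
        .reset_index()
    )
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    diag_q = table.diagnoses["age_at_diagnosis"].quantile([0, 0.25, 0.5, 0.75, 1.0])
    diag_q.rename("age_at_diagnosis").to_csv(out / "diagnosis_age_quantiles.tsv", sep="\t")

    n = geno.n
    n_cases = table.diagnoses["id"].nunique()
    print(f"cohort: {n} individuals, {geno.m} unlinked SNPs (seed {COHORT_SEED})")
    print(f"baseline ages {table.individuals.baseline_age.min():.1f}-"
          f"{table.individuals.baseline_age.max():.1f}, "
          f"{table.individuals.sex.mean():.1%} male-coded")
    print(f"disease 'dz': {n_cases} diagnosed ({n_cases / n:.1%} observed prevalence)")
    st = states["trait_ea"]
    cum = st.ea_increments.cumsum(axis=1)
    print("EA trait accumulated environmental variance by age bin:",
          np.round(cum.var(axis=0), 3))
    print(f"tables written under {out}/")


if __name__ == "__main__":
    main()
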