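"""Shared cohort construction for the numbered analysis scripts.

One stated synthetic world, regenerated identically by every script from the
same seed: 6,000 individuals, 500 unlinked SNPs, an EA quantitative trait
(h2 = 0.5 in the youngest bin, per-bin environmental increment variance
0.05), a constant-h2 control trait, four disease-liability biomarkers, and a
liability-threshold disease (h2 = 0.3, five onset bins of 4% so the desk-
scale cohort yields workable case counts).
"""

from pathlib import Path

import agearch as a

RESULTS = Path(__file__).resolve().parents[1] / "results"
GENO_SEED = 101
COHORT_SEED = 202
N_INDIVIDUALS = 6000
N_SNPS = 500


def build_cohort():
    geno = a.simulate_genotypes(N_INDIVIDUALS, N_SNPS, seed=GENO_SEED)
    cfg = a.CohortConfig(
        traits=[
            a.TraitSpec("trait_ea", h2=0.5, ea_increment_var=0.05,
                        measurement_error_var=0.2),
            a.TraitSpec("trait_flat", h2=0.5, measurement_error_var=0.2),
        ]
        + [
            a.TraitSpec(f"marker_{i}", loads_on="dz", loading=l,
                        measurement_error_var=0.1)
            for i, l in enumerate((0.6, 0.5, 0.4, 0.3))
        ],
        diseases=[a.DiseaseSpec("dz", h2=0.3, bin_fraction=0.04)],
        visit_offsets=(0.0, 4.0, 9.0),
        medication_flags={"hypertension_med": 0.15},
    )
    table, states = a.simulate_cohort(geno, cfg, seed=COHORT_SEED)
    return geno, table, states, cfg
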