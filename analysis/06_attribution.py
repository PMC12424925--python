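"""Attribution: how much of the PRS accuracy decline do the models explain?

Reads the per-bin incident R2obs series of the noise-matched QRS and the PRS
(from 05) and the disease-liability h2 trend surrogate (the EA trait trend
from 02), fits age trends to each, and computes: the QRS-explained proportion
tau (threshold model + incident design), the combined EA + threshold-model
expected change, and the z-test for a residual difference between QRS and PRS
slopes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RESULTS  # noqa: E402

import agearch as a  # noqa: E402
from agearch.io import read_table, write_table  # noqa: E402


def rel_change(df, label):
    series = a.MetricSeries.from_frame(df[df["metric"] == "r2_obs"], "r2_obs", label)
    trend = a.fit_metric_trend(series, n_mc=1000, seed=61)
    return a.relative_10yr_change(trend, float(series.values.mean()))


def main():
    pred = read_table(RESULTS / "prediction_estimates.tsv", "estimates")
    h2_trends = read_table(RESULTS / "heritability_trends.tsv", "trends")

    dq, dq_se = rel_change(pred, "dz:qrs")
    dp, dp_se = rel_change(pred, "dz:prs")
    ea_row = h2_trends[h2_trends["label"] == "trait_ea"].iloc[0]
    dh, dh_se = float(ea_row["rel_change_10yr"]), float(ea_row["rel_change_se"])

    tau = a.tau_explained([dq], [dp])
    z, p = a.slope_difference_test(dq, dp, dq_se, dp_se)
    combined, combined_se = a.combined_expected_change(dq, dh, dq_se, dh_se, seed=62)

    print(f"10-year relative change: QRS {dq:+.1%} (se {dq_se:.1%}), "
          f"PRS {dp:+.1%} (se {dp_se:.1%})")
    print(f"threshold-model share tau = {tau:.2f}; "
          f"QRS-PRS slope difference z = {z:.2f} (p = {p:.3f})")
    print(f"EA h2 trend (surrogate for liability h2): {dh:+.1%} (se {dh_se:.1%})")
    print(f"combined EA + threshold expected decline: {combined:+.1%} "
          f"(se {combined_se:.1%}) vs observed PRS decline {-dp:+.1%}")

    out = pd.DataFrame([{"disease": "dz", "delta_qrs": dq, "delta_prs": dp,
                         "delta_h2": dh, "expected_combined": combined,
                         "z": z, "p": p, "tau": tau}])
    write_table(out, RESULTS / "attribution.tsv", "attribution")
    print(f"wrote {RESULTS}/attribution.tsv")


if __name__ == "__main__":
    main()
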