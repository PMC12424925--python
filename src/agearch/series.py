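"""Per-age-bin metric series — the interchange container between estimation and trend fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MetricSeries:
    """A metric (h2, R2_obs, logHR, ...) with a standard error at each age index.

    One entry per age bin; ``median_ages`` carry the age coordinate used in
    trend fits (median baseline age for heritability series, median onset age
    for prediction-accuracy series).
    """

    metric: str
    values: np.ndarray
    ses: np.ndarray
    median_ages: np.ndarray
    ns: np.ndarray = field(default=None)
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.median_ages = np.asarray(self.median_ages, dtype=float)
        if self.ns is None:
            self.ns = np.full(len(self.values), -1)
        self.ns = np.asarray(self.ns)
        if not (len(self.values) == len(self.ses) == len(self.median_ages) == len(self.ns)):
            raise ValueError("value/se/age/n lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.label,
                "bin": np.arange(1, len(self) + 1),
                "median_age": self.median_ages,
                "n": self.ns,
                "estimate": self.values,
                "se": self.ses,
                "metric": self.metric,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric: str | None = None, label: str | None = None) -> "MetricSeries":
        sub = df
        if metric is not None:
            sub = sub[sub["metric"] == metric]
        if label is not None:
            sub = sub[sub["trait"] == label]
        sub = sub.sort_values("bin")
        return cls(
            metric=metric if metric is not None else str(sub["metric"].iloc[0]),
            values=sub["estimate"].to_numpy(),
            ses=sub["se"].to_numpy(),
            median_ages=sub["median_age"].to_numpy(),
            ns=sub["n"].to_numpy(),
            label=label if label is not None else str(sub["trait"].iloc[0]),
        )
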