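"""Liability-threshold disease simulators: linear and exposure-accumulation (EA) variants.

Both simulators draw a latent liability L = G + E with genetic variance h2 and
environmental variance 1 - h2, then assign disease onset to successive age bins
by ranking liability: the top ``bin_fraction`` of individuals become the
youngest onset group, the next slice the second group, and so on.  The EA
variant adds an independent normal increment to every individual's liability
when moving to each older age bin, so environmental variance accumulates while
genetic variance stays fixed — the mechanism that drives heritability down
with age.

Onset is percentile-based (ranking), not a fixed numeric threshold, which
makes the construction invariant to proportional amplification of all variance
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySetError, ParameterError

__all__ = [
    "LiabilityState",
    "SimulatedDisease",
    "CaseControlSet",
    "simulate_linear_threshold",
    "simulate_ea_threshold",
    "sim_case_control_sets",
]


@dataclass
class LiabilityState:
    """Per-individual liability decomposition across age bins.

    ``liability_at_bin[:, k]`` equals ``G + E0 + ea_increments[:, :k+1].sum(1)``;
    the first increment column is identically zero (no accumulation has happened
    by the first bin).  ``onset_bin`` is 1-based; 0 means never diseased.
    """

    G: np.ndarray
    E0: np.ndarray
    ea_increments: np.ndarray
    liability_at_bin: np.ndarray
    onset_bin: np.ndarray

    @property
    def n(self) -> int:
        return len(self.G)

    @property
    def n_bins(self) -> int:
        return self.liability_at_bin.shape[1]


@dataclass
class SimulatedDisease:
    state: LiabilityState
    n_bins: int
    bin_fraction: float
    thresholds: np.ndarray  # liability cut at each bin (lowest case liability in that bin)

    @property
    def n(self) -> int:
        return self.state.n

    @property
    def cases_per_bin(self) -> int:
        return int(np.floor(self.bin_fraction * self.n))


@dataclass
class CaseControlSet:
    """A 1:1 down-sampled case/control design at one age bin.

    ``K`` is the prevalence of case status in the eligible population before
    down-sampling (used for the observed- to liability-scale R2 transform);
    ``P`` is the case proportion after down-sampling (0.5 by construction).
    """

    case_ids: np.ndarray
    control_ids: np.ndarray
    bin: int
    design: str  # "prevalent" | "incident"
    K: float
    interval: tuple | None = None
    baseline_age: float | None = None

    @property
    def P(self) -> float:
        return len(self.case_ids) / (len(self.case_ids) + len(self.control_ids))

    def ids(self) -> np.ndarray:
        return np.concatenate([self.case_ids, self.control_ids])

    def outcome(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.case_ids)), np.zeros(len(self.control_ids))]
        )


def _check_common(n: int, h2: float, n_bins: int, bin_fraction: float) -> None:
    if n < 2:
        raise ParameterError("need at least 2 individuals")
    if not 0.0 <= h2 <= 1.0:
        raise ParameterError(f"h2 must be in [0, 1], got {h2}")
    if bin_fraction <= 0:
        raise ParameterError(f"bin_fraction must be positive, got {bin_fraction}")
    if n_bins * bin_fraction >= 1:
        raise ParameterError("n_bins * bin_fraction must be < 1")
    if int(np.floor(bin_fraction * n)) < 1:
        raise ParameterError("bin_fraction * n < 1: no cases per bin")


def _ranked_order(liability: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing liability; ties broken by the permutation."""
    shuffled = np.argsort(-liability[perm], kind="stable")
    return perm[shuffled]


def threshold_onsets(
    G: np.ndarray,
    E0: np.ndarray,
    ea_increments: np.ndarray,
    bin_fraction: float,
    rng: np.random.Generator,
) -> tuple[LiabilityState, np.ndarray]:
    """Assign onset bins by repeatedly extracting the top slice of current liability.

    Shared engine behind both simulators and the genotype-based cohort
    generator.  ``ea_increments`` must be (n, n_bins) with a zero first column
    for the linear model.
    """
    n, n_bins = ea_increments.shape
    liability_at_bin = (G + E0)[:, None] + np.cumsum(ea_increments, axis=1)
    onset = np.zeros(n, dtype=int)
    cases_per_bin = int(np.floor(bin_fraction * n))
    thresholds = np.empty(n_bins)
    perm = rng.permutation(n)
    for k in range(n_bins):
        at_risk = onset == 0
        order = _ranked_order(np.where(at_risk, liability_at_bin[:, k], -np.inf), perm)
        new_cases = order[:cases_per_bin]
        onset[new_cases] = k + 1
        thresholds[k] = liability_at_bin[new_cases[-1], k]
    state = LiabilityState(
        G=G,
        E0=E0,
        ea_increments=ea_increments,
        liability_at_bin=liability_at_bin,
        onset_bin=onset,
    )
    return state, thresholds


def simulate_linear_threshold(
    n: int,
    h2: float = 0.3,
    n_bins: int = 5,
    bin_fraction: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> SimulatedDisease:
    """Linear liability-threshold model: fixed liability, rising threshold crossings.

    G ~ N(0, h2), E ~ N(0, 1-h2); liability L = G + E is constant over bins.
    The top ``bin_fraction`` of L becomes the youngest onset group, the next
    slice the second group, etc.  Defaults match a disease with five onset
    quintiles of 2% prevalence each.
    """
    _check_common(n, h2, n_bins, bin_fraction)
    rng = np.random.default_rng(seed)
    G = rng.normal(0.0, np.sqrt(h2), n)
    E0 = rng.normal(0.0, np.sqrt(1.0 - h2), n)
    increments = np.zeros((n, n_bins))
    state, thresholds = threshold_onsets(G, E0, increments, bin_fraction, rng)
    return SimulatedDisease(state=state, n_bins=n_bins, bin_fraction=bin_fraction, thresholds=thresholds)


def simulate_ea_threshold(
    n: int,
    h2: float = 0.3,
    n_bins: int = 5,
    bin_fraction: float = 0.02,
    increment_var: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> SimulatedDisease:
    """EA liability-threshold model: liability gains a N(0, increment_var) draw per bin.

    Initial liability is drawn exactly as in the linear model (same seed stream,
    so ``increment_var=0`` reproduces it).  Moving to each older age bin, every
    individual receives an independent cumulative increment; each bin's cases
    are the top ``bin_fraction`` of current liability among the not-yet-diseased,
    keeping case counts equal to the linear simulator's.  With the default
    0.05 per-bin variance, accumulated increment variance reaches 20% of the
    initial liability variance by the fifth bin.
    """
    _check_common(n, h2, n_bins, bin_fraction)
    if increment_var < 0:
        raise ParameterError("increment_var must be >= 0")
    rng = np.random.default_rng(seed)
    G = rng.normal(0.0, np.sqrt(h2), n)
    E0 = rng.normal(0.0, np.sqrt(1.0 - h2), n)
    increments = np.zeros((n, n_bins))
    if n_bins > 1:
        increments[:, 1:] = rng.normal(0.0, np.sqrt(increment_var), (n, n_bins - 1))
    state, thresholds = threshold_onsets(G, E0, increments, bin_fraction, rng)
    return SimulatedDisease(state=state, n_bins=n_bins, bin_fraction=bin_fraction, thresholds=thresholds)


def sim_case_control_sets(
    sim: SimulatedDisease,
    design: str,
    bin: int,
    seed: int | np.random.Generator = 0,
) -> CaseControlSet:
    """Construct a 1:1 case/control set at one age bin of a simulated disease.

    prevalent: cases have onset at or before ``bin``; the control pool is
    everyone not yet diseased at the end of ``bin``.  incident: cases have
    onset exactly at ``bin``; the control pool is everyone never diseased by
    the end of ``bin`` (incident cases themselves are excluded).  Controls are
    down-sampled uniformly at random to a 1:1 ratio.
    """
    if design not in ("prevalent", "incident"):
        raise ParameterError(f"unknown design {design!r}")
    if not 1 <= bin <= sim.n_bins:
        raise ParameterError(f"bin must be in 1..{sim.n_bins}")
    onset = sim.state.onset_bin
    if design == "prevalent":
        cases = np.flatnonzero((onset >= 1) & (onset <= bin))
    else:
        cases = np.flatnonzero(onset == bin)
    pool = np.flatnonzero((onset == 0) | (onset > bin))
    if len(cases) == 0:
        raise EmptySetError(f"no {design} cases in bin {bin}")
    if len(pool) < len(cases):
        raise EmptySetError(f"control pool smaller than case set in bin {bin}")
    K = len(cases) / (len(cases) + len(pool))
    rng = np.random.default_rng(seed)
    controls = rng.choice(pool, size=len(cases), replace=False)
    return CaseControlSet(
        case_ids=cases, control_ids=controls, bin=bin, design=design, K=K
    )
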