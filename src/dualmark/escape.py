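"""Counter-selection escape-frequency estimation from plating experiments.

An escape plating spreads a known number of marker-bearing cells on
counter-selective agar and counts surviving colonies; the escape frequency is
the colony fraction.  Frequencies span ~1e-2 down to ~1e-11 with 0–1 colonies
on the best strains, so the single-plating interval is the exact
(Clopper–Pearson) binomial interval rather than a normal approximation.
Replicated platings are summarised as mean ± SEM over per-replicate
frequencies.  Two agents acting through independent mechanisms should multiply:
the predicted joint escape frequency is the product of the single-agent
frequencies, and the observed/predicted ratio quantifies deviation from
mechanistic independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlatingExperiment",
    "EscapeEstimate",
    "escape_frequency",
    "pooled_escape_frequency",
    "fold_reduction",
    "predicted_joint_escape",
    "clopper_pearson",
    "round_sig",
    "read_platings",
]


@dataclass(frozen=True)
class PlatingExperiment:
    """One plating: cells plated, colonies counted, agent combination."""

    cells_plated: int
    colonies: int
    agents: frozenset = frozenset()
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.cells_plated <= 0:
            raise ValueError("cells_plated must be positive")
        if not 0 <= self.colonies <= self.cells_plated:
            raise ValueError("colonies must lie in [0, cells_plated]")
        object.__setattr__(self, "agents", frozenset(self.agents))


@dataclass(frozen=True)
class EscapeEstimate:
    """Escape frequency with a 95% interval.

    Single-plating estimates carry an exact binomial interval and ``sem=None``;
    replicate-mode estimates carry mean ± SEM (``sem=None`` with one replicate,
    where the spread is undefined and the interval falls back to the exact
    interval on the single plating).
    """

    frequency: float
    ci_low: float
    ci_high: float
    n_replicates: int = 1
    sem: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.frequency <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


def clopper_pearson(k, n, alpha: float = 0.05):
    """Exact binomial 95% interval from beta quantiles (vectorized)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    low = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    high = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return low, high


def escape_frequency(exp: PlatingExperiment) -> EscapeEstimate:
    """Point estimate colonies / cells_plated with an exact 95% interval.

    Zero colonies give point 0 with the exact upper bound (~3.69/N at 95%).
    """
    low, high = clopper_pearson(exp.colonies, exp.cells_plated)
    return EscapeEstimate(
        frequency=exp.colonies / exp.cells_plated,
        ci_low=float(low),
        ci_high=float(high),
        n_replicates=1,
        sem=None,
    )


def pooled_escape_frequency(exps: list[PlatingExperiment]) -> EscapeEstimate:
    """Mean ± SEM over per-replicate frequencies (same agent set required).

    With a single replicate the SEM is undefined (``sem=None``) and the
    interval is the exact binomial interval of that plating.
    """
    if not exps:
        raise ValueError("need at least one plating")
    agent_sets = {e.agents for e in exps}
    if len(agent_sets) > 1:
        raise ValueError(f"mixed agent sets in replicates: {agent_sets}")
    if len(exps) == 1:
        return escape_frequency(exps[0])
    freqs = np.array([e.colonies / e.cells_plated for e in exps])
    mean = float(freqs.mean())
    sem = float(freqs.std(ddof=1) / math.sqrt(len(freqs)))
    return EscapeEstimate(
        frequency=mean,
        ci_low=max(0.0, mean - 1.96 * sem),
        ci_high=min(1.0, mean + 1.96 * sem),
        n_replicates=len(exps),
        sem=sem,
    )


def fold_reduction(
    baseline: EscapeEstimate,
    improved: EscapeEstimate,
    return_interval: bool = False,
):
    """Ratio baseline/improved of escape frequencies.

    If the improved estimate is exactly zero the ratio is reported against its
    exact-interval upper bound, i.e. a lower bound on the true fold reduction.
    With ``return_interval=True`` and SEMs available on both estimates, a 95%
    interval by the delta method on log frequencies is returned as well.
    """
    if baseline.frequency == 0:
        raise ValueError("baseline escape frequency is zero; fold reduction undefined")
    denom = improved.frequency if improved.frequency > 0 else improved.ci_high
    ratio = baseline.frequency / denom
    if not return_interval:
        return ratio
    if baseline.sem is None or improved.sem is None or improved.frequency == 0:
        return ratio, (float("nan"), float("nan"))
    var_log = (baseline.sem / baseline.frequency) ** 2 + (
        improved.sem / improved.frequency
    ) ** 2
    half = 1.96 * math.sqrt(var_log)
    return ratio, (ratio * math.exp(-half), ratio * math.exp(half))


def predicted_joint_escape(p1: float, p2: float, observed: float | None = None):
    """Joint escape frequency under mechanistic independence: p1 * p2.

    If an observed joint estimate is supplied, also returns the
    observed/predicted deviation factor.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    predicted = p1 * p2
    if observed is None:
        return predicted
    deviation = observed / predicted if predicted > 0 else float("inf")
    return predicted, deviation


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures for reporting (e.g. 4.3E-11, 8.5E-7)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def read_platings(path) -> pd.DataFrame:
    """Read a platings TSV: strain, agents (comma-joined), cells_plated,
    colonies, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "agents", "cells_plated", "colonies", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"platings TSV needs columns {sorted(required)}")
    return df


def platings_from_frame(df: pd.DataFrame) -> list[PlatingExperiment]:
    return [
        PlatingExperiment(
            cells_plated=int(row.cells_plated),
            colonies=int(row.colonies),
            agents=frozenset(str(row.agents).split(",")),
            replicate_id=str(row.replicate),
        )
        for row in df.itertuples()
    ]
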