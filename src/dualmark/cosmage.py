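"""Multi-cycle CoS-MAGE allele-conversion simulation.

Co-Selection MAGE (CoS-MAGE) pairs a pool of unselectable oligo-encoded edits
with repair of a selectable marker, so that selection after each recombineering
cycle enriches for clones that co-converted nearby target loci.  This module
models the accumulation of allele conversions across repeated cycles: a
population of lineages, each a binary genotype over ``L`` target loci, receives
one conversion "pattern" per cycle drawn from a per-cycle conversion
distribution, and converted loci never revert.

The per-cycle distribution can be empirical (resampled from a genotyped
single-cycle population, either as full patterns or as conversion counts placed
uniformly across loci) or parametric, a zero-inflated binomial (ZIB) calibrated
by moment matching to a printed (mean edits/clone, fraction unmodified) summary.
Inoculum bottlenecks are modelled as uniform subsampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConversionModel",
    "PopulationState",
    "TrajectorySummary",
    "InfeasibleCalibrationError",
    "fit_conversion_model",
    "empirical_distribution",
    "simulate_cycle",
    "simulate_trajectory",
    "apply_bottleneck",
    "summarize_population",
    "read_genotype_matrix",
    "write_genotype_matrix",
]

EMPIRICAL_PATTERN = "empirical_pattern"
EMPIRICAL_COUNT = "empirical_count"
PARAMETRIC_ZIB = "parametric_zib"


class InfeasibleCalibrationError(ValueError):
    """Raised when a (mean, unmodified-fraction) pair is not attainable by a
    zero-inflated binomial on L trials."""


@dataclass(frozen=True)
class ConversionModel:
    """Per-cycle distribution over allele-conversion patterns or counts.

    Parameters
    ----------
    mode : {"empirical_pattern", "empirical_count", "parametric_zib"}
        How one cycle's conversions are drawn for each lineage.
    L : int
        Number of target loci.
    patterns : (m, L) bool array, optional
        Distinct conversion patterns (``empirical_pattern`` mode).
    weights : (m,) float array, optional
        Pattern probabilities; must sum to 1.
    count_weights : (L + 1,) float array, optional
        Probability of converting exactly k loci (``empirical_count`` mode).
    pi : float, optional
        Zero-inflation mass (``parametric_zib`` mode).
    p : float, optional
        Per-locus conversion probability given the non-inflated component.
    """

    mode: str
    L: int
    patterns: np.ndarray | None = None
    weights: np.ndarray | None = None
    count_weights: np.ndarray | None = None
    pi: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mode == EMPIRICAL_PATTERN:
            if self.patterns is None or self.weights is None:
                raise ValueError("empirical_pattern mode requires patterns and weights")
            if self.patterns.shape[1] != self.L:
                raise ValueError("pattern width does not match L")
            if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
                raise ValueError("pattern weights must sum to 1")
        elif self.mode == EMPIRICAL_COUNT:
            if self.count_weights is None:
                raise ValueError("empirical_count mode requires count_weights")
            if len(self.count_weights) != self.L + 1:
                raise ValueError("count_weights must have length L + 1")
            if abs(float(np.sum(self.count_weights)) - 1.0) > 1e-9:
                raise ValueError("count weights must sum to 1")
        elif self.mode == PARAMETRIC_ZIB:
            if self.pi is None or self.p is None:
                raise ValueError("parametric_zib mode requires pi and p")
            if not (0.0 <= self.pi <= 1.0 and 0.0 <= self.p <= 1.0):
                raise ValueError("pi and p must lie in [0, 1]")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def mean_conversions(self) -> float:
        """Expected conversions per lineage per cycle."""
        if self.mode == EMPIRICAL_PATTERN:
            return float(self.patterns.sum(axis=1) @ self.weights)
        if self.mode == EMPIRICAL_COUNT:
            return float(np.arange(self.L + 1) @ self.count_weights)
        return (1.0 - self.pi) * self.L * self.p

    def draw_counts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n per-cycle conversion counts (count-based modes only)."""
        if self.mode == EMPIRICAL_COUNT:
            return rng.choice(self.L + 1, size=n, p=self.count_weights)
        if self.mode == PARAMETRIC_ZIB:
            counts = rng.binomial(self.L, self.p, size=n)
            counts[rng.random(n) < self.pi] = 0
            return counts
        raise ValueError("draw_counts is undefined for empirical_pattern mode")


@dataclass
class PopulationState:
    """A population of lineages: (n, L) boolean genotype matrix plus cycle index."""

    members: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.ndim != 2 or self.members.shape[0] < 1:
            raise ValueError("population must be a non-empty (n, L) matrix")

    @property
    def size(self) -> int:
        return self.members.shape[0]

    @property
    def L(self) -> int:
        return self.members.shape[1]


@dataclass
class TrajectorySummary:
    """Per-cycle summaries of a simulated trajectory."""

    per_cycle: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.per_cycle:
            row = {k: v for k, v in rec.items() if k != "count_histogram"}
            for k, c in enumerate(rec["count_histogram"]):
                row[f"n_{k}_conversions"] = c
            rows.append(row)
        return pd.DataFrame(rows)


def _zib_p0(pi: float, p: float, L: int) -> float:
    return pi + (1.0 - pi) * (1.0 - p) ** L


def fit_conversion_model(
    mean_conversions: float, unmodified_fraction: float, L: int
) -> ConversionModel:
    """Calibrate a zero-inflated binomial to a single-cycle summary.

    Solves for ``(pi, p)`` such that ``(1 - pi) * L * p = mean_conversions`` and
    ``pi + (1 - pi) * (1 - p)^L = unmodified_fraction``, by bisection on ``pi``
    (``p`` is eliminated through the mean constraint).

    Raises
    ------
    InfeasibleCalibrationError
        If no ZIB on ``L`` trials attains the pair.  Feasibility requires
        ``(1 - m/L)^L <= P0 <= 1 - m/L``: the lower limit is a plain binomial
        (no inflation), the upper limit puts all conversions in an all-or-none
        component (p = 1).
    """
    m, p0 = float(mean_conversions), float(unmodified_fraction)
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("unmodified_fraction must lie in [0, 1]")
    if m < 0 or m > L:
        raise InfeasibleCalibrationError(
            f"mean_conversions must lie in [0, L={L}]; got {m}"
        )
    if m == 0.0:
        if p0 != 1.0:
            raise InfeasibleCalibrationError(
                "zero mean conversions forces unmodified_fraction = 1"
            )
        return ConversionModel(mode=PARAMETRIC_ZIB, L=L, pi=1.0, p=0.0)

    lo_limit = (1.0 - m / L) ** L  # pi = 0 (plain binomial)
    hi_limit = 1.0 - m / L  # pi maximal, p = 1
    if p0 < lo_limit - 1e-12:
        raise InfeasibleCalibrationError(
            f"unmodified_fraction {p0} below the plain-binomial limit "
            f"(1 - mean/L)^L = {lo_limit:.6g}"
        )
    if p0 > hi_limit + 1e-12:
        raise InfeasibleCalibrationError(
            f"unmodified_fraction {p0} above the all-or-none limit "
            f"1 - mean/L = {hi_limit:.6g}"
        )

    def residual(pi: float) -> float:
        p = m / ((1.0 - pi) * L)
        return _zib_p0(pi, p, L) - p0

    lo, hi = 0.0, hi_limit
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    pi = 0.5 * (lo + hi)
    p = min(1.0, m / ((1.0 - pi) * L))
    if abs(_zib_p0(pi, p, L) - p0) > 1e-8:
        raise InfeasibleCalibrationError(
            f"bisection failed to reach residual < 1e-8 for ({m}, {p0}, {L})"
        )
    return ConversionModel(mode=PARAMETRIC_ZIB, L=L, pi=pi, p=p)


def empirical_distribution(
    genotypes: pd.DataFrame | np.ndarray, mode: str = EMPIRICAL_PATTERN
) -> ConversionModel:
    """Build an empirical per-cycle model from a genotyped single-cycle population.

    Each row of ``genotypes`` is one clone's binary conversion state over the L
    target loci (e.g. mascPCR calls).  ``mode="empirical_pattern"`` weights each
    distinct pattern by its relative frequency; ``mode="empirical_count"`` keeps
    only the conversion-count distribution (no positional structure).
    """
    mat = np.asarray(genotypes, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("genotype matrix must be non-empty and rectangular")
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError("genotype matrix cells must be 0/1")
    mat = mat.astype(bool)
    L = mat.shape[1]
    if mode == EMPIRICAL_PATTERN:
        patterns, counts = np.unique(mat, axis=0, return_counts=True)
        return ConversionModel(
            mode=EMPIRICAL_PATTERN,
            L=L,
            patterns=patterns,
            weights=counts / counts.sum(),
        )
    if mode == EMPIRICAL_COUNT:
        k = mat.sum(axis=1)
        hist = np.bincount(k, minlength=L + 1).astype(float)
        return ConversionModel(
            mode=EMPIRICAL_COUNT, L=L, count_weights=hist / hist.sum()
        )
    raise ValueError(f"unknown empirical mode {mode!r}")


def _draw_patterns(
    model: ConversionModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """One cycle's conversion patterns for n lineages, as an (n, L) bool matrix."""
    if model.mode == EMPIRICAL_PATTERN:
        idx = rng.choice(len(model.weights), size=n, p=model.weights)
        return model.patterns[idx]
    counts = model.draw_counts(n, rng)
    # k random loci per lineage: rank a uniform draw per row, keep the k smallest
    ranks = rng.random((n, model.L)).argsort(axis=1).argsort(axis=1)
    return ranks < counts[:, None]


def _cycle(pop: PopulationState, model: ConversionModel, rng: np.random.Generator) -> PopulationState:
    if model.L != pop.L:
        raise ValueError("model locus count does not match population")
    new = pop.members | _draw_patterns(model, pop.size, rng)
    return PopulationState(members=new, cycle_index=pop.cycle_index + 1)


def simulate_cycle(pop: PopulationState, model: ConversionModel, seed: int) -> PopulationState:
    """Apply one CoS-MAGE cycle: OR one drawn pattern onto each lineage.

    Conversions are monotone — a converted locus never reverts.
    """
    return _cycle(pop, model, np.random.default_rng(seed))


def summarize_population(pop: PopulationState) -> dict:
    """Summary record: mean conversions, count histogram, fully-converted and
    unmodified fractions."""
    counts = pop.members.sum(axis=1)
    hist = np.bincount(counts, minlength=pop.L + 1)
    n = pop.size
    return {
        "cycle": pop.cycle_index,
        "mean_conversions": float(counts.mean()),
        "count_histogram": hist.tolist(),
        "fully_converted_fraction": float(hist[pop.L] / n),
        "unmodified_fraction": float(hist[0] / n),
    }


def simulate_trajectory(
    n_lineages: int, n_cycles: int, model: ConversionModel, seed: int
) -> TrajectorySummary:
    """Simulate ``n_cycles`` cycles for ``n_lineages`` initially unmodified
    lineages and record per-cycle summaries (cycle 0 = starting state)."""
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    rng = np.random.default_rng(seed)
    pop = PopulationState(np.zeros((n_lineages, model.L), dtype=bool), cycle_index=0)
    summary = TrajectorySummary(per_cycle=[summarize_population(pop)])
    for _ in range(n_cycles):
        pop = _cycle(pop, model, rng)
        summary.per_cycle.append(summarize_population(pop))
    return summary


def apply_bottleneck(pop: PopulationState, size: int, seed: int) -> PopulationState:
    """Inoculum bottleneck: uniform subsample without replacement.

    Counter-selection inocula in cycling experiments are small relative to the
    culture, and small bottlenecks collapse genotype diversity by sampling.
    If ``size >= |pop|`` the population is returned unchanged.
    """
    if size < 1:
        raise ValueError("bottleneck size must be >= 1")
    if size >= pop.size:
        return pop
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.size, size=size, replace=False)
    return PopulationState(members=pop.members[idx], cycle_index=pop.cycle_index)


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a clones × loci 0/1 conversion matrix from TSV (header = locus names)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError("genotype matrix must be non-empty")
    if not df.isin((0, 1)).all().all():
        raise ValueError("genotype matrix cells must be 0/1")
    return df.astype(int)


def write_genotype_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
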