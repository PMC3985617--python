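"""Growth-curve selection statistics for liquid selections.

Liquid selections and counter-selections are scored kinetically: a culture's
time to reach an OD600 threshold (default 0.4) measures how much of its
inoculum was able to grow.  Three statistics are built on that threshold time:

* **NSA** (Normalized Selective Advantage), ``1 - [t_RS * (t_CNS / t_RNS)] / t_CS``,
  comparing recombinant (R) and control (C) cultures in selective (S) and
  nonselective (NS) media.  NSA -> 1 when controls never grow under selection
  (perfect selection); NSA -> 0 when recombinants and controls grow alike
  (complete escape).  The nonselective ratio normalizes away inoculum
  disparities.
* **Normalized Culture Time** (NCT), a causality score for a candidate escape
  mutation: the mutant culture's selective threshold time placed on the affine
  scale between a positive control (marker knockout, NCT ~ 0) and a mock
  recombination (NCT ~ 1).
* **Growth delay**, the threshold-time difference between a selective and a
  nonselective culture of the same strain, optionally expressed in doublings.

Cultures that never reach the threshold within the observation window are
*censored at the horizon*; censored times propagate a flag and make NSA a
conservative lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "ThresholdTime",
    "SelectionQuartet",
    "NSAResult",
    "CultureTimeResult",
    "GrowthDelayResult",
    "time_to_threshold",
    "nsa",
    "normalized_culture_time",
    "growth_delay",
    "read_quartet_csv",
]

DEFAULT_THRESHOLD = 0.4

QUARTET_CONDITIONS = ("RS", "CS", "RNS", "CNS")


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series (times strictly increasing, in minutes)."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("growth curve needs at least 2 samples")
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")

    def smoothed(self, window: int = 3) -> "GrowthCurve":
        """Moving-median spike removal (optional; off by default everywhere)."""
        od = pd.Series(self.od).rolling(window, center=True, min_periods=1).median()
        return GrowthCurve(self.times, od.to_numpy(), self.label)


@dataclass(frozen=True)
class ThresholdTime:
    """Minutes to first reach the OD threshold; censored => never reached
    within the observation window (time is then the last sample time)."""

    time: float
    censored: bool = False


@dataclass(frozen=True)
class SelectionQuartet:
    """The four threshold times feeding NSA (minutes), with censor flags."""

    t_rs: float
    t_cs: float
    t_rns: float
    t_cns: float
    horizon: float
    rs_censored: bool = False
    cs_censored: bool = False
    rns_censored: bool = False
    cns_censored: bool = False

    def __post_init__(self) -> None:
        for name in ("t_rs", "t_cs", "t_rns", "t_cns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_curves(
        cls,
        rs: GrowthCurve,
        cs: GrowthCurve,
        rns: GrowthCurve,
        cns: GrowthCurve,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "SelectionQuartet":
        tt = {
            "rs": time_to_threshold(rs, threshold),
            "cs": time_to_threshold(cs, threshold),
            "rns": time_to_threshold(rns, threshold),
            "cns": time_to_threshold(cns, threshold),
        }
        horizon = max(c.times[-1] for c in (rs, cs, rns, cns))
        return cls(
            t_rs=tt["rs"].time,
            t_cs=tt["cs"].time,
            t_rns=tt["rns"].time,
            t_cns=tt["cns"].time,
            horizon=horizon,
            rs_censored=tt["rs"].censored,
            cs_censored=tt["cs"].censored,
            rns_censored=tt["rns"].censored,
            cns_censored=tt["cns"].censored,
        )


@dataclass(frozen=True)
class NSAResult:
    nsa: float
    censored: bool


@dataclass(frozen=True)
class CultureTimeResult:
    nct: float
    t_oligo: float
    t_mock: float
    t_positive: float

    #: NCT below this is scored causal; [0.6, 1.0) is borderline.
    CAUSAL_THRESHOLD = 0.6

    @property
    def call(self) -> str:
        if self.nct < self.CAUSAL_THRESHOLD:
            return "causal"
        if self.nct < 1.0:
            return "borderline"
        return "unrelated"


@dataclass(frozen=True)
class GrowthDelayResult:
    delay_min: float | None
    no_growth: bool
    doublings: float | None = None


def time_to_threshold(
    curve: GrowthCurve, threshold: float = DEFAULT_THRESHOLD
) -> ThresholdTime:
    """Minimum time where OD600 >= threshold, linearly interpolated.

    If the first sample is already at/above the threshold its time is
    returned; if the curve never reaches it the result is censored at the
    last sample time.
    """
    od, t = curve.od, curve.times
    above = od >= threshold
    if not above.any():
        return ThresholdTime(time=float(t[-1]), censored=True)
    i = int(np.argmax(above))
    if i == 0:
        return ThresholdTime(time=float(t[0]), censored=False)
    # linear interpolation between the bracketing samples
    t0, t1, y0, y1 = t[i - 1], t[i], od[i - 1], od[i]
    frac = (threshold - y0) / (y1 - y0)
    return ThresholdTime(time=float(t0 + frac * (t1 - t0)), censored=False)


def nsa(q: SelectionQuartet) -> NSAResult:
    """Normalized Selective Advantage of a selection quartet.

    ``NSA = 1 - [t_RS * (t_CNS / t_RNS)] / t_CS``.  Any censored input sets the
    ``censored`` flag; in particular a censored t_CS (controls never grew) makes
    the value a lower bound evaluated at the horizon.
    """
    if q.rns_censored or q.cns_censored:
        raise ValueError(
            "nonselective cultures did not grow; NSA is uninterpretable"
        )
    value = 1.0 - (q.t_rs * q.t_cns / q.t_rns) / q.t_cs
    censored = q.rs_censored or q.cs_censored
    return NSAResult(nsa=float(value), censored=censored)


def normalized_culture_time(
    t_oligo: float, t_mock: float, t_positive: float
) -> CultureTimeResult:
    """Causality score for a candidate escape-mutation oligo.

    ``NCT = (t_oligo - t_positive) / (t_mock - t_positive)`` — 0 when the oligo
    culture grows like the knockout positive control (escape mutation), 1 when
    it grows like the mock recombination (unrelated).  Values slightly outside
    [0, 1] occur and are kept.
    """
    if t_mock == t_positive:
        raise ValueError("degenerate controls: t_mock equals t_positive")
    value = (t_oligo - t_positive) / (t_mock - t_positive)
    return CultureTimeResult(
        nct=float(value), t_oligo=t_oligo, t_mock=t_mock, t_positive=t_positive
    )


def growth_delay(
    selective: GrowthCurve,
    nonselective: GrowthCurve,
    threshold: float = DEFAULT_THRESHOLD,
    doubling_time: float | None = None,
) -> GrowthDelayResult:
    """Threshold-time delay of a selective culture relative to its
    nonselective control; "no growth" if the selective culture never reaches
    the threshold within its window."""
    t_non = time_to_threshold(nonselective, threshold)
    if t_non.censored:
        raise ValueError("nonselective control never reached the threshold")
    t_sel = time_to_threshold(selective, threshold)
    if t_sel.censored:
        return GrowthDelayResult(delay_min=None, no_growth=True)
    delay = t_sel.time - t_non.time
    doublings = delay / doubling_time if doubling_time else None
    return GrowthDelayResult(delay_min=float(delay), no_growth=False, doublings=doublings)


def read_quartet_csv(path, threshold: float = DEFAULT_THRESHOLD) -> SelectionQuartet:
    """Read a quartet from CSV with columns time_min, od600, label, condition
    (condition in RS/CS/RNS/CNS)."""
    df = pd.read_csv(path)
    required = {"time_min", "od600", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"quartet CSV needs columns {sorted(required)}")
    curves = {}
    for cond, grp in df.groupby("condition"):
        grp = grp.sort_values("time_min")
        label = str(grp["label"].iloc[0]) if "label" in grp else cond
        curves[cond] = GrowthCurve(
            grp["time_min"].to_numpy(), grp["od600"].to_numpy(), label=label
        )
    missing = set(QUARTET_CONDITIONS) - curves.keys()
    if missing:
        raise ValueError(f"quartet CSV missing conditions: {sorted(missing)}")
    return SelectionQuartet.from_curves(
        curves["RS"], curves["CS"], curves["RNS"], curves["CNS"], threshold
    )
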