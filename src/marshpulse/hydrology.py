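"""Flooding state and subsidy classification from paired water-level series.

The subsidy attribution rests on comparing an *inflow* marsh (receiving the
managed river pulse) against a hydrologically separated *reference* marsh
whose flooding is driven only by tides and weather. A drop sample taken in
the inflow area is *subsidized* when its flooding cannot be explained by the
reference hydrology:

  condition 1 — the reference marsh was not flooded at the sample time, or
  condition 2 — the reference marsh was flooded, but the inflow area's daily
      mean water depth exceeded the maximum daily mean flood depth observed
      in the reference area over the whole pulse window.

Flooding is strict (depth > 0); a stage exactly at marsh elevation is dry.
Pulse windows are half-open ``[start, end)`` and calendar days follow the
(naive) timestamps of the series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WaterLevelSeries",
    "PulseWindow",
    "SubsidyClassification",
    "depth_at",
    "flooded_fraction",
    "reference_max_mean_depth",
    "inflow_daily_mean_depth",
    "classify_sample",
    "classify_samples",
]

#: Averaging convention for the reference area's daily flood depth
#: ("flooded_only" mirrors the phrase "mean depth of flooding").
RefDayMean = Literal["flooded_only", "all_floored"]
#: Averaging convention for the inflow area's daily mean water level.
InflowDayMean = Literal["all_floored", "flooded_only"]


@dataclass(frozen=True)
class WaterLevelSeries:
    """Hourly stage for one area, with its marsh elevation on the same datum.

    Parameters
    ----------
    area_id:
        Label such as ``"inflow"`` or ``"reference"``.
    marsh_elevation:
        Marsh surface elevation (mm) on the common vertical datum.
    times:
        Strictly increasing hourly timestamps (naive local time).
    stage:
        Water surface elevation (mm) on the same datum, one value per hour.
    """

    area_id: str
    marsh_elevation: float
    times: pd.DatetimeIndex = field(repr=False)
    stage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        stage = np.asarray(self.stage, dtype=float)
        if len(times) != len(stage):
            raise ValueError("times and stage must have equal length")
        if len(times) < 2:
            raise ValueError("a water-level series needs at least two readings")
        deltas = np.diff(times.asi8)
        if not np.all(deltas == 3_600_000_000_000):
            raise ValueError(f"{self.area_id}: timestamps must be strictly "
                             "increasing with hourly spacing")
        if not np.all(np.isfinite(stage)):
            raise ValueError(f"{self.area_id}: stage contains non-finite values")
        if not np.isfinite(self.marsh_elevation):
            raise ValueError("marsh_elevation must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stage", stage)

    @property
    def depth(self) -> np.ndarray:
        """Signed depth above the marsh surface (mm); > 0 means flooded."""
        return self.stage - self.marsh_elevation

    def window_mask(self, window: "PulseWindow") -> np.ndarray:
        return (self.times >= window.start) & (self.times < window.end)

    def shifted(self, dz_mm: float) -> "WaterLevelSeries":
        """Return a copy with the stage raised uniformly by ``dz_mm``."""
        return WaterLevelSeries(self.area_id, self.marsh_elevation,
                                self.times, self.stage + dz_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "area": self.area_id,
                             "stage_mm": self.stage})


@dataclass(frozen=True)
class PulseWindow:
    """A half-open calendar interval ``[start, end)`` covering one pulse."""

    pulse_id: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError(f"pulse {self.pulse_id}: start must precede end")

    def contains(self, t: pd.Timestamp) -> bool:
        return self.start <= pd.Timestamp(t) < self.end


@dataclass(frozen=True)
class SubsidyClassification:
    """Outcome of the two-condition rule for one inflow sample."""

    sample_id: str
    subsidized: bool
    condition: Optional[int]  # 1, 2 or None
    inflow_daily_mean_depth: float
    reference_flooded_at_sample: bool
    reference_max_mean_depth: Optional[float]

    def __post_init__(self) -> None:
        if self.subsidized != (self.condition in (1, 2)):
            raise ValueError("subsidized flag inconsistent with condition")
        if self.condition == 2 and not self.reference_flooded_at_sample:
            raise ValueError("condition 2 requires the reference to be flooded")


def depth_at(series: WaterLevelSeries, t) -> float:
    """Signed depth (mm) at the reading nearest to ``t``; ties go earlier.

    ``t`` must fall within the series span extended by one hour on each side.
    """
    t = pd.Timestamp(t)
    lo, hi = series.times[0], series.times[-1]
    if not (lo - pd.Timedelta(hours=1) <= t <= hi + pd.Timedelta(hours=1)):
        raise ValueError(
            f"{series.area_id}: {t} outside series span [{lo}, {hi}] ± 1 h")
    pos = int(np.searchsorted(series.times.asi8, t.value))
    if pos == 0:
        idx = 0
    elif pos == len(series.times):
        idx = pos - 1
    else:
        before = t.value - series.times.asi8[pos - 1]
        after = series.times.asi8[pos] - t.value
        idx = pos - 1 if before <= after else pos  # tie -> earlier reading
    return float(series.depth[idx])


def flooded_fraction(series: WaterLevelSeries, window: PulseWindow) -> float:
    """Percent of hourly readings in ``[start, end)`` with depth > 0."""
    mask = series.window_mask(window)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"window {window.pulse_id} contains no readings of "
                         f"series {series.area_id}")
    return 100.0 * int(np.count_nonzero(series.depth[mask] > 0)) / n


def reference_max_mean_depth(
    ref: WaterLevelSeries,
    window: PulseWindow,
    convention: RefDayMean = "flooded_only",
) -> Optional[float]:
    """Maximum over calendar days of the daily mean flood depth (mm).

    Under the default convention each day's mean is taken over flooded
    readings only; days without a flooded reading do not contribute. Returns
    ``None`` when the reference never floods inside the window.
    """
    mask = ref.window_mask(window)
    if not mask.any():
        raise ValueError(f"window {window.pulse_id} outside series span")
    depth = ref.depth[mask]
    days = ref.times[mask].normalize()
    best: Optional[float] = None
    for _, d in pd.Series(depth, index=days).groupby(level=0):
        vals = d.values
        if convention == "flooded_only":
            vals = vals[vals > 0]
            if vals.size == 0:
                continue
            day_mean = float(vals.mean())
        else:
            if not (vals > 0).any():
                continue
            day_mean = float(np.clip(vals, 0.0, None).mean())
        if best is None or day_mean > best:
            best = day_mean
    return best


def inflow_daily_mean_depth(
    inflow: WaterLevelSeries,
    t,
    convention: InflowDayMean = "all_floored",
) -> float:
    """Mean depth (mm) over all readings of the calendar day containing ``t``.

    Dry readings count as zero depth (default convention); with
    ``"flooded_only"`` only flooded readings enter the mean (0 if none).
    """
    day = pd.Timestamp(t).normalize()
    mask = (inflow.times >= day) & (inflow.times < day + pd.Timedelta(days=1))
    if not mask.any():
        raise ValueError(f"no readings on {day.date()} in {inflow.area_id}")
    depth = inflow.depth[mask]
    if convention == "flooded_only":
        flooded = depth[depth > 0]
        return float(flooded.mean()) if flooded.size else 0.0
    return float(np.clip(depth, 0.0, None).mean())


def classify_sample(
    sample_id: str,
    sample_time,
    inflow: WaterLevelSeries,
    ref: WaterLevelSeries,
    window: PulseWindow,
    *,
    ref_day_mean: RefDayMean = "flooded_only",
    inflow_day_mean: InflowDayMean = "all_floored",
) -> SubsidyClassification:
    """Apply the two-condition subsidy rule to one inflow sample."""
    t = pd.Timestamp(sample_time)
    if not window.contains(t):
        raise ValueError(f"sample {sample_id} at {t} outside pulse window "
                         f"{window.pulse_id}")
    ref_depth = depth_at(ref, t)
    daily_mean = inflow_daily_mean_depth(inflow, t, convention=inflow_day_mean)
    ref_max = reference_max_mean_depth(ref, window, convention=ref_day_mean)

    if ref_depth <= 0:
        condition: Optional[int] = 1
    else:
        # ref flooded at the sample implies its day contributes a flooded
        # reading, so ref_max is defined here by construction
        assert ref_max is not None
        condition = 2 if daily_mean > ref_max else None
    return SubsidyClassification(
        sample_id=sample_id,
        subsidized=condition is not None,
        condition=condition,
        inflow_daily_mean_depth=daily_mean,
        reference_flooded_at_sample=ref_depth > 0,
        reference_max_mean_depth=ref_max,
    )


def classify_samples(
    samples: pd.DataFrame,
    inflow: WaterLevelSeries,
    ref: WaterLevelSeries,
    windows: Sequence[PulseWindow] | Iterable[PulseWindow],
    *,
    ref_day_mean: RefDayMean = "flooded_only",
    inflow_day_mean: InflowDayMean = "all_floored",
) -> pd.DataFrame:
    """Classify every sample row against its pulse window.

    ``samples`` needs columns ``sample_id``, ``timestamp`` and ``pulse_id``.
    Returns one row per sample: subsidized flag, condition, and the depth
    quantities entering the rule.
    """
    by_id = {w.pulse_id: w for w in windows}
    rows = []
    for rec in samples.itertuples(index=False):
        window = by_id.get(rec.pulse_id)
        if window is None:
            raise KeyError(f"sample {rec.sample_id}: unknown pulse "
                           f"{rec.pulse_id!r}")
        c = classify_sample(rec.sample_id, rec.timestamp, inflow, ref, window,
                            ref_day_mean=ref_day_mean,
                            inflow_day_mean=inflow_day_mean)
        rows.append({
            "sample_id": c.sample_id,
            "pulse_id": rec.pulse_id,
            "subsidized": c.subsidized,
            "condition": 0 if c.condition is None else c.condition,
            "inflow_daily_mean_depth_mm": c.inflow_daily_mean_depth,
            "ref_max_mean_depth_mm": (np.nan if c.reference_max_mean_depth
                                      is None else c.reference_max_mean_depth),
        })
    out = pd.DataFrame(rows)
    n_sub = int(out["subsidized"].sum()) if len(out) else 0
    logger.info("classified %d samples, %d subsidized", len(out), n_sub)
    return out
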