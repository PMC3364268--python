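"""Subsidy proportions, cross-pulse averaging, scaling, error propagation.

The headline quantity: for each standing-stock metric X (density, biomass,
energy density), the proportion of the total over all inflow samples that
sits in *subsidized* samples,

    p = X(subsidized samples) / X(total samples),

computed per pulse, averaged across pulses to Y (%) with SE, and applied to
the pooled inflow mean X̄ to give the scaled subsidy Z = X̄·Y/100 per m² of
flooded marsh. The subsidy SE combines the two relative errors; the default
rule is the quadrature sum

    Z_err = Z · sqrt((X_err/X̄)² + (Y_err/Y)²),

with ``product`` (Z·(X_err/X̄)·(Y_err/Y)) and ``mean-only`` (Z·X_err/X̄)
available as alternatives since published SE algebra for ratio-scaled
estimates is not always explicit about the combination rule.

Proportions are ratios of totals (mass-weighted), not means of per-sample
ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .energetics import SampleMetrics

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "PulseProportion",
    "SubsidyEstimate",
    "pulse_proportion",
    "cross_pulse_mean",
    "inflow_mean",
    "subsidy_estimate",
]

METRICS = ("density", "biomass", "energy")

_METRIC_ATTR = {"density": "density", "biomass": "biomass_dw",
                "energy": "energy_density"}

ErrorRule = Literal["quadrature", "product", "mean-only"]


@dataclass(frozen=True)
class PulseProportion:
    pulse_id: str
    metric: str
    proportion: float           # fraction in [0, 1]
    subsidized_total: float
    overall_total: float
    n_subsidized: int
    n_total: int


@dataclass(frozen=True)
class SubsidyEstimate:
    """One metric's scaled subsidy: Z = X·Y/100 with propagated SE."""

    metric: str
    inflow_mean: float           # X, per m^2
    inflow_se: Optional[float]   # X_err
    proportion_pct: float        # Y, percent
    proportion_se: Optional[float]  # Y_err, percent
    subsidy: float               # Z, per m^2
    subsidy_se: Optional[float]  # Z_err


def _metric_value(m: SampleMetrics, metric: str) -> float:
    try:
        return getattr(m, _METRIC_ATTR[metric])
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected one of "
                         f"{METRICS}") from None


def pulse_proportion(
    metrics: Sequence[SampleMetrics],
    flags: Mapping[str, bool],
    metric: str,
    pulse_id: str = "",
) -> PulseProportion:
    """Share of one pulse's total metric mass held by subsidized samples.

    ``flags`` maps sample_id → subsidized. Every sample must be flagged.
    A zero overall total yields proportion 0 with a warning.
    """
    if len(metrics) == 0:
        raise ValueError("no samples in pulse")
    missing = [m.sample_id for m in metrics if m.sample_id not in flags]
    if missing:
        raise KeyError(f"no subsidy flag for samples: {missing[:5]}")
    total = 0.0
    sub_total = 0.0
    n_sub = 0
    for m in metrics:
        v = _metric_value(m, metric)
        total += v
        if flags[m.sample_id]:
            sub_total += v
            n_sub += 1
    if total > 0:
        prop = sub_total / total
    else:
        logger.warning("pulse %s metric %s: zero overall total; "
                       "proportion set to 0", pulse_id, metric)
        prop = 0.0
    return PulseProportion(pulse_id, metric, prop, sub_total, total,
                           n_sub, len(metrics))


def cross_pulse_mean(
    props: Sequence[PulseProportion],
) -> tuple[float, Optional[float]]:
    """Mean (%) and SE (%) of per-pulse proportions.

    With two pulses the SE reduces to |p1 − p2|/2 × 100. SE is ``None``
    for a single pulse.
    """
    if len(props) == 0:
        raise ValueError("no pulse proportions")
    metrics = {p.metric for p in props}
    if len(metrics) != 1:
        raise ValueError(f"proportions mix metrics: {sorted(metrics)}")
    vals = np.array([p.proportion for p in props])
    mean = float(vals.mean()) * 100.0
    if len(vals) < 2:
        return mean, None
    se = float(vals.std(ddof=1) / math.sqrt(len(vals))) * 100.0
    return mean, se


def inflow_mean(
    metrics: Sequence[SampleMetrics],
    metric: str,
) -> tuple[float, Optional[float]]:
    """Pooled mean and SE per m² over all inflow samples of all pulses."""
    if len(metrics) == 0:
        raise ValueError("no samples")
    vals = np.array([_metric_value(m, metric) for m in metrics])
    mean = float(vals.mean())
    if len(vals) < 2:
        return mean, None
    se = float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return mean, se


def subsidy_estimate(
    X: float,
    X_err: Optional[float],
    Y: float,
    Y_err: Optional[float],
    metric: str = "",
    error_rule: ErrorRule = "quadrature",
) -> SubsidyEstimate:
    """Scale the inflow mean by the subsidized percentage and propagate SE.

    Z = X·Y/100. ``error_rule`` picks how the relative errors combine;
    missing errors contribute nothing under ``quadrature`` and make Z_err
    undefined under ``product``.
    """
    if not (X > 0):
        raise ValueError("inflow mean must be positive")
    if Y < 0:
        raise ValueError("proportion percentage must be non-negative")
    Z = X * Y / 100.0
    if Y == 0:
        return SubsidyEstimate(metric, X, X_err, Y, Y_err, 0.0, 0.0)

    rel_x = (X_err / X) if X_err is not None else None
    rel_y = (Y_err / Y) if Y_err is not None else None
    Z_err: Optional[float]
    if error_rule == "quadrature":
        terms = [r * r for r in (rel_x, rel_y) if r is not None]
        Z_err = Z * math.sqrt(sum(terms)) if terms else None
    elif error_rule == "product":
        Z_err = (Z * rel_x * rel_y
                 if rel_x is not None and rel_y is not None else None)
    elif error_rule == "mean-only":
        Z_err = Z * rel_x if rel_x is not None else None
    else:
        raise ValueError(f"unknown error rule {error_rule!r}")
    return SubsidyEstimate(metric, X, X_err, Y, Y_err, Z, Z_err)
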