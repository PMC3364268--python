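"""Per-species wet-weight to dry-weight conversion.

Field biomass from drop samples is weighed wet (pooled per species per
sample), while energy densities are expressed per gram dry weight, so each
species needs a linear wet:dry conversion fitted on individuals:

    DW = b0 + b1 * WW        (ordinary least squares)

The intercept is kept only when it differs significantly from zero
(two-sided t-test at ``alpha``, default 0.05); otherwise the model is refit
through the origin. For a through-origin fit the reported r² uses the
uncentered total sum of squares — conventions differ for no-intercept
models, and the uncentered form is what OLS software reports for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "WetDryRecord",
    "AllometricModel",
    "fit_wet_dry",
    "predict_dry_weight",
    "water_content_summary",
]


@dataclass(frozen=True)
class WetDryRecord:
    """One individual weighed wet, dried to constant weight, and reweighed."""

    species: str
    wet_g: float
    dry_g: float

    def __post_init__(self) -> None:
        if not (self.wet_g > 0):
            raise ValueError("wet weight must be positive")
        if not (0 < self.dry_g < self.wet_g):
            raise ValueError("dry weight must lie strictly between 0 and "
                             "the wet weight")


@dataclass(frozen=True)
class AllometricModel:
    """Fitted wet→dry conversion for one species.

    ``intercept`` is ``None`` exactly when the intercept was dropped as not
    significantly different from zero. ``mean_water_content`` is the mean of
    ``1 − dry/wet`` over the fitted individuals.
    """

    species: str
    slope: float
    intercept: Optional[float]
    intercept_dropped: bool
    r_squared: float
    n: int
    mean_water_content: float
    water_content_se: Optional[float]

    def __post_init__(self) -> None:
        if self.intercept_dropped != (self.intercept is None):
            raise ValueError("intercept_dropped inconsistent with intercept")


def fit_wet_dry(records: Sequence[WetDryRecord],
                alpha: float = 0.05) -> AllometricModel:
    """Fit DW = b0 + b1·WW on individuals with a significance-gated intercept.

    Requires at least three records of a single species and nonzero wet-weight
    variance. If the intercept's two-sided p-value is >= ``alpha`` the model
    is refit through the origin and ``intercept_dropped`` is set.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must be in (0, 0.5]")
    if len(records) < 3:
        raise ValueError("need at least 3 wet/dry records to fit")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records mix species: {sorted(species)}")
    ww = np.array([r.wet_g for r in records])
    dw = np.array([r.dry_g for r in records])
    if np.ptp(ww) == 0:
        raise ValueError("zero wet-weight variance; cannot fit a slope")

    full = sm.OLS(dw, sm.add_constant(ww)).fit()
    p_intercept = float(full.pvalues[0])
    if p_intercept < alpha:
        intercept: Optional[float] = float(full.params[0])
        slope = float(full.params[1])
        r2 = float(full.rsquared)
        dropped = False
    else:
        origin = sm.OLS(dw, ww[:, None]).fit()
        intercept = None
        slope = float(origin.params[0])
        r2 = float(origin.rsquared)  # uncentered for no-constant models
        dropped = True

    wc_mean, wc_se = water_content_summary(records)
    return AllometricModel(
        species=next(iter(species)),
        slope=slope,
        intercept=intercept,
        intercept_dropped=dropped,
        r_squared=r2,
        n=len(records),
        mean_water_content=wc_mean,
        water_content_se=wc_se,
    )


def predict_dry_weight(model: AllometricModel, pooled_wet_g: float,
                       count: int) -> float:
    """Convert a pooled wet weighing of ``count`` individuals to dry weight.

    The regression is fitted on individuals, so for an intercept model the
    intercept applies once per individual:  DW = count·b0 + b1·WW_pooled.
    A negative prediction (possible for tiny weights with a negative
    intercept) is floored at zero with a warning.
    """
    if pooled_wet_g < 0 or count < 0:
        raise ValueError("pooled wet weight and count must be non-negative")
    if count == 0 and pooled_wet_g != 0:
        raise ValueError("zero individuals cannot carry positive wet weight")
    dw = model.slope * pooled_wet_g
    if model.intercept is not None:
        dw += count * model.intercept
    if dw < 0:
        logger.warning("%s: predicted dry weight %.4g g floored at 0 "
                       "(count=%d, wet=%.4g g)", model.species, dw, count,
                       pooled_wet_g)
        dw = 0.0
    return dw


def water_content_summary(
    records: Sequence[WetDryRecord],
) -> tuple[float, Optional[float]]:
    """Mean and SE over individuals of the water content ``1 − dry/wet``.

    The SE is ``None`` for a single record.
    """
    if len(records) == 0:
        raise ValueError("no records")
    wc = np.array([1.0 - r.dry_g / r.wet_g for r in records])
    mean = float(wc.mean())
    if len(wc) < 2:
        return mean, None
    se = float(wc.std(ddof=1) / np.sqrt(len(wc)))
    return mean, se
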