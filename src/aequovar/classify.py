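"""Control-calibrated tri-category classification and functional scoring.

Thresholds for "normal" channel function are derived from a control group
(presumed-benign population variants plus homology controls): for each of
the two normalized assay parameters (AUC, latency) the control mean and SD
define a z-score band ``mean ± z × SD`` (default z = 2.56, a two-sided
p of about 0.01). A variant's parameter is then judged by where its own
``mean ± SD`` interval lies relative to that band:

* entirely below or above the band  → *outside*
* strictly inside the open band     → *inside*
* anything touching a band edge     → *overlap*

The tri-category rule: any parameter *outside* makes the variant
**functionally abnormal**; both parameters *inside* make it **functionally
normal**; every other combination is **functionally uncertain**.

For correlation with variant-effect predictors, AUC and latency are
combined into a single functional score FC in [0, 1] via min-max
normalization (with a piecewise latency map centred on the wild-type value
of 1) and equal weighting: ``FC = 0.5 · AUC_n + 0.5 · L_n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import VariantAssayResult
from .errors import CalibrationError, DegenerateContextError

__all__ = [
    "ParameterState",
    "FunctionalCategory",
    "ThresholdSet",
    "FunctionalScoreContext",
    "derive_thresholds",
    "classify_interval",
    "categorize",
    "compute_functional_scores",
]


class ParameterState(str, Enum):
    INSIDE = "inside"
    OUTSIDE = "outside"
    OVERLAP = "overlap"


class FunctionalCategory(str, Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class ThresholdSet:
    """Z-score bands derived from the control group (normalized units)."""

    z_multiplier: float
    auc_mean_control: float
    auc_sd_control: float
    latency_mean_control: float
    latency_sd_control: float

    def __post_init__(self) -> None:
        if self.auc_sd_control < 0 or self.latency_sd_control < 0:
            raise CalibrationError("control SD must be >= 0")

    @property
    def auc_lo(self) -> float:
        return self.auc_mean_control - self.z_multiplier * self.auc_sd_control

    @property
    def auc_hi(self) -> float:
        return self.auc_mean_control + self.z_multiplier * self.auc_sd_control

    @property
    def latency_lo(self) -> float:
        return self.latency_mean_control - self.z_multiplier * self.latency_sd_control

    @property
    def latency_hi(self) -> float:
        return self.latency_mean_control + self.z_multiplier * self.latency_sd_control


def derive_thresholds(control_results: Sequence[VariantAssayResult],
                      z_multiplier: float = 2.56) -> ThresholdSet:
    """Control mean/SD and z-score bands for AUC and latency.

    The SD uses the n-1 denominator over the control variants' per-variant
    normalized means.
    """
    if len(control_results) < 2:
        raise CalibrationError(
            f"need >= 2 control variants to calibrate thresholds, "
            f"got {len(control_results)}")
    auc = np.array([r.auc_norm_mean for r in control_results])
    lat = np.array([r.latency_norm_mean for r in control_results])
    return ThresholdSet(
        z_multiplier=z_multiplier,
        auc_mean_control=float(auc.mean()),
        auc_sd_control=float(auc.std(ddof=1)),
        latency_mean_control=float(lat.mean()),
        latency_sd_control=float(lat.std(ddof=1)),
    )


def classify_interval(mean: float, sd: float, lo: float, hi: float) -> ParameterState:
    """Position of the interval [mean - SD, mean + SD] relative to (lo, hi).

    An interval endpoint exactly on a band edge counts as overlap, so a
    variant that "hits the threshold" is never called inside or outside.
    """
    a, b = mean - sd, mean + sd
    if b < lo or a > hi:
        return ParameterState.OUTSIDE
    if lo < a and b < hi:
        return ParameterState.INSIDE
    return ParameterState.OVERLAP


def categorize(result: VariantAssayResult, thresholds: ThresholdSet,
               ) -> tuple[FunctionalCategory, ParameterState, ParameterState]:
    """Tri-category call for one variant; returns (category, AUC state,
    latency state). Precedence: abnormal > uncertain > normal."""
    auc_state = classify_interval(result.auc_norm_mean, result.auc_norm_sd,
                                  thresholds.auc_lo, thresholds.auc_hi)
    lat_state = classify_interval(result.latency_norm_mean, result.latency_norm_sd,
                                  thresholds.latency_lo, thresholds.latency_hi)
    if ParameterState.OUTSIDE in (auc_state, lat_state):
        cat = FunctionalCategory.ABNORMAL
    elif auc_state == ParameterState.INSIDE and lat_state == ParameterState.INSIDE:
        cat = FunctionalCategory.NORMAL
    else:
        cat = FunctionalCategory.UNCERTAIN
    return cat, auc_state, lat_state


@dataclass(frozen=True)
class FunctionalScoreContext:
    """Cohort extremes anchoring the min-max functional-score maps."""

    auc_min: float
    auc_max: float
    latency_min: float
    latency_max: float

    def auc_n(self, auc: float) -> float:
        return (auc - self.auc_min) / (self.auc_max - self.auc_min)

    def latency_n(self, latency: float) -> float:
        # piecewise map anchored at the wild-type latency of 1: values at or
        # below 1 scale from the cohort minimum, values above 1 scale to the
        # cohort maximum; both branches reach 1 at the wild-type point's side
        if latency <= 1.0:
            if self.latency_min == 1.0:
                return 1.0
            return (latency - self.latency_min) / (1.0 - self.latency_min)
        if self.latency_max <= 1.0:
            raise DegenerateContextError(
                f"latency {latency} exceeds 1 but the cohort maximum is "
                f"{self.latency_max}")
        return (latency - 1.0) / (self.latency_max - 1.0)

    def functional_score(self, auc: float, latency: float) -> float:
        return 0.5 * self.auc_n(auc) + 0.5 * self.latency_n(latency)


def compute_functional_scores(results: Sequence[VariantAssayResult],
                              ) -> tuple[FunctionalScoreContext, pd.DataFrame]:
    """Min-max normalized AUC_n, L_n and combined FC for a cohort.

    The cohort passed in defines the min-max context ("the dataset"); which
    variants belong to it — typically all assayed variants excluding
    dedicated control constructs — is the caller's choice.
    """
    if len(results) < 2:
        raise DegenerateContextError("functional scoring needs >= 2 variants")
    auc = np.array([r.auc_norm_mean for r in results])
    lat = np.array([r.latency_norm_mean for r in results])
    if auc.max() == auc.min():
        raise DegenerateContextError("all AUC values identical; min-max undefined")
    ctx = FunctionalScoreContext(
        auc_min=float(auc.min()), auc_max=float(auc.max()),
        latency_min=float(lat.min()), latency_max=float(lat.max()),
    )
    rows = []
    for r in results:
        auc_n = ctx.auc_n(r.auc_norm_mean)
        l_n = ctx.latency_n(r.latency_norm_mean)
        rows.append({
            "sample_id": r.sample_id,
            "AUC_n": auc_n, "L_n": l_n,
            "FC": 0.5 * auc_n + 0.5 * l_n,
        })
    return ctx, pd.DataFrame(rows)
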