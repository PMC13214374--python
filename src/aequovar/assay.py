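"""Metric extraction for aequorin-based plate-luminescence bioassays.

HEK293 cells stably expressing the Ca2+-sensitive photoprotein aequorin are
transfected with a cyclic nucleotide-gated (CNG) channel construct.
Injection of the membrane-permeable agonist 8-Br-cGMP opens functional
channels; the resulting Ca2+ influx triggers a luminescence transient
recorded by a plate reader. Two metrics summarise each well:

* **AUC** — the integral of the luminescence signal over a fixed window
  after agonist injection (default: 279 s starting 14 s post-injection),
  a proxy for overall channel activity.
* **latency** — the time from measurement onset to the maximal
  luminescence response, a proxy for response kinetics.

Both metrics are normalized to the wild-type control present on the same
plate, so that plate-to-plate sensitivity differences cancel and the
wild-type response equals 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    MissingWildtypeError,
    ValidationError,
    WindowCoverageError,
)

__all__ = [
    "Role",
    "AssayConfig",
    "LuminescenceTrace",
    "WellMetrics",
    "VariantAssayResult",
    "compute_auc",
    "compute_latency",
    "compute_well_metrics",
    "aggregate_technical",
    "normalize_to_plate_wildtype",
    "flag_nonfunctional",
    "process_plate_table",
    "read_trace_csv",
    "results_to_frame",
]

#: floor for the pre-injection mean when forming the post/pre response ratio,
#: in RLU; avoids division by zero for wells with a dark baseline
PRE_INJECTION_EPS = 1e-9


class Role(str, Enum):
    VARIANT = "variant"
    WILDTYPE_CONTROL = "wildtype_control"
    UNTRANSFECTED = "untransfected"


@dataclass(frozen=True)
class AssayConfig:
    """Tunable constants of the metric-extraction stage.

    Parameters
    ----------
    auc_window_offset:
        Seconds between agonist injection and the start of the AUC window.
    auc_window_length:
        Length of the AUC window in seconds.
    nonfunctional_auc_floor:
        Normalized-AUC value below which (strictly) the latency of a variant
        is forced to zero, because a peak position in a near-flat trace is
        noise, not kinetics.
    nonfunctional_response_ratio:
        Fold-change threshold on the post-/pre-injection mean signal below
        which a well is considered to show no agonist response.
    min_biological_replicates:
        Number of independent transfections expected per variant; fewer
        produces a warning column, not a failure.
    """

    auc_window_offset: float = 14.0
    auc_window_length: float = 279.0
    nonfunctional_auc_floor: float = 0.02
    nonfunctional_response_ratio: float = 1.5
    min_biological_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("auc_window_offset", "auc_window_length",
                     "nonfunctional_auc_floor", "nonfunctional_response_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"AssayConfig.{name} must be strictly positive")


@dataclass
class LuminescenceTrace:
    """One well's luminescence time series.

    ``times`` are seconds from measurement onset; ``injection_time`` marks
    the application of 8-Br-cGMP on the same clock.
    """

    well_id: str
    sample_id: str
    role: Role
    times: np.ndarray
    signal: np.ndarray
    injection_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size == 0:
            raise ValidationError(f"well {self.well_id}: empty trace")
        if self.times.shape != self.signal.shape:
            raise ValidationError(
                f"well {self.well_id}: times and signal differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"well {self.well_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValidationError(
                f"well {self.well_id}: signal values must be finite and >= 0")
        if not (self.times[0] <= self.injection_time <= self.times[-1]):
            raise ValidationError(
                f"well {self.well_id}: injection_time {self.injection_time} outside "
                f"recorded interval [{self.times[0]}, {self.times[-1]}]")
        self.role = Role(self.role)


@dataclass(frozen=True)
class WellMetrics:
    """Raw (un-normalized) metrics of a technically averaged trace."""

    auc_raw: float
    latency_raw: float
    peak_signal: float
    pre_injection_mean: float
    post_injection_mean: float


@dataclass
class VariantAssayResult:
    """Per-variant normalized metrics aggregated over biological replicates.

    All values are dimensionless ratios to the same-plate wild-type response
    (wild type = 1). A ``non_functional`` variant has its latency forced to
    0 with SD 0, as does any variant whose normalized AUC falls below the
    configured floor.
    """

    sample_id: str
    auc_norm_mean: float
    auc_norm_sd: float
    latency_norm_mean: float
    latency_norm_sd: float
    n_biological: int
    non_functional: bool

    def __post_init__(self) -> None:
        if self.n_biological < 1:
            raise ValidationError(f"{self.sample_id}: n_biological must be >= 1")
        if self.auc_norm_sd < 0 or self.latency_norm_sd < 0:
            raise ValidationError(f"{self.sample_id}: SD must be >= 0")
        if self.non_functional and (
                self.latency_norm_mean != 0 or self.latency_norm_sd != 0):
            raise ValidationError(
                f"{self.sample_id}: non-functional variants must carry zero latency")


def compute_auc(trace: LuminescenceTrace, config: AssayConfig | None = None,
                *, allow_partial_window: bool = False) -> float:
    """Trapezoid integral of the signal over the post-injection window.

    The window is ``[injection + offset, injection + offset + length]``.
    Window endpoints falling between samples are handled by linear
    interpolation of the signal at the exact endpoint.
    """
    config = config or AssayConfig()
    w0 = trace.injection_time + config.auc_window_offset
    w1 = w0 + config.auc_window_length
    t0, t1 = trace.times[0], trace.times[-1]
    if (w0 < t0 or w1 > t1) and not allow_partial_window:
        shortfall = max(t0 - w0, 0.0) + max(w1 - t1, 0.0)
        raise WindowCoverageError(
            f"well {trace.well_id}: AUC window [{w0:.3f}, {w1:.3f}] s extends "
            f"{shortfall:.3f} s beyond the recorded trace [{t0:.3f}, {t1:.3f}] s")
    w0, w1 = max(w0, t0), min(w1, t1)
    if w1 <= w0:
        return 0.0
    inner = (trace.times > w0) & (trace.times < w1)
    ts = np.concatenate(([w0], trace.times[inner], [w1]))
    ys = np.interp(ts, trace.times, trace.signal)
    return float(np.trapezoid(ys, ts))


def compute_latency(trace: LuminescenceTrace) -> float:
    """Time from measurement onset to the maximal signal.

    Ties are broken to the earliest time at which the maximum is reached
    (``argmax`` first occurrence), the conservative (shorter) latency.
    """
    idx = int(np.argmax(trace.signal))
    return float(trace.times[idx] - trace.times[0])


def compute_well_metrics(trace: LuminescenceTrace,
                         config: AssayConfig | None = None) -> WellMetrics:
    """All raw metrics of one (typically technically averaged) trace."""
    config = config or AssayConfig()
    pre = trace.signal[trace.times < trace.injection_time]
    post = trace.signal[trace.times >= trace.injection_time]
    return WellMetrics(
        auc_raw=compute_auc(trace, config),
        latency_raw=compute_latency(trace),
        peak_signal=float(np.max(trace.signal)),
        pre_injection_mean=float(np.mean(pre)) if pre.size else 0.0,
        post_injection_mean=float(np.mean(post)) if post.size else 0.0,
    )


def aggregate_technical(traces: Sequence[LuminescenceTrace]) -> LuminescenceTrace:
    """Pointwise mean of technical-replicate traces on an identical time grid.

    Metrics are computed on the averaged trace, not averaged from per-well
    metrics. Resampling mismatched grids is out of scope: a mismatch is an
    error.
    """
    if len(traces) == 0:
        raise ValidationError("no technical replicates to aggregate")
    ref = traces[0]
    for tr in traces[1:]:
        if not np.array_equal(tr.times, ref.times):
            raise ValidationError(
                f"technical replicates {ref.well_id} and {tr.well_id} "
                "are on different time grids")
        if tr.injection_time != ref.injection_time:
            raise ValidationError(
                f"technical replicates {ref.well_id} and {tr.well_id} "
                "have different injection times")
    mean_signal = np.mean([tr.signal for tr in traces], axis=0)
    return LuminescenceTrace(
        well_id="+".join(tr.well_id for tr in traces),
        sample_id=ref.sample_id,
        role=ref.role,
        times=ref.times.copy(),
        signal=mean_signal,
        injection_time=ref.injection_time,
    )


def normalize_to_plate_wildtype(metrics: pd.DataFrame) -> pd.DataFrame:
    """Divide each row's AUC and latency by the same-plate wild-type value.

    ``metrics`` has one row per (plate_id, sample_id, bio_replicate) after
    technical aggregation, with columns ``plate_id, sample_id, role,
    auc_raw, latency_raw``. The wild-type value of a plate is the mean over
    that plate's wild-type rows. Returns a copy with ``auc_norm`` and
    ``latency_norm`` columns added.
    """
    out = metrics.copy()
    out["auc_norm"] = np.nan
    out["latency_norm"] = np.nan
    for plate, grp in metrics.groupby("plate_id", sort=False):
        wt = grp[grp["role"] == Role.WILDTYPE_CONTROL.value]
        if wt.empty:
            raise MissingWildtypeError(f"plate {plate!r} has no wild-type control wells")
        wt_auc = float(wt["auc_raw"].mean())
        wt_lat = float(wt["latency_raw"].mean())
        if wt_auc <= 0:
            raise DegenerateControlError(f"plate {plate!r}: wild-type AUC is not positive")
        if wt_lat <= 0:
            raise DegenerateControlError(f"plate {plate!r}: wild-type latency is not positive")
        out.loc[grp.index, "auc_norm"] = grp["auc_raw"] / wt_auc
        out.loc[grp.index, "latency_norm"] = grp["latency_raw"] / wt_lat
    return out


def flag_nonfunctional(pre_injection_mean: float, post_injection_mean: float,
                       config: AssayConfig | None = None,
                       manual_override: bool | None = None) -> bool:
    """Automatic no-response rule with a manual-revision override.

    A well is non-functional when the post-/pre-injection mean-signal ratio
    falls below the configured fold change, or the manual override says so.
    The pre-injection mean is floored at a small epsilon so a dark baseline
    never crashes the ratio.
    """
    config = config or AssayConfig()
    if manual_override is not None:
        return bool(manual_override)
    ratio = post_injection_mean / max(pre_injection_mean, PRE_INJECTION_EPS)
    return ratio < config.nonfunctional_response_ratio


def _aggregate_biological(sample_id: str, rows: pd.DataFrame,
                          config: AssayConfig,
                          manual_override: bool | None) -> VariantAssayResult:
    n = len(rows)
    auc_mean = float(rows["auc_norm"].mean())
    auc_sd = float(rows["auc_norm"].std(ddof=1)) if n > 1 else 0.0
    lat_mean = float(rows["latency_norm"].mean())
    lat_sd = float(rows["latency_norm"].std(ddof=1)) if n > 1 else 0.0
    nonfunc = flag_nonfunctional(
        float(rows["pre_injection_mean"].mean()),
        float(rows["post_injection_mean"].mean()),
        config, manual_override)
    # a near-zero normalized AUC makes the peak position meaningless
    if nonfunc or auc_mean < config.nonfunctional_auc_floor:
        lat_mean, lat_sd = 0.0, 0.0
    return VariantAssayResult(
        sample_id=sample_id,
        auc_norm_mean=auc_mean, auc_norm_sd=auc_sd,
        latency_norm_mean=lat_mean, latency_norm_sd=lat_sd,
        n_biological=n, non_functional=nonfunc,
    )


def process_plate_table(traces: pd.DataFrame, config: AssayConfig | None = None,
                        manual_overrides: Mapping[str, bool] | None = None,
                        ) -> list[VariantAssayResult]:
    """Full metric-extraction chain on a long-format trace table.

    Expected columns: ``plate_id, well_id, sample_id, role, bio_replicate,
    tech_replicate, time_s, rlu, injection_time_s``. Per (plate, sample,
    biological replicate) the technical replicates are averaged, metrics
    computed on the averaged trace, normalized to the same-plate wild type,
    and finally aggregated over biological replicates (SD with the n-1
    denominator). Wild-type and untransfected samples are reported too so
    downstream stages can verify the self-normalization.
    """
    config = config or AssayConfig()
    manual_overrides = manual_overrides or {}
    records = []
    keys = ["plate_id", "sample_id", "bio_replicate"]
    for (plate, sample, bio), grp in traces.groupby(keys, sort=False):
        reps = []
        for well, wgrp in grp.groupby("well_id", sort=False):
            wgrp = wgrp.sort_values("time_s")
            reps.append(LuminescenceTrace(
                well_id=str(well), sample_id=str(sample),
                role=Role(wgrp["role"].iloc[0]),
                times=wgrp["time_s"].to_numpy(),
                signal=wgrp["rlu"].to_numpy(),
                injection_time=float(wgrp["injection_time_s"].iloc[0]),
            ))
        avg = aggregate_technical(reps)
        m = compute_well_metrics(avg, config)
        records.append({
            "plate_id": plate, "sample_id": sample, "bio_replicate": bio,
            "role": avg.role.value, "auc_raw": m.auc_raw,
            "latency_raw": m.latency_raw, "peak_signal": m.peak_signal,
            "pre_injection_mean": m.pre_injection_mean,
            "post_injection_mean": m.post_injection_mean,
        })
    per_bio = normalize_to_plate_wildtype(pd.DataFrame.from_records(records))
    results = []
    for sample, grp in per_bio.groupby("sample_id", sort=False):
        results.append(_aggregate_biological(
            str(sample), grp, config, manual_overrides.get(str(sample))))
    return results


def read_trace_csv(path: str | Path, injection_time: float | None = None) -> pd.DataFrame:
    """Read a long-format trace CSV; ``injection_time_s`` may be a column
    of the file or supplied as a single value for the whole run."""
    df = pd.read_csv(path)
    required = {"plate_id", "well_id", "sample_id", "role",
                "bio_replicate", "tech_replicate", "time_s", "rlu"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trace CSV is missing columns: {sorted(missing)}")
    if "injection_time_s" not in df.columns:
        if injection_time is None:
            raise ValidationError(
                "trace CSV has no injection_time_s column and no injection "
                "time was supplied")
        df["injection_time_s"] = float(injection_time)
    return df


def results_to_frame(results: Iterable[VariantAssayResult]) -> pd.DataFrame:
    """Tabulate results in the per-variant TSV layout."""
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "auc_norm_mean": r.auc_norm_mean, "auc_norm_sd": r.auc_norm_sd,
        "latency_norm_mean": r.latency_norm_mean,
        "latency_norm_sd": r.latency_norm_sd,
        "n_biological": r.n_biological, "non_functional": r.non_functional,
    } for r in results])
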