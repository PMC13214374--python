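"""Trace metrics: AUC window integration, latency, replicate handling,
per-plate wild-type normalization and no-response detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aequovar.assay import (
    AssayConfig,
    LuminescenceTrace,
    Role,
    aggregate_technical,
    compute_auc,
    compute_latency,
    compute_well_metrics,
    flag_nonfunctional,
    normalize_to_plate_wildtype,
    process_plate_table,
)
from aequovar.errors import (
    DegenerateControlError,
    MissingWildtypeError,
    ValidationError,
    WindowCoverageError,
)


def brute_force_auc(trace, w0, w1, n=200_000):
    """Riemann-sum oracle on a fine grid, independent of the trapezoid path."""
    ts = np.linspace(w0, w1, n)
    ys = np.interp(ts, trace.times, trace.signal)
    return np.sum(ys) * (w1 - w0) / n


class TestComputeAuc:
    def test_zero_signal_integrates_to_zero(self, make_trace):
        tr = make_trace(np.zeros(400), injection_time=50.0)
        assert compute_auc(tr) == 0.0

    def test_constant_signal_closed_form(self, make_trace):
        tr = make_trace(np.ones(400), injection_time=50.0)
        assert compute_auc(tr) == pytest.approx(279.0)

    def test_triangular_pulse_area(self, make_trace):
        # symmetric triangle of height 8 and base 60 s entirely in the window
        sig = np.zeros(400)
        t_peak, half = 150, 30
        for i in range(400):
            sig[i] = max(0.0, 8.0 * (1 - abs(i - t_peak) / half))
        tr = make_trace(sig, injection_time=50.0)
        expected = 8.0 * 60.0 / 2
        auc = compute_auc(tr)
        assert auc == pytest.approx(expected, rel=1e-6)
        assert auc == pytest.approx(brute_force_auc(tr, 64.0, 343.0), rel=1e-3)

    def test_window_endpoints_interpolated(self, make_trace):
        # coarse 7-s sampling puts both window edges between samples
        sig = np.linspace(0, 10, 60)
        tr = make_trace(sig, dt=7.0, injection_time=35.0)
        assert compute_auc(tr) == pytest.approx(
            brute_force_auc(tr, 49.0, 328.0), rel=1e-6)

    def test_window_beyond_trace_is_an_error(self, make_trace):
        tr = make_trace(np.ones(100), injection_time=50.0)
        with pytest.raises(WindowCoverageError, match="window"):
            compute_auc(tr)
        assert compute_auc(tr, allow_partial_window=True) > 0

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            LuminescenceTrace("w", "s", Role.VARIANT,
                              times=np.array([0.0, 2.0, 1.0]),
                              signal=np.ones(3), injection_time=0.0)

    @given(a=st.floats(0, 5), b=st.floats(0, 5), seed=st.integers(0, 10_000))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        times = np.arange(0.0, 400.0)
        s1, s2 = rng.random(400), rng.random(400)
        def auc(sig):
            return compute_auc(LuminescenceTrace(
                "w", "s", Role.VARIANT, times, sig, injection_time=50.0))
        assert auc(a * s1 + b * s2) == pytest.approx(
            a * auc(s1) + b * auc(s2), abs=1e-8)


class TestComputeLatency:
    def test_single_peak(self, make_trace):
        sig = np.zeros(100)
        sig[50] = 3.0
        assert compute_latency(make_trace(sig)) == 50.0

    def test_monotone_rise_peaks_at_end(self, make_trace):
        assert compute_latency(make_trace(np.arange(100.0))) == 99.0

    def test_plateau_ties_break_earliest(self, make_trace):
        sig = np.zeros(100)
        sig[40:61] = 5.0
        tr = make_trace(sig)
        # linear-scan oracle with first-occurrence rule
        best = max(range(100), key=lambda i: (sig[i], -i))
        assert compute_latency(tr) == float(tr.times[best]) == 40.0

    def test_measured_from_onset_not_injection(self, make_trace):
        sig = np.zeros(100)
        sig[70] = 1.0
        tr = make_trace(sig, t0=100.0, injection_time=130.0)
        assert compute_latency(tr) == 70.0

    @given(scale=st.sampled_from([0.25, 0.5, 2.0, 8.0, 64.0]),
           seed=st.integers(0, 10_000))
    def test_invariant_under_positive_scaling(self, make_trace, scale, seed):
        # dyadic scales keep float comparisons exact
        sig = np.random.default_rng(seed).random(50)
        assert compute_latency(make_trace(sig)) == compute_latency(
            make_trace(scale * sig))


class TestAggregateTechnical:
    def test_single_replicate_identity(self, make_trace):
        tr = make_trace(np.arange(10.0))
        np.testing.assert_array_equal(aggregate_technical([tr]).signal, tr.signal)

    def test_symmetric_pair_averages_to_constant(self, make_trace):
        v = np.linspace(0, 4, 20)
        avg = aggregate_technical([make_trace(v), make_trace(-v + 6.0)])
        np.testing.assert_allclose(avg.signal, 3.0)

    def test_three_replicates_match_elementwise_mean(self, make_trace, rng):
        sigs = [rng.random(30) for _ in range(3)]
        avg = aggregate_technical([make_trace(s) for s in sigs])
        np.testing.assert_allclose(avg.signal, np.mean(sigs, axis=0))

    def test_mismatched_grids_rejected(self, make_trace):
        with pytest.raises(ValidationError, match="time grids"):
            aggregate_technical([make_trace(np.ones(10)),
                                 make_trace(np.ones(10), dt=2.0)])


def _metrics_row(plate, sample, role, auc, lat):
    return {"plate_id": plate, "sample_id": sample, "role": role,
            "bio_replicate": 1, "auc_raw": auc, "latency_raw": lat,
            "pre_injection_mean": 0.0, "post_injection_mean": auc}


class TestNormalization:
    def test_wildtype_self_normalizes_to_one(self):
        df = pd.DataFrame([_metrics_row("P1", "WT", "wildtype_control", 50.0, 60.0)])
        out = normalize_to_plate_wildtype(df)
        assert out["auc_norm"].iloc[0] == 1.0
        assert out["latency_norm"].iloc[0] == 1.0

    def test_half_auc_gives_half_normalized(self):
        df = pd.DataFrame([
            _metrics_row("P1", "WT", "wildtype_control", 50.0, 60.0),
            _metrics_row("P1", "V1", "variant", 25.0, 60.0),
        ])
        out = normalize_to_plate_wildtype(df)
        assert out.loc[out.sample_id == "V1", "auc_norm"].iloc[0] == 0.5

    def test_normalization_is_per_plate_not_global(self):
        df = pd.DataFrame([
            _metrics_row("P1", "WT", "wildtype_control", 40.0, 60.0),
            _metrics_row("P1", "V1", "variant", 20.0, 60.0),
            _metrics_row("P2", "WT", "wildtype_control", 80.0, 60.0),
            _metrics_row("P2", "V2", "variant", 20.0, 60.0),
        ])
        out = normalize_to_plate_wildtype(df).set_index("sample_id")
        assert out.loc["V1", "auc_norm"] == 2 * out.loc["V2", "auc_norm"]

    def test_plate_without_wildtype_named_in_error(self):
        df = pd.DataFrame([_metrics_row("P9", "V1", "variant", 20.0, 60.0)])
        with pytest.raises(MissingWildtypeError, match="P9"):
            normalize_to_plate_wildtype(df)

    def test_zero_wildtype_auc_is_degenerate(self):
        df = pd.DataFrame([_metrics_row("P1", "WT", "wildtype_control", 0.0, 60.0)])
        with pytest.raises(DegenerateControlError):
            normalize_to_plate_wildtype(df)

    def test_plate_mean_of_wildtype_equals_one(self):
        df = pd.DataFrame([
            _metrics_row("P1", "WT", "wildtype_control", 40.0, 50.0),
            _metrics_row("P1", "WT2", "wildtype_control", 60.0, 70.0),
        ])
        out = normalize_to_plate_wildtype(df)
        assert out["auc_norm"].mean() == pytest.approx(1.0, abs=1e-15)
        assert out["latency_norm"].mean() == pytest.approx(1.0, abs=1e-15)


class TestNonfunctional:
    def test_flat_trace_flagged(self):
        assert flag_nonfunctional(pre_injection_mean=5.0, post_injection_mean=5.0)

    def test_responding_trace_not_flagged(self):
        assert not flag_nonfunctional(pre_injection_mean=5.0, post_injection_mean=50.0)

    def test_zero_pre_injection_never_crashes(self):
        assert not flag_nonfunctional(pre_injection_mean=0.0, post_injection_mean=10.0)
        assert flag_nonfunctional(pre_injection_mean=0.0, post_injection_mean=0.0)

    def test_manual_override_wins(self):
        assert flag_nonfunctional(5.0, 500.0, manual_override=True)
        assert not flag_nonfunctional(5.0, 5.0, manual_override=False)


def _long_table(samples, dt=1.0, n=400, injection=50.0):
    """samples: list of (plate, sample, role, bio, tech, signal array)."""
    rows = []
    for plate, sample, role, bio, tech, sig in samples:
        times = dt * np.arange(len(sig))
        rows.append(pd.DataFrame({
            "plate_id": plate, "well_id": f"{sample}.b{bio}.t{tech}",
            "sample_id": sample, "role": role, "bio_replicate": bio,
            "tech_replicate": tech, "time_s": times, "rlu": sig,
            "injection_time_s": injection,
        }))
    return pd.concat(rows, ignore_index=True)


def _pulse(n=400, height=10.0, peak=120, half=40):
    i = np.arange(n)
    return np.maximum(0.0, height * (1 - np.abs(i - peak) / half))


class TestProcessPlateTable:
    def test_latency_forced_zero_below_auc_floor(self):
        wt = _pulse(height=10.0)
        tiny = _pulse(height=0.1)  # normalized AUC 0.01 < 0.02
        df = _long_table([
            ("P1", "WT", "wildtype_control", 1, 1, wt),
            ("P1", "V1", "variant", 1, 1, tiny),
        ])
        res = {r.sample_id: r for r in process_plate_table(df)}
        assert res["V1"].latency_norm_mean == 0.0
        assert res["V1"].latency_norm_sd == 0.0

    def test_auc_floor_boundary_is_strict(self):
        wt = _pulse(height=10.0)
        at_floor = _pulse(height=0.2)  # normalized AUC exactly 0.02
        df = _long_table([
            ("P1", "WT", "wildtype_control", 1, 1, wt),
            ("P1", "V1", "variant", 1, 1, at_floor),
        ])
        res = {r.sample_id: r for r in process_plate_table(df)}
        assert res["V1"].auc_norm_mean == pytest.approx(0.02)
        assert res["V1"].latency_norm_mean > 0  # keeps its latency at the boundary

    def test_nonfunctional_variant_has_zero_latency(self):
        df = _long_table([
            ("P1", "WT", "wildtype_control", 1, 1, _pulse()),
            ("P1", "V1", "variant", 1, 1, np.full(400, 2.0)),  # flat, no response
        ])
        res = {r.sample_id: r for r in process_plate_table(df)}
        assert res["V1"].non_functional
        assert res["V1"].latency_norm_mean == 0.0

    def test_manual_override_reproduces_manual_revision(self):
        df = _long_table([
            ("P1", "WT", "wildtype_control", 1, 1, _pulse()),
            ("P1", "V1", "variant", 1, 1, _pulse(height=8.0)),
        ])
        res = {r.sample_id: r for r in process_plate_table(
            df, manual_overrides={"V1": True})}
        assert res["V1"].non_functional

    def test_sd_uses_n_minus_one(self):
        sigs = [_pulse(height=h) for h in (4.0, 6.0)]
        df = _long_table(
            [("P1", "WT", "wildtype_control", b, 1, _pulse()) for b in (1, 2)]
            + [("P1", "V1", "variant", b, 1, s) for b, s in enumerate(sigs, 1)])
        res = {r.sample_id: r for r in process_plate_table(df)}
        vals = [0.4, 0.6]
        assert res["V1"].auc_norm_mean == pytest.approx(0.5, rel=1e-9)
        assert res["V1"].auc_norm_sd == pytest.approx(np.std(vals, ddof=1), rel=1e-9)


def test_metrics_match_brute_force_on_random_traces(rng):
    """AUC and latency agree with fine-grid oracles over many random traces."""
    for _ in range(100):
        n = int(rng.integers(350, 450))
        dt = float(rng.uniform(0.5, 2.0))
        sig = rng.gamma(2.0, 2.0, size=n)
        times = dt * np.arange(n)
        inj = float(rng.uniform(times[0], times[-1] - 293.0 / 1.0)) \
            if times[-1] > 300 else times[0]
        tr = LuminescenceTrace("w", "s", Role.VARIANT, times, sig, inj)
        w0, w1 = inj + 14.0, inj + 293.0
        if w1 > times[-1]:
            continue
        assert compute_auc(tr) == pytest.approx(
            brute_force_auc(tr, w0, w1), rel=2e-4, abs=1e-6)
        assert compute_latency(tr) == times[int(np.argmax(sig))] - times[0]
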