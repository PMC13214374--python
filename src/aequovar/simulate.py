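"""Synthetic-data generator for the whole pipeline.

Emulates the statistical structure of the aequorin bioassay — plates with
per-plate wild-type controls, independent transfections (biological
replicates) with technical replicates, and variant-effect archetypes
(non-functional, reduced amplitude, delayed, wild-type-like) — plus
variant annotation tables whose predictor scores are noisy monotone
transforms of the simulated severity, so the concordance and ROC stages
see realistic signal.

The luminescence transient is modelled as a log-normal-shaped pulse after
agonist injection: the assayed metrics (AUC, peak time) are what matter,
not the exact kinetics, so any shape with a controllable integral and
peak position serves. Noise is multiplicative log-normal per transfection
(biological) and per well (technical), plus a multiplicative plate effect
shared by all wells on a plate — which the per-plate wild-type
normalization cancels by design. Background luminescence defaults to
zero; the dark pre-injection baseline is what the no-response detector
keys on.

Everything is deterministic given the seed (integer-state generator, no
time-based seeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assay import LuminescenceTrace, Role
from .errors import ValidationError

__all__ = [
    "TraceArchetype",
    "ARCHETYPES",
    "TraceSimConfig",
    "CohortSpec",
    "simulate_trace",
    "simulate_cohort",
    "generate_variant_table",
    "validation_split",
]


@dataclass(frozen=True)
class TraceArchetype:
    """A variant-effect phenotype class for the trace generator."""

    name: str
    amplitude_ratio: float  # expected AUC relative to wild type
    latency_ratio: float    # expected peak time relative to wild type
    noise_cv: float = 0.05  # per-well (technical) coefficient of variation
    bio_cv: float = 0.05    # per-transfection (biological) coefficient of variation
    # construct-level variation: distinct variants of one archetype have
    # genuinely different mean responses, which is what spreads a control
    # group wider than any single variant's replicate scatter
    sample_cv: float = 0.08
    sample_latency_cv: float = 0.04

    def __post_init__(self) -> None:
        if self.amplitude_ratio < 0:
            raise ValidationError("amplitude_ratio must be >= 0")
        if self.latency_ratio <= 0 and self.amplitude_ratio > 0:
            raise ValidationError("latency_ratio must be > 0 for responsive archetypes")
        if self.noise_cv < 0 or self.bio_cv < 0:
            raise ValidationError("coefficients of variation must be >= 0")


ARCHETYPES: Mapping[str, TraceArchetype] = {
    "wildtype_like": TraceArchetype("wildtype_like", 1.0, 1.0),
    "non_functional": TraceArchetype("non_functional", 0.0, 1.0),
    "reduced_amplitude": TraceArchetype("reduced_amplitude", 0.3, 1.0),
    "delayed": TraceArchetype("delayed", 1.0, 1.6),
    "reduced_and_delayed": TraceArchetype("reduced_and_delayed", 0.3, 1.6),
    "hyperfunctional": TraceArchetype("hyperfunctional", 1.5, 1.0),
}


@dataclass(frozen=True)
class TraceSimConfig:
    """Shape and sampling of a simulated luminescence measurement.

    The wild-type transient peaks ``wt_peak_delay`` seconds after
    injection with unit shape amplitude scaled to ``wt_peak_rlu``; the
    default measurement (330 s at 2-s sampling, injection at 30 s) covers
    the standard AUC window of 279 s starting 14 s post-injection.
    """

    duration_s: float = 330.0
    dt_s: float = 2.0
    injection_time_s: float = 30.0
    baseline_rlu: float = 0.0
    wt_peak_rlu: float = 1000.0
    wt_peak_delay_s: float = 30.0
    pulse_width: float = 0.5  # log-domain width of the transient
    latency_jitter_cv: float = 0.03


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))


def _pulse(times: np.ndarray, t_inj: float, peak_delay: float, width: float,
           ) -> np.ndarray:
    """Log-normal-shaped transient with unit peak at t_inj + peak_delay."""
    out = np.zeros_like(times)
    after = times > t_inj
    x = (times[after] - t_inj) / peak_delay
    out[after] = np.exp(-np.log(x) ** 2 / (2 * width ** 2))
    return out


def simulate_trace(archetype: TraceArchetype, rng: np.random.Generator,
                   config: TraceSimConfig | None = None,
                   *, well_id: str = "w", sample_id: str = "s",
                   role: Role = Role.VARIANT,
                   bio_factor: float = 1.0, plate_factor: float = 1.0,
                   latency_factor: float = 1.0,
                   ) -> LuminescenceTrace:
    """One well's trace; deterministic given the generator state.

    ``bio_factor`` carries the shared per-transfection amplitude factor so
    that technical replicates of the same biological replicate correlate.
    """
    config = config or TraceSimConfig()
    times = np.arange(0.0, config.duration_s + config.dt_s / 2, config.dt_s)
    amp = (config.wt_peak_rlu * archetype.amplitude_ratio
           * bio_factor * plate_factor
           * _lognormal_factor(rng, archetype.noise_cv))
    peak_delay = (config.wt_peak_delay_s * archetype.latency_ratio * latency_factor
                  * _lognormal_factor(rng, config.latency_jitter_cv))
    signal = config.baseline_rlu + amp * _pulse(
        times, config.injection_time_s, peak_delay, config.pulse_width)
    return LuminescenceTrace(
        well_id=well_id, sample_id=sample_id, role=role,
        times=times, signal=np.clip(signal, 0.0, None),
        injection_time=config.injection_time_s)


@dataclass(frozen=True)
class CohortSpec:
    """Size and composition of a simulated assay cohort.

    ``archetype_mix`` maps archetype names to proportions of the variant
    cohort (deterministic largest-remainder allocation, then a seeded
    shuffle). Controls are benign-like constructs simulated from the
    wild-type-like archetype. Biological replicate *b* of every sample is
    plated on plate ``(b - 1) mod n_plates``, and every plate carries its
    own wild-type control wells.
    """

    n_variants: int = 20
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"wildtype_like": 0.25, "non_functional": 0.35,
                                 "reduced_amplitude": 0.25, "delayed": 0.15})
    n_controls_benign: int = 3
    n_controls_homology: int = 17
    n_plates: int = 3
    bio_replicates: int = 3
    tech_replicates: int = 3
    plate_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("archetype_mix proportions must sum to 1")
        for name, count in (("n_variants", self.n_variants),
                            ("n_plates", self.n_plates),
                            ("bio_replicates", self.bio_replicates),
                            ("tech_replicates", self.tech_replicates)):
            if count < 1:
                raise ValidationError(f"CohortSpec.{name} must be >= 1")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes: {sorted(unknown)}")


def _allocate_archetypes(spec: CohortSpec, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of archetypes, then a seeded shuffle."""
    names = sorted(spec.archetype_mix)
    ideal = {n: spec.archetype_mix[n] * spec.n_variants for n in names}
    counts = {n: int(np.floor(ideal[n])) for n in names}
    short = spec.n_variants - sum(counts.values())
    for n in sorted(names, key=lambda n: ideal[n] - counts[n], reverse=True)[:short]:
        counts[n] += 1
    assignment = [n for n in names for _ in range(counts[n])]
    rng.shuffle(assignment)
    return assignment


def simulate_cohort(spec: CohortSpec, config: TraceSimConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full long-format cohort: (trace table, control manifest, truth table).

    The truth table records each sample's archetype and its expected
    amplitude/latency ratios for parameter-recovery checks.
    """
    config = config or TraceSimConfig()
    rng = np.random.default_rng(spec.seed)
    assignment = _allocate_archetypes(spec, rng)
    samples = [(f"VAR{i + 1:03d}", ARCHETYPES[a], Role.VARIANT, None)
               for i, a in enumerate(assignment)]
    samples += [(f"CTRLB{i + 1:02d}", ARCHETYPES["wildtype_like"], Role.VARIANT,
                 "gnomad_benign") for i in range(spec.n_controls_benign)]
    samples += [(f"CTRLH{i + 1:02d}", ARCHETYPES["wildtype_like"], Role.VARIANT,
                 "homology_control") for i in range(spec.n_controls_homology)]
    samples += [("CNGA3_WT", ARCHETYPES["wildtype_like"], Role.WILDTYPE_CONTROL, None),
                ("UT", ARCHETYPES["non_functional"], Role.UNTRANSFECTED, None)]

    plate_factors = {f"P{p + 1}": _lognormal_factor(rng, spec.plate_effect_sd)
                     for p in range(spec.n_plates)}
    rows = []
    for sample_id, arch, role, _ in samples:
        # wild-type wells define the normalization denominator; they carry
        # no construct effect by definition
        if role is Role.WILDTYPE_CONTROL:
            sample_factor, sample_lat = 1.0, 1.0
        else:
            sample_factor = _lognormal_factor(rng, arch.sample_cv)
            sample_lat = _lognormal_factor(rng, arch.sample_latency_cv)
        for b in range(1, spec.bio_replicates + 1):
            plate = f"P{(b - 1) % spec.n_plates + 1}"
            bio_factor = sample_factor * _lognormal_factor(rng, arch.bio_cv)
            for t in range(1, spec.tech_replicates + 1):
                well = f"{sample_id}.b{b}.t{t}"
                trace = simulate_trace(
                    arch, rng, config, well_id=well, sample_id=sample_id,
                    role=role, bio_factor=bio_factor,
                    plate_factor=plate_factors[plate],
                    latency_factor=sample_lat)
                rows.append(pd.DataFrame({
                    "plate_id": plate, "well_id": well, "sample_id": sample_id,
                    "role": role.value, "bio_replicate": b, "tech_replicate": t,
                    "time_s": trace.times, "rlu": trace.signal,
                    "injection_time_s": trace.injection_time,
                }))
    traces = pd.concat(rows, ignore_index=True)
    manifest = pd.DataFrame(
        [{"sample_id": s, "control_type": ctype}
         for s, _, _, ctype in samples if ctype is not None])
    truth = pd.DataFrame(
        [{"sample_id": s, "archetype": arch.name,
          "amplitude_ratio": arch.amplitude_ratio,
          "latency_ratio": arch.latency_ratio}
         for s, arch, role, _ in samples if role is Role.VARIANT])
    return traces, manifest, truth


def _severity(amplitude_ratio: float, latency_ratio: float) -> float:
    """True deleteriousness in [0, 1] implied by the archetype ratios."""
    sev = float(np.clip(1.0 - amplitude_ratio, 0.0, 1.0))
    if latency_ratio != 1.0:
        sev = max(sev, 0.5)
    return sev


def generate_variant_table(truth: pd.DataFrame, seed: int,
                           severity_noise_sd: float = 0.12,
                           n_common: int = 1,
                           clz_fraction: float = 0.05,
                           ) -> pd.DataFrame:
    """Variant annotation table with predictor scores correlated to truth.

    Predictor scores are the true severity plus Gaussian noise, clipped to
    each score's documented range; allele frequencies are mostly rare
    (log-uniform) with ``n_common`` common alleles to exercise the BA1 /
    BS1 / BS2 gates; a ``clz_fraction`` of variants is flagged as lying in
    the CLZ assembly domain.
    """
    rng = np.random.default_rng(seed)
    rows = []
    controls = truth["sample_id"].str.startswith("CTRL")
    n = len(truth)
    common_idx = set(rng.choice(np.flatnonzero(controls.to_numpy()), size=min(
        n_common, int(controls.sum())), replace=False)) if n_common else set()
    clz_idx = set(rng.choice(n, size=int(round(clz_fraction * n)), replace=False))
    for i, rec in enumerate(truth.itertuples()):
        sev = _severity(rec.amplitude_ratio, rec.latency_ratio)
        def score(lo=0.0, hi=1.0, scale=1.0):
            return float(np.clip(scale * sev + rng.normal(0, severity_noise_sd * scale),
                                 lo, hi))
        if i in common_idx:
            af = float(rng.uniform(0.05, 0.2))
            homozygotes = int(rng.integers(3, 50))
        else:
            af = float(10 ** rng.uniform(-6, -4))
            homozygotes = 0
        pos = 10 + 7 * i
        rows.append({
            "variant_id": rec.sample_id,
            "hgvs_c": f"c.{3 * pos - 1}A>G", "hgvs_p": f"p.(K{pos}R)",
            "grpmax_filtering_af": af, "popmax_af": af,
            "homozygote_count": homozygotes,
            "revel": score(), "spliceai": float(np.clip(rng.normal(0.02, 0.02), 0, 1)),
            "alphamissense": score(), "cpt1": score(),
            "cadd_phred": score(hi=99.0, scale=40.0), "primateai": score(),
            "domain_label": "CLZ" if i in clz_idx else "",
            "in_clz": i in clz_idx,
            "trans_lp_allele": bool(rng.random() < 0.3) if sev > 0.5 else None,
            "archetype": rec.archetype,
        })
    return pd.DataFrame(rows)


def validation_split() -> tuple[list, list, "object"]:
    """The assay-validation design as a ready-made results fixture.

    Encodes the per-variant parameter states of the 50-variant validation
    set — 20 benign-direction controls (19 with both mean±SD intervals
    inside the z-score bands, 1 with the AUC interval overlapping a band
    edge) and 30 likely-pathogenic variants (23 without any luminescence
    response, 4 with a reduced AUC and normal latency, 1 with reduced AUC
    and increased latency, 1 with both parameters inside, 1 with the AUC
    interval overlapping) — as normalized mean±SD values against a fixed
    threshold set.

    Returns ``(controls, lp_variants, thresholds)``.
    """
    from .assay import VariantAssayResult
    from .classify import ThresholdSet

    # bands (0.8, 1.2) for AUC and (0.85, 1.15) for latency at z = 2.56
    thresholds = ThresholdSet(
        z_multiplier=2.56,
        auc_mean_control=1.0, auc_sd_control=0.2 / 2.56,
        latency_mean_control=1.0, latency_sd_control=0.15 / 2.56)

    def res(sid, auc, auc_sd, lat, lat_sd, nonfunc=False):
        return VariantAssayResult(
            sample_id=sid, auc_norm_mean=auc, auc_norm_sd=auc_sd,
            latency_norm_mean=lat, latency_norm_sd=lat_sd,
            n_biological=3, non_functional=nonfunc)

    controls = [res(f"CTRL{i + 1:02d}", 1.0, 0.05, 1.0, 0.05) for i in range(19)]
    controls.append(res("CTRL20", 0.82, 0.05, 1.0, 0.05))  # AUC interval on the edge
    lp = [res(f"LP{i + 1:02d}", 0.0, 0.0, 0.0, 0.0, nonfunc=True) for i in range(23)]
    lp += [res(f"LP{i + 24:02d}", 0.3, 0.1, 1.0, 0.05) for i in range(4)]
    lp.append(res("LP28", 0.3, 0.1, 1.5, 0.1))   # reduced AUC, increased latency
    lp.append(res("LP29", 1.0, 0.05, 1.0, 0.05))  # CLZ-domain-like: appears normal
    lp.append(res("LP30", 0.82, 0.05, 1.0, 0.05))  # hits the threshold
    return controls, lp, thresholds
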