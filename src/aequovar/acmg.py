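"""Semi-automated ACMG/AMP criteria evaluation and five-tier combining.

Implements the numeric evidence gates used for *CNGA1* missense variants —
population-frequency criteria (BA1, BS1, BS2, PM2, PM3), in-silico
criteria (PP3 from REVEL bands and SpliceAI, BP4), and assay-derived
functional criteria (PS3/BS3 at OddsPath-calibrated strengths, withheld
for CLZ-domain and functionally uncertain variants) — and combines the
resulting evidence items into the five-tier scale B < LB < VUS < LP < P
using the standard combining rules. Evidence items carry an explicit
strength, so strength-modified criteria (PM2_supporting, PS3_moderate, …)
count in the tier of their applied strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calibration import STRENGTH_RANK, EvidenceStrength
from .classify import FunctionalCategory
from .errors import ValidationError

__all__ = [
    "AcmgClass",
    "EvidenceItem",
    "VariantAnnotation",
    "RuleConfig",
    "criterion_direction",
    "evaluate_population_criteria",
    "evaluate_insilico_criteria",
    "apply_functional_evidence",
    "combine_criteria",
    "reclassification_report",
    "ReclassificationReport",
]


class AcmgClass(IntEnum):
    """Five-tier classification, totally ordered B < LB < VUS < LP < P."""

    B = 0
    LB = 1
    VUS = 2
    LP = 3
    P = 4

    def __str__(self) -> str:  # noqa: D105 - report-friendly label
        return self.name


_DEFAULT_STRENGTH = {
    "PVS": EvidenceStrength.VERY_STRONG,
    "PS": EvidenceStrength.STRONG,
    "PM": EvidenceStrength.MODERATE,
    "PP": EvidenceStrength.SUPPORTING,
    "BA": EvidenceStrength.STAND_ALONE,
    "BS": EvidenceStrength.STRONG,
    "BP": EvidenceStrength.SUPPORTING,
}


def _criterion_prefix(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix) and code[len(prefix):].isdigit():
            return prefix
    raise ValidationError(f"unknown ACMG criterion code {code!r}")


def criterion_direction(code: str) -> str:
    """'pathogenic' or 'benign', from the criterion code prefix."""
    return "benign" if _criterion_prefix(code).startswith("B") else "pathogenic"


@dataclass(frozen=True)
class EvidenceItem:
    """One applied criterion at an explicit strength."""

    criterion: str
    strength: EvidenceStrength | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        prefix = _criterion_prefix(self.criterion)
        if self.strength is None:
            object.__setattr__(self, "strength", _DEFAULT_STRENGTH[prefix])
        if self.strength is EvidenceStrength.NONE:
            raise ValidationError("an applied criterion cannot have strength 'none'")
        if self.strength is EvidenceStrength.STAND_ALONE and prefix != "BA":
            raise ValidationError(
                f"stand-alone strength is reserved for BA1, got {self.criterion}")
        if (self.strength is EvidenceStrength.VERY_STRONG
                and criterion_direction(self.criterion) == "benign"):
            raise ValidationError(
                f"very-strong strength is not admissible for benign criterion "
                f"{self.criterion}")

    @property
    def direction(self) -> str:
        return criterion_direction(self.criterion)

    @property
    def label(self) -> str:
        return f"{self.criterion}_{self.strength.value}"


@dataclass
class VariantAnnotation:
    """Pre-computed per-variant annotation consumed by the rule engine.

    Frequencies are proportions; ``None`` means the field is missing from
    the source database (absence of data, not zero). Scores live in their
    documented ranges: 0-1 for REVEL, SpliceAI, AlphaMissense, CPT-1 and
    PrimateAI, 0-99 for CADD_Phred.
    """

    variant_id: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    grpmax_filtering_af: float | None = None
    popmax_af: float | None = None
    homozygote_count: int | None = None
    revel: float | None = None
    spliceai: float | None = None
    alphamissense: float | None = None
    cpt1: float | None = None
    cadd_phred: float | None = None
    primateai: float | None = None
    domain_label: str = ""
    in_clz: bool = False
    trans_lp_allele: bool | None = None

    def __post_init__(self) -> None:
        for name in ("grpmax_filtering_af", "popmax_af"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.variant_id}: {name} = {v} out of [0, 1]")
        if self.homozygote_count is not None and self.homozygote_count < 0:
            raise ValidationError(f"{self.variant_id}: homozygote_count < 0")
        for name in ("revel", "spliceai", "alphamissense", "cpt1", "primateai"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.variant_id}: {name} = {v} out of [0, 1]")
        if self.cadd_phred is not None and not 0.0 <= self.cadd_phred <= 99.0:
            raise ValidationError(
                f"{self.variant_id}: cadd_phred = {self.cadd_phred} out of [0, 99]")


@dataclass(frozen=True)
class RuleConfig:
    """Numeric gates of the rule engine.

    Defaults are the study's operating points: BA1 above 5% grpmax
    filtering AF; BS1 above the maximum credible AF for recessive RP
    (0.00297); BS2 for more than two population homozygotes; PM3 below a
    PopMax AF of 0.0022%; PP3_supporting from SpliceAI >= 0.2; BP4 only
    when SpliceAI <= 0.1 and REVEL <= 0.29. REVEL pathogenic bands follow
    the published calibrated thresholds. PM2 defaults to supporting
    strength with the rarity bound reused from the PM3 gate.
    """

    ba1_af: float = 0.05
    bs1_af: float = 0.00297
    bs2_min_homozygotes: int = 3
    pm2_max_af: float = 2.2e-5
    pm2_strength: EvidenceStrength = EvidenceStrength.SUPPORTING
    pm3_max_popmax_af: float = 2.2e-5
    pm3_require_trans: bool = False
    pp3_spliceai_min: float = 0.2
    bp4_spliceai_max: float = 0.1
    bp4_revel_max: float = 0.29
    #: (minimum REVEL score, strength) bands for pathogenic in-silico support
    revel_pathogenic_bands: tuple[tuple[float, EvidenceStrength], ...] = (
        (0.932, EvidenceStrength.STRONG),
        (0.773, EvidenceStrength.MODERATE),
        (0.644, EvidenceStrength.SUPPORTING),
    )
    alphamissense_lb_max: float = 0.34
    alphamissense_lp_min: float = 0.564
    ps3_default_strength: EvidenceStrength = EvidenceStrength.STRONG
    bs3_default_strength: EvidenceStrength = EvidenceStrength.SUPPORTING


def evaluate_population_criteria(ann: VariantAnnotation,
                                 config: RuleConfig | None = None,
                                 ) -> list[EvidenceItem]:
    """Frequency-based criteria; missing fields emit nothing except PM2,
    which treats absence from population data as rarity."""
    config = config or RuleConfig()
    items: list[EvidenceItem] = []
    af = ann.grpmax_filtering_af
    if af is not None and af > config.ba1_af:
        items.append(EvidenceItem("BA1", rationale=f"grpmax filtering AF {af} > {config.ba1_af}"))
    elif af is not None and af > config.bs1_af:
        items.append(EvidenceItem("BS1", rationale=f"grpmax filtering AF {af} > {config.bs1_af}"))
    if ann.homozygote_count is not None and ann.homozygote_count >= config.bs2_min_homozygotes:
        items.append(EvidenceItem(
            "BS2", rationale=f"{ann.homozygote_count} population homozygotes"))
    if af is None or af < config.pm2_max_af:
        items.append(EvidenceItem(
            "PM2", strength=config.pm2_strength,
            rationale="absent from population data" if af is None
            else f"grpmax filtering AF {af} < {config.pm2_max_af}"))
    if ann.popmax_af is not None and ann.popmax_af < config.pm3_max_popmax_af:
        if ann.trans_lp_allele is True:
            items.append(EvidenceItem(
                "PM3", strength=EvidenceStrength.MODERATE,
                rationale="rare and observed in trans with an LP allele"))
        elif ann.trans_lp_allele is None and not config.pm3_require_trans:
            # AF gate alone, at conservative supporting strength
            items.append(EvidenceItem(
                "PM3", strength=EvidenceStrength.SUPPORTING,
                rationale=f"PopMax AF {ann.popmax_af} < {config.pm3_max_popmax_af}"))
    return items


def evaluate_insilico_criteria(ann: VariantAnnotation,
                               config: RuleConfig | None = None,
                               ) -> list[EvidenceItem]:
    """Computational-prediction criteria: one PP3 item at the maximum
    strength triggered by REVEL bands or the SpliceAI gate (never
    stacked), and BP4 only when both SpliceAI and REVEL are benign."""
    config = config or RuleConfig()
    items: list[EvidenceItem] = []
    pp3: EvidenceStrength | None = None
    reasons = []
    if ann.revel is not None:
        for bound, strength in config.revel_pathogenic_bands:
            if ann.revel >= bound:
                pp3, reasons = strength, [f"REVEL {ann.revel} >= {bound}"]
                break
    if ann.spliceai is not None and ann.spliceai >= config.pp3_spliceai_min:
        if pp3 is None or STRENGTH_RANK[pp3] < STRENGTH_RANK[EvidenceStrength.SUPPORTING]:
            pp3 = pp3 or EvidenceStrength.SUPPORTING
        reasons.append(f"SpliceAI {ann.spliceai} >= {config.pp3_spliceai_min}")
    if pp3 is not None:
        items.append(EvidenceItem("PP3", strength=pp3, rationale="; ".join(reasons)))
    if (ann.spliceai is not None and ann.spliceai <= config.bp4_spliceai_max
            and ann.revel is not None and ann.revel <= config.bp4_revel_max):
        items.append(EvidenceItem(
            "BP4", rationale=f"SpliceAI {ann.spliceai} <= {config.bp4_spliceai_max} "
                             f"and REVEL {ann.revel} <= {config.bp4_revel_max}"))
    return items


def apply_functional_evidence(ann: VariantAnnotation,
                              category: FunctionalCategory,
                              ps3_strength: EvidenceStrength | None = None,
                              bs3_strength: EvidenceStrength | None = None,
                              config: RuleConfig | None = None,
                              ) -> list[EvidenceItem]:
    """PS3/BS3 from the bioassay category at OddsPath-calibrated strengths.

    The homomeric surrogate assay cannot report on assembly-domain (CLZ)
    variants, and uncertain readouts are uninformative: neither receives
    functional evidence. Incomplete-missplicing minigene results likewise
    never contribute evidence here.
    """
    config = config or RuleConfig()
    if ann.in_clz:
        return []
    if category is FunctionalCategory.ABNORMAL:
        return [EvidenceItem("PS3", strength=ps3_strength or config.ps3_default_strength,
                             rationale="functionally abnormal in the aequorin bioassay")]
    if category is FunctionalCategory.NORMAL:
        return [EvidenceItem("BS3", strength=bs3_strength or config.bs3_default_strength,
                             rationale="functionally normal in the aequorin bioassay")]
    return []


def _tier_counts(evidence: Iterable[EvidenceItem]) -> tuple[dict, dict]:
    """Collapse duplicate criteria to their maximum strength, then count
    items per direction and strength tier."""
    best: dict[str, EvidenceItem] = {}
    for item in evidence:
        prev = best.get(item.criterion)
        if prev is None or STRENGTH_RANK[item.strength] > STRENGTH_RANK[prev.strength]:
            best[item.criterion] = item
    path = {s: 0 for s in EvidenceStrength}
    ben = {s: 0 for s in EvidenceStrength}
    for item in best.values():
        (ben if item.direction == "benign" else path)[item.strength] += 1
    return path, ben


def combine_criteria(evidence: Sequence[EvidenceItem]) -> AcmgClass:
    """Five-tier class from the standard evidence-combining rules.

    Simultaneously satisfied pathogenic and benign combinations are
    contradictory evidence and yield VUS; BA1 alone is stand-alone benign.
    """
    path, ben = _tier_counts(evidence)
    pvs = path[EvidenceStrength.VERY_STRONG]
    ps = path[EvidenceStrength.STRONG]
    pm = path[EvidenceStrength.MODERATE]
    pp = path[EvidenceStrength.SUPPORTING]
    ba = ben[EvidenceStrength.STAND_ALONE]
    bs = ben[EvidenceStrength.STRONG]
    bp = ben[EvidenceStrength.SUPPORTING]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return AcmgClass.VUS
    if pathogenic:
        return AcmgClass.P
    if likely_pathogenic:
        return AcmgClass.LP
    if benign:
        return AcmgClass.B
    if likely_benign:
        return AcmgClass.LB
    return AcmgClass.VUS


@dataclass
class ReclassificationReport:
    """Before/after classes plus aggregate transition statistics."""

    per_variant: pd.DataFrame
    transition_matrix: pd.DataFrame
    n_variants: int
    n_reclassified: int

    @property
    def pct_reclassified(self) -> float:
        return 100.0 * self.n_reclassified / self.n_variants

    def pct_reclassified_from(self, initial: AcmgClass) -> float:
        """Percent of variants starting in ``initial`` that changed class."""
        sub = self.per_variant[self.per_variant["initial_class"] == initial.name]
        if sub.empty:
            raise ValidationError(f"no variants with initial class {initial.name}")
        return 100.0 * float((sub["final_class"] != sub["initial_class"]).mean())


def reclassification_report(initial: Mapping[str, AcmgClass],
                            final: Mapping[str, AcmgClass]) -> ReclassificationReport:
    """Compare two classification runs over the same variant set."""
    if set(initial) != set(final):
        raise ValidationError("initial and final runs cover different variant sets")
    names = [c.name for c in AcmgClass]
    per_variant = pd.DataFrame({
        "variant_id": list(initial),
        "initial_class": [initial[v].name for v in initial],
        "final_class": [final[v].name for v in initial],
    })
    matrix = pd.DataFrame(0, index=names, columns=names)
    for v in initial:
        matrix.loc[initial[v].name, final[v].name] += 1
    n_recls = int((per_variant["initial_class"] != per_variant["final_class"]).sum())
    return ReclassificationReport(
        per_variant=per_variant, transition_matrix=matrix,
        n_variants=len(per_variant), n_reclassified=n_recls)
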