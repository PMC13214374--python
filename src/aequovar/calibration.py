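"""OddsPath calibration of functional evidence and the BS1 frequency bound.

A functional assay earns its ACMG/AMP evidence strength from how well it
separates known pathogenic from known benign control variants. The
OddsPath likelihood ratio compares the proportion of pathogenic variants
in the whole control set (the prior, P1) with the proportion among
variants sharing a given readout (P2):

    OddsPath = [P2 / (1 - P2)] / [P1 / (1 - P1)]

Large values support pathogenicity (PS3), values near zero support a
benign interpretation (BS3); band thresholds map the ratio to an evidence
strength. When a readout cell is empty (e.g. no benign control scored
abnormal) a single opposite-class pseudo-count keeps the ratio finite and
conservative.

The module also provides the maximum credible population allele frequency
for a recessive (or dominant) disease model, the numeric gate behind the
BS1 criterion: an allele more frequent than what disease prevalence,
heterogeneity and penetrance can jointly support is evidence against
pathogenicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import DegenerateReadoutError, ValidationError

__all__ = [
    "PseudoCountPolicy",
    "EvidenceStrength",
    "OddsPathInput",
    "OddsPathResult",
    "StrengthBands",
    "DiseaseModel",
    "compute_oddspath",
    "map_oddspath_to_strength",
    "max_credible_af",
]


class PseudoCountPolicy(str, Enum):
    NONE = "none"
    ADD_ONE_OPPOSITE_IF_EMPTY = "add_one_opposite_if_empty"


class EvidenceStrength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NONE = "none"


#: rank used when collapsing/capping strengths (higher = stronger)
STRENGTH_RANK = {
    EvidenceStrength.NONE: 0,
    EvidenceStrength.SUPPORTING: 1,
    EvidenceStrength.MODERATE: 2,
    EvidenceStrength.STRONG: 3,
    EvidenceStrength.VERY_STRONG: 4,
    EvidenceStrength.STAND_ALONE: 5,
}


@dataclass(frozen=True)
class OddsPathInput:
    """Counts of the OddsPath contingency: the prior control set and the
    subset falling into one assay readout category."""

    n_pathogenic_controls: int
    n_benign_controls: int
    n_pathogenic_in_readout: int
    n_benign_in_readout: int
    pseudo_count_policy: PseudoCountPolicy = PseudoCountPolicy.ADD_ONE_OPPOSITE_IF_EMPTY

    def __post_init__(self) -> None:
        counts = (self.n_pathogenic_controls, self.n_benign_controls,
                  self.n_pathogenic_in_readout, self.n_benign_in_readout)
        if any(c < 0 for c in counts):
            raise ValidationError("OddsPath counts must be >= 0")
        if self.n_pathogenic_controls + self.n_benign_controls == 0:
            raise ValidationError("OddsPath prior has no controls")
        if self.n_pathogenic_in_readout + self.n_benign_in_readout == 0:
            raise ValidationError("OddsPath readout category is empty")


@dataclass(frozen=True)
class OddsPathResult:
    p1: float
    p2: float
    oddspath: float


def compute_oddspath(inp: OddsPathInput) -> OddsPathResult:
    """Likelihood ratio of pathogenicity for one readout category."""
    n_path, n_ben = inp.n_pathogenic_in_readout, inp.n_benign_in_readout
    if inp.pseudo_count_policy is PseudoCountPolicy.ADD_ONE_OPPOSITE_IF_EMPTY:
        if n_ben == 0 and n_path > 0:
            n_ben = 1
        elif n_path == 0 and n_ben > 0:
            n_path = 1
    p1 = inp.n_pathogenic_controls / (inp.n_pathogenic_controls + inp.n_benign_controls)
    p2 = n_path / (n_path + n_ben)
    if not 0.0 < p1 < 1.0:
        raise DegenerateReadoutError(
            f"prior proportion pathogenic P1 = {p1}; the control set needs "
            "both pathogenic and benign variants")
    if not 0.0 < p2 < 1.0:
        raise DegenerateReadoutError(
            f"readout proportion pathogenic P2 = {p2} after pseudo-count "
            f"policy {inp.pseudo_count_policy.value!r}; enable "
            "add_one_opposite_if_empty to regularize an empty cell")
    oddspath = (p2 / (1.0 - p2)) / (p1 / (1.0 - p1))
    return OddsPathResult(p1=p1, p2=p2, oddspath=oddspath)


@dataclass(frozen=True)
class StrengthBands:
    """OddsPath thresholds mapping the likelihood ratio to a strength.

    Defaults follow the published OddsPath calibration bands: pathogenic
    evidence at >= 2.1 (supporting), >= 4.3 (moderate), >= 18.7 (strong),
    >= 350 (very strong); benign evidence mirrored at the reciprocals.
    ``benign_cap`` limits the strength applied in the benign direction — a
    conservative downgrade (e.g. BS3 applied only at supporting strength)
    regardless of how small the ratio is.
    """

    pathogenic_very_strong: float = 350.0
    pathogenic_strong: float = 18.7
    pathogenic_moderate: float = 4.3
    pathogenic_supporting: float = 2.1
    benign_very_strong: float = 1 / 350.0
    benign_strong: float = 0.053
    benign_moderate: float = 0.23
    benign_supporting: float = 0.48
    benign_cap: EvidenceStrength | None = EvidenceStrength.SUPPORTING
    #: relative tolerance when comparing the ratio to a band edge, matching
    #: the printed precision at which OddsPath values are reported (a ratio
    #: of 18.67 reported as 18.7 earns the >= 18.7 band)
    rel_tol: float = 0.005


def map_oddspath_to_strength(oddspath: float, direction: str,
                             bands: StrengthBands | None = None) -> EvidenceStrength:
    """Evidence strength earned by an OddsPath ratio in a given direction."""
    bands = bands or StrengthBands()
    if oddspath <= 0:
        raise ValidationError(f"oddspath must be positive, got {oddspath}")
    tol = bands.rel_tol
    if direction == "pathogenic":
        if oddspath >= bands.pathogenic_very_strong * (1 - tol):
            return EvidenceStrength.VERY_STRONG
        if oddspath >= bands.pathogenic_strong * (1 - tol):
            return EvidenceStrength.STRONG
        if oddspath >= bands.pathogenic_moderate * (1 - tol):
            return EvidenceStrength.MODERATE
        if oddspath >= bands.pathogenic_supporting * (1 - tol):
            return EvidenceStrength.SUPPORTING
        return EvidenceStrength.NONE
    if direction == "benign":
        if oddspath <= bands.benign_very_strong * (1 + tol):
            strength = EvidenceStrength.VERY_STRONG
        elif oddspath <= bands.benign_strong * (1 + tol):
            strength = EvidenceStrength.STRONG
        elif oddspath <= bands.benign_moderate * (1 + tol):
            strength = EvidenceStrength.MODERATE
        elif oddspath <= bands.benign_supporting * (1 + tol):
            strength = EvidenceStrength.SUPPORTING
        else:
            strength = EvidenceStrength.NONE
        if (bands.benign_cap is not None and strength is not EvidenceStrength.NONE
                and STRENGTH_RANK[strength] > STRENGTH_RANK[bands.benign_cap]):
            strength = bands.benign_cap
        return strength
    raise ValidationError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class DiseaseModel:
    """Population-genetics model behind the maximum credible allele frequency.

    Parameters (all proportions in (0, 1]):

    prevalence
        Disease prevalence in the population (e.g. 1/4000 for retinitis
        pigmentosa).
    genetic_heterogeneity
        Fraction of disease attributable to the gene.
    allelic_heterogeneity
        Fraction of the gene's disease burden attributable to the single
        most common pathogenic allele.
    penetrance
        Probability of disease given the causal genotype.
    """

    prevalence: float
    genetic_heterogeneity: float
    allelic_heterogeneity: float
    penetrance: float
    inheritance: str = "recessive"

    def __post_init__(self) -> None:
        for name in ("prevalence", "genetic_heterogeneity",
                     "allelic_heterogeneity", "penetrance"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"DiseaseModel.{name} must be in (0, 1], got {v}")
        if self.inheritance not in ("recessive", "dominant"):
            raise ValidationError(f"unknown inheritance {self.inheritance!r}")


def max_credible_af(model: DiseaseModel) -> float:
    """Maximum credible population allele frequency for a pathogenic allele.

    Recessive: the causal genotype frequency is prevalence × genetic
    heterogeneity / penetrance; under Hardy-Weinberg its allele frequency
    is the square root, of which the most common single allele contributes
    the allelic-heterogeneity fraction:

        AF_max = allelic_het × sqrt(prevalence × genetic_het / penetrance)

    Dominant: AF_max = prevalence × genetic_het × allelic_het / (2 × penetrance).
    """
    if model.inheritance == "recessive":
        return model.allelic_heterogeneity * math.sqrt(
            model.prevalence * model.genetic_heterogeneity / model.penetrance)
    return (model.prevalence * model.genetic_heterogeneity
            * model.allelic_heterogeneity) / (2.0 * model.penetrance)
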