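"""Concordance of variant-effect predictors with bioassay functional data.

The functional score FC (1 = wild-type-like, 0 = most severe) is
correlated with predictor scores (higher = more likely pathogenic), so a
well-performing predictor shows a *negative* Spearman rho. Predictor
scores are banded into likely-benign / uncertain / likely-pathogenic
calls with published thresholds; for predictors without published
thresholds a ROC analysis against the functional normal/abnormal labels
supplies a Youden-optimal operating point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .classify import FunctionalCategory
from .errors import UndefinedCorrelationError, ValidationError

__all__ = [
    "VepBanding",
    "VepCall",
    "ConcordanceResult",
    "spearman_correlation",
    "categorize_by_vep",
    "roc_threshold",
    "concordance_table",
]


@dataclass(frozen=True)
class VepBanding:
    """Score thresholds banding a predictor into B/uncertain/P calls."""

    predictor: str
    lb_max: float
    lp_min: float
    score_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not (lo <= self.lb_max <= self.lp_min <= hi):
            raise ValidationError(
                f"{self.predictor}: banding thresholds ({self.lb_max}, "
                f"{self.lp_min}) must be ordered within {self.score_range}")


class VepCall(str):
    B_LIKE = "B_like"
    UNCERTAIN = "uncertain"
    P_LIKE = "P_like"


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks handle ties. The p-value uses the t-approximation for
    n > 9 and exact permutation enumeration for n <= 9, where the
    large-sample approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-d score vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 pairs for a correlation, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        num = pc @ rxc
        denom = np.sqrt((rxc @ rxc) * np.sum(pc * pc, axis=1))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def categorize_by_vep(score: float, banding: VepBanding) -> str:
    """Band a predictor score into a B_like / uncertain / P_like call."""
    lo, hi = banding.score_range
    if not lo <= score <= hi:
        raise ValidationError(
            f"{banding.predictor}: score {score} outside range {banding.score_range}")
    if score < banding.lb_max:
        return VepCall.B_LIKE
    if score > banding.lp_min:
        return VepCall.P_LIKE
    return VepCall.UNCERTAIN


def roc_threshold(scores, labels) -> tuple[float, float]:
    """ROC analysis of a predictor against functional labels.

    ``labels`` are truthy for functionally abnormal (the positive class);
    higher scores are assumed to indicate pathogenicity. Returns the
    Youden-J-optimal threshold (a variant is called positive when its
    score exceeds the threshold) and the area under the ROC curve.
    Candidate thresholds are midpoints between consecutive distinct
    scores, so a separable cohort yields a cut strictly between the two
    class score ranges; J-ties resolve to the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be paired 1-d vectors")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC analysis needs both label classes")
    auc = float(roc_auc_score(labels, scores))
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValidationError("all scores identical; no threshold exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    tpr = np.array([(scores[labels] > c).mean() for c in cuts])
    fpr = np.array([(scores[~labels] > c).mean() for c in cuts])
    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[0])  # tie -> lower threshold
    return float(cuts[best]), auc


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-predictor agreement with the bioassay over definitive variants."""

    predictor: str
    n: int
    spearman_rho: float
    spearman_p: float
    fraction_correct: float
    fraction_discordant: float
    fraction_uncertain_calls: float


def concordance_table(data: pd.DataFrame, bandings: list[VepBanding],
                      fc_column: str = "FC",
                      category_column: str = "category",
                      clz_column: str | None = "in_clz",
                      ) -> pd.DataFrame:
    """Concordance fractions and rank correlation per predictor.

    ``data`` holds one row per variant with the functional score, the
    tri-category call and one score column per predictor. Variants with
    an uncertain functional category — and CLZ-domain variants, for which
    the homomeric assay readout is unreliable — are excluded up front.
    Missing predictor scores are skipped pairwise (complete cases per
    predictor). Correct = functionally normal called B_like plus
    functionally abnormal called P_like; discordant = crossed calls;
    the remainder are uncertain-band calls. The three fractions sum to 1.
    """
    keep = data[category_column].isin(
        [FunctionalCategory.NORMAL.value, FunctionalCategory.ABNORMAL.value])
    if clz_column is not None and clz_column in data.columns:
        keep &= ~data[clz_column].astype(bool)
    sub = data[keep]
    rows = []
    for banding in bandings:
        col = banding.predictor
        cc = sub[sub[col].notna() & sub[fc_column].notna()]
        if cc.empty:
            raise ValidationError(
                f"{col}: no variants with both a score and a definitive "
                "functional category")
        calls = cc[col].map(lambda s: categorize_by_vep(float(s), banding))
        normal = cc[category_column] == FunctionalCategory.NORMAL.value
        correct = ((normal & (calls == VepCall.B_LIKE))
                   | (~normal & (calls == VepCall.P_LIKE))).mean()
        discordant = ((normal & (calls == VepCall.P_LIKE))
                      | (~normal & (calls == VepCall.B_LIKE))).mean()
        uncertain = (calls == VepCall.UNCERTAIN).mean()
        rho, p = spearman_correlation(cc[fc_column].to_numpy(), cc[col].to_numpy())
        rows.append(ConcordanceResult(
            predictor=col, n=len(cc), spearman_rho=rho, spearman_p=p,
            fraction_correct=float(correct),
            fraction_discordant=float(discordant),
            fraction_uncertain_calls=float(uncertain)))
    return pd.DataFrame([r.__dict__ for r in rows])
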