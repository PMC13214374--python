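"""Criteria gates, evidence strengths and the five-tier combiner."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aequovar.acmg import (
    AcmgClass,
    EvidenceItem,
    RuleConfig,
    VariantAnnotation,
    apply_functional_evidence,
    combine_criteria,
    evaluate_insilico_criteria,
    evaluate_population_criteria,
    reclassification_report,
)
from aequovar.calibration import EvidenceStrength as S
from aequovar.classify import FunctionalCategory
from aequovar.errors import ValidationError


def ann(**kw):
    return VariantAnnotation(variant_id=kw.pop("variant_id", "v1"), **kw)


def codes(items):
    return {i.criterion: i.strength for i in items}


class TestPopulationCriteria:
    def test_common_allele_triggers_ba1(self):
        got = codes(evaluate_population_criteria(ann(grpmax_filtering_af=0.06)))
        assert "BA1" in got and "BS1" not in got

    def test_bs1_between_bounds(self):
        got = codes(evaluate_population_criteria(ann(grpmax_filtering_af=0.01)))
        assert "BS1" in got and "BA1" not in got

    def test_three_homozygotes_trigger_bs2(self):
        got = codes(evaluate_population_criteria(
            ann(grpmax_filtering_af=0.001, homozygote_count=3)))
        assert "BS2" in got
        got2 = codes(evaluate_population_criteria(
            ann(grpmax_filtering_af=0.001, homozygote_count=2)))
        assert "BS2" not in got2

    def test_pm3_on_rare_variant_with_trans_allele(self):
        got = codes(evaluate_population_criteria(
            ann(popmax_af=1e-5, trans_lp_allele=True)))
        assert got["PM3"] is S.MODERATE

    def test_pm3_af_gate_alone_is_supporting(self):
        got = codes(evaluate_population_criteria(ann(popmax_af=1e-5)))
        assert got["PM3"] is S.SUPPORTING

    def test_pm3_suppressed_when_confirmed_in_cis(self):
        got = codes(evaluate_population_criteria(
            ann(popmax_af=1e-5, trans_lp_allele=False)))
        assert "PM3" not in got

    def test_absent_from_population_gives_pm2_only(self):
        got = codes(evaluate_population_criteria(ann()))
        assert set(got) == {"PM2"}
        assert got["PM2"] is S.SUPPORTING

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValidationError):
            ann(grpmax_filtering_af=-0.1)


class TestInsilicoCriteria:
    def test_spliceai_alone_gives_pp3_supporting(self):
        got = codes(evaluate_insilico_criteria(ann(spliceai=0.25)))
        assert got["PP3"] is S.SUPPORTING

    def test_bp4_requires_both_scores_low(self):
        got = codes(evaluate_insilico_criteria(ann(spliceai=0.05, revel=0.2)))
        assert "BP4" in got
        assert "PP3" not in got

    def test_between_gates_emits_nothing(self):
        got = codes(evaluate_insilico_criteria(ann(spliceai=0.15, revel=0.5)))
        assert got == {}

    def test_revel_bands_set_pp3_strength(self):
        assert codes(evaluate_insilico_criteria(ann(revel=0.95)))["PP3"] is S.STRONG
        assert codes(evaluate_insilico_criteria(ann(revel=0.8)))["PP3"] is S.MODERATE
        assert codes(evaluate_insilico_criteria(ann(revel=0.7)))["PP3"] is S.SUPPORTING

    def test_revel_and_spliceai_never_stack(self):
        got = evaluate_insilico_criteria(ann(revel=0.8, spliceai=0.9))
        assert len([i for i in got if i.criterion == "PP3"]) == 1
        assert codes(got)["PP3"] is S.MODERATE

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            ann(revel=1.2)


class TestFunctionalEvidence:
    def test_abnormal_outside_clz_earns_ps3(self):
        got = codes(apply_functional_evidence(ann(), FunctionalCategory.ABNORMAL))
        assert got["PS3"] is S.STRONG

    def test_normal_outside_clz_earns_bs3_supporting(self):
        got = codes(apply_functional_evidence(ann(), FunctionalCategory.NORMAL))
        assert got["BS3"] is S.SUPPORTING

    def test_clz_variants_get_no_functional_evidence(self):
        assert apply_functional_evidence(
            ann(in_clz=True), FunctionalCategory.ABNORMAL) == []
        assert apply_functional_evidence(
            ann(in_clz=True), FunctionalCategory.NORMAL) == []

    def test_uncertain_gets_nothing(self):
        assert apply_functional_evidence(ann(), FunctionalCategory.UNCERTAIN) == []


# ---------------------------------------------------------------------------
# combiner: spec examples plus an exhaustive enumeration oracle

def _oracle_class(pvs, ps, pm, pp, ba, bs, bp):
    """Literal re-statement of the published combining table."""
    pathogenic_combos = (
        pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2),
        ps >= 2,
        ps == 1 and pm >= 3,
        ps == 1 and pm == 2 and pp >= 2,
        ps == 1 and pm == 1 and pp >= 4,
    )
    lp_combos = (
        pvs == 1 and pm == 1,
        ps == 1 and (pm == 1 or pm == 2),
        ps == 1 and pp >= 2,
        pm >= 3,
        pm == 2 and pp >= 2,
        pm == 1 and pp >= 4,
    )
    benign_combos = (ba >= 1, bs >= 2)
    lb_combos = (bs == 1 and bp == 1, bp >= 2)
    # "greater or equal" reading for the counts the table states exactly
    path = any(pathogenic_combos) or (
        pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2)) or (
        ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    lp = any(lp_combos) or (pvs >= 1 and pm >= 1) or (
        ps >= 1 and pm >= 1) or (ps >= 1 and pp >= 2) or (
        pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)
    ben = any(benign_combos)
    lb = any(lb_combos) or (bs >= 1 and bp >= 1)
    if (path or lp) and (ben or lb):
        return AcmgClass.VUS
    if path:
        return AcmgClass.P
    if lp:
        return AcmgClass.LP
    if ben:
        return AcmgClass.B
    if lb:
        return AcmgClass.LB
    return AcmgClass.VUS


def _items(pvs, ps, pm, pp, ba, bs, bp):
    """Distinct criterion codes carrying the requested strength tiers."""
    items = []
    strengths = ([S.VERY_STRONG] * pvs + [S.STRONG] * ps
                 + [S.MODERATE] * pm + [S.SUPPORTING] * pp)
    for i, s in enumerate(strengths, start=1):
        items.append(EvidenceItem(f"PM{i}", strength=s))
    if ba:
        items.append(EvidenceItem("BA1"))
    bstr = [S.STRONG] * bs + [S.SUPPORTING] * bp
    for i, s in enumerate(bstr, start=1):
        items.append(EvidenceItem(f"BP{i}", strength=s))
    return items


class TestCombiner:
    def test_strong_plus_two_moderates_is_lp(self):
        items = [EvidenceItem("PS3", strength=S.STRONG),
                 EvidenceItem("PM2", strength=S.MODERATE),
                 EvidenceItem("PP3", strength=S.MODERATE)]
        assert combine_criteria(items) is AcmgClass.LP

    def test_ba1_alone_is_stand_alone_benign(self):
        assert combine_criteria([EvidenceItem("BA1")]) is AcmgClass.B

    def test_bs3_supporting_cannot_move_a_rare_variant(self):
        # BS3 at supporting strength plus PM2_supporting: neither side's
        # combinations are met, so the class stays VUS
        items = [EvidenceItem("BS3", strength=S.SUPPORTING),
                 EvidenceItem("PM2", strength=S.SUPPORTING)]
        assert combine_criteria(items) is AcmgClass.VUS

    def test_conflicting_evidence_is_vus(self):
        items = [EvidenceItem("PS1"), EvidenceItem("PS2"),
                 EvidenceItem("BS1"), EvidenceItem("BS2")]
        assert combine_criteria(items) is AcmgClass.VUS

    def test_duplicate_criteria_collapse_to_max_strength(self):
        items = [EvidenceItem("PP3", strength=S.SUPPORTING),
                 EvidenceItem("PP3", strength=S.STRONG),
                 EvidenceItem("PM2", strength=S.MODERATE)]
        assert combine_criteria(items) is AcmgClass.LP

    def test_exhaustive_enumeration_matches_oracle(self):
        """Every evidence multiset of size <= 6 over the seven strength
        atoms agrees with the literal rule-table oracle."""
        atoms = range(7)  # pvs, ps, pm, pp, ba, bs, bp
        n_checked = 0
        for size in range(7):
            for combo in itertools.combinations_with_replacement(atoms, size):
                counts = [combo.count(a) for a in atoms]
                if counts[4] > 1:
                    continue  # only one stand-alone criterion exists
                got = combine_criteria(_items(*counts))
                assert got is _oracle_class(*counts), (counts, got)
                n_checked += 1
        assert n_checked > 1300  # all multisets of size <= 6, one BA1 at most

    @given(st.lists(st.sampled_from(
        ["PVS1", "PS1", "PS2", "PM1", "PM2", "PP1", "PP2", "PP3"]),
        max_size=6))
    def test_adding_pathogenic_evidence_never_weakens(self, extra):
        base = [EvidenceItem("PM1"), EvidenceItem("PP1")]
        before = combine_criteria(base)
        after = combine_criteria(base + [EvidenceItem(c) for c in extra])
        assert after >= before  # no benign evidence present, so no conflict


class TestReclassification:
    def test_identical_runs_are_idempotent(self):
        classes = {"v1": AcmgClass.VUS, "v2": AcmgClass.LP}
        rep = reclassification_report(classes, dict(classes))
        assert rep.n_reclassified == 0

    def test_single_transition_is_one_off_diagonal(self):
        rep = reclassification_report({"v": AcmgClass.VUS}, {"v": AcmgClass.LP})
        m = rep.transition_matrix
        assert m.loc["VUS", "LP"] == 1
        assert m.to_numpy().sum() == 1

    def test_mirrored_vus_cohort_reclassifies_62_5_percent(self):
        # 56 VUS of which 33 gain decisive pathogenic and 2 decisive benign
        # evidence: 35/56 = 62.5% move
        initial = {f"v{i}": AcmgClass.VUS for i in range(56)}
        final = dict(initial)
        for i in range(33):
            final[f"v{i}"] = AcmgClass.LP
        for i in range(33, 35):
            final[f"v{i}"] = AcmgClass.LB
        rep = reclassification_report(initial, final)
        assert rep.pct_reclassified_from(AcmgClass.VUS) == pytest.approx(62.5)

    def test_mismatched_variant_sets_rejected(self):
        with pytest.raises(ValidationError):
            reclassification_report({"a": AcmgClass.VUS}, {"b": AcmgClass.VUS})


def test_round_trip_through_evidence_labels():
    """Serialized evidence labels re-parse to identical structures."""
    items = [EvidenceItem("PS3", strength=S.MODERATE, rationale="assay"),
             EvidenceItem("PM2", strength=S.SUPPORTING)]
    parsed = [EvidenceItem(lbl.rsplit("_", 1)[0] if not lbl.endswith("very_strong")
                           else lbl[:-len("_very_strong")],
                           strength=S(lbl.split("_", 1)[1]))
              for lbl in [i.label for i in items]]
    assert [(p.criterion, p.strength) for p in parsed] \
        == [(i.criterion, i.strength) for i in items]
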