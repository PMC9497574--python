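"""Screening rule: classification, cutoff tables, performance evaluation."""

import math

import pytest

from dcmscreen import (
    AgeBand,
    Classification,
    ConfusionTable,
    CutoffTable,
    Group,
    Sex,
    StratumKey,
    SubjectScore,
    Verdict,
    classify_combined,
    classify_single,
    derive_tool,
    evaluate_rule,
    likelihood_ratios,
    score_cohort,
    simulate_study,
    table1_defaults,
    youden_cutoff,
)
from dcmscreen.errors import ConfigurationError, InsufficientDataError
from dcmscreen.rule import TestSelector as Selector

M6069 = StratumKey(Sex.MALE, AgeBand.B60_69)


def make_score(stratum=M6069, group=Group.DCM, grt=15, grip=20.0, sid="s"):
    return SubjectScore(
        subject_id=sid, stratum=stratum, group=group, grt_min=grt, grip_min=grip
    )


class TestClassifySingle:
    @pytest.mark.parametrize(
        "value, cutoff, expected",
        [
            (17, 17, Classification.ABNORMAL),    # at the cutoff: abnormal
            (17.5, 17, Classification.NORMAL),    # strictly above: normal
            (0, 19, Classification.ABNORMAL),
            (16, 17, Classification.ABNORMAL),
        ],
    )
    def test_at_or_below_cutoff_is_abnormal(self, value, cutoff, expected):
        assert classify_single(value, cutoff) is expected


class TestClassifyCombined:
    def test_published_cutoffs_male_60s(self):
        table = CutoffTable.published()
        # male 60-69 cutoffs are GRT 17 / grip 29 kg
        grip_pos = make_score(grt=18, grip=28.5)
        assert classify_combined(grip_pos, table) is Verdict.POSITIVE
        both_neg = make_score(grt=18, grip=30.0)
        assert classify_combined(both_neg, table) is Verdict.NEGATIVE

    def test_exactly_at_both_cutoffs_is_positive(self):
        table = CutoffTable.published()
        assert classify_combined(make_score(grt=17, grip=29.0), table) is Verdict.POSITIVE

    def test_missing_stratum_is_configuration_error(self):
        table = CutoffTable({M6069: (17, 29)})
        other = make_score(stratum=StratumKey(Sex.FEMALE, AgeBand.B40_59))
        with pytest.raises(ConfigurationError):
            classify_combined(other, table)


class TestCutoffTable:
    def test_published_table_is_complete(self):
        table = CutoffTable.published()
        assert table.is_complete()
        assert table[M6069] == (17, 29)
        assert table[StratumKey(Sex.FEMALE, AgeBand.B80_89)] == (12, 10)

    def test_json_round_trip(self):
        table = CutoffTable.published()
        again = CutoffTable.from_json(table.to_json())
        assert dict(again.cutoffs) == {
            k: (float(g), float(p)) for k, (g, p) in table.cutoffs.items()
        }

    def test_text_rendering_mentions_rule(self):
        text = CutoffTable.published().to_text()
        assert "abnormal" in text
        assert "17" in text and "29" in text


class TestConfusionTable:
    def test_metrics(self):
        c = ConfusionTable(tp=17, fp=3, fn=8, tn=17)
        assert c.sensitivity == pytest.approx(0.68)
        assert c.specificity == pytest.approx(0.85)
        assert c.lr_pos == pytest.approx(0.68 / 0.15)
        assert c.lr_neg == pytest.approx(0.32 / 0.85)
        assert c.youden_j == pytest.approx(0.53)
        assert c.total == 45

    def test_undefined_metrics_are_nan(self):
        no_cases = ConfusionTable(tp=0, fp=2, fn=0, tn=8)
        assert math.isnan(no_cases.sensitivity)
        no_controls = ConfusionTable(tp=5, fp=0, fn=1, tn=0)
        assert math.isnan(no_controls.specificity)

    def test_addition_is_elementwise(self):
        a = ConfusionTable(1, 2, 3, 4)
        b = ConfusionTable(10, 20, 30, 40)
        assert a + b == ConfusionTable(11, 22, 33, 44)

    def test_perfect_specificity_gives_infinite_lr_pos(self):
        c = ConfusionTable(tp=8, fp=0, fn=4, tn=34)
        assert c.specificity == 1.0
        assert math.isinf(c.lr_pos)

    def test_likelihood_ratio_degenerate_cases(self):
        assert likelihood_ratios(1.0, 0.56) == (pytest.approx(1 / 0.44), 0.0)
        lr_pos, lr_neg = likelihood_ratios(0.0, 1.0)
        assert math.isnan(lr_pos)  # 0/0
        assert lr_neg == 1.0


class TestEvaluateRule:
    def test_counts_conserve_cohort_size(self):
        cohort = score_cohort(simulate_study(table1_defaults(), seed=9))
        perf = evaluate_rule(cohort, CutoffTable.published())
        assert sum(c.total for c in perf.strata.values()) == len(cohort)
        pooled = perf.pooled
        assert pooled.total == len(cohort)
        # pooled equals elementwise sum of stratum tables
        tp = sum(c.tp for c in perf.strata.values())
        assert pooled.tp == tp

    def test_perfectly_separated_stratum(self):
        table = CutoffTable({M6069: (17, 29)})
        cohort = [
            make_score(grt=10, grip=12.0, group=Group.DCM, sid="d1"),
            make_score(grt=12, grip=10.0, group=Group.DCM, sid="d2"),
            make_score(grt=20, grip=35.0, group=Group.CONTROL, sid="c1"),
            make_score(grt=22, grip=40.0, group=Group.CONTROL, sid="c2"),
        ]
        perf = evaluate_rule(cohort, table)
        assert perf.pooled.sensitivity == 1.0
        assert perf.pooled.specificity == 1.0

    def test_controls_only_stratum_flags_sensitivity_nan(self):
        table = CutoffTable({M6069: (17, 29)})
        cohort = [make_score(group=Group.CONTROL, grt=20, grip=35.0)]
        perf = evaluate_rule(cohort, table)
        assert math.isnan(perf.pooled.sensitivity)
        assert not math.isnan(perf.pooled.specificity)

    def test_empty_cohort_raises(self):
        with pytest.raises(InsufficientDataError):
            evaluate_rule([], CutoffTable.published())

    def test_or_rule_monotonicity(self):
        # the central screening trade-off: combining by OR can only gain
        # sensitivity and lose specificity relative to each component
        cohort = score_cohort(simulate_study(table1_defaults(), seed=13))
        table = derive_tool(cohort)
        combined = evaluate_rule(cohort, table, Selector.COMBINED)
        grt_only = evaluate_rule(cohort, table, Selector.GRT_ONLY)
        grip_only = evaluate_rule(cohort, table, Selector.GRIP_ONLY)
        for stratum in combined.strata:
            c = combined.strata[stratum]
            g = grt_only.strata[stratum]
            p = grip_only.strata[stratum]
            assert c.sensitivity >= max(g.sensitivity, p.sensitivity)
            assert c.specificity <= min(g.specificity, p.specificity)

    def test_to_frame_has_total_row(self):
        cohort = score_cohort(simulate_study(table1_defaults(), seed=9))
        frame = evaluate_rule(cohort, CutoffTable.published()).to_frame()
        assert list(frame["sex"])[-1] == "total"
        assert len(frame) == 9


class TestSplitCohort:
    def test_stratified_split_preserves_cells_and_size(self):
        from dcmscreen import split_cohort

        cohort = score_cohort(simulate_study(table1_defaults(), seed=29))
        train, test = split_cohort(cohort, test_fraction=0.25, seed=1)
        assert len(train) + len(test) == len(cohort)
        assert 0.2 < len(test) / len(cohort) < 0.3
        # every (stratum, group) cell keeps members on both sides
        def cells(scores):
            return {(s.stratum, s.group) for s in scores}
        assert cells(train) == cells(cohort)
        # held-out evaluation composes with the existing pipeline
        table = derive_tool(train)
        perf = evaluate_rule(test, table)
        assert perf.pooled.total == len(test)

    def test_bad_fraction_rejected(self):
        from dcmscreen import split_cohort

        with pytest.raises(ConfigurationError):
            split_cohort([], test_fraction=1.0)


class TestDeriveTool:
    def test_matches_per_stratum_youden_scan(self):
        cohort = score_cohort(simulate_study(table1_defaults(), seed=17))
        table = derive_tool(cohort)
        for stratum, (grt_cut, grip_cut) in table.cutoffs.items():
            cases = [s for s in cohort if s.stratum == stratum and s.group is Group.DCM]
            controls = [s for s in cohort if s.stratum == stratum and s.group is Group.CONTROL]
            oracle_grt = youden_cutoff(
                [s.grt_min for s in cases], [s.grt_min for s in controls]
            )
            oracle_grip = youden_cutoff(
                [s.grip_min for s in cases], [s.grip_min for s in controls]
            )
            assert grt_cut == oracle_grt.cutoff
            assert grip_cut == oracle_grip.cutoff

    def test_deterministic_for_identical_cohorts(self):
        a = score_cohort(simulate_study(table1_defaults(), seed=21))
        b = score_cohort(simulate_study(table1_defaults(), seed=21))
        assert derive_tool(a).cutoffs == derive_tool(b).cutoffs

    def test_stratum_without_cases_raises_named_error(self):
        cohort = [make_score(group=Group.CONTROL, grt=20, grip=35.0)]
        with pytest.raises(InsufficientDataError, match="male 60-69"):
            derive_tool(cohort)

    def test_cutoffs_are_attainable_measurement_values(self):
        cohort = score_cohort(simulate_study(table1_defaults(), seed=23))
        for grt_cut, grip_cut in derive_tool(cohort).cutoffs.values():
            assert grt_cut == int(grt_cut)  # integer repetition counts
            assert (grip_cut * 2) == int(grip_cut * 2)  # 0.5-kg grid
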