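"""Scoring, classification and cohort-summary rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from edtwin.phenotype import (
    CaseSourceFlags,
    EdGroup,
    Edi2ItemSet,
    classify_ed,
    cohort_summary,
    log_transform,
    parse_icd_flags,
    round_half_up,
    score_edi2,
    score_edi2_frame,
)
from edtwin.synthetic import synthetic_flag_cohort


def _items(dt=None, bu=None, bd=None, fill=2):
    return Edi2ItemSet(
        drive_for_thinness=dt if dt is not None else [fill] * 7,
        bulimia=bu if bu is not None else [fill] * 7,
        body_dissatisfaction=bd if bd is not None else [fill] * 9,
    )


class TestScoring:
    @pytest.mark.parametrize("fill,expected", [(1, 1.0), (6, 6.0), (3, 3.0)])
    def test_constant_responses(self, fill, expected):
        assert score_edi2(_items(fill=fill)) == expected

    def test_mean_pools_answered_items_across_subscales(self):
        items = _items(dt=[1] * 7, bu=[6] * 7, bd=[1] * 9)
        assert score_edi2(items) == pytest.approx((7 + 42 + 9) / 23)

    def test_75_percent_rule_blocks_scoring(self):
        # 5 of 7 answered on one subscale (minimum is 6) -> missing
        items = _items(dt=[2, 2, 2, 2, 2, None, None])
        assert score_edi2(items) is None

    def test_minimum_completion_is_scoreable(self):
        items = _items(dt=[4] * 6 + [None], bu=[4] * 6 + [None],
                       bd=[4] * 7 + [None, None])
        assert score_edi2(items) == pytest.approx(4.0)

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError, match="outside 1-6"):
            _items(dt=[7] + [2] * 6)

    @given(st.permutations(list(range(7))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance_within_subscale(self, perm):
        base = [1, 2, 3, 4, 5, 6, 1]
        shuffled = [base[i] for i in perm]
        assert score_edi2(_items(dt=shuffled)) == score_edi2(_items(dt=base))

    def test_frame_scoring_matches_scalar_rule(self):
        df = pd.DataFrame({
            **{f"dt{i}": [2, 2, np.nan] for i in range(1, 8)},
            **{f"bu{i}": [2, 4, 2] for i in range(1, 8)},
            **{f"bd{i}": [2, 4, 2] for i in range(1, 10)},
        })
        out = score_edi2_frame(df)
        assert out[0] == pytest.approx(2.0)
        assert out[1] == pytest.approx((7 * 2 + 16 * 4) / 23)
        assert np.isnan(out[2])  # whole subscale missing


class TestLogTransform:
    @pytest.mark.parametrize("x,expected", [
        (1.0, 0.0), (math.e, 1.0), (2.66, 0.9783)
    ])
    def test_values(self, x, expected):
        assert log_transform(x) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_transform(0.0)


class TestClassification:
    def test_an_precedence_over_other_sources(self):
        flags = CaseSourceFlags(npr_an=True, self_purging=True)
        assert classify_ed(flags).group is EdGroup.AN

    def test_purging_only_is_oed(self):
        out = classify_ed(CaseSourceFlags(self_purging=True))
        assert out.group is EdGroup.OED and out.any_ed

    def test_no_flags_is_none(self):
        out = classify_ed(CaseSourceFlags())
        assert out.group is EdGroup.NONE and not out.any_ed

    def test_missing_flags_count_as_absent(self):
        out = classify_ed(CaseSourceFlags(npr_an=None, self_purging=True))
        assert out.group is EdGroup.OED

    @given(st.lists(st.booleans(), min_size=5, max_size=5))
    @settings(max_examples=64, deadline=None)
    def test_adding_a_flag_never_demotes(self, bits):
        rank = {EdGroup.NONE: 0, EdGroup.OED: 1, EdGroup.AN: 2}
        names = ["npr_an", "npr_oed", "parent_treat_an", "parent_treat_bn",
                 "self_purging"]
        base = classify_ed(CaseSourceFlags(**dict(zip(names, bits))))
        for i in range(5):
            if not bits[i]:
                more = list(bits)
                more[i] = True
                out = classify_ed(CaseSourceFlags(**dict(zip(names, more))))
                assert rank[out.group] >= rank[base.group]


class TestIcdParsing:
    def test_accepts_dotted_and_plain_codes(self):
        f = parse_icd_flags(["F50.0"])
        g = parse_icd_flags(["F500"])
        assert f.npr_an and g.npr_an

    def test_excluded_codes_dropped(self):
        f = parse_icd_flags(["F50.4", "F98.2", "F50.9"])
        assert not f.npr_an and f.npr_oed

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            parse_icd_flags(["F99.9"])


class TestCohortSummary:
    def test_printed_margin_fixture(self):
        s = cohort_summary(synthetic_flag_cohort())
        assert s["any_ed"]["pct"] == 5.7
        assert s["sources"]["npr_any"]["pct"] == 3.1
        assert s["sources"]["self_purging"]["pct"] == 3.2
        assert s["overlap"]["any_ed_with_npr_pct"] == 55.0
        assert s["overlap"]["parent_an_with_npr_an_pct"] == 56.5
        assert s["overlap"]["parent_bn_with_npr_bn_pct"] == 12.5
        assert s["groups"]["AN"]["pct"] == 2.4
        assert s["groups"]["OED"]["pct"] == 3.3

    def test_group_percentages_sum_to_100(self):
        s = cohort_summary(synthetic_flag_cohort())
        total = sum(s["groups"][g]["pct"] for g in ("AN", "OED", "NONE"))
        assert total == pytest.approx(100.0, abs=0.15)

    def test_single_clean_individual(self):
        df = pd.DataFrame({"npr_an": [False], "npr_oed": [False],
                           "parent_treat_an": [False], "parent_treat_bn": [False],
                           "self_purging": [False]})
        s = cohort_summary(df)
        assert s["any_ed"]["n"] == 0 and s["any_ed"]["pct"] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame())

    def test_half_up_rounding(self):
        assert round_half_up(56.25, 1) == 56.3
        assert round_half_up(2.35, 1) == 2.4
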