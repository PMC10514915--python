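import pandas as pd
import pytest

from exotriage.prioritizer import (
    TOOL_ROSTER, CallClass, PrioritizerConfig, UnmappedLabelError, consensus_vote,
    normalize_call, prioritize, prioritize_table,
)

#: the published predictor row of the known WNT10A c.511C>T missense variant,
#: in roster order (tool 10, M-CAP, abstained)
WNT10A_ROW = ["DC", "D", "D", "D", "PD", "T", "LDC", "D", "N", "",
              "M", "T", "T", "U", "U", "U", "T", "D"]


class TestNormalizeCall:
    @pytest.mark.parametrize(
        "tool, raw, expected",
        [
            ("mutation_taster", "DC", CallClass.DELETERIOUS),
            ("revel", "LDC", CallClass.DELETERIOUS),
            ("polyphen2", "PD", CallClass.DELETERIOUS),
            ("eigen", "P", CallClass.DELETERIOUS),
            ("mutation_assessor", "M", CallClass.DELETERIOUS),
            ("mutation_assessor", "N", CallClass.NON_DELETERIOUS),
            ("mutation_assessor", "L", CallClass.NON_DELETERIOUS),
            ("sift", "T", CallClass.NON_DELETERIOUS),
            ("metalr", "B", CallClass.NON_DELETERIOUS),
            ("dann", "U", CallClass.UNCERTAIN),
            ("sift", "", CallClass.MISSING),
            ("sift", None, CallClass.MISSING),
        ],
    )
    def test_default_mapping(self, tool, raw, expected):
        assert normalize_call(tool, raw) == expected

    def test_ma_medium_is_config_reversible(self):
        cfg = PrioritizerConfig(ma_medium_deleterious=False)
        assert normalize_call("mutation_assessor", "M", cfg) == CallClass.NON_DELETERIOUS

    def test_unmapped_label_names_tool_and_label(self):
        with pytest.raises(UnmappedLabelError, match="XX.*sift|sift.*XX"):
            normalize_call("sift", "XX")
        with pytest.raises(UnmappedLabelError, match="M"):
            normalize_call("sift", "M")  # medium is Mutation Assessor-only

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError, match="unknown tool"):
            normalize_call("alphamissense", "D")


class TestConsensusVote:
    def _calls(self, labels):
        return {t: normalize_call(t, raw) for t, raw in zip(TOOL_ROSTER, labels)}

    def test_published_row_hand_count(self):
        """9 of 17 available calls are deleterious in the WNT10A row
        (counted by hand from the printed labels: DC, D, D, D, PD, LDC, D,
        M, D — tool 10 abstains), exactly meeting threshold ceil(17/2) = 9."""
        vote = consensus_vote(self._calls(WNT10A_ROW))
        assert (vote.n_deleterious, vote.n_available) == (9, 17)
        assert vote.threshold == 9 and vote.passed

    def test_all_deleterious(self):
        vote = consensus_vote(self._calls(["D" if t != "mutation_taster" else "DC"
                                           for t in TOOL_ROSTER]))
        assert vote.n_deleterious == 18 and vote.passed

    @pytest.mark.parametrize("n_del, passed", [(9, True), (8, False)])
    def test_at_least_half_boundary(self, n_del, passed):
        labels = ["D"] * n_del + ["T"] * (18 - n_del)
        labels[0] = "DC" if n_del else "N"
        vote = consensus_vote(self._calls(labels))
        assert vote.n_available == 18 and vote.threshold == 9
        assert vote.passed is passed

    def test_uncertain_counts_in_denominator_only(self):
        labels = ["D"] * 5 + ["U"] * 13
        labels[0] = "DC"
        vote = consensus_vote(self._calls(labels))
        assert (vote.n_deleterious, vote.n_available, vote.threshold) == (5, 18, 9)
        assert not vote.passed

    def test_no_calls_signalled(self):
        with pytest.raises(ValueError, match="no_calls"):
            consensus_vote({t: CallClass.MISSING for t in TOOL_ROSTER})

    def test_fixed18_denominator_rule(self):
        cfg = PrioritizerConfig(vote_denominator="fixed18")
        labels = ["D"] * 8 + [""] * 10
        vote = consensus_vote(self._calls(labels), cfg)
        assert vote.threshold == 9 and not vote.passed

    def test_monotone_in_single_flip(self):
        """Flipping any one non-deleterious call to deleterious never turns
        a passing vote into a failing one."""
        base = ["D"] * 9 + ["T"] * 9
        base[0] = "DC"
        assert consensus_vote(self._calls(base)).passed
        for i in range(9, 18):
            flipped = list(base)
            flipped[i] = "D"
            assert consensus_vote(self._calls(flipped)).passed


class TestPrioritize:
    def test_stop_gain_bypasses_vote(self, annotation_row):
        """A truncating variant with no predictor calls and CADD 36 is
        prioritized through the loss-of-function bypass."""
        d = prioritize(annotation_row(effect="stop_gained", cadd=36.0,
                                      clinical_sig="conflicting"))
        assert d.vote_bypassed and d.prioritized
        assert "vote:bypassed_lof" in d.reasons

    def test_cadd_gate_is_strict(self, annotation_row):
        row = annotation_row(cadd=19.9)
        row.update({t: "D" for t in TOOL_ROSTER if t != "mutation_taster"})
        row["mutation_taster"] = "DC"
        d = prioritize(row)
        assert d.vote.passed and not d.cadd_pass and not d.prioritized
        row["cadd"] = 20.0
        assert not prioritize(row).prioritized  # "above 20" is strict
        row["cadd"] = 20.1
        assert prioritize(row).prioritized

    def test_missing_cadd_fails_with_reason(self, annotation_row):
        d = prioritize(annotation_row(effect="stop_gained", cadd=None))
        assert not d.prioritized and "cadd:missing" in d.reasons

    def test_benign_excluded_uncertain_retained(self, annotation_row):
        row = annotation_row(cadd=25.0, clinical_sig="benign")
        row.update({t: "D" for t in TOOL_ROSTER if t != "mutation_taster"})
        row["mutation_taster"] = "DC"
        d = prioritize(row)
        assert d.benign_excluded and not d.prioritized
        row["clinical_sig"] = "conflicting"
        assert prioritize(row).prioritized
        row["clinical_sig"] = "uncertain_significance"
        assert prioritize(row).prioritized

    def test_idempotent_and_deterministic_table(self, recovery_data):
        from exotriage.filters import run_cascade
        _, surviving = run_cascade(recovery_data.annotations, "panel",
                                   panel=recovery_data.panel)
        t1 = prioritize_table(surviving)
        t2 = prioritize_table(surviving)
        pd.testing.assert_frame_equal(t1, t2)
        kept = surviving[t1["prioritized"].to_numpy(dtype=bool)]
        t3 = prioritize_table(kept)
        assert t3["prioritized"].all()  # re-running on survivors is identity
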