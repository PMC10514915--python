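import numpy as np
import pandas as pd
import pytest

from exotriage.filters import af_filter, impact_filter, panel_filter, run_cascade
from exotriage.variant_io import GenePanel, variant_key_column


def _annots(rows):
    base = {
        "chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gene": "G1",
        "effect": "missense_variant", "impact": "MODERATE", "hgvs_c": "c.1A>G",
        "hgvs_p": "p.?", "transcript": "NM_1", "af_gnomad": 0.001,
        "af_1kg": 0.001, "cadd": 25.0, "clinical_sig": None,
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(base)
        row.update(r)
        row["pos"] = i + 1
        out.append(row)
    return pd.DataFrame(out)


class TestImpactFilter:
    def test_low_excluded_high_kept_missing_excluded(self):
        df = _annots([
            {"impact": "LOW"},
            {"impact": "HIGH", "effect": "stop_gained"},
            {"impact": None},
            {"impact": "MODERATE"},
        ])
        kept = impact_filter(df)
        assert list(kept["impact"]) == ["HIGH", "MODERATE"]

    def test_generator_truth(self, default_data):
        ann = default_data.annotations
        kept = impact_filter(ann)
        assert len(kept) == int(ann["impact"].isin(["MODERATE", "HIGH"]).sum())


class TestAfFilter:
    def test_rare_kept_boundary_excluded(self):
        df = _annots([{"af_gnomad": 0.001}, {"af_gnomad": 0.01}])
        kept = af_filter(df, ("gnomad",))
        assert list(kept["af_gnomad"]) == [0.001]

    def test_both_source_rule(self):
        df = _annots([{"af_gnomad": 0.0001, "af_1kg": 0.02}])
        assert len(af_filter(df, ("gnomad",))) == 1
        assert len(af_filter(df, ("gnomad", "1kg"))) == 0

    def test_missing_af_treated_as_novel(self):
        df = _annots([{"af_gnomad": None, "af_1kg": None}])
        assert len(af_filter(df, ("gnomad", "1kg"))) == 1

    def test_out_of_range_af_is_error(self):
        df = _annots([{"af_gnomad": 1.2}])
        with pytest.raises(ValueError):
            af_filter(df, ("gnomad",))

    def test_no_sources_is_error(self):
        with pytest.raises(ValueError):
            af_filter(_annots([{}]), ())


class TestPanelFilter:
    def test_membership(self):
        df = _annots([{"gene": "LAMA3"}, {"gene": "NOTINPANEL"}])
        kept = panel_filter(df, GenePanel(frozenset({"LAMA3", "CDH1"})))
        assert list(kept["gene"]) == ["LAMA3"]

    def test_generator_planted_in_panel_count(self, default_data):
        ann = default_data.annotations
        kept = panel_filter(ann, default_data.panel)
        in_panel_genes = {g.name for g in default_data.config.genes if g.in_panel}
        assert len(kept) == int(ann["gene"].isin(in_panel_genes).sum())


class TestCascade:
    def test_empty_input_all_zero_trace(self, default_data):
        empty = default_data.annotations.iloc[0:0]
        trace, surviving = run_cascade(empty, "panel", panel=default_data.panel)
        assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in trace.stages)
        assert surviving.empty and trace.surviving == []

    def test_counts_non_increasing_and_surviving_matches(self, recovery_data):
        trace, surviving = run_cascade(
            recovery_data.annotations, "panel", panel=recovery_data.panel)
        counts = [n for _, n, _ in trace.stages] + [trace.stages[-1][2]]
        assert counts == sorted(counts, reverse=True)
        assert trace.surviving == list(variant_key_column(surviving))

    def test_thirteen_planted_candidates_survive(self, recovery_data):
        trace, surviving = run_cascade(
            recovery_data.annotations, "panel", panel=recovery_data.panel)
        assert sorted(trace.surviving) == sorted(recovery_data.truth.planted_candidates)
        assert len(surviving) == 13

    def test_predicates_commute(self, recovery_data):
        """The surviving set is the pure intersection of the predicates, so
        any application order yields the same rows."""
        ann = recovery_data.annotations
        panel = recovery_data.panel
        orders = [
            lambda df: af_filter(impact_filter(panel_filter(df, panel)), ("gnomad", "1kg")),
            lambda df: panel_filter(af_filter(impact_filter(df), ("gnomad", "1kg")), panel),
            lambda df: impact_filter(panel_filter(af_filter(df, ("gnomad", "1kg")), panel)),
        ]
        results = [set(variant_key_column(f(ann))) for f in orders]
        assert results[0] == results[1] == results[2]

    def test_predicates_idempotent(self, recovery_data):
        ann = recovery_data.annotations
        once = impact_filter(ann)
        pd.testing.assert_frame_equal(once, impact_filter(once))
        rare = af_filter(ann, ("gnomad",))
        pd.testing.assert_frame_equal(rare, af_filter(rare, ("gnomad",)))

    def test_case_control_requires_assoc(self, default_data):
        with pytest.raises(ValueError, match="assoc"):
            run_cascade(default_data.annotations, "case_control")

    def test_case_control_recovers_spike(self, default_data):
        from exotriage.assoc import associate
        records = associate(default_data.variants, default_data.cohort)
        trace, surviving = run_cascade(
            default_data.annotations, "case_control", assoc_records=records)
        assert [s[0] for s in trace.stages] == [
            "significant_association", "impact_moderate_high", "af_lt_0.01_gnomad"]
        assert any(k.startswith("13:13900000") for k in trace.surviving)
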