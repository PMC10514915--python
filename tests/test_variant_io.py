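import numpy as np
import pytest

from exotriage.variant_io import (
    AlleleCount, Cohort, GenePanel, GeneSet, GeneSetCollection, UnknownSampleError,
    VcfParseError, read_annotations, read_gene_sets, read_panel, read_vcf,
    site_allele_counts, write_annotations, write_gene_sets, write_panel, write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _write(tmp_path, body, samples=("s1", "s2")):
    path = tmp_path / "t.vcf"
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    path.write_text(header + body)
    return path


class TestReadVcf:
    def test_single_het_site(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        recs, cohort = read_vcf(path, {"s1": "case", "s2": "control"})
        assert len(recs) == 1
        counts = site_allele_counts(recs[0], cohort, "case")
        assert (counts.n_ref, counts.n_alt, counts.n_missing) == (1, 1, 0)

    def test_multiallelic_split_shares_position(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tG\tA,T\t.\t.\t.\tGT\t1/2\t0/1\n")
        recs, _ = read_vcf(path, {"s1": "case", "s2": "control"})
        assert [r.alt for r in recs] == ["A", "T"]
        assert {(r.chrom, r.pos, r.ref) for r in recs} == {("1", 100, "G")}
        # summed per-alt counts reconstruct the site's total alt-slot count
        total_alt = sum(int((r.genotypes == 1).sum()) for r in recs)
        assert total_alt == 3

    def test_half_missing_genotype(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t./1\t0/0\n")
        recs, cohort = read_vcf(path, {"s1": "case", "s2": "control"})
        c = site_allele_counts(recs[0], cohort, "case")
        assert (c.n_ref, c.n_alt, c.n_missing) == (0, 1, 1)

    def test_unknown_sample_is_labeled_error(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        with pytest.raises(UnknownSampleError, match="s2"):
            read_vcf(path, {"s1": "case"})

    def test_malformed_line_names_line_number(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\n")  # one GT missing
        with pytest.raises(VcfParseError, match="line 4"):
            read_vcf(path, {"s1": "case", "s2": "control"})

    def test_round_trip_identity(self, tmp_path, default_data):
        """Write-then-read of the full synthetic cohort reproduces every
        genotype slot and record key."""
        path = tmp_path / "cohort.vcf"
        write_vcf(path, default_data.variants, default_data.cohort)
        groups = dict(zip(default_data.cohort.samples, default_data.cohort.groups))
        recs, cohort = read_vcf(path, groups)
        assert cohort == default_data.cohort
        assert len(recs) == len(default_data.variants)
        for got, want in zip(recs, default_data.variants):
            assert got.key == want.key
            assert np.array_equal(got.genotypes, want.genotypes)


class TestAlleleCounts:
    def _cohort(self, n_case=20, n_control=0):
        names = tuple(f"s{i}" for i in range(n_case + n_control))
        return Cohort(names, tuple(["case"] * n_case + ["control"] * n_control))

    def test_all_hom_ref(self):
        from exotriage.variant_io import VariantRecord
        rec = VariantRecord("1", 1, "A", "G", np.zeros((20, 2), dtype=np.int8))
        c = site_allele_counts(rec, self._cohort(), "case")
        assert (c.n_ref, c.n_alt, c.n_missing) == (40, 0, 0)

    def test_het_and_hom_alt_arithmetic(self):
        from exotriage.variant_io import VariantRecord
        g = np.zeros((20, 2), dtype=np.int8)
        g[0:3, 1] = 1          # 3 hets
        g[3, :] = 1            # 1 hom alt
        rec = VariantRecord("1", 1, "A", "G", g)
        c = site_allele_counts(rec, self._cohort(), "case")
        assert (c.n_ref, c.n_alt, c.n_missing) == (35, 5, 0)

    def test_generator_truth_and_conservation(self, default_data):
        """Recomputed counts equal the generator's ground truth, and the
        conservation invariant holds for every site and group."""
        cohort = default_data.cohort
        for rec in default_data.variants:
            case = site_allele_counts(rec, cohort, "case")
            ctrl = site_allele_counts(rec, cohort, "control")
            assert case.total == 2 * cohort.n("case")
            assert ctrl.total == 2 * cohort.n("control")
            want = default_data.truth.site_alt_counts[rec.key_str]
            assert (case.n_alt, ctrl.n_alt) == tuple(want)

    def test_empty_group_is_error(self):
        from exotriage.variant_io import VariantRecord
        rec = VariantRecord("1", 1, "A", "G", np.zeros((5, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            site_allele_counts(rec, self._cohort(5, 0), "control")


class TestGeneSets:
    def test_published_style_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:0034329\tCell junction assembly\tITGB4\tCDH1\tLAMA3\tLAMB3\n")
        coll = read_gene_sets(path)
        assert len(coll) == 1
        assert set(coll.sets[0].genes) == {"ITGB4", "CDH1", "LAMA3", "LAMB3"}

    def test_empty_file_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert len(read_gene_sets(path)) == 0

    def test_short_line_names_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GO:1\tok\tA\nGO:2\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gene_sets(path)

    def test_duplicates_deduplicated(self, tmp_path, caplog):
        path = tmp_path / "dup.gmt"
        path.write_text("GO:1\tdesc\tA\tB\tA\n")
        coll = read_gene_sets(path)
        assert coll.sets[0].genes == ("A", "B")

    def test_large_set_round_trips(self, tmp_path):
        genes = tuple(f"G{i:04d}" for i in range(280))
        coll = GeneSetCollection([GeneSet("SYN:1", "synthetic 280-gene set", genes)])
        path = tmp_path / "rt.gmt"
        write_gene_sets(path, coll)
        back = read_gene_sets(path)
        assert back.sets[0].genes == genes


class TestPanelAndAnnotations:
    def test_panel_round_trip_with_comments(self, tmp_path, default_data):
        path = tmp_path / "panel.txt"
        write_panel(path, default_data.panel)
        back = read_panel(path)
        assert back.genes == default_data.panel.genes
        assert len(back) == 112

    def test_annotation_round_trip(self, tmp_path, default_data):
        path = tmp_path / "ann.tsv"
        write_annotations(path, default_data.annotations)
        back = read_annotations(path)
        orig = default_data.annotations.reindex(columns=back.columns)
        orig = orig.where(orig.notna(), other=np.nan)  # None -> NaN for comparison
        import pandas.testing as pdt
        pdt.assert_frame_equal(
            back.reset_index(drop=True), orig.reset_index(drop=True),
            check_dtype=False,
        )

    def test_af_out_of_range_rejected(self, default_data):
        bad = default_data.annotations.copy()
        bad.loc[bad.index[0], "af_gnomad"] = 1.5
        with pytest.raises(ValueError, match="af_gnomad"):
            write_annotations("/dev/null", bad)
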