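import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstage import synthio
from crosstage.quantify import (
    ExactMatchAssigner,
    GeneLocus,
    ReadAssignment,
    count_umis,
    merge_gene_loci,
    parse_read_pairs,
    quantify_fastq,
    umi_to_transcripts,
)


class TestLocusMerging:
    def test_identical_intervals_merge(self):
        loci = [GeneLocus("a", "1", 0, 100), GeneLocus("b", "1", 0, 100)]
        merged, id_map = merge_gene_loci(loci)
        assert len(merged) == 1
        assert id_map["a"] == id_map["b"]

    def test_eighty_percent_overlap_merges_at_075(self):
        # overlap 80 nt of shorter 100 nt = 80% > 75% -> merged
        loci = [GeneLocus("a", "1", 0, 100), GeneLocus("b", "1", 20, 120)]
        merged, id_map = merge_gene_loci(loci, 0.75)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 120)

    def test_fifty_percent_overlap_does_not_merge(self):
        loci = [GeneLocus("a", "1", 0, 100), GeneLocus("b", "1", 50, 150)]
        merged, _ = merge_gene_loci(loci, 0.75)
        assert len(merged) == 2

    def test_merging_is_transitive(self):
        # a~b and b~c overlap pairwise above threshold; a and c need not
        loci = [
            GeneLocus("a", "1", 0, 100),
            GeneLocus("b", "1", 10, 110),
            GeneLocus("c", "1", 20, 120),
        ]
        merged, id_map = merge_gene_loci(loci, 0.75)
        assert len(merged) == 1
        assert len(set(id_map.values())) == 1

    def test_boundary_exactly_threshold_not_merged(self):
        # overlap 75 of shorter 100 = exactly 75%: strict inequality keeps apart
        loci = [GeneLocus("a", "1", 0, 100), GeneLocus("b", "1", 25, 125)]
        merged, _ = merge_gene_loci(loci, 0.75)
        assert len(merged) == 2

    def test_different_chromosomes_never_merge(self):
        loci = [GeneLocus("a", "1", 0, 100), GeneLocus("b", "2", 0, 100)]
        merged, _ = merge_gene_loci(loci)
        assert len(merged) == 2

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GeneLocus("a", "1", -5, 100)


class TestUmiCorrection:
    def test_zero_and_one_are_fixed_points(self):
        assert umi_to_transcripts(0, 4096) == 0.0
        assert umi_to_transcripts(1, 4096) == pytest.approx(1.0, abs=1e-12)

    def test_near_saturation_matches_closed_form(self):
        k, K = 4095, 4096
        expected = np.log(1 / 4096) / np.log(1 - 1 / 4096)
        assert umi_to_transcripts(k, K) == pytest.approx(expected, rel=1e-12)

    def test_saturated_count_clamped(self):
        assert umi_to_transcripts(4096, 4096) == umi_to_transcripts(4095, 4096)

    def test_monotone_in_k(self):
        K = 4096
        t = umi_to_transcripts(np.arange(K), K)
        assert np.all(np.diff(t) > 0)

    def test_correction_vanishes_for_large_umi_space(self):
        t = umi_to_transcripts(np.arange(101), K=10**8)
        assert np.max(np.abs(t - np.arange(101))) < 0.01

    def test_correction_at_least_k(self):
        K = 4096
        k = np.arange(K)
        assert np.all(umi_to_transcripts(k, K) >= k)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            umi_to_transcripts(4097, 4096)
        with pytest.raises(ValueError):
            umi_to_transcripts(-1, 4096)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 4095), st.integers(0, 4095))
    def test_monotonicity_property(self, k1, k2):
        t1, t2 = umi_to_transcripts(k1), umi_to_transcripts(k2)
        assert (t1 <= t2) == (k1 <= k2) or k1 == k2


class TestCounting:
    def test_distinct_umis_counted_once(self):
        assignments = [
            ReadAssignment("r1", "ACGTAC", "AAAAAA", "g1"),
            ReadAssignment("r2", "ACGTAC", "AAAAAA", "g1"),
            ReadAssignment("r3", "ACGTAC", "CCCCCC", "g1"),
        ]
        mat = count_umis(assignments)
        assert mat.counts.loc["g1", "ACGTAC"] == 2

    def test_empty_assignments_give_empty_matrix(self):
        mat = count_umis([])
        assert mat.counts.size == 0

    def test_multi_and_unmapped_skipped(self):
        assignments = [
            ReadAssignment("r1", "ACGTAC", "AAAAAA", "MULTI"),
            ReadAssignment("r2", "ACGTAC", "AAAAAA", "UNMAPPED"),
            ReadAssignment("r3", "ACGTAC", "AAAAAA", "g1"),
        ]
        mat = count_umis(assignments)
        assert mat.counts.values.sum() == 1

    def test_id_map_aggregates_merged_loci(self):
        assignments = [
            ReadAssignment("r1", "ACGTAC", "AAAAAA", "iso1"),
            ReadAssignment("r2", "ACGTAC", "CCCCCC", "iso2"),
        ]
        mat = count_umis(assignments, id_map={"iso1": "gene", "iso2": "gene"})
        assert mat.counts.loc["gene", "ACGTAC"] == 2

    def test_spike_ins_tagged(self):
        assignments = [
            ReadAssignment("r1", "ACGTAC", "AAAAAA", "ERCC-00001"),
            ReadAssignment("r2", "ACGTAC", "AAAAAA", "g1"),
        ]
        mat = count_umis(assignments)
        assert mat.spike_genes == ("ERCC-00001",)


class TestParsing:
    def test_multimapping_read_flagged_multi(self):
        assigner = ExactMatchAssigner({"g1": "AAACCCGGG", "g2": "CCCGGGTTT"})
        assert len(assigner("CCCGGG")) == 2

    def test_antisense_read_unmapped(self):
        # reverse complement of a locus substring is not a sense match
        assigner = ExactMatchAssigner({"g1": "ATGGCAAGGATT"})
        read = "TGGCAA"
        revcomp = read[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert assigner(read) == ["g1"]
        assert assigner(revcomp) == []

    def test_roundtrip_uncorrupted_fastq(self, tmp_path):
        cfg = synthio.SynthConfig(seed=9, n_cells_per_stage=10)
        left, right, truth, wl, seqs = synthio.generate_toy_fastq(
            cfg, 25, tmp_path
        )
        assignments, report = parse_read_pairs(
            left, right, wl, ExactMatchAssigner(seqs)
        )
        assert report["off_whitelist"] == 0
        got = {(a.read_id, a.barcode, a.umi, a.locus) for a in assignments}
        expected = {
            (r.read_id, r.barcode, r.umi, r.locus)
            for r in truth.itertuples(index=False)
        }
        assert got == expected

    def test_off_whitelist_and_multi_excluded(self, tmp_path):
        cfg = synthio.SynthConfig(seed=10, n_cells_per_stage=10)
        left, right, truth, wl, seqs = synthio.generate_toy_fastq(
            cfg, 40, tmp_path, multimap_fraction=0.2, off_whitelist_fraction=0.2
        )
        assignments, report = parse_read_pairs(
            left, right, wl, ExactMatchAssigner(seqs)
        )
        n_off = (~truth.expected_barcode_ok).sum()
        assert report["off_whitelist"] == n_off
        n_multi_expected = (
            truth.loc[truth.expected_barcode_ok, "locus"] == "MULTI"
        ).sum()
        assert report["multi"] == n_multi_expected

    def test_mismatched_fastq_lengths_error(self, tmp_path):
        l = tmp_path / "l.fastq"
        r = tmp_path / "r.fastq"
        l.write_text("@r1\nAAAAAACCCCCCTTTTTTTTTTTT\n+\nIIIIIIIIIIIIIIIIIIIIIIII\n" * 2)
        r.write_text("@r1\nACGTACGTAC\n+\nIIIIIIIIII\n")
        with pytest.raises(ValueError, match="record"):
            parse_read_pairs(l, r, ["CCCCCC"], lambda s: [])

    def test_ambiguous_bases_excluded_and_reported(self, tmp_path):
        l = tmp_path / "l.fastq"
        r = tmp_path / "r.fastq"
        l.write_text("@r1\nAANAAACCCCCCTTTTTTTTTTTT\n+\nIIIIIIIIIIIIIIIIIIIIIIII\n")
        r.write_text("@r1\nACGTACGTAC\n+\nIIIIIIIIII\n")
        assignments, report = parse_read_pairs(l, r, ["CCCCCC"], lambda s: [])
        assert report["ambiguous_base"] == 1
        assert assignments == []


def test_end_to_end_matrix_equals_truth(tmp_path):
    """Toy FASTQ at 0% corruption -> UMI matrix identical to generator truth."""
    cfg = synthio.SynthConfig(seed=3, n_cells_per_stage=20)
    left, right, truth, wl, seqs = synthio.generate_toy_fastq(
        cfg, 30, tmp_path, duplicate_fraction=0.1
    )
    umi_mat, corrected, _ = quantify_fastq(left, right, wl, ExactMatchAssigner(seqs))
    expected = synthio.truth_umi_counts(truth, wl)
    got = umi_mat.counts.reindex(
        index=expected.index, columns=expected.columns, fill_value=0
    )
    assert (got.values == expected.values).all()
    # corrected counts exceed or equal observed distinct UMIs
    assert (corrected.values >= umi_mat.counts.values).all()
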