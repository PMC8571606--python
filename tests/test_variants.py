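import math

import pytest

from strainfate.synth import gen_pileup
from strainfate.variants import (
    FilterThresholds,
    Partitioner,
    PileupFormatError,
    PileupSite,
    ReadCall,
    VariantCall,
    call_variants,
    distance_matrix,
    filter_site,
    pairwise_distance,
    parse_pileup,
    read_partition_bed,
    write_vcf,
)


def site(ref="A", alt="G", n_alt_fwd=5, n_alt_rev=4, n_ref=1, bq=40, mq=60,
         contig="chrI", pos=100):
    calls = []
    for _ in range(n_alt_fwd):
        calls.append(ReadCall(alt, "+", bq, mq))
    for _ in range(n_alt_rev):
        calls.append(ReadCall(alt, "-", bq, mq))
    for i in range(n_ref):
        calls.append(ReadCall(ref, "+" if i % 2 == 0 else "-", bq, mq))
    return PileupSite(contig, pos, ref, len(calls), tuple(calls))


class TestParsePileup:
    def test_simple_matches_with_strand(self):
        s = next(parse_pileup(["chrI\t100\tA\t4\t..,,\tIIII"]))
        assert s.contig == "chrI" and s.position == 100 and s.ref_base == "A"
        assert [c.allele for c in s.calls] == ["A"] * 4
        assert [c.strand for c in s.calls] == ["+", "+", "-", "-"]
        assert all(c.base_quality == 40 for c in s.calls)

    def test_empty_stream(self):
        assert list(parse_pileup([])) == []

    def test_read_start_mark_stripped(self):
        s = next(parse_pileup(["chrI\t5\tG\t1\t^].\tI"]))
        assert s.calls == (ReadCall("G", "+", 40, None),)

    def test_read_end_mark_stripped(self):
        s = next(parse_pileup(["chrI\t5\tG\t2\t.$,\tII"]))
        assert len(s.calls) == 2

    def test_substitutions_case_strand(self):
        s = next(parse_pileup(["chrI\t5\tA\t3\tGg.\tIII"]))
        assert [(c.allele, c.strand) for c in s.calls] == [
            ("G", "+"), ("G", "-"), ("A", "+"),
        ]

    def test_insertion_attached(self):
        s = next(parse_pileup(["chrI\t5\tA\t2\t.+2TT,\tII"]))
        assert s.calls[0].allele == "A+TT"
        assert s.calls[1].allele == "A"

    def test_deletion_attached(self):
        s = next(parse_pileup(["chrI\t5\tA\t2\t.-1t,\tII"]))
        assert s.calls[0].allele == "A-T"

    def test_star_placeholder(self):
        s = next(parse_pileup(["chrI\t5\tA\t2\t*,\tII"]))
        assert s.calls[0].allele == "*"

    def test_mapping_quality_column(self):
        s = next(parse_pileup(["chrI\t5\tA\t2\t.,\tII\t]5"]))
        assert [c.mapping_quality for c in s.calls] == [60, 20]

    def test_depth_mismatch_reports_line(self):
        with pytest.raises(PileupFormatError, match="line 1"):
            list(parse_pileup(["chrI\t5\tA\t3\t..\tII"]))

    def test_malformed_fields(self):
        with pytest.raises(PileupFormatError, match="fields"):
            list(parse_pileup(["chrI\t5\tA"]))

    def test_quality_length_mismatch(self):
        with pytest.raises(PileupFormatError):
            list(parse_pileup(["chrI\t5\tA\t2\t..\tIII"]))


class TestFilterSite:
    def test_clean_variant_passes(self):
        call = filter_site(site(n_alt_fwd=5, n_alt_rev=4, n_ref=1))
        assert call.verdict == "pass"
        assert call.support_fraction == pytest.approx(0.9)
        assert call.supporting_reads == 9
        assert call.strand_bias == pytest.approx(1.25)

    def test_single_strand_fails_strand(self):
        call = filter_site(site(n_alt_fwd=8, n_alt_rev=0, n_ref=2))
        assert (call.verdict, call.fail_reason) == ("fail", "strand")
        assert math.isinf(call.strand_bias)

    def test_few_reads_fails_min_reads(self):
        call = filter_site(site(n_alt_fwd=2, n_alt_rev=2, n_ref=6))
        assert (call.verdict, call.fail_reason) == ("fail", "min_reads")

    def test_low_fraction_fails(self):
        call = filter_site(site(n_alt_fwd=3, n_alt_rev=3, n_ref=4))
        assert (call.verdict, call.fail_reason) == ("fail", "min_fraction")

    def test_extreme_bias_fails(self):
        call = filter_site(site(n_alt_fwd=11, n_alt_rev=2, n_ref=0))
        assert (call.verdict, call.fail_reason) == ("fail", "strand_bias")

    def test_bias_bounds_are_strict(self):
        call = filter_site(site(n_alt_fwd=10, n_alt_rev=2, n_ref=0))
        assert call.strand_bias == pytest.approx(5.0)
        assert call.fail_reason == "strand_bias"

    def test_low_quality_reads_removed_first(self):
        # 9 high-quality alt reads plus 10 low-quality ref reads: the ref
        # reads are not "quality reads", so the fraction is 9/10 over the
        # single remaining ref read
        calls = (
            [ReadCall("G", "+", 40, 60)] * 5
            + [ReadCall("G", "-", 40, 60)] * 4
            + [ReadCall("A", "+", 10, 60)] * 10
            + [ReadCall("A", "-", 40, 60)]
        )
        s = PileupSite("chrI", 1, "A", len(calls), tuple(calls))
        call = filter_site(s)
        assert call.verdict == "pass"
        assert call.support_fraction == pytest.approx(0.9)

    def test_low_mapping_quality_removed(self):
        calls = [ReadCall("G", "+", 40, 10)] * 5 + [ReadCall("G", "-", 40, 10)] * 5
        s = PileupSite("chrI", 1, "A", 10, tuple(calls))
        assert filter_site(s) is None

    def test_no_alt_returns_none(self):
        calls = tuple(ReadCall("A", "+", 40, 60) for _ in range(10))
        assert filter_site(PileupSite("chrI", 1, "A", 10, calls)) is None

    def test_indel_filtered_like_snp(self):
        calls = [ReadCall("A+TT", "+", 40, 60)] * 5 + [ReadCall("A+TT", "-", 40, 60)] * 4
        calls += [ReadCall("A", "-", 40, 60)]
        call = filter_site(PileupSite("chrI", 1, "A", 10, tuple(calls)))
        assert call.verdict == "pass"
        assert (call.ref, call.alt) == ("A", "ATT")
        assert not call.is_snp

    def test_quality_floor_reshapes_denominator(self):
        # raising min_bq removes low-quality REF reads from the "quality
        # reads" denominator, so it can flip a fail into a pass — this is why
        # the monotonicity property covers only the variant-level thresholds
        calls = (
            [ReadCall("G", "+", 40, 60)] * 3
            + [ReadCall("G", "-", 40, 60)] * 2
            + [ReadCall("A", "+", 31, 60)] * 5
        )
        s = PileupSite("chrI", 1, "A", 10, tuple(calls))
        assert filter_site(s).verdict == "fail"
        relaxed = filter_site(s, FilterThresholds(min_base_quality=40))
        assert relaxed.verdict == "pass"

    def test_monotonicity_raising_thresholds(self):
        s = site(n_alt_fwd=5, n_alt_rev=4, n_ref=1)
        base = filter_site(s)
        assert base.verdict == "pass"
        stricter = [
            FilterThresholds(min_reads=10),
            FilterThresholds(min_fraction=0.95),
            FilterThresholds(min_base_quality=50),
            FilterThresholds(bias_low=1.3),
            FilterThresholds(bias_high=1.2),
        ]
        for th in stricter:
            call = filter_site(s, th)
            assert call is None or call.verdict == "fail"


class TestCallVariants:
    def test_end_to_end_planted_snps(self):
        lines, truth = gen_pileup(
            500, variant_positions=[50, 200, 450], depth=10, error_rate=0.0, seed=5
        )
        calls = call_variants(parse_pileup(lines))
        assert [(c.contig, c.position, c.ref, c.alt) for c in calls] == list(
            truth.true_variant_positions
        )

    def test_strand_bias_decoy_rejected(self):
        lines, _ = gen_pileup(200, depth=10, strand_bias_at=[99], seed=6)
        assert call_variants(parse_pileup(lines)) == []

    def test_unsorted_input_rejected(self):
        lines = ["chrI\t10\tA\t1\t.\tI", "chrI\t5\tA\t1\t.\tI"]
        with pytest.raises(ValueError, match="unsorted"):
            call_variants(parse_pileup(lines))

    def test_split_contig_blocks_rejected(self):
        lines = [
            "chrI\t1\tA\t1\t.\tI",
            "chrII\t1\tA\t1\t.\tI",
            "chrI\t2\tA\t1\t.\tI",
        ]
        with pytest.raises(ValueError, match="non-contiguous"):
            call_variants(parse_pileup(lines))

    def test_empty_genome_valid_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], path)
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert text.rstrip().endswith("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def test_vcf_records(self, tmp_path):
        lines, truth = gen_pileup(100, variant_positions=[42], depth=10, seed=8)
        calls = call_variants(parse_pileup(lines))
        path = tmp_path / "calls.vcf"
        write_vcf(calls, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1
        chrom, pos, _, ref, alt, _, filt, info = body[0].split("\t")
        assert (chrom, int(pos), ref, alt, filt) == (
            truth.true_variant_positions[0][0],
            truth.true_variant_positions[0][1],
            truth.true_variant_positions[0][2],
            truth.true_variant_positions[0][3],
            "PASS",
        )
        assert "SR=9" in info


def make_call(pos, alt, contig="chrI", ref="A", verdict="pass"):
    reason = None if verdict == "pass" else "min_reads"
    return VariantCall(contig, pos, ref, alt, 9, 0.9, 1.0, verdict, reason)


PARTS = Partitioner({"chrI": "nuclear", "chrII": "nuclear", "mito": "mitochondrial"})
BASES = {"nuclear": 1000, "mitochondrial": 500}


class TestPairwiseDistance:
    def test_identical_sets_zero(self):
        a = [make_call(10, "G"), make_call(20, "T")]
        for d in pairwise_distance(a, list(a), PARTS, BASES):
            assert d.distance == 0.0

    def test_three_snps_per_kb(self):
        a = [make_call(p, "G") for p in (10, 20, 30)]
        dists = {d.partition: d for d in pairwise_distance(a, [], PARTS, BASES)}
        assert dists["nuclear"].snp_differences == 3
        assert dists["nuclear"].distance == pytest.approx(3.0)
        assert dists["mitochondrial"].distance == 0.0

    def test_alt_vs_alt_counts_once(self):
        a = [make_call(100, "G")]
        b = [make_call(100, "T")]
        d = {x.partition: x for x in pairwise_distance(a, b, PARTS, BASES)}
        assert d["nuclear"].snp_differences == 1

    def test_indels_and_fails_excluded(self):
        a = [
            make_call(10, "G"),
            make_call(11, "GTT"),  # insertion: not a SNP
            make_call(12, "T", verdict="fail"),
        ]
        d = {x.partition: x for x in pairwise_distance(a, [], PARTS, BASES)}
        assert d["nuclear"].snp_differences == 1

    def test_partition_routing(self):
        a = [make_call(10, "G", contig="mito")]
        d = {x.partition: x for x in pairwise_distance(a, [], PARTS, BASES)}
        assert d["mitochondrial"].snp_differences == 1
        assert d["mitochondrial"].distance == pytest.approx(2.0)

    def test_unknown_contig_errors(self):
        a = [make_call(10, "G", contig="chrX")]
        with pytest.raises(KeyError, match="chrX"):
            pairwise_distance(a, [], PARTS, BASES)

    def test_bed_interval_overrides_contig(self, tmp_path):
        bed = tmp_path / "mating.bed"
        bed.write_text("chrII\t100\t200\tmating\n")
        parts = Partitioner({"chrI": "nuclear", "chrII": "nuclear"},
                            read_partition_bed(bed))
        assert parts.partition_of("chrII", 150) == "mating"
        assert parts.partition_of("chrII", 100) == "nuclear"  # BED start is 0-based
        assert parts.partition_of("chrII", 200) == "mating"
        assert parts.partition_of("chrII", 201) == "nuclear"


class TestDistanceMatrix:
    def test_two_identical_genomes(self):
        calls = [make_call(10, "G")]
        m = distance_matrix({"a": calls, "b": list(calls)}, PARTS, BASES)
        assert m["nuclear"].loc["a", "b"] == 0.0
        assert m["nuclear"].loc["a", "a"] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        genomes = {
            "a": [make_call(10, "G"), make_call(50, "T")],
            "b": [make_call(10, "C")],
            "c": [],
        }
        for df in distance_matrix(genomes, PARTS, BASES).values():
            assert (df.values == df.values.T).all()
            assert (df.values.diagonal() == 0.0).all()

    def test_adding_genome_preserves_entries(self):
        g = {"a": [make_call(10, "G")], "b": []}
        before = distance_matrix(g, PARTS, BASES)["nuclear"].loc["a", "b"]
        g["c"] = [make_call(99, "T")]
        after = distance_matrix(g, PARTS, BASES)["nuclear"].loc["a", "b"]
        assert before == after

    def test_needs_two_genomes(self):
        with pytest.raises(ValueError):
            distance_matrix({"a": []}, PARTS, BASES)
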