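import numpy as np
import pytest

from idrcons.seq_regions import RegionAnnotation, RegionClass, RegionSet
from idrcons.simulate import (CohortSimConfig, simulate_vcf_cohort,
                              write_cohort, write_vcf)
from idrcons.variants import (Consequence, ConsequenceCall, Genotype,
                              TranscriptModel, VariantRecord,
                              annotate_consequence, balancer_subtract,
                              prioritize_and_map, read_transcript_table,
                              read_vcf, site_filter, triage_cohort,
                              union_callsets, write_transcript_table)
from oracles import oracle_consequence, oracle_protein_change


def make_variant(pos=100, ref="A", alt="T", qual=500.0, depth=30,
                 genotype=Genotype.HET, chrom="chr1", line_id="l1"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                         depth=depth, genotype=genotype, line_id=line_id)


class TestReadVcf:
    def test_het_snv_roundtrip(self, tmp_path):
        v = make_variant()
        p = tmp_path / "a.vcf"
        write_vcf([v], p, chrom_length=1000, sample="l1")
        assert read_vcf(p) == [v]

    def test_multiallelic_site_split(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tG\tA,T\t500.0\t.\t.\tGT:DP\t1/2:30\n")
        recs = read_vcf(p)
        assert [(r.alt, r.genotype) for r in recs] == [
            ("A", Genotype.HET), ("T", Genotype.HET)]

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("chr1\t100\t.\tG\tA\t500\t.\t.\n")
        with pytest.raises((ValueError, OSError)):
            read_vcf(p)

    def test_genotype_classification(self, tmp_path):
        p = tmp_path / "g.vcf"
        body = "".join(
            f"chr1\t{pos}\t.\tG\tA\t500.0\t.\t.\tGT:DP\t{gt}:30\n"
            for pos, gt in [(10, "0/0"), (20, "0/1"), (30, "1/1")])
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            + body)
        recs = read_vcf(p)
        assert [r.genotype for r in recs] == [
            Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]


class TestSiteFilter:
    @pytest.mark.parametrize("qual, depth, expect", [
        (150.0, 10, "filtered"),   # QUAL branch
        (250.0, 1, "filtered"),    # DP branch
        (250.0, 30, "pass"),
        (199.0, 2, "pass"),        # boundary: thresholds are strict <
        (198.9, 2, "filtered"),
    ])
    def test_hard_filter_expression(self, qual, depth, expect):
        assert site_filter(make_variant(qual=qual, depth=depth)) == expect


class TestBalancerSubtract:
    def test_variant_in_all_lines_removed(self):
        shared = dict(pos=50, ref="G", alt="C")
        cohort = {
            f"l{i}": [make_variant(line_id=f"l{i}", **shared),
                      make_variant(pos=100 + i, line_id=f"l{i}")]
            for i in range(20)
        }
        out = balancer_subtract(cohort)
        for line, variants in out.items():
            assert all(v.pos != 50 for v in variants)
            assert len(variants) == 1

    def test_variant_in_one_line_retained(self):
        cohort = {
            "l1": [make_variant(pos=10), make_variant(pos=99)],
            "l2": [make_variant(pos=10, line_id="l2")],
        }
        out = balancer_subtract(cohort)
        assert [v.pos for v in out["l1"]] == [99]

    def test_output_subset_of_input(self, rng):
        cohort = {
            f"l{i}": [make_variant(pos=int(p), line_id=f"l{i}")
                      for p in rng.choice(200, size=20, replace=False) + 1]
            for i in range(5)
        }
        out = balancer_subtract(cohort)
        for line in cohort:
            assert set(v.key for v in out[line]) <= \
                set(v.key for v in cohort[line])

    def test_hom_ref_call_does_not_count_as_shared(self):
        cohort = {
            "l1": [make_variant(pos=10)],
            "l2": [make_variant(pos=10, genotype=Genotype.HOM_REF,
                                line_id="l2")],
        }
        out = balancer_subtract(cohort)
        assert [v.pos for v in out["l1"]] == [10]

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            balancer_subtract({"l1": []})


def toy_transcript():
    # + strand, two exons; CDS 11..40 and 61..90 -> 60 bases, 20 codons
    return TranscriptModel(chrom="chrT", strand="+",
                           exons=[(1, 40), (61, 100)],
                           cds_start=11, cds_end=90)


def toy_genome(rng, tx):
    bases = np.array(list("ACGT"))
    g = list("".join(bases[rng.integers(0, 4, 120)]))
    g[40] = "G"   # donor base 1 of intron 1 (position 41)
    g[41] = "T"
    return "".join(g)


class TestAnnotateConsequence:
    def test_gln_to_stop_notation(self, rng):
        tx = toy_transcript()
        g = list(toy_genome(rng, tx))
        # codon 5 occupies CDS bases 13-15 -> genomic 23-25
        g[22:25] = list("CAG")
        genome = "".join(g)
        call = annotate_consequence(
            make_variant(pos=23, ref="C", alt="T", chrom="chrT"), tx, genome)
        assert call.category is Consequence.NONSENSE
        assert call.notation == "Q5STOP"
        assert call.protein_pos == 5

    def test_splice_donor_first_two_intron_bases(self, rng):
        tx = toy_transcript()
        genome = toy_genome(rng, tx)
        call = annotate_consequence(
            make_variant(pos=41, ref="G", alt="A", chrom="chrT"), tx, genome)
        assert call.category is Consequence.SPLICE_DONOR
        assert call.intron_index == 1
        call2 = annotate_consequence(
            make_variant(pos=42, ref="T", alt="C", chrom="chrT"), tx, genome)
        assert call2.category is Consequence.SPLICE_DONOR

    def test_frameshift_deletion(self, rng):
        tx = toy_transcript()
        genome = toy_genome(rng, tx)
        ref = genome[19:24]  # 4-base deletion anchored at pos 20
        call = annotate_consequence(
            make_variant(pos=20, ref=ref, alt=ref[0], chrom="chrT"),
            tx, genome)
        assert call.category is Consequence.FRAMESHIFT

    def test_inframe_deletion_is_other(self, rng):
        tx = toy_transcript()
        genome = toy_genome(rng, tx)
        ref = genome[19:23]  # 3-base deletion
        call = annotate_consequence(
            make_variant(pos=20, ref=ref, alt=ref[0], chrom="chrT"),
            tx, genome)
        assert call.category is Consequence.OTHER

    def test_ref_mismatch_with_genome_rejected(self, rng):
        tx = toy_transcript()
        genome = toy_genome(rng, tx)
        ref = genome[22]
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match="disagrees"):
            annotate_consequence(
                make_variant(pos=23, ref=wrong, alt="T", chrom="chrT"),
                tx, genome)

    def test_agrees_with_translation_oracle_on_random_snvs(self, rng):
        """Codon-level calls match a whole-CDS translate-before/after oracle
        on 1,000 random SNVs, for both strands."""
        for strand in "+-":
            tx = TranscriptModel(chrom="chrT", strand=strand,
                                 exons=[(1, 40), (61, 100)],
                                 cds_start=11, cds_end=90)
            genome = toy_genome(rng, tx)
            for _ in range(500):
                pos = int(rng.integers(1, 101))
                ref = genome[pos - 1]
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
                call = annotate_consequence(
                    make_variant(pos=pos, ref=ref, alt=alt, chrom="chrT"),
                    tx, genome)
                want = oracle_consequence(pos, ref, alt, tx, genome)
                assert call.category.value == want, (strand, pos, ref, alt)
                if want in ("missense", "nonsense"):
                    ppos, _aa_ref, _aa_alt = oracle_protein_change(
                        pos, ref, alt, tx, genome)
                    assert call.protein_pos == ppos

    def test_minus_strand_codon_extraction(self, rng):
        tx = TranscriptModel(chrom="chrT", strand="-",
                             exons=[(1, 40), (61, 100)],
                             cds_start=11, cds_end=90)
        g = list(toy_genome(rng, tx))
        # last CDS codon in transcription order = genomic 11-13 reversed;
        # plant CTG on the - strand (genomic CAG at 11-13)
        g[10:13] = list("CTG")  # revcomp = CAG = Gln codon 20
        genome = "".join(g)
        call = annotate_consequence(
            make_variant(pos=12, ref="T", alt="C", chrom="chrT"), tx, genome)
        # revcomp of alt C is G -> codon CGG (Arg): missense Q20R
        assert call.category is Consequence.MISSENSE
        assert call.notation == "Q20R"


class TestPrioritizeAndMap:
    REGIONS = RegionSet("ref", [
        RegionAnnotation("D1", 30, 60, RegionClass.DOMAIN),
        RegionAnnotation("D2", 80, 100, RegionClass.DOMAIN)])

    def test_nonsense_outranks_missense(self):
        calls = [
            ConsequenceCall(Consequence.MISSENSE, protein_pos=10,
                            notation="D10G", variant=make_variant(pos=5)),
            ConsequenceCall(Consequence.NONSENSE, protein_pos=70,
                            notation="Q70STOP", variant=make_variant(pos=9)),
        ]
        ranked = prioritize_and_map(calls, self.REGIONS)
        assert ranked[0].call.category is Consequence.NONSENSE

    def test_stop_at_first_residue_loses_everything(self):
        call = ConsequenceCall(Consequence.NONSENSE, protein_pos=1,
                               notation="M1STOP", variant=make_variant())
        entry = prioritize_and_map([call], self.REGIONS)[0]
        assert set(entry.truncation_map.values()) == {"lost"}

    def test_interior_stop_splits_regions(self):
        call = ConsequenceCall(Consequence.NONSENSE, protein_pos=70,
                               notation="Q70STOP", variant=make_variant())
        entry = prioritize_and_map([call], self.REGIONS)[0]
        assert entry.truncation_map == {"D1": "retained", "D2": "lost"}

    def test_stop_inside_region_truncates_it(self):
        call = ConsequenceCall(Consequence.NONSENSE, protein_pos=50,
                               notation="Q50STOP", variant=make_variant())
        entry = prioritize_and_map([call], self.REGIONS)[0]
        assert entry.truncation_map["D1"] == "truncated"


class TestUnionCallsets:
    def test_union_on_key_with_first_caller_precedence(self):
        a = [make_variant(pos=10, qual=300.0)]
        b = [make_variant(pos=10, qual=250.0), make_variant(pos=20)]
        merged = union_callsets(a, b)
        assert [v.pos for v in merged] == [10, 20]
        assert merged[0].qual == 300.0


class TestTriageEndToEnd:
    def test_cohort_recovered_exactly(self, tmp_path):
        """The pipeline reports precisely the planted lesion of every line:
        no balancer variant, noise variant or synonymous change survives."""
        for seed in (0, 1):
            truth = simulate_vcf_cohort(seed=seed)
            paths = write_cohort(truth, tmp_path / f"s{seed}")
            cohort = {line: read_vcf(p) for line, p in paths.items()}
            entries = triage_cohort(cohort, truth.transcript, truth.genome)
            assert set(entries) == set(truth.lesions)
            for line, want in truth.lesions.items():
                got = entries[line]
                assert got.call.category is Consequence.NONSENSE
                assert got.call.notation == want["notation"]
                assert got.call.variant.pos == want["pos"]

    def test_subthreshold_noise_never_passes_filter(self):
        truth = simulate_vcf_cohort(seed=3)
        for variants in truth.cohort.values():
            for v in variants:
                if v.qual < 199.0 or v.depth < 2:
                    assert site_filter(v) == "filtered"

    def test_transcript_table_roundtrip(self, tmp_path):
        tx = toy_transcript()
        p = tmp_path / "tx.tsv"
        write_transcript_table(tx, p)
        back = read_transcript_table(p)
        assert (back.chrom, back.strand, back.exons,
                back.cds_start, back.cds_end) == \
            (tx.chrom, tx.strand, tx.exons, tx.cds_start, tx.cds_end)
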