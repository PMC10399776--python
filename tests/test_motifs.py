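import numpy as np
import pytest

from idrcons.alignment import GAP, MultiAlignment
from idrcons.motifs import (AnnotationInterval, Motif, ScanConfig,
                            StructureConfidence, find_conserved_motifs,
                            interval_overlap, load_annotation_table,
                            model_confidence, motif_report,
                            _maximal_scoring_segments)
from idrcons.simulate import simulate_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def two_row_msa(ref: str, other: str) -> MultiAlignment:
    return MultiAlignment(rows={"ref": ref, "cmp": other})


def mismatch_of(s: str) -> str:
    table = str.maketrans(AA, AA[1:] + AA[0])
    return s.translate(table)


class TestFindConservedMotifs:
    def test_identical_rows_give_one_full_length_motif(self):
        row = ("ACDEFGHIKLMNPQRSTVWY" * 5)
        motifs = find_conserved_motifs(two_row_msa(row, row), "ref")
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.aln_start, m.aln_end) == (1, 100)
        assert m.identity == 100.0
        assert (m.ref_start, m.ref_end) == (1, 100)

    def test_island_in_mismatch_flanks_is_exact(self):
        """A 20-column identical block flanked by all-mismatch columns is
        reported exactly, with no extension into the flanks."""
        core = "ACDEFGHIKLMNPQRSTVWY"
        flank = "WYACDEFGHIKLMNPQRSTV"
        ref = flank + core + flank
        other = mismatch_of(flank) + core + mismatch_of(flank)
        motifs = find_conserved_motifs(two_row_msa(ref, other), "ref")
        assert [(m.aln_start, m.aln_end) for m in motifs] == [(21, 40)]
        assert motifs[0].identity == 100.0

    def test_exhaustive_window_check_on_toy_alignment(self, rng):
        """Every qualifying window of the toy alignment is inside a reported
        motif, and every reported motif meets the length/identity criteria."""
        n = 120
        match = rng.random(n) < 0.35
        match[40:70] = True  # one strong island
        ref = "".join(np.array(list(AA))[rng.integers(0, 20, n)])
        other = "".join(r if m else mismatch_of(r)
                        for r, m in zip(ref, match))
        cfg = ScanConfig(min_len=14, min_identity=60.0)
        motifs = find_conserved_motifs(two_row_msa(ref, other), "ref", cfg)
        covered = set()
        for m in motifs:
            assert m.n_columns >= cfg.min_len
            assert m.identity >= cfg.min_identity
            covered.update(range(m.aln_start - 1, m.aln_end))
        assert set(range(40, 70)) <= covered

    def test_gap_columns_never_match(self):
        core = "ACDEFGHIKLMNPQRSTVWY"
        ref = core + core
        other = core + "-" * 20
        motifs = find_conserved_motifs(two_row_msa(ref, other), "ref")
        assert [(m.aln_start, m.aln_end) for m in motifs] == [(1, 20)]

    def test_reference_coordinates_skip_gaps(self):
        core = "ACDEFGHIKLMNPQRSTVWY"
        ref = "-" * 5 + core
        other = "WYWYW" + core
        motifs = find_conserved_motifs(two_row_msa(ref, other), "ref")
        assert (motifs[0].ref_start, motifs[0].ref_end) == (1, 20)

    def test_comparator_must_exist(self):
        msa = two_row_msa("ACDE", "ACDE")
        with pytest.raises(KeyError):
            find_conserved_motifs(msa, "ref", ScanConfig(comparator_id="zz"))

    def test_motifs_sorted_and_disjoint(self, rng):
        n = 300
        match = rng.random(n) < 0.2
        for s in (30, 120, 240):
            match[s:s + 20] = rng.random(20) < 0.95
        ref = "".join(np.array(list(AA))[rng.integers(0, 20, n)])
        other = "".join(r if m else mismatch_of(r) for r, m in zip(ref, match))
        motifs = find_conserved_motifs(two_row_msa(ref, other), "ref")
        spans = [(m.aln_start, m.aln_end) for m in motifs]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_lower_threshold_never_shrinks_coverage(self, rng):
        """Coverage of reported motif columns grows monotonically as the
        identity threshold is lowered (min_len=1 isolates the threshold)."""
        n = 200
        ref = "".join(np.array(list(AA))[rng.integers(0, 20, n)])
        match = rng.random(n) < 0.5
        other = "".join(r if m else mismatch_of(r) for r, m in zip(ref, match))
        msa = two_row_msa(ref, other)
        prev: set[int] = set()
        for thr in (90.0, 70.0, 50.0, 30.0):
            cfg = ScanConfig(min_len=1, min_identity=thr)
            cov = set()
            for m in find_conserved_motifs(msa, "ref", cfg):
                cov.update(range(m.aln_start, m.aln_end + 1))
            assert prev <= cov, thr
            prev = cov

    def test_planted_motif_recovery_on_simulated_family(self):
        """Planted slow-evolving motifs are recovered from the true
        alignment with high recall and no spurious calls outside them."""
        hits = total = 0
        for seed in range(10):
            truth = simulate_family(seed=seed)
            taxon = truth.taxa[-1].id
            pa = truth.alignments[taxon]
            msa = MultiAlignment(rows={"ref": pa.row_a, taxon: pa.row_b})
            # restrict to the IDR columns like the real analysis does
            reg = truth.region_sets["ref"].get("IDR")
            respos, cols = 0, []
            for c, ch in enumerate(pa.row_a):
                if ch != GAP:
                    respos += 1
                if reg.start <= respos <= reg.end:
                    cols.append(c)
            lo, hi = cols[0], cols[-1]
            sub = MultiAlignment(rows={"ref": pa.row_a[lo:hi + 1],
                                       taxon: pa.row_b[lo:hi + 1]})
            found = [(m.aln_start + lo, m.aln_end + lo)
                     for m in find_conserved_motifs(sub, "ref")]
            spans = truth.true_motif_alignment_spans(taxon)
            for ts, te in spans:
                total += 1
                hits += any(min(te, fe) >= max(ts, fs) for fs, fe in found)
            for fs, fe in found:
                assert any(min(te, fe) >= max(ts, fs) for ts, te in spans), \
                    "reported motif outside any planted one"
        assert hits / total >= 0.9


class TestMaximalScoringSegments:
    def test_textbook_example(self):
        # classic Ruzzo-Tompa example
        scores = [4, -5, 3, -3, 1, 2, -2, 2, -2, 1, 5]
        segs = _maximal_scoring_segments([float(s) for s in scores])
        assert segs == [(0, 0), (2, 2), (4, 10)]

    def test_all_negative_yields_nothing(self):
        assert _maximal_scoring_segments([-1.0, -2.0]) == []

    def test_segments_have_positive_score_and_match_ends(self, rng):
        scores = list(rng.choice([0.52, -0.48], size=500, p=[0.4, 0.6]))
        for s, e in _maximal_scoring_segments(scores):
            assert scores[s] > 0 and scores[e] > 0
            assert sum(scores[s:e + 1]) > 0


class TestIntervalOverlap:
    def make_motif(self, start, end):
        return Motif(aln_start=start, aln_end=end, ref_start=start,
                     ref_end=end, identity=80.0)

    def test_exact_overlap(self):
        m = self.make_motif(10, 30)
        recs = interval_overlap([m], [AnnotationInterval("h1", 10, 30, "helix")])
        assert recs[0].overlap_length == 21
        assert recs[0].jaccard == 1.0
        assert m.helical

    def test_partial_overlap_hand_count(self):
        m = self.make_motif(10, 30)
        recs = interval_overlap([m], [AnnotationInterval("h1", 20, 40, "helix")])
        assert recs[0].overlap_length == 11
        assert recs[0].jaccard == pytest.approx(11 / 31)

    def test_disjoint(self):
        m = self.make_motif(10, 30)
        recs = interval_overlap([m], [AnnotationInterval("h1", 50, 60, "helix")])
        assert recs[0].overlap_length == 0 and recs[0].jaccard == 0.0
        assert not m.helical

    def test_helical_requires_helix_class(self):
        m = self.make_motif(10, 30)
        interval_overlap([m], [AnnotationInterval("site", 10, 30, "binding")])
        assert not m.helical

    def test_annotation_table_roundtrip(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("protein_id\tlabel\tstart\tend\tclass\n"
                     "cno\thelix-1\t1403\t1455\thelix\n"
                     "cno\tFAB\t1500\t1665\tbinding\n")
        ann = load_annotation_table(p)
        assert [a.label for a in ann["cno"]] == ["helix-1", "FAB"]


class TestModelConfidence:
    @pytest.mark.parametrize("ptm, iptm, expect", [
        (1.0, 1.0, 1.0),
        (0.0, 0.0, 0.0),
        (0.5, 1.0, 0.9),
    ])
    def test_weighted_combination(self, ptm, iptm, expect):
        assert model_confidence(StructureConfidence(ptm=ptm, iptm=iptm)) \
            == pytest.approx(expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            StructureConfidence(ptm=1.2, iptm=0.5)


def test_motif_report_written(tmp_path):
    m = Motif(aln_start=1, aln_end=20, ref_start=1, ref_end=20, identity=85.0)
    df = motif_report([m], tmp_path / "motifs.tsv")
    assert df.shape[0] == 1
    assert (tmp_path / "motifs.tsv").exists()
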