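import numpy as np
import pytest

import _oracles
from conftest import mini_config
from ntarseq import (
    AlignedRead,
    GenomeAnnotation,
    Interval,
    Transcript,
    build_exon_mask,
    classify_all,
    classify_ntar,
    condense_genes,
    coverage_track,
    detect_ntars,
    plant_recovery_report,
    simulate_genome,
    simulate_reads,
)
from ntarseq.discovery import DiscoveryError, NtarCandidate, _PRIORITY

SIZES = {"chr1": 100_000}


def _cand(start, end, chrom="chr1"):
    return NtarCandidate(Interval(chrom, start, end, "."), 5.0, 10, 3)


def _annotation(gene_defs):
    """gene_defs: list of (symbol, strand, [(exon_start, exon_end), ...])."""
    transcripts = [
        Transcript(f"{sym}.1", sym, [Interval("chr1", s, e, strand) for s, e in exons])
        for sym, strand, exons in gene_defs
    ]
    return GenomeAnnotation(transcripts, condense_genes(transcripts), SIZES)


class TestDetect:
    def _mask(self, intervals):
        transcripts = [
            Transcript(f"m{i}.1", f"m{i}", [Interval("chr1", s, e, "+")])
            for i, (s, e) in enumerate(intervals)
        ]
        return build_exon_mask(transcripts)

    def test_passing_candidate(self):
        # 60 bp unmasked run at depth >= 4, with >= 6 reads and >= 3 SPs
        reads = []
        for s in (1000, 1005, 1010, 1015, 1020, 1025):
            reads.append(AlignedRead("chr1", s, s + 35, "+"))
        track = coverage_track(reads, SIZES)
        (cand,) = detect_ntars(track, self._mask([]), min_length=50)
        assert (cand.interval.start, cand.interval.end) == (1000, 1060)
        assert cand.n_reads == 6 and cand.n_start_points == 6

    def test_run_below_minimum_length_rejected(self):
        # 49 bp run at depth 10 with 2 start points: length filter alone rejects
        reads = [AlignedRead("chr1", 1000, 1049, "+") for _ in range(9)]
        reads.append(AlignedRead("chr1", 1005, 1049, "+"))
        track = coverage_track(reads, SIZES)
        assert detect_ntars(track, self._mask([]), min_length=50) == []
        assert len(detect_ntars(track, self._mask([]), min_length=49)) == 1

    def test_mask_splitting_rejects_short_pieces(self):
        # 80 bp covered run whose middle 40 bp are masked -> two 20 bp runs, dropped
        reads = [AlignedRead("chr1", 1000, 1080, "+") for _ in range(6)]
        reads += [AlignedRead("chr1", s, s + 40, "+") for s in (1000, 1010, 1040)]
        track = coverage_track(reads, SIZES)
        assert detect_ntars(track, self._mask([(1020, 1060)])) == []
        # same coverage, no mask: one 80 bp candidate
        (cand,) = detect_ntars(track, self._mask([]))
        assert (cand.interval.start, cand.interval.end) == (1000, 1080)

    def test_low_mean_depth_rejected(self):
        reads = [AlignedRead("chr1", s, s + 35, "+") for s in (1000, 1010, 1020, 1030, 1040)]
        track = coverage_track(reads, SIZES)
        # depth ~ 2.3 on average over the 75 bp run
        assert detect_ntars(track, self._mask([]), min_avg_cov=3.0) == []
        assert len(detect_ntars(track, self._mask([]), min_avg_cov=2.0)) == 1

    def test_candidates_never_overlap_mask(self, mini_genome):
        mask = build_exon_mask(*mini_genome.sources.values())
        reads = [r for r in simulate_reads(mini_genome, "screening", "tissueA") if r.unique]
        track = coverage_track(reads, mini_genome.annotation.chrom_sizes)
        for cand in detect_ntars(track, mask):
            assert mask.overlap_bases(cand.interval) == 0


class TestClassify:
    def test_ise_outranks_exon_linked(self):
        ann = _annotation([("G", "+", [(10_000, 10_500), (10_800, 11_300)])])
        cls = classify_ntar(_cand(10_500, 10_800), ann)  # whole intron, flush both exons
        assert cls.label == "ISE"
        assert cls.related_gene.gene_symbol == "G"

    def test_far_candidate_is_nga(self):
        ann = _annotation([("G", "+", [(10_000, 11_000)])])
        assert classify_ntar(_cand(23_001, 23_100), ann).label == "NGA"  # 12,001 bp away
        assert classify_ntar(_cand(20_900, 21_000), ann).label == "DGN"  # 9,900 bp away

    def test_gene_intersection_strand_mirror(self):
        # flush with the right end of the span: DGI on '+', UGI on '-'
        for strand, expected in (("+", "DGI"), ("-", "UGI")):
            ann = _annotation([("G", strand, [(10_000, 10_500), (10_800, 11_300)])])
            cls = classify_ntar(_cand(11_300, 11_400), ann)
            assert cls.label == expected
            assert cls.distance == 0

    def test_intronic_placements_match_rule_table(self):
        # exhaustive sweep of a candidate across one gene's intron
        exons = [(10_000, 10_500), (11_000, 11_600)]
        for strand in "+-":
            ann = _annotation([("G", strand, exons)])
            for start in range(10_500, 10_951, 25):
                cand = _cand(start, start + 50)
                got = classify_ntar(cand, ann).label
                expected, _ = _oracles.brute_classify(
                    "chr1", start, start + 50, ann.condensed, window=10_000
                )
                assert got == expected, (strand, start)
                # hand rule: flush left edge -> ELD on '+', ELU on '-'; flush right
                # edge -> ELU on '+'; interior -> IGE; whole intron impossible (50 < 500)
                if start == 10_500:
                    assert got == ("ELD" if strand == "+" else "ELU")
                elif start + 50 == 11_000:
                    assert got == ("ELU" if strand == "+" else "ELD")
                else:
                    assert got == "IGE"

    def test_whole_intron_detection_requires_full_coverage(self):
        ann = _annotation([("G", "+", [(10_000, 10_500), (10_700, 11_300)])])
        assert classify_ntar(_cand(10_500, 10_700), ann).label == "ISE"
        assert classify_ntar(_cand(10_500, 10_699), ann).label == "ELD"
        assert classify_ntar(_cand(10_501, 10_700), ann).label == "ELU"
        assert classify_ntar(_cand(10_501, 10_699), ann).label == "IGE"

    def test_neighbourhood_binds_to_closest_gene(self):
        ann = _annotation(
            [("A", "+", [(10_000, 11_000)]), ("B", "+", [(20_000, 21_000)])]
        )
        cls = classify_ntar(_cand(12_000, 12_100), ann)  # 1000 from A, 7900 from B
        assert (cls.label, cls.related_gene.gene_symbol, cls.distance) == ("DGN", "A", 1000)
        cls = classify_ntar(_cand(18_000, 18_100), ann)  # 1900 from B upstream
        assert (cls.label, cls.related_gene.gene_symbol) == ("UGN", "B")

    def test_enclosing_gene_outranks_closer_neighbour(self):
        # candidate in an intron of A but nearer to B's span: gene-internal class wins
        ann = _annotation(
            [("A", "+", [(10_000, 10_100), (18_000, 18_100)]), ("B", "+", [(13_300, 14_000)])]
        )
        cand = _cand(13_000, 13_100)  # inside A's intron, 200 bp from B
        cls = classify_ntar(cand, ann)
        assert (cls.label, cls.related_gene.gene_symbol) == ("IGE", "A")

    def test_mask_overlap_precondition(self, mini_genome):
        mask = build_exon_mask(*mini_genome.sources.values())
        exon = mini_genome.annotation.condensed[0].exons[0]
        cand = _cand(exon.start, exon.end, chrom=exon.chrom)
        with pytest.raises(DiscoveryError, match="mask"):
            classify_ntar(cand, mini_genome.annotation, mask=mask)

    def test_classification_is_total_and_single_valued(self, mini_genome):
        rng = np.random.default_rng(13)
        cands = []
        mask = build_exon_mask(*mini_genome.sources.values())
        while len(cands) < 100:
            s = int(rng.integers(0, 99_000))
            iv = Interval("chr1", s, s + int(rng.integers(50, 400)))
            if mask.overlap_bases(iv) == 0:
                cands.append(NtarCandidate(iv, 5.0, 10, 3))
        classes = classify_all(cands, mini_genome.annotation, window=3000, mask=mask)
        assert len(classes) == len(cands)
        for cls in classes:
            assert cls.label in _PRIORITY or cls.label == "NGA"
            assert (cls.related_gene is None) == (cls.label == "NGA")


class TestStrandMirror:
    def test_mirroring_swaps_upstream_downstream(self):
        """Mirroring the coordinate axis (gene strands kept) swaps every U<->D
        label and preserves NGA/IGE/ISE; mirroring plus a strand flip (a true
        reverse complement) leaves every label unchanged.  Checked over 1000
        random candidates on a random gene set."""
        L = SIZES["chr1"]
        rng = np.random.default_rng(14)
        gene_defs, mirror_defs, revcomp_defs = [], [], []
        p = 5000
        for gi in range(6):
            n_ex = int(rng.integers(2, 5))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(100, 400))
                exons.append((p, p + length))
                p += length + int(rng.integers(200, 800))
            p += int(rng.integers(4000, 9000))
            strand = "+" if rng.random() < 0.5 else "-"
            m_exons = [(L - e, L - s) for s, e in reversed(exons)]
            gene_defs.append((f"g{gi}", strand, exons))
            mirror_defs.append((f"g{gi}", strand, m_exons))
            revcomp_defs.append((f"g{gi}", "-" if strand == "+" else "+", m_exons))
        ann = _annotation(gene_defs)
        ann_mirror = _annotation(mirror_defs)
        ann_revcomp = _annotation(revcomp_defs)
        mask = build_exon_mask(ann.transcripts)
        swap = {"UGN": "DGN", "DGN": "UGN", "UGI": "DGI", "DGI": "UGI", "ELU": "ELD", "ELD": "ELU"}
        n_done = 0
        while n_done < 1000:
            s = int(rng.integers(0, L - 400))
            iv = Interval("chr1", s, s + int(rng.integers(50, 400)))
            if mask.overlap_bases(iv) > 0:
                continue
            cls = classify_ntar(NtarCandidate(iv, 5.0, 10, 3), ann)
            ivm = Interval("chr1", L - iv.end, L - iv.start)
            cls_mirror = classify_ntar(NtarCandidate(ivm, 5.0, 10, 3), ann_mirror)
            cls_revcomp = classify_ntar(NtarCandidate(ivm, 5.0, 10, 3), ann_revcomp)
            assert cls_mirror.label == swap.get(cls.label, cls.label), (iv.start, iv.end, cls.label)
            assert cls_mirror.distance == cls.distance
            assert cls_revcomp.label == cls.label
            n_done += 1


class TestRecoveryReport:
    def _perfect(self, mini_genome):
        truth = [(n.interval, n.ntar_class) for n in mini_genome.truth.ntars]
        cands = [NtarCandidate(iv, 12.0, 20, 5) for iv, _ in truth]
        mask = build_exon_mask(*mini_genome.sources.values())
        classes = classify_all(cands, mini_genome.annotation, window=3000, mask=mask)
        return cands, classes, truth

    def test_perfect_detection_identity_matrix(self, mini_genome):
        cands, classes, truth = self._perfect(mini_genome)
        rep = plant_recovery_report(cands, classes, truth)
        assert rep["overall_recall"] == 1.0
        for label, stats in rep["per_class"].items():
            if stats["n_truth"]:
                assert stats["recall"] == 1.0 and stats["precision"] == 1.0

    def test_shifted_candidate_still_matches(self, mini_genome):
        truth = [(n.interval, n.ntar_class) for n in mini_genome.truth.ntars]
        iv, label = truth[0]
        shifted = Interval(iv.chrom, iv.start + 10, iv.end + 10)
        rep = plant_recovery_report(
            [NtarCandidate(shifted, 5.0, 10, 3)],
            [type("C", (), {"label": label})()],
            [(iv, label)],
        )
        assert rep["matrix"][label][label] == 1


def test_planted_classes_verified_by_rule_table():
    """Planted nTAR geometry must satisfy the independent per-base classifier."""
    for seed in range(5):
        genome = simulate_genome(mini_config(seed))
        genes = genome.annotation.condensed
        for planted in genome.truth.ntars:
            iv = planted.interval
            label, symbol = _oracles.brute_classify(iv.chrom, iv.start, iv.end, genes, window=3000)
            assert label == planted.ntar_class, (seed, planted)
            if planted.ntar_class != "NGA":
                assert symbol == planted.related_gene
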