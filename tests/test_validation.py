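import math

import numpy as np
import pytest

from conftest import mini_config
from ntarseq import (
    AlignedRead,
    Interval,
    Transcript,
    class_orientation_summary,
    condense_genes,
    confirm_polyA,
    coverage_track,
    detection_ratio,
    differential_ntar,
    simulate_genome,
    simulate_reads,
    validate_ntar,
)
from ntarseq.discovery import NtarCandidate, NtarClass
from ntarseq.validation import ValidationError

SIZES = {"chr1": 50_000}


def _gene(symbol="G", strand="+", exons=((1000, 2000),)):
    (g,) = condense_genes(
        [Transcript(f"{symbol}.1", symbol, [Interval("chr1", s, e, strand) for s, e in exons])]
    )
    return g


def _cand(start=5000, end=5200):
    return NtarCandidate(Interval("chr1", start, end, "."), 5.0, 10, 3)


def _stranded(n_plus, n_minus, start=5000):
    reads = [AlignedRead("chr1", start + i, start + i + 35, "+", "validation") for i in range(n_plus)]
    reads += [AlignedRead("chr1", start + i, start + i + 35, "-", "validation") for i in range(n_minus)]
    return reads


class TestValidate:
    def test_pure_sense_confirmed(self):
        v = validate_ntar(_cand(), NtarClass("IGE", _gene(strand="+"), 0), _stranded(5, 0))
        assert (v.confirmed, v.orientation, v.sense_reads, v.antisense_reads) == (True, "sense", 5, 0)

    def test_two_reads_unconfirmed(self):
        v = validate_ntar(_cand(), NtarClass("IGE", _gene(), 0), _stranded(2, 0))
        assert not v.confirmed

    def test_mixed_reads_are_ambiguous(self):
        v = validate_ntar(_cand(), NtarClass("IGE", _gene(), 0), _stranded(4, 2))
        assert v.confirmed and v.orientation == "ambiguous"

    def test_sense_is_gene_relative(self):
        v = validate_ntar(_cand(), NtarClass("DGN", _gene(strand="-"), 100), _stranded(0, 4))
        assert v.orientation == "sense" and v.sense_reads == 4

    def test_nga_orientation_undetermined(self):
        v = validate_ntar(_cand(), NtarClass("NGA", None, 15000), _stranded(4, 1))
        assert v.confirmed and v.orientation == "undetermined"
        assert (v.sense_reads, v.antisense_reads) == (4, 1)  # genomic-strand bookkeeping

    def test_orientation_partition(self, default_genome):
        """sense + antisense + ambiguous + undetermined = confirmed count."""
        from ntarseq import build_exon_mask, classify_all, detect_ntars

        mask = build_exon_mask(*default_genome.sources.values())
        screening = [r for r in simulate_reads(default_genome, "screening", "tissueA") if r.unique]
        val = [r for r in simulate_reads(default_genome, "validation", "tissueA") if r.unique]
        track = coverage_track(screening, default_genome.annotation.chrom_sizes)
        cands = detect_ntars(track, mask)
        classes = classify_all(cands, default_genome.annotation, mask=mask)
        validated = [validate_ntar(c, k, val) for c, k in zip(cands, classes)]
        confirmed = [v for v in validated if v.confirmed]
        by_orient = {}
        for v in confirmed:
            by_orient[v.orientation] = by_orient.get(v.orientation, 0) + 1
        assert sum(by_orient.values()) == len(confirmed)
        for v in confirmed:
            assert v.sense_reads + v.antisense_reads >= 3


class TestOrientationSummary:
    def _validated(self, label, orient, confirmed=True):
        v = validate_ntar(
            _cand(), NtarClass(label, _gene(), 0),
            _stranded(5, 0) if orient == "sense" else _stranded(0, 5),
        )
        return v

    def test_ratio_arithmetic(self):
        vs = [self._validated("IGE", "sense") for _ in range(10)]
        vs += [self._validated("IGE", "antisense") for _ in range(2)]
        (s,) = class_orientation_summary(vs)
        assert (s.ntar_class, s.n_sense, s.n_antisense, s.ratio) == ("IGE", 10, 2, 5.0)

    def test_zero_antisense_is_infinite(self):
        vs = [self._validated("ELU", "sense") for _ in range(3)]
        (s,) = class_orientation_summary(vs)
        assert math.isinf(s.ratio)

    def test_planted_sense_fraction_recovered(self):
        """Pooled over 20 seeded runs, the sense:antisense ratio among planted
        gene-related nTARs tracks the planted 9:1 mix within binomial error."""
        n_sense = n_anti = 0
        for seed in range(20):
            genome = simulate_genome(mini_config(seed, sense_fraction=0.9))
            val = [r for r in simulate_reads(genome, "validation", "tissueA") if r.unique]
            genes = {g.gene_symbol: g for g in genome.annotation.condensed}
            for p in genome.truth.ntars:
                if p.related_gene == ".":
                    continue
                cand = NtarCandidate(p.interval, 12.0, 20, 5)
                v = validate_ntar(cand, NtarClass(p.ntar_class, genes[p.related_gene], 0), val)
                if v.orientation == "sense":
                    n_sense += 1
                elif v.orientation == "antisense":
                    n_anti += 1
        total = n_sense + n_anti
        assert total > 100
        p_hat = n_sense / total
        se = math.sqrt(0.9 * 0.1 / total)
        assert abs(p_hat - 0.9) < 4 * se


class TestDetectionRatio:
    def test_quarter_ratio_bin(self):
        gene = _gene(exons=((1000, 2000),))
        reads = [AlignedRead("chr1", s, s + 100, "+") for s in range(1000, 2000, 100)] * 8
        reads += [AlignedRead("chr1", 5000, 5200, "+")] * 2
        track = coverage_track(reads, SIZES)
        ratio, label = detection_ratio(_cand(5000, 5200), gene, track)
        assert ratio == pytest.approx(0.25)
        assert label == "<=0.25"

    def test_unexpressed_gene_category(self):
        gene = _gene()
        track = coverage_track([AlignedRead("chr1", 5000, 5200, "+")] * 3, SIZES)
        ratio, label = detection_ratio(_cand(5000, 5200), gene, track)
        assert ratio is None and label == "related gene not expressed"

    def test_nga_raises(self):
        track = coverage_track([], SIZES)
        with pytest.raises(ValidationError):
            detection_ratio(_cand(), None, track)

    def test_matches_mean_depth_oracle_and_scale_invariance(self):
        rng = np.random.default_rng(15)
        gene = _gene(exons=((1000, 1400), (1600, 2000)))
        reads = [
            AlignedRead("chr1", int(s), int(s) + 50, "+")
            for s in rng.integers(900, 5300, size=400)
        ]
        track = coverage_track(reads, SIZES)
        track2 = coverage_track(reads * 3, SIZES)  # scale both depths by 3
        cand = _cand(5000, 5200)
        ratio, _ = detection_ratio(cand, gene, track)
        depth = np.zeros(SIZES["chr1"])
        for r in reads:
            depth[r.start : r.end] += 1
        gene_mean = (depth[1000:1400].sum() + depth[1600:2000].sum()) / 800
        assert ratio == pytest.approx(depth[5000:5200].mean() / gene_mean)
        ratio3, _ = detection_ratio(cand, gene, track2)
        assert ratio3 == pytest.approx(ratio)


class TestDifferential:
    def test_perfect_coregulation_not_differential(self):
        d = differential_ntar("n", 6.0, 1.0, 6.0, 1.0)
        assert d.corrected_fold == pytest.approx(1.0)
        assert not d.differential

    def test_nga_uncorrected(self):
        d = differential_ntar("n", 40.0, 10.0, None, None)
        assert d.differential and d.corrected_fold == pytest.approx(40 / 11)

    def test_direction_b_reports_reciprocal_fold(self):
        d = differential_ntar("n", 10.0, 120.0, None, None)
        assert d.differential
        assert d.corrected_fold == pytest.approx(11 / 120)

    def test_planted_excess_over_flat_gene_flagged(self):
        """An nTAR 5x up in tissue A over a flat gene is flagged in >= 90% of
        20 Poisson-resampled replicates."""
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cov_a = rng.poisson(60 * 200 / 35) * 35 / 200  # depth 60 target
            cov_b = rng.poisson(12 * 200 / 35) * 35 / 200  # depth 12
            gene_a = rng.poisson(500) / 50.0
            gene_b = rng.poisson(500) / 50.0
            d = differential_ntar("n", cov_a, cov_b, gene_a, gene_b)
            flagged += d.differential
        assert flagged >= 18

    def test_corrected_fold_is_one_for_covarying_pairs(self):
        rng = np.random.default_rng(16)
        for _ in range(200):
            base = 10 ** rng.uniform(-1, 2)
            fold = 10 ** rng.uniform(-1, 1)
            d = differential_ntar("n", base * fold, base, base * fold, base)
            assert d.corrected_fold == pytest.approx(1.0)
            assert not d.differential


class TestPolyA:
    def test_tag_ending_inside_confirms(self):
        tags = [AlignedRead("chr1", 5150, 5185, "+", "polyA_tag")]
        confirmed, orient = confirm_polyA(_cand(5000, 5200), tags, _gene(strand="+"))
        assert confirmed and orient == "sense"

    def test_overlapping_tag_with_outside_anchor_does_not_confirm(self):
        tags = [AlignedRead("chr1", 5180, 5215, "+", "polyA_tag")]  # 3' end at 5214
        confirmed, _ = confirm_polyA(_cand(5000, 5200), tags, _gene())
        assert not confirmed

    def test_minus_tag_anchor_is_leftmost_base(self):
        tags = [AlignedRead("chr1", 5100, 5135, "-", "polyA_tag")]
        confirmed, orient = confirm_polyA(_cand(5000, 5200), tags, _gene(strand="+"))
        assert confirmed and orient == "antisense"

    def test_planted_polyA_truth(self, default_genome):
        tags = simulate_reads(default_genome, "polyA", "tissueA")
        genes = {g.gene_symbol: g for g in default_genome.annotation.condensed}
        for p in default_genome.truth.ntars:
            cand = NtarCandidate(p.interval, 12.0, 20, 5)
            related = genes.get(p.related_gene)
            confirmed, _ = confirm_polyA(cand, tags, related)
            assert confirmed == p.polyA, p.ntar_id
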