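"""Detection of novel transcriptionally active regions (nTARs) and 9-class positional labelling.

An nTAR candidate is a maximal run of covered bases outside every
annotated exon that passes length, mean-depth, read-count and
start-point thresholds.  Each candidate is then placed into one of nine
positional classes relative to the condensed gene models:

====  =========================================================
ISE   intron-spanning: inside a gene, covers a whole intron
ELU   exon-linked upstream: flush with an exon's 5' edge
ELD   exon-linked downstream: flush with an exon's 3' edge
UGI   upstream gene intersection: flush with the gene's 5' end
DGI   downstream gene intersection: flush with the gene's 3' end
IGE   intragenic element: intronic, touching no exon
UGN   upstream gene neighbourhood: within the window, 5' side
DGN   downstream gene neighbourhood: within the window, 3' side
NGA   non-gene associated: farther than the window from any gene
====  =========================================================

When several rules match, the first in the priority order
ISE > ELD/ELU > UGI/DGI > IGE > UGN/DGN > NGA wins; up/downstream is
always relative to the related gene's strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import (
    CondensedGene,
    GenomeAnnotation,
    GenomicMask,
    Interval,
    genes_near,
    nearest_gene,
)
from .coverage import CoverageTrack, _runs

MIN_NTAR_LENGTH = 50
MIN_AVG_COV = 3.0
MIN_READS = 5
MIN_START_POINTS = 2
NEIGHBOURHOOD_WINDOW = 10_000

CLASS_LABELS = ("NGA", "UGN", "DGN", "UGI", "DGI", "ELU", "ELD", "IGE", "ISE")
# lower rank = higher priority; U/D twins share a rank
_PRIORITY = {"ISE": 0, "ELD": 1, "ELU": 1, "UGI": 2, "DGI": 2, "IGE": 3, "UGN": 4, "DGN": 4, "NGA": 5}


class DiscoveryError(ValueError):
    pass


@dataclass
class NtarCandidate:
    interval: Interval
    mean_depth: float
    n_reads: int
    n_start_points: int
    tissue: str = ""


@dataclass
class NtarClass:
    label: str
    related_gene: CondensedGene | None  # None iff NGA
    distance: int  # bp to the related gene (0 if inside or flush)


def detect_ntars(
    track: CoverageTrack,
    mask: GenomicMask,
    min_length: int = MIN_NTAR_LENGTH,
    min_avg_cov: float = MIN_AVG_COV,
    min_reads: int = MIN_READS,
    min_sp: int = MIN_START_POINTS,
    tissue: str = "",
) -> list[NtarCandidate]:
    """Maximal covered runs outside the exon mask passing all thresholds.

    Runs split by mask subtraction become separate candidates; thresholds
    apply to each piece independently.
    """
    out: list[NtarCandidate] = []
    for chrom in sorted(track.chrom_sizes):
        depth = track.depth_array(chrom)
        covered = depth >= 1
        for iv in mask.intervals.get(chrom, []):
            covered[iv.start : iv.end] = False
        for start, end in _runs(covered):
            if end - start < min_length:
                continue
            iv = Interval(chrom, start, end, ".")
            mean_depth = float(depth[start:end].mean())
            if mean_depth < min_avg_cov:
                continue
            n_reads = track.reads_overlapping(iv)
            if n_reads < min_reads:
                continue
            n_sp = track.start_points_in(iv)
            if n_sp < min_sp:
                continue
            out.append(NtarCandidate(iv, mean_depth, n_reads, n_sp, tissue))
    return out


def _classify_against_gene(
    cand: Interval, gene: CondensedGene, window: int, gap_tolerance: int
) -> tuple[str, int] | None:
    """Best (label, distance) achievable for this candidate against one gene."""
    span = gene.span
    plus = gene.strand == "+"
    overlaps_span = span.start < cand.end and cand.start < span.end
    if overlaps_span:
        # candidate never overlaps exons, so it sits in intronic space
        for intron in gene.introns:
            if cand.start <= intron.start and cand.end >= intron.end:
                return "ISE", 0
        # flush with an exon edge?  (touching the exon's 5' or 3' side)
        labels = []
        for exon in gene.exons:
            if abs(cand.end - exon.start) <= gap_tolerance and cand.end <= exon.start + gap_tolerance:
                # candidate ends at the exon's left edge
                labels.append("ELU" if plus else "ELD")
            if abs(cand.start - exon.end) <= gap_tolerance and cand.start >= exon.end - gap_tolerance:
                # candidate starts at the exon's right edge
                labels.append("ELD" if plus else "ELU")
        if labels:
            # ELD and ELU share priority; deterministic tie-break: ELD first
            return ("ELD" if "ELD" in labels else "ELU"), 0
        return "IGE", 0
    # outside the span
    if cand.end <= span.start:
        gap = span.start - cand.end
        left = True
    else:
        gap = cand.start - span.end
        left = False
    at_five_prime = left if plus else not left
    if gap <= gap_tolerance:
        return ("UGI" if at_five_prime else "DGI"), 0
    if gap <= window:
        return ("UGN" if at_five_prime else "DGN"), gap
    return None


def classify_ntar(
    cand: NtarCandidate,
    annotation: GenomeAnnotation,
    window: int = NEIGHBOURHOOD_WINDOW,
    mask: GenomicMask | None = None,
    gap_tolerance: int = 0,
) -> NtarClass:
    """Assign one of the nine positional classes to a candidate.

    Gene-internal classes bind to the enclosing gene; neighbourhood classes
    to the closest gene.  Conflicts resolve by class priority, then smaller
    distance, then gene order (span start, symbol).
    """
    iv = cand.interval
    if mask is not None and mask.overlap_bases(iv) > 0:
        raise DiscoveryError(f"candidate {iv.chrom}:{iv.start}-{iv.end} overlaps the exon mask")
    genes = genes_near(iv, annotation.genes_on(iv.chrom), window + gap_tolerance + 1)
    best: tuple[int, int, int, str, str, CondensedGene] | None = None
    for gene in genes:
        res = _classify_against_gene(iv, gene, window, gap_tolerance)
        if res is None:
            continue
        label, dist = res
        key = (_PRIORITY[label], dist, gene.span.start, gene.gene_symbol, label, gene)
        if best is None or key[:4] < best[:4]:
            best = key
    if best is None:
        g, dist, _side = nearest_gene(iv, annotation.genes_on(iv.chrom))
        return NtarClass("NGA", None, dist if g is not None else -1)
    _, dist, _, _, label, gene = best
    return NtarClass(label, gene, dist)


def classify_all(
    candidates: list[NtarCandidate],
    annotation: GenomeAnnotation,
    window: int = NEIGHBOURHOOD_WINDOW,
    mask: GenomicMask | None = None,
    gap_tolerance: int = 0,
) -> list[NtarClass]:
    return [classify_ntar(c, annotation, window, mask, gap_tolerance) for c in candidates]


# ---------------------------------------------------------------------------
# planted-truth comparison harness


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def plant_recovery_report(
    candidates: list[NtarCandidate],
    classes: list[NtarClass],
    truth: list[tuple[Interval, str]],
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Confusion matrix of predicted vs planted classes at >= 50% reciprocal overlap.

    Returns per-class recall/precision plus the raw matrix (rows = truth,
    columns = prediction, extra column 'missed' for unmatched truths and
    row 'spurious' for unmatched candidates).
    """
    labels = list(CLASS_LABELS)
    matrix = {t: {p: 0 for p in labels + ["missed"]} for t in labels + ["spurious"]}
    used = [False] * len(candidates)
    for t_iv, t_label in truth:
        best_j, best_ov = -1, min_reciprocal_overlap
        for j, c in enumerate(candidates):
            if used[j]:
                continue
            ov = _reciprocal_overlap(t_iv, c.interval)
            if ov >= best_ov:
                best_j, best_ov = j, ov
        if best_j < 0:
            matrix[t_label]["missed"] += 1
        else:
            used[best_j] = True
            matrix[t_label][classes[best_j].label] += 1
    for j, c in enumerate(candidates):
        if not used[j]:
            matrix["spurious"][classes[j].label] += 1
    per_class = {}
    for lab in labels:
        n_truth = sum(matrix[lab].values())
        n_pred = sum(matrix[t][lab] for t in labels + ["spurious"])
        tp = matrix[lab][lab]
        per_class[lab] = {
            "n_truth": n_truth,
            "recall": tp / n_truth if n_truth else float("nan"),
            "precision": tp / n_pred if n_pred else float("nan"),
        }
    total_truth = sum(sum(matrix[lab].values()) for lab in labels)
    total_correct = sum(matrix[lab][lab] for lab in labels)
    return {
        "matrix": matrix,
        "per_class": per_class,
        "overall_recall": total_correct / total_truth if total_truth else float("nan"),
    }


def write_candidates_bed(
    candidates: list[NtarCandidate], classes: list[NtarClass] | None, path: str
) -> None:
    """BED6: name = class:related_symbol, score = rounded mean depth."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            if classes is not None:
                cls = classes[i]
                sym = cls.related_gene.gene_symbol if cls.related_gene else "."
                name = f"{cls.label}:{sym}"
            else:
                name = f"candidate{i}"
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{name}\t{round(c.mean_depth)}\t.\n"
            )
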