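"""Independent brute-force reference implementations used only by the tests.

Everything here works per base with plain Python sets and loops, sharing
no code path with the package's interval/searchsorted implementations.
"""

from __future__ import annotations

import numpy as np


def brute_coverage(reads, chrom_sizes) -> dict:
    """Per-base depth by looping over every read and every base."""
    depth = {c: np.zeros(n, dtype=int) for c, n in chrom_sizes.items()}
    for r in reads:
        for s, e in [(r.start, r.end), *r.blocks]:
            for b in range(s, e):
                depth[r.chrom][b] += 1
    return depth


def brute_segments(depth: dict, min_depth: int = 1) -> list:
    """Maximal covered runs by linear scan."""
    out = []
    for chrom in sorted(depth):
        arr = depth[chrom]
        start = None
        for i, d in enumerate(arr):
            if d >= min_depth and start is None:
                start = i
            elif d < min_depth and start is not None:
                out.append((chrom, start, i))
                start = None
        if start is not None:
            out.append((chrom, start, len(arr)))
    return out


def brute_start_points(reads, chrom, start, end, strand="any") -> int:
    coords = set()
    for r in reads:
        if r.chrom != chrom:
            continue
        if strand in ("+", "-") and r.strand != strand:
            continue
        r_end = r.blocks[-1][1] if r.blocks else r.end
        if r.start < end and start < r_end:
            coords.add(r_end - 1 if r.strand == "-" else r.start)
    return len(coords)


def brute_reads_overlapping(reads, chrom, start, end) -> int:
    n = 0
    for r in reads:
        r_end = r.blocks[-1][1] if r.blocks else r.end
        if r.chrom == chrom and r.start < end and start < r_end:
            n += 1
    return n


def brute_detect(reads, chrom_sizes, mask_intervals, min_length=50, min_avg_cov=3.0,
                 min_reads=5, min_sp=2) -> list:
    """nTAR candidate intervals via per-base boolean arrays and rescans."""
    depth = brute_coverage(reads, chrom_sizes)
    out = []
    for chrom in sorted(chrom_sizes):
        keep = depth[chrom] >= 1
        for iv in mask_intervals.get(chrom, []):
            for b in range(iv.start, iv.end):
                keep[b] = False
        start = None
        runs = []
        for i, k in enumerate(keep):
            if k and start is None:
                start = i
            elif not k and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(keep)))
        for s, e in runs:
            if e - s < min_length:
                continue
            if depth[chrom][s:e].mean() < min_avg_cov:
                continue
            if brute_reads_overlapping(reads, chrom, s, e) < min_reads:
                continue
            if brute_start_points(reads, chrom, s, e) < min_sp:
                continue
            out.append((chrom, s, e))
    return out


def brute_classify(chrom, start, end, genes, window=10_000) -> tuple:
    """(label, related symbol) from the positional rule table, evaluated literally.

    genes: list of objects with gene_symbol, chrom, strand, exons (list with
    .start/.end), span.  Priority: ISE > ELD/ELU > UGI/DGI > IGE > UGN/DGN > NGA.
    """
    rank = {"ISE": 0, "ELD": 1, "ELU": 1, "UGI": 2, "DGI": 2, "IGE": 3, "UGN": 4, "DGN": 4}
    cand_bases = set(range(start, end))
    options = []  # (rank, distance, span start, symbol, label)
    for g in genes:
        if g.chrom != chrom:
            continue
        span = g.span
        span_bases = set(range(span.start, span.end))
        if cand_bases & span_bases:
            # inside the gene: ISE / ELU / ELD / IGE
            label = None
            for a, b in zip(g.exons, g.exons[1:]):
                intron = set(range(a.end, b.start))
                if intron and intron <= cand_bases:
                    label = "ISE"
                    break
            if label is None:
                touch = []
                for exon in g.exons:
                    if end == exon.start:  # flush with the exon's left edge
                        touch.append("ELU" if g.strand == "+" else "ELD")
                    if start == exon.end:  # flush with the exon's right edge
                        touch.append("ELD" if g.strand == "+" else "ELU")
                if touch:
                    label = "ELD" if "ELD" in touch else "ELU"
                else:
                    label = "IGE"
            options.append((rank[label], 0, span.start, g.gene_symbol, label))
        else:
            if end <= span.start:
                gap = span.start - end
                five_prime_side = g.strand == "+"
            else:
                gap = start - span.end
                five_prime_side = g.strand == "-"
            if gap == 0:
                label = "UGI" if five_prime_side else "DGI"
                options.append((rank[label], 0, span.start, g.gene_symbol, label))
            elif gap <= window:
                label = "UGN" if five_prime_side else "DGN"
                options.append((rank[label], gap, span.start, g.gene_symbol, label))
    if not options:
        return "NGA", "."
    options.sort()
    return options[0][4], options[0][3]
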