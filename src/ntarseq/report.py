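"""Pipeline orchestration and summary-report arithmetic.

``run_pipeline`` chains the stages — annotation loading, isoform
condensation, exon masking, coverage tracks, expression and presence
calls, nTAR detection/classification, strand-specific validation,
detection ratios, gene-corrected differential calls, optional
saturation — and assembles a :class:`RunReport` whose internal count
identities are checked on construction.  The small arithmetic helpers
(percent with half-up rounding, presence partitions, magnitude
histograms) live here because every printed summary number flows
through them.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from . import discovery, expression, saturation, validation
from .annotation import build_exon_mask
from .coverage import coverage_track, write_bedgraph
from .expression import ExpressionRecord
from .simulate import SimulatedGenome, SimulationConfig, simulate_genome, simulate_reads

logger = logging.getLogger("ntarseq")


class ReportError(ValueError):
    pass


def percent(part: int, whole: int, decimals: int = 1) -> float:
    """100*part/whole, rounded half-up at ``decimals`` (printed-scale percentage)."""
    if whole <= 0:
        raise ReportError("percentage denominator must be positive")
    value = Decimal(100) * Decimal(part) / Decimal(whole)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def presence_partition(
    records_a: list[ExpressionRecord], records_b: list[ExpressionRecord]
) -> tuple[int, int, int, int]:
    """(present in both, A only, B only, total present) over a shared unit universe."""
    a_map = {r.unit_id: r.present for r in records_a}
    b_map = {r.unit_id: r.present for r in records_b}
    if set(a_map) != set(b_map):
        raise ReportError("presence partition requires the same unit universe in both tissues")
    both = only_a = only_b = 0
    for uid, pa in a_map.items():
        pb = b_map[uid]
        if pa and pb:
            both += 1
        elif pa:
            only_a += 1
        elif pb:
            only_b += 1
    return both, only_a, only_b, both + only_a + only_b


def enhancement_tally(calls: list[expression.EnhancementCall]) -> tuple[int, int, int]:
    """(enhanced in A, enhanced in B, total differential) over shared-present units."""
    n_a = sum(1 for c in calls if c.enhanced_in == "A")
    n_b = sum(1 for c in calls if c.enhanced_in == "B")
    return n_a, n_b, n_a + n_b


MAGNITUDE_EDGES = (0.01, 0.1, 1.0, 10.0, 100.0)


def expression_magnitude_histogram(records: list[ExpressionRecord]) -> dict[str, int]:
    """Counts per order-of-magnitude FPKM class plus 'absent'; bins sum to the universe."""
    labels = [
        f"({MAGNITUDE_EDGES[i]:g},{MAGNITUDE_EDGES[i + 1]:g}]"
        for i in range(len(MAGNITUDE_EDGES) - 1)
    ] + [f">{MAGNITUDE_EDGES[-1]:g}"]
    out = {lab: 0 for lab in labels}
    out["absent"] = 0
    for r in records:
        if not r.present:
            out["absent"] += 1
            continue
        placed = False
        for i in range(len(MAGNITUDE_EDGES) - 1):
            if MAGNITUDE_EDGES[i] < r.fpkm <= MAGNITUDE_EDGES[i + 1]:
                out[labels[i]] += 1
                placed = True
                break
        if not placed:
            out[labels[-1]] += 1
    return out


@dataclass
class RunReport:
    """All dataset-level tallies of one pipeline run, with self-checking identities."""

    tissues: tuple[str, str]
    total_reads: dict = field(default_factory=dict)  # tissue -> reads used (screening)
    present_genes: dict = field(default_factory=dict)  # tissue -> present count
    present_both: int = 0
    present_only: dict = field(default_factory=dict)  # tissue -> exclusive count
    total_present: int = 0
    enhanced: dict = field(default_factory=dict)  # tissue -> enhanced count
    total_differential_shared: int = 0
    magnitude_histogram: dict = field(default_factory=dict)  # tissue -> histogram
    ntar_candidates: dict = field(default_factory=dict)  # tissue -> candidate count
    ntar_confirmed: dict = field(default_factory=dict)
    class_counts: dict = field(default_factory=dict)  # tissue -> {label: confirmed count}
    orientation_ratios: dict = field(default_factory=dict)  # tissue -> {label: ratio}
    detection_ratio_bins: dict = field(default_factory=dict)  # tissue -> {bin: count}
    differential_ntars: int = 0
    polyA_confirmed: dict = field(default_factory=dict)
    saturation_asymptote: float | None = None
    recovery: dict | None = None  # planted-truth metrics when simulated

    def check_identities(self) -> None:
        a, b = self.tissues
        if self.present_both + self.present_only[a] + self.present_only[b] != self.total_present:
            raise ReportError("presence partition identity violated")
        if self.enhanced and self.enhanced[a] + self.enhanced[b] != self.total_differential_shared:
            raise ReportError("enhancement tally identity violated")
        for tissue, counts in self.class_counts.items():
            if sum(counts.values()) != self.ntar_confirmed[tissue]:
                raise ReportError(f"class counts do not sum to confirmed nTARs in {tissue}")

    def to_json(self, path: str) -> None:
        def _default(o):
            if isinstance(o, float) and o != o:
                return None
            return str(o)

        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=_default)

    def to_text(self) -> str:
        a, b = self.tissues
        lines = [
            "ntarseq run report",
            "==================",
            f"screening reads used: {a}={self.total_reads.get(a)}, {b}={self.total_reads.get(b)}",
            f"present genes: {a}={self.present_genes.get(a)}, {b}={self.present_genes.get(b)}",
            f"present in both: {self.present_both}; only {a}: {self.present_only.get(a)}; "
            f"only {b}: {self.present_only.get(b)}; total present: {self.total_present}",
            f"tissue-enhanced (shared present): {a}={self.enhanced.get(a)}, "
            f"{b}={self.enhanced.get(b)}, total={self.total_differential_shared}",
        ]
        for tissue in self.tissues:
            lines.append(
                f"nTARs {tissue}: candidates={self.ntar_candidates.get(tissue)}, "
                f"confirmed={self.ntar_confirmed.get(tissue)}"
            )
            counts = self.class_counts.get(tissue, {})
            if counts:
                lines.append(
                    "  classes: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
                )
        if self.saturation_asymptote is not None:
            lines.append(f"saturation asymptote (detectable genes): {self.saturation_asymptote:.1f}")
        if self.recovery is not None:
            lines.append(
                f"planted-truth recovery: {self.recovery['overall_recall']:.3f} "
                f"correct class; orientation accuracy "
                f"{self.recovery.get('orientation_accuracy', float('nan')):.3f}"
            )
        return "\n".join(lines)


def run_pipeline(
    config: SimulationConfig | dict | str,
    outdir: str | None = None,
    run_saturation: bool = False,
    thresholds: dict | None = None,
) -> RunReport:
    """Execute every stage on a synthetic run defined by ``config``.

    ``config`` may be a :class:`SimulationConfig`, a dict of its fields, or
    a path to a JSON file of them.  Intermediate artifacts are written
    under ``outdir`` when given.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = json.load(fh)
    if isinstance(config, dict):
        cfg_fields = {f.name for f in SimulationConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        config = SimulationConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in config.items() if k in cfg_fields
        })
    th = {
        "min_ntar_length": discovery.MIN_NTAR_LENGTH,
        "min_avg_cov": discovery.MIN_AVG_COV,
        "min_reads": discovery.MIN_READS,
        "min_sp": discovery.MIN_START_POINTS,
        "confirm_reads": validation.CONFIRM_MIN_READS,
        "window": config.neighbourhood_window,
        "fold": 3.0,
        "penalty": 1.0,
        "present_fpkm": expression.PRESENCE_FPKM,
    }
    th.update(thresholds or {})

    logger.info("stage simulate: seed=%d genes=%d", config.seed, config.n_genes)
    genome = simulate_genome(config)
    return _run_on_genome(genome, outdir, run_saturation, th)


def _run_on_genome(
    genome: SimulatedGenome, outdir: str | None, run_saturation: bool, th: dict
) -> RunReport:
    cfg = genome.config
    a, b = cfg.tissues
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    annotation = genome.annotation
    condensed = annotation.condensed
    logger.info("stage condense: %d transcripts -> %d condensed genes",
                len(annotation.transcripts), len(condensed))
    mask = build_exon_mask(
        *(genome.sources[tag] for tag in sorted(genome.sources)),
        chrom_sizes=annotation.chrom_sizes,
    )
    logger.info("stage mask: %d masked bases", mask.masked_bases())

    report = RunReport(tissues=cfg.tissues)
    tracks, val_reads, records = {}, {}, {}
    for tissue in cfg.tissues:
        screening = simulate_reads(genome, "screening", tissue)
        validating = simulate_reads(genome, "validation", tissue)
        screening = [r for r in screening if r.unique]
        validating = [r for r in validating if r.unique]
        logger.info("stage tracks[%s]: %d screening, %d validation unique reads",
                    tissue, len(screening), len(validating))
        tracks[tissue] = coverage_track(screening, annotation.chrom_sizes, stranded=False)
        val_reads[tissue] = validating
        report.total_reads[tissue] = len(screening)
        records[tissue] = expression.quantify(
            condensed, tracks[tissue], tissue, threshold=th["present_fpkm"]
        )
        report.present_genes[tissue] = sum(r.present for r in records[tissue])
        report.magnitude_histogram[tissue] = expression_magnitude_histogram(records[tissue])

    both, only_a, only_b, total = presence_partition(records[a], records[b])
    report.present_both, report.total_present = both, total
    report.present_only = {a: only_a, b: only_b}
    fpkm_a = {r.unit_id: r.fpkm for r in records[a]}
    fpkm_b = {r.unit_id: r.fpkm for r in records[b]}
    present_b = {r.unit_id for r in records[b] if r.present}
    shared = [r.unit_id for r in records[a] if r.present and r.unit_id in present_b]
    calls = [
        expression.enhancement_call(uid, fpkm_a[uid], fpkm_b[uid], th["fold"], th["penalty"])
        for uid in shared
    ]
    n_a, n_b, n_tot = enhancement_tally(calls)
    report.enhanced = {a: n_a, b: n_b}
    report.total_differential_shared = n_tot

    polyA = {t: simulate_reads(genome, "polyA", t) for t in cfg.tissues}
    validated_by_tissue = {}
    for tissue in cfg.tissues:
        candidates = discovery.detect_ntars(
            tracks[tissue], mask,
            min_length=th["min_ntar_length"], min_avg_cov=th["min_avg_cov"],
            min_reads=th["min_reads"], min_sp=th["min_sp"], tissue=tissue,
        )
        classes = discovery.classify_all(candidates, annotation, th["window"], mask)
        logger.info("stage detect[%s]: %d candidates", tissue, len(candidates))
        validated = []
        for cand, cls in zip(candidates, classes):
            v = validation.validate_ntar(cand, cls, val_reads[tissue], th["confirm_reads"])
            if cls.related_gene is not None:
                v.detection_ratio, v.detection_ratio_bin = validation.detection_ratio(
                    cand, cls.related_gene, tracks[tissue]
                )
            v.polyA_confirmed, _ = validation.confirm_polyA(
                cand, polyA[tissue], cls.related_gene
            )
            validated.append(v)
        validated_by_tissue[tissue] = validated
        confirmed = [v for v in validated if v.confirmed]
        report.ntar_candidates[tissue] = len(candidates)
        report.ntar_confirmed[tissue] = len(confirmed)
        counts: dict[str, int] = {}
        for v in confirmed:
            counts[v.ntar_class.label] = counts.get(v.ntar_class.label, 0) + 1
        report.class_counts[tissue] = counts
        report.orientation_ratios[tissue] = {
            s.ntar_class: s.ratio for s in validation.class_orientation_summary(validated)
        }
        bins: dict[str, int] = {}
        for v in validated:
            if v.detection_ratio_bin:
                bins[v.detection_ratio_bin] = bins.get(v.detection_ratio_bin, 0) + 1
        report.detection_ratio_bins[tissue] = bins
        report.polyA_confirmed[tissue] = sum(v.polyA_confirmed for v in confirmed)
        if outdir:
            validation.write_validated_tsv(
                validated, os.path.join(outdir, f"ntars_{tissue}.tsv")
            )
            validation.write_validated_bed(
                validated, os.path.join(outdir, f"ntars_{tissue}.bed")
            )
            write_bedgraph(tracks[tissue], os.path.join(outdir, f"coverage_{tissue}"))

    # cross-tissue differential nTARs, gene-corrected, on tissue A's confirmed set
    n_diff = 0
    for v in validated_by_tissue[a]:
        if not v.confirmed:
            continue
        cov_a = tracks[a].mean_depth(v.candidate.interval)
        cov_b = tracks[b].mean_depth(v.candidate.interval)
        if v.ntar_class.related_gene is not None:
            sym = v.ntar_class.related_gene.gene_symbol
            d = validation.differential_ntar(
                "x", cov_a, cov_b, fpkm_a[sym], fpkm_b[sym], th["fold"], th["penalty"]
            )
        else:
            d = validation.differential_ntar(
                "x", cov_a, cov_b, None, None, th["fold"], th["penalty"]
            )
        n_diff += d.differential
    report.differential_ntars = n_diff

    if run_saturation:
        screening_a = [r for r in simulate_reads(genome, "screening", a) if r.unique]
        step = max(len(screening_a) // 30, 1)
        curve = saturation.detection_curve(screening_a, condensed, step, seed=cfg.seed)
        try:
            fit = saturation.fit_saturation(curve)
            report.saturation_asymptote = saturation.estimate_max_genes(fit)
        except saturation.SaturationError as exc:
            logger.warning("saturation fit failed: %s", exc)

    # planted-truth comparison (simulation is always the input here)
    truth_pairs = [(n.interval, n.ntar_class) for n in genome.truth.ntars]
    candidates_a = [v.candidate for v in validated_by_tissue[a]]
    classes_a = [v.ntar_class for v in validated_by_tissue[a]]
    recovery = discovery.plant_recovery_report(candidates_a, classes_a, truth_pairs)
    recovery["orientation_accuracy"] = _orientation_accuracy(
        validated_by_tissue[a], genome.truth.ntars
    )
    report.recovery = recovery

    report.check_identities()
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        report.to_json(os.path.join(outdir, "report.json"))
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(report.to_text() + "\n")
    return report


def _orientation_accuracy(validated, planted) -> float:
    """Fraction of unambiguous confirmed calls matching the planted orientation."""
    from .discovery import _reciprocal_overlap

    n_ok = n_tot = 0
    for v in validated:
        if not v.confirmed or v.orientation not in ("sense", "antisense"):
            continue
        for p in planted:
            if p.orientation in ("sense", "antisense") and \
                    _reciprocal_overlap(v.candidate.interval, p.interval) >= 0.5:
                n_tot += 1
                n_ok += v.orientation == p.orientation
                break
    return n_ok / n_tot if n_tot else float("nan")
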