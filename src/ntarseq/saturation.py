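"""Gene-detection saturation curves and asymptote estimation by iterative refitting.

Reads are drawn at random without replacement; after each increment the
number of condensed genes with at least ``min_reads`` assigned reads is
recorded.  A saturating model is fitted, then refitted on the points at
and beyond the second crossing of the fitted curve with the observed
sequence, repeating until the Pearson correlation of the current fit
reaches the target.  The model asymptote estimates the total number of
genes detectable at unlimited sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .annotation import CondensedGene
from .coverage import AlignedRead


class SaturationError(ValueError):
    pass


@dataclass
class SaturationCurve:
    points: list[tuple[int, int]]  # (reads drawn, genes detected)
    min_reads_for_detection: int
    seed: int

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass
class SaturationFit:
    model: str  # 'hyperbolic' | 'exponential'
    asymptote: float  # a: genes detectable at unlimited depth
    half_saturation: float  # b: reads at half (hyperbolic) / e-fold (exponential) saturation
    correlation: float  # Pearson r over the points used in the final round
    refit_rounds: int
    fit_window_start: int  # index of the first point used in the final fit

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _MODELS[self.model](np.asarray(x, dtype=float), self.asymptote, self.half_saturation)


def _hyperbolic(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * x / (b + x)


def _exponential(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * (1.0 - np.exp(-x / b))


_MODELS = {"hyperbolic": _hyperbolic, "exponential": _exponential}


def assign_reads_to_genes(
    reads: list[AlignedRead], condensed: list[CondensedGene]
) -> np.ndarray:
    """Map each read to the index of a condensed gene (or -1 if intergenic/intronic).

    A read counts toward a gene when it overlaps any exonic base; a read
    touching two genes is credited to the one with the larger overlap
    (ties: first gene in sorted order).
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, g in enumerate(condensed):
        for e in g.exons:
            by_chrom.setdefault(g.chrom, []).append((e.start, e.end, gi))
    starts_map, ends_map, gis_map = {}, {}, {}
    for chrom, exons in by_chrom.items():
        exons.sort()
        starts_map[chrom] = np.array([e[0] for e in exons], dtype=np.int64)
        ends_map[chrom] = np.array([e[1] for e in exons], dtype=np.int64)
        gis_map[chrom] = np.array([e[2] for e in exons], dtype=np.int64)
    out = np.full(len(reads), -1, dtype=np.int64)
    for ri, r in enumerate(reads):
        starts = starts_map.get(r.chrom)
        if starts is None:
            continue
        ends, gis = ends_map[r.chrom], gis_map[r.chrom]
        iv = r.interval
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        best_gi, best_ov = -1, 0
        for k in range(lo, hi):
            ov = min(iv.end, int(ends[k])) - max(iv.start, int(starts[k]))
            if ov > best_ov:
                best_gi, best_ov = int(gis[k]), ov
        out[ri] = best_gi
    return out


def detection_curve(
    reads: list[AlignedRead],
    condensed: list[CondensedGene],
    step: int,
    min_reads: int = 5,
    seed: int = 0,
) -> SaturationCurve:
    """Randomly draw reads in increments of ``step`` and record detected genes.

    A gene is detected once its cumulative drawn-read count reaches
    ``min_reads``.  The final point always uses every read, so it is
    independent of the drawing order.
    """
    if step < 1:
        raise SaturationError("step must be >= 1")
    rng = np.random.default_rng(seed)
    gene_of = assign_reads_to_genes(reads, condensed)
    order = rng.permutation(len(reads))
    shuffled = gene_of[order]
    counts = np.zeros(len(condensed), dtype=np.int64)
    detected = 0
    points: list[tuple[int, int]] = []
    drawn = 0
    while drawn < len(reads):
        take = min(step, len(reads) - drawn)
        chunk = shuffled[drawn : drawn + take]
        chunk = chunk[chunk >= 0]
        if len(chunk):
            add = np.bincount(chunk, minlength=len(condensed))
            newly = np.count_nonzero((counts < min_reads) & (counts + add >= min_reads))
            counts += add
            detected += int(newly)
        drawn += take
        points.append((drawn, detected))
    if not points:
        points = [(0, 0)]
    return SaturationCurve(points, min_reads, seed)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fit_once(x: np.ndarray, y: np.ndarray, model: str) -> tuple[float, float]:
    f = _MODELS[model]
    a0 = max(float(y.max()), 1.0)
    b0 = max(float(x[np.searchsorted(y, y.max() / 2.0)]), 1.0) if len(x) > 1 else 1.0
    popt, _ = curve_fit(
        f, x, y, p0=(a0 * 1.2, b0), bounds=((1e-9, 1e-9), (np.inf, np.inf)), maxfev=20000
    )
    return float(popt[0]), float(popt[1])


def _second_sign_change(residuals: np.ndarray) -> int | None:
    """Index just after the second sign change of the residual sequence."""
    changes = 0
    for i in range(1, len(residuals)):
        s_prev = np.sign(residuals[i - 1]) or 1.0
        s_cur = np.sign(residuals[i]) or 1.0
        if s_cur != s_prev:
            changes += 1
            if changes == 2:
                return i
    return None


def fit_saturation(
    curve: SaturationCurve,
    model: str = "hyperbolic",
    r_target: float = 0.99,
    max_rounds: int = 20,
    min_improvement: float = 1e-4,
) -> SaturationFit:
    """Fit the saturating model, iteratively restricting to points past the
    second crossing of fit and data until the correlation reaches ``r_target``.
    """
    if model not in _MODELS:
        raise SaturationError(f"unknown model {model!r}")
    x_all, y_all = curve.x, curve.y
    if len(x_all) < 4:
        raise SaturationError("need at least 4 curve points to fit")
    if np.all(y_all == 0):
        raise SaturationError("degenerate curve: no genes ever detected")
    window = 0
    rounds = 0
    last_r = -np.inf
    best: SaturationFit | None = None
    while True:
        x, y = x_all[window:], y_all[window:]
        try:
            a, b = _fit_once(x, y, model)
        except RuntimeError as exc:
            if best is not None:
                return best
            raise SaturationError(f"non-convergent fit (window={window}): {exc}") from exc
        fitted = _MODELS[model](x, a, b)
        r = _pearson(y, fitted)
        best = SaturationFit(model, a, b, r, rounds, window)
        if r >= r_target or rounds >= max_rounds or (r - last_r) < min_improvement and rounds > 0:
            return best
        cross = _second_sign_change(y - fitted)
        if cross is None or len(x) - cross < 4:
            return best
        window += cross
        rounds += 1
        last_r = r


def estimate_max_genes(fit: SaturationFit) -> float:
    """Asymptote of the fitted model: genes detectable as reads -> infinity."""
    return fit.asymptote


def write_curve_tsv(curve: SaturationCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reads_drawn\tgenes_detected\n")
        for x, y in curve.points:
            fh.write(f"{x}\t{y}\n")
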