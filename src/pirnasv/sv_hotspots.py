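"""Consensus filtering of SV call sets and kernel-density SV hotspot
detection with permutation significance.

Hotspot calling follows the hotspotter approach: SV midpoints are smoothed
with a Gaussian kernel of a per-chromosome-class bandwidth, the same number
of points is re-placed uniformly ``num_trial`` times, and maximal runs of
grid points whose empirical p-value is at or below alpha become hotspots
(extended by bw/2 per side and merged).

The empirical p at a grid point is the fraction of null trials whose
maximum density anywhere on the chromosome reaches the observed density at
that point.  Referencing the null maximum makes the test family-wise: on
uniform data whole chromosomes produce no calls at alpha = 0.001, instead
of every isolated event exceeding a pointwise null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from pirnasv.core_model import ChromSizes, GenomicInterval, SVRecord

__all__ = [
    "ConsensusParams",
    "Hotspot",
    "ChromClass",
    "BANDWIDTH_CANDIDATES",
    "consensus_sv",
    "classify_chromosomes",
    "call_hotspots",
    "select_bandwidth",
]

BANDWIDTH_CANDIDATES = (200, 2_000, 20_000, 200_000, 2_000_000)
MICRO_MAX = 20_000_000  # microchromosome: < 20 Mb
BW_MACRO = 2_000
BW_MICRO = 200
BW_SEX = 20_000


@dataclass
class ConsensusParams:
    min_support: int = 10
    min_score: float = 10.0
    slop: int = 500
    min_reciprocal: float = 0.5

    def __post_init__(self):
        if self.slop < 0:
            raise ValueError("slop must be >= 0")
        if not 0 < self.min_reciprocal <= 1:
            raise ValueError("min_reciprocal must be in (0, 1]")


@dataclass
class Hotspot:
    interval: GenomicInterval
    sv_count: int
    p_empirical: float
    bw: int


@dataclass
class ChromClass:
    label: str  # macro | intermediate | micro | sex | unassigned
    bw: int


def _breakpoints_match(a: SVRecord, b: SVRecord, slop: int) -> bool:
    return (abs(a.interval.start - b.interval.start) <= slop
            and abs(a.interval.end - b.interval.end) <= slop)


def consensus_sv(calls_a, calls_b, params: ConsensusParams | None = None
                 ) -> list[SVRecord]:
    """Two-caller consensus.

    DEL/INV/DUP from caller A are kept only when a same-type record in
    caller B has both breakpoints within ``slop`` and reciprocal size
    ratio >= ``min_reciprocal``; INS are kept from caller A alone.  Kept
    records must satisfy ``min_support`` (caller A); matched records must
    also satisfy ``min_score`` (caller B).
    """
    if params is None:
        params = ConsensusParams()
    b_by_key: dict[tuple[str, str], list[SVRecord]] = {}
    for rec in calls_b:
        b_by_key.setdefault((rec.interval.chrom, rec.sv_type), []).append(rec)

    kept: list[SVRecord] = []
    for rec in calls_a:
        if rec.support_reads < params.min_support:
            continue
        if rec.sv_type == "INS":
            kept.append(rec)
            continue
        for other in b_by_key.get((rec.interval.chrom, rec.sv_type), ()):
            if not _breakpoints_match(rec, other, params.slop):
                continue
            ratio = min(rec.length, other.length) / max(rec.length, other.length)
            if ratio < params.min_reciprocal:
                continue
            if other.score < params.min_score:
                continue
            kept.append(rec)
            break
    return kept


def classify_chromosomes(sizes: ChromSizes, sex_names=(),
                         unassigned_names=()) -> dict[str, ChromClass]:
    """Per-chromosome class and kernel bandwidth.

    Sex chromosomes get bw 20,000; chromosomes < 20 Mb (and unassigned
    contigs) get bw 200; everything else (macro/intermediate) gets bw
    2,000.
    """
    sex = set(sex_names)
    unassigned = set(unassigned_names)
    out: dict[str, ChromClass] = {}
    for name, length in sizes.items():
        if name in sex:
            out[name] = ChromClass("sex", BW_SEX)
        elif name in unassigned:
            out[name] = ChromClass("unassigned", BW_MICRO)
        elif length < MICRO_MAX:
            out[name] = ChromClass("micro", BW_MICRO)
        elif length >= 40_000_000:
            out[name] = ChromClass("macro", BW_MACRO)
        else:
            out[name] = ChromClass("intermediate", BW_MACRO)
    return out


_SIGMA_BINS = 10.0  # grid step is bw/10, so the kernel sd is 10 bins
_KERNEL_HALF = int(4 * _SIGMA_BINS)
_KERNEL = np.exp(-np.arange(-_KERNEL_HALF, _KERNEL_HALF + 1) ** 2
                 / (2 * _SIGMA_BINS ** 2))
_KERNEL /= _KERNEL.sum()


def _batch_density(points: np.ndarray, n_grid: int, step: float) -> np.ndarray:
    """Gaussian-kernel density on the grid for a (T, n) batch of points.

    Point sets are sparse relative to the grid, so each point scatters its
    truncated kernel directly instead of smoothing a full histogram.
    """
    if points.ndim == 1:
        points = points[None, :]
    T, n = points.shape
    bins = (points / step).astype(np.int64).clip(0, n_grid - 1)
    offsets = np.arange(-_KERNEL_HALF, _KERNEL_HALF + 1)
    idx = bins[:, :, None] + offsets[None, None, :]
    weights = np.tile(_KERNEL, T * n)
    inside = ((idx >= 0) & (idx < n_grid)).ravel()
    flat = (idx + np.arange(T)[:, None, None] * n_grid).ravel()
    dens = np.bincount(flat[inside], weights=weights[inside],
                       minlength=T * n_grid)
    return dens.reshape(T, n_grid)


def call_hotspots(svs, sizes: ChromSizes, bw_per_chrom,
                  num_trial: int = 1000, alpha: float = 0.001,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> list[Hotspot]:
    """Kernel-density hotspot calling with a uniform-replacement null.

    ``bw_per_chrom`` maps chromosome name to bandwidth (bp) or may be a
    single integer applied everywhere.  Chromosomes with < 2 SVs are
    skipped; chromosomes shorter than the bandwidth are skipped with a
    warning.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(bw_per_chrom, int):
        bw_map = {name: bw_per_chrom for name in sizes}
    elif isinstance(bw_per_chrom, dict) and bw_per_chrom and isinstance(
            next(iter(bw_per_chrom.values())), ChromClass):
        bw_map = {name: cc.bw for name, cc in bw_per_chrom.items()}
    else:
        bw_map = dict(bw_per_chrom)

    points_by_chrom: dict[str, list[int]] = {}
    for rec in svs:
        points_by_chrom.setdefault(rec.interval.chrom, []).append(rec.midpoint)

    hotspots: list[Hotspot] = []
    for chrom in sorted(points_by_chrom):
        pts = np.array(sorted(points_by_chrom[chrom]), dtype=float)
        if pts.size < 2:
            continue
        chrom_len = sizes[chrom]
        bw = bw_map[chrom]
        if bw >= chrom_len:
            warnings.warn(f"bandwidth {bw} >= length of {chrom}; skipped")
            continue
        step = bw / 10
        n_grid = int(np.ceil(chrom_len / step))
        observed = _batch_density(pts, n_grid, step)[0]

        # null: uniform re-placement of the same number of points; record
        # each trial's maximum density anywhere on the chromosome
        null_max = np.empty(num_trial)
        # keep both the scatter target and the scatter source small enough
        # to stay in cache
        batch = max(1, min(num_trial, int(5e5 // n_grid),
                           int(2e6 // (pts.size * _KERNEL.size))))
        done = 0
        while done < num_trial:
            b = min(batch, num_trial - done)
            null_pts = rng.uniform(0, chrom_len, size=(b, pts.size))
            dens = _batch_density(null_pts, n_grid, step)
            null_max[done:done + b] = dens.max(axis=1)
            done += b
        null_max.sort()
        # p[g] = fraction of trials whose max density >= observed[g]
        pvals = 1.0 - np.searchsorted(null_max, observed - 1e-12,
                                      side="left") / num_trial

        sig = pvals <= alpha
        if not sig.any():
            continue
        # maximal significant runs -> intervals, extended by bw/2, merged
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8),
                                                       [0]))))
        raw_runs = [(edges[i], edges[i + 1] - 1) for i in range(0, len(edges), 2)]
        intervals = []
        for g0, g1 in raw_runs:
            start = max(0, int(g0 * step - bw / 2))
            end = min(chrom_len, int((g1 + 1) * step + bw / 2))
            intervals.append([start, end, pvals[g0:g1 + 1].min()])
        merged = [intervals[0]]
        for start, end, p in intervals[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] = min(merged[-1][2], p)
            else:
                merged.append([start, end, p])
        for start, end, p in merged:
            n_in = int(((pts >= start) & (pts < end)).sum())
            if n_in < 1:
                continue
            hotspots.append(Hotspot(GenomicInterval(chrom, start, end),
                                    n_in, float(p), bw))
    return hotspots


def select_bandwidth(svs, sizes: ChromSizes,
                     candidates=BANDWIDTH_CANDIDATES,
                     num_trial: int = 1000, alpha: float = 0.001,
                     seed: int | None = None):
    """Pick the most parsimonious bandwidth.

    Parsimony score = SVs whose midpoint falls inside hotspots divided by
    total hotspot bp; the maximizing candidate wins, ties to the smaller
    bandwidth.  Returns (bw, report) where report rows are
    (bw, n_hotspots, svs_covered, bp_covered, score).
    """
    if not candidates:
        raise ValueError("need >= 1 candidate bandwidth")
    report = []
    for bw in sorted(candidates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hs = call_hotspots(svs, sizes, int(bw), num_trial=num_trial,
                               alpha=alpha, seed=seed)
        bp = sum(h.interval.length for h in hs)
        covered = sum(h.sv_count for h in hs)
        score = covered / bp if bp > 0 else 0.0
        report.append((int(bw), len(hs), covered, bp, score))
    best = max(report, key=lambda row: (row[4], -row[0]))
    if best[4] == 0.0:
        raise ValueError("no signal: all candidate bandwidths yield zero hotspots")
    return best[0], report
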