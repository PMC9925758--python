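"""piRNA-producing locus detection by iterative dynamic-programming
segmentation of per-window abundance.

The score recursion along each chromosome is

    s[i] = max(0, s[i-1] + a[i] - penalty)

The window with the maximal score ends the current cluster; the cluster
starts at the window after the most recent zero score.  The cluster's
windows are zeroed and the recursion repeated until all scores are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pirnasv.core_model import ChromSizes, GenomicInterval
from pirnasv.smallrna_quant import Library, PIRNA_MIN_LEN

__all__ = [
    "ClusterParams",
    "PirnaCluster",
    "window_abundance",
    "penalty_score",
    "detect_clusters_windows",
    "detect_clusters",
    "refine_boundaries",
    "base_abundance",
]


@dataclass
class ClusterParams:
    window: int = 1000
    genome_fraction: float = 0.05
    min_unique_reads: int = 1

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.genome_fraction < 1:
            raise ValueError("genome_fraction must be in (0, 1)")


@dataclass
class PirnaCluster:
    interval: GenomicInterval
    score: float
    abundance: float
    unique_reads: int


def _iter_filtered_mappings(lib: Library, min_len: int):
    for sp in lib.species:
        if sp.length < min_len or sp.n_genome_mappings == 0:
            continue
        frac = sp.count / sp.n_genome_mappings
        for chrom, pos, strand in sp.mappings:
            yield sp, chrom, pos, frac


def window_abundance(lib: Library, sizes: ChromSizes, window: int = 1000,
                     min_len: int = PIRNA_MIN_LEN) -> dict[str, np.ndarray]:
    """Per-chromosome window counts of filtered reads (5'-base assignment,
    fractional multi-mappers).  Sum over windows equals the filtered count
    on that chromosome."""
    if window < 1:
        raise ValueError("window must be >= 1")
    arrays = {
        chrom: np.zeros(-(-length // window))
        for chrom, length in sizes.items()
    }
    for sp, chrom, pos, frac in _iter_filtered_mappings(lib, min_len):
        if chrom in arrays:
            arrays[chrom][pos // window] += frac
    return arrays


def base_abundance(lib: Library, sizes: ChromSizes,
                   min_len: int = PIRNA_MIN_LEN) -> dict[str, np.ndarray]:
    """Per-base 5'-end abundance (for boundary refinement)."""
    arrays = {chrom: np.zeros(length) for chrom, length in sizes.items()}
    for sp, chrom, pos, frac in _iter_filtered_mappings(lib, min_len):
        if chrom in arrays:
            arrays[chrom][pos] += frac
    return arrays


def penalty_score(windows: dict[str, np.ndarray] | np.ndarray,
                  genome_fraction: float = 0.05) -> float:
    """Mean of the top ``genome_fraction`` of windows, genome-wide."""
    if isinstance(windows, dict):
        flat = np.concatenate([np.asarray(a, dtype=float) for a in windows.values()])
    else:
        flat = np.asarray(windows, dtype=float)
    if flat.size < 20:
        raise ValueError("need >= 20 windows to set a penalty")
    if not flat.any():
        raise ValueError("all windows are zero: no piRNA signal")
    k = int(np.ceil(genome_fraction * flat.size))
    top = np.sort(flat)[-k:]
    return float(top.mean())


def _dp_scores(a: np.ndarray, penalty: float) -> np.ndarray:
    s = np.empty_like(a)
    prev = 0.0
    for i, ai in enumerate(a):
        prev = prev + ai - penalty
        if prev < 0.0:
            prev = 0.0
        s[i] = prev
    return s


def detect_clusters_windows(a: np.ndarray, penalty: float
                            ) -> list[tuple[int, int, float]]:
    """Iteratively extract clusters from one chromosome's window array.

    Returns (first_window, last_window_inclusive, score) tuples in
    extraction order.  Ties for the maximal score break leftmost; the
    cluster start is the window after the most recent zero score.
    """
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    a = np.asarray(a, dtype=float).copy()
    out: list[tuple[int, int, float]] = []
    while True:
        s = _dp_scores(a, penalty)
        best = float(s.max()) if s.size else 0.0
        if best <= 0:
            break
        end = int(np.argmax(s))  # leftmost maximal
        start = end
        while start > 0 and s[start - 1] > 0:
            start -= 1
        out.append((start, end, best))
        a[start:end + 1] = 0.0
    return out


def detect_clusters(windows: dict[str, np.ndarray], penalty: float,
                    lib: Library | None = None, window: int = 1000,
                    min_unique_reads: int = 1,
                    sizes: ChromSizes | None = None) -> list[PirnaCluster]:
    """Genome-wide cluster extraction with the unique-read filter.

    Clusters failing ``min_unique_reads`` are discarded after extraction
    (their windows are still consumed by the iteration).
    """
    # index unique-mapper 5' ends per chromosome for the filter
    unique_pos: dict[str, np.ndarray] = {}
    if lib is not None:
        per: dict[str, list[int]] = {}
        for sp in lib.species:
            if sp.length >= PIRNA_MIN_LEN and sp.is_unique:
                chrom, pos, strand = sp.mappings[0]
                per.setdefault(chrom, []).append(pos)
        unique_pos = {c: np.sort(np.array(p)) for c, p in per.items()}

    clusters: list[PirnaCluster] = []
    for chrom in sorted(windows):
        a = windows[chrom]
        chrom_len = sizes[chrom] if sizes is not None else len(a) * window
        for wstart, wend, score in detect_clusters_windows(a, penalty):
            start = wstart * window
            end = min((wend + 1) * window, chrom_len)
            n_unique = 0
            if chrom in unique_pos:
                pos = unique_pos[chrom]
                n_unique = int(np.searchsorted(pos, end) -
                               np.searchsorted(pos, start))
            if lib is not None and n_unique < min_unique_reads:
                continue
            abundance = float(a[wstart:wend + 1].sum())
            clusters.append(PirnaCluster(
                GenomicInterval(chrom, start, end), score, abundance, n_unique))
    return clusters


def refine_boundaries(cluster: PirnaCluster, per_base: np.ndarray,
                      penalty: float, window: int = 1000) -> GenomicInterval:
    """Trim cluster ends to the outermost bases whose per-base abundance
    exceeds penalty / window.  Falls back to the window-resolution interval
    when no base qualifies."""
    iv = cluster.interval
    threshold = penalty / window
    region = np.asarray(per_base[iv.start:iv.end], dtype=float)
    above = np.nonzero(region > threshold)[0]
    if above.size == 0:
        return iv
    return GenomicInterval(iv.chrom, iv.start + int(above[0]),
                           iv.start + int(above[-1]) + 1,
                           iv.strand, iv.name)
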