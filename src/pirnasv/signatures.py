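"""Ping-pong 5'-5' overlap spectra with the 10-bp Z-score, and
ribosome-footprint nucleotide periodicity spectra.

Overlap convention: for a plus-strand 5' end at p and a minus-strand 5'
end at q on the same chromosome, the overlap extension is k = q - p + 1,
so k = 10 means the two 5' ends span exactly 10 bases — the canonical
ping-pong register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pirnasv.core_model import GenomicInterval, SmallRNASpecies

__all__ = [
    "OverlapSpectrum",
    "PeriodicitySpectrum",
    "overlap_spectrum",
    "pingpong_z",
    "periodicity",
]

K_MIN, K_MAX = 1, 30
Z10_K = 10
BACKGROUND_KS = tuple(k for k in range(K_MIN, K_MAX + 1) if k != Z10_K)


@dataclass
class OverlapSpectrum:
    """Overlap score per extension k in 1..30."""

    S: dict[int, float] = field(
        default_factory=lambda: {k: 0.0 for k in range(K_MIN, K_MAX + 1)})

    @property
    def z10(self) -> float:
        return pingpong_z(self)


@dataclass
class PeriodicitySpectrum:
    distance_spectrum: dict[int, float]
    relative_density: dict[int, float]
    frequencies: dict[int, float]


def _position_counts(species: Sequence[SmallRNASpecies],
                     region: Sequence[GenomicInterval] | None):
    """Aggregate read counts per (chrom, 5'-pos) split by strand."""
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if region is not None:
        for iv in region:
            region_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def in_region(chrom, pos):
        if region is None:
            return True
        return any(s <= pos < e for s, e in region_by_chrom.get(chrom, ()))

    plus: dict[str, dict[int, float]] = {}
    minus: dict[str, dict[int, float]] = {}
    for sp in species:
        for chrom, pos, strand in sp.mappings:
            if not in_region(chrom, pos):
                continue
            table = plus if strand == "+" else minus
            per = table.setdefault(chrom, {})
            per[pos] = per.get(pos, 0.0) + sp.count
    return plus, minus


def overlap_spectrum(species: Sequence[SmallRNASpecies],
                     region: Sequence[GenomicInterval] | None = None
                     ) -> OverlapSpectrum:
    """Sum-of-count-products overlap scores over all opposite-strand 5'-end
    pairs on the same chromosome, for extensions 1-30.

    3'-end heterogeneity is ignored: only 5' positions and counts enter.
    Implemented as an O(n) join on per-position count maps; the O(n^2)
    pair enumeration is kept as the test oracle.
    """
    plus, minus = _position_counts(species, region)
    spec = OverlapSpectrum()
    for chrom, pmap in plus.items():
        mmap = minus.get(chrom)
        if not mmap:
            continue
        for p, c_plus in pmap.items():
            for k in range(K_MIN, K_MAX + 1):
                q = p + k - 1
                c_minus = mmap.get(q)
                if c_minus:
                    spec.S[k] += c_plus * c_minus
    return spec


def pingpong_z(spec: OverlapSpectrum) -> float:
    """Z-score of S(10) against the background set {1..9, 11..30}.

    Uses the population (n-denominator) standard deviation of the 29
    enumerated background values.  Degenerate backgrounds: sd 0 with
    S(10) equal to the background mean gives 0; sd 0 otherwise gives
    +/- inf as a flagged extreme.
    """
    bg = np.array([spec.S[k] for k in BACKGROUND_KS])
    mean = bg.mean()
    sd = bg.std(ddof=0)
    s10 = spec.S[Z10_K]
    if sd == 0:
        if s10 == mean:
            return 0.0
        return math.inf if s10 > mean else -math.inf
    return float((s10 - mean) / sd)


def periodicity(reads: Sequence[SmallRNASpecies], D: int = 100,
                min_len: int = 26, max_len: int = 32,
                unique_only: bool = True) -> PeriodicitySpectrum:
    """Distance spectrum of same-strand 5'-end separations and its
    periodogram.

    Reads are filtered to ``min_len``-``max_len`` nt unique mappers.  The
    distance spectrum at d is the sum over same-strand read pairs with 5'
    separation exactly d of the product of counts.  The power spectrum is
    the squared DFT magnitude of the mean-subtracted spectrum; relative
    density is normalized to the first (lowest non-zero) frequency.
    """
    filtered = [r for r in reads
                if min_len <= r.length <= max_len
                and (not unique_only or r.is_unique)]
    if not filtered:
        raise ValueError("no reads pass the length/uniqueness filters")

    per: dict[tuple[str, str], dict[int, float]] = {}
    for sp in filtered:
        for chrom, pos, strand in sp.mappings:
            table = per.setdefault((chrom, strand), {})
            table[pos] = table.get(pos, 0.0) + sp.count

    dist = {d: 0.0 for d in range(D + 1)}
    for table in per.values():
        positions = sorted(table)
        arr = np.array(positions)
        for i, p in enumerate(positions):
            j_hi = np.searchsorted(arr, p + D, side="right")
            for j in range(i, j_hi):
                q = positions[j]
                dist[q - p] += table[p] * table[q]

    signal = np.array([dist[d] for d in range(D + 1)], dtype=float)
    centered = signal - signal.mean()
    power = np.abs(np.fft.rfft(centered)) ** 2
    freqs = np.fft.rfftfreq(len(centered))
    # index 0 is the (zeroed) DC term; normalize to the first real frequency
    if len(power) > 1 and power[1] > 0:
        rel = power / power[1]
    else:
        rel = np.ones_like(power) if power.max() == 0 else power / max(power.max(), 1)
    relative_density = {i: float(rel[i]) for i in range(1, len(rel))}
    frequencies = {i: float(freqs[i]) for i in range(1, len(freqs))}
    return PeriodicitySpectrum(dist, relative_density, frequencies)
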