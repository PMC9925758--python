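"""Small-RNA library normalization, per-feature abundance, diversity,
strand bias, expression variance, and sequence complexity."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from pirnasv.core_model import GenomicInterval, SequenceRecord, SmallRNASpecies

__all__ = [
    "Library",
    "FeatureAbundance",
    "VarianceRecord",
    "normalize_to_mirna",
    "calibrate_oxidized",
    "feature_abundance",
    "shannon_diversity",
    "strand_bias",
    "expression_variance",
    "wf_complexity",
]

PIRNA_MIN_LEN = 24  # reads > 23 nt
PSEUDO_COUNT = 0.001


@dataclass
class Library:
    """A small-RNA library: collapsed species plus the miRNA pool total."""

    label: str
    species: list[SmallRNASpecies]
    mirna_total: float
    is_oxidized: bool = False

    def __post_init__(self):
        if self.mirna_total < 0:
            raise ValueError("mirna_total must be >= 0")

    def total_genome_reads(self) -> float:
        """Total genome-mapping reads, all lengths."""
        return sum(s.count for s in self.species if s.n_genome_mappings > 0)


@dataclass
class FeatureAbundance:
    feature: GenomicInterval
    ppm: float
    rpkm: float
    watson_count: float
    crick_count: float
    species_counts: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> float:
        return self.watson_count + self.crick_count


@dataclass
class VarianceRecord:
    feature: str
    median_expr: float
    cv: float
    residual: float


def normalize_to_mirna(libs: Sequence[Library], scale: float = 1e6) -> list[Library]:
    """Scale every species count by ``scale / mirna_total`` per library."""
    out = []
    for lib in libs:
        if lib.mirna_total == 0:
            raise ValueError(f"library {lib.label!r} has miRNA total 0")
        f = scale / lib.mirna_total
        scaled = [
            SmallRNASpecies(s.sequence, s.count * f, list(s.mappings))
            for s in lib.species
        ]
        out.append(Library(lib.label, scaled, scale, lib.is_oxidized))
    return out


def calibrate_oxidized(oxidized: Library, total: Library) -> Library:
    """Calibrate an oxidized library against its total small-RNA library.

    The factor is the ratio of summed counts over the shared species
    (> 23 nt) present in both libraries; after calibration the oxidized
    library's summed shared-species abundance matches the total library's.
    """
    tot_by_seq = {s.sequence: s.count for s in total.species
                  if s.length >= PIRNA_MIN_LEN}
    shared_total = 0.0
    shared_ox = 0.0
    for s in oxidized.species:
        if s.length >= PIRNA_MIN_LEN and s.sequence in tot_by_seq:
            shared_total += tot_by_seq[s.sequence]
            shared_ox += s.count
    if shared_ox == 0:
        raise ValueError(
            f"no shared species > 23 nt between {oxidized.label!r} and "
            f"{total.label!r}")
    f = shared_total / shared_ox
    scaled = [SmallRNASpecies(s.sequence, s.count * f, list(s.mappings))
              for s in oxidized.species]
    return Library(oxidized.label, scaled, oxidized.mirna_total * f, True)


def feature_abundance(lib: Library, features: Sequence[GenomicInterval],
                      min_len: int = PIRNA_MIN_LEN) -> list[FeatureAbundance]:
    """Per-feature piRNA abundance.

    A read mapping is assigned to a feature when its 5' base lies within
    the interval.  Species shorter than ``min_len`` are ignored.
    Multi-mappers contribute count / n_genome_mappings per mapping.
    ppm and rpkm use total genome-mapping reads (all lengths) as the
    denominator, with a 0.001 pseudo-count added to both.
    """
    if not features:
        return []
    denom = lib.total_genome_reads()
    # index features per chromosome for the 5'-containment test
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for fi, iv in enumerate(features):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fi))
    for lst in by_chrom.values():
        lst.sort()

    watson = np.zeros(len(features))
    crick = np.zeros(len(features))
    species_counts: list[dict[str, float]] = [dict() for _ in features]

    for sp in lib.species:
        if sp.length < min_len or sp.n_genome_mappings == 0:
            continue
        frac = sp.count / sp.n_genome_mappings
        for chrom, pos, strand in sp.mappings:
            for fstart, fend, fi in by_chrom.get(chrom, ()):
                if fstart <= pos < fend:
                    if strand == "+":
                        watson[fi] += frac
                    else:
                        crick[fi] += frac
                    sc = species_counts[fi]
                    sc[sp.sequence] = sc.get(sp.sequence, 0.0) + frac

    out = []
    for fi, iv in enumerate(features):
        total = watson[fi] + crick[fi]
        ppm = total / denom * 1e6 + PSEUDO_COUNT if denom > 0 else PSEUDO_COUNT
        rpkm = (total / denom * 1e6 / (iv.length / 1000) + PSEUDO_COUNT
                if denom > 0 else PSEUDO_COUNT)
        out.append(FeatureAbundance(iv, ppm, rpkm, watson[fi], crick[fi],
                                    species_counts[fi]))
    return out


def shannon_diversity(species_counts: Mapping[str, float] | Iterable[float]) -> float:
    """Shannon index H = -sum p_i ln p_i over non-zero counts."""
    if isinstance(species_counts, Mapping):
        counts = list(species_counts.values())
    else:
        counts = list(species_counts)
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if total <= 0:
        raise ValueError("all species counts are zero")
    return -sum((c / total) * math.log(c / total) for c in counts)


def strand_bias(fa: FeatureAbundance) -> float | None:
    """Watson fraction of feature reads; None when the feature is empty."""
    total = fa.watson_count + fa.crick_count
    if total == 0:
        return None
    return fa.watson_count / total


def expression_variance(matrix, loess_span: float = 0.75,
                        pseudo: float = 0.01) -> list[VarianceRecord]:
    """CV residuals relative to a LOESS trend of CV on log10 median.

    ``matrix`` is a pandas DataFrame (features x individuals) or a 2-D
    array of normalized values.  Features with zero mean are dropped with
    a warning.  Residual = CV - fitted CV at that feature's median.
    """
    import pandas as pd

    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix))
    if matrix.shape[0] < 10:
        raise ValueError("need >= 10 features")
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 individuals")

    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1)
    keep = means > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} features with zero mean dropped")
    values = values[keep]
    names = [str(n) for n in matrix.index[keep]]
    means = means[keep]
    medians = np.median(values, axis=1)
    sds = values.std(axis=1, ddof=1)
    cvs = sds / means
    x = np.log10(medians + pseudo)

    fitted = lowess(cvs, x, frac=loess_span, return_sorted=False)
    residuals = cvs - fitted
    return [VarianceRecord(names[i], float(medians[i]), float(cvs[i]),
                           float(residuals[i]))
            for i in range(len(names))]


def wf_complexity(rec: SequenceRecord | str) -> float:
    """Wootton-Federhen complexity: (1/N) * log4(N! / prod n_i!).

    Evaluated with log-gamma so long sequences cannot overflow.
    """
    seq = rec.seq if isinstance(rec, SequenceRecord) else rec
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    n = len(seq)
    counts = [seq.count(b) for b in "ACGT"]
    log_multinomial = gammaln(n + 1) - sum(gammaln(c + 1) for c in counts)
    return float(log_multinomial / (n * math.log(4)))
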