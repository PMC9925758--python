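"""Same-chromosome interval shuffling and permutation statistics.

Each query interval is re-placed uniformly on its own chromosome with its
length preserved (self-overlap among shuffled intervals is allowed).  The
null distribution of a statistic over T shuffles yields

    Pl = #(M_i <= M_obs) / T        Pu = #(M_i >= M_obs) / T
    P_printed = min(1, max(Pl, Pu))

P_printed follows the published formula (which cannot fall below 0.5
because Pl + Pu >= 1); the one-tailed p for a declared direction is
reported alongside, with a zero exceedance count flagged as "< 1/T".

Distance convention: gap in bp between the closest ends of half-open
intervals; overlapping or boundary-sharing intervals are at distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pirnasv.core_model import ChromSizes, GenomicInterval, ScoreTrack, SVRecord

__all__ = [
    "StatisticSpec",
    "ShuffleResult",
    "shuffle_intervals",
    "compute_statistic",
    "permutation_test",
]

STAT_KINDS = ("count_in_features", "n_overlapping", "median_nearest_distance",
              "median_mean_score")


@dataclass
class StatisticSpec:
    kind: str
    query: Sequence  # GenomicInterval or SVRecord
    features: Sequence[GenomicInterval] | None = None
    track: ScoreTrack | None = None
    point_mode: str = "midpoint"  # count_in_features: midpoint | overlap

    def __post_init__(self):
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind == "median_mean_score" and self.track is None:
            raise ValueError("median_mean_score requires a score track")
        if self.kind != "median_mean_score" and self.features is None:
            raise ValueError(f"{self.kind} requires a feature set")
        if not self.query:
            raise ValueError("empty query")


@dataclass
class ShuffleResult:
    M_obs: float
    M: np.ndarray
    Pl: float
    Pu: float
    P_printed: float
    P_one_tailed: float
    direction: str

    @property
    def p_one_tailed_str(self) -> str:
        if self.P_one_tailed == 0:
            return f"< {1 / len(self.M):g}"
        return f"{self.P_one_tailed:g}"


def _as_interval(q) -> GenomicInterval:
    return q.interval if isinstance(q, SVRecord) else q


def shuffle_intervals(query: Sequence, sizes: ChromSizes,
                      rng: np.random.Generator) -> list[GenomicInterval]:
    """Uniformly re-place each interval on its own chromosome."""
    out = []
    for q in query:
        iv = _as_interval(q)
        room = sizes[iv.chrom] - iv.length
        if room < 0:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} longer than chromosome")
        start = int(rng.integers(0, room + 1))
        out.append(GenomicInterval(iv.chrom, start, start + iv.length,
                                   iv.strand, iv.name))
    return out


def _merge_features(features: Sequence[GenomicInterval]):
    """Per-chromosome sorted, merged (start, end) arrays."""
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in features:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in per.items():
        spans.sort()
        ms, me = [], []
        for s, e in spans:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    return merged


class _Engine:
    """Precomputed per-chromosome structures for vectorized evaluation.

    Evaluates the statistic on a (T, n) matrix of shuffled starts per
    chromosome so that 10,000-trial runs stay fast.
    """

    def __init__(self, spec: StatisticSpec, sizes: ChromSizes):
        self.spec = spec
        self.sizes = sizes
        ivs = [_as_interval(q) for q in spec.query]
        for iv in ivs:
            if iv.length > sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} longer than "
                    "chromosome")
        self.by_chrom: dict[str, dict] = {}
        for iv in ivs:
            d = self.by_chrom.setdefault(iv.chrom, {"starts": [], "lengths": []})
            d["starts"].append(iv.start)
            d["lengths"].append(iv.length)
        for chrom, d in self.by_chrom.items():
            d["starts"] = np.array(d["starts"], dtype=np.int64)
            d["lengths"] = np.array(d["lengths"], dtype=np.int64)

        self.merged = (_merge_features(spec.features)
                       if spec.features is not None else {})
        if spec.kind == "median_mean_score":
            self.cumsums = {}
            for chrom in self.by_chrom:
                length = sizes[chrom]
                dense = np.full(length, spec.track.fill)
                for pos, val in spec.track.positions(chrom).items():
                    dense[pos] = val
                self.cumsums[chrom] = np.concatenate(
                    ([0.0], np.cumsum(dense)))

    # each _eval_* receives starts with shape (T, n_chrom_elements)

    def _eval_count(self, chrom, starts, lengths):
        if chrom not in self.merged:
            return np.zeros(starts.shape[0])
        ms, me = self.merged[chrom]
        if self.spec.point_mode == "midpoint":
            points = starts + lengths // 2
            bounds = np.empty(ms.size * 2, dtype=np.int64)
            bounds[0::2], bounds[1::2] = ms, me
            inside = np.searchsorted(bounds, points, side="right") % 2 == 1
            return inside.sum(axis=1).astype(float)
        return self._overlap_mask(chrom, starts, lengths).sum(axis=1).astype(float)

    def _overlap_mask(self, chrom, starts, lengths):
        ms, me = self.merged[chrom]
        ends = starts + lengths
        j = np.searchsorted(me, starts, side="right")
        valid = j < ms.size
        fstart = np.where(valid, ms[np.minimum(j, ms.size - 1)], np.iinfo(np.int64).max)
        return valid & (fstart < ends)

    def _eval_overlap(self, chrom, starts, lengths):
        if chrom not in self.merged:
            return np.zeros(starts.shape[0])
        return self._overlap_mask(chrom, starts, lengths).sum(axis=1).astype(float)

    def _distances(self, chrom, starts, lengths):
        if chrom not in self.merged:
            return np.full(starts.shape, np.inf)
        ms, me = self.merged[chrom]
        ends = starts + lengths
        j = np.searchsorted(me, starts, side="right")
        has_next = j < ms.size
        next_start = np.where(has_next, ms[np.minimum(j, ms.size - 1)], 0)
        has_prev = j > 0
        prev_end = np.where(has_prev, me[np.maximum(j - 1, 0)], 0)
        overlap = has_next & (next_start < ends)
        d_next = np.where(has_next, np.maximum(next_start - ends, 0), np.inf)
        d_prev = np.where(has_prev, np.maximum(starts - prev_end, 0), np.inf)
        dist = np.minimum(d_next, d_prev)
        return np.where(overlap, 0.0, dist)

    def _eval_scores(self, chrom, starts, lengths):
        cs = self.cumsums[chrom]
        ends = starts + lengths
        return (cs[ends] - cs[starts]) / lengths

    def evaluate(self, starts_by_chrom: dict[str, np.ndarray]) -> np.ndarray:
        """Statistic per trial; starts_by_chrom[chrom] has shape (T, n_c)."""
        kind = self.spec.kind
        T = next(iter(starts_by_chrom.values())).shape[0]
        if kind in ("count_in_features", "n_overlapping"):
            total = np.zeros(T)
            for chrom, d in self.by_chrom.items():
                starts = starts_by_chrom[chrom]
                fn = self._eval_count if kind == "count_in_features" else \
                    self._eval_overlap
                total += fn(chrom, starts, d["lengths"][None, :])
            return total
        # median over the pooled per-element values
        cols = []
        for chrom, d in self.by_chrom.items():
            starts = starts_by_chrom[chrom]
            if kind == "median_nearest_distance":
                cols.append(self._distances(chrom, starts, d["lengths"][None, :]))
            else:
                cols.append(self._eval_scores(chrom, starts, d["lengths"][None, :]))
        return np.median(np.concatenate(cols, axis=1), axis=1)

    def observed(self) -> float:
        starts = {chrom: d["starts"][None, :] for chrom, d in self.by_chrom.items()}
        return float(self.evaluate(starts)[0])

    def null(self, T: int, rng: np.random.Generator) -> np.ndarray:
        starts = {}
        for chrom, d in self.by_chrom.items():
            room = self.sizes[chrom] - d["lengths"] + 1
            starts[chrom] = rng.integers(0, room[None, :], size=(T, d["lengths"].size))
        return self.evaluate(starts)


def compute_statistic(spec: StatisticSpec, sizes: ChromSizes | None = None) -> float:
    """Observed value of the statistic for the query as given."""
    if sizes is None:
        sizes = _implied_sizes(spec)
    return _Engine(spec, sizes).observed()


def _implied_sizes(spec: StatisticSpec) -> ChromSizes:
    ends: dict[str, int] = {}
    pool = [_as_interval(q) for q in spec.query]
    if spec.features:
        pool += list(spec.features)
    for iv in pool:
        ends[iv.chrom] = max(ends.get(iv.chrom, 1), iv.end)
    return ChromSizes(ends)


def permutation_test(spec: StatisticSpec, sizes: ChromSizes, T: int = 10000,
                     seed: int | None = None, direction: str = "greater",
                     rng: np.random.Generator | None = None) -> ShuffleResult:
    """Shuffle the query T times and summarize the null.

    ``direction`` declares which tail the one-tailed p covers: "greater"
    tests for observed values larger than the null.
    """
    if T < 100:
        raise ValueError("need T >= 100 trials")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if rng is None:
        rng = np.random.default_rng(seed)
    engine = _Engine(spec, sizes)
    m_obs = engine.observed()
    null = engine.null(T, rng)
    pl = float((null <= m_obs).sum() / T)
    pu = float((null >= m_obs).sum() / T)
    p_printed = min(1.0, max(pl, pu))
    p_one = pu if direction == "greater" else pl
    return ShuffleResult(m_obs, null, pl, pu, p_printed, p_one, direction)
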