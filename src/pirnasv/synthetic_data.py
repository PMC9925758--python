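"""Synthetic genomes, SV call sets, small-RNA libraries, and TE insertions
with the statistical structure the downstream analyses assume.

All generators are pure functions of (config, seed): the same config yields
byte-identical outputs.  Reads are emitted as collapsed species with
genomic mappings (alignment is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pirnasv.core_model import ChromSizes, GenomicInterval, SVRecord, SmallRNASpecies
from pirnasv.smallrna_quant import Library
from pirnasv.te_pipeline import TEHit

__all__ = [
    "ChromSpec",
    "HotspotSpec",
    "ClusterSpec",
    "SVSimSpec",
    "TEFamilySpec",
    "TESpec",
    "SimConfig",
    "TESimResult",
    "simulate_genome",
    "simulate_sv_calls",
    "simulate_smallrna_reads",
    "simulate_te_insertions",
]

BASES = np.array(list("ACGT"))

MACRO_MIN = 40_000_000
MICRO_MAX = 20_000_000


@dataclass
class ChromSpec:
    name: str
    length: int
    class_hint: str = ""

    @property
    def size_class(self) -> str:
        if self.class_hint:
            return self.class_hint
        if self.length >= MACRO_MIN:
            return "macro"
        if self.length < MICRO_MAX:
            return "micro"
        return "intermediate"


@dataclass
class HotspotSpec:
    chrom: str
    start: int
    end: int
    excess: float  # rate multiplier inside the interval

    def __post_init__(self):
        if self.excess < 0:
            raise ValueError("excess must be >= 0")


@dataclass
class ClusterSpec:
    chrom: str
    start: int
    end: int
    n_reads: int
    strand_bias: float = 0.7
    pingpong_fraction: float = 0.0

    def __post_init__(self):
        if not 0 <= self.pingpong_fraction <= 1:
            raise ValueError("pingpong_fraction must be in [0, 1]")
        if self.n_reads == 0 and self.pingpong_fraction > 0:
            raise ValueError("cluster depth 0 with ping-pong fraction > 0")


@dataclass
class SVSimSpec:
    n_per_type: dict = field(default_factory=lambda: {"DEL": 100, "INS": 100})
    hotspot: HotspotSpec | None = None
    both_caller_fraction: float = 0.8
    slop: int = 100
    length_range: tuple[int, int] = (50, 2000)
    support_range: tuple[int, int] = (10, 40)
    score_range: tuple[float, float] = (10.0, 60.0)


@dataclass
class TEFamilySpec:
    name: str
    te_class: str  # LTR | LTR_internal | LINE
    consensus_len: int
    divergence: float = 0.02

    def __post_init__(self):
        if self.divergence >= 0.75:
            raise ValueError("divergence >= 0.75: JC69 undefined")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass
class TESpec:
    ltr: TEFamilySpec = field(
        default_factory=lambda: TEFamilySpec("ERV1_LTR", "LTR", 300))
    internal: TEFamilySpec = field(
        default_factory=lambda: TEFamilySpec("ERV1_I", "LTR_internal", 5000))
    line: TEFamilySpec = field(
        default_factory=lambda: TEFamilySpec("CR1-F2", "LINE", 4600))
    n_solo_ltr: int = 10
    n_intact_erv: int = 5
    n_line: int = 2
    n_line_internal3p_decoy: int = 2  # 3' end in the middle of the insertion
    n_erv_reference_solo_decoy: int = 1  # intact ERV on a reference solo-LTR


@dataclass
class SimConfig:
    seed: int
    chromosomes: list[ChromSpec] = field(default_factory=list)
    n_genes: int = 20
    n_repeats: int = 50
    sv: SVSimSpec = field(default_factory=SVSimSpec)
    clusters: list[ClusterSpec] = field(default_factory=list)
    background_reads: int = 100
    mirna_pool_size: float = 10000.0
    mirna_species: int = 50
    te: TESpec = field(default_factory=TESpec)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def validate_intervals(self) -> None:
        lengths = {c.name: c.length for c in self.chromosomes}
        planted = list(self.clusters)
        if self.sv.hotspot is not None:
            planted.append(self.sv.hotspot)
        for spec in planted:
            if spec.chrom not in lengths:
                raise ValueError(f"planted interval on unknown chromosome "
                                 f"{spec.chrom!r}")
            if not 0 <= spec.start < spec.end <= lengths[spec.chrom]:
                raise ValueError(
                    f"planted interval {spec.chrom}:{spec.start}-{spec.end} "
                    "outside chromosome")


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig):
    """ChromSizes plus random, non-degenerate gene and repeat annotations."""
    if not config.chromosomes:
        raise ValueError("config declares zero chromosomes")
    config.validate_intervals()
    sizes = ChromSizes({c.name: c.length for c in config.chromosomes})
    rng = _rng(config, 1)
    names = sorted(sizes.names())
    lengths = np.array([sizes[n] for n in names], dtype=float)
    probs = lengths / lengths.sum()

    def random_intervals(n, min_len, max_len, prefix):
        out = []
        for i in range(n):
            chrom = names[rng.choice(len(names), p=probs)]
            span = int(rng.integers(min_len, max_len + 1))
            span = min(span, sizes[chrom] - 1)
            start = int(rng.integers(0, sizes[chrom] - span))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(GenomicInterval(chrom, start, start + span, strand,
                                       f"{prefix}{i}"))
        return out

    genes = random_intervals(config.n_genes, 1000, 20000, "gene")
    repeats = random_intervals(config.n_repeats, 100, 5000, "rep")
    return sizes, genes, repeats


def _sample_positions(rng, n, chrom_len, hotspot=None):
    """Uniform positions with an excess-rate multiplier inside the hotspot."""
    if hotspot is None or hotspot.excess == 1.0:
        return rng.integers(0, chrom_len, size=n)
    hot_len = hotspot.end - hotspot.start
    w_hot = hotspot.excess * hot_len
    p_hot = w_hot / (w_hot + (chrom_len - hot_len))
    in_hot = rng.random(n) < p_hot
    pos = np.empty(n, dtype=np.int64)
    pos[in_hot] = rng.integers(hotspot.start, hotspot.end, size=int(in_hot.sum()))
    # rejection-free sample of the complement: shift past the hotspot
    raw = rng.integers(0, chrom_len - hot_len, size=int((~in_hot).sum()))
    raw = np.where(raw >= hotspot.start, raw + hot_len, raw)
    pos[~in_hot] = raw
    return pos


def simulate_sv_calls(config: SimConfig, sizes: ChromSizes):
    """Two caller-specific SVRecord lists with a planted midpoint hotspot.

    A ``both_caller_fraction`` of DEL/INV/DUP events appears in both call
    sets with breakpoints jittered by at most ``slop``; the rest appear in
    one caller only.  INS events are emitted by caller A.
    """
    config.validate_intervals()
    spec = config.sv
    rng = _rng(config, 2)
    names = sorted(sizes.names())
    lengths = np.array([sizes[n] for n in names], dtype=float)
    probs = lengths / lengths.sum()
    calls_a: list[SVRecord] = []
    calls_b: list[SVRecord] = []

    for sv_type in sorted(spec.n_per_type):
        n = spec.n_per_type[sv_type]
        for _ in range(n):
            chrom = names[rng.choice(len(names), p=probs)]
            hotspot = (spec.hotspot if spec.hotspot is not None
                       and spec.hotspot.chrom == chrom else None)
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            mid = int(_sample_positions(rng, 1, sizes[chrom], hotspot)[0])
            support = int(rng.integers(*spec.support_range))
            score = float(rng.uniform(*spec.score_range))
            if sv_type == "INS":
                start = min(mid, sizes[chrom] - 1)
                iv = GenomicInterval(chrom, start, start + 1)
                seq = _random_seq(rng, length)
                calls_a.append(SVRecord(iv, "INS", length, support, score,
                                        "callerA", seq))
                continue
            start = max(0, min(mid - length // 2, sizes[chrom] - length))
            iv = GenomicInterval(chrom, start, start + length)
            rec_a = SVRecord(iv, sv_type, length, support, score, "callerA")
            in_both = rng.random() < spec.both_caller_fraction
            if in_both:
                jitter = (int(rng.integers(-spec.slop, spec.slop + 1))
                          if spec.slop > 0 else 0)
                b_start = max(0, min(start + jitter, sizes[chrom] - length))
                iv_b = GenomicInterval(chrom, b_start, b_start + length)
                rec_b = SVRecord(iv_b, sv_type, length,
                                 int(rng.integers(*spec.support_range)),
                                 float(rng.uniform(*spec.score_range)),
                                 "callerB")
                calls_a.append(rec_a)
                calls_b.append(rec_b)
            elif rng.random() < 0.5:
                calls_a.append(rec_a)
            else:
                calls_b.append(rec_b_only := SVRecord(
                    iv, sv_type, length, support, score, "callerB"))
    return calls_a, calls_b


def simulate_smallrna_reads(config: SimConfig, sizes: ChromSizes,
                            label: str = "sim") -> Library:
    """A collapsed small-RNA library with planted clusters.

    Background reads are uniform at low depth; each planted cluster emits
    24-32 nt reads at the configured depth and strand bias, a configured
    fraction of which are plus/minus pairs whose 5' ends overlap by
    exactly 10 nt.  A separate 21-23 nt miRNA pool of the configured total
    count supports normalization tests.
    """
    config.validate_intervals()
    rng = _rng(config, 3)
    names = sorted(sizes.names())
    lengths = np.array([sizes[n] for n in names], dtype=float)
    probs = lengths / lengths.sum()
    species: list[SmallRNASpecies] = []

    def emit(chrom, five_prime, strand, read_len=None, count=None):
        read_len = read_len or int(rng.integers(24, 33))
        count = count if count is not None else float(rng.integers(1, 6))
        species.append(SmallRNASpecies(
            _random_seq(rng, read_len), count, [(chrom, five_prime, strand)]))

    for _ in range(config.background_reads):
        chrom = names[rng.choice(len(names), p=probs)]
        pos = int(rng.integers(0, sizes[chrom]))
        emit(chrom, pos, "+" if rng.random() < 0.5 else "-")

    for cl in config.clusters:
        n_pairs = int(round(cl.n_reads * cl.pingpong_fraction / 2))
        n_single = cl.n_reads - 2 * n_pairs
        for _ in range(n_pairs):
            # plus 5' at p, minus 5' at p+9: a 10-nt 5'-5' overlap
            p = int(rng.integers(cl.start, max(cl.start + 1, cl.end - 10)))
            count = float(rng.integers(1, 6))
            emit(cl.chrom, p, "+", count=count)
            emit(cl.chrom, p + 9, "-", count=count)
        for _ in range(n_single):
            pos = int(rng.integers(cl.start, cl.end))
            emit(cl.chrom, pos, "+" if rng.random() < cl.strand_bias else "-")

    # miRNA pool: 21-23 nt species whose counts sum to mirna_pool_size
    n_mirna = config.mirna_species
    if n_mirna > 0 and config.mirna_pool_size > 0:
        weights = rng.dirichlet(np.ones(n_mirna))
        for w in weights:
            chrom = names[rng.choice(len(names), p=probs)]
            pos = int(rng.integers(0, sizes[chrom]))
            emit(chrom, pos, "+", read_len=int(rng.integers(21, 24)),
                 count=float(w * config.mirna_pool_size))

    return Library(label, species, mirna_total=float(config.mirna_pool_size))


# ---------------------------------------------------------------------------
# TE insertions


@dataclass
class TESimResult:
    consensus: dict[str, str]
    consensus_meta: dict[str, tuple[str, int]]  # family -> (class, length)
    insertions: dict[str, str]  # insertion_id -> sequence
    insertion_sites: dict[str, GenomicInterval]
    hits: list[TEHit]
    reference_solo_ltrs: list[GenomicInterval]
    truth: dict[str, str]  # insertion_id -> expected classification status


def _mutate(rng, seq: str, p: float) -> tuple[str, float]:
    """Per-site substitution to a uniformly chosen different base.

    Returns the mutated sequence and the realized divergence.
    """
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < p
    n_hit = int(hit.sum())
    if n_hit:
        originals = arr[hit]
        subs = np.empty(n_hit, dtype=originals.dtype)
        for i, b in enumerate(originals):
            choices = [c for c in "ACGT" if c != b]
            subs[i] = choices[rng.integers(0, 3)]
        arr[hit] = subs
    return "".join(arr), n_hit / arr.size


def simulate_te_insertions(config: SimConfig) -> TESimResult:
    """Insertion sequences of each structural category with true-alignment
    hit tables (no aligner is run).

    Categories: solo-LTR; intact ERV (LTR-internal-LTR); LINE with the
    consensus 3' end at an insertion terminus and random 5' truncation;
    decoy LINE with its 3' end internal to the insertion; decoy intact ERV
    at a reference solo-LTR site.
    """
    te = config.te
    for fam in (te.ltr, te.internal, te.line):
        if fam.divergence >= 0.75:
            raise ValueError("divergence >= 0.75: JC69 undefined")
    rng = _rng(config, 4)
    anchor_chrom = (sorted(c.name for c in config.chromosomes)[0]
                    if config.chromosomes else "chrSim")
    chrom_len = (max(c.length for c in config.chromosomes)
                 if config.chromosomes else 100_000_000)

    consensus = {
        te.ltr.name: _random_seq(rng, te.ltr.consensus_len),
        te.internal.name: _random_seq(rng, te.internal.consensus_len),
        te.line.name: _random_seq(rng, te.line.consensus_len),
    }
    consensus_meta = {
        te.ltr.name: ("LTR", te.ltr.consensus_len),
        te.internal.name: ("LTR_internal", te.internal.consensus_len),
        te.line.name: ("LINE", te.line.consensus_len),
    }

    insertions: dict[str, str] = {}
    sites: dict[str, GenomicInterval] = {}
    hits: list[TEHit] = []
    reference_solo_ltrs: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    counter = 0

    def new_site():
        pos = int(rng.integers(0, chrom_len - 1))
        return GenomicInterval(anchor_chrom, pos, pos + 1)

    def add_hit(ins_id, fam_spec, q0, q1, s0, s1, realized_p):
        hits.append(TEHit(
            insertion_id=ins_id, family=fam_spec.name,
            te_class=consensus_meta[fam_spec.name][0],
            q_start=q0, q_end=q1, s_start=s0, s_end=s1,
            pident=100.0 * (1.0 - realized_p), aln_len=q1 - q0,
            gap_frac=0.0, evalue=1e-30,
            consensus_len=fam_spec.consensus_len, orientation="+"))

    def make_copy(fam_spec):
        return _mutate(rng, consensus[fam_spec.name], fam_spec.divergence)

    for _ in range(te.n_solo_ltr):
        ins_id = f"ins{counter}"; counter += 1
        seq, p = make_copy(te.ltr)
        insertions[ins_id] = seq
        sites[ins_id] = new_site()
        add_hit(ins_id, te.ltr, 0, len(seq), 0, te.ltr.consensus_len, p)
        truth[ins_id] = "solo_LTR"

    def build_erv(ins_id):
        ltr5, p5 = make_copy(te.ltr)
        inner, pi = make_copy(te.internal)
        ltr3, p3 = make_copy(te.ltr)
        seq = ltr5 + inner + ltr3
        insertions[ins_id] = seq
        L, I = te.ltr.consensus_len, te.internal.consensus_len
        add_hit(ins_id, te.ltr, 0, L, 0, L, p5)
        add_hit(ins_id, te.internal, L, L + I, 0, I, pi)
        add_hit(ins_id, te.ltr, L + I, L + I + L, 0, L, p3)

    for _ in range(te.n_intact_erv):
        ins_id = f"ins{counter}"; counter += 1
        build_erv(ins_id)
        sites[ins_id] = new_site()
        truth[ins_id] = "intact_ERV"

    for _ in range(te.n_erv_reference_solo_decoy):
        ins_id = f"ins{counter}"; counter += 1
        build_erv(ins_id)
        site = new_site()
        sites[ins_id] = site
        reference_solo_ltrs.append(GenomicInterval(
            site.chrom, max(0, site.start - 50), site.start + 50, ".",
            f"refSolo_{ins_id}"))
        truth[ins_id] = "rejected_reference_soloLTR"

    line_len = te.line.consensus_len
    for _ in range(te.n_line):
        ins_id = f"ins{counter}"; counter += 1
        trunc = int(rng.integers(0, line_len - 400))  # keep >= 400 bp of 3' end
        seq, p = _mutate(rng, consensus[te.line.name][trunc:], te.line.divergence)
        insertions[ins_id] = seq
        sites[ins_id] = new_site()
        add_hit(ins_id, te.line, 0, len(seq), trunc, line_len, p)
        truth[ins_id] = "nonLTR_transposition"

    for _ in range(te.n_line_internal3p_decoy):
        ins_id = f"ins{counter}"; counter += 1
        trunc = int(rng.integers(0, line_len - 400))
        body, p = _mutate(rng, consensus[te.line.name][trunc:], te.line.divergence)
        tail = _random_seq(rng, 500)  # unmapped extra sequence past the 3' end
        insertions[ins_id] = body + tail
        sites[ins_id] = new_site()
        add_hit(ins_id, te.line, 0, len(body), trunc, line_len, p)
        truth[ins_id] = "rejected_internal_3prime"

    return TESimResult(consensus, consensus_meta, insertions, sites, hits,
                       reference_solo_ltrs, truth)
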