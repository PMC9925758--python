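"""Shared data model and readers/writers for the standard formats the
pipeline touches.

All coordinates are 0-based, half-open internally.  The only 1-based
interchange happens inside the VCF reader.  Writers emit deterministic,
sorted output so that write/read round trips are identities.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "SVRecord",
    "SmallRNASpecies",
    "SequenceRecord",
    "ScoreTrack",
    "FormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "write_intervals",
    "read_sv_calls",
    "write_sv_calls",
    "read_collapsed_reads",
    "write_collapsed_reads",
    "read_score_track",
    "write_score_track",
]

SV_TYPES = ("INS", "DEL", "INV", "DUP")
MIN_SV_LENGTH = 50

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ChromSizes:
    """Mapping from chromosome name to length in bp.

    Names are unique (dict semantics); lengths must be >= 1.
    """

    def __init__(self, entries: Mapping[str, int]):
        self._entries: dict[str, int] = {}
        for name, length in entries.items():
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._entries[str(name)] = length

    def __getitem__(self, name: str) -> int:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"ChromSizes({self._entries!r})"

    def items(self):
        return self._entries.items()

    def names(self) -> list[str]:
        return list(self._entries)

    def total(self) -> int:
        return sum(self._entries.values())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located feature: 0-based half-open [start, end) with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, sizes: ChromSizes) -> None:
        if self.chrom not in sizes:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > sizes[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {sizes[self.chrom]}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant with caller metadata.

    INS records are anchored at a 1-bp interval; the inserted sequence, when
    known, has length ``length``.  For DEL/INV/DUP, ``end - start == length``.
    """

    interval: GenomicInterval
    sv_type: str
    length: int
    support_reads: int
    score: float
    caller: str = ""
    inserted_seq: str | None = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.length < MIN_SV_LENGTH:
            raise ValueError(
                f"SV length {self.length} < {MIN_SV_LENGTH} bp minimum"
            )
        if self.sv_type == "INS":
            if self.interval.length != 1:
                raise ValueError("INS records must be anchored at a 1-bp interval")
            if self.inserted_seq is not None and len(self.inserted_seq) != self.length:
                raise ValueError("inserted_seq length does not match SV length")
        else:
            if self.interval.length != self.length:
                raise ValueError(
                    f"{self.sv_type} interval span {self.interval.length} "
                    f"!= length {self.length}"
                )

    @property
    def midpoint(self) -> int:
        """Event point: midpoint for spanning types, anchor for INS."""
        if self.sv_type == "INS":
            return self.interval.start
        return self.interval.midpoint


@dataclass
class SmallRNASpecies:
    """A collapsed small-RNA read: one sequence with a count and mappings.

    ``mappings`` holds (chrom, five_prime_pos, strand) triples; for a
    minus-strand mapping, five_prime_pos is the highest genomic coordinate
    covered by the read.  Counts may be real-valued after calibration.
    """

    sequence: str
    count: float
    mappings: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be non-negative")
        for m in self.mappings:
            if m[2] not in ("+", "-"):
                raise ValueError(f"invalid mapping strand {m[2]!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_genome_mappings(self) -> int:
        return len(self.mappings)

    @property
    def is_unique(self) -> bool:
        return len(self.mappings) == 1


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with its base composition."""

    seq: str

    @property
    def N(self) -> int:
        return len(self.seq)

    @property
    def base_counts(self) -> dict[str, int]:
        return {b: self.seq.upper().count(b) for b in "ACGT"}


class ScoreTrack:
    """Sparse per-base numeric values addressed by (chrom, pos).

    Missing positions carry a configurable fill value.
    """

    def __init__(self, fill: float = 0.0):
        self.fill = float(fill)
        self._data: dict[str, dict[int, float]] = {}

    def set_range(self, chrom: str, start: int, end: int, value: float) -> None:
        per = self._data.setdefault(chrom, {})
        for pos in range(start, end):
            per[pos] = float(value)

    def get(self, chrom: str, pos: int) -> float:
        return self._data.get(chrom, {}).get(pos, self.fill)

    def mean_over(self, iv: GenomicInterval) -> float:
        per = self._data.get(iv.chrom, {})
        total = 0.0
        for pos in range(iv.start, iv.end):
            total += per.get(pos, self.fill)
        return total / iv.length

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def positions(self, chrom: str) -> dict[int, float]:
        return dict(self._data.get(chrom, {}))


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> ChromSizes:
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                entries[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return ChromSizes(entries)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sorted(sizes.items()):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path, sizes: ChromSizes | None = None) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into validated intervals.

    Strand column (6) is honored when present, else intervals are
    unstranded.  Malformed lines and out-of-bounds records raise
    :class:`FormatError` naming the offending line.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, start, end, strand, name)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if sizes is not None:
                try:
                    iv.validate(sizes)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path, extra_cols=None) -> None:
    """Write BED6 (plus optional extra columns, parallel to intervals)."""
    ivs = sorted(intervals)
    extras = list(extra_cols) if extra_cols is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".", "0", iv.strand]
            if extras is not None:
                row.extend(str(x) for x in extras[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# SV calls (TSV and minimal VCF)

_SV_TSV_COLUMNS = ["chrom", "start", "end", "type", "length", "support", "score", "caller"]


def read_sv_calls(path, sizes: ChromSizes | None = None):
    """Read SV calls from TSV or a minimal VCF.

    Returns ``(records, n_rejected)`` where rejected rows are those with
    length below the 50-bp floor (each emits a warning).  Unknown sv_type
    raises.
    """
    path = str(path)
    if path.endswith(".vcf"):
        return _read_sv_vcf(path, sizes)
    return _read_sv_tsv(path, sizes)


def _make_sv(chrom, start, end, sv_type, length, support, score, caller,
             seq, sizes, where):
    if sv_type not in SV_TYPES:
        raise FormatError(f"{where}: unknown sv_type {sv_type!r}")
    if length < MIN_SV_LENGTH:
        warnings.warn(f"{where}: SV length {length} < {MIN_SV_LENGTH} bp, rejected")
        return None
    if sv_type == "INS":
        iv = GenomicInterval(chrom, start, start + 1)
    else:
        iv = GenomicInterval(chrom, start, end)
    if sizes is not None:
        iv.validate(sizes)
    return SVRecord(iv, sv_type, length, support, score, caller, seq)


def _read_sv_tsv(path, sizes):
    records: list[SVRecord] = []
    n_rejected = 0
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "chrom":
                header = parts
                continue
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                length = int(parts[4])
                support = int(parts[5])
                score = float(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            seq = parts[8] if len(parts) > 8 and parts[8] not in (".", "") else None
            rec = _make_sv(chrom, start, end, parts[3], length, support, score,
                           parts[7], seq, sizes, f"{path}:{lineno}")
            if rec is None:
                n_rejected += 1
            else:
                records.append(rec)
    return records, n_rejected


_INFO_RE = re.compile(r"([^;=]+)(?:=([^;]*))?")


def _read_sv_vcf(path, sizes):
    records: list[SVRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 VCF columns")
            chrom, pos = parts[0], int(parts[1]) - 1  # 1-based -> 0-based
            info = dict(m.groups() for m in _INFO_RE.finditer(parts[7]))
            sv_type = info.get("SVTYPE")
            if sv_type is None:
                raise FormatError(f"{path}:{lineno}: missing SVTYPE")
            svlen = abs(int(info["SVLEN"])) if "SVLEN" in info else None
            end = int(info["END"]) if "END" in info else None
            if sv_type == "INS":
                seq = info.get("SEQ")
                if svlen is None and seq is not None:
                    svlen = len(seq)
                if svlen is None:
                    raise FormatError(f"{path}:{lineno}: INS without SVLEN or SEQ")
                start, stop = pos, pos + 1
            else:
                seq = None
                if end is None and svlen is not None:
                    end = pos + svlen
                if end is None:
                    raise FormatError(f"{path}:{lineno}: missing END/SVLEN")
                if svlen is None:
                    svlen = end - pos
                start, stop = pos, end
            support = int(info.get("RE", 0))
            score = float(info.get("SCORE", parts[5])) if parts[5] != "." else float(
                info.get("SCORE", 0))
            caller = info.get("CALLER", "")
            rec = _make_sv(chrom, start, stop, sv_type, svlen, support, score,
                           caller, seq, sizes, f"{path}:{lineno}")
            if rec is None:
                n_rejected += 1
            else:
                records.append(rec)
    return records, n_rejected


def write_sv_calls(records: Sequence[SVRecord], path) -> None:
    recs = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start,
                                          r.sv_type, r.length))
    with open(path, "w") as fh:
        fh.write("\t".join(_SV_TSV_COLUMNS + ["seq"]) + "\n")
        for r in recs:
            iv = r.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end), r.sv_type, str(r.length),
                str(r.support_reads), repr(r.score) if r.score != int(r.score)
                else str(int(r.score)),
                r.caller, r.inserted_seq or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Collapsed small-RNA reads

_COUNT_HEADER_RE = re.compile(r"^(?P<id>.+?)_count(?P<count>[0-9.eE+-]+)$")


def read_collapsed_reads(path, mappings_path=None) -> list[SmallRNASpecies]:
    """Read collapsed reads from FASTA with ``>id_countN`` headers.

    Duplicate sequences are merged by summing counts.  An optional mappings
    TSV (id, chrom, five_prime_pos, strand) attaches genomic mappings; the
    id refers to the FASTA record id (pre-merge ids all attach to the merged
    species).
    """
    by_seq: dict[str, SmallRNASpecies] = {}
    id_to_seq: dict[str, str] = {}
    with open(path) as fh:
        header = None
        seq_parts: list[str] = []

        def flush():
            if header is None:
                return
            m = _COUNT_HEADER_RE.match(header)
            if m is None:
                raise FormatError(f"{path}: header {header!r} lacks _countN suffix")
            try:
                count = float(m.group("count"))
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable count in {header!r}") from exc
            if count <= 0:
                raise FormatError(f"{path}: non-positive count in {header!r}")
            seq = "".join(seq_parts).upper()
            id_to_seq[m.group("id")] = seq
            if seq in by_seq:
                by_seq[seq].count += count
            else:
                by_seq[seq] = SmallRNASpecies(seq, count)

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        flush()

    if mappings_path is not None:
        with open(mappings_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(
                        f"{mappings_path}:{lineno}: expected 4 columns")
                rid, chrom, pos, strand = parts[0], parts[1], int(parts[2]), parts[3]
                if rid not in id_to_seq:
                    raise FormatError(
                        f"{mappings_path}:{lineno}: unknown read id {rid!r}")
                by_seq[id_to_seq[rid]].mappings.append((chrom, pos, strand))
    return list(by_seq.values())


def write_collapsed_reads(species: Sequence[SmallRNASpecies], fasta_path,
                          mappings_path=None) -> None:
    ordered = sorted(species, key=lambda s: s.sequence)
    with open(fasta_path, "w") as fh:
        for i, sp in enumerate(ordered):
            count = sp.count
            cstr = str(int(count)) if count == int(count) else repr(count)
            fh.write(f">s{i}_count{cstr}\n{sp.sequence}\n")
    if mappings_path is not None:
        with open(mappings_path, "w") as fh:
            for i, sp in enumerate(ordered):
                for chrom, pos, strand in sorted(sp.mappings):
                    fh.write(f"s{i}\t{chrom}\t{pos}\t{strand}\n")


# ---------------------------------------------------------------------------
# bedGraph score tracks


def read_score_track(path, sizes: ChromSizes | None = None,
                     fill: float = 0.0) -> ScoreTrack:
    track = ScoreTrack(fill=fill)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            value = float(parts[3])
            if sizes is not None and (chrom not in sizes or end > sizes[chrom]):
                raise FormatError(f"{path}:{lineno}: out of chromosome bounds")
            track.set_range(chrom, start, end, value)
    return track


def write_score_track(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            per = track.positions(chrom)
            # merge runs of equal values into bedGraph intervals
            run_start = None
            run_val = None
            prev = None
            for pos in sorted(per):
                val = per[pos]
                if run_start is not None and (pos != prev + 1 or val != run_val):
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")
                    run_start = None
                if run_start is None:
                    run_start, run_val = pos, val
                prev = pos
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val:g}\n")
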