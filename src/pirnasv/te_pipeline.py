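"""TE insertion classification from consensus-alignment hit tables, active
family calling, and Jukes-Cantor age estimation.

Classification cascade (exclusive, order-independent in its inputs):

1. no hit surviving the filters             -> rejected_no_hit
2. LTR / DNA classes: the insertion must start and end with TE alignment
   (within ``end_tol``)                     -> else rejected_not_TE_bounded
   and hits must reach both consensus termini:
   - only-LTR hits spanning the insertion   -> solo_LTR
   - LTR + internal + LTR order             -> intact_ERV
     (unless the site overlaps a reference solo-LTR -> rejected_reference_soloLTR)
3. LINE class: the consensus 3' terminus must align at an insertion end
   (orientation-aware); 5' truncation is allowed, with a >= 200 bp 3'
   block replacing the 80%-length rule      -> nonLTR_transposition
   (3' end internal to the insertion        -> rejected_internal_3prime)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from pirnasv.core_model import FormatError, GenomicInterval

__all__ = [
    "TEHit",
    "InsertionCall",
    "AgeEstimate",
    "filter_hits",
    "classify_insertion",
    "call_active_families",
    "estimate_age",
    "read_hit_table",
    "SUBSTITUTION_RATE",
]

TE_CLASSES = ("LTR", "LTR_internal", "LINE", "SINE", "DNA")
EVALUE_MAX = 1e-10
END_TOL = 20
LINE_MIN_3P_BLOCK = 200
SUBSTITUTION_RATE = 1.9e-3  # substitutions / site / My

ACCEPTED_STATUSES = ("solo_LTR", "intact_ERV", "nonLTR_transposition")
REJECTED_STATUSES = (
    "rejected_no_hit", "rejected_incomplete_ends", "rejected_internal_3prime",
    "rejected_not_TE_bounded", "rejected_reference_soloLTR", "rejected_filters",
)


@dataclass(frozen=True)
class TEHit:
    insertion_id: str
    family: str
    te_class: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    pident: float
    aln_len: int
    gap_frac: float
    evalue: float
    consensus_len: int
    orientation: str = "+"

    def __post_init__(self):
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if not 0 <= self.q_start < self.q_end:
            raise ValueError("invalid query coordinates")
        if not 0 <= self.pident <= 100:
            raise ValueError("pident must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class InsertionCall:
    insertion_id: str
    status: str
    families: set[str] = field(default_factory=set)
    notes: str = ""

    @property
    def accepted(self) -> bool:
        return self.status in ACCEPTED_STATUSES


@dataclass
class AgeEstimate:
    family: str
    p_divergence: float
    K: float
    age_my: float
    rate: float = SUBSTITUTION_RATE


def filter_hits(hits: Iterable[TEHit], evalue_max: float = EVALUE_MAX,
                min_pident: float = 80.0, min_len_frac: float = 0.8,
                max_gap_frac: float = 0.2,
                waive_length_for_line: bool = True) -> list[TEHit]:
    """80-80-80 filter: > 80% identity over > 80% of the consensus with
    < 20% gaps, after the e-value cutoff.

    The alignment-length rule is waived for LINE hits (the classifier's
    3'-anchored path substitutes a minimum 3' block instead).
    """
    out = []
    for h in hits:
        if h.evalue > evalue_max:
            continue
        if h.pident <= min_pident:
            continue
        if h.gap_frac >= max_gap_frac:
            continue
        if h.aln_len <= min_len_frac * h.consensus_len and not (
                waive_length_for_line and h.te_class == "LINE"):
            continue
        out.append(h)
    return out


def _covers_insertion_ends(hits: Sequence[TEHit], insertion_len: int,
                           tol: int) -> bool:
    starts_ok = any(h.q_start <= tol for h in hits)
    ends_ok = any(h.q_end >= insertion_len - tol for h in hits)
    return starts_ok and ends_ok


def _reaches_both_consensus_ends(h: TEHit, tol: int) -> bool:
    return h.s_start <= tol and h.s_end >= h.consensus_len - tol


def classify_insertion(insertion_id: str, insertion_len: int,
                       hits: Sequence[TEHit],
                       reference_solo_ltrs: Sequence[GenomicInterval] = (),
                       insertion_site: GenomicInterval | None = None,
                       end_tol: int = END_TOL) -> InsertionCall:
    """Apply the structural decision cascade to one insertion.

    ``hits`` must already have passed :func:`filter_hits`.
    """
    hits = [h for h in hits if h.insertion_id == insertion_id]
    if not hits:
        return InsertionCall(insertion_id, "rejected_no_hit")

    classes = {h.te_class for h in hits}
    families = {h.family for h in hits}

    if classes <= {"LTR", "LTR_internal", "DNA"}:
        # "must start and end with TEs" applies to the ERV/DNA path
        if not _covers_insertion_ends(hits, insertion_len, end_tol):
            return InsertionCall(insertion_id, "rejected_not_TE_bounded",
                                 families)
        # ambiguity guard: unrelated families spanning the two termini
        base_families = {h.family.replace("_I", "").replace("_LTR", "")
                         for h in hits}
        if len(base_families) > 1:
            return InsertionCall(insertion_id, "rejected_filters", families,
                                 "ambiguous")
        incomplete = [h for h in hits
                      if not _reaches_both_consensus_ends(h, end_tol)]
        if incomplete:
            return InsertionCall(insertion_id, "rejected_incomplete_ends",
                                 families)
        if classes <= {"LTR"}:
            return InsertionCall(insertion_id, "solo_LTR", families)
        if classes == {"DNA"}:
            return InsertionCall(insertion_id, "nonLTR_transposition", families,
                                 "DNA transposon")
        # LTR + internal: require LTR - internal - LTR order on the insertion
        ordered = sorted(hits, key=lambda h: h.q_start)
        pattern = [h.te_class for h in ordered]
        if (len(ordered) >= 3 and pattern[0] == "LTR" and pattern[-1] == "LTR"
                and all(c == "LTR_internal" for c in pattern[1:-1])):
            if insertion_site is not None and any(
                    insertion_site.overlaps(iv) for iv in reference_solo_ltrs):
                return InsertionCall(insertion_id, "rejected_reference_soloLTR",
                                     families)
            return InsertionCall(insertion_id, "intact_ERV", families)
        return InsertionCall(insertion_id, "rejected_incomplete_ends",
                             families, "LTR/internal order violated")

    if classes <= {"LINE", "SINE"}:
        # 3'-anchored rule: the consensus 3' terminus must sit at an
        # insertion end; which insertion end depends on orientation.
        saw_short_block = False
        saw_internal_3p = False
        for h in hits:
            if h.s_end < h.consensus_len - end_tol:
                continue  # alignment never reaches the consensus 3' end
            if h.orientation == "+":
                at_end = h.q_end >= insertion_len - end_tol
            else:
                at_end = h.q_start <= end_tol
            if not at_end:
                saw_internal_3p = True
                continue
            if h.s_end - h.s_start < LINE_MIN_3P_BLOCK:
                saw_short_block = True
                continue
            return InsertionCall(insertion_id, "nonLTR_transposition",
                                 {h.family})
        if saw_internal_3p:
            return InsertionCall(insertion_id, "rejected_internal_3prime",
                                 families)
        if saw_short_block:
            return InsertionCall(insertion_id, "rejected_incomplete_ends",
                                 families, "3' block < 200 bp")
        return InsertionCall(insertion_id, "rejected_incomplete_ends", families)

    return InsertionCall(insertion_id, "rejected_filters", families, "ambiguous")


def call_active_families(calls: Sequence[InsertionCall],
                         ltr_internal_map: Mapping[str, str] | None = None,
                         dna_families: set[str] | None = None):
    """Union of families over accepted calls, expanding each accepted
    solo-LTR / intact-ERV family with its internal counterpart.

    Returns ``(retrotransposon_families, dna_transposon_families)``.
    """
    ltr_internal_map = dict(ltr_internal_map or {})
    dna_families = set(dna_families or ())
    active: set[str] = set()
    for call in calls:
        if not call.accepted:
            continue
        active |= call.families
        if call.status in ("solo_LTR", "intact_ERV"):
            for fam in call.families:
                if fam in ltr_internal_map:
                    active.add(ltr_internal_map[fam])
                elif call.status == "solo_LTR":
                    warnings.warn(f"no internal counterpart mapped for {fam}")
    dna = active & dna_families
    return active - dna, dna


def jc69_distance(p: float) -> float:
    """K = -(3/4) ln(1 - (4/3) p); undefined at p >= 0.75."""
    if not 0 <= p < 0.75:
        raise ValueError(f"divergence p={p} outside [0, 0.75): JC69 saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_age(copies_by_family: Mapping[str, Sequence[float]],
                 rate: float = SUBSTITUTION_RATE):
    """Per-family JC69 age from mean copy divergence, plus the cohort median.

    Family age = K(mean p) / rate, in million years.  Returns
    ``(list of AgeEstimate, median age)``.
    """
    estimates = []
    for family in sorted(copies_by_family):
        ps = list(copies_by_family[family])
        if not ps:
            raise ValueError(f"family {family!r} has no copies")
        p_mean = float(np.mean(ps))
        k = jc69_distance(p_mean)
        estimates.append(AgeEstimate(family, p_mean, k, k / rate, rate))
    median_age = float(np.median([e.age_my for e in estimates]))
    return estimates, median_age


# ---------------------------------------------------------------------------
# I/O: BLAST outfmt-6-style hit table plus a consensus-length sidecar


def read_hit_table(path, consensus_meta_path) -> list[TEHit]:
    """Read hits from a tabular file with columns:

    insertion_id, family, q_start, q_end, s_start, s_end, pident, aln_len,
    gap_frac, evalue, orientation

    ``consensus_meta_path`` is a TSV of (family, te_class, consensus_len).
    """
    meta: dict[str, tuple[str, int]] = {}
    with open(consensus_meta_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{consensus_meta_path}:{lineno}: "
                                  "expected 3 columns")
            meta[parts[0]] = (parts[1], int(parts[2]))

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("insertion_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 columns")
            family = parts[1]
            if family not in meta:
                raise FormatError(f"{path}:{lineno}: unknown family {family!r}")
            te_class, consensus_len = meta[family]
            hits.append(TEHit(
                insertion_id=parts[0], family=family, te_class=te_class,
                q_start=int(parts[2]), q_end=int(parts[3]),
                s_start=int(parts[4]), s_end=int(parts[5]),
                pident=float(parts[6]), aln_len=int(parts[7]),
                gap_frac=float(parts[8]), evalue=float(parts[9]),
                consensus_len=consensus_len, orientation=parts[10]))
    return hits


def write_hit_table(hits: Sequence[TEHit], path, consensus_meta_path) -> None:
    meta = {}
    with open(path, "w") as fh:
        fh.write("insertion_id\tfamily\tq_start\tq_end\ts_start\ts_end\t"
                 "pident\taln_len\tgap_frac\tevalue\torientation\n")
        for h in sorted(hits, key=lambda h: (h.insertion_id, h.q_start)):
            meta[h.family] = (h.te_class, h.consensus_len)
            fh.write("\t".join([
                h.insertion_id, h.family, str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), f"{h.pident:g}",
                str(h.aln_len), f"{h.gap_frac:g}", f"{h.evalue:g}",
                h.orientation]) + "\n")
    with open(consensus_meta_path, "w") as fh:
        fh.write("family\tte_class\tconsensus_len\n")
        for family in sorted(meta):
            te_class, clen = meta[family]
            fh.write(f"{family}\t{te_class}\t{clen}\n")
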