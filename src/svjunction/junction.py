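"""Junction-supporting read detection in alignment data.

Two counting modes are implemented:

* soft-clip fuzzy matching (WGS modes): reads with >= 10 clipped bases are
  screened for both 20 bp junction flanks (each within a small mismatch
  budget) and then compared to the full junction sequence, retained when
  the edit distance is at most 2.5% of the read length;
* perfect-window counting (hybrid-capture mode): reads aligned to the
  junction references are counted when they cover the 20 bp on each side
  of the junction centre with a 100% match.

Molecule counts are obtained by collapsing hits on (SV, UMI, alignment
start); reads without a UMI fall back to their read name.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .editdist import find_approx, find_hamming, semiglobal_distance
from .sv_panel import JunctionReference
from .sequtil import revcomp

__all__ = [
    "AlignedRead",
    "JunctionHit",
    "SvReadCounts",
    "MatchWgsParams",
    "read_sam",
    "extract_softclip_candidates",
    "match_junction_read",
    "match_junction_reads",
    "count_capture_reads",
    "dedup_by_umi",
    "wgs_af",
]

_QUERY_OPS = set("MIS=X")


@dataclass
class AlignedRead:
    """Minimal alignment record used by the junction matchers."""

    name: str
    ref_name: str
    pos: int  # 1-based leftmost aligned base; 0 for unmapped
    cigar: list  # [(op, length)]
    seq: str
    umi: str = ""
    mapq: int = 0
    is_unmapped: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.cigar and not self.is_unmapped:
            qlen = sum(l for op, l in self.cigar if op in _QUERY_OPS and op != "H")
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.name}: cigar consumes {qlen} query bases but seq has {len(self.seq)}"
                )

    @classmethod
    def from_pysam(cls, rec) -> "AlignedRead":
        cigar = []
        if rec.cigartuples:
            ops = "MIDNSHP=X"
            cigar = [(ops[op], ln) for op, ln in rec.cigartuples]
        umi = ""
        if rec.has_tag("RX"):
            umi = rec.get_tag("RX")
        return cls(
            name=rec.query_name,
            ref_name=rec.reference_name or "",
            pos=(rec.reference_start + 1) if rec.reference_start is not None and not rec.is_unmapped else 0,
            cigar=cigar,
            seq=rec.query_sequence or "",
            umi=umi,
            mapq=rec.mapping_quality,
            is_unmapped=rec.is_unmapped,
            is_reverse=rec.is_reverse,
        )


@dataclass
class JunctionHit:
    sv_id: str
    read_name: str
    umi: str
    align_start: int
    edit_distance: int
    mode: str  # softclip_match | capture_window


@dataclass
class SvReadCounts:
    """Per-SV raw read and UMI-deduplicated molecule counts."""

    per_sv: dict = field(default_factory=dict)  # sv_id -> [read_count, molecule_count]

    def read_count(self, sv_id: str) -> int:
        return self.per_sv.get(sv_id, (0, 0))[0]

    def molecule_count(self, sv_id: str) -> int:
        return self.per_sv.get(sv_id, (0, 0))[1]

    @property
    def total_reads(self) -> int:
        return sum(v[0] for v in self.per_sv.values())

    @property
    def total_molecules(self) -> int:
        return sum(v[1] for v in self.per_sv.values())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sv_id": s, "read_count": rc, "molecule_count": mc}
                for s, (rc, mc) in sorted(self.per_sv.items())
            ],
            columns=["sv_id", "read_count", "molecule_count"],
        )


@dataclass
class MatchWgsParams:
    flank_len: int = 20
    flank_max_mismatch: int = 2
    max_edit_frac: float = 0.025
    umi_len: int = 0  # >0: UMI is a read prefix, stripped before matching
    substitutions_only: bool = False


def read_sam(path: str) -> Iterable[AlignedRead]:
    """Stream alignment records from a SAM/BAM file."""
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            yield AlignedRead.from_pysam(rec)


def extract_softclip_candidates(
    reads: Iterable[AlignedRead], min_clip: int = 10
) -> Iterable[AlignedRead]:
    """Mapped reads whose alignment starts or ends with a clip of >= ``min_clip``."""
    skipped = 0
    for read in reads:
        if read.is_unmapped or not read.cigar:
            continue
        try:
            first_op, first_len = read.cigar[0]
            last_op, last_len = read.cigar[-1]
        except (TypeError, ValueError):
            skipped += 1
            continue
        if (first_op in "SH" and first_len >= min_clip) or (
            last_op in "SH" and last_len >= min_clip
        ):
            yield read
    if skipped:
        warnings.warn(f"skipped {skipped} records with malformed CIGAR strings")


def _find_flank(flank: str, seq: str, budget: int, substitutions_only: bool):
    if substitutions_only:
        return find_hamming(flank, seq, budget)
    return find_approx(flank, seq, budget)


def match_junction_read(
    read: AlignedRead,
    junction: JunctionReference,
    params: Optional[MatchWgsParams] = None,
) -> Optional[JunctionHit]:
    """Match one candidate read against one junction reference.

    A hit requires both 20 bp flanks of the junction to occur in the read
    (each within the flank budget, left before right), and the edit
    distance of the whole read against the junction sequence to be at most
    ``floor(max_edit_frac * read length)``.  The UMI prefix (when present
    in the read) is excluded from both tests; both strands are tried.
    """
    params = params or MatchWgsParams()
    fl = params.flank_len
    if junction.center < fl or len(junction.sequence) - junction.center < fl:
        raise ValueError(
            f"{junction.sv_id}: junction needs >= {fl} bp on each side of the center"
        )
    seq = read.seq.upper()
    umi = read.umi
    if params.umi_len > 0 and not umi:
        umi, seq = seq[: params.umi_len], seq[params.umi_len :]
    if not seq:
        return None
    budget = math.floor(params.max_edit_frac * len(seq))
    left = junction.sequence[junction.center - fl : junction.center]
    right = junction.sequence[junction.center : junction.center + fl]
    for oriented in (seq, revcomp(seq)):
        left_occ = _find_flank(left, oriented, params.flank_max_mismatch, params.substitutions_only)
        if left_occ is None:
            continue
        right_occ = _find_flank(right, oriented, params.flank_max_mismatch, params.substitutions_only)
        if right_occ is None or right_occ.start < left_occ.start:
            continue
        dist = semiglobal_distance(oriented, junction.sequence)
        if dist <= budget:
            return JunctionHit(
                sv_id=junction.sv_id,
                read_name=read.name,
                umi=umi,
                align_start=junction.center - fl - left_occ.start,
                edit_distance=dist,
                mode="softclip_match",
            )
    return None


def match_junction_reads(
    reads: Iterable[AlignedRead],
    junctions: Sequence[JunctionReference],
    params: Optional[MatchWgsParams] = None,
    min_clip: int = 10,
) -> list:
    """Soft-clip screen plus junction matching over a read stream."""
    hits = []
    for read in extract_softclip_candidates(reads, min_clip=min_clip):
        for junction in junctions:
            hit = match_junction_read(read, junction, params)
            if hit is not None:
                hits.append(hit)
                break
    return hits


def _window_match(read: AlignedRead, junction: JunctionReference, window: int) -> bool:
    """True iff the alignment covers center±window with identical bases and no indel."""
    lo = junction.center - window
    hi = junction.center + window  # half-open; 2*window reference bases
    covered: dict = {}
    qpos = 0
    rpos = read.pos - 1
    for op, length in read.cigar:
        if op in "M=X":
            for k in range(length):
                r = rpos + k
                if lo <= r < hi:
                    covered[r] = read.seq[qpos + k]
            qpos += length
            rpos += length
        elif op == "I":
            if lo < rpos < hi:  # insertion strictly inside the window
                return False
            qpos += length
        elif op in "DN":
            if rpos < hi and rpos + length > lo:  # deletion overlapping the window
                return False
            rpos += length
        elif op == "S":
            qpos += length
        # H and P consume nothing we track
    if len(covered) != hi - lo:
        return False
    ref = junction.sequence
    return all(covered[r] == ref[r] for r in range(lo, hi))


def count_capture_reads(
    reads: Iterable[AlignedRead],
    junctions: Mapping[str, JunctionReference],
    window: int = 20,
    collect_hits: Optional[list] = None,
) -> SvReadCounts:
    """Count reads with a perfect match across the junction-center window.

    ``reads`` must be aligned to the junction references (reference name ==
    sv_id).  A read is counted iff its alignment covers ``window`` bases on
    each side of the center and matches the reference exactly there.
    """
    hits = []
    unknown: set = set()
    for read in reads:
        if read.is_unmapped:
            continue
        junction = junctions.get(read.ref_name)
        if junction is None:
            unknown.add(read.ref_name)
            continue
        if _window_match(read, junction, window):
            hits.append(
                JunctionHit(
                    sv_id=junction.sv_id,
                    read_name=read.name,
                    umi=read.umi,
                    align_start=read.pos - 1,
                    edit_distance=0,
                    mode="capture_window",
                )
            )
    if unknown:
        warnings.warn(f"skipped reads aligned to unknown references: {sorted(unknown)}")
    if collect_hits is not None:
        collect_hits.extend(hits)
    counts = dedup_by_umi(hits)
    for sv_id in junctions:
        counts.per_sv.setdefault(sv_id, [0, 0])
    return counts


def dedup_by_umi(hits: Iterable[JunctionHit]) -> SvReadCounts:
    """Collapse PCR duplicates: one molecule per (sv, UMI, alignment start).

    Hits with an empty UMI fall back to (sv, read name) so they are never
    collapsed across reads.
    """
    counts = SvReadCounts()
    keys: set = set()
    for hit in hits:
        entry = counts.per_sv.setdefault(hit.sv_id, [0, 0])
        entry[0] += 1
        if hit.umi:
            key = (hit.sv_id, hit.umi, hit.align_start)
        else:
            key = (hit.sv_id, hit.read_name)
        if key not in keys:
            keys.add(key)
            entry[1] += 1
    return counts


def wgs_af(total_junction_reads: int, mean_depth: float, n_svs: int) -> float:
    """Allele fraction for WGS modes: reads / (2 × depth × number of SVs)."""
    if total_junction_reads < 0:
        raise ValueError("read count must be non-negative")
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if n_svs < 1:
        raise ValueError("n_svs must be >= 1")
    return total_junction_reads / (2.0 * mean_depth * n_svs)
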