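"""Selection of high-confidence patient-specific SVs and junction construction.

The panel-building stage takes somatic SV calls (VCF breakend records or a
tabular format), copy-number segments, repeat/gap masks and a pooled-cohort
breakpoint blacklist, applies the high-confidence filters, and builds one
synthetic junction reference sequence per retained SV (default 150 bp of
flanking sequence on each side of the predicted breakpoint).

Coordinate conventions
----------------------
Breakpoint positions are 1-based: ``pos_a`` is the last reference base
before the junction on side A and ``pos_b`` the first base after it on
side B.  All interval arithmetic is 0-based half-open internally.
Orientation ``orient_a='+'`` retains the sequence ending at ``pos_a``
(``'-'`` retains the sequence starting there, reverse-complemented);
``orient_b='+'`` retains the sequence starting at ``pos_b`` (``'-'`` the
sequence ending there, reverse-complemented).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .sequtil import (
    chrom_sort_key,
    is_primary_chrom,
    parse_center_tag,
    revcomp,
    write_fasta,
)

__all__ = [
    "SvCall",
    "CnSegment",
    "RegionMask",
    "JunctionReference",
    "FilterReport",
    "FilterParams",
    "parse_sv_calls",
    "find_cn_steps",
    "cluster_recurrent_breakpoints",
    "filter_high_confidence",
    "build_junction_reference",
    "write_junction_fasta",
    "load_junction_fasta",
]

REJECT_REASONS = (
    "low_score",
    "non_primary_chrom",
    "repeat_or_gap_adjacent",
    "recurrent_breakpoint",
    "short_intra_span",
    "no_cn_step",
)


@dataclass
class SvCall:
    """A somatic SV as a canonicalized breakpoint pair."""

    sv_id: str
    chrom_a: str
    pos_a: int
    orient_a: str
    chrom_b: str
    pos_b: int
    orient_b: str
    somatic_score: int = 0
    inserted_seq: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError(f"{self.sv_id}: breakpoint positions must be >= 1")
        if self.orient_a not in "+-" or self.orient_b not in "+-":
            raise ValueError(f"{self.sv_id}: orientations must be '+' or '-'")

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b

    @property
    def span(self) -> Optional[int]:
        if self.is_interchromosomal:
            return None
        return abs(self.pos_b - self.pos_a)

    def canonicalized(self) -> "SvCall":
        """Return a copy with side A <= side B (chromosome order, then position)."""
        key_a = (chrom_sort_key(self.chrom_a), self.pos_a)
        key_b = (chrom_sort_key(self.chrom_b), self.pos_b)
        if key_a <= key_b:
            return self
        flip = {"+": "-", "-": "+"}
        return SvCall(
            sv_id=self.sv_id,
            chrom_a=self.chrom_b,
            pos_a=self.pos_b,
            orient_a=flip[self.orient_b],
            chrom_b=self.chrom_a,
            pos_b=self.pos_a,
            orient_b=flip[self.orient_a],
            somatic_score=self.somatic_score,
            inserted_seq=revcomp(self.inserted_seq),
            sample_id=self.sample_id,
        )


@dataclass
class CnSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CN segment {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")


@dataclass
class RegionMask:
    """Gap and simple-repeat intervals, 0-based half-open."""

    intervals: list = field(default_factory=list)  # (chrom, start, end, kind)

    def __post_init__(self) -> None:
        for chrom, start, end, kind in self.intervals:
            if start >= end:
                raise ValueError(f"mask interval {chrom}:{start}-{end}: start must be < end")
            if kind not in ("gap", "simple_repeat"):
                raise ValueError(f"unknown mask kind {kind!r}")

    @classmethod
    def from_bed(cls, path: str, kind_column: int = 3) -> "RegionMask":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), f[kind_column]))
        return cls(rows)

    def hits_breakpoint(
        self, chrom: str, pos: int, adjacency_window: int = 100, repeat_min_len: int = 100
    ) -> bool:
        """True if the 1-based breakpoint is near a gap or inside a long simple repeat."""
        p = pos - 1
        for c, start, end, kind in self.intervals:
            if c != chrom:
                continue
            if kind == "gap":
                if start - adjacency_window <= p < end + adjacency_window:
                    return True
            else:  # simple_repeat
                if end - start > repeat_min_len and start <= p < end:
                    return True
        return False


@dataclass
class JunctionReference:
    """Synthetic junction contig: side-A flank + inserted sequence + side-B flank."""

    sv_id: str
    sequence: str
    center: int  # 0-based index of the first base contributed by side B
    flank_len: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.center < len(self.sequence)):
            raise ValueError(f"{self.sv_id}: center must be strictly inside the sequence")


@dataclass
class FilterReport:
    """Per-SV audit trail of the high-confidence filters."""

    reasons: dict = field(default_factory=dict)  # sv_id -> tuple of reject reasons

    def decision(self, sv_id: str) -> str:
        return "retained" if not self.reasons[sv_id] else "rejected"

    @property
    def retained_ids(self) -> list:
        return [sv_id for sv_id, r in self.reasons.items() if not r]

    @property
    def rejected_ids(self) -> list:
        return [sv_id for sv_id, r in self.reasons.items() if r]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sv_id": list(self.reasons),
                "decision": [self.decision(s) for s in self.reasons],
                "reject_reasons": [",".join(r) for r in self.reasons.values()],
            }
        )


@dataclass
class FilterParams:
    min_score: int = 31
    min_span: int = 100_000
    cn_step_window: int = 10_000
    repeat_min_len: int = 100
    adjacency_window: int = 100
    require_both_cn_steps: bool = False


# ---------------------------------------------------------------------------
# parsing

_BND_RE = re.compile(
    r"^(?P<lead>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<trail>[ACGTNacgtn]*)$"
)

_TSV_COLUMNS = [
    "sv_id",
    "chrom_a",
    "pos_a",
    "orient_a",
    "chrom_b",
    "pos_b",
    "orient_b",
    "somatic_score",
    "inserted_seq",
    "sample_id",
]


def parse_sv_calls(path: str, sample_id: Optional[str] = None) -> list:
    """Parse SV calls from a VCF (BND notation) or TSV file into ``SvCall`` objects.

    VCF mate pairs are collapsed to a single canonicalized call; an unpaired
    BND record raises a ``ValueError`` naming the record.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.endswith(".vcf"):
        return _parse_vcf(path, sample_id)
    return _parse_tsv(path)


def _parse_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"SV TSV missing required columns: {missing}")
    calls = []
    for i, row in df.iterrows():
        try:
            call = SvCall(
                sv_id=row["sv_id"],
                chrom_a=row["chrom_a"],
                pos_a=int(row["pos_a"]),
                orient_a=row["orient_a"],
                chrom_b=row["chrom_b"],
                pos_b=int(row["pos_b"]),
                orient_b=row["orient_b"],
                somatic_score=int(row.get("somatic_score", 0) or 0),
                inserted_seq=row.get("inserted_seq", "") or "",
                sample_id=row.get("sample_id", "") or "",
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed SV record at line {i + 2}: {exc}") from exc
        calls.append(call.canonicalized())
    _check_unique([c.sv_id for c in calls])
    return calls


def _parse_vcf(path: str, sample_id: Optional[str]) -> list:
    records: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"malformed VCF line {lineno}")
            chrom, pos, vid, ref, alt, _qual, _filt, info = f[:8]
            info_d = dict(
                kv.split("=", 1) if "=" in kv else (kv, True) for kv in info.split(";") if kv
            )
            if info_d.get("SVTYPE") != "BND":
                continue
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(f"malformed coordinates at VCF line {lineno}") from exc
            records[vid] = {
                "chrom": chrom,
                "pos": pos_i,
                "ref": ref,
                "alt": alt,
                "mate": info_d.get("MATEID"),
                "score": int(info_d.get("SOMATICSCORE", 0)),
                "line": lineno,
            }
    calls = []
    seen = set()
    for vid, rec in records.items():
        if vid in seen:
            continue
        mate_id = rec["mate"]
        if mate_id is None or mate_id not in records:
            raise ValueError(f"unpaired BND record {vid!r} (VCF line {rec['line']})")
        mate = records[mate_id]
        seen.update((vid, mate_id))
        # build from the mate that is canonical side A
        key_self = (chrom_sort_key(rec["chrom"]), rec["pos"])
        key_mate = (chrom_sort_key(mate["chrom"]), mate["pos"])
        a = rec if key_self <= key_mate else mate
        call = _bnd_to_call(a, base_id=vid.rsplit(":", 1)[0], sample_id=sample_id or "")
        calls.append(call)
    _check_unique([c.sv_id for c in calls])
    return calls


def _bnd_to_call(rec: dict, base_id: str, sample_id: str) -> SvCall:
    m = _BND_RE.match(rec["alt"])
    if m is None:
        raise ValueError(f"unparseable BND ALT {rec['alt']!r} (VCF line {rec['line']})")
    lead, trail = m.group("lead"), m.group("trail")
    bracket = m.group("b1")
    if bracket != m.group("b2"):
        raise ValueError(f"inconsistent brackets in BND ALT {rec['alt']!r}")
    ref = rec["ref"]
    if lead:  # t[p[ or t]p] : this side retains its left flank
        orient_a = "+"
        inserted = lead[len(ref):]
    else:  # ]p]t or [p[t : this side retains its right flank
        orient_a = "-"
        inserted = revcomp(trail[: len(trail) - len(ref)])
    orient_b = "+" if bracket == "[" else "-"
    return SvCall(
        sv_id=base_id,
        chrom_a=rec["chrom"],
        pos_a=rec["pos"],
        orient_a=orient_a,
        chrom_b=m.group("chrom"),
        pos_b=int(m.group("pos")),
        orient_b=orient_b,
        somatic_score=rec["score"],
        inserted_seq=inserted,
        sample_id=sample_id,
    ).canonicalized()


def _check_unique(ids: Sequence[str]) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate sv_id {i!r} in call set")
        seen.add(i)


# ---------------------------------------------------------------------------
# filters


def find_cn_steps(segments: Iterable[CnSegment]) -> list:
    """Boundaries between adjacent same-chromosome segments with unequal copy number.

    Returns ``(chrom, position)`` tuples where position is the end of the
    left segment.  Overlapping segments raise a validation error.
    """
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    steps = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        for left, right in zip(segs, segs[1:]):
            if right.start < left.end:
                raise ValueError(
                    f"overlapping CN segments on {chrom}: "
                    f"{left.start}-{left.end} and {right.start}-{right.end}"
                )
            if left.copy_number != right.copy_number:
                steps.append((chrom, left.end))
    return steps


def _qualifies_rule_i(call: SvCall, min_span: int = 100_000) -> bool:
    return call.is_interchromosomal or (call.span is not None and call.span > min_span)


def _cluster_positions(
    points: list, max_dist: int
) -> Iterable[list]:
    """Single-linkage clusters of (chrom, pos, sample_id) within ``max_dist``."""
    by_chrom: dict = {}
    for p in points:
        by_chrom.setdefault(p[0], []).append(p)
    for chrom in by_chrom:
        pts = sorted(by_chrom[chrom], key=lambda p: p[1])
        cluster = [pts[0]]
        for p in pts[1:]:
            if p[1] - cluster[-1][1] < max_dist:
                cluster.append(p)
            else:
                yield cluster
                cluster = [p]
        yield cluster


def cluster_recurrent_breakpoints(
    pooled_calls: Iterable[SvCall],
    large_span: int = 100_000,
    large_cluster_dist: int = 2_000,
    any_cluster_dist: int = 200,
) -> set:
    """Blacklist breakpoint positions recurrent across tumors in a pooled cohort.

    Rule (i): breakpoints of large (>100 kb span) or inter-chromosomal SVs
    from different samples separated by < 2 kb.  Rule (ii): any two
    breakpoints from different samples separated by < 200 bp.  Clustering
    is single-linkage; a cluster is recurrent only if it contains >= 2
    distinct sample ids.  Returns a set of ``(chrom, pos)``.
    """
    calls = list(pooled_calls)
    samples = {c.sample_id for c in calls}
    if len(samples) < 2:
        warnings.warn("recurrent-breakpoint clustering needs calls from >= 2 samples; empty blacklist")
        return set()
    all_points = []
    large_points = []
    for c in calls:
        for chrom, pos in ((c.chrom_a, c.pos_a), (c.chrom_b, c.pos_b)):
            all_points.append((chrom, pos, c.sample_id))
            if _qualifies_rule_i(c, large_span):
                large_points.append((chrom, pos, c.sample_id))
    blacklist: set = set()
    for points, dist in ((large_points, large_cluster_dist), (all_points, any_cluster_dist)):
        if not points:
            continue
        for cluster in _cluster_positions(points, dist):
            if len({p[2] for p in cluster}) >= 2:
                blacklist.update((p[0], p[1]) for p in cluster)
    return blacklist


def filter_high_confidence(
    calls: Iterable[SvCall],
    cn_steps: Sequence = (),
    mask: Optional[RegionMask] = None,
    blacklist: Optional[set] = None,
    params: Optional[FilterParams] = None,
) -> FilterReport:
    """Apply the high-confidence SV filters; every input SV gets a decision.

    Retained iff: somatic score >= ``min_score``; both breakpoints on primary
    chromosomes; neither breakpoint near a gap or inside a long simple repeat;
    neither breakpoint blacklisted; inter-chromosomal or span > ``min_span``;
    and a breakpoint within ``cn_step_window`` of a copy-number step (one
    breakpoint by default, both with ``require_both_cn_steps``).
    """
    params = params or FilterParams()
    blacklist = blacklist or set()
    steps_by_chrom: dict = {}
    for chrom, pos in cn_steps:
        steps_by_chrom.setdefault(chrom, []).append(pos)

    def near_step(chrom: str, pos: int) -> bool:
        return any(abs(pos - s) <= params.cn_step_window for s in steps_by_chrom.get(chrom, ()))

    report = FilterReport()
    for call in calls:
        reasons = []
        if call.somatic_score < params.min_score:
            reasons.append("low_score")
        if not (is_primary_chrom(call.chrom_a) and is_primary_chrom(call.chrom_b)):
            reasons.append("non_primary_chrom")
        if mask is not None and (
            mask.hits_breakpoint(call.chrom_a, call.pos_a, params.adjacency_window, params.repeat_min_len)
            or mask.hits_breakpoint(call.chrom_b, call.pos_b, params.adjacency_window, params.repeat_min_len)
        ):
            reasons.append("repeat_or_gap_adjacent")
        if (call.chrom_a, call.pos_a) in blacklist or (call.chrom_b, call.pos_b) in blacklist:
            reasons.append("recurrent_breakpoint")
        if not call.is_interchromosomal and (call.span or 0) <= params.min_span:
            reasons.append("short_intra_span")
        hits = (near_step(call.chrom_a, call.pos_a), near_step(call.chrom_b, call.pos_b))
        ok = all(hits) if params.require_both_cn_steps else any(hits)
        if not ok:
            reasons.append("no_cn_step")
        report.reasons[call.sv_id] = tuple(reasons)
    return report


# ---------------------------------------------------------------------------
# junction construction


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch from a dict or pyfaidx-style genome."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    if isinstance(seq, str):
        if start < 0 or end > len(seq):
            raise ValueError(f"region {chrom}:{start}-{end} out of contig bounds")
        return seq[start:end]
    frag = seq[start:end]  # pyfaidx checks bounds itself for start<0
    out = str(frag)
    if start < 0 or len(out) < end - start:
        raise ValueError(f"region {chrom}:{start}-{end} out of contig bounds")
    return out


def build_junction_reference(
    sv: SvCall,
    genome: Union[str, Mapping[str, str]],
    flank_len: int = 150,
) -> JunctionReference:
    """Build the synthetic junction contig for one SV.

    ``genome`` may be a FASTA path or a mapping of contig name to sequence.
    The result is ``flank_len`` bases from side A, the inserted sequence,
    then ``flank_len`` bases from side B, with '-' orientations
    reverse-complemented so the junction reads left-to-right across the
    breakpoint.
    """
    if isinstance(genome, str):
        import pyfaidx

        genome = pyfaidx.Fasta(genome)
    try:
        if sv.orient_a == "+":
            flank_a = _fetch(genome, sv.chrom_a, sv.pos_a - flank_len, sv.pos_a)
        else:
            flank_a = revcomp(_fetch(genome, sv.chrom_a, sv.pos_a - 1, sv.pos_a - 1 + flank_len))
        if sv.orient_b == "+":
            flank_b = _fetch(genome, sv.chrom_b, sv.pos_b - 1, sv.pos_b - 1 + flank_len)
        else:
            flank_b = revcomp(_fetch(genome, sv.chrom_b, sv.pos_b - flank_len, sv.pos_b))
    except ValueError as exc:
        raise ValueError(
            f"{sv.sv_id}: breakpoint closer than flank_len={flank_len} to a contig end "
            f"({exc}); reduce flank_len"
        ) from exc
    sequence = (flank_a + sv.inserted_seq + flank_b).upper()
    return JunctionReference(
        sv_id=sv.sv_id,
        sequence=sequence,
        center=flank_len + len(sv.inserted_seq),
        flank_len=flank_len,
    )


def _bnd_alt(call: SvCall, ref_base: str) -> str:
    """ALT bracket string for the side-A record of a canonicalized call."""
    bracket = "[" if call.orient_b == "+" else "]"
    mate = f"{bracket}{call.chrom_b}:{call.pos_b}{bracket}"
    if call.orient_a == "+":
        return f"{ref_base}{call.inserted_seq}{mate}"
    return f"{mate}{revcomp(call.inserted_seq)}{ref_base}"


def write_sv_vcf(calls: Iterable[SvCall], genome: Mapping[str, str], path: str) -> None:
    """Write canonicalized calls as mated VCF BND record pairs."""
    flip = {"+": "-", "-": "+"}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=SOMATICSCORE,Number=1,Type=Integer,Description="Somatic score">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for call in calls:
        call = call.canonicalized()
        # the mate record is the side-A record of the flipped representation
        mate_view = SvCall(
            sv_id=call.sv_id,
            chrom_a=call.chrom_b, pos_a=call.pos_b, orient_a=flip[call.orient_b],
            chrom_b=call.chrom_a, pos_b=call.pos_a, orient_b=flip[call.orient_a],
            somatic_score=call.somatic_score,
            inserted_seq=revcomp(call.inserted_seq),
            sample_id=call.sample_id,
        )
        for view, tag, mate_tag in ((call, "0", "1"), (mate_view, "1", "0")):
            ref_base = genome[view.chrom_a][view.pos_a - 1].upper()
            info = (
                f"SVTYPE=BND;MATEID={call.sv_id}:{mate_tag};"
                f"SOMATICSCORE={call.somatic_score}"
            )
            lines.append(
                f"{view.chrom_a}\t{view.pos_a}\t{call.sv_id}:{tag}\t{ref_base}\t"
                f"{_bnd_alt(view, ref_base)}\t.\tPASS\t{info}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_junction_fasta(junctions: Iterable[JunctionReference], path: str) -> None:
    juncs = list(junctions)
    write_fasta(
        {j.sv_id: j.sequence for j in juncs},
        path,
        headers={j.sv_id: f"center={j.center}" for j in juncs},
    )


def load_junction_fasta(path: str) -> list:
    """Read a junction multi-FASTA written by :func:`write_junction_fasta`."""
    out = []
    name = None
    header = ""
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append(_junction_from_parts(name, header, chunks))
                header = line[1:]
                name = header.split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out.append(_junction_from_parts(name, header, chunks))
    return out


def _junction_from_parts(name: str, header: str, chunks: list) -> JunctionReference:
    seq = "".join(chunks)
    center = parse_center_tag(header)
    return JunctionReference(sv_id=name, sequence=seq, center=center, flank_len=min(center, len(seq) - center))
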