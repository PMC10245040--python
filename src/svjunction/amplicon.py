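"""Fuzzy classification of multiplex-PCR read pairs against an amplicon panel.

Each read pair is tested against every amplicon in the panel through four
gates, in order: primer location (forward and reverse primer each found
with at most ``primer_max_edit`` edits), product size (inter-primer target
at least ``min_product`` bp), whole-amplicon comparison (at most
``amplicon_max_edit`` edits against the expected sequence, primers
included), and pair concordance (both reads resolve to the same amplicon).
Read 1 is matched on the forward strand of the amplicon and read 2 against
its reverse complement.  Edit distances are unit-cost Levenshtein: a
mismatch, insertion or deletion each count 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .editdist import find_approx, levenshtein
from .sequtil import revcomp

__all__ = [
    "PrimerPair",
    "ReadPair",
    "AmpliconMatch",
    "MatchParams",
    "WellCountTable",
    "locate_primer",
    "classify_read_pair",
    "classify_pairs",
    "tabulate_counts",
    "control_qc",
    "load_panel",
    "read_fastq_pairs",
]

STATUSES = ("matched", "no_primer", "short_product", "amplicon_mismatch", "discordant_pair", "ambiguous")


@dataclass
class PrimerPair:
    """One panel entry: primer pair plus the expected amplicon sequence.

    ``rev_seq`` is the reverse primer as synthesized, i.e. on the opposite
    strand; ``expected_amplicon`` is the forward-strand product flanked by
    and including both primers.
    """

    amplicon_id: str
    sv_id: str
    fwd_seq: str
    rev_seq: str
    expected_amplicon: str
    is_control: bool = False

    def __post_init__(self) -> None:
        self.fwd_seq = self.fwd_seq.upper()
        self.rev_seq = self.rev_seq.upper()
        self.expected_amplicon = self.expected_amplicon.upper()
        if not self.expected_amplicon.startswith(self.fwd_seq):
            raise ValueError(f"{self.amplicon_id}: expected_amplicon must start with fwd primer")
        if not self.expected_amplicon.endswith(revcomp(self.rev_seq)):
            raise ValueError(
                f"{self.amplicon_id}: expected_amplicon must end with reverse-complement of rev primer"
            )
        if len(self.expected_amplicon) <= len(self.fwd_seq) + len(self.rev_seq):
            raise ValueError(f"{self.amplicon_id}: amplicon shorter than its primers")


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    sample_id: str = ""
    well_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.pair_id}: sequence/quality length mismatch")


@dataclass
class AmpliconMatch:
    pair_id: str
    status: str
    amplicon_id: Optional[str] = None
    edits: Tuple[int, int, int, int] = (0, 0, 0, 0)  # fwd_r1, rev_r1, amp_r1, amp_r2


@dataclass
class MatchParams:
    primer_max_edit: int = 2
    amplicon_max_edit: int = 5
    min_product: int = 25
    swap_orientation: bool = False


@dataclass
class WellCountTable:
    """Matched-pair counts per (sample, well, amplicon) with input copy numbers."""

    rows: pd.DataFrame  # sample_id, well_id, amplicon_id, matched_pair_count, input_copies

    def total_matched(self) -> int:
        return int(self.rows["matched_pair_count"].sum())


def locate_primer(
    read_seq: str, primer: str, max_edit: int = 2
) -> Optional[Tuple[int, int]]:
    """Best approximate occurrence of ``primer`` in ``read_seq``.

    Returns ``(offset, edit_distance)`` of the occurrence with the lowest
    distance (ties: leftmost), or ``None`` if no occurrence is within
    ``max_edit`` edits.
    """
    if not read_seq:
        return None
    occ = find_approx(primer.upper(), read_seq.upper(), max_edit)
    if occ is None:
        return None
    return occ.start, occ.distance


def _match_one_read(
    seq: str, fwd: str, rev_rc: str, expected: str, params: MatchParams
) -> Tuple[str, Tuple[int, int, int]]:
    """Run one read through the gates against one amplicon orientation.

    Returns (outcome, (fwd_edits, rev_edits, amplicon_edits)) where outcome
    is 'pass' or the name of the first failing gate.
    """
    seq = seq.upper()
    f_occ = find_approx(fwd, seq, params.primer_max_edit)
    if f_occ is None:
        return "no_primer", (0, 0, 0)
    tail = seq[f_occ.end :]
    r_occ = find_approx(rev_rc, tail, params.primer_max_edit)
    if r_occ is None:
        return "no_primer", (f_occ.distance, 0, 0)
    target_len = r_occ.start  # bases between the two primer occurrences
    if target_len < params.min_product:
        return "short_product", (f_occ.distance, r_occ.distance, 0)
    observed = seq[f_occ.start : f_occ.end + r_occ.end]
    amp_edits = levenshtein(observed, expected)
    if amp_edits > params.amplicon_max_edit:
        return "amplicon_mismatch", (f_occ.distance, r_occ.distance, amp_edits)
    return "pass", (f_occ.distance, r_occ.distance, amp_edits)


def classify_read_pair(
    pair: ReadPair,
    panel: Sequence[PrimerPair],
    params: Optional[MatchParams] = None,
) -> AmpliconMatch:
    """Classify one read pair against the panel.

    Both reads must independently pass all gates for the same amplicon for
    a ``matched`` call; among fully passing amplicons the lowest total edit
    distance wins, an exact tie is ``ambiguous``.  Otherwise the status is
    the most advanced failure reached by any amplicon, in the order
    no_primer < short_product < amplicon_mismatch < discordant_pair.
    """
    params = params or MatchParams()
    if not panel:
        raise ValueError("panel must be non-empty")
    seq1, seq2 = pair.seq1, pair.seq2
    if params.swap_orientation:
        seq1, seq2 = seq2, seq1
    progress = {"no_primer": 0, "short_product": 1, "amplicon_mismatch": 2, "pass": 3}
    r1_pass: dict = {}
    r2_pass: dict = {}
    furthest = 0
    for pp in panel:
        rev_rc = revcomp(pp.rev_seq)
        exp_rc = revcomp(pp.expected_amplicon)
        out1, ed1 = _match_one_read(seq1, pp.fwd_seq, rev_rc, pp.expected_amplicon, params)
        # read 2 is the opposite strand: it starts with the reverse primer
        # as synthesized and the expected sequence is the amplicon's RC
        out2, ed2 = _match_one_read(seq2, pp.rev_seq, revcomp(pp.fwd_seq), exp_rc, params)
        if out1 == "pass":
            r1_pass[pp.amplicon_id] = ed1
        if out2 == "pass":
            r2_pass[pp.amplicon_id] = ed2
        # how far this candidate got as a pair: its weaker read sets the gate
        furthest = max(furthest, min(progress[out1], progress[out2]))
    both = set(r1_pass) & set(r2_pass)
    if both:
        scored = sorted(
            (sum(r1_pass[a]) + sum(r2_pass[a]), a) for a in both
        )
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            return AmpliconMatch(pair.pair_id, "ambiguous")
        amp = scored[0][1]
        ed1, ed2 = r1_pass[amp], r2_pass[amp]
        return AmpliconMatch(
            pair.pair_id, "matched", amp, (ed1[0], ed1[1], ed1[2], ed2[2])
        )
    if r1_pass and r2_pass:  # the reads fully resolve, but to different amplicons
        return AmpliconMatch(pair.pair_id, "discordant_pair")
    names = ("no_primer", "short_product", "amplicon_mismatch")
    return AmpliconMatch(pair.pair_id, names[min(furthest, 2)])


def classify_pairs(
    pairs: Iterable[ReadPair],
    panel: Sequence[PrimerPair],
    params: Optional[MatchParams] = None,
) -> list:
    return [classify_read_pair(p, panel, params) for p in pairs]


def tabulate_counts(
    matches: Iterable[AmpliconMatch],
    layout: Mapping[str, Tuple[str, str]],
    copies: Mapping[str, float],
    panel: Optional[Sequence[PrimerPair]] = None,
) -> WellCountTable:
    """Count matched pairs per (sample, well, amplicon).

    ``layout`` maps pair_id to ``(sample_id, well_id)``; ``copies`` maps
    well_id to input amplifiable copies.  Zero rows are emitted for every
    panel amplicon in every observed well.  Matched pairs missing from the
    layout raise an error listing the offending pair ids.
    """
    counts: dict = {}
    missing = []
    wells_seen = []
    for m in matches:
        if m.status != "matched":
            continue
        if m.pair_id not in layout:
            missing.append(m.pair_id)
            continue
        sample, well = layout[m.pair_id]
        if (sample, well) not in wells_seen:
            wells_seen.append((sample, well))
        key = (sample, well, m.amplicon_id)
        counts[key] = counts.get(key, 0) + 1
    if missing:
        raise ValueError(f"matched pairs missing from layout: {missing}")
    for sample, well in dict.fromkeys(list(wells_seen) + _layout_wells(layout)):
        for pp in panel or ():
            counts.setdefault((sample, well, pp.amplicon_id), 0)
    rows = pd.DataFrame(
        [
            {
                "sample_id": s,
                "well_id": w,
                "amplicon_id": a,
                "matched_pair_count": n,
                "input_copies": copies.get(w, float("nan")),
            }
            for (s, w, a), n in sorted(counts.items())
        ],
        columns=["sample_id", "well_id", "amplicon_id", "matched_pair_count", "input_copies"],
    )
    return WellCountTable(rows)


def _layout_wells(layout: Mapping[str, Tuple[str, str]]) -> list:
    return list(dict.fromkeys(layout.values()))


def control_qc(table: WellCountTable, panel: Sequence[PrimerPair]) -> pd.DataFrame:
    """Per-well QC: a well fails if its positive-control amplicon has zero reads."""
    control_ids = {pp.amplicon_id for pp in panel if pp.is_control}
    if not control_ids:
        raise ValueError("panel has no control amplicon")
    df = table.rows
    out = []
    for (sample, well), grp in df.groupby(["sample_id", "well_id"], sort=True):
        ctrl = int(grp[grp["amplicon_id"].isin(control_ids)]["matched_pair_count"].sum())
        out.append({"sample_id": sample, "well_id": well, "control_count": ctrl, "qc_pass": ctrl > 0})
    res = pd.DataFrame(out, columns=["sample_id", "well_id", "control_count", "qc_pass"])
    if len(res) and not res["qc_pass"].any():
        warnings.warn("all wells failed control QC: run-level amplification failure")
    return res


# ---------------------------------------------------------------------------
# I/O


def load_panel(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["amplicon_id", "sv_id", "fwd_seq", "rev_seq", "expected_amplicon"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel TSV missing columns: {missing}")
    return [
        PrimerPair(
            amplicon_id=r["amplicon_id"],
            sv_id=r["sv_id"],
            fwd_seq=r["fwd_seq"],
            rev_seq=r["rev_seq"],
            expected_amplicon=r["expected_amplicon"],
            is_control=str(r.get("is_control", "")).lower() in ("1", "true", "yes"),
        )
        for _, r in df.iterrows()
    ]


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterable[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    import gzip

    def opener(p):
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with opener(r1_path) as f1, opener(r2_path) as f2:
        while True:
            h1 = f1.readline().strip()
            h2 = f2.readline().strip()
            if not h1:
                if h2:
                    raise ValueError("FASTQ files have different numbers of records")
                return
            s1, _, q1 = f1.readline().strip(), f1.readline(), f1.readline().strip()
            s2, _, q2 = f2.readline().strip(), f2.readline(), f2.readline().strip()
            pid1 = h1[1:].split()[0].removesuffix("/1")
            pid2 = h2[1:].split()[0].removesuffix("/2")
            if pid1 != pid2:
                raise ValueError(f"read pair mismatch: {pid1} vs {pid2}")
            yield ReadPair(pair_id=pid1, seq1=s1, qual1=q1, seq2=s2, qual2=q2)
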