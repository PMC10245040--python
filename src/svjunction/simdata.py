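"""Synthetic inputs with machine-readable truth for every pipeline stage.

Generators cover: toy genomes with planted SVs (all four breakpoint
orientation combinations, plus decoy calls for filter testing), multiplex
amplicon read pairs with PCR/sequencing errors in a digital well layout,
the seven-level tumor dilution design, soft-clipped WGS alignments with
UMIs, and two-component cfDNA fragment-size mixtures.  All randomness
flows through a single ``numpy`` generator, so a fixed seed reproduces
identical artifacts.

Molecule sampling uses the limiting-dilution Poisson regime: the number of
mutant molecules for a given SV in a well with ``c`` input copies at
allele fraction ``f`` is Poisson(c·f), so the probability that the
(SV, well) target is positive is ``1 − exp(−c·f)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .amplicon import PrimerPair, ReadPair
from .fragments import FragmentRecord
from .junction import AlignedRead
from .quantify import DilutionPoint
from .sv_panel import CnSegment, JunctionReference, RegionMask, SvCall
from .sequtil import revcomp

__all__ = [
    "SimConfig",
    "SimGenome",
    "AmpliconTruth",
    "WgsReadTruth",
    "DEFAULT_DILUTION_DESIGN",
    "make_genome_with_svs",
    "design_panel",
    "simulate_amplicon_run",
    "simulate_dilution_series",
    "simulate_wgs_alignments",
    "simulate_fragment_sizes",
    "write_fastq_pairs",
    "write_sam",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: the seven-level tumor dilution design: (expected AF, wells, copies per well)
DEFAULT_DILUTION_DESIGN: List[Tuple[float, int, float]] = [
    (0.10, 3, 10.0),
    (0.01, 3, 30.0),
    (0.001, 3, 300.0),
    (0.0001, 5, 900.0),
    (0.00003, 5, 900.0),
    (0.00001, 5, 900.0),
    (0.000004, 5, 900.0),
]


@dataclass
class SimConfig:
    seed: int = 0
    read_len: int = 150
    per_base_error: float = 0.0
    indel_error: float = 0.0
    reads_per_molecule: float = 3.0  # mean of a geometric (>= 1) count
    umi_len: int = 8
    control_reads_mean: float = 50.0  # control-amplicon reads per well
    min_clip: int = 10

    def __post_init__(self) -> None:
        for p in (self.per_base_error, self.indel_error):
            if not 0 <= p <= 1:
                raise ValueError("error probabilities must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class JunctionTruth:
    sv_id: str
    sequence: str  # planted junction: flank + insertion + flank as in the tumor genome
    center: int
    tumor_contig: str
    tumor_offset: int  # index of the first side-B base in the tumor contig


@dataclass
class SimGenome:
    reference: dict  # contig -> sequence
    tumor: dict
    calls: List[SvCall]  # high-confidence planted calls
    decoys: List[SvCall]
    junction_truth: List[JunctionTruth]
    cn_segments: List[CnSegment]
    mask: RegionMask


@dataclass
class AmpliconTruth:
    pair_id: str
    well_id: str
    amplicon_id: str
    molecule_id: str
    errors_r1: int
    errors_r2: int
    expected_status: str


@dataclass
class WgsReadTruth:
    read_name: str
    sv_id: str  # '' for wild-type background reads
    umi: str
    molecule_id: str
    n_errors: int
    expected_detectable: bool


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def _mutate(
    seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float = 0.0
) -> Tuple[str, int]:
    """Apply uniform substitution (and optional 1 bp indel) errors.

    Returns the mutated sequence and the number of planted errors.
    """
    if sub_rate <= 0 and indel_rate <= 0:
        return seq, 0
    out = list(seq)
    n_err = 0
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(out)) < sub_rate)
        for i in hits:
            alts = [b for b in "ACGT" if b != out[i]]
            out[i] = alts[rng.integers(0, 3)]
        n_err += len(hits)
    if indel_rate > 0:
        hits = np.flatnonzero(rng.random(len(out)) < indel_rate)
        for i in sorted(hits, reverse=True):
            if rng.random() < 0.5 and len(out) > 1:
                del out[i]
            else:
                out.insert(i, "ACGT"[rng.integers(0, 4)])
            n_err += 1
    return "".join(out), n_err


def _plant_errors(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Substitute exactly the given positions with a different base."""
    out = list(seq)
    for i in positions:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return "".join(out)


def _geometric_count(rng: np.random.Generator, mean: float) -> int:
    """Positive read-per-molecule count with the given mean (geometric)."""
    if mean <= 1:
        return 1
    return int(rng.geometric(1.0 / mean))


# ---------------------------------------------------------------------------
# genomes with planted SVs


def _junction_kmers(seq: str, center: int, k: int = 25) -> List[str]:
    """All k-mers spanning the junction point."""
    lo = max(0, center - k + 1)
    hi = min(len(seq) - k, center - 1)
    return [seq[i : i + k] for i in range(lo, hi + 1)]


def make_genome_with_svs(
    n_contigs: int = 2,
    contig_len: int = 300_000,
    n_svs: int = 3,
    sv_types: Optional[Sequence[str]] = None,
    flank_len: int = 150,
    insert_prob: float = 0.3,
    with_decoys: bool = True,
    seed: int = 0,
) -> SimGenome:
    """Build a toy reference, plant SVs by cut-and-paste, and emit call truth.

    SV types cycle through translocations, large (>100 kb) deletions and
    inversion-type junctions, exercising all four orientation pairs.
    Junction-spanning 25-mers are verified absent from the reference (both
    strands) by construction, re-drawing the genome if necessary.  Decoy
    calls (low score, repeat-adjacent, recurrent across two samples, short
    span) are emitted alongside matching mask/CN-segment fixtures.
    """
    if contig_len < 2 * flank_len + 1000:
        raise ValueError("contigs too short for the requested flanks")
    if sv_types is None:
        sv_types = ["translocation", "deletion", "inversion", "inversion_rc"]
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        genome = {f"chr{i + 1}": _random_seq(rng, contig_len) for i in range(n_contigs)}
        result = _plant_svs(genome, n_svs, sv_types, flank_len, insert_prob, contig_len, rng)
        if result is not None:
            calls, truths, tumor = result
            break
    else:  # pragma: no cover - vanishingly unlikely for random sequence
        raise RuntimeError("could not generate a genome with unique junction k-mers")

    cn_segments, mask, decoys = [], RegionMask([]), []
    # CN steps at (or near) the true breakpoints so the planted calls pass
    step_positions = sorted(
        {(c.chrom_a, c.pos_a) for c in calls} | {(c.chrom_b, c.pos_b) for c in calls}
    )
    by_chrom: dict = {}
    for chrom, pos in step_positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in genome:
        bounds = [0] + sorted(by_chrom.get(chrom, [])) + [contig_len]
        cn = 2.0
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            cn_segments.append(CnSegment(chrom, lo, hi, cn))
            cn = 4.0 if cn == 2.0 else 2.0
    if with_decoys:
        decoys, mask = _make_decoys(genome, contig_len, rng, calls)
    return SimGenome(
        reference=genome,
        tumor=tumor,
        calls=calls,
        decoys=decoys,
        junction_truth=truths,
        cn_segments=cn_segments,
        mask=mask,
    )


def _plant_svs(genome, n_svs, sv_types, flank_len, insert_prob, contig_len, rng):
    contigs = list(genome)
    calls: List[SvCall] = []
    truths: List[JunctionTruth] = []
    tumor: dict = {}
    occupied: set = set()
    for i in range(n_svs):
        sv_type = sv_types[i % len(sv_types)]
        sv_id = f"SV{i + 1:03d}"
        margin = flank_len + 500
        ins = _random_seq(rng, int(rng.integers(3, 9))) if rng.random() < insert_prob else ""
        if sv_type == "translocation":
            ca, cb = rng.choice(contigs, size=2, replace=len(contigs) < 2)
            pos_a = int(rng.integers(margin, contig_len - margin))
            pos_b = int(rng.integers(margin, contig_len - margin))
            orient_a, orient_b = "+", "+"
            if len(contigs) >= 2 and ca == cb:
                cb = contigs[(contigs.index(ca) + 1) % len(contigs)]
        elif sv_type == "deletion":
            ca = cb = contigs[int(rng.integers(0, len(contigs)))]
            span = int(rng.integers(110_000, min(200_000, contig_len - 2 * margin)))
            pos_a = int(rng.integers(margin, contig_len - margin - span))
            pos_b = pos_a + span
            orient_a, orient_b = "+", "+"
        elif sv_type == "inversion":
            ca = cb = contigs[int(rng.integers(0, len(contigs)))]
            span = int(rng.integers(110_000, min(200_000, contig_len - 2 * margin)))
            pos_a = int(rng.integers(margin, contig_len - margin - span))
            pos_b = pos_a + span
            orient_a, orient_b = "+", "-"
        else:  # inversion_rc: the ('-','+') junction of an inversion
            ca = cb = contigs[int(rng.integers(0, len(contigs)))]
            span = int(rng.integers(110_000, min(200_000, contig_len - 2 * margin)))
            pos_a = int(rng.integers(margin, contig_len - margin - span))
            pos_b = pos_a + span
            orient_a, orient_b = "-", "+"
        key = (ca, pos_a // 1000, cb, pos_b // 1000)
        if key in occupied:
            continue
        occupied.add(key)
        call = SvCall(
            sv_id=sv_id,
            chrom_a=ca,
            pos_a=pos_a,
            orient_a=orient_a,
            chrom_b=cb,
            pos_b=pos_b,
            orient_b=orient_b,
            somatic_score=int(rng.integers(35, 90)),
            inserted_seq=ins,
            sample_id="case01",
        ).canonicalized()
        seq_a = genome[call.chrom_a]
        seq_b = genome[call.chrom_b]
        # cut-and-paste tumor contig
        if call.orient_a == "+":
            left = seq_a[: call.pos_a]
        else:
            left = revcomp(seq_a[call.pos_a - 1 :])
        if call.orient_b == "+":
            right = seq_b[call.pos_b - 1 :]
        else:
            right = revcomp(seq_b[: call.pos_b])
        tumor_contig = left + call.inserted_seq + right
        offset = len(left) + len(call.inserted_seq)
        junction_seq = tumor_contig[offset - flank_len - len(call.inserted_seq) : offset + flank_len]
        truth = JunctionTruth(
            sv_id=sv_id,
            sequence=junction_seq.upper(),
            center=flank_len + len(call.inserted_seq),
            tumor_contig=f"tumor_{sv_id}",
            tumor_offset=offset,
        )
        # specificity by construction: junction 25-mers absent from reference
        for kmer in _junction_kmers(truth.sequence, truth.center):
            for contig in genome.values():
                if kmer in contig or revcomp(kmer) in contig:
                    return None
        calls.append(call)
        truths.append(truth)
        tumor[truth.tumor_contig] = tumor_contig
    return calls, truths, tumor


def _make_decoys(genome, contig_len, rng, calls=()):
    contigs = list(genome)
    c0 = contigs[0]
    true_bps = sorted(
        p for c in calls for ch, p in ((c.chrom_a, c.pos_a), (c.chrom_b, c.pos_b)) if ch == c0
    )

    def free_pos(start: int, clearance: int = 3_000) -> int:
        # walk forward until the position is clear of every true breakpoint,
        # so decoy recurrent clusters never blacklist a planted call
        pos = start
        while any(abs(pos - bp) < clearance for bp in true_bps):
            pos += clearance
        return pos

    mask_start = free_pos(contig_len // 2, 15_000)
    mask = RegionMask(
        [
            (c0, mask_start, mask_start + 500, "simple_repeat"),
            (c0, mask_start + 10_000, mask_start + 10_050, "gap"),
        ]
    )
    mk = lambda i, **kw: SvCall(sv_id=f"DEC{i:03d}", **kw).canonicalized()
    decoys = [
        # low somatic score
        mk(1, chrom_a=c0, pos_a=5_000, orient_a="+", chrom_b=c0, pos_b=160_000,
           orient_b="+", somatic_score=12, sample_id="case01"),
        # breakpoint inside the long simple repeat
        mk(2, chrom_a=c0, pos_a=mask_start + 100, orient_a="+", chrom_b=c0,
           pos_b=min(mask_start + 150_000, contig_len - 1_000), orient_b="+",
           somatic_score=60, sample_id="case01"),
        # short intra-chromosomal span
        mk(3, chrom_a=c0, pos_a=20_000, orient_a="+", chrom_b=c0, pos_b=60_000,
           orient_b="+", somatic_score=60, sample_id="case01"),
        # recurrent pair: same breakpoints in two different samples
        mk(4, chrom_a=c0, pos_a=free_pos(80_000), orient_a="+", chrom_b=c0,
           pos_b=free_pos(230_000), orient_b="+", somatic_score=60, sample_id="case01"),
        mk(5, chrom_a=c0, pos_a=free_pos(80_000) + 50, orient_a="+", chrom_b=c0,
           pos_b=free_pos(230_000) + 80, orient_b="+", somatic_score=60, sample_id="case02"),
    ]
    return decoys, mask


# ---------------------------------------------------------------------------
# amplicon panel + reads


def design_panel(
    junctions: Sequence[JunctionReference],
    primer_len: int = 25,
    amplicon_len: int = 100,
    control_id: str = "RPP30_97bp",
    control_len: int = 97,
    seed: int = 7,
) -> List[PrimerPair]:
    """Derive a primer panel from junction references, plus a positive control.

    Each amplicon is a window of the junction sequence centred on the
    breakpoint, so its breakpoint-spanning k-mers are absent from the
    unmodified reference by construction.
    """
    half = amplicon_len // 2
    panel = []
    for j in junctions:
        if j.center < half or len(j.sequence) - j.center < half:
            raise ValueError(f"{j.sv_id}: junction too short for a {amplicon_len} bp amplicon")
        amp = j.sequence[j.center - half : j.center + half]
        panel.append(
            PrimerPair(
                amplicon_id=f"amp_{j.sv_id}",
                sv_id=j.sv_id,
                fwd_seq=amp[:primer_len],
                rev_seq=revcomp(amp[-primer_len:]),
                expected_amplicon=amp,
            )
        )
    rng = np.random.default_rng(seed)
    ctrl = _random_seq(rng, control_len)
    panel.append(
        PrimerPair(
            amplicon_id=control_id,
            sv_id=control_id,
            fwd_seq=ctrl[:primer_len],
            rev_seq=revcomp(ctrl[-primer_len:]),
            expected_amplicon=ctrl,
            is_control=True,
        )
    )
    return panel


def _amplicon_read_pair(
    amp: str, read_len: int, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> Tuple[str, str, int, int]:
    """Read 1 on the forward strand, read 2 on the reverse; random tail fill."""
    r1, e1 = _mutate(amp, rng, sub_rate, indel_rate)
    r2, e2 = _mutate(revcomp(amp), rng, sub_rate, indel_rate)
    if len(r1) < read_len:
        r1 += _random_seq(rng, read_len - len(r1))
    if len(r2) < read_len:
        r2 += _random_seq(rng, read_len - len(r2))
    return r1[:read_len], r2[:read_len], e1, e2


def simulate_amplicon_run(
    panel: Sequence[PrimerPair],
    af: float,
    wells: int,
    copies_per_well: float,
    config: Optional[SimConfig] = None,
    sample_id: str = "S1",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[ReadPair], dict, dict, List[AmpliconTruth]]:
    """Digital multiplex run: Poisson molecules per (SV, well), reads per molecule.

    Returns (read pairs, layout pair_id -> (sample, well), copies well ->
    input copies, truth records).  Control-amplicon reads are emitted in
    every well.
    """
    config = config or SimConfig()
    rng = rng if rng is not None else config.rng()
    pairs: List[ReadPair] = []
    truth: List[AmpliconTruth] = []
    layout: dict = {}
    copies: dict = {}
    sv_amps = [p for p in panel if not p.is_control]
    controls = [p for p in panel if p.is_control]
    serial = 0
    for w in range(1, wells + 1):
        well_id = f"W{w:02d}"
        copies[well_id] = copies_per_well
        for pp in sv_amps:
            n_mol = int(rng.poisson(copies_per_well * af)) if af > 0 else 0
            for mol in range(n_mol):
                molecule_id = f"{pp.amplicon_id}:{well_id}:m{mol}"
                for _ in range(_geometric_count(rng, config.reads_per_molecule)):
                    serial += 1
                    pair_id = f"rp{serial:07d}"
                    r1, r2, e1, e2 = _amplicon_read_pair(
                        pp.expected_amplicon, config.read_len, rng,
                        config.per_base_error, config.indel_error,
                    )
                    q = "I" * config.read_len
                    pairs.append(ReadPair(pair_id, r1, q, r2, q, sample_id, well_id))
                    layout[pair_id] = (sample_id, well_id)
                    truth.append(
                        AmpliconTruth(
                            pair_id, well_id, pp.amplicon_id, molecule_id, e1, e2,
                            "matched" if max(e1, e2) <= 2 else "uncertain",
                        )
                    )
        for pp in controls:
            n_reads = int(rng.poisson(config.control_reads_mean))
            for k in range(n_reads):
                serial += 1
                pair_id = f"rp{serial:07d}"
                r1, r2, e1, e2 = _amplicon_read_pair(
                    pp.expected_amplicon, config.read_len, rng,
                    config.per_base_error, config.indel_error,
                )
                q = "I" * config.read_len
                pairs.append(ReadPair(pair_id, r1, q, r2, q, sample_id, well_id))
                layout[pair_id] = (sample_id, well_id)
                truth.append(
                    AmpliconTruth(
                        pair_id, well_id, pp.amplicon_id, f"ctrl:{well_id}:{k}", e1, e2,
                        "matched" if max(e1, e2) <= 2 else "uncertain",
                    )
                )
    return pairs, layout, copies, truth


# ---------------------------------------------------------------------------
# dilution series


def simulate_dilution_series(
    n_svs: int,
    design: Optional[Sequence[Tuple[float, int, float]]] = None,
    expectation: bool = False,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[DilutionPoint]:
    """Draw (or compute) positive (SV, well) events through a dilution design.

    ``design`` rows are (expected AF, wells, copies per well); the default
    is the seven-level design from 10% down to 0.0004% AF.  In
    ``expectation`` mode the draws are replaced by their real-valued
    expectation ``wells × n_svs × (1 − exp(−copies × af))`` for
    deterministic estimator checks.  Observed AF uses the Poisson
    estimator (0 when no event was positive).
    """
    design = design if design is not None else DEFAULT_DILUTION_DESIGN
    rng = rng if rng is not None else np.random.default_rng(seed)
    points = []
    for af, wells, cpw in design:
        total = wells * n_svs
        p_positive = 1.0 - math.exp(-cpw * af)
        if expectation:
            events: float = total * p_positive
        else:
            events = int(rng.binomial(total, p_positive))
        if 0 < events < total:
            observed = -(1.0 / cpw) * math.log(1.0 - events / total)
        elif events == 0:
            observed = 0.0
        else:  # saturation: fall back to just under full occupancy
            observed = -(1.0 / cpw) * math.log(1.0 / total)
        points.append(
            DilutionPoint(
                expected_af=af,
                wells=wells,
                copies_per_well=cpw,
                positive_events=events,
                observed_af=observed,
            )
        )
    return points


# ---------------------------------------------------------------------------
# WGS alignments


def simulate_wgs_alignments(
    junctions: Sequence[JunctionReference],
    genome: Mapping[str, str],
    af: float,
    depth: float,
    calls: Optional[Sequence[SvCall]] = None,
    config: Optional[SimConfig] = None,
    n_background: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[AlignedRead], List[WgsReadTruth]]:
    """Soft-clipped junction reads plus wild-type background alignments.

    Junction molecules per SV are Poisson(2 × depth × af); each molecule
    emits geometric-count PCR duplicates sharing a UMI and start position.
    Junction reads are aligned to the side-A locus with the junction-side
    bases soft-clipped; background reads are sampled from the reference
    with full-match CIGARs.  Truth records whether each junction read is
    expected to be recoverable under the default edit budgets.
    """
    config = config or SimConfig()
    rng = rng if rng is not None else config.rng()
    read_len = config.read_len
    budget = math.floor(0.025 * read_len)
    reads: List[AlignedRead] = []
    truth: List[WgsReadTruth] = []
    call_by_id = {c.sv_id: c for c in (calls or [])}
    serial = 0
    for j in junctions:
        n_mol = int(rng.poisson(2.0 * depth * af)) if af > 0 else 0
        for mol in range(n_mol):
            umi = _random_seq(rng, config.umi_len)
            lo = max(0, j.center - read_len + config.min_clip + 10)
            hi = min(j.center - 20, len(j.sequence) - read_len)
            start = int(rng.integers(lo, max(lo + 1, hi)))
            base_read = j.sequence[start : start + read_len]
            aligned_len = j.center - start
            molecule_id = f"{j.sv_id}:m{mol}"
            call = call_by_id.get(j.sv_id)
            ref_name = call.chrom_a if call else next(iter(genome))
            pos = max(1, (call.pos_a - aligned_len + 1) if call else 1)
            for _dup in range(_geometric_count(rng, config.reads_per_molecule)):
                serial += 1
                seq, n_err = _mutate(base_read, rng, config.per_base_error, config.indel_error)
                name = f"wgs{serial:07d}"
                clip = len(seq) - aligned_len
                cigar = [("M", aligned_len), ("S", clip)] if clip > 0 else [("M", len(seq))]
                reads.append(
                    AlignedRead(
                        name=name, ref_name=ref_name, pos=pos, cigar=cigar,
                        seq=seq, umi=umi, mapq=60,
                    )
                )
                truth.append(
                    WgsReadTruth(
                        read_name=name, sv_id=j.sv_id, umi=umi, molecule_id=molecule_id,
                        n_errors=n_err,
                        expected_detectable=(config.indel_error == 0 and n_err <= budget),
                    )
                )
    total_len = sum(len(s) for s in genome.values())
    n_bg = n_background if n_background is not None else int(depth * total_len / read_len)
    contigs = list(genome)
    for _ in range(n_bg):
        serial += 1
        contig = contigs[int(rng.integers(0, len(contigs)))]
        seq_full = genome[contig]
        start = int(rng.integers(0, max(1, len(seq_full) - read_len)))
        seq, n_err = _mutate(seq_full[start : start + read_len], rng, config.per_base_error)
        name = f"wgs{serial:07d}"
        reads.append(
            AlignedRead(
                name=name, ref_name=contig, pos=start + 1,
                cigar=[("M", len(seq))], seq=seq,
                umi=_random_seq(rng, config.umi_len), mapq=60,
            )
        )
        truth.append(WgsReadTruth(name, "", "", f"bg:{name}", n_err, False))
    return reads, truth


# ---------------------------------------------------------------------------
# fragment sizes


def simulate_fragment_sizes(
    n: int,
    tumor_fraction: float,
    tumor_mode: float = 145.0,
    normal_mode: float = 166.0,
    sd: float = 15.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[FragmentRecord]:
    """Two-component discretized normal length mixture, truncated at >= 50 bp."""
    if sd <= 0 or tumor_mode <= 0 or normal_mode <= 0:
        raise ValueError("modes and sd must be positive")
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    is_tumor = rng.random(n) < tumor_fraction
    means = np.where(is_tumor, tumor_mode, normal_mode)
    lengths = np.maximum(50, np.rint(rng.normal(means, sd))).astype(int)
    return [
        FragmentRecord(
            name=f"frag{i:07d}", chrom="chr1", start=0, end=int(l), is_tumor=bool(t)
        )
        for i, (l, t) in enumerate(zip(lengths, is_tumor))
    ]


# ---------------------------------------------------------------------------
# writers


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str, r2_path: str) -> None:
    import gzip

    def opener(p):
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_sam(
    reads: Iterable[AlignedRead], ref_lengths: Mapping[str, int], path: str
) -> None:
    """Minimal SAM with RX-tagged UMIs, readable back via ``junction.read_sam``."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            cigar = "".join(f"{l}{op}" for op, l in r.cigar) if r.cigar else "*"
            flag = 4 if r.is_unmapped else (16 if r.is_reverse else 0)
            fields = [
                r.name, str(flag), r.ref_name or "*", str(max(r.pos, 0)),
                str(r.mapq), cigar, "*", "0", "0", r.seq, "I" * len(r.seq),
            ]
            if r.umi:
                fields.append(f"RX:Z:{r.umi}")
            fh.write("\t".join(fields) + "\n")
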