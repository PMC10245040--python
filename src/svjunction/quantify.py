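"""Detection calling, allele-fraction estimation and dilution-series statistics.

The multiplex assay is digital: each (SV, well) pair is a binary target
that is positive when its read count exceeds a control-derived threshold.
Allele fractions follow either the linear estimator

    AF = positive events / (total input copies × number of SVs targeted)

or, for high allele fractions where wells saturate, the Poisson-corrected
estimator

    AF = -(1 / copies per well) × ln(1 − events / (wells × number of SVs)).

The theoretical limit of detection of the digital assay is
``1 / (copies × number of SVs)`` — the AF at which one positive event is
expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .amplicon import PrimerPair, WellCountTable
from .junction import SvReadCounts, wgs_af

__all__ = [
    "ControlSummary",
    "DetectionResult",
    "DilutionPoint",
    "RegressionFit",
    "derive_threshold",
    "call_multiplex",
    "af_linear",
    "af_poisson",
    "theoretical_lod",
    "required_svs",
    "required_copies",
    "call_capture",
    "fit_loglog",
    "correlate_assays",
]


@dataclass
class ControlSummary:
    """Background signal summarized over all negative/unrelated controls."""

    max_target_reads: int = 0
    max_positive_svs: int = 0

    def __post_init__(self) -> None:
        if self.max_target_reads < 0 or self.max_positive_svs < 0:
            raise ValueError("control summaries must be non-negative")


@dataclass
class DetectionResult:
    sample_id: str
    assay: str  # multiplex | capture | wgs
    detected: bool
    positive_events: int
    af: Optional[float]
    lod: Optional[float]
    threshold_used: int


@dataclass
class DilutionPoint:
    expected_af: float
    wells: int
    copies_per_well: float
    positive_events: float
    observed_af: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def derive_threshold(controls: Optional[ControlSummary]) -> int:
    """Detection threshold: 2 × the highest control read count (strict >)."""
    if controls is None:
        raise ValueError("threshold undefined without control samples")
    return 2 * controls.max_target_reads


def af_linear(events: float, total_copies: float, n_svs: int) -> float:
    """Linear AF estimator: events / (total input copies × SVs targeted)."""
    if total_copies <= 0:
        raise ValueError("total_copies must be positive")
    if n_svs < 1:
        raise ValueError("n_svs must be >= 1")
    if events < 0:
        raise ValueError("events must be non-negative")
    if events > total_copies * n_svs:
        raise ValueError(
            f"{events} positive events exceed the {total_copies * n_svs:.0f} possible targets"
        )
    return events / (total_copies * n_svs)


def af_poisson(events: float, copies_per_well: float, wells: int, n_svs: int) -> float:
    """Poisson-corrected AF: -(1/copies per well) × ln(1 − events/(wells × SVs))."""
    if copies_per_well <= 0:
        raise ValueError("copies_per_well must be positive")
    total = wells * n_svs
    if not 0 <= events < total:
        if events == total:
            raise ValueError("all targets positive: assay saturated, dilute the sample")
        raise ValueError("events must satisfy 0 <= events < wells * n_svs")
    return -(1.0 / copies_per_well) * math.log(1.0 - events / total)


def theoretical_lod(copies: float, n_svs: int) -> float:
    """Theoretical limit of detection: 1 / (input copies × SVs targeted)."""
    if copies <= 0 or n_svs < 1:
        raise ValueError("copies and n_svs must be positive")
    return af_linear(1, copies, n_svs)


def _ceil_tolerant(x: float) -> int:
    # guard against float noise pushing an exact integer over the ceiling
    return math.ceil(x - 1e-9 * max(1.0, abs(x)))


def required_svs(af: float, copies: float) -> int:
    """Smallest SV panel size with >= 1 expected positive event at this AF."""
    if af <= 0:
        raise ValueError("af must be positive")
    if af >= 1:
        return 1
    return _ceil_tolerant(1.0 / (af * copies))


def required_copies(af: float, n_svs: int) -> int:
    """Smallest copy input with >= 1 expected positive event at this AF."""
    if af <= 0:
        raise ValueError("af must be positive")
    if af >= 1:
        return 1
    return _ceil_tolerant(1.0 / (af * n_svs))


def call_multiplex(
    table: WellCountTable,
    n_svs: int,
    threshold: int,
    panel: Optional[Sequence[PrimerPair]] = None,
    sample_id: str = "",
) -> DetectionResult:
    """Detection call for one multiplex-PCR sample.

    Positive events are (SV, well) pairs whose matched-read count strictly
    exceeds the threshold; control amplicons are excluded.  The AF uses the
    linear estimator over the summed input copies, and the LOD is the
    theoretical one for that input.
    """
    df = table.rows
    if panel is not None:
        control_ids = {pp.amplicon_id for pp in panel if pp.is_control}
        df = df[~df["amplicon_id"].isin(control_ids)]
    if df["input_copies"].isna().any():
        raise ValueError("input_copies missing for one or more wells")
    positive = int((df["matched_pair_count"] > threshold).sum())
    total_copies = float(
        df.drop_duplicates(["sample_id", "well_id"])["input_copies"].sum()
    )
    return DetectionResult(
        sample_id=sample_id,
        assay="multiplex",
        detected=positive >= 1,
        positive_events=positive,
        af=af_linear(positive, total_copies, n_svs),
        lod=theoretical_lod(total_copies, n_svs),
        threshold_used=threshold,
    )


def call_capture(
    counts: SvReadCounts,
    controls: Optional[ControlSummary],
    mean_depth: float,
    n_svs: int,
    sample_id: str = "",
) -> DetectionResult:
    """Detection call for the hybrid-capture assay.

    Detected iff (a) any SV has more than 2 × the highest control read
    count, or (b) the number of SVs with any reads is more than 2 × the
    highest such number in controls.  The AF includes ALL positive reads,
    using the WGS estimator against the on-target mean depth.
    """
    if controls is None:
        raise ValueError("capture detection requires control summaries")
    read_threshold = 2 * controls.max_target_reads
    sv_threshold = 2 * controls.max_positive_svs
    read_counts = [counts.read_count(s) for s in counts.per_sv]
    rule_a = any(c > read_threshold for c in read_counts)
    positive_svs = sum(1 for c in read_counts if c >= 1)
    rule_b = positive_svs > sv_threshold
    total_reads = counts.total_reads
    return DetectionResult(
        sample_id=sample_id,
        assay="capture",
        detected=bool(rule_a or rule_b),
        positive_events=positive_svs,
        af=wgs_af(total_reads, mean_depth, n_svs) if mean_depth > 0 else None,
        lod=None,
        threshold_used=read_threshold,
    )


def fit_loglog(points: Iterable[DilutionPoint]) -> RegressionFit:
    """OLS of log10(observed AF) on log10(expected AF) over detected dilutions.

    Points with a non-positive observed AF are excluded (log undefined); at
    least 3 usable points are required.  The slope p-value is the Wald
    t-test from the standard linear-regression machinery.
    """
    usable = [p for p in points if p.observed_af > 0 and p.expected_af > 0]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 dilution points with positive observed AF, got {len(usable)}")
    x = np.log10([p.expected_af for p in usable])
    y = np.log10([p.observed_af for p in usable])
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_slope=float(res.pvalue),
    )


def correlate_assays(
    af_a: Sequence[Optional[float]], af_b: Sequence[Optional[float]]
) -> Tuple[float, float, float]:
    """Pearson r (on log10 AFs) and Spearman rho between two assays' AFs.

    Pairs where either AF is undefined or non-positive are dropped; at
    least 3 mutually detected pairs are required.  Returns
    ``(pearson_r, pearson_p, spearman_rho)``.
    """
    if len(af_a) != len(af_b):
        raise ValueError("AF vectors must be paired (equal length)")
    pairs = [
        (a, b)
        for a, b in zip(af_a, af_b)
        if a is not None and b is not None and a > 0 and b > 0
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 mutually detected AF pairs, got {len(pairs)}")
    xa = np.log10([p[0] for p in pairs])
    xb = np.log10([p[1] for p in pairs])
    r, p = stats.pearsonr(xa, xb)
    rho, _ = stats.spearmanr(xa, xb)
    return float(r), float(p), float(rho)
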