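"""In-silico cfDNA fragment-size selection and size summaries.

Tumor-derived cell-free DNA fragments are on average shorter than those
from normal cells, so restricting analysis to 90-150 bp fragments
(inclusive bounds) enriches tumor signal before copy-number analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List

__all__ = ["FragmentRecord", "size_select", "size_histogram", "filter_bam_by_size"]


@dataclass
class FragmentRecord:
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    is_tumor: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"{self.name}: fragment length must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


def size_select(
    fragments: Iterable[FragmentRecord], lo: int = 90, hi: int = 150
) -> List[FragmentRecord]:
    """Fragments with length in ``[lo, hi]`` (inclusive); order preserved."""
    if lo > hi:
        raise ValueError(f"invalid size window: lo={lo} > hi={hi}")
    return [f for f in fragments if lo <= f.length <= hi]


def size_histogram(fragments: Iterable[FragmentRecord]) -> Counter:
    """Fragment counts per length (1 bp bins); counts sum to the input size."""
    return Counter(f.length for f in fragments)


def filter_bam_by_size(in_path: str, out_path: str, lo: int = 90, hi: int = 150) -> dict:
    """Pass through alignment records whose absolute template length is in [lo, hi].

    Records with zero/undefined template length are dropped with a counted
    warning.  Returns summary counts.
    """
    import pysam

    if lo > hi:
        raise ValueError(f"invalid size window: lo={lo} > hi={hi}")
    read_mode = "rb" if in_path.endswith(".bam") else "r"
    write_mode = "wb" if out_path.endswith(".bam") else "w"
    n_in = n_out = n_undefined = 0
    with pysam.AlignmentFile(in_path, read_mode, check_sq=False) as src:
        with pysam.AlignmentFile(out_path, write_mode, template=src) as dst:
            for rec in src:
                n_in += 1
                tlen = abs(rec.template_length)
                if tlen == 0:
                    n_undefined += 1
                    continue
                if lo <= tlen <= hi:
                    dst.write(rec)
                    n_out += 1
    if n_undefined:
        warnings.warn(f"dropped {n_undefined} records with zero/undefined template length")
    return {"records_in": n_in, "records_out": n_out, "undefined_tlen": n_undefined}
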