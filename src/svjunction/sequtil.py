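"""Small sequence/coordinate helpers shared across modules."""

from __future__ import annotations

import re
from typing import Union

_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMSWrykmsw", "TGCAtgcaNnYRMKSWyrmksw")

PRIMARY_CHROMS = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y"]
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def norm_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix for comparisons; name itself is kept elsewhere."""
    return name[3:] if name.lower().startswith("chr") else name


def is_primary_chrom(name: str) -> bool:
    """Autosomes plus X and Y; chrM/unplaced contigs are excluded."""
    return norm_chrom(name).upper() in PRIMARY_CHROMS


def chrom_sort_key(name: str) -> tuple:
    """Natural ordering: 1..22, X, Y, M, then other contigs lexicographically."""
    base = norm_chrom(name)
    if base.isdigit():
        return (0, int(base), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if base.upper() in order:
        return (0, order[base.upper()], "")
    return (1, 0, base)


def parse_fasta(path_or_handle: Union[str, "object"]) -> dict:
    """Read a (small) FASTA file into an ordered ``{name: sequence}`` dict."""
    seqs: dict = {}
    name = None
    chunks: list = []
    close = False
    if isinstance(path_or_handle, str):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks)
    finally:
        if close:
            handle.close()
    return seqs


def write_fasta(seqs: dict, path: str, width: int = 70, headers: dict | None = None) -> None:
    """Write ``{name: sequence}`` to FASTA; ``headers`` adds per-record suffixes."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            extra = f" {headers[name]}" if headers and name in headers else ""
            fh.write(f">{name}{extra}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_FASTA_CENTER_RE = re.compile(r"center=(\d+)")


def parse_center_tag(header: str) -> int:
    """Extract the ``center=<int>`` tag from a junction-FASTA header line."""
    m = _FASTA_CENTER_RE.search(header)
    if m is None:
        raise ValueError(f"no center= tag in FASTA header: {header!r}")
    return int(m.group(1))
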