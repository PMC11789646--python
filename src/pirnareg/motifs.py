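"""Exact IUPAC consensus-motif scanning on both strands.

The scanner matches short ambiguity-coded consensus strings (e.g. the
Ovo/OVOL2 binding site CCGTTA, or its degenerate form CNGTTA) exactly:
every position of the window must fall in the expansion of the
corresponding IUPAC code.  An 'N' in the *genome* never matches
anything, including pattern N, so assembly gaps cannot inflate counts.
Overlapping occurrences are all reported; a hit is attributed to an
interval only when the full match lies inside it.

Position-weight-matrix scoring is deliberately not implemented: the
motifs handled here are short consensus strings and the downstream
enrichment statistics are count-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHit",
    "iupac_match",
    "revcomp",
    "scan_sequence",
    "scan_genome",
    "count_in_intervals",
    "motif_density",
    "read_fasta",
    "write_fasta",
]

# IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` lies in the expansion of IUPAC ``code``.

    A genome 'N' matches nothing — not even pattern N.
    """
    code = code.upper()
    if code not in IUPAC:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return base.upper() in IUPAC[code]


def revcomp(seq: str) -> str:
    """Reverse complement of a concrete A/C/G/T/N sequence."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return up.translate(_BASE_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC consensus pattern, case-insensitive."""

    symbols: str

    def __post_init__(self) -> None:
        sym = self.symbols.upper()
        if not sym:
            raise ValueError("empty motif pattern")
        bad = set(sym) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")
        object.__setattr__(self, "symbols", sym)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(self.symbols.translate(_COMPLEMENT)[::-1])

    def _regex(self) -> re.Pattern:
        # Lookahead so overlapping occurrences are all found.  Expansions
        # contain concrete bases only, so genome 'N' can never match.
        body = "".join(
            "[" + "".join(sorted(IUPAC[c])) + "]" for c in self.symbols
        )
        return re.compile(f"(?=({body}))")

    def matches(self, window: str) -> bool:
        """Exact per-position IUPAC match of a window of equal length."""
        if len(window) != len(self):
            return False
        w = window.upper()
        return all(b in IUPAC[c] for c, b in zip(self.symbols, w))


@dataclass(frozen=True)
class MotifHit:
    """A stranded occurrence of a pattern, in plus-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    matched: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("hit strand must be '+' or '-'")

    def to_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, strand=self.strand)


def scan_sequence(
    seq: str, pattern: MotifPattern, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All pattern occurrences in ``seq``; offsets are plus-strand.

    Plus-strand hits are offsets where the window matches ``pattern``;
    minus-strand hits are offsets where the window matches the
    reverse-complemented pattern.  Sorted by ``(offset, strand)``.
    """
    s = seq.upper()
    hits = [(m.start(), "+") for m in pattern._regex().finditer(s)]
    if both_strands:
        rc = pattern.reverse_complement()
        hits += [(m.start(), "-") for m in rc._regex().finditer(s)]
    hits.sort()
    return hits


def scan_genome(
    genome: Mapping[str, str], pattern: MotifPattern, both_strands: bool = True
) -> list[MotifHit]:
    """Scan every chromosome; hits sorted by (chrom, start, strand)."""
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for off, strand in scan_sequence(seq, pattern, both_strands):
            window = seq[off : off + len(pattern)]
            matched = window if strand == "+" else revcomp(window)
            hits.append(MotifHit(chrom, off, off + len(pattern), strand, matched))
    return hits


def count_in_intervals(
    genome: Mapping[str, str],
    intervals: Sequence[Interval],
    pattern: MotifPattern,
    hits: Sequence[MotifHit] | None = None,
) -> tuple[np.ndarray, list[MotifHit]]:
    """Per-interval hit counts (full containment; both strands).

    Duplicate ``(chrom, start, strand)`` hits are counted once.  A
    pre-computed genome-wide hit list may be passed to avoid rescanning.
    Returns ``(counts, hits)``.
    """
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval chromosome {iv.chrom!r} not in genome")
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} runs off the chromosome"
            )
    if hits is None:
        hits = scan_genome(genome, pattern)
    unique = sorted({(h.chrom, h.start, h.strand): h for h in hits}.values(),
                    key=lambda h: (h.chrom, h.start, h.strand))
    tmp: dict[str, list[int]] = {}
    for h in unique:
        tmp.setdefault(h.chrom, []).append(h.start)
    arr = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in tmp.items()}
    L = len(pattern)
    counts = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        starts = arr.get(iv.chrom)
        if starts is None or len(starts) == 0:
            continue
        lo = np.searchsorted(starts, iv.start, side="left")
        hi = np.searchsorted(starts, iv.end - L, side="right")
        counts[i] = max(0, hi - lo)
    return counts, list(unique)


def motif_density(count: int, length: int) -> float:
    """Hits per 10 kb: ``count * 1e4 / length``."""
    if length <= 0:
        raise ValueError("length must be positive")
    return count * 1e4 / length


# ---------------------------------------------------------------------------
# FASTA I/O (thin wrappers around Biopython)


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, possibly wrapped) FASTA into a dict of
    uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in sorted(genome)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    """Write motif hits as BED6 with strand."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\thit{i + 1}\t0\t{h.strand}\n")
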