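"""Genomic interval algebra: promoter windows, overlaps, peak annotation,
chromatin-state partition and windowed signal means.

All coordinates are 0-based, half-open (BED convention) throughout the
package.  1-based inputs are not accepted; conversion is the caller's
responsibility.  The transcription start site (TSS) of a minus-strand
gene is ``end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "Peak",
    "GeneModel",
    "SignalTrack",
    "parse_bed",
    "format_bed",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "promoter_window",
    "overlaps",
    "annotate_peak",
    "annotate_peaks",
    "classify_chromatin",
    "mean_signal_in_window",
]


@dataclass(frozen=True)
class Interval:
    """A genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak(Interval):
    """An interval with a summit, stored as an offset from ``start``."""

    summit_offset: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 <= self.summit_offset < len(self):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length {len(self)}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position (0-based)."""
        return self.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """Gene span with a mandatory strand; the TSS anchors promoter windows."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}-{self.end}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# BED / gene-table I/O


def parse_bed(line: str) -> Interval | Peak:
    """Parse one BED line into an :class:`Interval` or :class:`Peak`.

    Columns follow the BED spec (0-based, half-open).  When a 7th column
    (thickStart) is present and falls inside the span, it is interpreted
    as the absolute summit position and a :class:`Peak` is returned.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"BED line needs >=3 tab-separated fields: {line!r}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"non-integer coordinates in BED line: {line!r}") from exc
    if start >= end:
        raise ValueError(f"start >= end in BED line: {line!r}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    strand = fields[5] if len(fields) > 5 else "."
    if len(fields) > 6:
        summit = int(fields[6])
        if start <= summit < end:
            return Peak(chrom, start, end, name, strand, summit_offset=summit - start)
    return Interval(chrom, start, end, name, strand)


def format_bed(iv: Interval) -> str:
    """Render an interval as a canonical BED6 (or BED6+summit) line."""
    base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
    if isinstance(iv, Peak):
        return base + f"\t{iv.summit}"
    return base


def read_bed(path) -> list[Interval | Peak]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                out.append(parse_bed(line))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(format_bed(iv) + "\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "is_tf", "is_seed"]


def read_gene_table(path) -> tuple[list[GeneModel], pd.DataFrame]:
    """Read the gene TSV; returns gene models plus the flag table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    genes = [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    flags = df.set_index("gene_id")[["is_tf", "is_seed"]].astype(bool)
    return genes, flags


def write_gene_table(genes: Sequence[GeneModel], flags: pd.DataFrame, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "is_tf": bool(flags.loc[g.gene_id, "is_tf"]),
            "is_seed": bool(flags.loc[g.gene_id, "is_seed"]),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval operations


def promoter_window(g: GeneModel, flank: int, chrom_len: int | None = None) -> Interval:
    """Window of ``[TSS - flank, TSS + flank)``, clipped to the chromosome.

    The TSS is strand-aware (``end - 1`` on minus-strand genes), so the
    window always contains the TSS regardless of clipping.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    tss = g.tss
    start = max(0, tss - flank)
    end = tss + flank
    if chrom_len is not None:
        end = min(end, chrom_len)
    return Interval(g.chrom, start, end, name=g.gene_id, strand=g.strand)


def overlaps(a: Interval, b: Interval, min_bp: int = 1) -> bool:
    """True iff the two spans share at least ``min_bp`` bases (strand ignored)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def _tss_distance(summit: int, gene: GeneModel) -> int:
    """Signed summit-to-TSS distance; negative = upstream in gene orientation."""
    if gene.strand == "+":
        return summit - gene.tss
    return gene.tss - summit


def annotate_peak(
    p: Peak,
    genes: Sequence[GeneModel],
    promoter_bp: int = 1000,
    distal_bp: int = 10000,
) -> tuple[str, float]:
    """Categorise a peak by its summit's distance to the nearest TSS.

    Returns ``(category, signed distance)`` with categories
    ``promoter`` (|d| <= promoter_bp), ``genic`` (summit inside a gene
    body), ``distal_intergenic`` (|d| > distal_bp), or
    ``upstream``/``downstream`` otherwise.  A chromosome absent from the
    annotation yields ``("distal_intergenic", inf)``.
    """
    if not genes:
        raise ValueError("annotation is empty")
    same_chrom = [g for g in genes if g.chrom == p.chrom]
    if not same_chrom:
        return "distal_intergenic", math.inf
    summit = p.summit
    best = min(same_chrom, key=lambda g: (abs(_tss_distance(summit, g)), g.gene_id))
    d = _tss_distance(summit, best)
    if abs(d) <= promoter_bp:
        return "promoter", d
    if any(g.start <= summit < g.end for g in same_chrom):
        return "genic", d
    if abs(d) > distal_bp:
        return "distal_intergenic", d
    return ("upstream", d) if d < 0 else ("downstream", d)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_bp: int = 1000,
    distal_bp: int = 10000,
) -> pd.DataFrame:
    """Annotate every peak; one row per peak, fixed column order."""
    rows = []
    for i, p in enumerate(peaks):
        cat, d = annotate_peak(p, genes, promoter_bp, distal_bp)
        rows.append(
            {
                "peak_id": p.name or f"peak{i + 1}",
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "summit": p.summit,
                "category": cat,
                "tss_distance": d,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "start", "end", "summit", "category", "tss_distance"],
    )


def annotation_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category counts and fractions over an annotated peak table."""
    counts = annotated["category"].value_counts()
    order = ["promoter", "genic", "upstream", "downstream", "distal_intergenic"]
    rows = [
        {"category": c, "count": int(counts.get(c, 0)), "fraction": counts.get(c, 0) / len(annotated)}
        for c in order
    ]
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])


def classify_chromatin(
    peaks: Sequence[Peak], open_regions: Sequence[Interval]
) -> list[str]:
    """Label each peak ``open`` iff it overlaps >=1 bp of any open region."""
    by_chrom: dict[str, list[Interval]] = {}
    for r in open_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    labels = []
    for p in peaks:
        hit = any(overlaps(p, r) for r in by_chrom.get(p.chrom, ()))
        labels.append("open" if hit else "closed")
    return labels


# ---------------------------------------------------------------------------
# Signal tracks


class SignalTrack:
    """Piecewise-constant coverage signal, per chromosome.

    Steps are sorted, non-overlapping ``(start, end, value)`` triples;
    uncovered bases have value 0.  This is the in-memory form of a
    bedGraph file.
    """

    def __init__(self, steps: Mapping[str, Sequence[tuple[int, int, float]]] | None = None):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if steps:
            for chrom, triples in steps.items():
                self.set_chrom(chrom, triples)

    def set_chrom(self, chrom: str, triples: Sequence[tuple[int, int, float]]) -> None:
        triples = sorted(triples)
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        values = np.array([t[2] for t in triples], dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping steps on {chrom}")
        if np.any(starts >= ends):
            raise ValueError(f"empty step on {chrom}")
        self._steps[chrom] = (starts, ends, values)

    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
        track = cls()
        for chrom, sub in df.groupby("chrom", sort=True):
            track.set_chrom(
                str(chrom),
                list(zip(sub["start"].astype(int), sub["end"].astype(int), sub["value"])),
            )
        return track

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._steps):
                starts, ends, values = self._steps[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def mean_signal_in_window(t: SignalTrack, w: Interval) -> float:
    """Length-weighted mean of step values over ``w``; uncovered bases count 0."""
    starts, ends, values = t.steps(w.chrom)
    if len(starts) == 0:
        return 0.0
    lo = np.maximum(starts, w.start)
    hi = np.minimum(ends, w.end)
    lengths = np.clip(hi - lo, 0, None)
    return float(np.dot(lengths, values) / len(w))
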