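"""piRNA cluster quantification, classification and ranking.

Clusters are quantified as RPKM (reads per kilobase of cluster per
million library reads) in each of two tissues, ovary and testis.  A
cluster counts as expressed in a tissue when its RPKM is strictly
greater than a threshold (default 1); the combination of the two
tissues yields the four classes ovary-specific / testis-specific /
shared / unexpressed.  Within a chosen tissue, expressed clusters are
ranked by RPKM and assigned the fraction of cluster-mapping reads they
account for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import Interval

__all__ = [
    "ClusterCounts",
    "ClusterExpression",
    "rpkm",
    "classify_cluster",
    "rank_and_fraction",
    "cluster_expression_frame",
]


@dataclass(frozen=True)
class ClusterCounts:
    """Reads mapping to one cluster in one tissue, plus the library size."""

    cluster_id: str
    interval: Interval
    count: float
    library_size: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.cluster_id}: negative count")
        if self.library_size <= 0:
            raise ValueError(f"{self.cluster_id}: library size must be positive")

    @property
    def rpkm(self) -> float:
        return rpkm(self.count, len(self.interval), self.library_size)


@dataclass(frozen=True)
class ClusterExpression:
    cluster_id: str
    interval: Interval
    rpkm_ovary: float
    rpkm_testis: float
    cluster_class: str
    fraction: float
    rank: int


def rpkm(count: float, length_bp: int, library_size: float) -> float:
    """Reads per kb of feature per million library reads."""
    if length_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / ((length_bp / 1e3) * (library_size / 1e6))


def classify_cluster(
    rpkm_ovary: float, rpkm_testis: float, threshold: float = 1.0
) -> str:
    """Classify by the strict '>' expression rule in each tissue."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ov = rpkm_ovary > threshold
    te = rpkm_testis > threshold
    if ov and te:
        return "shared"
    if ov:
        return "ovary-specific"
    if te:
        return "testis-specific"
    return "unexpressed"


def rank_and_fraction(
    ovary: Sequence[ClusterCounts],
    testis: Sequence[ClusterCounts],
    threshold: float = 1.0,
    tissue: str = "ovary",
) -> list[ClusterExpression]:
    """Rank clusters expressed in ``tissue`` and compute read fractions.

    Returns one :class:`ClusterExpression` per cluster whose RPKM in the
    chosen tissue exceeds ``threshold``, sorted by rank (RPKM
    descending, ties broken by cluster id).  ``fraction`` is the
    cluster's share of reads over all clusters passing the rule in that
    tissue.  Class labels use both tissues.  An empty table raises; if
    no cluster is expressed, an empty list is returned with a warning.
    """
    if not ovary:
        raise ValueError("empty cluster table")
    if tissue not in ("ovary", "testis"):
        raise ValueError("tissue must be 'ovary' or 'testis'")
    by_id_o = {c.cluster_id: c for c in ovary}
    by_id_t = {c.cluster_id: c for c in testis}
    if set(by_id_o) != set(by_id_t):
        raise ValueError("ovary and testis tables cover different clusters")

    rows = []
    for cid in by_id_o:
        o, t = by_id_o[cid], by_id_t[cid]
        rows.append((cid, o.interval, o.rpkm, t.rpkm, o.count if tissue == "ovary" else t.count))

    expressed = [
        r for r in rows if (r[2] if tissue == "ovary" else r[3]) > threshold
    ]
    if not expressed:
        warnings.warn("no cluster passes the expression rule; empty ranking")
        return []
    total = sum(r[4] for r in expressed)
    key_rpkm = (lambda r: r[2]) if tissue == "ovary" else (lambda r: r[3])
    expressed.sort(key=lambda r: (-key_rpkm(r), r[0]))
    return [
        ClusterExpression(
            cluster_id=cid,
            interval=iv,
            rpkm_ovary=ro,
            rpkm_testis=rt,
            cluster_class=classify_cluster(ro, rt, threshold),
            fraction=(cnt / total) if total > 0 else 0.0,
            rank=i + 1,
        )
        for i, (cid, iv, ro, rt, cnt) in enumerate(expressed)
    ]


CLUSTER_COLUMNS = [
    "cluster_id", "chrom", "start", "end",
    "rpkm_ovary", "rpkm_testis", "class", "ovary_fraction", "rank",
]


def cluster_expression_frame(rows: Sequence[ClusterExpression]) -> pd.DataFrame:
    """Fixed-column table of ranked cluster expression, for TSV output."""
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "rpkm_ovary": r.rpkm_ovary,
                "rpkm_testis": r.rpkm_testis,
                "class": r.cluster_class,
                "ovary_fraction": r.fraction,
                "rank": r.rank,
            }
            for r in rows
        ],
        columns=CLUSTER_COLUMNS,
    )


def read_cluster_counts(counts_path, libsize_path, clusters: Sequence[Interval], tissue: str) -> list[ClusterCounts]:
    """Assemble ClusterCounts from a count TSV + library-size sidecar."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="cluster_id")["count"]
    libs = pd.read_csv(libsize_path, sep="\t", index_col="tissue")["library_size"]
    N = float(libs.loc[tissue])
    by_name = {iv.name: iv for iv in clusters}
    return [
        ClusterCounts(cid, by_name[cid], float(c), N) for cid, c in counts.items()
    ]
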