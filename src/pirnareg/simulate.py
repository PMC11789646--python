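"""Synthetic data generators with recorded ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis chain is testable without any external download:

* a single-cell count matrix in which a germline subpopulation carries
  a latent expression program shared by one planted TF and a small seed
  module of pathway genes (negative-binomial counts, log-normal cell
  size factors);
* a genome of i.i.d. nucleotide background with a consensus motif
  planted at Poisson-distributed density — elevated inside designated
  piRNA-cluster intervals and, optionally, placed inside target gene
  promoters;
* a ChIP-style peak set whose summits sit on planted promoter motifs,
  plus intergenic decoy peaks;
* ovary/testis small-RNA cluster count tables realising requested
  expression classes under the >1 RPKM rule;
* a piecewise-constant coverage track with elevated signal over peaks.

All generators are pure functions of (config, seed): each derives its
own labelled random stream from the root seed, so adding one generator
never perturbs another's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .clusters import ClusterCounts, rpkm
from .coexpression import CellMatrix
from .intervals import GeneModel, Interval, Peak, SignalTrack, promoter_window
from .motifs import IUPAC, MotifHit, MotifPattern, revcomp, scan_sequence

__all__ = [
    "ScSimConfig",
    "GenomeSimConfig",
    "SimTruth",
    "generate_sc_counts",
    "generate_genome",
    "generate_gene_annotation",
    "generate_peakset",
    "generate_smallrna_counts",
    "generate_signal_track",
    "tile_clusters",
]


@dataclass(frozen=True)
class ScSimConfig:
    """Study conditions for the single-cell simulation.

    ``loading`` is the log-scale effect of the latent germline program
    on loaded genes (the planted TF and the seed module); ``dispersion``
    is the negative-binomial dispersion phi in Var = mu + phi * mu^2
    (0 gives Poisson counts); ``base_mean_range`` bounds per-gene base
    mean counts; ``libsize_sigma`` is the log-normal spread of cell
    size factors.
    """

    n_cells_germ: int = 300
    n_cells_soma: int = 700
    n_genes: int = 200
    n_tfs: int = 40
    n_seed_genes: int = 5
    loading: float = 0.8
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (2.0, 10.0)
    libsize_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells_germ", "n_cells_soma", "n_genes", "n_tfs", "n_seed_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_tfs < 1:
            raise ValueError("need at least one TF (the planted regulator)")
        if self.n_seed_genes + 1 > self.n_genes or self.n_tfs + self.n_seed_genes > self.n_genes:
            raise ValueError("gene budget too small for TFs + seed genes")
        if self.loading < 0:
            raise ValueError("loading must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")
        lo, hi = self.base_mean_range
        if not 0 < lo <= hi:
            raise ValueError("base_mean_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class GenomeSimConfig:
    """Study conditions for the synthetic genome.

    ``background_rate`` is planted motifs per bp per strand outside
    clusters; inside cluster intervals the planting rate is
    ``cluster_fold`` times higher.  With ``scrub_background`` set,
    chance occurrences of the pattern outside planted sites are
    resampled away, so a scan recovers exactly the planted hits.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    gc: float = 0.42
    background_rate: float = 1e-4
    cluster_fold: float = 2.5
    scrub_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.cluster_fold < 1:
            raise ValueError("cluster_fold must be >= 1")


@dataclass
class SimTruth:
    """Recorded ground truth of a simulation run."""

    planted_tf_id: str | None = None
    seed_gene_ids: list[str] = field(default_factory=list)
    planted_hits: list[MotifHit] = field(default_factory=list)
    cluster_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_tf_id": self.planted_tf_id,
            "seed_gene_ids": self.seed_gene_ids,
            "planted_hits": [
                [h.chrom, int(h.start), int(h.end), h.strand, h.matched]
                for h in self.planted_hits
            ],
            "cluster_classes": self.cluster_classes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_tf_id=payload["planted_tf_id"],
            seed_gene_ids=payload["seed_gene_ids"],
            planted_hits=[MotifHit(*h) for h in payload["planted_hits"]],
            cluster_classes=payload["cluster_classes"],
        )


# ---------------------------------------------------------------------------
# Single-cell counts


def generate_sc_counts(cfg: ScSimConfig) -> tuple[CellMatrix, SimTruth]:
    """Simulate a gene-by-cell count matrix with one planted regulator.

    Germ cells carry a latent program activity a_c ~ Gamma(2, 0.5);
    soma cells have a_c = 0.  The mean of gene g in cell c is
    ``s_c * base_g * exp(loading_g * a_c)`` with ``loading_g`` equal to
    ``cfg.loading`` for the planted TF and the seed genes and 0 for all
    decoys; counts are negative-binomial with dispersion phi
    (Var = mu + phi mu^2), Poisson when phi = 0.
    """
    rng = stream(cfg.seed, "sc_counts")
    n_cells = cfg.n_cells_germ + cfg.n_cells_soma
    if n_cells == 0:
        raise ValueError("no cells requested")

    tf_ids = [f"tf{i + 1:03d}" for i in range(cfg.n_tfs)]
    seed_ids = [f"seed{i + 1:02d}" for i in range(cfg.n_seed_genes)]
    n_other = cfg.n_genes - cfg.n_tfs - cfg.n_seed_genes
    other_ids = [f"gene{i + 1:04d}" for i in range(n_other)]
    gene_ids = tf_ids + seed_ids + other_ids
    planted_tf = tf_ids[0]

    cell_ids = [f"cell{j + 1:05d}" for j in range(n_cells)]
    labels = pd.Series(
        ["germ"] * cfg.n_cells_germ + ["soma"] * cfg.n_cells_soma,
        index=cell_ids, name="label",
    )

    lo, hi = cfg.base_mean_range
    base = rng.uniform(lo, hi, size=cfg.n_genes)
    a = np.zeros(n_cells)
    a[: cfg.n_cells_germ] = rng.gamma(shape=2.0, scale=0.5, size=cfg.n_cells_germ)
    s = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n_cells) if cfg.libsize_sigma > 0 else np.ones(n_cells)

    loading = np.zeros(cfg.n_genes)
    loaded = {planted_tf, *seed_ids}
    for i, g in enumerate(gene_ids):
        if g in loaded:
            loading[i] = cfg.loading

    mu = s[None, :] * base[:, None] * np.exp(loading[:, None] * a[None, :])
    if cfg.dispersion > 0:
        size = 1.0 / cfg.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    counts = counts.astype(np.int64)

    flags = pd.DataFrame(
        {
            "is_tf": [g in set(tf_ids) for g in gene_ids],
            "is_seed": [g in set(seed_ids) for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    matrix = CellMatrix(counts, gene_ids, cell_ids, labels, flags)
    truth = SimTruth(planted_tf_id=planted_tf, seed_gene_ids=seed_ids)
    return matrix, truth


# ---------------------------------------------------------------------------
# Genome with planted motifs


def _realize_pattern(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Draw one concrete sequence matching the IUPAC pattern."""
    return "".join(
        rng.choice(sorted(IUPAC[c])) if len(IUPAC[c]) > 1 else next(iter(IUPAC[c]))
        for c in pattern.symbols
    )


def _draw_positions(
    regions: list[tuple[int, int]],
    rate: float,
    L: int,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[int]:
    """Poisson-count uniform positions inside regions, rejecting overlap.

    Overlapping candidate sites are re-drawn, never truncated.
    """
    usable = [(s, e) for s, e in regions if e - s >= L]
    total = sum(e - s - L + 1 for s, e in usable)
    if total <= 0 or rate <= 0:
        return []
    n = rng.poisson(rate * sum(e - s for s, e in usable))
    lengths = np.array([e - s - L + 1 for s, e in usable])
    cum = np.cumsum(lengths)
    placed: list[int] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 1000 * max(1, n):
            break  # pathologically dense request; keep what fits
        u = int(rng.integers(0, total))
        idx = int(np.searchsorted(cum, u, side="right"))
        offset = u - (cum[idx - 1] if idx else 0)
        pos = usable[idx][0] + offset
        span = (pos, pos + L)
        if any(s < span[1] and span[0] < e for s, e in occupied) or any(
            s < span[1] and span[0] < e for s, e in ((p, p + L) for p in placed)
        ):
            continue
        placed.append(pos)
    return placed


def _complement_regions(length: int, blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out, prev = [], 0
    for s, e in sorted(blocks):
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def generate_genome(
    cfg: GenomeSimConfig,
    pattern: MotifPattern,
    cluster_intervals: Sequence[Interval],
    promoter_intervals: Sequence[Interval] | None = None,
    motifs_per_promoter: int = 2,
) -> tuple[dict[str, str], SimTruth]:
    """Generate a genome with the pattern planted at known positions.

    Background is i.i.d. nucleotides at the configured GC.  Motif
    instances are planted at Poisson-distributed counts: rate
    ``background_rate`` per bp per strand outside clusters and
    ``cluster_fold`` times that inside the cluster intervals.  When
    ``promoter_intervals`` are given, exactly ``motifs_per_promoter``
    instances are additionally planted inside each (for ChIP peak /
    target-gene simulations).  With ``scrub_background``, chance
    occurrences of the pattern outside planted sites are resampled away
    so that a scan recovers the planted hits exactly.
    """
    L = len(pattern)
    if L > min(cfg.chrom_lengths.values()):
        raise ValueError("pattern longer than the smallest chromosome")
    for iv in cluster_intervals:
        if iv.chrom not in cfg.chrom_lengths or iv.end > cfg.chrom_lengths[iv.chrom]:
            raise ValueError(f"cluster {iv.chrom}:{iv.start}-{iv.end} outside genome bounds")
    rng = stream(cfg.seed, "genome")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])

    genome: dict[str, str] = {}
    truth = SimTruth()
    clusters_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cluster_intervals:
        clusters_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    promoters_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in promoter_intervals or ():
        if iv.chrom not in cfg.chrom_lengths or iv.end > cfg.chrom_lengths[iv.chrom]:
            raise ValueError(f"promoter {iv.chrom}:{iv.start}-{iv.end} outside genome bounds")
        promoters_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        seq = rng.choice(bases, size=length, p=p)

        cluster_blocks = sorted(clusters_by_chrom.get(chrom, []))
        outside = _complement_regions(length, cluster_blocks)

        occupied: list[tuple[int, int]] = []
        sites: list[tuple[int, str]] = []  # (pos, strand)

        # fixed promoter plantings first (they take priority for space)
        for ps, pe in promoters_by_chrom.get(chrom, []):
            for _ in range(motifs_per_promoter):
                # rate-free exact placement: draw until one lands
                tries = 0
                pos = None
                while pos is None:
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError(f"cannot place promoter motif in {chrom}:{ps}-{pe}")
                    cand = int(rng.integers(ps, pe - L + 1))
                    if not any(s < cand + L and cand < e for s, e in occupied):
                        pos = cand
                strand = "+" if rng.random() < 0.5 else "-"
                occupied.append((pos, pos + L))
                sites.append((pos, strand))

        for regions, rate in (
            (cluster_blocks, cfg.cluster_fold * cfg.background_rate),
            (outside, cfg.background_rate),
        ):
            for strand in ("+", "-"):
                for pos in _draw_positions(regions, rate, L, occupied, rng):
                    occupied.append((pos, pos + L))
                    sites.append((pos, strand))

        # write the planted realizations into the sequence
        planted_mask = np.zeros(length, dtype=bool)
        for pos, strand in sorted(sites):
            real = _realize_pattern(pattern, rng)
            written = real if strand == "+" else revcomp(real)
            seq[pos : pos + L] = np.frombuffer(written.encode(), dtype="S1")
            planted_mask[pos : pos + L] = True

        planted_set = {(pos, strand) for pos, strand in sites}

        if cfg.scrub_background:
            for _ in range(200):
                s_str = seq.tobytes().decode("ascii")
                chance = [
                    (off, strand)
                    for off, strand in scan_sequence(s_str, pattern)
                    if (off, strand) not in planted_set
                ]
                if not chance:
                    break
                rc = pattern.reverse_complement()
                for off, _strand in chance:
                    free = [
                        i for i in range(off, off + L) if not planted_mask[i]
                    ]
                    if free:
                        seq[free] = rng.choice(bases, size=len(free), p=p)
                        continue
                    # A planted realization also matches on the other
                    # strand at the same offset: redraw a realization
                    # that matches the pattern but not its reverse
                    # complement, preserving the planted strand.
                    planted_strand = "+" if (off, "+") in planted_set else "-"
                    for _try in range(200):
                        real = _realize_pattern(pattern, rng)
                        if not rc.matches(real):
                            break
                    else:
                        raise ValueError(
                            "scrub_background impossible: every realization of "
                            f"{pattern} is self-reverse-complementary"
                        )
                    seq[off : off + L] = np.frombuffer(
                        (real if planted_strand == "+" else revcomp(real)).encode(), dtype="S1"
                    )
            else:
                raise RuntimeError(f"background scrubbing failed to converge on {chrom}")

        final = seq.tobytes().decode("ascii")
        genome[chrom] = final
        for pos, strand in sorted(sites):
            window = final[pos : pos + L]
            matched = window if strand == "+" else revcomp(window)
            truth.planted_hits.append(MotifHit(chrom, pos, pos + L, strand, matched))

    return genome, truth


def tile_clusters(
    chrom_lengths: Mapping[str, int],
    n_per_chrom: int,
    length: int,
    margin: int = 10_000,
) -> list[Interval]:
    """Evenly spaced, deterministic cluster intervals per chromosome."""
    out = []
    i = 0
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        span = clen - 2 * margin
        if span < n_per_chrom * length:
            raise ValueError(f"{chrom} too short for {n_per_chrom} clusters of {length} bp")
        gap = (span - n_per_chrom * length) // max(1, n_per_chrom)
        pos = margin
        for _ in range(n_per_chrom):
            i += 1
            out.append(Interval(chrom, pos, pos + length, name=f"cluster{i:02d}"))
            pos += length + gap
    return out


# ---------------------------------------------------------------------------
# Gene annotation on the synthetic genome


def generate_gene_annotation(
    chrom_lengths: Mapping[str, int],
    gene_ids: Sequence[str],
    avoid: Sequence[Interval] = (),
    gene_length: int = 2_000,
    spacing: int = 3_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place genes on the genome, outside ``avoid`` intervals.

    Genes are laid out left to right with fixed length and spacing
    (deterministic layout), skipping avoided blocks; strands are drawn
    from the seeded stream.  Raises if the genome cannot host all genes.
    """
    rng = stream(seed, "gene_annotation")
    avoid_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in avoid:
        avoid_by_chrom.setdefault(iv.chrom, []).append((iv.start - spacing, iv.end + spacing))
    slots: list[tuple[str, int]] = []
    for chrom in sorted(chrom_lengths):
        free = _complement_regions(
            chrom_lengths[chrom], [(max(0, s), e) for s, e in sorted(avoid_by_chrom.get(chrom, []))]
        )
        for s, e in free:
            pos = s + spacing
            while pos + gene_length + spacing <= e:
                slots.append((chrom, pos))
                pos += gene_length + spacing
    if len(slots) < len(gene_ids):
        raise ValueError(
            f"genome hosts only {len(slots)} gene slots but {len(gene_ids)} genes requested"
        )
    strands = rng.choice(["+", "-"], size=len(gene_ids))
    return [
        GeneModel(g, chrom, start, start + gene_length, strand)
        for g, (chrom, start), strand in zip(gene_ids, slots, strands)
    ]


# ---------------------------------------------------------------------------
# Peaks, small-RNA counts, signal track


def generate_peakset(
    genes: Sequence[GeneModel],
    targets: Sequence[str],
    truth: SimTruth,
    n_decoys: int = 0,
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
    promoter_flank: int = 500,
    peak_halfwidth: int = 150,
    decoy_min_gene_distance: int = 1_500,
) -> list[Peak]:
    """ChIP-style peaks: one per target gene, summit on a planted
    promoter motif, plus uniform intergenic decoys.

    Raises if a target gene's promoter (TSS +/- ``promoter_flank``)
    contains no planted motif.
    """
    rng = stream(seed, "peakset")
    by_id = {g.gene_id: g for g in genes}
    hits_by_chrom: dict[str, list[MotifHit]] = {}
    for h in truth.planted_hits:
        hits_by_chrom.setdefault(h.chrom, []).append(h)

    peaks: list[Peak] = []
    for t in targets:
        if t not in by_id:
            raise ValueError(f"target gene {t!r} not in annotation")
        g = by_id[t]
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        win = promoter_window(g, promoter_flank, clen)
        in_prom = [
            h for h in hits_by_chrom.get(g.chrom, [])
            if h.start >= win.start and h.end <= win.end
        ]
        if not in_prom:
            raise ValueError(f"target promoter of {t!r} contains no planted motif")
        hit = in_prom[0]
        summit = (hit.start + hit.end) // 2
        start = max(0, summit - peak_halfwidth)
        end = summit + peak_halfwidth
        if clen is not None:
            end = min(end, clen)
        peaks.append(Peak(g.chrom, start, end, name=f"peak_{t}", strand=".",
                          summit_offset=summit - start))

    if n_decoys:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths required to place decoy peaks")
        chroms = sorted(chrom_lengths)
        lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        probs = lens / lens.sum()
        width = 2 * peak_halfwidth
        placed = 0
        attempts = 0
        while placed < n_decoys:
            attempts += 1
            if attempts > 10_000 * n_decoys:
                raise RuntimeError("cannot place decoy peaks away from genes")
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            start = int(rng.integers(0, chrom_lengths[chrom] - width))
            summit = start + peak_halfwidth
            near_gene = any(
                g.chrom == chrom
                and g.start - decoy_min_gene_distance <= summit < g.end + decoy_min_gene_distance
                for g in genes
            )
            if near_gene:
                continue
            placed += 1
            peaks.append(Peak(chrom, start, start + width, name=f"decoy{placed:03d}",
                              strand=".", summit_offset=peak_halfwidth))
    return peaks


def generate_smallrna_counts(
    clusters: Sequence[Interval],
    classes: Mapping[str, str],
    depth_ovary: int = 5_000_000,
    depth_testis: int = 5_000_000,
    seed: int = 0,
    expressed_rpkm_range: tuple[float, float] = (5.0, 50.0),
    silent_rpkm_mean: float = 0.2,
    max_redraws: int = 1000,
) -> tuple[list[ClusterCounts], list[ClusterCounts], SimTruth]:
    """Ovary and testis cluster count tables realising requested classes.

    Each cluster is assigned a class in {ovary, testis, shared, silent};
    counts are Poisson draws re-drawn until the realized RPKM is > 1 in
    tissues where the class says expressed and <= 1 where silent.
    """
    rng = stream(seed, "smallrna")
    valid = {"ovary", "testis", "shared", "silent"}
    for iv in clusters:
        if iv.name not in classes:
            raise ValueError(f"cluster {iv.name!r} has no class assignment")
        if classes[iv.name] not in valid:
            raise ValueError(f"invalid class {classes[iv.name]!r} for {iv.name!r}")

    def draw(iv: Interval, expressed: bool, depth: int) -> float:
        lo, hi = expressed_rpkm_range
        for _ in range(max_redraws):
            if expressed:
                target = rng.uniform(lo, hi)
            else:
                target = silent_rpkm_mean
            lam = target * (len(iv) / 1e3) * (depth / 1e6)
            c = float(rng.poisson(lam))
            r = rpkm(c, len(iv), depth)
            if (expressed and r > 1.0) or (not expressed and r <= 1.0):
                return c
        raise RuntimeError(
            f"cluster {iv.name!r} ({len(iv)} bp) cannot realize "
            f"{'expressed' if expressed else 'silent'} state at depth {depth} "
            f"after {max_redraws} redraws"
        )

    ovary, testis = [], []
    truth = SimTruth()
    for iv in clusters:
        cls = classes[iv.name]
        truth.cluster_classes[iv.name] = cls
        ovary.append(
            ClusterCounts(iv.name, iv, draw(iv, cls in ("ovary", "shared"), depth_ovary), depth_ovary)
        )
        testis.append(
            ClusterCounts(iv.name, iv, draw(iv, cls in ("testis", "shared"), depth_testis), depth_testis)
        )
    return ovary, testis, truth


def generate_signal_track(
    peaks: Sequence[Peak],
    height: float,
    background: float,
    chrom_lengths: Mapping[str, int],
) -> SignalTrack:
    """Piecewise-constant track: ``height`` over peaks, ``background``
    elsewhere; overlapping peaks are merged before writing."""
    if not height > background or background < 0:
        raise ValueError("need height > background >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    track = SignalTrack()
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        merged: list[tuple[int, int]] = []
        for s, e in sorted(by_chrom.get(chrom, [])):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, min(e, length)))
        steps: list[tuple[int, int, float]] = []
        prev = 0
        for s, e in merged:
            if s > prev:
                steps.append((prev, s, background))
            steps.append((s, e, height))
            prev = e
        if prev < length:
            steps.append((prev, length, background))
        track.set_chrom(chrom, steps)
    return track


def write_smallrna_tables(
    ovary: Sequence[ClusterCounts],
    testis: Sequence[ClusterCounts],
    ovary_path, testis_path, libsize_path,
) -> None:
    """Write per-tissue count TSVs plus the library-size sidecar."""
    for table, path in ((ovary, ovary_path), (testis, testis_path)):
        pd.DataFrame(
            [{"cluster_id": c.cluster_id, "count": c.count} for c in table],
            columns=["cluster_id", "count"],
        ).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"tissue": "ovary", "library_size": ovary[0].library_size if ovary else 0},
            {"tissue": "testis", "library_size": testis[0].library_size if testis else 0},
        ]
    ).to_csv(libsize_path, sep="\t", index=False)
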