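"""End-to-end orchestration of the analysis stages.

``run_full`` wires the stages together — simulate (or load) inputs,
rank TFs by seed-module coexpression, scan motifs and annotate peaks,
quantify and classify piRNA clusters, test motif enrichment against
genomic background, and account for gene-set overlaps — writing one TSV
per stage plus a manifest.  Identical config + seed give bitwise
identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import cluster_expression_frame, rank_and_fraction, read_cluster_counts
from .coexpression import CellMatrix, normalize_counts, rank_tfs, ranked_tfs_frame
from .intervals import (
    GeneModel,
    Interval,
    Peak,
    SignalTrack,
    annotate_peaks,
    annotation_summary,
    classify_chromatin,
    promoter_window,
    read_bed,
    read_gene_table,
    write_bed,
    write_gene_table,
)
from .motifs import MotifPattern, read_fasta, scan_genome, write_fasta, write_hits_bed
from .simulate import (
    GenomeSimConfig,
    ScSimConfig,
    SimTruth,
    generate_gene_annotation,
    generate_genome,
    generate_peakset,
    generate_sc_counts,
    generate_signal_track,
    generate_smallrna_counts,
    tile_clusters,
    write_smallrna_tables,
)
from .stats import (
    mann_whitney_u,
    motif_enrichment,
    promoter_motif_contrast,
    promoter_signal_contrast,
)

__all__ = [
    "RunConfig",
    "default_config",
    "gene_set_from_de",
    "overlap_accounting",
    "run_full",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``simulate=True`` (the default) every input is generated by the
    synthetic module; otherwise ``paths`` must name the input files
    (matrix, cell labels, gene table, genome FASTA, cluster BED, peak
    BED, signal bedGraph, small-RNA count TSVs and library sizes).
    """

    seed: int = 0
    simulate: bool = True
    paths: dict[str, str] = field(default_factory=dict)
    # simulation
    sc: ScSimConfig = field(default_factory=ScSimConfig)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 400_000}
    )
    gc: float = 0.42
    background_rate: float = 1e-4
    cluster_fold: float = 2.5
    scrub_background: bool = True
    clusters_per_chrom: int = 4
    cluster_length: int = 5_000
    n_decoy_peaks: int = 20
    depth_ovary: int = 5_000_000
    depth_testis: int = 5_000_000
    signal_height: float = 4.0
    signal_background: float = 2.0
    # analysis thresholds
    pattern: str = "CCGTTA"
    promoter_bp: int = 1_000
    summit_flank: int = 500
    rpkm_threshold: float = 1.0
    lfc_min: float = 1.0
    padj_max: float = 0.01
    min_detect_frac: float = 0.01
    k_background: int = 10
    alpha: float = 0.05

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sc"] = dataclasses.asdict(self.sc)
        d["sc"]["base_mean_range"] = list(self.sc.base_mean_range)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sc = d.pop("sc", {})
        if "base_mean_range" in sc:
            sc["base_mean_range"] = tuple(sc["base_mean_range"])
        return cls(sc=ScSimConfig(**sc), **d)

    def validate(self) -> None:
        if not self.simulate:
            required = [
                "matrix", "cell_labels", "gene_table", "genome", "clusters",
                "peaks", "signal", "smallrna_ovary", "smallrna_testis", "library_sizes",
            ]
            for key in required:
                if key not in self.paths:
                    raise ValueError(f"missing input path for {key!r}")
                if not Path(self.paths[key]).exists():
                    raise FileNotFoundError(
                        f"input {key!r} not found at {self.paths[key]}"
                    )


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed, sc=dataclasses.replace(ScSimConfig(), seed=seed))


# ---------------------------------------------------------------------------
# Gene sets


def gene_set_from_de(
    t: pd.DataFrame, lfc_min: float, padj_max: float, direction: str
) -> set[str]:
    """Threshold a differential-expression table into a gene set.

    ``up``: log2fc > lfc_min and padj < padj_max;
    ``down``: log2fc < -lfc_min and padj < padj_max.
    Inequalities are strict.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in t.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if direction == "up":
        mask = (t["log2fc"] > lfc_min) & (t["padj"] < padj_max)
    elif direction == "down":
        mask = (t["log2fc"] < -lfc_min) & (t["padj"] < padj_max)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return set(t.loc[mask, "gene_id"])


def overlap_accounting(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """|A∩B| and |A∩B|/|A| for every ordered pair of named gene sets."""
    if not sets or all(len(s) == 0 for s in sets.values()):
        raise ValueError("empty gene universe")
    rows = []
    for a in sorted(sets):
        for b in sorted(sets):
            if a == b:
                continue
            inter = len(sets[a] & sets[b])
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "size_a": len(sets[a]),
                    "intersection": inter,
                    "fraction_of_a": inter / len(sets[a]) if sets[a] else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["set_a", "set_b", "size_a", "intersection", "fraction_of_a"]
    )


def de_table_from_matrix(matrix: CellMatrix) -> pd.DataFrame:
    """Synthetic germ-vs-soma DE table (plumbing, not a DESeq2 fit).

    Log2 fold change of mean log-normalised expression between germ and
    soma cells with a pseudocount, Mann-Whitney p per gene, Bonferroni
    adjusted — enough structure for gene-set thresholding downstream.
    """
    X = normalize_counts(matrix)
    germ = matrix.cell_labels.to_numpy() == "germ"
    soma = ~germ
    eps = 1e-3
    mg = X[:, germ].mean(axis=1)
    ms = X[:, soma].mean(axis=1)
    lfc = np.log2((mg + eps) / (ms + eps))
    rows = []
    m = matrix.n_genes
    for i, g in enumerate(matrix.gene_ids):
        a, b = X[i, germ], X[i, soma]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = mann_whitney_u(a, b, alternative="two-sided").p
        rows.append({"gene_id": g, "log2fc": float(lfc[i]), "padj": min(1.0, m * p)})
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])


# ---------------------------------------------------------------------------
# Full run


@dataclass
class _Bundle:
    matrix: CellMatrix
    truth: SimTruth
    genome: dict[str, str]
    genes: list[GeneModel]
    clusters: list[Interval]
    peaks: list[Peak]
    track: SignalTrack
    ovary: list
    testis: list


def _simulate_inputs(cfg: RunConfig, simdir: Path) -> _Bundle:
    simdir.mkdir(parents=True, exist_ok=True)
    pattern = MotifPattern(cfg.pattern)

    matrix, truth = generate_sc_counts(cfg.sc)
    matrix.write(simdir / "counts.tsv", simdir / "cell_labels.tsv")

    clusters = tile_clusters(cfg.chrom_lengths, cfg.clusters_per_chrom, cfg.cluster_length)
    genes = generate_gene_annotation(
        cfg.chrom_lengths, matrix.gene_ids, avoid=clusters,
        gene_length=1_500, spacing=1_500, seed=cfg.seed,
    )
    write_gene_table(genes, matrix.gene_flags, simdir / "gene_table.tsv")

    targets = [truth.planted_tf_id, *truth.seed_gene_ids]
    by_id = {g.gene_id: g for g in genes}
    promoters = [
        promoter_window(by_id[t], cfg.summit_flank, cfg.chrom_lengths[by_id[t].chrom])
        for t in targets
    ]
    gcfg = GenomeSimConfig(
        chrom_lengths=cfg.chrom_lengths,
        gc=cfg.gc,
        background_rate=cfg.background_rate,
        cluster_fold=cfg.cluster_fold,
        scrub_background=cfg.scrub_background,
        seed=cfg.seed,
    )
    genome, gtruth = generate_genome(gcfg, pattern, clusters, promoter_intervals=promoters)
    truth.planted_hits = gtruth.planted_hits
    write_fasta(genome, simdir / "genome.fa")
    write_bed(clusters, simdir / "clusters.bed")

    peaks = generate_peakset(
        genes, targets, truth, n_decoys=cfg.n_decoy_peaks, seed=cfg.seed,
        chrom_lengths=cfg.chrom_lengths, promoter_flank=cfg.summit_flank,
    )
    write_bed(peaks, simdir / "peaks.bed")

    track = generate_signal_track(
        [p for p in peaks if p.name and p.name.startswith("peak_")],
        cfg.signal_height, cfg.signal_background, cfg.chrom_lengths,
    )
    track.to_bedgraph(simdir / "signal.bedgraph")

    class_cycle = ["ovary", "testis", "shared", "silent"]
    classes = {
        iv.name: class_cycle[i % len(class_cycle)] for i, iv in enumerate(clusters)
    }
    ovary, testis, struth = generate_smallrna_counts(
        clusters, classes, cfg.depth_ovary, cfg.depth_testis, seed=cfg.seed
    )
    truth.cluster_classes = struth.cluster_classes
    write_smallrna_tables(
        ovary, testis,
        simdir / "smallrna_ovary.tsv", simdir / "smallrna_testis.tsv",
        simdir / "library_sizes.tsv",
    )
    truth.to_json(simdir / "truth.json")
    return _Bundle(matrix, truth, genome, genes, clusters, peaks, track, ovary, testis)


def _load_inputs(cfg: RunConfig) -> _Bundle:
    p = cfg.paths
    genes, flags = read_gene_table(p["gene_table"])
    matrix = CellMatrix.read(p["matrix"], p["cell_labels"], flags)
    genome = read_fasta(p["genome"])
    clusters = [iv for iv in read_bed(p["clusters"])]
    peaks = [pk for pk in read_bed(p["peaks"]) if isinstance(pk, Peak)]
    track = SignalTrack.from_bedgraph(p["signal"])
    ovary = read_cluster_counts(p["smallrna_ovary"], p["library_sizes"], clusters, "ovary")
    testis = read_cluster_counts(p["smallrna_testis"], p["library_sizes"], clusters, "testis")
    seed_ids = [g for g in flags.index if flags.loc[g, "is_seed"]]
    truth = SimTruth(planted_tf_id=None, seed_gene_ids=seed_ids)
    return _Bundle(matrix, truth, genome, genes, clusters, peaks, track, ovary, testis)


def run_full(cfg: RunConfig, outdir) -> Path:
    """Execute every stage and write the report directory.

    Stage failures abort with the stage name in the message.  The same
    config and seed always produce bitwise-identical TSVs.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pattern = MotifPattern(cfg.pattern)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if cfg.simulate:
        data = stage("simulate", _simulate_inputs, cfg, outdir / "sim")
    else:
        data = stage("load", _load_inputs, cfg)

    # 1. TF coexpression ranking
    ranked, excluded = stage(
        "rank_tfs", rank_tfs, data.matrix, data.truth.seed_gene_ids,
        min_detect_frac=cfg.min_detect_frac,
    )
    ranked_tfs_frame(ranked).to_csv(outdir / "ranked_tfs.tsv", sep="\t", index=False)

    # 2. motif scan + peak annotation + chromatin partition
    hits = stage("scan", scan_genome, data.genome, pattern)
    write_hits_bed(hits, outdir / "motif_hits.bed")
    annotated = stage("annotate", annotate_peaks, data.peaks, data.genes, cfg.promoter_bp)
    annotated.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
    annotation_summary(annotated).to_csv(
        outdir / "peak_annotation_summary.tsv", sep="\t", index=False
    )
    by_id = {g.gene_id: g for g in data.genes}
    open_regions = [
        promoter_window(by_id[t], cfg.promoter_bp) for t in
        ([data.truth.planted_tf_id, *data.truth.seed_gene_ids] if data.truth.planted_tf_id else data.truth.seed_gene_ids)
        if t in by_id
    ]
    chromatin = classify_chromatin(data.peaks, open_regions)
    pd.DataFrame(
        {
            "peak_id": [pk.name or f"peak{i + 1}" for i, pk in enumerate(data.peaks)],
            "state": chromatin,
        }
    ).to_csv(outdir / "chromatin_state.tsv", sep="\t", index=False)

    # 3. piRNA cluster table
    expressed = stage(
        "clusters", rank_and_fraction, data.ovary, data.testis, cfg.rpkm_threshold
    )
    cluster_expression_frame(expressed).to_csv(
        outdir / "cluster_expression.tsv", sep="\t", index=False
    )

    # 4. enrichment + promoter contrasts
    enr = stage(
        "enrich", motif_enrichment, data.genome, data.clusters, pattern,
        k=cfg.k_background, seed=cfg.seed, hits=hits,
    )
    pd.DataFrame(
        {
            "interval_id": [iv.name or f"iv{i + 1}" for i, iv in enumerate(data.clusters)],
            "length": [len(iv) for iv in data.clusters],
            "density": enr.cluster_densities,
            "bg_density": enr.background_densities,
            "diff": enr.cluster_densities - enr.background_densities,
        }
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "n": enr.n, "fold": enr.fold, "W": enr.statistic, "p": enr.p,
                "method": enr.method, "alternative": enr.alternative, "seed": cfg.seed,
            }
        ]
    ).to_csv(outdir / "enrichment_summary.tsv", sep="\t", index=False)

    targets = [t for t in ([data.truth.planted_tf_id] if data.truth.planted_tf_id else []) + list(data.truth.seed_gene_ids) if t in by_id]
    others = sorted(set(by_id) - set(targets))
    chrom_lengths = {c: len(s) for c, s in data.genome.items()}
    sig = stage(
        "signal_contrast", promoter_signal_contrast,
        data.track, targets, others, by_id, cfg.summit_flank, chrom_lengths,
    )
    mot = stage(
        "motif_contrast", promoter_motif_contrast,
        data.genome, pattern, targets, others, by_id, cfg.summit_flank,
    )
    pd.DataFrame(
        [
            {"contrast": "promoter_signal", "fold": sig.fold, "p": sig.p,
             "test": sig.test, "n_a": sig.n_a, "n_b": sig.n_b},
            {"contrast": "promoter_motifs", "fold": mot.fold, "p": mot.p,
             "test": mot.test, "n_a": mot.n_a, "n_b": mot.n_b},
        ]
    ).to_csv(outdir / "promoter_contrasts.tsv", sep="\t", index=False)

    # 5. DE gene sets + overlap accounting
    de = stage("de_table", de_table_from_matrix, data.matrix)
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
    germline = gene_set_from_de(de, cfg.lfc_min, cfg.padj_max, "up")
    soma = gene_set_from_de(de, cfg.lfc_min, cfg.padj_max, "down")
    planted = set(targets)
    accounting = stage(
        "accounting", overlap_accounting,
        {"germline_enriched": germline, "soma_enriched": soma, "planted_module": planted},
    )
    accounting.to_csv(outdir / "accounting.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = io.StringIO()
    manifest.write(f"pirnareg {__version__}\n")
    manifest.write("coordinate convention: 0-based half-open (BED)\n")
    manifest.write(f"seed: {cfg.seed}\n")
    manifest.write("config:\n")
    manifest.write(cfg.to_yaml())
    manifest.write(f"excluded_tfs: {sorted(excluded.items())}\n")
    (outdir / "manifest.txt").write_text(manifest.getvalue())
    return outdir
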