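"""Synthetic-data generators: determinism, planted ground truth
recovery, and the construction guarantees each generator makes."""

import numpy as np
import pytest

from pirnareg.coexpression import normalize_counts, pearson_r
from pirnareg.intervals import Interval, Peak, annotate_peak, mean_signal_in_window
from pirnareg.motifs import MotifPattern, scan_genome
from pirnareg.simulate import (
    GenomeSimConfig,
    ScSimConfig,
    generate_gene_annotation,
    generate_genome,
    generate_peakset,
    generate_sc_counts,
    generate_signal_track,
    tile_clusters,
)

PAT = MotifPattern("CCGTTA")


class TestScSimConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ScSimConfig(n_genes=-5)
        with pytest.raises(ValueError):
            ScSimConfig(n_genes=3, n_tfs=2, n_seed_genes=2)

    def test_negative_loading_rejected(self):
        with pytest.raises(ValueError):
            ScSimConfig(loading=-1.0)


class TestGenerateScCounts:
    def test_counts_are_nonnegative_integers_with_positive_cells(self):
        m, _ = generate_sc_counts(ScSimConfig(seed=0))
        assert np.issubdtype(m.counts.dtype, np.integer)
        assert np.all(m.counts >= 0)
        assert np.all(m.counts.sum(axis=0) > 0)

    def test_seeded_determinism_bitwise(self):
        cfg = ScSimConfig(seed=13)
        a, _ = generate_sc_counts(cfg)
        b, _ = generate_sc_counts(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert a.gene_ids == b.gene_ids and a.cell_ids == b.cell_ids

    def test_labels_and_flags_recorded(self):
        cfg = ScSimConfig(n_cells_germ=30, n_cells_soma=70, n_genes=30,
                          n_tfs=5, n_seed_genes=2, seed=1)
        m, truth = generate_sc_counts(cfg)
        assert (m.cell_labels == "germ").sum() == 30
        assert m.gene_flags["is_tf"].sum() == 5
        assert m.gene_flags["is_seed"].sum() == 2
        assert m.gene_flags.loc[truth.planted_tf_id, "is_tf"]
        assert all(m.gene_flags.loc[s, "is_seed"] for s in truth.seed_gene_ids)

    def test_null_loading_gives_zero_mean_correlation(self):
        """With loading 0, the planted-TF/seed correlations average to
        ~0 across 100 replicate simulations (Monte-Carlo null)."""
        rs = []
        for seed in range(100):
            cfg = ScSimConfig(n_cells_germ=30, n_cells_soma=70, n_genes=20,
                              n_tfs=4, n_seed_genes=3, loading=0.0, seed=seed)
            m, truth = generate_sc_counts(cfg)
            X = normalize_counts(m)
            idx = {g: i for i, g in enumerate(m.gene_ids)}
            tf_row = X[idx[truth.planted_tf_id]]
            for s in truth.seed_gene_ids:
                rs.append(pearson_r(tf_row, X[idx[s]]))
        assert abs(np.mean(rs)) < 0.05

    def test_noiseless_limit_gives_near_perfect_correlation(self):
        """No soma, no dispersion, no size-factor noise, strong loading:
        TF and seed genes are monotone in the same latent activity."""
        cfg = ScSimConfig(n_cells_germ=200, n_cells_soma=0, n_genes=20,
                          n_tfs=4, n_seed_genes=3, loading=3.0,
                          dispersion=0.0, libsize_sigma=0.0, seed=3)
        m, truth = generate_sc_counts(cfg)
        idx = {g: i for i, g in enumerate(m.gene_ids)}
        tf_row = m.counts[idx[truth.planted_tf_id]].astype(float)
        for s in truth.seed_gene_ids:
            assert pearson_r(tf_row, m.counts[idx[s]].astype(float)) > 0.9


class TestGenerateGenome:
    chroms = {"chr1": 50_000, "chr2": 50_000}
    clusters = [Interval("chr1", 10_000, 20_000, name="cl1"),
                Interval("chr2", 10_000, 20_000, name="cl2")]

    def test_scrubbed_scan_equals_planted_truth(self):
        cfg = GenomeSimConfig(chrom_lengths=self.chroms, background_rate=2e-4,
                              cluster_fold=2.0, scrub_background=True, seed=8)
        genome, truth = generate_genome(cfg, PAT, self.clusters)
        found = {(h.chrom, h.start, h.strand) for h in scan_genome(genome, PAT)}
        planted = {(h.chrom, h.start, h.strand) for h in truth.planted_hits}
        assert found == planted

    def test_zero_background_rate_only_cluster_hits(self):
        cfg = GenomeSimConfig(chrom_lengths=self.chroms, background_rate=0.0,
                              cluster_fold=1.0, scrub_background=True, seed=8)
        genome, truth = generate_genome(
            cfg, PAT, self.clusters, promoter_intervals=None
        )
        assert scan_genome(genome, PAT) == []
        assert truth.planted_hits == []

    def test_unscrubbed_scan_superset_of_planted(self):
        cfg = GenomeSimConfig(chrom_lengths=self.chroms, background_rate=2e-4,
                              scrub_background=False, seed=8)
        genome, truth = generate_genome(cfg, PAT, self.clusters)
        found = {(h.chrom, h.start, h.strand) for h in scan_genome(genome, PAT)}
        planted = {(h.chrom, h.start, h.strand) for h in truth.planted_hits}
        assert planted <= found

    def test_fasta_determinism(self):
        cfg = GenomeSimConfig(chrom_lengths=self.chroms, scrub_background=True, seed=5)
        g1, _ = generate_genome(cfg, PAT, self.clusters)
        g2, _ = generate_genome(cfg, PAT, self.clusters)
        assert g1 == g2

    def test_planted_sites_never_overlap(self):
        cfg = GenomeSimConfig(chrom_lengths={"chr1": 20_000}, background_rate=2e-3,
                              cluster_fold=1.0, seed=2)
        _, truth = generate_genome(cfg, PAT, [])
        spans = sorted((h.chrom, h.start, h.end) for h in truth.planted_hits)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or s2 >= e1

    def test_promoter_planting_places_exact_number(self):
        promoters = [Interval("chr1", 30_000, 31_000, name="p1")]
        cfg = GenomeSimConfig(chrom_lengths=self.chroms, background_rate=0.0,
                              scrub_background=True, seed=4)
        genome, truth = generate_genome(
            cfg, PAT, self.clusters, promoter_intervals=promoters, motifs_per_promoter=2
        )
        inside = [h for h in truth.planted_hits if 30_000 <= h.start and h.end <= 31_000]
        assert len(inside) == 2
        assert len(scan_genome(genome, PAT)) == 2

    def test_pattern_longer_than_chromosome_rejected(self):
        cfg = GenomeSimConfig(chrom_lengths={"c": 4}, seed=0)
        with pytest.raises(ValueError):
            generate_genome(cfg, PAT, [])

    def test_cluster_outside_bounds_rejected(self):
        cfg = GenomeSimConfig(chrom_lengths={"c": 1000}, seed=0)
        with pytest.raises(ValueError):
            generate_genome(cfg, PAT, [Interval("c", 500, 2000)])


class TestGenerateGeneAnnotation:
    def test_genes_avoid_blocks_and_fit(self):
        chroms = {"chr1": 100_000}
        avoid = [Interval("chr1", 40_000, 60_000)]
        genes = generate_gene_annotation(chroms, [f"g{i}" for i in range(10)],
                                         avoid=avoid, seed=1)
        assert len(genes) == 10
        for g in genes:
            assert g.end <= 100_000
            assert g.end <= 40_000 or g.start >= 60_000

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_annotation({"c": 10_000}, [f"g{i}" for i in range(50)])


class TestGeneratePeakset:
    def _setup(self, seed=0):
        chroms = {"chr1": 120_000}
        genes = generate_gene_annotation(chroms, [f"g{i}" for i in range(8)], seed=seed)
        targets = [g.gene_id for g in genes[:3]]
        by_id = {g.gene_id: g for g in genes}
        from pirnareg.intervals import promoter_window

        promoters = [promoter_window(by_id[t], 500, 120_000) for t in targets]
        cfg = GenomeSimConfig(chrom_lengths=chroms, background_rate=0.0,
                              scrub_background=True, seed=seed)
        genome, truth = generate_genome(cfg, PAT, [], promoter_intervals=promoters)
        return chroms, genes, targets, truth

    def test_target_summits_inside_promoters(self):
        chroms, genes, targets, truth = self._setup()
        peaks = generate_peakset(genes, targets, truth, n_decoys=0,
                                 chrom_lengths=chroms)
        by_id = {g.gene_id: g for g in genes}
        for t, p in zip(targets, peaks):
            assert abs(p.summit - by_id[t].tss) <= 500

    def test_target_peaks_annotate_as_promoter(self):
        chroms, genes, targets, truth = self._setup()
        peaks = generate_peakset(genes, targets, truth, n_decoys=0,
                                 chrom_lengths=chroms)
        for p in peaks:
            cat, _ = annotate_peak(p, genes, promoter_bp=1000)
            assert cat == "promoter"

    def test_decoys_fall_outside_promoters(self):
        chroms, genes, targets, truth = self._setup()
        peaks = generate_peakset(genes, targets, truth, n_decoys=10,
                                 seed=3, chrom_lengths=chroms)
        decoys = [p for p in peaks if p.name.startswith("decoy")]
        assert len(decoys) == 10
        for p in decoys:
            cat, _ = annotate_peak(p, genes, promoter_bp=1000)
            assert cat != "promoter"

    def test_motifless_target_promoter_rejected(self):
        chroms, genes, targets, truth = self._setup()
        truth.planted_hits = []
        with pytest.raises(ValueError, match="planted motif"):
            generate_peakset(genes, targets, truth, chrom_lengths=chroms)


class TestGenerateSignalTrack:
    peaks = [
        # two overlapping peaks must merge
        Peak("chr1", 1000, 2000, name="a", summit_offset=500),
        Peak("chr1", 1500, 2500, name="b", summit_offset=500),
    ]

    def test_inside_peak_equals_height(self):
        t = generate_signal_track(self.peaks, 4.0, 1.0, {"chr1": 10_000})
        assert mean_signal_in_window(t, Interval("chr1", 1200, 1800)) == 4.0

    def test_outside_peak_equals_background(self):
        t = generate_signal_track(self.peaks, 4.0, 1.0, {"chr1": 10_000})
        assert mean_signal_in_window(t, Interval("chr1", 5000, 6000)) == 1.0

    def test_half_in_half_out(self):
        t = generate_signal_track(self.peaks, 4.0, 1.0, {"chr1": 10_000})
        assert mean_signal_in_window(t, Interval("chr1", 500, 1500)) == 2.5

    def test_height_not_above_background_rejected(self):
        with pytest.raises(ValueError):
            generate_signal_track(self.peaks, 1.0, 1.0, {"chr1": 10_000})


class TestTileClusters:
    def test_deterministic_and_in_bounds(self):
        chroms = {"chr1": 200_000, "chr2": 200_000}
        a = tile_clusters(chroms, 4, 10_000)
        b = tile_clusters(chroms, 4, 10_000)
        assert a == b and len(a) == 8
        for iv in a:
            assert 0 <= iv.start < iv.end <= 200_000
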