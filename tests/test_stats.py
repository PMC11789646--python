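"""Enrichment statistics: exact rank tests against enumeration oracles
and scipy, background sampling invariants, paired enrichment and
promoter contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

from pirnareg.intervals import GeneModel, Interval, SignalTrack
from pirnareg.motifs import MotifPattern
from pirnareg.simulate import GenomeSimConfig, generate_genome
from pirnareg.stats import (
    mann_whitney_u,
    motif_enrichment,
    paired_enrichment,
    promoter_motif_contrast,
    promoter_signal_contrast,
    sample_background,
    wilcoxon_signed_rank,
)
from conftest import enumerate_mannwhitney_p, enumerate_signed_rank_p


class TestWilcoxonSignedRank:
    def test_all_positive_three(self):
        res = wilcoxon_signed_rank([1, 2, 3], "greater")
        assert res.statistic == 6.0 and res.p == pytest.approx(1 / 8)
        assert res.method == "exact"

    def test_mixed_signs(self):
        res = wilcoxon_signed_rank([1, -2, 3], "greater")
        assert res.statistic == 4.0 and res.p == pytest.approx(3 / 8)

    def test_all_negative_one_sided(self):
        assert wilcoxon_signed_rank([-1, -2, -3], "greater").p >= 0.5

    def test_zeros_discarded(self):
        a = wilcoxon_signed_rank([0, 1, 2, 3, 0], "greater")
        b = wilcoxon_signed_rank([1, 2, 3], "greater")
        assert a.p == b.p and a.n == 3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(20):
            d = rng.integers(-4, 5, size=7).astype(float)
            if np.all(d == 0):
                continue
            for alt in ("greater", "less", "two-sided"):
                assert wilcoxon_signed_rank(d, alt).p == pytest.approx(
                    enumerate_signed_rank_p(d, alt)
                )

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            d = rng.normal(size=12)
            ours = wilcoxon_signed_rank(d, "greater")
            ref = sps.wilcoxon(d, alternative="greater", method="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self, rng):
        d = rng.normal(0.3, 1, size=60)
        ours = wilcoxon_signed_rank(d, "greater")
        ref = sps.wilcoxon(d, alternative="greater", method="approx", correction=True)
        assert ours.method == "normal-approx"
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitneyU:
    def test_separated_groups(self):
        res = mann_whitney_u([4, 5, 6], [1, 2, 3], "greater")
        assert res.statistic == 9.0 and res.p == pytest.approx(1 / 20)
        assert res.method == "exact"

    def test_identical_groups_one_sided(self):
        assert mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater").p >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_label_swap_identity(self, rng):
        for _ in range(10):
            a = rng.permutation(np.arange(1.0, 9.0))[:4]
            b = rng.permutation(np.arange(9.0, 20.0))[:5]
            assert mann_whitney_u(a, b, "less").p == pytest.approx(
                enumerate_mannwhitney_p(b, a, "greater")
            )
            assert mann_whitney_u(b, a, "greater").p == pytest.approx(
                enumerate_mannwhitney_p(b, a, "greater")
            )

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1, size=8)
            ours = mann_whitney_u(a, b, "greater")
            ref = sps.mannwhitneyu(a, b, alternative="greater", method="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_data_uses_approximation_matching_scipy(self, rng):
        a = rng.integers(0, 4, size=15).astype(float)
        b = rng.integers(1, 5, size=18).astype(float)
        ours = mann_whitney_u(a, b, "greater")
        ref = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        assert ours.method == "normal-approx"
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


GENOME = {
    "chr1": "ACGT" * 5000,   # 20 kb
    "chr2": "TTGA" * 5000,
}


class TestSampleBackground:
    source = [Interval("chr1", 1000, 2000, name="s1"), Interval("chr1", 5000, 5500, name="s2")]

    def test_k_zero_gives_empty(self):
        draws = sample_background(GENOME, self.source, 0, seed=1)
        assert draws == [[], []]

    def test_lengths_match_paired_source(self):
        draws = sample_background(GENOME, self.source, 5, seed=1)
        for src, ds in zip(self.source, draws):
            assert all(len(d) == len(src) for d in ds)

    def test_no_overlap_with_source_set(self):
        draws = sample_background(GENOME, self.source, 8, seed=2)
        for ds in draws:
            for d in ds:
                for src in self.source:
                    assert not (
                        d.chrom == src.chrom and d.start < src.end and src.start < d.end
                    )

    def test_deterministic_under_seed(self):
        a = sample_background(GENOME, self.source, 4, seed=7)
        b = sample_background(GENOME, self.source, 4, seed=7)
        assert a == b

    def test_removing_interval_preserves_other_draws(self):
        both = sample_background(GENOME, self.source, 4, seed=7)
        only_second = sample_background(
            GENOME, [self.source[1]], 4, seed=7, exclusions=[self.source[0]]
        )
        assert both[1] == only_second[0]

    def test_n_runs_excluded(self):
        genome = {"chr1": "A" * 2000 + "N" * 500 + "C" * 2000}
        src = [Interval("chr1", 0, 100, name="s")]
        draws = sample_background(genome, src, 20, seed=3)
        for d in draws[0]:
            assert not (d.start < 2500 and 2000 < d.end)


class TestPairedEnrichment:
    def test_uniform_2p5_fold(self):
        res = paired_enrichment([5, 5, 5, 5, 5], [2, 2, 2, 2, 2], "greater")
        assert res.fold == pytest.approx(2.5)
        assert res.statistic == 15.0
        assert res.p == pytest.approx(1 / 32)
        assert res.method == "exact"

    def test_zero_background_mean_flags_infinite(self):
        res = paired_enrichment([1, 2, 3], [0, 0, 0])
        assert np.isinf(res.fold)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_enrichment([1, 2], [1, 2, 3])


class TestMotifEnrichment:
    def test_planted_enrichment_detected(self):
        chroms = {f"chr{i}": 100_000 for i in range(1, 4)}
        clusters = [
            Interval(c, 20_000, 30_000, name=f"cl_{c}") for c in sorted(chroms)
        ] + [Interval(c, 60_000, 70_000, name=f"cl2_{c}") for c in sorted(chroms)]
        cfg = GenomeSimConfig(
            chrom_lengths=chroms, background_rate=1e-4, cluster_fold=3.0,
            scrub_background=True, seed=11,
        )
        genome, _ = generate_genome(cfg, MotifPattern("CCGTTA"), clusters)
        res = motif_enrichment(genome, clusters, MotifPattern("CCGTTA"), k=10, seed=11)
        assert res.n == 6
        assert res.fold > 1.5
        assert res.p < 0.2  # small n; direction must at least be right

    def test_empty_interval_set_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(GENOME, [], MotifPattern("CCGTTA"))


def _gene_layout():
    genes = {}
    for i in range(6):
        gid = f"ga{i}" if i < 3 else f"gb{i - 3}"
        genes[gid] = GeneModel(gid, "chr1", 2000 + 4000 * i, 4000 + 4000 * i, "+")
    return genes


class TestPromoterContrasts:
    def test_signal_only_on_group_a_promoters(self):
        genes = _gene_layout()
        steps = []
        for h, gid in zip((2.0, 3.0, 4.0), ("ga0", "ga1", "ga2")):
            tss = genes[gid].tss
            steps.append((tss - 500, tss + 500, h))
        track = SignalTrack({"chr1": sorted(steps)})
        res = promoter_signal_contrast(
            track, ["ga0", "ga1", "ga2"], ["gb0", "gb1", "gb2"], genes, flank=500
        )
        assert res.infinite_fold
        assert res.p < 0.05  # fully separated groups

    def test_identical_groups_fold_one(self):
        genes = _gene_layout()
        track = SignalTrack({"chr1": [(0, 30_000, 2.0)]})
        res = promoter_signal_contrast(track, ["ga0", "ga1"], ["ga0", "ga1"], genes, flank=500)
        assert res.fold == pytest.approx(1.0)

    def test_missing_gene_rejected(self):
        genes = _gene_layout()
        track = SignalTrack({"chr1": [(0, 30_000, 1.0)]})
        with pytest.raises(ValueError, match="ghost"):
            promoter_signal_contrast(track, ["ghost"], ["ga0"], genes)

    def test_motif_counts_exact_on_constructed_genome(self):
        from pirnareg.motifs import count_in_intervals
        from pirnareg.intervals import promoter_window

        genes = _gene_layout()
        seq = ["T"] * 30_000
        for gid in ("ga0", "ga1", "ga2"):
            tss = genes[gid].tss
            for shift in (-200, 200):
                pos = tss + shift
                seq[pos : pos + 6] = list("CCGTTA")
        genome = {"chr1": "".join(seq)}
        wa = [promoter_window(genes[g], 500) for g in ("ga0", "ga1", "ga2")]
        wb = [promoter_window(genes[g], 500) for g in ("gb0", "gb1", "gb2")]
        ca, _ = count_in_intervals(genome, wa, MotifPattern("CCGTTA"))
        cb, _ = count_in_intervals(genome, wb, MotifPattern("CCGTTA"))
        assert ca.tolist() == [2, 2, 2] and cb.tolist() == [0, 0, 0]
        res = promoter_motif_contrast(
            genome, MotifPattern("CCGTTA"),
            ["ga0", "ga1", "ga2"], ["gb0", "gb1", "gb2"], genes, flank=500,
        )
        assert res.infinite_fold  # B promoters contain no motif at all
        assert res.p < 0.1
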