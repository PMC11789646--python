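"""Test motif-density enrichment at piRNA clusters vs genomic background.

Plants CCGTTA at 2.5-fold elevated density inside 20 clusters of 10 kb
on a 1 Mb genome, then compares each cluster's per-10 kb motif density
with the mean density of 10 length-matched background intervals using
a one-sided Wilcoxon signed-rank test.
"""

from pirnareg import (
    GenomeSimConfig,
    MotifPattern,
    generate_genome,
    motif_enrichment,
    tile_clusters,
)

pattern = MotifPattern("CCGTTA")
chrom_lengths = {f"chr{i}": 200_000 for i in range(1, 6)}
clusters = tile_clusters(chrom_lengths, 4, 10_000)
cfg = GenomeSimConfig(
    chrom_lengths=chrom_lengths, background_rate=1e-4,
    cluster_fold=2.5, scrub_background=True, seed=9,
)
genome, _ = generate_genome(cfg, pattern, clusters)

res = motif_enrichment(genome, clusters, pattern, k=10, seed=9)
print(f"clusters tested      : {res.n}")
print(f"mean cluster density : {res.cluster_densities.mean():.2f} per 10 kb")
print(f"mean background      : {res.background_densities.mean():.2f} per 10 kb")
print(f"fold enrichment      : {res.fold:.2f}")
print(f"signed-rank W+       : {res.statistic:.0f}   p = {res.p:.2e} ({res.method})")

# The fold estimate should recover the planted 2.5x density ratio and
# the one-sided p-value should fall well below 0.05.
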