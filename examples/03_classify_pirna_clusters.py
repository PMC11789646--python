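"""Quantify, classify and rank piRNA clusters from small-RNA counts.

Generates ovary and testis small-RNA count tables for eight clusters
with known expression classes, computes RPKM in each tissue, applies
the strict >1 RPKM expression rule, and ranks the ovary-expressed
clusters by RPKM with their read fractions.
"""

from pirnareg import Interval, generate_smallrna_counts, rank_and_fraction

clusters = [Interval("chr1", i * 20_000, i * 20_000 + 8_000, name=f"cl{i+1}")
            for i in range(8)]
classes = {"cl1": "ovary", "cl2": "ovary", "cl3": "shared", "cl4": "testis",
           "cl5": "silent", "cl6": "ovary", "cl7": "shared", "cl8": "silent"}
ovary, testis, truth = generate_smallrna_counts(clusters, classes, seed=2)

ranked = rank_and_fraction(ovary, testis, threshold=1.0, tissue="ovary")
print(f"{'cluster':<9}{'rpkm_ov':>9}{'rpkm_te':>9}  {'class':<16}{'fraction':>9}{'rank':>6}")
for r in ranked:
    print(f"{r.cluster_id:<9}{r.rpkm_ovary:>9.2f}{r.rpkm_testis:>9.2f}  "
          f"{r.cluster_class:<16}{r.fraction:>9.3f}{r.rank:>6}")

# Only clusters with ovary RPKM > 1 appear; fractions are each
# cluster's share of ovary reads over the expressed set and sum to 1.
# Testis-only and silent clusters are excluded by the expression rule.
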