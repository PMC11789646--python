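# pirnareg

Regulatory genomics of the ovarian germline piRNA pathway.

The piRNA pathway silences transposons in animal gonads, and its
germline-specific arm (in the fly ovary: *aub*, *vas*, *ago3* and
their partners) is switched on by ovary-specific transcription
factors of the Ovo/OVOL family, which bind short conserved CCGTTA
(more degenerately CNGTTA) promoter motifs.  `pirnareg` implements the
computational chain used to discover and validate such a regulator and
its motif, as a tested, reusable library:

* **TF coexpression ranking** — given a gene×cell count matrix, rank
  every flagged DNA-binding TF by its average Pearson *r* with a seed
  module of pathway genes, with a conservative per-TF p-value
  (the least significant seed-gene correlation, t-transform
  `t = r·√((n−2)/(1−r²))`) adjusted by Bonferroni over all
  (TF, seed gene) tests.
* **IUPAC motif scanning** — exact consensus matching of both strands,
  overlapping occurrences included, with per-interval counts (full
  containment) and densities per 10 kb.
* **Peak/promoter integration** — strand-aware promoter windows
  (±flank of the TSS), summit-to-TSS peak annotation
  (promoter / genic / upstream / downstream / distal), open/closed
  chromatin partition against accessibility intervals, and windowed
  means over piecewise-constant coverage tracks.
* **piRNA cluster quantification** — RPKM per cluster and tissue,
  the strict “> 1 RPKM” expression rule yielding ovary-specific /
  testis-specific / shared / unexpressed classes, ranking and read
  fractions.
* **Enrichment statistics** — motif density of an interval set versus
  *k* length-matched, exclusion-aware background draws per interval
  (paired by mean), tested with a one-sided Wilcoxon signed-rank test
  (exact by dynamic programming up to 25 nonzero pairs, tie-corrected
  normal approximation beyond); Mann–Whitney U (exact for small untied
  samples) for two-group promoter signal and motif-count contrasts.
* **Synthetic data with planted ground truth** — every input the
  pipeline consumes can be generated with known answers: a germline
  subpopulation whose latent program drives one planted TF and the
  seed module (negative-binomial counts), genomes with motifs planted
  at known positions and elevated cluster density, peaks with summits
  on planted promoter motifs, class-realising small-RNA count tables,
  and step-function coverage tracks.

Everything runs on a desk-scale synthetic genome in seconds; no
downloads are required.

## Worked example

```python
from pirnareg import ScSimConfig, generate_sc_counts, rank_tfs

matrix, truth = generate_sc_counts(ScSimConfig(seed=1))
ranked, excluded = rank_tfs(matrix, truth.seed_gene_ids)
for r in ranked[:3]:
    print(r.tf_id, round(r.mean_r, 3), f"{r.p_adj:.2e}", r.rank)
```

prints

```
tf001 0.404 2.25e-33 1
tf009 0.023 1.00e+00 2
tf037 0.006 1.00e+00 3
```

`tf001` is the planted regulator: it shares a latent germline program
with the five seed genes, so its average Pearson *r* (0.404 across
1000 cells) dwarfs the decoy TFs and its Bonferroni-adjusted p-value
is vanishingly small.  The same recovery works end to end:

```sh
python examples/04_motif_enrichment.py
```

```
clusters tested      : 20
mean cluster density : 4.95 per 10 kb
mean background      : 2.00 per 10 kb
fold enrichment      : 2.48
signed-rank W+       : 208   p = 3.81e-06 (exact)
```

Here CCGTTA was planted at 2.5-fold elevated density inside 20 piRNA
clusters of 10 kb; the paired signed-rank test against length-matched
genomic background recovers the fold (2.48) and rejects the null.
The other scripts in `examples/` cover motif scanning, cluster
classification and the full pipeline; `pirnareg --help` exposes the
same stages as a CLI (`simulate`, `rank-tfs`, `scan`, `annotate`,
`clusters`, `enrich`, `accounting`, `run-all`).

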