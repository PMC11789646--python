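# Methods

This note documents the models, statistics and design choices behind
`pirnareg`, and what the synthetic-data tests do and do not establish
about real data.

## The analysis chain

The package reproduces a regulator-discovery workflow for the ovarian
germline piRNA pathway: (1) rank candidate transcription factors by
coexpression with a seed module of pathway genes in single-cell
expression data; (2) locate the candidate's consensus binding motif
across a genome; (3) integrate binding peaks with promoters and
chromatin accessibility; (4) quantify and classify piRNA clusters from
ovary/testis small-RNA counts; (5) test whether the motif is enriched
in ovary piRNA clusters relative to genomic background, and whether
promoter binding signal and motif counts are elevated at responsive
genes.

## Coexpression ranking

Counts are log-normalised per cell, `log(1 + s·c/total)` with scale
`s = 10⁴` — a deliberately simple, dependency-free transform (the
variance-stabilising transforms used by single-cell toolkits are out
of scope; correlations are rank-dominated and robust to this choice).
For each flagged TF detected in at least `min_detect_frac` (default
0.01) of the chosen cell subset, the score is the mean Pearson *r*
against the seed genes.  Three decisions were genuinely open and are
resolved as follows:

* **Correlation test.** The two-sided t-transform
  `t = r·√((n−2)/(1−r²))` on `n−2` degrees of freedom.  A permutation
  oracle at small *n* confirms it preserves the ranking of evidence.
* **Combining seed genes into one TF-level p.** The *maximum*
  per-seed-gene p-value (the least significant seed gene).  This is
  conservative: a TF is only called significant when it correlates
  with the entire module, not with one member.
* **Multiplicity.** Bonferroni with `m = (#tested TFs)·(#seed genes)`,
  counting every correlation actually computed.

Ties in mean *r* break by adjusted p, then lexicographic id, so the
ranking is a deterministic total order.  TFs excluded by detection or
zero variance are reported with the reason rather than scored zero.

## Motif scanning

Patterns are IUPAC consensus strings matched exactly, position by
position, on both strands; minus-strand hits are offsets where the
window matches the reverse-complemented pattern, reported in
plus-strand coordinates.  Position-weight-matrix scoring is not
implemented: the motifs in scope are short consensus strings and all
downstream claims are count-based.  Conventions chosen where practice
varies:

* a genome `N` matches nothing, including pattern `N`, so gap-rich
  assemblies cannot inflate counts;
* overlapping occurrences are all counted (CCGTTA cannot self-overlap
  on one strand, but degenerate patterns can);
* a hit is attributed to an interval only if the full match lies
  inside it, and duplicate (chrom, start, strand) hits count once.

Density is hits·10⁴/length (“per 10 kb”), additive over abutting
intervals.

## Interval conventions

All coordinates are 0-based, half-open (BED); 1-based inputs are not
accepted.  The TSS of a minus-strand gene is `end − 1`.  Promoter
windows are `[TSS − flank, TSS + flank)` clipped to the chromosome, so
they always contain the TSS.  Peak annotation measures the signed
summit-to-TSS distance (negative = upstream in gene orientation) to
the nearest TSS: `promoter` within ±1 kb by default, else `genic`
when the summit lies in a gene body, else `distal_intergenic` beyond
10 kb, else `upstream`/`downstream`.  Whether distance should anchor
at the summit or the peak edge is a convention, not a fact; the summit
is used throughout.  A peak is `open` chromatin iff it shares ≥1 bp
with any accessibility interval.

## Cluster quantification

RPKM is `C/((L/10³)·(N/10⁶))` for `C` reads in a cluster of `L` bp
against library size `N` (multimapping means `C ≤ N` is not assumed).
A cluster is expressed in a tissue iff RPKM is **strictly** greater
than the threshold (default 1), giving the four classes
ovary-specific / testis-specific / shared / unexpressed.  Read
fractions are computed over clusters passing the rule in the ranked
tissue — i.e. the denominator is cluster-mapping reads of the
expressed set, the one unambiguous choice available without read-level
data; it is configurable by construction (pass a different table).

## Enrichment statistics

**Background model.**  For each query interval, `k = 10` background
intervals of identical length are drawn uniformly over the genome,
rejecting draws that overlap the query set, runs of ≥100 `N`, or any
extra exclusions.  Each query is paired with the *mean* density of its
own draws; the random stream of each query interval is derived from
(seed, its coordinates), so removing one interval never perturbs
another's background.  Uniform length-matched sampling (rather than
GC- or chromatin-matched) is the declared model; the synthetic genome
is compositionally homogeneous, so matching on composition would be
vacuous there anyway.

**Wilcoxon signed-rank.**  Zero differences are discarded; |diffs| get
average ranks under ties; the statistic is W⁺.  For up to
`exact_limit = 25` nonzero pairs the p-value is exact, computed by a
count-by-sum dynamic program over the doubled (hence integral) ranks —
equivalent to enumerating all 2ⁿ sign assignments without the 2ⁿ cost.
Beyond that, a normal approximation with tie-corrected variance
(`−Σ(t³−t)/48`) and continuity correction 0.5 is used.  Enrichment
tests are one-sided (“greater”) by default, matching the directional
claim being made; two-sided is available.

**Mann–Whitney U.**  Average ranks under ties; exact p by a rank-sum
dynamic program over all C(n₁+n₂, n₁) orderings when the smaller group
has ≤10 observations and there are no ties, else the tie-corrected
normal approximation.  The group-contrast test (promoter signal and
motif counts between gene sets) is Mann–Whitney by decision — the
contrasts are between small, skewed samples — and the output records
the test name so results are self-describing.

Fold is the ratio of group/interval means; a zero denominator with a
positive numerator is flagged as infinite rather than silently
clamped.

## Synthetic data: what it emulates

The generators realise the study conditions the pipeline is meant to
detect, with recorded ground truth; all are pure functions of
(config, root seed), with per-generator streams derived from fixed
labels so adding a generator never shifts another's output.

**Single-cell counts.**  Germ cells draw a latent program activity
`a_c ~ Gamma(shape 2, scale 0.5)` (positive, graded — a crude stand-in
for progression through oogenesis); soma cells have `a_c = 0`.  Gene
means are `s_c · base_g · exp(loading_g · a_c)` with
`s_c ~ LogNormal(0, 0.3)` size factors, `base_g ~ Uniform(2, 10)`
(well-detected, marker-grade genes — chosen once so the planted
correlation is clearly resolvable, mirroring studies where the
regulator's coexpression is strong), and `loading_g = 0.8` on exactly
one planted TF and the seed module.  Counts are negative binomial with
dispersion φ = 0.1 (variance μ + φμ²; φ = 0 gives Poisson).  Defaults:
300 germ + 700 soma cells, 200 genes of which 40 TFs and 5 seed genes.

**Genome.**  I.i.d. nucleotides at GC 0.42; motif instances planted at
Poisson counts — rate 10⁻⁴ per bp per strand outside clusters,
`cluster_fold` (default 2.5) times that inside; overlapping planted
sites are re-drawn, never truncated, so each site's identity is
testable.  With `scrub_background`, chance occurrences of the pattern
outside planted sites are iteratively resampled away, making
scan = truth exact; patterns whose every realisation is
self-reverse-complementary cannot be scrubbed and raise.  Target-gene
promoters can additionally receive a fixed number of planted motifs,
which the peak generator requires.

**Peaks, tracks, small-RNA tables.**  One peak per target gene with
its summit on a planted promoter motif plus uniform intergenic decoys;
coverage tracks are piecewise constant (`height` over merged peak
spans, `background` elsewhere); small-RNA counts are Poisson draws
re-drawn (≤1000 times) until the realized RPKM respects the requested
class under the strict >1 rule, with expressed clusters targeting
RPKM uniform in (5, 50) and silent ones 0.2.

**What passing tests do not show.**  The simulations have no ambient
RNA, doublets, batch effects, read-level error, nucleotide composition
beyond i.i.d. GC, GC-biased backgrounds, or correlated decoy programs.
Recovery and calibration results therefore validate the *statistics
and bookkeeping* — that the pipeline finds exactly what was planted
and rejects at nominal rates when nothing is — not robustness to the
confounders of real ovary data.

## Calibration and power (measured, not assumed)

At the reference enrichment conditions (five 200 kb chromosomes,
twenty 10 kb clusters, ~2 planted motifs per 10 kb of background,
scrubbed), the one-sided signed-rank test detects a planted 2.5-fold
density at p < 0.05 in ≥ 90% of replicates with mean estimated fold
≈ 2.5, and rejects in ~4–6% of replicates when the planted fold is
1.0.  The paired difference (cluster − mean of 10 backgrounds) is not
exactly symmetric under the null (Poisson skew against a near-normal
background mean), but at n = 20 the empirical size stays within the
nominal band.  Problem sizes throughout (1 Mb genomes, 1000-cell
matrices, 20-replicate recovery runs) were chosen so the whole suite
runs on a laptop-class single core in about two minutes.

## Numerical details and degenerate inputs

* Correlations clip to [−1, 1] against rounding; |r| = 1 maps to the
  smallest positive double rather than 0.
* Zero-variance vectors raise a dedicated error; callers exclude the
  gene and report why.
* A cell with zero total counts is an error naming the cell.
* Bonferroni caps at 1; adjusted p is never below raw p.
* Background sampling gives up with an error after 10⁴ rejected draws
  per interval; class-realising count draws after 1000.
* All tabular outputs have fixed column orders, and the pipeline
  manifest (config echo + seed + conventions) suffices to reproduce a
  run bit for bit.

## Known limitations

* Exact IUPAC matching cannot express graded motif affinity; a PWM
  scanner would be needed for that.
* The conservative max-p combination can under-rank a TF that drives
  only part of the seed module.
* The uniform background model ignores composition and accessibility;
  on real genomes a matched background is often preferable.
* Cluster read fractions depend on the annotated cluster set; they are
  not fractions of all mapped reads.
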