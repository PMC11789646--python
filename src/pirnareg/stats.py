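"""Comparative statistics for motif and signal enrichment.

Two nonparametric tests are implemented from first principles because
their exact small-sample behaviour is part of the contract:

* a Wilcoxon signed-rank test on paired density differences, exact by
  dynamic programming over rank sums for up to ``exact_limit`` nonzero
  pairs, with the tie-corrected normal approximation beyond;
* a Mann-Whitney U test for two-group contrasts, exact by enumeration
  (again a rank-sum DP) for small untied samples.

On top of these sit the domain operations: length-matched background
sampling over a genome, motif-density enrichment of an interval set
against its paired background, and promoter-level signal / motif-count
contrasts between gene sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from ._rng import stream
from .intervals import GeneModel, Interval, SignalTrack, mean_signal_in_window, overlaps, promoter_window
from .motifs import MotifHit, MotifPattern, count_in_intervals, motif_density, scan_genome

__all__ = [
    "TestResult",
    "EnrichmentResult",
    "ContrastResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "sample_background",
    "paired_enrichment",
    "motif_enrichment",
    "promoter_signal_contrast",
    "promoter_motif_contrast",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    alternative: str
    method: str  # "exact" | "normal-approx"


@dataclass(frozen=True)
class EnrichmentResult:
    """Paired density enrichment of an interval set vs background."""

    n: int
    cluster_densities: np.ndarray
    background_densities: np.ndarray
    fold: float
    statistic: float
    p: float
    alternative: str
    method: str


@dataclass(frozen=True)
class ContrastResult:
    """Two-group promoter-level contrast (fold of means + rank test)."""

    fold: float
    p: float
    test: str
    n_a: int
    n_b: int
    infinite_fold: bool = False


# ---------------------------------------------------------------------------
# Exact rank tests


def _subset_sum_counts(weights: Sequence[int]) -> np.ndarray:
    """counts[s] = number of subsets of ``weights`` with sum s (DP)."""
    total = int(sum(weights))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in weights:
        counts[w:] += counts[: total + 1 - w].copy()
    return counts


def wilcoxon_signed_rank(
    diffs: Sequence[float],
    alternative: str = "greater",
    exact_limit: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; |differences| are ranked with
    average ranks for ties; the statistic is W+ (sum of ranks of the
    positive differences).  For up to ``exact_limit`` nonzero pairs the
    p-value is exact over all 2^n sign assignments, computed by a
    count-by-sum dynamic program over the (doubled, hence integer)
    ranks.  Beyond that, a normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        # Doubling makes tied (half-integer) average ranks integral.
        weights = np.rint(2 * ranks).astype(int)
        counts = _subset_sum_counts(weights)
        total = 2.0 ** n
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(w_plus, float(p), n, alternative, "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - 0.5 - mean) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_plus + 0.5 - mean) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(w_plus - mean) - 0.5) / sd
        p = 2 * sps.norm.sf(z)
    return TestResult(w_plus, float(min(1.0, p)), n, alternative, "normal-approx")


def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of orderings with U statistic u (no ties)."""
    # Classic recurrence: choose n1 ranks out of 1..n1+n2; U = rank sum
    # of group 1 minus its minimum.  DP over ranks, bounded subset size.
    max_u = n1 * n2
    # f[k][u]: ways to pick k ranks with reduced sum u
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, n1 + n2 + 1):
        for k in range(min(n1, r), 0, -1):
            # adding rank r as the k-th smallest contributes r - k to U
            shift = r - k
            if shift > max_u:
                continue
            f[k, shift:] += f[k - 1, : max_u + 1 - shift]
    return f[n1]


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "greater",
    exact_limit: int = 10,
) -> TestResult:
    """Mann-Whitney U test on two independent samples.

    The statistic is U of group ``a`` with average ranks for ties.
    Exact p by enumeration over all C(n_a + n_b, n_a) orderings when the
    smaller group has at most ``exact_limit`` observations and there are
    no ties; otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < n1 + n2

    if min(n1, n2) <= exact_limit and not has_ties:
        counts = _u_distribution(n1, n2)
        total = counts.sum()
        u_int = int(round(u_a))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u_a, float(p), n1 + n2, alternative, "exact")

    N = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    sd = np.sqrt(var)
    if sd == 0:
        return TestResult(u_a, 1.0, N, alternative, "normal-approx")
    if alternative == "greater":
        p = sps.norm.sf((u_a - 0.5 - mean) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((u_a + 0.5 - mean) / sd)
    else:
        p = 2 * sps.norm.sf((abs(u_a - mean) - 0.5) / sd)
    return TestResult(u_a, float(min(1.0, p)), N, alternative, "normal-approx")


# ---------------------------------------------------------------------------
# Background sampling


def _n_runs(seq: str, min_len: int = 100) -> list[tuple[int, int]]:
    return [
        (m.start(), m.end())
        for m in re.finditer(r"N{%d,}" % min_len, seq.upper())
    ]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def sample_background(
    genome: Mapping[str, str],
    source: Sequence[Interval],
    k_per_interval: int,
    exclusions: Sequence[Interval] | None = None,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[list[Interval]]:
    """Length-matched background intervals, ``k`` per source interval.

    Draws are uniform over all genome positions admitting the interval
    length, rejecting any draw that overlaps the exclusion set (the
    source set itself plus runs of >=100 N, plus any extra exclusions).
    The random stream for each source interval is derived from
    ``(seed, its coordinates)``, so dropping one source interval leaves
    every other interval's draws unchanged.

    Returns a list parallel to ``source``; element ``i`` holds the k
    draws paired with source interval ``i``.
    """
    excl: list[Interval] = list(source)
    if exclusions:
        excl.extend(exclusions)
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in excl:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, seq in genome.items():
        for s, e in _n_runs(seq):
            excl_by_chrom.setdefault(chrom, []).append((s, e))
    excl_by_chrom = {c: _merge(v) for c, v in excl_by_chrom.items()}
    excl_arrays = {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in excl_by_chrom.items()
    }

    chrom_names = sorted(genome)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=np.int64)

    out: list[list[Interval]] = []
    for iv in source:
        L = len(iv)
        slots = np.clip(chrom_lens - L + 1, 0, None)
        if slots.sum() == 0:
            raise ValueError(f"no chromosome can host an interval of length {L}")
        probs = slots / slots.sum()
        rng = stream(seed, f"background:{iv.chrom}:{iv.start}-{iv.end}")
        draws: list[Interval] = []
        attempts = 0
        while len(draws) < k_per_interval:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"background sampling failed after {max_attempts} attempts "
                    f"for source {iv.chrom}:{iv.start}-{iv.end}"
                )
            ci = rng.choice(len(chrom_names), p=probs)
            chrom = chrom_names[ci]
            start = int(rng.integers(0, slots[ci]))
            end = start + L
            es, ee = excl_arrays.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            if len(es) and np.any((np.minimum(ee, end) - np.maximum(es, start)) > 0):
                continue
            draws.append(Interval(chrom, start, end, name=f"bg_{iv.name or iv.start}_{len(draws)}"))
        out.append(draws)
    return out


# ---------------------------------------------------------------------------
# Enrichment and contrasts


def paired_enrichment(
    cluster_densities: Sequence[float],
    background_densities: Sequence[float],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Signed-rank enrichment of paired per-interval densities.

    ``fold`` is the ratio of mean densities (inf when the background
    mean is zero but the cluster mean is not).
    """
    cd = np.asarray(cluster_densities, dtype=float)
    bd = np.asarray(background_densities, dtype=float)
    if cd.shape != bd.shape or cd.ndim != 1 or len(cd) == 0:
        raise ValueError("paired density vectors must be equal-length and non-empty")
    test = wilcoxon_signed_rank(cd - bd, alternative=alternative)
    bg_mean = bd.mean()
    if bg_mean > 0:
        fold = float(cd.mean() / bg_mean)
    else:
        fold = float("inf") if cd.mean() > 0 else float("nan")
    return EnrichmentResult(
        n=len(cd),
        cluster_densities=cd,
        background_densities=bd,
        fold=fold,
        statistic=test.statistic,
        p=test.p,
        alternative=alternative,
        method=test.method,
    )


def motif_enrichment(
    genome: Mapping[str, str],
    intervals: Sequence[Interval],
    pattern: MotifPattern,
    k: int = 10,
    seed: int = 0,
    alternative: str = "greater",
    hits: Sequence[MotifHit] | None = None,
) -> EnrichmentResult:
    """Motif-density enrichment of an interval set vs genomic background.

    Per interval: motif density (hits per 10 kb, full containment, both
    strands) is paired with the mean density over ``k`` length-matched
    background draws excluding the source set.  The paired differences
    feed a one-sided (by default) Wilcoxon signed-rank test.
    """
    if not intervals:
        raise ValueError("interval set is empty")
    if hits is None:
        hits = scan_genome(genome, pattern)
    counts, hits = count_in_intervals(genome, intervals, pattern, hits=hits)
    dens = np.array(
        [motif_density(c, len(iv)) for c, iv in zip(counts, intervals)]
    )
    bg_sets = sample_background(genome, intervals, k, seed=seed)
    bg_means = np.empty(len(intervals))
    for i, draws in enumerate(bg_sets):
        bg_counts, _ = count_in_intervals(genome, draws, pattern, hits=hits)
        bg_means[i] = float(
            np.mean([motif_density(c, len(d)) for c, d in zip(bg_counts, draws)])
        )
    return paired_enrichment(dens, bg_means, alternative=alternative)


def _resolve_promoters(
    gene_ids: Sequence[str],
    annotation: Mapping[str, GeneModel],
    flank: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Interval]:
    windows = []
    for g in gene_ids:
        if g not in annotation:
            raise ValueError(f"gene {g!r} missing from annotation")
        model = annotation[g]
        clen = chrom_lengths.get(model.chrom) if chrom_lengths else None
        windows.append(promoter_window(model, flank, clen))
    return windows


def promoter_signal_contrast(
    track: SignalTrack,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    annotation: Mapping[str, GeneModel],
    flank: int = 1000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ContrastResult:
    """Fold + rank-test contrast of mean promoter signal, A vs B."""
    wa = _resolve_promoters(genes_a, annotation, flank, chrom_lengths)
    wb = _resolve_promoters(genes_b, annotation, flank, chrom_lengths)
    va = np.array([mean_signal_in_window(track, w) for w in wa])
    vb = np.array([mean_signal_in_window(track, w) for w in wb])
    test = mann_whitney_u(va, vb, alternative="greater")
    mb = vb.mean()
    if mb > 0:
        return ContrastResult(float(va.mean() / mb), test.p, "mann-whitney", len(va), len(vb))
    return ContrastResult(float("inf"), test.p, "mann-whitney", len(va), len(vb), infinite_fold=True)


def promoter_motif_contrast(
    genome: Mapping[str, str],
    pattern: MotifPattern,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    annotation: Mapping[str, GeneModel],
    flank: int = 1000,
) -> ContrastResult:
    """Fold + rank-test contrast of promoter motif counts, A vs B."""
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    wa = _resolve_promoters(genes_a, annotation, flank, chrom_lengths)
    wb = _resolve_promoters(genes_b, annotation, flank, chrom_lengths)
    hits = scan_genome(genome, pattern)
    ca, _ = count_in_intervals(genome, wa, pattern, hits=hits)
    cb, _ = count_in_intervals(genome, wb, pattern, hits=hits)
    test = mann_whitney_u(ca.astype(float), cb.astype(float), alternative="greater")
    mb = cb.mean()
    if mb > 0:
        return ContrastResult(float(ca.mean() / mb), test.p, "mann-whitney", len(ca), len(cb))
    return ContrastResult(float("inf"), test.p, "mann-whitney", len(ca), len(cb), infinite_fold=True)
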