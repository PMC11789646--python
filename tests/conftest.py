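"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (per-position scans, all-pairs
overlap checks, full enumeration of sign patterns/orderings) so they
stay independent of the implementation paths they verify.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pirnareg.motifs import IUPAC, MotifPattern

# ---------------------------------------------------------------------------
# Brute-force oracles


def naive_scan(seq: str, pattern: MotifPattern) -> list[tuple[int, str]]:
    """Per-position IUPAC scan of both strands (O(n * |pattern|))."""
    seq = seq.upper()
    L = len(pattern)
    rc = pattern.reverse_complement()
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if "N" not in window:
            if all(b in IUPAC[c] for c, b in zip(pattern.symbols, window)):
                hits.append((off, "+"))
            if all(b in IUPAC[c] for c, b in zip(rc.symbols, window)):
                hits.append((off, "-"))
        else:
            # genome N never matches; check base by base anyway
            if all(b != "N" and b in IUPAC[c] for c, b in zip(pattern.symbols, window)):
                hits.append((off, "+"))
            if all(b != "N" and b in IUPAC[c] for c, b in zip(rc.symbols, window)):
                hits.append((off, "-"))
    return sorted(hits)


def brute_overlap(a, b, min_bp=1) -> bool:
    if a.chrom != b.chrom:
        return False
    shared = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    return shared >= min_bp


def enumerate_signed_rank_p(diffs, alternative="greater") -> float:
    """Exact signed-rank p by direct enumeration of all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    total = 2 ** n
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


def enumerate_mannwhitney_p(a, b, alternative="greater") -> float:
    """Exact Mann-Whitney p by enumeration of all group-label assignments."""
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    ge = le = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        ge += u >= u_obs - 1e-9
        le += u <= u_obs + 1e-9
        total += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated expression matrix with planted regulator."""
    from pirnareg.simulate import ScSimConfig, generate_sc_counts

    cfg = ScSimConfig(
        n_cells_germ=60, n_cells_soma=140, n_genes=50, n_tfs=10,
        n_seed_genes=3, seed=5,
    )
    return generate_sc_counts(cfg)
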