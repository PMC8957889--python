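"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive — exact rational arithmetic, explicit
loops, textbook formulas — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by full enumeration with rational arithmetic
# ---------------------------------------------------------------------------

def hwe_exact_bruteforce(n_hom1: int, n_het: int, n_hom2: int) -> float:
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        h1 = (n_a - h) // 2
        h2 = (n_b - h) // 2
        num = (
            Fraction(math.factorial(n), math.factorial(h1) * math.factorial(h) * math.factorial(h2))
            * Fraction(2) ** h
            * Fraction(math.factorial(n_a) * math.factorial(n_b), math.factorial(2 * n))
        )
        return num

    n_rare = min(n_a, n_b)
    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_het]
    total = sum(p for p in probs.values() if p <= p_obs)
    return float(min(Fraction(1), total))


# ---------------------------------------------------------------------------
# Per-site pi by explicit pairwise chromosome comparison
# ---------------------------------------------------------------------------

def pi_site_bruteforce(genotypes: np.ndarray) -> float:
    """Fraction of chromosome pairs differing at one site (0/1/2/-1 codes)."""
    alleles = []
    for g in genotypes:
        if g == MISSING:
            continue
        alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff += alleles[i] != alleles[j]
    return diff / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Tajima's D: a second, literal transliteration
# ---------------------------------------------------------------------------

def tajima_d_reference(pi_sum: float, n_segregating: int, n_chr: int) -> float:
    if n_segregating < 1 or n_chr < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n_chr))
    a2 = sum(1.0 / i**2 for i in range(1, n_chr))
    n = n_chr
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    S = n_segregating
    var = e1 * S + e2 * S * (S - 1)
    return (pi_sum - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components via nested-ANOVA sums of squares
# ---------------------------------------------------------------------------

def wc_site_anova(genotype_lists: list[np.ndarray]) -> tuple[float, float, float]:
    """Per-site (a, b, c) from the alleles-in-individuals-in-populations ANOVA.

    Method-of-moments on observed sums of squares — an algebraically
    different route than the closed-form frequency/heterozygosity formulas.
    Returns NaNs when any population has < 2 non-missing individuals.
    """
    pops = []
    for g in genotype_lists:
        g = np.asarray(g)
        g = g[g != MISSING]
        if len(g) < 2:
            return (float("nan"),) * 3
        pops.append(g)
    r = len(pops)
    n_i = np.array([len(g) for g in pops], dtype=float)
    N = n_i.sum()

    # allele indicator data: individual means are code/2
    ind_means = [g / 2.0 for g in pops]
    pop_means = np.array([im.mean() for im in ind_means])
    grand = sum(im.sum() for im in ind_means) / N

    ssg = sum(0.5 * (g == 1).sum() for g in pops)  # within-individual
    ssi = sum(2.0 * ((im - pm) ** 2).sum() for im, pm in zip(ind_means, pop_means))
    ssp = float((2.0 * n_i * (pop_means - grand) ** 2).sum())

    msg = ssg / N
    msi = ssi / (N - r)
    msp = ssp / (r - 1)
    n_c = (N - (n_i**2).sum() / N) / (r - 1)

    c = msg
    b = (msi - msg) / 2.0
    a = (msp - msi) / (2.0 * n_c)
    return float(a), float(b), float(c)


# ---------------------------------------------------------------------------
# OLS by the closed-form normal equations
# ---------------------------------------------------------------------------

def ols_closed_form(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(beta, se) via (X'X)^-1 X'y and the classical variance estimate."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return beta, se


# ---------------------------------------------------------------------------
# Exhaustive ROH scan implementing the window semantics with plain loops
# ---------------------------------------------------------------------------

def roh_bruteforce(
    genotypes, positions, *, window_snps, window_max_het, window_max_missing,
    window_hit_fraction, max_gap_bp, min_length_bp, min_snp_count,
    min_density_bp_per_snp,
) -> list[tuple[int, int, int]]:
    """Segments (start_bp, end_bp, n_snps) for one individual's chromosome."""
    g = list(genotypes)
    pos = list(positions)
    m = len(g)
    w = min(window_snps, m)
    n_win = m - w + 1
    qualifies = []
    for s in range(n_win):
        window = g[s : s + w]
        n_het = sum(1 for x in window if x == 1)
        n_mis = sum(1 for x in window if x == MISSING)
        qualifies.append(n_het <= window_max_het and n_mis <= window_max_missing)
    eligible = []
    for i in range(m):
        wins = [s for s in range(n_win) if s <= i <= s + w - 1]
        frac = sum(1 for s in wins if qualifies[s]) / len(wins)
        eligible.append(frac >= window_hit_fraction)
    # maximal runs, split on gaps, filter
    segments = []
    i = 0
    while i < m:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and eligible[j + 1]:
            j += 1
        pieces = []
        start = i
        for k in range(i, j):
            if pos[k + 1] - pos[k] > max_gap_bp:
                pieces.append((start, k))
                start = k + 1
        pieces.append((start, j))
        for a, b in pieces:
            n = b - a + 1
            length = pos[b] - pos[a] + 1
            if length < min_length_bp:
                continue
            if n < min_snp_count:
                continue
            if length / n > min_density_bp_per_snp:
                continue
            segments.append((int(pos[a]), int(pos[b]), n))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Quadratic all-pairs interval overlap
# ---------------------------------------------------------------------------

def overlap_bruteforce(query, subject) -> set[tuple]:
    """(q_idx, s_idx, overlap_bp) for every overlapping pair (1-based incl)."""
    hits = set()
    for qi, (qc, qs, qe) in enumerate(query):
        for si, (sc, ss, se) in enumerate(subject):
            if qc != sc:
                continue
            ov = min(qe, se) - max(qs, ss) + 1
            if ov >= 1:
                hits.add((qi, si, ov))
    return hits
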