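"""Windowed diversity and differentiation statistics, and LD-based Ne.

Windows are non-overlapping tiles of ``window_bp`` (default 500 kb) laid
along each chromosome from position 1; the step is exposed for sliding use.

* **pi** — per-site nucleotide diversity is the fraction of chromosome pairs
  differing at the site, ``c1*c2 / C(n,2)`` for allele counts ``c1, c2`` over
  ``n`` non-missing chromosomes; a window's pi is the per-site sum divided by
  the window span in bp.
* **Tajima's D** — the classical standardized difference between the
  pairwise-diversity and segregating-sites estimators of theta, with the
  usual a1..e2 constants.  With missing data the chromosome count ``n`` for a
  window's constants is the minimum non-missing count over member sites (the
  constants assume a single n).
* **FST** — Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals within populations), c (within
  individuals), estimated per site from sample sizes, allele frequencies and
  observed heterozygote frequencies; window and genome summaries are the
  ratio of sums ``sum(a) / sum(a+b+c)`` (a weighted, ratio-of-averages
  estimator), with the unweighted mean of window values also reported.
* **Ne** — from the decay of inter-marker LD: pairs of markers are binned by
  distance; with ``c`` the bin's midpoint distance in Morgans (1 Mb = 1 cM),
  ``t = 1/(2c)`` generations ago and
  ``Ne = (4c)^-1 (1/r2_adj - alpha)`` where ``r2_adj = mean r2 - 1/n``
  corrects the sampling bias of the unphased dosage correlation.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# Per-marker heterozygosity
# ---------------------------------------------------------------------------

def het_stats(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-marker Ho, He and MAF, plus unweighted genome means.

    Ho is the heterozygote fraction among non-missing calls; He = 2p(1-p)
    with p the sample allele frequency.  All-missing markers are excluded
    from the means.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    nm = (matrix.calls != MISSING).sum(axis=0)
    het = (matrix.calls == 1).sum(axis=0)
    p = matrix.allele2_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(nm > 0, het / nm, np.nan)
    he = 2.0 * p * (1.0 - p)
    maf = np.minimum(p, 1.0 - p)
    table = matrix.markers[["marker_id", "chrom", "pos_bp"]].copy()
    table["n_nonmissing"] = nm
    table["ho"] = ho
    table["he"] = he
    table["maf"] = maf
    ok = nm > 0
    means = {
        "ho_mean": float(np.nanmean(ho[ok])) if ok.any() else np.nan,
        "he_mean": float(np.nanmean(he[ok])) if ok.any() else np.nan,
        "maf_mean": float(np.nanmean(maf[ok])) if ok.any() else np.nan,
    }
    return table, means


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def assign_windows(pos_bp: np.ndarray, window_bp: int, step_bp: Optional[int] = None):
    """Yield (win_start_bp, win_end_bp, member_index_array) tiles over positions.

    Positions must be sorted.  With ``step_bp`` < ``window_bp`` windows
    overlap (sliding); default step equals the window size (tiling).
    """
    step = step_bp or window_bp
    if window_bp <= 0 or step <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    if len(pos_bp) == 0:
        return
    last = int(pos_bp[-1])
    start = 1
    while start <= last:
        end = start + window_bp - 1
        lo = np.searchsorted(pos_bp, start, side="left")
        hi = np.searchsorted(pos_bp, end, side="right")
        yield start, end, np.arange(lo, hi)
        start += step


def _per_site_pi(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pi and non-missing chromosome counts for a call block."""
    nm = (calls != MISSING).sum(axis=0)
    n_chr = 2 * nm
    dose = np.where(calls == MISSING, 0, calls).sum(axis=0)
    c2 = dose
    c1 = n_chr - dose
    pairs = n_chr * (n_chr - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, c1 * c2 / pairs, 0.0)
    return pi, n_chr


def windowed_pi(
    matrix: GenotypeMatrix, window_bp: int = 500_000, step_bp: Optional[int] = None
) -> pd.DataFrame:
    """Windowed nucleotide diversity (per-bp), tiled per chromosome.

    Windows without SNPs report pi = 0 (monomorphic assumption) and are
    flagged with ``n_snps = 0``.
    """
    rows = []
    for chrom, sub in matrix.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy()
        pi_site, _ = _per_site_pi(matrix.calls[:, idx])
        for w_start, w_end, members in assign_windows(pos, window_bp, step_bp):
            rows.append(
                {
                    "chrom": str(chrom),
                    "win_start_bp": w_start,
                    "win_end_bp": w_end,
                    "n_snps": len(members),
                    "pi": float(pi_site[members].sum()) / window_bp,
                }
            )
    return pd.DataFrame(rows)


def tajima_constants(n_chr: int) -> dict[str, float]:
    """Tajima's a1, a2, b1, b2, c1, c2, e1, e2 for n chromosomes."""
    if n_chr < 2:
        raise ValueError("need n_chr >= 2")
    n = float(n_chr)
    i = np.arange(1, n_chr)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_window(pi_sum: float, n_segregating: int, n_chr: int) -> float:
    """Tajima's D from summed per-site pi, segregating-site count and n.

    NaN when there are no segregating sites or fewer than 4 chromosomes.
    """
    if n_segregating < 1 or n_chr < 4:
        return float("nan")
    k = tajima_constants(n_chr)
    s = float(n_segregating)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


def windowed_tajima_d(
    matrix: GenotypeMatrix, window_bp: int = 500_000, step_bp: Optional[int] = None
) -> pd.DataFrame:
    """Windowed Tajima's D; missing where S = 0 or n_chr < 4.

    Per window, n_chr is the minimum non-missing chromosome count across the
    member sites that have any data — a conservative single-n choice, since
    the variance constants assume one sample size.
    """
    rows = []
    for chrom, sub in matrix.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy()
        block = matrix.calls[:, idx]
        pi_site, n_chr_site = _per_site_pi(block)
        seg = pi_site > 0
        for w_start, w_end, members in assign_windows(pos, window_bp, step_bp):
            with_data = members[n_chr_site[members] > 0]
            s = int(seg[members].sum())
            n_chr = int(n_chr_site[with_data].min()) if len(with_data) else 0
            d = tajima_d_from_window(float(pi_site[members].sum()), s, n_chr)
            rows.append(
                {
                    "chrom": str(chrom),
                    "win_start_bp": w_start,
                    "win_end_bp": w_end,
                    "n_snps": len(members),
                    "n_segregating": s,
                    "n_chr": n_chr,
                    "tajima_d": d,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_components(
    matrices: Sequence[GenotypeMatrix],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components (a, b, c).

    One matrix per population on identical marker maps.  Sites where any
    population has fewer than two non-missing samples get NaN components.
    """
    r = len(matrices)
    if r < 2:
        raise ValueError("need >= 2 populations")
    base = matrices[0].markers[["marker_id", "chrom", "pos_bp"]]
    for m in matrices[1:]:
        if not base.equals(m.markers[["marker_id", "chrom", "pos_bp"]]):
            raise ValueError("populations are on different marker maps")
    n_i = np.stack([(m.calls != MISSING).sum(axis=0) for m in matrices]).astype(float)
    p_i = np.stack([m.allele2_freq() for m in matrices])
    h_i = np.stack(
        [
            np.where(
                (m.calls != MISSING).sum(axis=0) > 0,
                (m.calls == 1).sum(axis=0) / np.maximum((m.calls != MISSING).sum(axis=0), 1),
                np.nan,
            )
            for m in matrices
        ]
    )
    valid = (n_i >= 2).all(axis=0)

    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def fst_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums FST over sites; NaN-component or zero-denominator sites drop."""
    ok = ~np.isnan(a)
    denom = (a + b + c)[ok]
    keep = denom != 0
    if not keep.any():
        return float("nan")
    return float(a[ok][keep].sum() / denom[keep].sum())


def windowed_fst(
    matrix_pop1: GenotypeMatrix,
    matrix_pop2: GenotypeMatrix,
    window_bp: int = 500_000,
    step_bp: Optional[int] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Windowed and genome-wide pairwise Weir-Cockerham FST.

    Returns the window frame plus a summary dict with the weighted
    (ratio-of-averages) genome estimate and the unweighted mean of windows.
    """
    a, b, c = wc_components([matrix_pop1, matrix_pop2])
    rows = []
    for chrom, sub in matrix_pop1.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy()
        for w_start, w_end, members in assign_windows(pos, window_bp, step_bp):
            sel = idx[members]
            rows.append(
                {
                    "chrom": str(chrom),
                    "win_start_bp": w_start,
                    "win_end_bp": w_end,
                    "n_snps": len(members),
                    "fst": fst_from_components(a[sel], b[sel], c[sel]),
                }
            )
    windows = pd.DataFrame(rows)
    summary = {
        "fst_weighted": fst_from_components(a, b, c),
        "fst_mean_of_windows": float(windows["fst"].mean(skipna=True))
        if len(windows)
        else float("nan"),
    }
    return windows, summary


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------

class NeEstimate(NamedTuple):
    bin_low_bp: int
    bin_high_bp: int
    n_pairs: int
    c_recomb: float  # Morgans, bin midpoint at 1 Mb = 1 cM
    t_generations: float
    mean_r2: float
    mean_r2_adj: float
    ne: float


def pairwise_r2(matrix: GenotypeMatrix, max_dist_bp: int) -> pd.DataFrame:
    """Genotype (dosage) r^2 for all same-chromosome marker pairs within range.

    Pairwise-complete over samples; pairs with < 3 complete samples or a
    monomorphic member are dropped.  Columns: chrom, dist_bp, r2.
    """
    out_d, out_r2 = [], []
    for chrom, sub in matrix.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos_bp"].to_numpy()
        g = matrix.calls[:, idx].astype(float)
        g[g == MISSING] = np.nan
        m = len(idx)
        for j in range(m - 1):
            hi = np.searchsorted(pos, pos[j] + max_dist_bp, side="right")
            if hi <= j + 1:
                continue
            x = g[:, j]
            block = g[:, j + 1 : hi]
            v = ~np.isnan(x)[:, None] & ~np.isnan(block)
            n = v.sum(axis=0)
            xv = np.where(v, x[:, None], 0.0)
            yv = np.where(v, block, 0.0)
            sx = xv.sum(axis=0)
            sy = yv.sum(axis=0)
            sxx = (xv**2).sum(axis=0)
            syy = (yv**2).sum(axis=0)
            sxy = (xv * yv).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / n
                varx = sxx - sx**2 / n
                vary = syy - sy**2 / n
                r2 = cov**2 / (varx * vary)
            ok = (n >= 3) & (varx > 0) & (vary > 0)
            out_d.append((pos[j + 1 : hi] - pos[j])[ok])
            out_r2.append(r2[ok])
    if not out_d:
        return pd.DataFrame(columns=["dist_bp", "r2"])
    return pd.DataFrame(
        {"dist_bp": np.concatenate(out_d), "r2": np.concatenate(out_r2)}
    )


def ne_ld(
    matrix: GenotypeMatrix,
    distance_bins_bp: Sequence[int],
    alpha_const: float = 2.2,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """LD-decay estimates of effective population size per distance bin.

    ``distance_bins_bp`` gives bin edges (low, ..., high); each bin's
    recombination distance is its midpoint at 1 Mb = 1 cM, the dated
    generation is ``t = 1/(2c)``, and
    ``Ne = (4c)^-1 (1/r2_adj - alpha_const)`` with
    ``r2_adj = mean(r2) - 1/n_samples``.  Bins where r2_adj <= 0 report NaN.
    """
    edges = sorted(int(e) for e in distance_bins_bp)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    freq = matrix.allele2_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(maf) & (maf >= maf_min)
    sub = matrix.subset_markers(keep)
    pairs = pairwise_r2(sub, max_dist_bp=edges[-1])
    n = matrix.n_samples
    rows = []
    for low, high in zip(edges[:-1], edges[1:]):
        in_bin = (pairs["dist_bp"] > low) & (pairs["dist_bp"] <= high)
        r2_vals = pairs.loc[in_bin, "r2"].to_numpy()
        mid_bp = (low + high) / 2.0
        c = mid_bp * 1e-8  # Morgans at 1 Mb = 1 cM
        t = 1.0 / (2.0 * c)
        mean_r2 = float(r2_vals.mean()) if r2_vals.size else float("nan")
        r2_adj = mean_r2 - 1.0 / n
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha_const) if r2_adj > 0 else float("nan")
        if not np.isnan(ne) and ne <= 0:
            ne = float("nan")
        rows.append(
            NeEstimate(low, high, int(r2_vals.size), c, t, mean_r2, r2_adj, ne)
        )
    return pd.DataFrame(rows)
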