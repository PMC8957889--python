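"""Genomic inbreeding coefficients from ROH and from excess homozygosity.

Two per-individual estimators:

* ``F_ROH = L_ROH / L_auto`` — summed ROH length over the autosomal span
  covered by the chip (default 2.45 Gb for the 18 pig autosomes), reported
  for the total and for the 1-5 / 5-10 / >10 Mb length classes;
* ``F_HOM = (O_hom - E_hom) / (N - E_hom)`` — the method-of-moments
  coefficient from the excess of observed over expected homozygous
  genotypes, with the small-sample correction ``2n/(2n-1)`` on the expected
  heterozygosity and allele frequencies estimated from the full sample
  (focal individual included).

The module also provides Pearson correlations among the coefficients and a
two-sided Wilcoxon rank-sum comparison between groups (sex or population);
the test used is named in the output.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix
from .roh import CLASS_LABELS

#: Autosomal span covered by the 50K chip in pig, bp.
DEFAULT_L_AUTO_BP: int = 2_450_000_000

F_COLUMNS = ["f_roh_total", "f_roh_1_5", "f_roh_5_10", "f_roh_gt10", "f_hom"]

_CLASS_TO_COLUMN = {
    CLASS_LABELS[0]: "f_roh_1_5",
    CLASS_LABELS[1]: "f_roh_5_10",
    CLASS_LABELS[2]: "f_roh_gt10",
}


def f_roh(
    segments: pd.DataFrame,
    sample_ids: Iterable[str],
    l_auto_bp: int = DEFAULT_L_AUTO_BP,
) -> pd.DataFrame:
    """Per-individual F_ROH, total and per length class.

    ``sample_ids`` supplies the full cohort so individuals without any
    segment get zeros.  The class columns sum to the total by construction.
    """
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    ids = [str(s) for s in sample_ids]
    out = pd.DataFrame(
        0.0,
        index=pd.Index(ids, name="sample_id"),
        columns=["f_roh_total", "f_roh_1_5", "f_roh_5_10", "f_roh_gt10"],
    )
    out["l_roh_bp"] = 0
    if not segments.empty:
        per_class = (
            segments.groupby(["sample_id", "length_class"])["length_bp"].sum().unstack(
                fill_value=0
            )
        )
        for cls, col in _CLASS_TO_COLUMN.items():
            if cls in per_class.columns:
                hit = per_class.index.intersection(out.index)
                out.loc[hit, col] = per_class.loc[hit, cls] / l_auto_bp
        totals = segments.groupby("sample_id")["length_bp"].sum()
        hit = totals.index.intersection(out.index)
        out.loc[hit, "l_roh_bp"] = totals.loc[hit]
        out["f_roh_total"] = (
            out["f_roh_1_5"] + out["f_roh_5_10"] + out["f_roh_gt10"]
        )
    return out.reset_index()


def expected_hom_per_marker(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-marker expected homozygosity 1 - 2p(1-p) * 2n/(2n-1).

    ``p`` is the sample allele frequency and ``n`` the non-missing sample
    count at the marker; a monomorphic (or single-sample) marker contributes
    1 — it carries no information about inbreeding.
    """
    nm = (matrix.calls != MISSING).sum(axis=0).astype(float)
    p = matrix.allele2_freq()
    e = np.ones(matrix.n_markers)
    ok = (nm >= 1) & ~np.isnan(p)
    two_n = 2.0 * nm[ok]
    corr = np.where(two_n > 1, two_n / (two_n - 1.0), 1.0)
    e[ok] = 1.0 - 2.0 * p[ok] * (1.0 - p[ok]) * corr
    return e


def f_hom(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual excess-homozygosity inbreeding coefficient.

    ``F = (O_hom - E_hom) / (N_nm - E_hom)`` where sums run over the
    individual's non-missing markers.  NaN when the denominator is exactly 0.
    """
    if matrix.n_samples < 2:
        raise ValueError("f_hom needs >= 2 samples to estimate allele frequencies")
    e_marker = expected_hom_per_marker(matrix)
    nonmiss = matrix.calls != MISSING
    obs_hom = ((matrix.calls == 0) | (matrix.calls == 2)).sum(axis=1).astype(float)
    n_nm = nonmiss.sum(axis=1).astype(float)
    e_hom = nonmiss @ e_marker
    denom = n_nm - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom != 0, (obs_hom - e_hom) / denom, np.nan)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids.astype(str),
            "n_nonmissing": n_nm.astype(int),
            "obs_hom": obs_hom.astype(int),
            "exp_hom": e_hom,
            "f_hom": f,
        }
    )


def inbreeding_table(
    matrix: GenotypeMatrix,
    segments: pd.DataFrame,
    l_auto_bp: int = DEFAULT_L_AUTO_BP,
) -> pd.DataFrame:
    """Joined per-individual table: F_ROH (total + classes), F_HOM, metadata."""
    roh = f_roh(segments, matrix.sample_ids, l_auto_bp)
    hom = f_hom(matrix)[["sample_id", "f_hom"]]
    meta = matrix.samples[["sample_id", "population", "sex"]].astype({"sample_id": str})
    return meta.merge(roh, on="sample_id").merge(hom, on="sample_id")


def correlate_inbreeding(
    records: pd.DataFrame, columns: Sequence[str] = tuple(F_COLUMNS)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and two-sided p) matrices over the inbreeding columns.

    Pairwise-complete observations; a zero-variance variable yields NaN for
    its pairs.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records for correlation")
    cols = list(columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a in cols:
        for b in cols:
            sub = records[list(dict.fromkeys((a, b)))].dropna()
            if len(sub) < 3:
                continue
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = res.statistic
            p.loc[a, b] = res.pvalue
    return r, p


def group_compare(
    records: pd.DataFrame,
    grouping: str,
    value_columns: Sequence[str] = tuple(F_COLUMNS),
) -> pd.DataFrame:
    """Group means plus a two-sided Wilcoxon rank-sum test per value column.

    Exactly two groups are compared (more raise, as do singleton groups);
    the output names the test in a ``test`` column.
    """
    groups = [g for g, _ in records.groupby(grouping)]
    if len(groups) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than 2 groups")
    if len(groups) > 2:
        raise ValueError(
            f"grouping {grouping!r} has {len(groups)} levels; compare two at a time"
        )
    g1 = records[records[grouping] == groups[0]]
    g2 = records[records[grouping] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 members")
    rows = []
    for col in value_columns:
        x = g1[col].dropna().to_numpy()
        y = g2[col].dropna().to_numpy()
        stat, p = stats.ranksums(x, y)
        rows.append(
            {
                "variable": col,
                f"mean_{groups[0]}": float(np.mean(x)),
                f"mean_{groups[1]}": float(np.mean(y)),
                "mean_difference": float(np.mean(x) - np.mean(y)),
                "statistic": float(stat),
                "p_value": float(p),
                "test": "wilcoxon_rank_sum",
            }
        )
    return pd.DataFrame(rows)
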