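"""Sliding-window detection of runs of homozygosity (ROH).

The caller reproduces the scanning-window semantics of the standard
SNP-array ROH tools.  Per individual and chromosome:

1. a window of ``window_snps`` consecutive markers slides one marker at a
   time; a window *qualifies* when it contains at most ``window_max_het``
   heterozygous and ``window_max_missing`` missing calls;
2. a marker is *eligible* when the fraction of windows containing it that
   qualify is at least ``window_hit_fraction``;
3. maximal runs of consecutive eligible markers become candidate segments;
4. candidates are split wherever adjacent marker spacing exceeds
   ``max_gap_bp``;
5. candidates failing the minimum length, minimum SNP count, or SNP density
   criteria are discarded.

Segment bounds are the first/last eligible marker positions and lengths are
``end - start + 1`` bp.  Chromosomes shorter than the window are scanned with
a single truncated window (logged), not skipped.

The minimum SNP count can be set from the false-positive-control formula

    l = ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het)

rounded up, where ``mean_het`` is the heterozygous-call proportion across all
genotypes.  With the chip-scale inputs alpha=0.05, 45,424 SNPs, 2,096
individuals and mean het 0.27 this gives l = 68.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_bp",
    "length_class",
]

#: Length-class boundaries in bp: [1, 5) Mb, [5, 10) Mb, [10, inf) Mb.
CLASS_EDGES_BP = (5_000_000, 10_000_000)
CLASS_LABELS = ("1-5Mb", "5-10Mb", ">10Mb")


@dataclass(frozen=True)
class ROHParams:
    """Detection criteria; defaults follow 50K-chip practice."""

    min_length_bp: int = 1_000_000
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000
    #: When None, computed at detection time from ``alpha`` and the matrix.
    min_snp_count: Optional[int] = None
    window_hit_fraction: float = 0.05
    alpha: float = 0.05

    def __post_init__(self):
        if min(
            self.min_length_bp,
            self.window_snps,
            self.max_gap_bp,
            self.min_density_bp_per_snp,
        ) <= 0:
            raise ValueError("length/window/gap/density parameters must be positive")
        if self.window_max_het >= self.window_snps:
            raise ValueError("window_max_het must be < window_snps")
        if not 0.0 < self.window_hit_fraction <= 1.0:
            raise ValueError("window_hit_fraction must be in (0, 1]")
        if self.min_snp_count is not None and self.min_snp_count < 1:
            raise ValueError("min_snp_count must be >= 1")


class ROHSegment(NamedTuple):
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_bp: int
    length_class: str


def min_snp_count(alpha: float, n_snps: int, n_inds: int, mean_het: float) -> int:
    """Minimum consecutive-SNP threshold controlling false-positive ROH.

    Ceiling of ``ln(alpha/(n_snps*n_inds)) / ln(1 - mean_het)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_snps < 1 or n_inds < 1:
        raise ValueError("n_snps and n_inds must be >= 1")
    if mean_het <= 0.0:
        raise ZeroDivisionError(
            "mean_het must be > 0: the threshold formula divides by ln(1 - mean_het)"
        )
    if mean_het >= 1.0:
        raise ValueError("mean_het must be < 1")
    value = math.log(alpha / (n_snps * n_inds)) / math.log(1.0 - mean_het)
    return int(math.ceil(value))


def classify_length(length_bp: int) -> str:
    """Length class on left-closed boundaries: [1,5), [5,10), [10,inf) Mb."""
    if length_bp < CLASS_EDGES_BP[0]:
        return CLASS_LABELS[0]
    if length_bp < CLASS_EDGES_BP[1]:
        return CLASS_LABELS[1]
    return CLASS_LABELS[2]


def resolve_min_snp_count(matrix: GenotypeMatrix, params: ROHParams) -> int:
    """The SNP-count threshold actually used: user-set, or from the formula."""
    if params.min_snp_count is not None:
        return params.min_snp_count
    return min_snp_count(
        params.alpha, matrix.n_markers, matrix.n_samples, matrix.het_proportion()
    )


def _eligible_markers(genotypes: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean eligibility per marker for one individual on one chromosome."""
    m = genotypes.shape[0]
    w = params.window_snps
    if m < w:
        w = m  # single truncated window
    n_win = m - w + 1
    het = (genotypes == 1).astype(np.int32)
    mis = (genotypes == MISSING).astype(np.int32)
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(mis)))
    starts = np.arange(n_win)
    ok = (
        (het_c[starts + w] - het_c[starts] <= params.window_max_het)
        & (mis_c[starts + w] - mis_c[starts] <= params.window_max_missing)
    )
    ok_c = np.concatenate(([0], np.cumsum(ok)))
    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    n_ok = ok_c[hi + 1] - ok_c[lo]
    n_tot = hi - lo + 1
    return (n_ok / n_tot) >= params.window_hit_fraction


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_roh(
    matrix: GenotypeMatrix, params: ROHParams | None = None
) -> pd.DataFrame:
    """Detect ROH for every individual; returns a segment frame.

    Columns: ``sample_id, chrom, start_bp, end_bp, n_snps, length_bp,
    length_class``, sorted by (sample order, chrom, start).
    """
    params = params or ROHParams()
    min_snps = resolve_min_snp_count(matrix, params)

    chrom_codes, chrom_uniques = pd.factorize(matrix.markers["chrom"], sort=False)
    pos_all = matrix.markers["pos_bp"].to_numpy()
    chrom_slices = []
    for k, chrom in enumerate(chrom_uniques):
        idx = np.flatnonzero(chrom_codes == k)
        chrom_slices.append((str(chrom), idx))
        if len(idx) < params.window_snps:
            log.info(
                "chromosome %s has %d markers < window of %d; using one truncated window",
                chrom,
                len(idx),
                params.window_snps,
            )

    rows: list[ROHSegment] = []
    for i in range(matrix.n_samples):
        sid = str(matrix.sample_ids.iat[i])
        for chrom, idx in chrom_slices:
            g = matrix.calls[i, idx]
            pos = pos_all[idx]
            eligible = _eligible_markers(g, params)
            for r0, r1 in _runs(eligible):
                # split at gaps exceeding max_gap_bp between adjacent markers
                cut_points = [r0]
                gaps = np.diff(pos[r0 : r1 + 1])
                for off in np.flatnonzero(gaps > params.max_gap_bp):
                    cut_points.append(r0 + off + 1)
                cut_points.append(r1 + 1)
                for a, b in zip(cut_points[:-1], cut_points[1:]):
                    b -= 1
                    if b < a:
                        continue
                    n_snps = b - a + 1
                    start, end = int(pos[a]), int(pos[b])
                    length = end - start + 1
                    if length < params.min_length_bp:
                        continue
                    if n_snps < min_snps:
                        continue
                    if length / n_snps > params.min_density_bp_per_snp:
                        continue
                    rows.append(
                        ROHSegment(
                            sid, chrom, start, end, n_snps, length, classify_length(length)
                        )
                    )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def classify_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Counts and summed lengths per (sample, chromosome, length class).

    Empty input yields an empty frame with the summary columns.
    """
    cols = ["sample_id", "chrom", "length_class", "n_segments", "total_length_bp"]
    if segments.empty:
        return pd.DataFrame(columns=cols)
    out = (
        segments.groupby(["sample_id", "chrom", "length_class"], sort=False)
        .agg(n_segments=("length_bp", "size"), total_length_bp=("length_bp", "sum"))
        .reset_index()
    )
    return out[cols]


def class_summary(segments: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide counts, length sums and shares per length class."""
    out = pd.DataFrame(
        {
            "length_class": CLASS_LABELS,
            "n_segments": [0] * 3,
            "total_length_bp": [0] * 3,
        }
    ).set_index("length_class")
    if not segments.empty:
        g = segments.groupby("length_class")["length_bp"].agg(["size", "sum"])
        for cls in g.index:
            out.loc[cls, "n_segments"] = int(g.loc[cls, "size"])
            out.loc[cls, "total_length_bp"] = int(g.loc[cls, "sum"])
    total = out["total_length_bp"].sum()
    out["count_share"] = (
        out["n_segments"] / out["n_segments"].sum() if out["n_segments"].sum() else 0.0
    )
    out["length_share"] = out["total_length_bp"] / total if total else 0.0
    return out.reset_index()


def chromosome_coverage(
    segments: pd.DataFrame, chrom_span_bp: dict[str, int]
) -> pd.DataFrame:
    """Fraction of each chromosome span covered by ROH, averaged over samples.

    ``chrom_span_bp`` maps chromosome label to its covered span in bp.
    """
    n_samples = segments["sample_id"].nunique() if not segments.empty else 0
    rows = []
    for chrom, span in chrom_span_bp.items():
        if segments.empty:
            total = 0
        else:
            total = int(segments.loc[segments["chrom"] == str(chrom), "length_bp"].sum())
        cov = total / (span * n_samples) if n_samples and span else 0.0
        rows.append((str(chrom), span, total, cov))
    return pd.DataFrame(
        rows, columns=["chrom", "span_bp", "total_roh_bp", "mean_coverage"]
    )


def generations_from_length(length_mb: float) -> float:
    """Expected age (generations) of an ROH of the given length.

    Uses the expected IBD-segment length relation L = 100 / (2 g) cM with
    1 cM ~ 1 Mb, i.e. g = 100 / (2 L_Mb): a 10 Mb segment dates to about
    5 generations ago.
    """
    if length_mb <= 0:
        raise ValueError("length_mb must be positive")
    return 100.0 / (2.0 * length_mb)
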