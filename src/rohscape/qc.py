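"""Quality control of a genotype matrix.

The filter battery mirrors common SNP-chip practice: drop non-autosomal or
unmapped markers, then markers with low call rate, then individuals with low
call rate (recomputed on surviving markers), then markers out of
Hardy-Weinberg equilibrium by an exact test, then (optionally) low-MAF
markers.  The order is fixed and every step's removals are reported so counts
are reproducible.

Hardy-Weinberg testing uses the exact conditional test: the two-sided p-value
is the summed probability of heterozygote counts no more likely than the one
observed, conditional on the allele counts.  Mid-p is not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import GenotypeMatrix, is_autosome_label


@dataclass
class QCParams:
    """Thresholds for :func:`apply_qc`.

    ``maf_min=None`` disables the MAF filter (the right choice upstream of ROH
    detection, where pruning rare alleles erases homozygous regions);
    diversity statistics typically use ``maf_min=0.01``.
    """

    min_call_rate_snp: float = 0.90
    min_call_rate_ind: float = 0.90
    hwe_min_p: float = 1e-6
    maf_min: float | None = None
    autosomes_only: bool = True
    #: "per_population": test HWE within each population label and remove a
    #: marker that fails in any of them; "pooled": test on all samples at once.
    hwe_mode: str = "per_population"

    def __post_init__(self):
        for name in ("min_call_rate_snp", "min_call_rate_ind"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.hwe_min_p < 1.0:
            raise ValueError("hwe_min_p must be in (0, 1)")
        if self.maf_min is not None and not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5] or None")
        if self.hwe_mode not in ("per_population", "pooled"):
            raise ValueError("hwe_mode must be 'per_population' or 'pooled'")


@dataclass
class QCReport:
    """Per-step removal counts plus the parameters that produced them."""

    params: QCParams
    n_markers_in: int = 0
    n_samples_in: int = 0
    removed_non_autosomal: int = 0
    removed_marker_call_rate: int = 0
    removed_sample_call_rate: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0
    notes: list[str] = field(default_factory=list)


class EmptyResultError(RuntimeError):
    """All markers or all samples were filtered out."""


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one.
    A monomorphic marker returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom1 + n_het  # copies of the rarer-or-not allele 1
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    n_rare = min(n_a, n_b)
    # log P(het = h | allele counts), h runs over n_rare % 2, step 2
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homs_rare = (n_rare - hets) // 2
    homs_common = (n_a + n_b - n_rare - hets) // 2 - 0  # = ((2n - n_rare) - hets)/2
    logp = (
        gammaln(n + 1)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = int(n_het)
    p_obs = probs[hets == obs]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("observed het count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_exact_p_markers(matrix: GenotypeMatrix) -> np.ndarray:
    """Vector of exact HWE p-values over markers (pooled samples)."""
    counts = matrix.genotype_counts()
    return np.array(
        [
            hwe_exact_p(int(r.n_hom1), int(r.n_het), int(r.n_hom2))
            if (r.n_hom1 + r.n_het + r.n_hom2) > 0
            else 1.0
            for r in counts.itertuples()
        ]
    )


def apply_qc(matrix: GenotypeMatrix, params: QCParams | None = None) -> tuple[
    GenotypeMatrix, QCReport
]:
    """Run the fixed-order filter battery; returns the filtered matrix + report.

    Steps: (1) non-autosomal/unmapped markers; (2) marker call rate;
    (3) individual call rate on surviving markers; (4) HWE exact test;
    (5) optional MAF.  Raises :class:`EmptyResultError` when nothing survives.
    """
    params = params or QCParams()
    report = QCReport(
        params=params, n_markers_in=matrix.n_markers, n_samples_in=matrix.n_samples
    )

    m = matrix
    # (1) autosomes / mapped positions
    if params.autosomes_only:
        keep = np.array(
            [is_autosome_label(c) for c in m.markers["chrom"]], dtype=bool
        ) & (m.markers["pos_bp"].to_numpy() >= 1)
        report.removed_non_autosomal = int((~keep).sum())
        m = m.subset_markers(keep)

    # (2) marker call rate
    if m.n_markers:
        keep = m.marker_call_rate() >= params.min_call_rate_snp
        report.removed_marker_call_rate = int((~keep).sum())
        m = m.subset_markers(keep)

    # (3) individual call rate, on surviving markers only
    if m.n_markers and m.n_samples:
        keep = m.sample_call_rate() >= params.min_call_rate_ind
        report.removed_sample_call_rate = int((~keep).sum())
        m = m.subset_samples(keep)

    # (4) HWE
    if m.n_markers and m.n_samples:
        if params.hwe_mode == "per_population" and len(m.populations) > 1:
            fail = np.zeros(m.n_markers, dtype=bool)
            for pop, sub in m.by_population().items():
                fail |= hwe_exact_p_markers(sub) < params.hwe_min_p
            report.notes.append("hwe tested per population; fail-in-any removed")
        else:
            fail = hwe_exact_p_markers(m) < params.hwe_min_p
            report.notes.append("hwe tested on pooled samples")
        report.removed_hwe = int(fail.sum())
        m = m.subset_markers(~fail)

    # (5) MAF, computed on surviving samples
    if params.maf_min is not None and m.n_markers:
        freq = m.allele2_freq()
        maf = np.minimum(freq, 1.0 - freq)
        keep = ~(maf < params.maf_min)  # NaN (all-missing) kept; impossible post step 2
        report.removed_maf = int((~keep).sum())
        m = m.subset_markers(keep)

    report.n_markers_out = m.n_markers
    report.n_samples_out = m.n_samples
    if m.n_markers == 0 or m.n_samples == 0:
        raise EmptyResultError(
            f"QC removed everything (markers left: {m.n_markers}, "
            f"samples left: {m.n_samples})"
        )
    return m, report
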