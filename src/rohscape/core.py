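"""Core containers for SNP-array genotype data.

The substrate of every analysis stage is a :class:`GenotypeMatrix`: a dense
``(n_samples, n_markers)`` array of diploid genotype codes plus two pandas
frames carrying sample metadata and the marker map.  Genotype codes count
copies of ``allele2`` at each marker:

* ``0`` — homozygous for ``allele1``
* ``1`` — heterozygous
* ``2`` — homozygous for ``allele2``
* ``-1`` (:data:`MISSING`) — no call

The coding is frequency-independent (it follows the allele *labels*, not the
minor or derived allele); minor/derived orientation is resolved downstream in
the diversity and association modules.

Coordinates are 1-based and inclusive everywhere inside the package; the BED
half-open convention exists only at the file boundary (see :mod:`rohscape.io`).
Markers are kept globally sorted by ``(chrom, pos_bp)`` — every downstream
module relies on that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing call.
MISSING: int = -1

#: Valid genotype codes (missing included).
VALID_CODES = (MISSING, 0, 1, 2)

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "population", "sex"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def chrom_sort_key(label) -> tuple:
    """Sort key placing numeric chromosome labels first, in numeric order.

    Non-numeric labels (``"X"``, contig names, ...) follow, lexicographically.
    """
    s = str(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def is_autosome_label(label) -> bool:
    """True when *label* parses as a positive integer (autosome convention)."""
    try:
        return int(str(label)) >= 1
    except ValueError:
        return False


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int
    name: Optional[str] = None

    def __post_init__(self):
        if self.start_bp < 1 or self.end_bp < 1:
            raise ValueError(f"interval coordinates must be >= 1: {self}")
        if self.start_bp > self.end_bp:
            raise ValueError(f"start_bp > end_bp: {self}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    """Tabulate intervals as a DataFrame (chrom, start_bp, end_bp, name)."""
    rows = [(iv.chrom, iv.start_bp, iv.end_bp, iv.name) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def frame_to_intervals(frame: pd.DataFrame) -> list[GenomicInterval]:
    name = frame["name"] if "name" in frame.columns else [None] * len(frame)
    return [
        GenomicInterval(str(c), int(s), int(e), None if pd.isna(n) else n)
        for c, s, e, n in zip(frame["chrom"], frame["start_bp"], frame["end_bp"], name)
    ]


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check marker-map invariants: unique ids, positions >= 1, sorted within chrom."""
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise ValueError(f"marker map lacks columns: {missing_cols}")
    if markers["marker_id"].duplicated().any():
        dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id: {dup!r}")
    if (markers["pos_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1")
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")


class GenotypeMatrix:
    """Individuals x markers diploid genotype codes with metadata.

    Parameters
    ----------
    calls
        ``(n_samples, n_markers)`` integer array of codes in ``{-1, 0, 1, 2}``.
    samples
        Frame with at least ``sample_id`` (unique); ``population`` and ``sex``
        are filled with defaults when absent.
    markers
        Marker map frame with ``marker_id, chrom, pos_bp, allele1, allele2``.
    sort
        When true (default) markers are re-sorted by ``(chrom, pos_bp)`` and
        the call columns permuted consistently.
    """

    def __init__(
        self,
        calls: np.ndarray,
        samples: pd.DataFrame,
        markers: pd.DataFrame,
        *,
        sort: bool = True,
        validate: bool = True,
    ):
        calls = np.asarray(calls, dtype=np.int8)
        samples = samples.reset_index(drop=True).copy()
        markers = markers.reset_index(drop=True).copy()
        if "population" not in samples.columns:
            samples["population"] = "pop1"
        if "sex" not in samples.columns:
            samples["sex"] = "unknown"
        markers["chrom"] = markers["chrom"].astype(str)
        markers["pos_bp"] = markers["pos_bp"].astype(np.int64)

        if calls.ndim != 2 or calls.shape != (len(samples), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, "
                f"n_markers={len(markers)})"
            )
        if sort:
            # global sort by (chrom, pos_bp), numeric chromosomes first
            order = sorted(
                range(len(markers)),
                key=lambda i: (
                    chrom_sort_key(markers["chrom"].iat[i]),
                    markers["pos_bp"].iat[i],
                ),
            )
            order = np.asarray(order)
            markers = markers.iloc[order].reset_index(drop=True)
            calls = calls[:, order]
        if validate:
            if samples["sample_id"].duplicated().any():
                dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
                raise ValueError(f"duplicate sample_id: {dup!r}")
            validate_marker_map(markers)
            bad = ~np.isin(calls, VALID_CODES)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"invalid genotype code {calls[i, j]} at sample {i}, marker {j}"
                )
        self.calls = calls
        self.samples = samples
        self.markers = markers

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.samples["sample_id"]

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix(n_samples={self.n_samples}, n_markers={self.n_markers}, "
            f"populations={self.populations})"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.samples[SAMPLE_COLUMNS].equals(other.samples[SAMPLE_COLUMNS])
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
        )

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        """Restrict to samples selected by boolean mask or id list."""
        if isinstance(mask_or_ids, (list, tuple, pd.Series, np.ndarray)) and len(
            mask_or_ids
        ) == self.n_samples and np.asarray(mask_or_ids).dtype == bool:
            mask = np.asarray(mask_or_ids)
        else:
            wanted = set(mask_or_ids)
            mask = self.samples["sample_id"].isin(wanted).to_numpy()
        return GenotypeMatrix(
            self.calls[mask], self.samples.loc[mask], self.markers, sort=False, validate=False
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Restrict to markers selected by a boolean mask (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.calls[:, mask],
            self.samples,
            self.markers.loc[mask],
            sort=False,
            validate=False,
        )

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        """Split into one matrix per population label (marker map shared)."""
        return {
            pop: self.subset_samples((self.samples["population"] == pop).to_numpy())
            for pop in self.populations
        }

    # -- elementary per-axis summaries ------------------------------------
    def marker_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of codes 0/1/2 and missing."""
        out = pd.DataFrame(
            {
                "n_hom1": (self.calls == 0).sum(axis=0),
                "n_het": (self.calls == 1).sum(axis=0),
                "n_hom2": (self.calls == 2).sum(axis=0),
                "n_missing": (self.calls == MISSING).sum(axis=0),
            }
        )
        return out

    def allele2_freq(self) -> np.ndarray:
        """Per-marker frequency of allele2 among non-missing calls (NaN if none)."""
        nm = (self.calls != MISSING).sum(axis=0)
        dose = np.where(self.calls == MISSING, 0, self.calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nm > 0, dose / (2.0 * nm), np.nan)

    def het_proportion(self) -> float:
        """Proportion of heterozygous calls among all non-missing calls."""
        nm = int((self.calls != MISSING).sum())
        if nm == 0:
            raise ValueError("matrix has no called genotypes")
        return float((self.calls == 1).sum() / nm)


def make_samples(
    sample_ids: Sequence[str],
    populations: Optional[Sequence[str]] = None,
    sexes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Convenience builder for a sample-metadata frame."""
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "population": list(populations) if populations is not None else ["pop1"] * n,
            "sex": list(sexes) if sexes is not None else ["unknown"] * n,
        }
    )


def make_markers(
    chroms: Sequence,
    positions: Sequence[int],
    marker_ids: Optional[Sequence[str]] = None,
    allele1: Optional[Sequence[str]] = None,
    allele2: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Convenience builder for a marker map frame."""
    n = len(positions)
    if marker_ids is None:
        marker_ids = [f"snp{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "chrom": [str(c) for c in chroms],
            "pos_bp": np.asarray(positions, dtype=np.int64),
            "allele1": list(allele1) if allele1 is not None else ["A"] * n,
            "allele2": list(allele2) if allele2 is not None else ["G"] * n,
        }
    )
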