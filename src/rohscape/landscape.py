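"""ROH landscape: per-SNP occurrence, hotspots, coldspots, interval overlap.

The *occurrence* of a marker is the fraction of individuals whose ROH cover
its position.  Maximal runs of consecutive markers at occurrence >= 0.80
(inclusive by default) form hotspot regions, interpreted as putative
selection signatures; runs at occurrence exactly 0 in *every* supplied
population form coldspots, putatively intolerant of homozygosity.  Regions
can be expanded by a flanking margin (50 kb each side by default) and
intersected with user-supplied gene/QTL interval files.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenotypeMatrix, chrom_sort_key

TRACK_COLUMNS = ["marker_id", "chrom", "pos_bp", "n_in_roh", "occurrence"]
REGION_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "mean_occurrence",
    "max_occurrence",
]


def occurrence(matrix: GenotypeMatrix, segments: pd.DataFrame) -> pd.DataFrame:
    """Per-marker ROH occurrence track for the individuals in *matrix*.

    A marker counts for an individual when its position lies inside any of
    that individual's segments (1-based inclusive bounds).  The denominator
    is every individual in the matrix, with or without ROH.
    """
    n_in = np.zeros(matrix.n_markers, dtype=np.int64)
    ids = set(matrix.sample_ids.astype(str))
    if not segments.empty:
        markers = matrix.markers
        pos_by_chrom = {
            str(chrom): (sub.index.to_numpy(), sub["pos_bp"].to_numpy())
            for chrom, sub in markers.groupby("chrom", sort=False)
        }
        for (sid, chrom), sub in segments.groupby(["sample_id", "chrom"], sort=False):
            if str(sid) not in ids or str(chrom) not in pos_by_chrom:
                continue
            idx, pos = pos_by_chrom[str(chrom)]
            covered = np.zeros(len(pos), dtype=bool)
            for start, end in zip(sub["start_bp"], sub["end_bp"]):
                lo = np.searchsorted(pos, start, side="left")
                hi = np.searchsorted(pos, end, side="right")
                covered[lo:hi] = True
            n_in[idx[covered]] += 1
    track = matrix.markers[["marker_id", "chrom", "pos_bp"]].copy()
    track["n_in_roh"] = n_in
    track["occurrence"] = n_in / matrix.n_samples
    return track


def _track_regions(track: pd.DataFrame, member: np.ndarray) -> pd.DataFrame:
    """Collapse a boolean marker mask into maximal consecutive-run regions."""
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        mask = member[sub.index.to_numpy()]
        padded = np.concatenate(([False], mask, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        pos = sub["pos_bp"].to_numpy()
        occ = sub["occurrence"].to_numpy()
        for a, b in zip(starts, ends):
            rows.append(
                (
                    str(chrom),
                    int(pos[a]),
                    int(pos[b]),
                    int(b - a + 1),
                    float(occ[a : b + 1].mean()),
                    float(occ[a : b + 1].max()),
                )
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def call_hotspots(
    track: pd.DataFrame, threshold: float = 0.80, *, inclusive: bool = True
) -> pd.DataFrame:
    """Hotspot regions: maximal runs of markers at occurrence >= threshold.

    A single sub-threshold marker breaks a run (no bridging); single-marker
    regions are allowed.  ``inclusive=False`` uses a strict ``>`` comparison.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    track = track.reset_index(drop=True)
    occ = track["occurrence"].to_numpy()
    member = occ >= threshold if inclusive else occ > threshold
    return _track_regions(track, member)


def call_coldspots(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Coldspot regions: runs of markers with zero occurrence in all tracks.

    All tracks must share an identical marker map (same markers, same order).
    """
    if not tracks:
        raise ValueError("need at least one occurrence track")
    base = tracks[0].reset_index(drop=True)
    key = base[["marker_id", "chrom", "pos_bp"]]
    for t in tracks[1:]:
        other = t.reset_index(drop=True)[["marker_id", "chrom", "pos_bp"]]
        if not key.equals(other):
            raise ValueError("occurrence tracks are on different marker maps")
    zero = np.ones(len(base), dtype=bool)
    for t in tracks:
        zero &= t.reset_index(drop=True)["occurrence"].to_numpy() == 0
    out = _track_regions(base, zero)
    # occurrence is 0 by construction in every member marker
    return out.drop(columns=["mean_occurrence", "max_occurrence"]).assign(occurrence=0.0)


def flank_regions(
    regions: pd.DataFrame,
    flank_bp: int = 50_000,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Expand intervals (or points, start==end) by ``flank_bp`` on both sides.

    Expansion clips at 1 and — when ``chrom_sizes`` is given — at the
    chromosome end; overlapping or bp-adjacent expansions are merged.
    Input needs columns ``chrom, start_bp, end_bp``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if regions.empty:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp"])
    rows = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        limit = chrom_sizes.get(str(chrom)) if chrom_sizes else None
        ivs = sorted(
            (max(1, int(s) - flank_bp),
             int(e) + flank_bp if limit is None else min(limit, int(e) + flank_bp))
            for s, e in zip(sub["start_bp"], sub["end_bp"])
        )
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rows += [(str(chrom), s, e) for s, e in merged]
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp"])


def overlap_intervals(
    query: pd.DataFrame,
    subject: pd.DataFrame,
    max_subject_length_bp: Optional[int] = 1_000_000,
) -> pd.DataFrame:
    """All (query, subject) interval pairs with >= 1 bp overlap.

    ``max_subject_length_bp`` pre-filters subject intervals (the usual QTL
    length filter; set None to disable).  Interval frames need columns
    ``chrom, start_bp, end_bp`` and optionally ``name``.
    """
    sub = subject.reset_index(drop=True)
    if max_subject_length_bp is not None:
        keep = (sub["end_bp"] - sub["start_bp"] + 1) <= max_subject_length_bp
        sub = sub.loc[keep].reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for chrom, s in sub.groupby("chrom", sort=False):
        t = IntervalTree()
        for i, (a, b) in zip(s.index, zip(s["start_bp"], s["end_bp"])):
            t.addi(int(a), int(b) + 1, i)  # half-open internally to the tree
        trees[str(chrom)] = t
    rows = []
    qname = query["name"] if "name" in query.columns else [None] * len(query)
    sname = sub["name"] if "name" in sub.columns else pd.Series([None] * len(sub))
    for (_, q), qn in zip(query.reset_index(drop=True).iterrows(), qname):
        tree = trees.get(str(q["chrom"]))
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(q["start_bp"]), int(q["end_bp"]) + 1)):
            i = hit.data
            ov = min(int(q["end_bp"]), int(sub["end_bp"].iat[i])) - max(
                int(q["start_bp"]), int(sub["start_bp"].iat[i])
            ) + 1
            rows.append(
                {
                    "chrom": str(q["chrom"]),
                    "query_start_bp": int(q["start_bp"]),
                    "query_end_bp": int(q["end_bp"]),
                    "query_name": qn,
                    "subject_start_bp": int(sub["start_bp"].iat[i]),
                    "subject_end_bp": int(sub["end_bp"].iat[i]),
                    "subject_name": sname.iat[i],
                    "overlap_bp": ov,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "query_start_bp",
            "query_end_bp",
            "query_name",
            "subject_start_bp",
            "subject_end_bp",
            "subject_name",
            "overlap_bp",
        ],
    )
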