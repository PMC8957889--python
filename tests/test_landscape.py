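import numpy as np
import pandas as pd
import pytest

from rohscape import (
    GenotypeMatrix,
    call_coldspots,
    call_hotspots,
    flank_regions,
    make_markers,
    make_samples,
    occurrence,
    overlap_intervals,
)

from oracles import overlap_bruteforce


def _matrix(n_samples, positions, chroms=None):
    markers = make_markers(chroms or ["1"] * len(positions), positions)
    calls = np.zeros((n_samples, len(positions)), dtype=np.int8)
    return GenotypeMatrix(calls, make_samples([f"s{i}" for i in range(n_samples)]), markers)


def _segs(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])


class TestOccurrence:
    def test_full_and_zero_coverage(self):
        m = _matrix(4, [100, 200, 300])
        segs = _segs([(f"s{i}", "1", 50, 250) for i in range(4)])
        track = occurrence(m, segs)
        assert list(track["occurrence"]) == [1.0, 1.0, 0.0]
        empty = occurrence(m, _segs([]))
        assert (empty["occurrence"] == 0).all()

    def test_matches_exhaustive_membership_count(self, rng):
        positions = sorted(rng.choice(np.arange(1, 10**6), size=60, replace=False))
        m = _matrix(10, list(positions))
        rows = []
        for i in range(10):
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(1, 10**6))
                rows.append((f"s{i}", "1", s, s + int(rng.integers(1, 2 * 10**5))))
        segs = _segs(rows)
        track = occurrence(m, segs)
        for j, pos in enumerate(positions):
            n = sum(
                any(
                    (r.start_bp <= pos <= r.end_bp) and r.sample_id == f"s{i}"
                    for r in segs.itertuples()
                )
                for i in range(10)
            )
            assert track["n_in_roh"].iloc[j] == n

    def test_conservation_between_track_and_segments(self, rng):
        """Sum of per-marker counts equals sum over segments of contained markers."""
        positions = list(range(10_000, 510_000, 10_000))
        m = _matrix(6, positions)
        rows = []
        for i in range(6):
            s = int(rng.integers(1, 400_000))
            rows.append((f"s{i}", "1", s, s + 50_000))
        segs = _segs(rows)
        track = occurrence(m, segs)
        pos = np.asarray(positions)
        per_segment = sum(
            int(((pos >= r.start_bp) & (pos <= r.end_bp)).sum()) for r in segs.itertuples()
        )
        assert int(track["n_in_roh"].sum()) == per_segment


class TestHotspots:
    def _track(self, occs, positions=None, chroms=None):
        n = len(occs)
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n)],
                "chrom": chroms or ["1"] * n,
                "pos_bp": positions or [(i + 1) * 1000 for i in range(n)],
                "n_in_roh": [0] * n,
                "occurrence": occs,
            }
        )

    def test_uniform_high_track_is_one_region(self):
        track = self._track([0.85] * 10)
        hot = call_hotspots(track)
        assert len(hot) == 1
        assert hot.iloc[0].n_snps == 10
        assert hot.iloc[0].start_bp == 1000 and hot.iloc[0].end_bp == 10_000

    def test_alternating_values_yield_singletons(self):
        track = self._track([0.85, 0.5] * 5)
        hot = call_hotspots(track)
        assert len(hot) == 5
        assert (hot["n_snps"] == 1).all()

    def test_threshold_inclusive_flag(self):
        track = self._track([0.80, 0.85])
        assert len(call_hotspots(track, 0.80, inclusive=True)) == 1
        hot = call_hotspots(track, 0.80, inclusive=False)
        assert len(hot) == 1 and hot.iloc[0].n_snps == 1

    def test_monotone_in_threshold(self, rng):
        track = self._track(list(rng.random(200)))
        hi = call_hotspots(track, 0.85)
        lo = call_hotspots(track, 0.80)
        # every 0.85-region is contained in some 0.80-region
        for r in hi.itertuples():
            assert any(
                (q.start_bp <= r.start_bp) and (q.end_bp >= r.end_bp)
                for q in lo.itertuples()
            )


class TestColdspots:
    def _track(self, occs):
        n = len(occs)
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n)],
                "chrom": ["1"] * n,
                "pos_bp": [(i + 1) * 1000 for i in range(n)],
                "n_in_roh": [0] * n,
                "occurrence": occs,
            }
        )

    def test_intersection_requires_zero_in_all(self):
        zero = self._track([0.0] * 5)
        nonzero = self._track([0.2] * 5)
        assert call_coldspots([zero, nonzero]).empty

    def test_fifteen_marker_shared_zero_region(self):
        occs_a = [0.0] * 15 + [0.3] * 5
        occs_b = [0.0] * 15 + [0.1] * 5
        cold = call_coldspots([self._track(occs_a), self._track(occs_b)])
        assert len(cold) == 1
        assert cold.iloc[0].n_snps == 15
        assert cold.iloc[0].occurrence == 0.0

    def test_all_nonzero_is_empty(self):
        assert call_coldspots([self._track([0.5] * 8)]).empty

    def test_map_mismatch_rejected(self):
        a = self._track([0.0] * 4)
        b = self._track([0.0] * 4)
        b.loc[2, "pos_bp"] = 999_999
        with pytest.raises(ValueError, match="different marker maps"):
            call_coldspots([a, b])


class TestFlanking:
    def test_point_expansion(self):
        regions = pd.DataFrame({"chrom": ["1"], "start_bp": [100_000], "end_bp": [100_000]})
        out = flank_regions(regions, 50_000)
        assert out.iloc[0].start_bp == 50_000 and out.iloc[0].end_bp == 150_000

    def test_clipping_at_chromosome_start_and_end(self):
        regions = pd.DataFrame({"chrom": ["1"], "start_bp": [20_000], "end_bp": [20_000]})
        out = flank_regions(regions, 50_000)
        assert out.iloc[0].start_bp == 1 and out.iloc[0].end_bp == 70_000
        clipped = flank_regions(regions, 50_000, chrom_sizes={"1": 60_000})
        assert clipped.iloc[0].end_bp == 60_000

    def test_overlapping_expansions_merge(self):
        regions = pd.DataFrame(
            {"chrom": ["1", "1"], "start_bp": [100_000, 160_000], "end_bp": [100_000, 160_000]}
        )
        out = flank_regions(regions, 50_000)
        assert len(out) == 1
        assert out.iloc[0].start_bp == 50_000 and out.iloc[0].end_bp == 210_000

    def test_zero_flank_is_identity_and_merge_idempotent(self):
        regions = pd.DataFrame(
            {"chrom": ["1", "2"], "start_bp": [10, 40], "end_bp": [20, 60]}
        )
        out = flank_regions(regions, 0)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True),
            regions.astype({"start_bp": out["start_bp"].dtype, "end_bp": out["end_bp"].dtype}),
        )
        again = flank_regions(out, 0)
        pd.testing.assert_frame_equal(out, again)


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = pd.DataFrame({"chrom": ["1"], "start_bp": [100], "end_bp": [200]})
        out = overlap_intervals(a, a, None)
        assert len(out) == 1 and out.iloc[0].overlap_bp == 101
        b = pd.DataFrame({"chrom": ["1"], "start_bp": [300], "end_bp": [400]})
        assert overlap_intervals(a, b, None).empty

    def test_subject_length_prefilter(self):
        q = pd.DataFrame({"chrom": ["1"], "start_bp": [1], "end_bp": [10_000_000]})
        s = pd.DataFrame(
            {"chrom": ["1", "1"], "start_bp": [10, 20], "end_bp": [500_000, 2_000_000]}
        )
        out = overlap_intervals(q, s, max_subject_length_bp=1_000_000)
        assert len(out) == 1 and out.iloc[0].subject_end_bp == 500_000

    def test_matches_quadratic_bruteforce(self, rng):
        def random_ivs(n):
            starts = rng.integers(1, 10**6, size=n)
            return pd.DataFrame(
                {
                    "chrom": rng.choice(["1", "2"], size=n),
                    "start_bp": starts,
                    "end_bp": starts + rng.integers(0, 10**5, size=n),
                }
            )

        q, s = random_ivs(100), random_ivs(100)
        got = overlap_intervals(q, s, None)
        got_set = {
            (r.chrom, r.query_start_bp, r.subject_start_bp, r.overlap_bp)
            for r in got.itertuples()
        }
        expected = overlap_bruteforce(
            list(zip(q["chrom"], q["start_bp"], q["end_bp"])),
            list(zip(s["chrom"], s["start_bp"], s["end_bp"])),
        )
        exp_set = {
            (q["chrom"].iat[qi], int(q["start_bp"].iat[qi]), int(s["start_bp"].iat[si]), ov)
            for qi, si, ov in expected
        }
        assert got_set == exp_set
        assert len(got) == len(expected)
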