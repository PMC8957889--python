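import math

import numpy as np
import pandas as pd
import pytest

from rohscape import (
    GenotypeMatrix,
    ROHParams,
    classify_segments,
    detect_roh,
    generations_from_length,
    make_markers,
    make_samples,
    min_snp_count,
)
from rohscape.roh import class_summary, classify_length, resolve_min_snp_count

from oracles import roh_bruteforce


def _one_sample(calls, positions, chroms=None):
    calls = np.asarray([calls], dtype=np.int8)
    markers = make_markers(chroms or ["1"] * calls.shape[1], positions)
    return GenotypeMatrix(calls, make_samples(["s1"]), markers)


class TestMinSnpCount:
    def test_chip_scale_inputs(self):
        # 45,424 SNPs x 2,096 individuals at mean het 0.27 -> 68 SNPs
        assert min_snp_count(0.05, 45_424, 2_096, 0.27) == 68

    def test_identity_ratio(self):
        assert min_snp_count(0.5, 1, 1, 0.5) == 1

    def test_matches_direct_formula(self):
        value = math.log(0.05 / (39_416 * 3_770)) / math.log(1 - 0.29)
        assert min_snp_count(0.05, 39_416, 3_770, 0.29) == math.ceil(value)

    def test_zero_het_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            min_snp_count(0.05, 100, 10, 0.0)


class TestDetectRoh:
    def test_all_het_individual_has_no_segments(self):
        m = _one_sample([1] * 120, [(i + 1) * 50_000 for i in range(120)])
        assert detect_roh(m, ROHParams(min_snp_count=10)).empty

    def test_uniform_homozygous_chromosome_boundary_arithmetic(self):
        """201 all-hom markers at exact 50-kb spacing give one segment of
        10,000,001 bp spanning markers 1..201, class >10Mb."""
        positions = [(i * 50_000) + 1 for i in range(201)]
        m = _one_sample([0] * 201, positions)
        segs = detect_roh(m, ROHParams(min_snp_count=63))
        assert len(segs) == 1
        seg = segs.iloc[0]
        assert seg.start_bp == 1 and seg.end_bp == 10_000_001
        assert seg.n_snps == 201
        assert seg.length_bp == 10_000_001
        assert seg.length_class == ">10Mb"

    def test_planted_tract_with_het_flanks_has_tight_bounds(self):
        """A clean homozygous tract between fully heterozygous flanks is
        recovered with both bounds within one inter-marker interval."""
        spacing = 50_000
        n_flank, n_tract = 60, 100  # 5 Mb tract
        geno = [1] * n_flank + [0] * n_tract + [1] * n_flank
        positions = [(i + 1) * spacing for i in range(len(geno))]
        m = _one_sample(geno, positions)
        segs = detect_roh(m, ROHParams(min_snp_count=50))
        assert len(segs) == 1
        seg = segs.iloc[0]
        true_start = (n_flank + 1) * spacing
        true_end = (n_flank + n_tract) * spacing
        assert abs(seg.start_bp - true_start) <= spacing
        assert abs(seg.end_bp - true_end) <= spacing

    def test_gap_rule_splits_candidates(self):
        spacing = 20_000
        pos_left = [(i + 1) * spacing for i in range(80)]
        pos_right = [pos_left[-1] + 2_000_000 + i * spacing for i in range(80)]
        m = _one_sample([0] * 160, pos_left + pos_right)
        segs = detect_roh(
            m, ROHParams(min_snp_count=30, min_length_bp=1_000_000, max_gap_bp=1_000_000)
        )
        assert len(segs) == 2

    def test_short_chromosome_uses_truncated_window(self):
        m = _one_sample([0] * 30, [(i + 1) * 40_000 for i in range(30)])
        segs = detect_roh(m, ROHParams(min_snp_count=20, min_length_bp=1_000_000))
        assert len(segs) == 1 and segs.iloc[0].n_snps == 30

    def test_monotone_in_thresholds(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, 4, 200, p_het=0.05)
        base = len(detect_roh(m, ROHParams(min_snp_count=10, min_length_bp=200_000)))
        stricter_len = len(
            detect_roh(m, ROHParams(min_snp_count=10, min_length_bp=2_000_000))
        )
        stricter_snps = len(
            detect_roh(m, ROHParams(min_snp_count=40, min_length_bp=200_000))
        )
        assert stricter_len <= base and stricter_snps <= base

    def test_invariant_to_sample_order_and_chrom_labels(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, 5, 150, n_chrom=2, p_het=0.08)
        params = ROHParams(min_snp_count=10, min_length_bp=300_000)
        segs = detect_roh(m, params)
        perm = rng.permutation(m.n_samples)
        m2 = GenotypeMatrix(m.calls[perm], m.samples.iloc[perm], m.markers, sort=False)
        segs2 = detect_roh(m2, params)
        key = ["sample_id", "chrom", "start_bp"]
        pd.testing.assert_frame_equal(
            segs.sort_values(key).reset_index(drop=True),
            segs2.sort_values(key).reset_index(drop=True),
        )
        relabel = m.markers.copy()
        relabel["chrom"] = relabel["chrom"].map({"1": "7", "2": "9"})
        m3 = GenotypeMatrix(m.calls, m.samples, relabel, sort=False)
        segs3 = detect_roh(m3, params)
        assert len(segs3) == len(segs)
        assert list(segs3["start_bp"]) == list(segs["start_bp"])

    @pytest.mark.parametrize("trial", range(40))
    def test_equals_bruteforce_scan(self, trial):
        """Vectorized caller equals the exhaustive plain-loop scan."""
        rng = np.random.default_rng(1000 + trial)
        m_markers = int(rng.integers(30, 300))
        p_het = float(rng.choice([0.02, 0.1, 0.3]))
        p_mis = float(rng.choice([0.0, 0.05]))
        spacing = int(rng.choice([20_000, 60_000, 120_000]))
        geno = rng.choice(
            [0, 1, 2, -1],
            size=m_markers,
            p=[(1 - p_het - p_mis) * 0.6, p_het, (1 - p_het - p_mis) * 0.4, p_mis],
        )
        positions = np.cumsum(rng.integers(1, spacing, size=m_markers))
        params = ROHParams(
            window_snps=int(rng.choice([10, 25, 50])),
            window_max_het=int(rng.choice([0, 1, 2])),
            window_max_missing=int(rng.choice([0, 2, 5])),
            window_hit_fraction=float(rng.choice([0.05, 0.1, 0.5])),
            min_snp_count=int(rng.choice([5, 15, 30])),
            min_length_bp=int(rng.choice([200_000, 1_000_000])),
            max_gap_bp=int(rng.choice([200_000, 1_000_000])),
            min_density_bp_per_snp=int(rng.choice([50_000, 100_000])),
        )
        m = _one_sample(list(geno), list(positions))
        got = [
            (int(r.start_bp), int(r.end_bp), int(r.n_snps))
            for r in detect_roh(m, params).itertuples()
        ]
        expected = roh_bruteforce(
            geno,
            positions,
            window_snps=params.window_snps,
            window_max_het=params.window_max_het,
            window_max_missing=params.window_max_missing,
            window_hit_fraction=params.window_hit_fraction,
            max_gap_bp=params.max_gap_bp,
            min_length_bp=params.min_length_bp,
            min_snp_count=params.min_snp_count,
            min_density_bp_per_snp=params.min_density_bp_per_snp,
        )
        assert got == expected


class TestClassification:
    @pytest.mark.parametrize(
        "length_bp,label",
        [
            (1_000_000, "1-5Mb"),
            (4_999_999, "1-5Mb"),
            (5_000_000, "5-10Mb"),
            (9_999_999, "5-10Mb"),
            (10_000_000, ">10Mb"),
            (25_000_000, ">10Mb"),
        ],
    )
    def test_left_closed_boundaries(self, length_bp, label):
        assert classify_length(length_bp) == label

    def test_summary_counts_and_shares(self):
        segs = pd.DataFrame(
            {
                "sample_id": ["a", "a", "b"],
                "chrom": ["1", "2", "1"],
                "start_bp": [1, 1, 1],
                "end_bp": [2_000_000, 7_000_000, 12_000_000],
                "n_snps": [40, 140, 240],
                "length_bp": [2_000_000, 7_000_000, 12_000_000],
                "length_class": ["1-5Mb", "5-10Mb", ">10Mb"],
            }
        )
        summary = class_summary(segs).set_index("length_class")
        assert list(summary["n_segments"]) == [1, 1, 1]
        assert summary.loc["1-5Mb", "length_share"] == pytest.approx(2 / 21)
        assert summary.loc["5-10Mb", "length_share"] == pytest.approx(7 / 21)
        assert summary.loc[">10Mb", "length_share"] == pytest.approx(12 / 21)
        per = classify_segments(segs)
        assert per["n_segments"].sum() == 3

    def test_empty_summary_is_zero(self):
        summary = class_summary(pd.DataFrame(columns=["length_bp", "length_class"]))
        assert summary["n_segments"].sum() == 0


class TestGenerationDating:
    @pytest.mark.parametrize("mb,g", [(10.0, 5.0), (50.0, 1.0), (1.0, 50.0)])
    def test_expected_age(self, mb, g):
        assert generations_from_length(mb) == pytest.approx(g)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generations_from_length(0.0)


def test_resolved_threshold_uses_observed_het(tiny_matrix):
    params = ROHParams(alpha=0.05)
    expected = min_snp_count(
        0.05, tiny_matrix.n_markers, tiny_matrix.n_samples, tiny_matrix.het_proportion()
    )
    assert resolve_min_snp_count(tiny_matrix, params) == expected
    assert resolve_min_snp_count(tiny_matrix, ROHParams(min_snp_count=7)) == 7
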