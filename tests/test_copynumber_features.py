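import numpy as np
import pytest

import darcsign as ds
from darcsign.copynumber_features import (
    DEFAULT_SCHEMA,
    breakpoints_per_10mb,
    breaks_per_arm,
    burden_summary,
    cn_state_counts,
    cncp_features,
    copy_fraction,
    segment_size_features,
)
from darcsign.mutation_features import build_catalog
from darcsign.types import CopySegment, ValidationError
from conftest import make_segment
import oracles

MB = 1_000_000


def seg(chrom="1", start=1, end=MB, t=2, a=1, b=1):
    return CopySegment(chrom=chrom, start=start, end=end, total_cn=t,
                       major_cn=a, minor_cn=b)


def to_rows(segments):
    return [(s.chrom, s.start, s.end, s.total_cn, s.major_cn, s.minor_cn)
            for s in segments]


def from_rows(rows):
    return [CopySegment(chrom=c, start=s, end=e, total_cn=t, major_cn=a, minor_cn=b)
            for (c, s, e, t, a, b) in rows]


@pytest.fixture(scope="module")
def random_genomes(toy_arm_map):
    lengths = {c: a.length for c, a in toy_arm_map.chromosomes.items()}
    rng = np.random.default_rng(42)
    return [oracles.random_genome(rng, lengths) for _ in range(120)], lengths


class TestBreakpointsPer10Mb:
    def test_single_whole_chromosome_segments_count_zero(self, toy_arm_map):
        segments = [seg(chrom="1", end=100 * MB), seg(chrom="2", end=60 * MB)]
        hist = breakpoints_per_10mb(segments, toy_arm_map)
        assert hist[0] == 16  # 10 + 6 windows, all empty
        assert hist[1:].sum() == 0

    def test_three_endpoints_in_one_window_minus_terminal(self, toy_arm_map):
        segments = [
            seg(chrom="1", start=1, end=2 * MB),
            seg(chrom="1", start=2 * MB + 1, end=5 * MB),
            seg(chrom="1", start=5 * MB + 1, end=100 * MB),  # terminal: excluded
            seg(chrom="2", end=60 * MB),
        ]
        hist = breakpoints_per_10mb(segments, toy_arm_map)
        assert hist[2] == 1  # two counted endpoints in the first window

    def test_segment_beyond_chromosome_end_rejected(self, toy_arm_map):
        with pytest.raises(ValidationError, match="beyond chromosome end"):
            breakpoints_per_10mb([seg(end=200 * MB)], toy_arm_map)

    def test_matches_oracle_on_random_genomes(self, toy_arm_map, random_genomes):
        genomes, lengths = random_genomes
        for rows in genomes:
            got = breakpoints_per_10mb(from_rows(rows), toy_arm_map)
            assert got.tolist() == oracles.oracle_bc10(rows, lengths)


class TestBreaksPerArm:
    def test_one_segment_per_arm_means_no_breaks(self, toy_arm_map):
        segments = []
        for chrom, arms in toy_arm_map.chromosomes.items():
            segments.append(seg(chrom=chrom, start=arms.p[0], end=arms.p[1]))
            segments.append(seg(chrom=chrom, start=arms.q[0], end=arms.q[1]))
        hist = breaks_per_arm(segments, toy_arm_map)
        assert hist[0] == 4 and hist[1:].sum() == 0

    def test_four_segments_on_an_arm_is_three_breaks(self, toy_arm_map):
        starts = [1, 10 * MB, 20 * MB, 30 * MB]
        segments = [
            seg(chrom="1", start=s + (1 if s > 1 else 0), end=e)
            for s, e in zip(starts, [10 * MB, 20 * MB, 30 * MB, 40 * MB])
        ]
        hist = breaks_per_arm(segments, toy_arm_map)
        assert hist[3] == 1

    def test_straddling_segment_counts_in_both_arms(self, toy_arm_map):
        segments = [seg(chrom="1", start=39 * MB, end=41 * MB)]
        # one segment overlapping p and q: zero breaks in each arm
        hist = breaks_per_arm(segments, toy_arm_map)
        rows = to_rows(segments)
        arms = [(c, s, e) for (c, _n, s, e) in toy_arm_map.arms()]
        assert hist.tolist() == oracles.oracle_bcperca(rows, arms)

    def test_unknown_chromosome_rejected(self, toy_arm_map):
        with pytest.raises(ValidationError, match="absent from arm map"):
            breaks_per_arm([seg(chrom="17")], toy_arm_map)

    def test_matches_oracle_on_random_genomes(self, toy_arm_map, random_genomes):
        genomes, _ = random_genomes
        arms = [(c, s, e) for (c, _n, s, e) in toy_arm_map.arms()]
        for rows in genomes:
            got = breaks_per_arm(from_rows(rows), toy_arm_map)
            assert got.tolist() == oracles.oracle_bcperca(rows, arms)


class TestStateAndSizeCategories:
    def test_all_diploid_counts(self):
        segments = [seg(start=1 + i * MB, end=(i + 1) * MB) for i in range(5)]
        assert cn_state_counts(segments)[2] == 5

    def test_high_state_clamped_to_top_bin(self):
        assert cn_state_counts([seg(t=12, a=6, b=6)])[8] == 1

    def test_copy_fraction_halves(self):
        segments = [
            seg(start=1, end=10 * MB, t=2, a=1, b=1),
            seg(start=10 * MB + 1, end=20 * MB, t=4, a=2, b=2),
        ]
        frac = copy_fraction(segments)
        assert frac[2] == pytest.approx(0.5)
        assert frac[4] == pytest.approx(0.5)

    def test_copy_fraction_empty_is_zero(self):
        assert copy_fraction([]).sum() == 0

    def test_segsize_bins(self):
        assert segment_size_features([seg(end=100 * MB)])[9] == 1  # SegSize_10
        assert segment_size_features([seg(end=4_000)])[0] == 1     # below 5 kb

    def test_cncp_alternating_pattern(self):
        # copy pattern 2,3,2,3 -> three |delta|=1 change points
        totals = [2, 3, 2, 3]
        segments = [
            seg(start=1 + i * MB, end=(i + 1) * MB, t=t, a=t - 1, b=1)
            for i, t in enumerate(totals)
        ]
        assert cncp_features(segments)[0] == 3

    def test_single_segment_chromosomes_have_no_change_points(self):
        segments = [seg(chrom="1"), seg(chrom="2")]
        assert cncp_features(segments).sum() == 0

    def test_categories_match_oracles_on_random_genomes(self, random_genomes):
        genomes, _ = random_genomes
        edges = list(DEFAULT_SCHEMA.segsize_edges)
        for rows in genomes:
            segments = from_rows(rows)
            assert cn_state_counts(segments).tolist() == oracles.oracle_cn_counts(rows)
            assert np.allclose(copy_fraction(segments),
                               oracles.oracle_copy_fraction(rows))
            assert segment_size_features(segments).tolist() == \
                oracles.oracle_segsize(rows, edges)
            assert cncp_features(segments).tolist() == oracles.oracle_cncp(rows)

    def test_copy_fraction_sums_to_one(self, random_genomes):
        genomes, _ = random_genomes
        for rows in genomes[:30]:
            assert copy_fraction(from_rows(rows)).sum() == pytest.approx(1.0, abs=1e-9)


class TestExtractCnFeatures:
    def test_empty_input_gives_45_zeros(self, toy_arm_map):
        features = ds.extract_cn_features([], toy_arm_map)
        assert len(features) == 45
        # windows/arms still exist, so count-bin zero classes are populated
        assert features["CN_2"] == 0 and features["SegSize_1"] == 0

    def test_permutation_invariance(self, toy_arm_map, random_genomes):
        genomes, _ = random_genomes
        rng = np.random.default_rng(0)
        for rows in genomes[:10]:
            segments = from_rows(rows)
            shuffled = list(segments)
            rng.shuffle(shuffled)
            a = ds.extract_cn_features(segments, toy_arm_map)
            b = ds.extract_cn_features(shuffled, toy_arm_map)
            assert (a == b).all()

    def test_equals_concatenated_category_vectors(self, toy_arm_map, random_genomes):
        genomes, _ = random_genomes
        rows = genomes[0]
        segments = from_rows(rows)
        features = ds.extract_cn_features(segments, toy_arm_map)
        concat = np.concatenate([
            breakpoints_per_10mb(segments, toy_arm_map),
            breaks_per_arm(segments, toy_arm_map),
            cn_state_counts(segments),
            copy_fraction(segments),
            segment_size_features(segments),
            cncp_features(segments),
        ])
        assert np.allclose(features.values, concat)


class TestScarScores:
    def test_hrd_loh_inner_region(self):
        segments = [
            seg(start=1, end=30 * MB, t=2, a=1, b=1),
            seg(start=30 * MB + 1, end=50 * MB, t=1, a=1, b=0),  # 20 Mb LOH
            seg(start=50 * MB + 1, end=100 * MB, t=2, a=1, b=1),
        ]
        assert ds.hrd_loh(segments) == 1

    def test_whole_chromosome_loh_excluded(self):
        assert ds.hrd_loh([seg(start=1, end=100 * MB, t=1, a=1, b=0)]) == 0

    def test_fourteen_mb_loh_below_threshold(self):
        segments = [
            seg(start=1, end=30 * MB),
            seg(start=30 * MB + 1, end=44 * MB, t=1, a=1, b=0),
            seg(start=44 * MB + 1, end=100 * MB),
        ]
        assert ds.hrd_loh(segments) == 0

    def test_adjacent_loh_segments_merged_before_length_test(self):
        segments = [
            seg(start=1, end=30 * MB),
            seg(start=30 * MB + 1, end=40 * MB, t=1, a=1, b=0),
            seg(start=40 * MB + 1, end=50 * MB, t=2, a=2, b=0),
            seg(start=50 * MB + 1, end=100 * MB),
        ]
        assert ds.hrd_loh(segments) == 1  # merged 20 Mb LOH region

    def test_lst_on_adjacent_large_segments(self):
        segments = [
            seg(start=1, end=12 * MB, t=2, a=1, b=1),
            seg(start=12 * MB + 1, end=24 * MB, t=3, a=2, b=1),
        ]
        assert ds.lst(segments) == 1

    def test_lst_requires_both_segments_large(self):
        segments = [
            seg(start=1, end=12 * MB, t=2, a=1, b=1),
            seg(start=12 * MB + 1, end=20 * MB, t=3, a=2, b=1),  # 8 Mb
        ]
        assert ds.lst(segments) == 0

    def test_lst_zero_for_single_segments(self):
        assert ds.lst([seg(chrom="1"), seg(chrom="2")]) == 0

    def test_telomeric_imbalance_at_chromosome_end(self, toy_arm_map):
        segments = [
            seg(start=1, end=60 * MB, t=2, a=1, b=1),
            seg(start=60 * MB + 1, end=100 * MB, t=3, a=2, b=1),
        ]
        assert ds.telomeric_ai(segments, toy_arm_map) == 1

    def test_balanced_telomeric_segment_not_counted(self, toy_arm_map):
        segments = [seg(start=1, end=50 * MB, t=2, a=1, b=1)]
        assert ds.telomeric_ai(segments, toy_arm_map) == 0

    def test_whole_chromosome_imbalance_excluded(self, toy_arm_map):
        segments = [seg(start=1, end=100 * MB, t=3, a=2, b=1)]
        assert ds.telomeric_ai(segments, toy_arm_map) == 0

    def test_total_is_component_sum(self, toy_arm_map, random_genomes):
        genomes, _ = random_genomes
        for rows in genomes[:10]:
            scores = ds.scar_scores(from_rows(rows), toy_arm_map)
            assert scores.total == scores.hrd_loh + scores.lst + scores.telomeric_ai

    def test_diploid_balanced_genome_scores_zero(self, toy_arm_map):
        segments = [seg(chrom="1", end=100 * MB), seg(chrom="2", end=60 * MB)]
        scores = ds.scar_scores(segments, toy_arm_map)
        assert (scores.hrd_loh, scores.lst, scores.telomeric_ai, scores.total) == (0, 0, 0, 0)

    def test_scar_components_match_oracles_on_random_genomes(
        self, toy_arm_map, random_genomes
    ):
        genomes, lengths = random_genomes
        for rows in genomes:
            segments = from_rows(rows)
            assert ds.hrd_loh(segments) == oracles.oracle_hrd_loh(rows)
            assert ds.lst(segments) == oracles.oracle_lst(rows)
            assert ds.telomeric_ai(segments, toy_arm_map) == \
                oracles.oracle_tai(rows, lengths)


class TestBurdenAndEffectSize:
    def test_all_diploid_unaltered(self):
        catalog = build_catalog([], "s")
        summary = burden_summary(catalog, [seg(end=50 * MB)])
        assert summary.altered_fraction == 0.0
        assert summary.base_ploidy == 2

    def test_half_genome_gained(self):
        catalog = build_catalog([], "s")
        segments = [
            seg(start=1, end=50 * MB, t=2, a=1, b=1),
            seg(start=50 * MB + 1, end=75 * MB, t=4, a=2, b=2),
            seg(start=75 * MB + 1, end=100 * MB, t=4, a=3, b=1),
        ]
        summary = burden_summary(catalog, segments)
        assert summary.altered_fraction == pytest.approx(0.5)
        assert summary.mean_ploidy == pytest.approx(3.0)

    def test_cohens_d_identical_groups_zero(self):
        assert ds.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_cohens_d_unit_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 5000)
        b = rng.normal(0.0, 1.0, 5000)
        assert ds.cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_cohens_d_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        a = rng.normal(3.0, 2.0, 37)
        b = rng.normal(1.0, 1.5, 23)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
                         / (na + nb - 2))
        assert ds.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)
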