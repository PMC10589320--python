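"""Copy-number profile filling, ploidy, base-level comparison, gene events.

The interval-based comparison is checked against a per-base brute-force
oracle on small toy genomes.
"""

import numpy as np
import pytest

from wesconcord.cna_concordance import (
    CNEventClass,
    GeneAgreement,
    aggregate_match_fraction,
    call_gene_event,
    cn_diff_summary,
    compare_profiles,
    fill_profile,
    gene_event_matrix,
    predominant_ploidy,
)
from wesconcord.core_io import CNSegment, GeneInterval, GenomeModel, ValidationError

TOY = GenomeModel(("chr1",), {"chr1": 1_000_000}, ("chr1",))
TWO_CHROM = GenomeModel(
    ("chr1", "chr2"), {"chr1": 60_000, "chr2": 40_000}, ("chr1", "chr2")
)


def seg(start, end, cn, chrom="chr1"):
    return CNSegment(chrom, start, end, cn)


def random_profile(rng, genome, max_cn=8, name="x"):
    segments = []
    for chrom in genome.included_chromosomes:
        length = genome.lengths[chrom]
        n_breaks = int(rng.integers(0, 6))
        breaks = sorted(set(int(b) for b in rng.integers(1, length, n_breaks)))
        bounds = [0, *breaks, length]
        for s, e in zip(bounds, bounds[1:]):
            segments.append(seg(s, e, int(rng.integers(0, max_cn + 1)), chrom))
    return fill_profile(segments, genome, institution_id=name)


def per_base_oracle(a, b, rule="ratio"):
    """Brute-force base loop: (exact, duplication, mismatch, histogram)."""
    pa, pb = predominant_ploidy(a), predominant_ploidy(b)
    exact = dup = mis = 0
    hist: dict[int, int] = {}
    for chrom in a.genome.included_chromosomes:
        arr_a = np.empty(a.genome.lengths[chrom], dtype=int)
        arr_b = np.empty_like(arr_a)
        for s in a.segments[chrom]:
            arr_a[s.start:s.end] = s.total_cn
        for s in b.segments[chrom]:
            arr_b[s.start:s.end] = s.total_cn
        for ca, cb in zip(arr_a, arr_b):
            if ca == cb:
                exact += 1
            elif pa != pb and (
                (rule == "ratio" and ca * pb == cb * pa)
                or (rule == "delta" and ca - pa == cb - pb)
            ):
                dup += 1
            else:
                mis += 1
                hist[abs(ca - cb)] = hist.get(abs(ca - cb), 0) + 1
    return exact, dup, mis, hist


class TestFillProfile:
    def test_empty_input_gives_neutral_genome(self):
        profile = fill_profile([], TOY)
        (only,) = profile.segments["chr1"]
        assert (only.start, only.end, only.total_cn) == (0, 1_000_000, 2)

    def test_gap_filling_around_one_segment(self):
        profile = fill_profile([seg(100, 200, 4)], TOY)
        cns = [(s.start, s.end, s.total_cn) for s in profile.segments["chr1"]]
        assert cns == [(0, 100, 2), (100, 200, 4), (200, 1_000_000, 2)]

    def test_fill_round_trip_re_extracts_input(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(1, 6))
            bounds = sorted(rng.choice(np.arange(1, 1_000_000), 2 * n, replace=False))
            segments = []
            for i in range(n):
                cn = int(rng.choice([0, 1, 3, 4, 5]))  # non-neutral
                segments.append(seg(int(bounds[2 * i]), int(bounds[2 * i + 1]), cn))
            profile = fill_profile(segments, TOY)
            back = [s for s in profile.segments["chr1"] if s.total_cn != 2]
            # merge adjacent equal-CN input segments the way fill does
            merged = []
            for s in segments:
                if merged and merged[-1].end == s.start and merged[-1].total_cn == s.total_cn:
                    merged[-1] = seg(merged[-1].start, s.end, s.total_cn)
                else:
                    merged.append(s)
            assert back == merged

    def test_idempotent(self):
        profile = fill_profile([seg(0, 500, 3)], TOY)
        again = fill_profile(
            [s for chrom in profile.segments.values() for s in chrom], TOY
        )
        assert again.segments == profile.segments

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            fill_profile([seg(0, 2_000_000, 2)], TOY)

    def test_allele_specific_neutral_fill(self):
        profile = fill_profile([], TOY, allele_specific=True)
        (only,) = profile.segments["chr1"]
        assert (only.major_cn, only.minor_cn) == (1, 1)


class TestPredominantPloidy:
    def test_uniform_diploid(self):
        assert predominant_ploidy(fill_profile([], TOY)) == 2

    def test_majority_rule(self):
        profile = fill_profile([seg(0, 600_000, 4)], TOY)
        assert predominant_ploidy(profile) == 4

    def test_tie_breaks_toward_lower_cn(self):
        profile = fill_profile([seg(0, 500_000, 4)], TOY)
        assert predominant_ploidy(profile) == 2


class TestCompareProfiles:
    def test_identical_profiles_match_exactly(self):
        a = fill_profile([seg(0, 300, 3)], TOY, institution_id="A")
        cmp = compare_profiles(a, a)
        assert cmp.fractions["exact"] == 1.0

    def test_exact_doubling_is_fully_duplication_explained(self):
        rng = np.random.default_rng(7)
        a = random_profile(rng, TWO_CHROM, name="A")
        doubled = [
            CNSegment(s.chromosome, s.start, s.end, s.total_cn * 2)
            for chrom in TWO_CHROM.included_chromosomes
            for s in a.segments[chrom]
        ]
        b = fill_profile(doubled, TWO_CHROM, institution_id="B", neutral_cn=4)
        cmp = compare_profiles(a, b)
        assert cmp.mismatch_bp == 0
        assert cmp.fractions["exact"] + cmp.fractions["duplication"] == pytest.approx(1.0)

    @pytest.mark.parametrize("rule", ["ratio", "delta"])
    def test_interval_equals_per_base_oracle(self, rule):
        genome = GenomeModel(
            ("chr1", "chr2"), {"chr1": 60_000, "chr2": 40_000}, ("chr1", "chr2")
        )
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = random_profile(rng, genome, name="A")
            b = random_profile(rng, genome, name="B")
            cmp = compare_profiles(a, b, rule=rule)
            exact, dup, mis, hist = per_base_oracle(a, b, rule=rule)
            assert (cmp.exact_match_bp, cmp.duplication_match_bp, cmp.mismatch_bp) == \
                (exact, dup, mis)
            assert cmp.cn_diff_histogram == hist

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a = random_profile(rng, TWO_CHROM, name="A")
            b = random_profile(rng, TWO_CHROM, name="B")
            ab, ba = compare_profiles(a, b), compare_profiles(b, a)
            assert ab.exact_match_bp == ba.exact_match_bp
            assert ab.duplication_match_bp == ba.duplication_match_bp
            assert ab.cn_diff_histogram == ba.cn_diff_histogram

    def test_base_count_conservation(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = random_profile(rng, TWO_CHROM, name="A")
            b = random_profile(rng, TWO_CHROM, name="B")
            cmp = compare_profiles(a, b)
            assert cmp.genome_bp == TWO_CHROM.included_length
            assert sum(cmp.cn_diff_histogram.values()) == cmp.mismatch_bp
            assert sum(cmp.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_genome_mismatch_rejected(self):
        a = fill_profile([], TOY)
        b = fill_profile([], TWO_CHROM)
        with pytest.raises(ValidationError, match="genome"):
            compare_profiles(a, b)


class TestDiffSummary:
    def test_single_delta(self):
        a = fill_profile([seg(0, 1000, 3)], TOY, institution_id="A")
        b = fill_profile([], TOY, institution_id="B")
        summary = cn_diff_summary([compare_profiles(a, b)])
        assert summary == {1: 1.0}

    def test_three_to_one_ratio(self):
        a = fill_profile([seg(0, 300, 3), seg(300, 400, 4)], TOY, institution_id="A")
        b = fill_profile([], TOY, institution_id="B")
        summary = cn_diff_summary([compare_profiles(a, b)])
        assert summary == {1: pytest.approx(0.75), 2: pytest.approx(0.25)}

    def test_no_mismatch_gives_empty_distribution(self):
        a = fill_profile([], TOY)
        assert cn_diff_summary([compare_profiles(a, a)]) == {}

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(23)
        a = random_profile(rng, TWO_CHROM, name="A")
        b = random_profile(rng, TWO_CHROM, name="B")
        permuted = GenomeModel(
            ("chr2", "chr1"), TWO_CHROM.lengths, ("chr2", "chr1")
        )
        a2 = fill_profile(
            [s for c in a.segments.values() for s in c], permuted, institution_id="A"
        )
        b2 = fill_profile(
            [s for c in b.segments.values() for s in c], permuted, institution_id="B"
        )
        assert compare_profiles(a, b).fractions == compare_profiles(a2, b2).fractions


class TestGeneEvents:
    def _profile(self, cn, ploidy_cn=2):
        return fill_profile(
            [seg(1000, 3000, cn)], TOY, institution_id="A", neutral_cn=ploidy_cn
        )

    def test_high_amplification_delta_from_ploidy(self):
        event = call_gene_event(self._profile(7), "G", "chr1", 1500, 2500)
        assert event.classification is CNEventClass.HIGH_AMP

    def test_low_amplification_below_delta(self):
        event = call_gene_event(self._profile(4), "G", "chr1", 1500, 2500)
        assert event.classification is CNEventClass.LOW_AMP

    def test_monoallelic_and_deep_deletion(self):
        assert call_gene_event(self._profile(1), "G", "chr1", 1500, 2500).classification \
            is CNEventClass.MONOALLELIC_DEL
        assert call_gene_event(self._profile(0), "G", "chr1", 1500, 2500).classification \
            is CNEventClass.DEEP_DEL

    def test_high_amp_relative_to_tetraploid(self):
        profile = fill_profile([seg(1000, 3000, 7)], TOY, neutral_cn=4)
        event = call_gene_event(profile, "G", "chr1", 1500, 2500)
        assert event.ploidy == 4
        assert event.classification is CNEventClass.LOW_AMP  # delta 3 < 5

    def test_interval_outside_genome_rejected(self):
        with pytest.raises(ValidationError):
            call_gene_event(self._profile(2), "G", "chr1", 900_000, 2_000_000)

    def test_matrix_agreement_categories(self):
        gi = GeneInterval("G", "chr1", 1500, 2500)
        def profiles(cns):
            return {
                f"I{i}": self._profile(cn) for i, cn in enumerate(cns)
            }
        _, agree = gene_event_matrix(profiles([8, 8, 8, 8, 8]), [gi])
        assert agree["G"] is GeneAgreement.ALL_AGREE
        _, agree = gene_event_matrix(profiles([7, 7, 6, 4, 7]), [gi])
        assert agree["G"] is GeneAgreement.THRESHOLD_DISAGREEMENT
        _, agree = gene_event_matrix(profiles([0, 0, 0, 0, 1]), [gi])
        assert agree["G"] is GeneAgreement.PRESENCE_DISAGREEMENT


class TestAggregation:
    def test_pooled_and_per_pair_aggregates(self):
        a = fill_profile([], TOY, institution_id="A")
        b = fill_profile([seg(0, 500_000, 3)], TOY, institution_id="B")
        full = compare_profiles(a, a)
        half = compare_profiles(a, b)
        agg = aggregate_match_fraction([full, half])
        assert agg["pooled"] == pytest.approx(0.75)
        assert agg["per_pair_mean"] == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_match_fraction([])
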