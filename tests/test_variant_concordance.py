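"""Consensus references, PPA/PPV, support histogram, discordance taxonomy."""

import numpy as np
import pytest
from scipy.stats import binom

from wesconcord.core_io import (
    AnnotationTable,
    FilterStatus,
    Flag,
    TherapeuticAnnotation,
    ValidationError,
    VariantCall,
    VariantKey,
)
from wesconcord.variant_concordance import (
    CallSetCollection,
    Cause,
    Direction,
    aggregate_concordance,
    annotate_therapeutic,
    build_consensus,
    classify_all_discordant,
    classify_discordance,
    clopper_pearson,
    restrict_to_panel,
    score_against_reference,
    support_histogram,
    therapeutic_concordance_matrix,
)


def key(i: int, chrom: str = "chr1") -> VariantKey:
    return VariantKey(chrom, 100 + i * 10, "A", "G")


def call(case, inst, k, vaf=0.4, depth=200, gene="", flags=(), status=FilterStatus.PASS,
         evidence_reads=None):
    return VariantCall(
        case_id=case, institution_id=inst, key=k, vaf=vaf, depth=depth,
        gene=gene, flags=frozenset(flags), filter_status=status,
        evidence_reads=evidence_reads,
    )


def collection_from(spec: dict, roster=("A", "B", "C", "D", "E")) -> CallSetCollection:
    """spec: {institution: [variant index, ...]} for a single case 'c1'."""
    calls = [call("c1", inst, key(i)) for inst, idxs in spec.items() for i in idxs]
    return CallSetCollection.from_calls(calls, roster=roster)


class TestConsensus:
    def test_membership_by_support_level(self):
        col = collection_from({"A": [1, 2], "B": [1, 2], "C": [1], "D": [], "E": []})
        ref3 = build_consensus(col, "c1", 3)
        ref2 = build_consensus(col, "c1", 2)
        assert key(1) in ref3.variants and key(1) in ref2.variants
        assert key(2) not in ref3.variants and key(2) in ref2.variants

    def test_empty_case_gives_empty_reference(self):
        col = CallSetCollection.from_calls(
            [call("c29", "A", key(1), vaf=0.2)], roster=("A", "B")
        )
        col.calls[("c29", "A")] = {}
        ref = build_consensus(col, "c29", 2)
        assert ref.variants == frozenset()

    def test_unknown_case_rejected(self):
        col = collection_from({"A": [1]})
        with pytest.raises(ValidationError, match="unknown case"):
            build_consensus(col, "nope", 2)

    def test_min_support_bounds(self):
        col = collection_from({"A": [1]})
        with pytest.raises(ValidationError):
            build_consensus(col, "c1", 1)
        with pytest.raises(ValidationError):
            build_consensus(col, "c1", 6)

    def test_monotone_nesting_on_random_collections(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            spec = {
                inst: list(rng.choice(20, size=rng.integers(0, 15), replace=False))
                for inst in "ABCDE"
            }
            col = collection_from(spec)
            refs = [build_consensus(col, "c1", k) for k in (2, 3, 4, 5)]
            for tighter, looser in zip(refs[1:], refs):
                assert tighter.variants <= looser.variants


class TestScoring:
    def test_counts_and_ratios(self):
        col = collection_from({"A": [1, 2, 4], "B": [1, 2, 3], "C": [1, 2, 3], "D": [3], "E": []})
        ref = build_consensus(col, "c1", 2)  # {1, 2, 3}
        res = score_against_reference(col, ref, "A")
        assert (res.tp, res.fn, res.fp) == (2, 1, 1)
        assert res.ppa == pytest.approx(2 / 3)
        assert res.ppv == pytest.approx(2 / 3)

    def test_identity_scores_one(self):
        col = collection_from({"A": [1, 2], "B": [1, 2], "C": []})
        ref = build_consensus(col, "c1", 2)
        res = score_against_reference(col, ref, "A")
        assert res.ppa == 1.0 and res.ppv == 1.0

    def test_undefined_ratios_are_none_not_zero(self):
        col = collection_from({"A": [], "B": [], "C": []})
        col.calls[("c1", "A")] = {}
        ref = build_consensus(col, "c1", 2)
        res = score_against_reference(col, ref, "A")
        assert res.ppa is None and res.ppv is None
        agg = aggregate_concordance([res], mode="per_case_mean")
        assert agg["ppa"] is None

    def test_sum_rules_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            spec = {
                inst: list(rng.choice(30, size=rng.integers(0, 20), replace=False))
                for inst in "ABCDE"
            }
            col = collection_from(spec)
            ref = build_consensus(col, "c1", int(rng.integers(2, 6)))
            for inst in "ABCDE":
                res = score_against_reference(col, ref, inst)
                assert res.tp + res.fn == len(ref.variants)
                assert res.tp + res.fp == len(col.keys_for("c1", inst))

    def test_unknown_institution_rejected(self):
        col = collection_from({"A": [1], "B": [1]})
        ref = build_consensus(col, "c1", 2)
        with pytest.raises(ValidationError, match="roster"):
            score_against_reference(col, ref, "Z")

    def test_ppa_tracks_designed_detection_probability(self):
        """Mean PPA over seeded replicates sits inside the binomial CI of p."""
        p = 0.93
        n_variants, n_reps = 200, 100
        rng = np.random.default_rng(42)
        ppas = []
        for _ in range(n_reps):
            detected = rng.random(n_variants) < p
            ppas.append(detected.mean())
        lo, hi = binom.interval(0.95, n_variants * n_reps, p)
        total = np.sum(ppas) * n_variants
        assert lo <= total <= hi


class TestSupportHistogram:
    def test_single_variant_all_institutions(self):
        col = collection_from({inst: [1] for inst in "ABCDE"})
        hist = support_histogram(col)
        assert dict(hist.counts) == {5: 1}
        assert hist.buckets == {"all": 1, "some": 0, "single": 0}

    def test_mixed_support(self):
        col = collection_from({"A": [1, 2], "B": [1], "C": [], "D": [], "E": []})
        hist = support_histogram(col)
        assert dict(hist.counts) == {2: 1, 1: 1}

    def test_bucket_sum_equals_unique_pairs(self, small_collection):
        hist = support_histogram(small_collection)
        unique_pairs = sum(
            len(small_collection.unique_keys(case)) for case in small_collection.cases
        )
        assert hist.total == unique_pairs
        assert sum(hist.buckets.values()) == unique_pairs

    def test_matches_exhaustive_enumeration_on_simulated_cohort(
        self, small_cohort, small_collection
    ):
        hist = support_histogram(small_collection)
        brute = {}
        for case in small_collection.cases:
            seen = {}
            for inst in small_collection.roster:
                for k in small_collection.keys_for(case, inst):
                    seen[k] = seen.get(k, 0) + 1
            for level in seen.values():
                brute[level] = brute.get(level, 0) + 1
        assert dict(hist.counts) == brute


class TestDiscordanceClassification:
    def _missed_setup(self, evidence):
        col = collection_from({"A": [], "B": [1], "C": [1], "D": [1], "E": [1]})
        return classify_discordance(key(1), "c1", "A", col, evidence=evidence)

    def test_low_vaf_and_coverage(self):
        rec = self._missed_setup(call("c1", "A", key(1), vaf=0.053, depth=78))
        assert rec.cause is Cause.LOW_VAF_OR_COVERAGE
        assert rec.direction is Direction.MISSED_BY_INSTITUTION

    def test_filter_removed(self):
        rec = self._missed_setup(
            call("c1", "A", key(1), vaf=0.4, depth=200, status=FilterStatus.QUALITY_FILTERED)
        )
        assert rec.cause is Cause.QUALITY_OR_PASS_FILTER

    def test_annotation_merged(self):
        rec = self._missed_setup(
            call("c1", "A", key(1), flags={Flag.ANNOTATION_MERGED})
        )
        assert rec.cause is Cause.ANNOTATION_MERGED

    def test_no_supporting_reads(self):
        rec = self._missed_setup(call("c1", "A", key(1), evidence_reads=0))
        assert rec.cause is Cause.NO_SUPPORTING_READS_OR_OFF_TARGET

    def test_unexplained_without_evidence(self):
        rec = self._missed_setup(None)
        assert rec.cause is Cause.UNEXPLAINED

    def test_singleton_structural_variant_flag(self):
        calls = [call("c1", "A", key(1), flags={Flag.REPORTED_AS_SV})]
        col = CallSetCollection.from_calls(calls, roster=("A", "B", "C", "D", "E"))
        rec = classify_discordance(key(1), "c1", "A", col)
        assert rec.direction is Direction.CALLED_ONLY_BY_INSTITUTION
        assert rec.cause is Cause.STRUCTURAL_VARIANT_CALL

    def test_singleton_somatic_loh(self):
        calls = [call("c1", "A", key(1), flags={Flag.LOH_EVENT})]
        col = CallSetCollection.from_calls(calls, roster=("A", "B"))
        assert classify_discordance(key(1), "c1", "A", col).cause is Cause.SOMATIC_LOH

    def test_concordant_variant_rejected(self):
        col = collection_from({"A": [1], "B": [1], "C": [1], "D": [1], "E": [1]})
        with pytest.raises(ValidationError, match="not discordant"):
            classify_discordance(key(1), "c1", "A", col)

    def test_one_record_per_affected_institution(self):
        col = collection_from({"A": [1], "B": [1], "C": [1], "D": [], "E": []})
        records = classify_all_discordant(col)
        affected = {(r.institution_id, r.direction) for r in records}
        assert affected == {
            ("D", Direction.MISSED_BY_INSTITUTION),
            ("E", Direction.MISSED_BY_INSTITUTION),
        }


class TestClopperPearson:
    def test_closed_forms_at_boundaries(self):
        # k=0: upper = 1 - (alpha/2)^(1/n); k=n: lower = (alpha/2)^(1/n)
        for n in range(1, 51):
            lo0, hi0 = clopper_pearson(0, n, 0.05)
            lon, hin = clopper_pearson(n, n, 0.05)
            assert lo0 == 0.0 and hin == 1.0
            assert hi0 == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-9)
            assert lon == pytest.approx(0.025 ** (1 / n), abs=1e-9)

    def test_k0_n10_value(self):
        _, hi = clopper_pearson(0, 10, 0.05)
        assert hi == pytest.approx(0.3085, abs=5e-5)

    def test_matches_tail_bisection_oracle(self):
        """Interval bounds solve the two-sided binomial tail equations."""
        def bisect(f, lo, hi, tol=1e-12):
            for _ in range(80):
                mid = (lo + hi) / 2
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < tol:
                    break
            return (lo + hi) / 2

        alpha = 0.05
        for n in (1, 2, 5, 10):
            for k in range(0, n + 1):
                lo, hi = clopper_pearson(k, n, alpha)
                if k > 0:
                    # lower bound p solves P(X >= k | p) = alpha/2
                    oracle = bisect(lambda p: alpha / 2 - binom.sf(k - 1, n, p), 0, 1)
                    assert lo == pytest.approx(oracle, abs=1e-6)
                if k < n:
                    oracle = bisect(lambda p: binom.cdf(k, n, p) - alpha / 2, 0, 1)
                    assert hi == pytest.approx(oracle, abs=1e-6)

    def test_interval_contains_point_estimate(self):
        for n in range(1, 51):
            for k in range(0, n + 1):
                lo, hi = clopper_pearson(k, n)
                assert lo <= k / n <= hi

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 20, 40, 80):
            lo, hi = clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        for bad in [(-1, 10, 0.05), (11, 10, 0.05), (0, 0, 0.05), (5, 10, 0.0)]:
            with pytest.raises(ValidationError):
                clopper_pearson(*bad)


class TestPanelAndTherapeutic:
    def test_gene_restriction_and_germline_subtraction(self):
        calls = [
            call("c1", "A", key(1), gene="TP53"),
            call("c1", "A", key(2), gene="OFFPANEL"),
            call("c1", "A", key(3), gene="KRAS"),
        ]
        kept = restrict_to_panel(calls, genes=["TP53", "KRAS"], germline_keys={key(3)})
        assert [c.key for c in kept] == [key(1)]

    def test_disjoint_germline_is_identity(self):
        calls = [call("c1", "A", key(1), gene="TP53")]
        assert restrict_to_panel(calls, genes=["TP53"], germline_keys={key(9)}) == calls

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError, match="empty gene list"):
            restrict_to_panel([], genes=[])

    def test_annotation_tagging(self):
        table = AnnotationTable(variant_rows=[
            TherapeuticAnnotation("EGFR", "*", 1, "osimertinib"),
        ])
        tagged = annotate_therapeutic(
            [call("c1", "A", key(1), gene="EGFR"), call("c1", "A", key(2), gene="XYZ")],
            table,
        )
        assert len(tagged) == 1 and tagged[0].level == 1

    def test_seventeen_druggable_variants_sixteen_full_agreement(self):
        """16 of 17 annotated variants detected by all five institutions."""
        table = AnnotationTable(variant_rows=[
            TherapeuticAnnotation(f"G{i}", "*", (i % 4) + 1, "drug") for i in range(17)
        ])
        calls = []
        for i in range(17):
            insts = ["A"] if i == 16 else list("ABCDE")  # one singleton variant
            for inst in insts:
                calls.append(call("c1", inst, key(i), gene=f"G{i}"))
        col = CallSetCollection.from_calls(calls, roster=tuple("ABCDE"))
        matrix = therapeutic_concordance_matrix(col, table)
        assert len(matrix) == 17
        assert int(matrix["full_agreement"].sum()) == 16
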