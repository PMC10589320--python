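"""Somatic variant call-set concordance.

Builds per-case consensus references (variants detected by at least *k*
institutions), scores each institution against a reference via positive
percentage agreement (PPA, the sensitivity analogue when no ground truth
exists) and positive predictive value (PPV), produces the detection-support
histogram, and classifies the causes of discordant calls.

Since clinical tissue samples carry no absolute truth set, the consensus of
>= k institutions serves as the surrogate reference; PPA and PPV are exact
set statistics on normalized variant keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from scipy.stats import beta as _beta

from wesconcord.core_io import (
    AnnotationTable,
    FilterStatus,
    Flag,
    GeneInterval,
    ValidationError,
    VariantCall,
    VariantClass,
    VariantKey,
)


class Direction(str, Enum):
    MISSED_BY_INSTITUTION = "missed_by_institution"
    CALLED_ONLY_BY_INSTITUTION = "called_only_by_institution"


class Cause(str, Enum):
    """Discordance cause taxonomy (one cause per discordant call)."""

    LOW_VAF_OR_COVERAGE = "low_vaf_or_coverage"
    QUALITY_OR_PASS_FILTER = "quality_or_pass_filter"
    ANNOTATION_MERGED = "annotation_merged"
    GERMLINE_MISLABEL = "germline_mislabel"
    GERMLINE_MISSED = "germline_missed"
    STRUCTURAL_VARIANT_CALL = "structural_variant_call"
    INTRON_OR_POLYMORPHISM_FILTER = "intron_or_polymorphism_filter"
    NO_SUPPORTING_READS_OR_OFF_TARGET = "no_supporting_reads_or_off_target"
    SPLICE_CLASSIFICATION = "splice_classification"
    INDEL_REPRESENTATION = "indel_representation"
    PROMOTER_REGION = "promoter_region"
    SOMATIC_LOH = "somatic_LOH"
    HOMOLOGOUS_REGION = "homologous_region"
    UNEXPLAINED = "unexplained"


# --------------------------------------------------------------------------
# Call-set collection
# --------------------------------------------------------------------------

@dataclass
class CallSetCollection:
    """All institutions' call sets for a cohort, keyed by (case, institution)."""

    roster: tuple[str, ...]
    calls: dict[tuple[str, str], dict[VariantKey, VariantCall]] = field(default_factory=dict)

    @classmethod
    def from_calls(
        cls, calls: Iterable[VariantCall], roster: Sequence[str] | None = None
    ) -> "CallSetCollection":
        mapping: dict[tuple[str, str], dict[VariantKey, VariantCall]] = {}
        seen_institutions: list[str] = []
        for call in calls:
            if call.institution_id not in seen_institutions:
                seen_institutions.append(call.institution_id)
            mapping.setdefault((call.case_id, call.institution_id), {})[call.key] = call
        final_roster = tuple(roster) if roster is not None else tuple(sorted(seen_institutions))
        missing = set(seen_institutions) - set(final_roster)
        if missing:
            raise ValidationError(f"calls from institutions outside roster: {sorted(missing)}")
        return cls(roster=final_roster, calls=mapping)

    @property
    def cases(self) -> tuple[str, ...]:
        return tuple(sorted({case for case, _ in self.calls}))

    def keys_for(self, case_id: str, institution_id: str) -> set[VariantKey]:
        return set(self.calls.get((case_id, institution_id), {}))

    def call_for(self, case_id: str, institution_id: str, key: VariantKey) -> VariantCall | None:
        return self.calls.get((case_id, institution_id), {}).get(key)

    def support(self, case_id: str, key: VariantKey) -> int:
        """Number of distinct roster institutions calling ``key`` in the case."""
        return sum(1 for inst in self.roster if key in self.calls.get((case_id, inst), {}))

    def unique_keys(self, case_id: str) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for inst in self.roster:
            out |= self.keys_for(case_id, inst)
        return out


# --------------------------------------------------------------------------
# Consensus references and PPA / PPV
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusReference:
    case_id: str
    min_support: int
    variants: frozenset[VariantKey]
    support_count: Mapping[VariantKey, int]
    label: str = ""

    def __post_init__(self) -> None:
        bad = [v for v in self.variants if self.support_count.get(v, 0) < self.min_support]
        if bad:
            raise ValidationError(f"variants below min_support in reference: {bad[:3]}")


def build_consensus(
    collection: CallSetCollection, case_id: str, min_support: int
) -> ConsensusReference:
    """Consensus reference: variants called by >= ``min_support`` institutions.

    ``min_support=3`` is the three-institution consensus ("consensus 3x"),
    ``min_support=2`` the two-institution consensus.  A case with no calls
    yields a legal empty reference.
    """
    if min_support < 2:
        raise ValidationError("min_support must be >= 2")
    if min_support > len(collection.roster):
        raise ValidationError("min_support exceeds roster size")
    if case_id not in {c for c, _ in collection.calls}:
        raise ValidationError(f"unknown case {case_id!r}")
    support = {key: collection.support(case_id, key) for key in collection.unique_keys(case_id)}
    variants = frozenset(k for k, n in support.items() if n >= min_support)
    return ConsensusReference(
        case_id=case_id, min_support=min_support, variants=variants,
        support_count=support, label=f"consensus_{min_support}x",
    )


def reference_from_keys(case_id: str, keys: Iterable[VariantKey], label: str) -> ConsensusReference:
    """Wrap an external truth/panel call set (e.g. a validated LDT assay)."""
    keys = frozenset(keys)
    return ConsensusReference(
        case_id=case_id, min_support=2,
        variants=keys, support_count={k: 2 for k in keys}, label=label,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """TP/FP/FN counts and PPA/PPV of one institution against one reference.

    Ratios with an empty denominator are ``None`` (undefined), never 0.
    """

    case_id: str
    institution_id: str
    reference_label: str
    tp: int
    fp: int
    fn: int

    @property
    def ppa(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def ppv(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)


def score_against_reference(
    collection: CallSetCollection,
    reference: ConsensusReference,
    institution_id: str,
) -> ConcordanceResult:
    """Exact set comparison of one institution's calls against a reference."""
    if institution_id not in collection.roster:
        raise ValidationError(f"institution {institution_id!r} not in roster")
    calls = collection.keys_for(reference.case_id, institution_id)
    ref = set(reference.variants)
    tp = len(calls & ref)
    return ConcordanceResult(
        case_id=reference.case_id, institution_id=institution_id,
        reference_label=reference.label,
        tp=tp, fp=len(calls - ref), fn=len(ref - calls),
    )


def aggregate_concordance(
    results: Sequence[ConcordanceResult], mode: str = "pooled"
) -> dict[str, float | None]:
    """Aggregate per-case results across a cohort.

    ``pooled`` sums TP/FP/FN before forming the ratios (primary);
    ``per_case_mean`` averages defined per-case ratios (secondary).
    Cases with undefined ratios (empty reference or empty call set) are
    excluded from the per-case mean.
    """
    if mode == "pooled":
        tp = sum(r.tp for r in results)
        fp = sum(r.fp for r in results)
        fn = sum(r.fn for r in results)
        return {
            "ppa": None if tp + fn == 0 else tp / (tp + fn),
            "ppv": None if tp + fp == 0 else tp / (tp + fp),
            "tp": tp, "fp": fp, "fn": fn,
        }
    if mode == "per_case_mean":
        ppas = [r.ppa for r in results if r.ppa is not None]
        ppvs = [r.ppv for r in results if r.ppv is not None]
        return {
            "ppa": sum(ppas) / len(ppas) if ppas else None,
            "ppv": sum(ppvs) / len(ppvs) if ppvs else None,
            "n_cases_ppa": len(ppas), "n_cases_ppv": len(ppvs),
        }
    raise ValidationError(f"unknown aggregation mode {mode!r}")


# --------------------------------------------------------------------------
# Support histogram
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SupportHistogram:
    """Unique variants bucketed by how many institutions detected them."""

    n_institutions: int
    counts: Mapping[int, int]  # support level -> number of unique (case, variant) pairs

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def buckets(self) -> dict[str, int]:
        """all / some (2..N-1 detections) / single buckets."""
        n = self.n_institutions
        return {
            "all": self.counts.get(n, 0),
            "some": sum(c for lvl, c in self.counts.items() if 1 < lvl < n),
            "single": self.counts.get(1, 0),
        }

    @property
    def bucket_fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in ("all", "some", "single")}
        return {k: v / total for k, v in self.buckets.items()}


def support_histogram(
    collection: CallSetCollection, cases: Sequence[str] | None = None
) -> SupportHistogram:
    """Count each unique (case, variant) pair once at its support level."""
    if not collection.roster:
        raise ValidationError("empty roster")
    counts: dict[int, int] = {}
    for case in (cases if cases is not None else collection.cases):
        for key in collection.unique_keys(case):
            level = collection.support(case, key)
            counts[level] = counts.get(level, 0) + 1
    return SupportHistogram(n_institutions=len(collection.roster), counts=counts)


# --------------------------------------------------------------------------
# Discordance classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordanceRecord:
    case_id: str
    variant: VariantKey
    institution_id: str
    direction: Direction
    cause: Cause


def _in_target(key: VariantKey, target: Sequence[GeneInterval] | None) -> bool:
    if target is None:
        return True
    return any(
        gi.chromosome == key.chromosome and gi.start < key.position <= gi.end
        for gi in target
    )


def classify_discordance(
    key: VariantKey,
    case_id: str,
    institution_id: str,
    collection: CallSetCollection,
    evidence: VariantCall | None = None,
    vaf_threshold: float = 0.10,
    cov_threshold: int = 100,
    target_region: Sequence[GeneInterval] | None = None,
) -> DiscordanceRecord:
    """Assign one cause to one discordant (variant, institution) pair.

    ``evidence`` is the institution's pre-filter observation of the variant
    (from raw-data re-inspection or the simulator's evidence channel); it may
    carry a non-PASS filter status, explanatory flags and the number of
    supporting reads.  Causes are tested in a fixed precedence order:

    1.  low VAF or coverage (below the configured thresholds),
    2.  removed by a quality/PASS/other filter,
    3.  annotated as part of another alteration (merged),
    4.  germline branch (mislabeled as germline for misses; a germline
        variant missed by the others for singletons),
    5.  reported as a structural variant,
    6.  filtered as intronic or polymorphism,
    7.  no supporting reads in the raw data, or off target,
    8.  remaining flag-driven causes (splice classification, promoter
        region, somatic LOH, homologous region), then singleton-indel
        representation,
    9.  unexplained when no evidence supports any mechanism.
    """
    support = collection.support(case_id, key)
    called = key in collection.keys_for(case_id, institution_id)
    if called and support == 1:
        direction = Direction.CALLED_ONLY_BY_INSTITUTION
    elif not called and support >= 2:
        direction = Direction.MISSED_BY_INSTITUTION
    else:
        raise ValidationError(
            f"variant {key} is not discordant for {institution_id} (support={support})"
        )

    if direction is Direction.CALLED_ONLY_BY_INSTITUTION and evidence is None:
        evidence = collection.call_for(case_id, institution_id, key)

    cause = _classify_cause(key, direction, evidence, vaf_threshold, cov_threshold, target_region)
    return DiscordanceRecord(
        case_id=case_id, variant=key, institution_id=institution_id,
        direction=direction, cause=cause,
    )


def _classify_cause(
    key: VariantKey,
    direction: Direction,
    evidence: VariantCall | None,
    vaf_threshold: float,
    cov_threshold: int,
    target_region: Sequence[GeneInterval] | None,
) -> Cause:
    if evidence is None:
        return Cause.UNEXPLAINED
    flags = evidence.flags
    if evidence.vaf < vaf_threshold or evidence.depth < cov_threshold:
        return Cause.LOW_VAF_OR_COVERAGE
    if (
        direction is Direction.MISSED_BY_INSTITUTION
        and evidence.filter_status is not FilterStatus.PASS
        and not (flags & {Flag.INTRONIC, Flag.POLYMORPHISM})
    ):
        return Cause.QUALITY_OR_PASS_FILTER
    if Flag.ANNOTATION_MERGED in flags:
        return Cause.ANNOTATION_MERGED
    if Flag.GERMLINE_OVERLAP in flags:
        return (
            Cause.GERMLINE_MISLABEL
            if direction is Direction.MISSED_BY_INSTITUTION
            else Cause.GERMLINE_MISSED
        )
    if Flag.REPORTED_AS_SV in flags:
        return Cause.STRUCTURAL_VARIANT_CALL
    if flags & {Flag.INTRONIC, Flag.POLYMORPHISM}:
        return Cause.INTRON_OR_POLYMORPHISM_FILTER
    if evidence.evidence_reads == 0 or not _in_target(key, target_region):
        return Cause.NO_SUPPORTING_READS_OR_OFF_TARGET
    if Flag.SPLICE_SITE in flags:
        return Cause.SPLICE_CLASSIFICATION
    if Flag.PROMOTER in flags:
        return Cause.PROMOTER_REGION
    if Flag.LOH_EVENT in flags:
        return Cause.SOMATIC_LOH
    if Flag.HOMOLOGOUS_REGION in flags:
        return Cause.HOMOLOGOUS_REGION
    if (
        direction is Direction.CALLED_ONLY_BY_INSTITUTION
        and key.variant_class is not VariantClass.SNV
    ):
        return Cause.INDEL_REPRESENTATION
    return Cause.UNEXPLAINED


def classify_all_discordant(
    collection: CallSetCollection,
    evidence_lookup: Mapping[tuple[str, str, VariantKey], VariantCall] | None = None,
    vaf_threshold: float = 0.10,
    cov_threshold: int = 100,
    target_region: Sequence[GeneInterval] | None = None,
) -> list[DiscordanceRecord]:
    """Classify every discordant (case, variant, institution) in a cohort.

    For a variant detected by 2..N-1 institutions one record is produced per
    missing institution; a singleton produces one record for the single
    caller.  ``evidence_lookup`` supplies pre-filter evidence keyed by
    (case, institution, variant).
    """
    records: list[DiscordanceRecord] = []
    n = len(collection.roster)
    for case in collection.cases:
        for key in sorted(collection.unique_keys(case)):
            support = collection.support(case, key)
            if support == n:
                continue
            if support == 1:
                inst = next(
                    i for i in collection.roster if key in collection.keys_for(case, i)
                )
                affected = [inst]
            else:
                affected = [
                    i for i in collection.roster if key not in collection.keys_for(case, i)
                ]
            for inst in affected:
                evidence = None
                if evidence_lookup is not None:
                    evidence = evidence_lookup.get((case, inst, key))
                records.append(classify_discordance(
                    key, case, inst, collection, evidence=evidence,
                    vaf_threshold=vaf_threshold, cov_threshold=cov_threshold,
                    target_region=target_region,
                ))
    return records


# --------------------------------------------------------------------------
# Clopper-Pearson exact binomial interval
# --------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via Beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1), upper = BetaInv(1-alpha/2; k+1, n-k),
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    lower = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


# --------------------------------------------------------------------------
# Panel restriction and therapeutic annotation
# --------------------------------------------------------------------------

def restrict_to_panel(
    calls: Iterable[VariantCall],
    genes: Sequence[str] | None = None,
    intervals: Sequence[GeneInterval] | None = None,
    germline_keys: Iterable[VariantKey] = (),
) -> list[VariantCall]:
    """Restrict a call set to a gene panel and subtract pooled germline calls.

    A call survives iff its gene is in ``genes`` (when given), its position
    falls in ``intervals`` (when given), and its key is absent from the
    union of germline keys from all institutions.  Germline subtraction
    matches on the normalized key only.
    """
    if genes is not None and len(genes) == 0:
        raise ValidationError("empty gene list")
    gene_set = set(genes) if genes is not None else None
    germline = set(germline_keys)
    out = []
    for call in calls:
        if gene_set is not None and call.gene not in gene_set:
            continue
        if intervals is not None and not _in_target(call.key, intervals):
            continue
        if call.key in germline:
            continue
        out.append(call)
    return out


@dataclass(frozen=True)
class AnnotatedCall:
    call: VariantCall
    level: int
    treatment: str


def annotate_therapeutic(
    calls: Iterable[VariantCall], table: AnnotationTable
) -> list[AnnotatedCall]:
    """Tag calls whose gene/alteration matches a level 1-4 annotation row."""
    out = []
    for call in calls:
        hit = table.match(call.gene, str(call.key))
        if hit is not None:
            out.append(AnnotatedCall(call=call, level=hit.level, treatment=hit.treatment))
    return out


def therapeutic_concordance_matrix(
    collection: CallSetCollection, table: AnnotationTable
) -> "pd.DataFrame":
    """Per therapeutic variant x institution detection matrix with agreement.

    Rows are unique annotated (case, variant) pairs; columns are roster
    institutions (1 = detected) plus evidence level, treatment and a
    ``full_agreement`` column marking variants detected by every institution.
    """
    import pandas as pd

    rows = []
    for case in collection.cases:
        for key in sorted(collection.unique_keys(case)):
            gene = ""
            for inst in collection.roster:
                call = collection.call_for(case, inst, key)
                if call is not None and call.gene:
                    gene = call.gene
                    break
            hit = table.match(gene, str(key))
            if hit is None:
                continue
            detected = {
                inst: int(key in collection.keys_for(case, inst))
                for inst in collection.roster
            }
            rows.append({
                "case_id": case, "variant": str(key), "gene": gene,
                "level": hit.level, "treatment": hit.treatment,
                **detected,
                "full_agreement": int(all(detected.values())),
            })
    return pd.DataFrame(rows)
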