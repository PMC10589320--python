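"""Base-resolution copy-number profile comparison.

Each institution's segmentation is completed into a gap-free tiling of the
genome (unreported regions are set to the diploid CN of 2), the predominant
ploidy (the CN covering the largest base fraction) is derived, and profiles
are compared pairwise base by base.  Bases agree either exactly, or after
correcting for a discordant genome-duplication call (equal CN relative to
the respective predominant ploidies), or they mismatch, in which case the
absolute CN difference is accumulated into a histogram.

The comparison is implemented over interval intersections (union of both
profiles' breakpoints), which is exactly equivalent to a per-base loop but
costs O(segments) instead of O(genome size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from wesconcord.core_io import CNSegment, GenomeModel, ValidationError


@dataclass(frozen=True)
class FilledCNProfile:
    """Complete, gap-free segmentation of a genome's included chromosomes."""

    case_id: str
    institution_id: str
    genome: GenomeModel
    segments: Mapping[str, tuple[CNSegment, ...]]  # chromosome -> sorted tiling
    purity: float | None = None

    @property
    def predominant_ploidy(self) -> int:
        return predominant_ploidy(self)

    def cn_fractions(self) -> dict[int, float]:
        """Fraction of the included genome at each total CN level."""
        total = self.genome.included_length
        counts: dict[int, int] = {}
        for chrom in self.genome.included_chromosomes:
            for seg in self.segments.get(chrom, ()):
                counts[seg.total_cn] = counts.get(seg.total_cn, 0) + seg.length
        return {cn: bp / total for cn, bp in sorted(counts.items())}


def fill_profile(
    segments: Iterable[CNSegment],
    genome: GenomeModel,
    case_id: str = "",
    institution_id: str = "",
    allele_specific: bool = False,
    purity: float | None = None,
    neutral_cn: int = 2,
) -> FilledCNProfile:
    """Complete a sparse segmentation into a gap-free genome tiling.

    Regions without a reported CN change are set to ``neutral_cn`` (default
    2; major=1/minor=1 in allele-specific mode), and adjacent segments with
    equal CN are merged.  Segments on chromosomes outside the genome's
    included set are dropped; segments beyond a chromosome's length are an
    error.  Idempotent: filling an already-filled profile is a no-op.
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        if seg.chromosome not in genome.lengths:
            raise ValidationError(f"segment on unknown chromosome {seg.chromosome!r}")
        if seg.end > genome.lengths[seg.chromosome]:
            raise ValidationError(
                f"segment [{seg.start},{seg.end}) exceeds {seg.chromosome} length "
                f"{genome.lengths[seg.chromosome]}"
            )
        if seg.chromosome in genome.included_chromosomes:
            by_chrom.setdefault(seg.chromosome, []).append(seg)

    neutral_major = (neutral_cn + 1) // 2 if allele_specific else None
    neutral_minor = neutral_cn // 2 if allele_specific else None

    tiling: dict[str, tuple[CNSegment, ...]] = {}
    for chrom in genome.included_chromosomes:
        length = genome.lengths[chrom]
        segs = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )
        filled: list[CNSegment] = []
        cursor = 0
        for seg in segs:
            if seg.start > cursor:
                filled.append(CNSegment(
                    chromosome=chrom, start=cursor, end=seg.start,
                    total_cn=neutral_cn, major_cn=neutral_major, minor_cn=neutral_minor,
                ))
            filled.append(seg)
            cursor = seg.end
        if cursor < length:
            filled.append(CNSegment(
                chromosome=chrom, start=cursor, end=length,
                total_cn=neutral_cn, major_cn=neutral_major, minor_cn=neutral_minor,
            ))
        tiling[chrom] = tuple(_merge_equal(filled))

    return FilledCNProfile(
        case_id=case_id, institution_id=institution_id, genome=genome,
        segments=tiling, purity=purity,
    )


def _merge_equal(segs: list[CNSegment]) -> list[CNSegment]:
    out: list[CNSegment] = []
    for seg in segs:
        if (
            out
            and out[-1].end == seg.start
            and out[-1].total_cn == seg.total_cn
            and out[-1].major_cn == seg.major_cn
            and out[-1].minor_cn == seg.minor_cn
        ):
            prev = out.pop()
            seg = CNSegment(
                chromosome=seg.chromosome, start=prev.start, end=seg.end,
                total_cn=seg.total_cn, major_cn=seg.major_cn, minor_cn=seg.minor_cn,
            )
        out.append(seg)
    return out


def predominant_ploidy(profile: FilledCNProfile) -> int:
    """CN level covering the largest base fraction; ties break toward lower CN."""
    counts: dict[int, int] = {}
    for chrom in profile.genome.included_chromosomes:
        for seg in profile.segments.get(chrom, ()):
            counts[seg.total_cn] = counts.get(seg.total_cn, 0) + seg.length
    if not counts:
        raise ValidationError("profile covers no included chromosome")
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


# --------------------------------------------------------------------------
# Pairwise comparison
# --------------------------------------------------------------------------

@dataclass
class PairwiseCNComparison:
    """Base-count agreement between two institutions' profiles for one case."""

    case_id: str
    institution_a: str
    institution_b: str
    ploidy_a: int
    ploidy_b: int
    exact_match_bp: int = 0
    duplication_match_bp: int = 0
    mismatch_bp: int = 0
    cn_diff_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def genome_bp(self) -> int:
        return self.exact_match_bp + self.duplication_match_bp + self.mismatch_bp

    @property
    def fractions(self) -> dict[str, float]:
        total = self.genome_bp
        return {
            "exact": self.exact_match_bp / total,
            "duplication": self.duplication_match_bp / total,
            "mismatch": self.mismatch_bp / total,
        }


def compare_profiles(
    a: FilledCNProfile, b: FilledCNProfile, rule: str = "ratio"
) -> PairwiseCNComparison:
    """Classify every base of the included genome by agreement category.

    A base agrees exactly when both profiles assign the same total CN.
    Otherwise it is duplication-explained when the discrepancy is accounted
    for by a discordant genome-duplication call: under the default ``ratio``
    rule when ``cn_a / ploidy_a == cn_b / ploidy_b`` (a doubled genome is
    fully explained), under the alternative ``delta`` rule when
    ``cn_a - ploidy_a == cn_b - ploidy_b``.  Remaining bases mismatch and
    contribute |cn_a - cn_b| to the difference histogram.
    """
    if a.genome != b.genome:
        raise ValidationError("profiles must share one genome model")
    if rule not in ("delta", "ratio"):
        raise ValidationError(f"unknown duplication rule {rule!r}")
    ploidy_a, ploidy_b = predominant_ploidy(a), predominant_ploidy(b)
    cmp = PairwiseCNComparison(
        case_id=a.case_id, institution_a=a.institution_id,
        institution_b=b.institution_id, ploidy_a=ploidy_a, ploidy_b=ploidy_b,
    )
    for chrom in a.genome.included_chromosomes:
        for start, end, cn_a, cn_b in _paired_intervals(
            a.segments.get(chrom, ()), b.segments.get(chrom, ())
        ):
            bp = end - start
            if cn_a == cn_b:
                cmp.exact_match_bp += bp
            elif _duplication_explained(cn_a, cn_b, ploidy_a, ploidy_b, rule):
                cmp.duplication_match_bp += bp
            else:
                cmp.mismatch_bp += bp
                delta = abs(cn_a - cn_b)
                cmp.cn_diff_histogram[delta] = cmp.cn_diff_histogram.get(delta, 0) + bp
    return cmp


def _duplication_explained(cn_a: int, cn_b: int, ploidy_a: int, ploidy_b: int, rule: str) -> bool:
    if ploidy_a == ploidy_b:
        return False
    if rule == "delta":
        return cn_a - ploidy_a == cn_b - ploidy_b
    return cn_a * ploidy_b == cn_b * ploidy_a  # cn_a/ploidy_a == cn_b/ploidy_b


def _paired_intervals(
    segs_a: Sequence[CNSegment], segs_b: Sequence[CNSegment]
):
    """Walk two tilings of one chromosome, yielding (start, end, cn_a, cn_b)."""
    ia = ib = 0
    pos = 0
    while ia < len(segs_a) and ib < len(segs_b):
        a, b = segs_a[ia], segs_b[ib]
        end = min(a.end, b.end)
        if end > pos:
            yield pos, end, a.total_cn, b.total_cn
        pos = end
        if a.end == end:
            ia += 1
        if b.end == end:
            ib += 1


def cn_diff_summary(
    comparisons: Iterable[PairwiseCNComparison],
) -> dict[int, float]:
    """Pooled |delta-CN| distribution over mismatched bases, as fractions.

    Empty when no base mismatches in any comparison.
    """
    pooled: dict[int, int] = {}
    for cmp in comparisons:
        for delta, bp in cmp.cn_diff_histogram.items():
            pooled[delta] = pooled.get(delta, 0) + bp
    total = sum(pooled.values())
    if total == 0:
        return {}
    return {delta: bp / total for delta, bp in sorted(pooled.items())}


def aggregate_match_fraction(
    comparisons: Sequence[PairwiseCNComparison],
) -> dict[str, float]:
    """Matched (exact + duplication-explained) fraction across comparisons.

    ``pooled`` is bp-weighted over all pairs pooled; ``per_pair_mean``
    averages each pair's matched fraction.
    """
    if not comparisons:
        raise ValidationError("no comparisons to aggregate")
    matched = sum(c.exact_match_bp + c.duplication_match_bp for c in comparisons)
    total = sum(c.genome_bp for c in comparisons)
    per_pair = [
        (c.exact_match_bp + c.duplication_match_bp) / c.genome_bp for c in comparisons
    ]
    return {
        "pooled": matched / total,
        "per_pair_mean": sum(per_pair) / len(per_pair),
    }


# --------------------------------------------------------------------------
# Gene-level CN events
# --------------------------------------------------------------------------

class CNEventClass(str, Enum):
    HIGH_AMP = "high_amp"
    LOW_AMP = "low_amp"
    NEUTRAL = "neutral"
    MONOALLELIC_DEL = "monoallelic_del"
    DEEP_DEL = "deep_del"


class GeneAgreement(str, Enum):
    ALL_AGREE = "all_agree"
    THRESHOLD_DISAGREEMENT = "threshold_disagreement"
    PRESENCE_DISAGREEMENT = "presence_disagreement"


@dataclass(frozen=True)
class GeneCNEvent:
    gene: str
    chromosome: str
    start: int
    end: int
    institution_id: str
    min_cn: int  # representative CN for deletion calling
    max_cn: int  # representative CN for amplification calling
    ploidy: int
    classification: CNEventClass


def call_gene_event(
    profile: FilledCNProfile,
    gene: str,
    chromosome: str,
    start: int,
    end: int,
    amp_delta: int = 5,
) -> GeneCNEvent:
    """Classify a gene's CN state in one profile.

    The representative CN is the minimum over the gene interval for deletion
    calling and the maximum for amplification calling.  Deletions use fixed
    absolute thresholds (deep at CN 0, monoallelic at CN 1) while high-level
    amplification is relative to ploidy (CN >= ploidy + ``amp_delta``);
    CN above ploidy but below that threshold is a low-level amplification.
    """
    if chromosome not in profile.genome.included_chromosomes:
        raise ValidationError(f"chromosome {chromosome!r} not in included genome")
    if end > profile.genome.lengths[chromosome] or start < 0 or start >= end:
        raise ValidationError(f"gene interval [{start},{end}) outside genome")
    cns = [
        seg.total_cn
        for seg in profile.segments[chromosome]
        if seg.start < end and seg.end > start
    ]
    min_cn, max_cn = min(cns), max(cns)
    ploidy = predominant_ploidy(profile)
    if min_cn == 0:
        cls = CNEventClass.DEEP_DEL
    elif min_cn == 1:
        cls = CNEventClass.MONOALLELIC_DEL
    elif max_cn >= ploidy + amp_delta:
        cls = CNEventClass.HIGH_AMP
    elif max_cn > ploidy:
        cls = CNEventClass.LOW_AMP
    else:
        cls = CNEventClass.NEUTRAL
    return GeneCNEvent(
        gene=gene, chromosome=chromosome, start=start, end=end,
        institution_id=profile.institution_id,
        min_cn=min_cn, max_cn=max_cn, ploidy=ploidy, classification=cls,
    )


def gene_event_matrix(
    profiles: Mapping[str, FilledCNProfile],
    gene_intervals: Sequence,
    amp_delta: int = 5,
) -> tuple[dict[str, dict[str, GeneCNEvent]], dict[str, GeneAgreement]]:
    """Per-gene x institution event classification with agreement summary.

    Agreement per gene: ``all_agree`` when every institution assigns the
    same class; ``threshold_disagreement`` when classes differ only between
    high- and low-level amplification (the event is present everywhere, the
    high-level threshold is not met by all); any other mixture (including
    deep vs monoallelic deletion) is a ``presence_disagreement``.
    """
    matrix: dict[str, dict[str, GeneCNEvent]] = {}
    agreement: dict[str, GeneAgreement] = {}
    for gi in gene_intervals:
        events = {
            inst: call_gene_event(
                profile, gi.gene, gi.chromosome, gi.start, gi.end, amp_delta=amp_delta
            )
            for inst, profile in sorted(profiles.items())
        }
        matrix[gi.gene] = events
        classes = {e.classification for e in events.values()}
        if len(classes) == 1:
            agreement[gi.gene] = GeneAgreement.ALL_AGREE
        elif classes <= {CNEventClass.HIGH_AMP, CNEventClass.LOW_AMP}:
            agreement[gi.gene] = GeneAgreement.THRESHOLD_DISAGREEMENT
        else:
            agreement[gi.gene] = GeneAgreement.PRESENCE_DISAGREEMENT
    return matrix, agreement
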