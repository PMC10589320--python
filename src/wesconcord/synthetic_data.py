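"""Synthetic multi-case, multi-institution cohort generator.

Emulates the statistical structure of a multi-center whole-exome
comparison: a shared per-case truth (somatic variants with VAFs, a
copy-number profile, complex biomarker values, tumor purity) observed
through institution-specific channels that reproduce the known discordance
mechanisms — VAF/coverage-dependent detection, filter-based misses,
annotation merging, per-case false positives with a low-VAF spectrum,
whole-genome-duplication misclassification, purity-estimation noise, and
multiplicative institution biases on biomarker scores.

Every stochastic channel records its ground-truth label, so the analysis
modules can be validated against the generative design.  All randomness
derives from a single master seed through per-(case, institution, channel)
sub-streams: regenerating one institution leaves the others byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from wesconcord.core_io import (
    AnnotationTable,
    BiomarkerRecord,
    CNSegment,
    FilterStatus,
    Flag,
    GeneInterval,
    GenomeModel,
    TherapeuticAnnotation,
    ValidationError,
    VariantCall,
    VariantKey,
    write_biomarker_table,
    write_cn_segments,
    write_gene_intervals,
    write_variant_calls,
)
from wesconcord.cna_concordance import FilledCNProfile, fill_profile
from wesconcord.variance_decomposition import BIOINFORMATIC, WETLAB

_BASES = "ACGT"


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class InstitutionProfile:
    """Observation model of one institution (laboratory + pipeline).

    Detection is two-regime: confident variants (VAF >= the confident-VAF
    threshold and depth >= the confident-depth threshold) are detected with
    ``p_detect_confident``, low-evidence variants with ``p_detect_low``.
    Detected variants may still be removed by a filter or merged into
    another annotation.  Biomarker scores are observed as
    ``bias x truth + N(0, sd)``.
    """

    institution_id: str
    p_detect_confident: float = 0.95
    p_detect_low: float = 0.45
    p_filter_miss: float = 0.03
    p_annotation_merge: float = 0.02
    fp_rate: float = 1.5  # mean false-positive calls per case
    mean_coverage: float = 200.0
    coverage_dispersion: float = 8.0  # negative-binomial shape; larger = tighter
    p_wgd_misclass: float = 0.06
    cn_noise_p: float = 0.08  # P(segment CN shifts by +1) = P(-1) at reference purity
    breakpoint_jitter_bp: int = 50_000
    purity_noise_sd: float = 0.04
    p_purity_missing: float = 0.0
    biomarker_bias: dict[str, float] = field(
        default_factory=lambda: {"hrd_sum": 1.0, "tmb": 1.0, "msi": 1.0}
    )
    biomarker_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"hrd_sum": 1.5, "tmb": 0.3, "msi": 0.3}
    )
    msi_cutoff: float = 10.0

    def __post_init__(self) -> None:
        probs = [
            self.p_detect_confident, self.p_detect_low, self.p_filter_miss,
            self.p_annotation_merge, self.p_wgd_misclass, self.p_purity_missing,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if any(b <= 0 for b in self.biomarker_bias.values()):
            raise ValidationError("biomarker biases must be positive")
        if any(s < 0 for s in self.biomarker_noise_sd.values()):
            raise ValidationError("noise sds must be >= 0")


def default_toy_genome() -> GenomeModel:
    """Scaled-down genome: five included chromosomes (incl. chrX), chrY excluded."""
    lengths = {
        "chr1": 30_000_000, "chr2": 25_000_000, "chr3": 20_000_000,
        "chr4": 15_000_000, "chrX": 10_000_000, "chrY": 3_000_000,
    }
    return GenomeModel(
        names=tuple(lengths),
        lengths=lengths,
        included_chromosomes=("chr1", "chr2", "chr3", "chr4", "chrX"),
    )


def default_institutions() -> list[InstitutionProfile]:
    """Five institution profiles with realistic heterogeneity.

    Detection probabilities, coverage levels, and multiplicative biomarker
    biases differ per institution; one institution under-reports TMB by
    about 12 percent and one uses a 40 percent MSI cutoff from a different
    MSI tool.
    """
    spec = [
        # id,     p_conf, p_low, p_filt, p_merge, fp,  cov,   hrd_b, tmb_b, msi_b, msi_cut
        ("ZPM-1", 0.975, 0.60, 0.020, 0.015, 0.4, 250.0, 1.00, 1.00, 1.10, 40.0),
        ("ZPM-2", 0.985, 0.65, 0.012, 0.012, 0.3, 320.0, 0.97, 1.01, 1.00, 10.0),
        ("ZPM-3", 0.970, 0.55, 0.025, 0.015, 0.5, 180.0, 1.03, 0.99, 1.00, 10.0),
        ("ZPM-4", 0.975, 0.60, 0.018, 0.020, 0.4, 280.0, 0.85, 1.00, 1.00, 10.0),
        ("ZPM-5", 0.965, 0.50, 0.020, 0.015, 0.6, 220.0, 1.09, 0.88, 1.00, 10.0),
    ]
    out = []
    for (iid, pc, pl, pf, pm, fp, cov, hb, tb, mb, mc) in spec:
        out.append(InstitutionProfile(
            institution_id=iid, p_detect_confident=pc, p_detect_low=pl,
            p_filter_miss=pf, p_annotation_merge=pm, fp_rate=fp,
            mean_coverage=cov, coverage_dispersion=20.0,
            biomarker_bias={"hrd_sum": hb, "tmb": tb, "msi": mb},
            msi_cutoff=mc,
            p_purity_missing=0.01 if iid == "ZPM-1" else 0.0,
        ))
    return out


@dataclass
class SimulationConfig:
    """Generative parameters of a cohort.

    Defaults emulate the pilot-study conditions: 30 cases, five
    institutions, about 32 somatic variants per case (84 percent SNVs),
    a clonal/subclonal VAF mixture, tumor purity uniform in [0.46, 0.90],
    and independent truth draws for HRDsum, TMB and MSI.
    """

    seed: int
    n_cases: int = 30
    institutions: list[InstitutionProfile] = field(default_factory=default_institutions)
    genome: GenomeModel = field(default_factory=default_toy_genome)
    n_genes: int = 200
    gene_length: int = 20_000
    variants_per_case_mean: float = 9.0
    indel_fraction: float = 0.16
    clonal_weight: float = 0.86
    clonal_beta: tuple[float, float] = (7.0, 13.0)     # mean VAF ~ 0.35
    subclonal_beta: tuple[float, float] = (2.0, 25.0)  # mean VAF ~ 0.074
    vaf_confident: float = 0.10
    depth_confident: int = 100
    segments_per_chromosome_mean: float = 2.0
    p_wgd_truth: float = 0.2
    cn_delta_levels: tuple[int, ...] = (-2, -1, 0, 1, 2, 3, 5, 6)
    cn_delta_probs: tuple[float, ...] = (0.04, 0.15, 0.55, 0.14, 0.06, 0.02, 0.02, 0.02)
    hrd_mean: float = 30.0
    hrd_sd: float = 18.0
    tmb_log_mean: float = 1.4   # log(4.0) -- median TMB ~ 4 mut/MB
    tmb_log_sd: float = 0.7
    msi_scale: float = 2.0
    purity_range: tuple[float, float] = (0.46, 0.90)
    reference_purity: float = 0.68  # CN noise scales as reference_purity / purity
    tmb_consistency: bool = False   # tie TMB truth to simulated variant count

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if abs(sum(self.cn_delta_probs) - 1.0) > 1e-9:
            raise ValidationError("cn_delta_probs must sum to 1")
        if len(self.cn_delta_levels) != len(self.cn_delta_probs):
            raise ValidationError("cn_delta_levels and cn_delta_probs must align")

    @property
    def roster(self) -> tuple[str, ...]:
        return tuple(p.institution_id for p in self.institutions)

    def gene_intervals(self) -> list[GeneInterval]:
        """Deterministic gene panel: genes tiled across included chromosomes."""
        chroms = self.genome.included_chromosomes
        out = []
        per_chrom = self.n_genes // len(chroms)
        extra = self.n_genes % len(chroms)
        counter = 0
        for ci, chrom in enumerate(chroms):
            n_here = per_chrom + (1 if ci < extra else 0)
            length = self.genome.lengths[chrom]
            spacing = length // (n_here + 1)
            for g in range(n_here):
                start = (g + 1) * spacing
                out.append(GeneInterval(
                    gene=f"GENE{counter:03d}", chromosome=chrom,
                    start=start, end=min(start + self.gene_length, length),
                ))
                counter += 1
        return out

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["genome"] = self.genome.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _rng(seed: int, *stream: int | str) -> np.random.Generator:
    """Counter-based sub-stream: independent generator per (seed, stream...)."""
    entropy = [seed & 0x7FFFFFFF]
    for item in stream:
        if isinstance(item, str):
            entropy.append(zlib.crc32(item.encode()))
        else:
            entropy.append(int(item) & 0xFFFFFFFF)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


# --------------------------------------------------------------------------
# Truth generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueVariant:
    key: VariantKey
    vaf: float
    gene: str


@dataclass
class CaseTruth:
    case_id: str
    variants: list[TrueVariant]
    cn_segments: list[CNSegment]  # complete tiling of included chromosomes
    purity: float
    hrd_sum: float
    tmb: float
    msi: float

    def cn_profile(self, genome: GenomeModel) -> FilledCNProfile:
        return fill_profile(
            self.cn_segments, genome, case_id=self.case_id,
            institution_id="truth", purity=self.purity,
        )


def simulate_truth(config: SimulationConfig, case_index: int) -> CaseTruth:
    """Draw one case's ground truth, reproducibly under the master seed."""
    case_id = f"case{case_index + 1:02d}"
    rng = _rng(config.seed, "truth", case_index)
    genes = config.gene_intervals()

    n_variants = rng.poisson(config.variants_per_case_mean)
    purity = rng.uniform(*config.purity_range)

    # Variants: positions drawn within panel genes; unique per case.
    variants: list[TrueVariant] = []
    used: set[tuple[str, int]] = set()
    while len(variants) < n_variants:
        gi = genes[rng.integers(len(genes))]
        pos = int(rng.integers(gi.start + 2, gi.end))  # 1-based, room to the left
        if (gi.chromosome, pos) in used:
            continue
        used.add((gi.chromosome, pos))
        if rng.random() < config.clonal_weight:
            vaf = float(rng.beta(*config.clonal_beta))
        else:
            vaf = float(rng.beta(*config.subclonal_beta))
        vaf = min(max(vaf, 0.005), 1.0)
        ref = _BASES[rng.integers(4)]
        if rng.random() >= config.indel_fraction:
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        else:
            inserted = "".join(_BASES[rng.integers(4)] for _ in range(int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                alt = ref + inserted  # insertion
            else:
                ref, alt = ref + inserted, ref  # deletion
        variants.append(TrueVariant(
            key=VariantKey(chromosome=gi.chromosome, position=pos, ref=ref, alt=alt),
            vaf=vaf, gene=gi.gene,
        ))
    variants.sort(key=lambda v: v.key)

    # Copy-number truth: per-chromosome segmentation around a baseline ploidy.
    baseline = 4 if rng.random() < config.p_wgd_truth else 2
    cn_segments: list[CNSegment] = []
    for chrom in config.genome.included_chromosomes:
        length = config.genome.lengths[chrom]
        n_breaks = rng.poisson(config.segments_per_chromosome_mean)
        breaks = sorted(set(int(b) for b in rng.integers(1, length, size=n_breaks)))
        bounds = [0, *breaks, length]
        spans = list(zip(bounds, bounds[1:]))
        # the longest span of each chromosome stays at the baseline ploidy,
        # so the predominant ploidy reflects the intended genome state
        longest = max(range(len(spans)), key=lambda i: spans[i][1] - spans[i][0])
        for i, (start, end) in enumerate(spans):
            delta = (
                0 if i == longest
                else int(rng.choice(config.cn_delta_levels, p=config.cn_delta_probs))
            )
            cn_segments.append(CNSegment(
                chromosome=chrom, start=start, end=end,
                total_cn=max(0, baseline + delta),
            ))

    hrd = float(np.clip(rng.normal(config.hrd_mean, config.hrd_sd), 0, 100))
    if config.tmb_consistency:
        panel_mb = sum(g.end - g.start for g in genes) / 1e6
        tmb = n_variants / panel_mb
    else:
        tmb = float(rng.lognormal(config.tmb_log_mean, config.tmb_log_sd))
    msi = float(np.clip(rng.exponential(config.msi_scale), 0, 35))
    return CaseTruth(
        case_id=case_id, variants=variants, cn_segments=cn_segments,
        purity=purity, hrd_sum=hrd, tmb=tmb, msi=msi,
    )


# --------------------------------------------------------------------------
# Institution observation channels
# --------------------------------------------------------------------------

@dataclass
class CallSetObservation:
    """One institution's call set plus miss evidence and generative labels."""

    calls: list[VariantCall]
    evidence: list[VariantCall]  # pre-filter evidence for every missed truth variant
    miss_labels: dict[VariantKey, str]  # truth variant -> mechanism
    fp_keys: set[VariantKey]


def simulate_institution_callset(
    truth: CaseTruth,
    profile: InstitutionProfile,
    config: SimulationConfig,
) -> CallSetObservation:
    """Observe a case's truth variants through one institution's channels.

    Detection is two-regime on (VAF, depth).  Non-detections of low-evidence
    variants are labeled ``low_vaf_or_coverage``; non-detections of
    confident variants model absent read support and are labeled
    ``no_supporting_reads_or_off_target`` (their evidence records carry
    zero supporting reads).  Detected confident variants may be removed by
    a quality/other filter (``quality_or_pass_filter``) or merged into
    another annotation (``annotation_merged``).  False positives are drawn
    from a low-VAF spectrum at ``fp_rate`` per case.  Every miss gets an
    evidence record describing the variant in this institution's raw data.
    """
    rng = _rng(config.seed, "calls", truth.case_id, profile.institution_id)
    calls: list[VariantCall] = []
    evidence: list[VariantCall] = []
    labels: dict[VariantKey, str] = {}

    nb_n = profile.coverage_dispersion
    nb_p = nb_n / (nb_n + profile.mean_coverage)

    for tv in truth.variants:
        depth = max(1, int(rng.negative_binomial(nb_n, nb_p)))
        confident = tv.vaf >= config.vaf_confident and depth >= config.depth_confident
        p_detect = profile.p_detect_confident if confident else profile.p_detect_low
        obs_vaf = float(np.clip(tv.vaf + rng.normal(0, 0.01), 0.001, 1.0))
        supporting = max(1, round(obs_vaf * depth))

        if rng.random() >= p_detect:
            if confident:
                labels[tv.key] = "no_supporting_reads_or_off_target"
                evidence.append(VariantCall(
                    case_id=truth.case_id, institution_id=profile.institution_id,
                    key=tv.key, vaf=tv.vaf, depth=depth, gene=tv.gene,
                    filter_status=FilterStatus.PASS, evidence_reads=0,
                ))
            else:
                labels[tv.key] = "low_vaf_or_coverage"
                # evidence carries the variant-level VAF so the cause check
                # sees the same (vaf, depth) pair the detection regime used
                evidence.append(VariantCall(
                    case_id=truth.case_id, institution_id=profile.institution_id,
                    key=tv.key, vaf=tv.vaf, depth=depth, gene=tv.gene,
                    filter_status=FilterStatus.PASS,
                    evidence_reads=min(depth, max(0, round(tv.vaf * depth))),
                ))
            continue

        channel = rng.random()
        if confident and channel < profile.p_filter_miss:
            labels[tv.key] = "quality_or_pass_filter"
            status = (
                FilterStatus.QUALITY_FILTERED if rng.random() < 0.7
                else FilterStatus.OTHER_FILTERED
            )
            evidence.append(VariantCall(
                case_id=truth.case_id, institution_id=profile.institution_id,
                key=tv.key, vaf=tv.vaf, depth=depth, gene=tv.gene,
                filter_status=status, evidence_reads=min(depth, supporting),
            ))
            continue
        if confident and channel < profile.p_filter_miss + profile.p_annotation_merge:
            labels[tv.key] = "annotation_merged"
            evidence.append(VariantCall(
                case_id=truth.case_id, institution_id=profile.institution_id,
                key=tv.key, vaf=tv.vaf, depth=depth, gene=tv.gene,
                filter_status=FilterStatus.PASS,
                flags=frozenset({Flag.ANNOTATION_MERGED}),
                evidence_reads=min(depth, supporting),
            ))
            continue

        calls.append(VariantCall(
            case_id=truth.case_id, institution_id=profile.institution_id,
            key=tv.key, vaf=obs_vaf, depth=depth, gene=tv.gene,
            filter_status=FilterStatus.PASS,
            evidence_reads=min(depth, supporting),
        ))

    # False positives: low-VAF spectrum, placed at unused panel positions.
    fp_keys: set[VariantKey] = set()
    truth_positions = {(tv.key.chromosome, tv.key.position) for tv in truth.variants}
    genes = config.gene_intervals()
    for _ in range(rng.poisson(profile.fp_rate)):
        for _attempt in range(20):
            gi = genes[rng.integers(len(genes))]
            pos = int(rng.integers(gi.start + 2, gi.end))
            if (gi.chromosome, pos) not in truth_positions:
                break
        else:
            continue
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        key = VariantKey(chromosome=gi.chromosome, position=pos, ref=ref, alt=alt)
        if key in fp_keys:
            continue
        fp_keys.add(key)
        vaf = float(np.clip(rng.beta(1.3, 12.0), 0.005, 1.0))
        depth = max(1, int(rng.negative_binomial(nb_n, nb_p)))
        calls.append(VariantCall(
            case_id=truth.case_id, institution_id=profile.institution_id,
            key=key, vaf=vaf, depth=depth, gene=gi.gene,
            filter_status=FilterStatus.PASS,
            evidence_reads=max(1, min(depth, round(vaf * depth))),
        ))

    return CallSetObservation(calls=calls, evidence=evidence, miss_labels=labels, fp_keys=fp_keys)


@dataclass
class CNObservation:
    profile: FilledCNProfile
    purity_estimate: float | None
    wgd_misclassified: bool


def simulate_cn_observation(
    truth: CaseTruth,
    profile: InstitutionProfile,
    config: SimulationConfig,
) -> CNObservation:
    """Perturb a truth CN profile into one institution's observation.

    With probability ``p_wgd_misclass`` the entire profile is doubled (a
    discordant genome-duplication call).  Each segment's CN then shifts by
    +/-1 with a probability that scales inversely with tumor purity, and
    interior breakpoints jitter by up to ``breakpoint_jitter_bp``.  The
    purity estimate is the truth plus Gaussian noise, clipped to (0, 1].
    """
    rng = _rng(config.seed, "cn", truth.case_id, profile.institution_id)
    wgd = rng.random() < profile.p_wgd_misclass
    p_shift = min(0.45, profile.cn_noise_p * config.reference_purity / truth.purity)

    segments: list[CNSegment] = []
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in truth.cn_segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        bounds = [s.start for s in segs] + [segs[-1].end]
        # jitter interior boundaries, preserving order
        for i in range(1, len(bounds) - 1):
            jitter = int(rng.integers(-profile.breakpoint_jitter_bp,
                                      profile.breakpoint_jitter_bp + 1))
            bounds[i] = int(np.clip(bounds[i] + jitter, bounds[i - 1] + 1, bounds[i + 1] - 1))
        for seg, start, end in zip(segs, bounds, bounds[1:]):
            cn = seg.total_cn * 2 if wgd else seg.total_cn
            u = rng.random()
            if u < p_shift:
                cn += 1
            elif u < 2 * p_shift:
                cn -= 1
            segments.append(CNSegment(
                chromosome=chrom, start=start, end=end, total_cn=max(0, cn),
            ))

    purity_est: float | None
    if rng.random() < profile.p_purity_missing:
        purity_est = None
    else:
        purity_est = float(np.clip(
            truth.purity + rng.normal(0, profile.purity_noise_sd), 0.05, 1.0
        ))
    filled = fill_profile(
        segments, config.genome, case_id=truth.case_id,
        institution_id=profile.institution_id, purity=purity_est,
    )
    return CNObservation(profile=filled, purity_estimate=purity_est, wgd_misclassified=wgd)


def simulate_biomarkers(
    truth: CaseTruth,
    profile: InstitutionProfile,
    config: SimulationConfig,
    cn_observation: CNObservation | None = None,
) -> BiomarkerRecord:
    """Observe biomarker truths through multiplicative bias plus noise.

    ``observed = bias x truth + N(0, sd)``, clipped at zero (and 100 for
    the MSI percentage).  Purity and ploidy come from the institution's CN
    observation when provided.
    """
    rng = _rng(config.seed, "biomarker", truth.case_id, profile.institution_id)

    def observe(name: str, value: float) -> float:
        bias = profile.biomarker_bias.get(name, 1.0)
        sd = profile.biomarker_noise_sd.get(name, 0.0)
        return float(bias * value + (rng.normal(0, sd) if sd > 0 else 0.0))

    hrd = max(0.0, observe("hrd_sum", truth.hrd_sum))
    tmb = max(0.0, observe("tmb", truth.tmb))
    msi = float(np.clip(observe("msi", truth.msi), 0.0, 100.0))
    purity = ploidy = None
    if cn_observation is not None:
        purity = cn_observation.purity_estimate
        ploidy = float(cn_observation.profile.predominant_ploidy)
    return BiomarkerRecord(
        case_id=truth.case_id, institution_id=profile.institution_id,
        hrd_sum=hrd, tmb=tmb, msi=msi, purity=purity, ploidy=ploidy,
    )


# --------------------------------------------------------------------------
# Replicate-design simulation (variance decomposition ground truth)
# --------------------------------------------------------------------------

def simulate_variability_study(
    config: SimulationConfig,
    biomarker: str = "hrd_sum",
    sigma_bioinf: float = 1.0,
    sigma_wetlab: float = 2.0,
    n_replicates: int = 3,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Long-format replicate design with known noise split.

    For each sample a biomarker truth is drawn; the bioinformatic axis
    observes it through ``n_replicates`` pipelines with additive noise
    ``sigma_bioinf`` and per-pipeline multiplicative bias, the wet-lab axis
    through ``n_replicates`` laboratories with noise ``sigma_wetlab``.
    Returns columns (sample, replicate_id, axis, biomarker, value).
    """
    rng = _rng(config.seed, "variability", biomarker)
    n = n_samples if n_samples is not None else config.n_cases
    if biomarker == "hrd_sum":
        truths = np.clip(rng.normal(config.hrd_mean, config.hrd_sd, size=n), 0, 100)
    elif biomarker == "tmb":
        truths = rng.lognormal(config.tmb_log_mean, config.tmb_log_sd, size=n)
    elif biomarker == "msi":
        truths = np.clip(rng.exponential(config.msi_scale, size=n), 0, 35)
    else:
        raise ValidationError(f"unsupported biomarker {biomarker!r}")

    rows = []
    for axis, sigma, prefix in (
        (BIOINFORMATIC, sigma_bioinf, "pipeline"),
        (WETLAB, sigma_wetlab, "lab"),
    ):
        biases = rng.uniform(0.9, 1.1, size=n_replicates)
        biases[0] = 1.0  # reference replicate on the truth scale
        for r in range(n_replicates):
            values = biases[r] * truths + rng.normal(0, sigma, size=n)
            for s in range(n):
                rows.append({
                    "sample": f"S{s + 1:03d}",
                    "replicate_id": f"{prefix}{r + 1}",
                    "axis": axis,
                    "biomarker": biomarker,
                    "value": float(max(values[s], 0.0)),
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort assembly and on-disk output
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory simulated cohort with all generative labels."""

    config: SimulationConfig
    truths: list[CaseTruth]
    calls: list[VariantCall]
    evidence: list[VariantCall]
    miss_labels: dict[tuple[str, str, VariantKey], str]  # (case, inst, key) -> mechanism
    fp_keys: dict[tuple[str, str], set[VariantKey]]
    cn_profiles: dict[tuple[str, str], FilledCNProfile]
    wgd_flags: dict[tuple[str, str], bool]
    biomarkers: list[BiomarkerRecord]


def simulate_case(config: SimulationConfig, case_index: int) -> tuple[CaseTruth, dict]:
    truth = simulate_truth(config, case_index)
    per_inst = {}
    for profile in config.institutions:
        callset = simulate_institution_callset(truth, profile, config)
        cn = simulate_cn_observation(truth, profile, config)
        biomarker = simulate_biomarkers(truth, profile, config, cn_observation=cn)
        per_inst[profile.institution_id] = (callset, cn, biomarker)
    return truth, per_inst


def simulate_cohort_in_memory(config: SimulationConfig) -> Cohort:
    cohort = Cohort(
        config=config, truths=[], calls=[], evidence=[], miss_labels={},
        fp_keys={}, cn_profiles={}, wgd_flags={}, biomarkers=[],
    )
    for case_index in range(config.n_cases):
        truth, per_inst = simulate_case(config, case_index)
        cohort.truths.append(truth)
        for inst, (callset, cn, biomarker) in per_inst.items():
            cohort.calls.extend(callset.calls)
            cohort.evidence.extend(callset.evidence)
            for key, mechanism in callset.miss_labels.items():
                cohort.miss_labels[(truth.case_id, inst, key)] = mechanism
            cohort.fp_keys[(truth.case_id, inst)] = callset.fp_keys
            cohort.cn_profiles[(truth.case_id, inst)] = cn.profile
            cohort.wgd_flags[(truth.case_id, inst)] = cn.wgd_misclassified
            cohort.biomarkers.append(biomarker)
    return cohort


def default_annotation_table(config: SimulationConfig) -> AnnotationTable:
    """Small deterministic therapeutic-annotation table over the toy panel."""
    genes = [gi.gene for gi in config.gene_intervals()]
    table = AnnotationTable()
    for i, gene in enumerate(genes[:20]):
        table.variant_rows.append(TherapeuticAnnotation(
            gene=gene, alteration="*", level=(i % 4) + 1, treatment=f"drug{(i % 4) + 1}",
        ))
    for gene in genes[::10][:15]:
        table.cn_genes.setdefault(gene, set()).add("amplification")
    for gene in genes[5::10][:15]:
        table.cn_genes.setdefault(gene, set()).add("deletion")
    return table


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path, force: bool = False
) -> Cohort:
    """Simulate a cohort and write it in the dialects the readers accept.

    Writes variants.tsv, evidence.tsv, segments.tsv (non-neutral segments
    only — regions without a reported change are implicitly CN 2),
    biomarkers.tsv, genes.bed, annotations.tsv, genome.json,
    variability.tsv, truth.json and manifest.json.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort_in_memory(config)
    write_variant_calls(cohort.calls, out / "variants.tsv")
    write_variant_calls(cohort.evidence, out / "evidence.tsv")

    # Sparse segment output: drop neutral (CN = 2) segments.
    sparse: dict[tuple[str, str], list[CNSegment]] = {}
    for key, profile in cohort.cn_profiles.items():
        segs = [
            s for chrom in profile.genome.included_chromosomes
            for s in profile.segments[chrom] if s.total_cn != 2
        ]
        sparse[key] = segs
    write_cn_segments(sparse, out / "segments.tsv")
    write_biomarker_table(cohort.biomarkers, out / "biomarkers.tsv")
    write_gene_intervals(config.gene_intervals(), out / "genes.bed")

    table = default_annotation_table(config)
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("type\tgene\talteration\tlevel\ttreatment\n")
        for row in table.variant_rows:
            fh.write(f"variant\t{row.gene}\t{row.alteration}\t{row.level}\t{row.treatment}\n")
        for gene in sorted(table.cn_genes):
            for kind in sorted(table.cn_genes[gene]):
                fh.write(f"{kind}\t{gene}\t*\t1\t\n")

    with open(out / "genome.json", "w") as fh:
        json.dump(config.genome.to_dict(), fh, indent=1, sort_keys=True)

    variability = pd.concat([
        simulate_variability_study(config, "hrd_sum", sigma_bioinf=1.0, sigma_wetlab=2.0),
        simulate_variability_study(config, "tmb", sigma_bioinf=0.15, sigma_wetlab=0.3),
        simulate_variability_study(config, "msi", sigma_bioinf=0.05, sigma_wetlab=0.1),
    ])
    variability.to_csv(out / "variability.tsv", sep="\t", index=False)

    truth_payload = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "roster": list(config.roster),
        "cases": [
            {
                "case_id": t.case_id,
                "purity": t.purity,
                "hrd_sum": t.hrd_sum, "tmb": t.tmb, "msi": t.msi,
                "variants": [
                    {
                        "chrom": v.key.chromosome, "pos": v.key.position,
                        "ref": v.key.ref, "alt": v.key.alt,
                        "vaf": v.vaf, "gene": v.gene,
                    }
                    for v in t.variants
                ],
                "cn_segments": [
                    {
                        "chrom": s.chromosome, "start": s.start,
                        "end": s.end, "total_cn": s.total_cn,
                    }
                    for s in t.cn_segments
                ],
            }
            for t in cohort.truths
        ],
        "miss_labels": [
            {"case_id": c, "institution_id": i, "variant": str(k), "mechanism": m}
            for (c, i, k), m in sorted(
                cohort.miss_labels.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
            )
        ],
        "false_positives": [
            {"case_id": c, "institution_id": i, "variant": str(k)}
            for (c, i), keys in sorted(cohort.fp_keys.items())
            for k in sorted(keys)
        ],
        "wgd_misclassified": [
            {"case_id": c, "institution_id": i, "wgd": flag}
            for (c, i), flag in sorted(cohort.wgd_flags.items())
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_cases": config.n_cases,
        "roster": list(config.roster),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return cohort
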