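"""Domain types, file readers/writers and variant normalization.

Conventions
-----------
Variants are 1-based (VCF convention); copy-number segments are stored
0-based half-open (BED convention).  Input dialects that use other
conventions are converted on read.  All variant identity comparisons in
the downstream modules operate on :class:`VariantKey` objects produced by
:func:`normalize_variant`, so that equivalent representations of the same
DNA edit compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a domain invariant."""


# --------------------------------------------------------------------------
# Enums
# --------------------------------------------------------------------------

class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


class FilterStatus(str, Enum):
    PASS = "PASS"
    QUALITY_FILTERED = "quality_filtered"
    OTHER_FILTERED = "other_filtered"


class Flag(str, Enum):
    """Evidence annotations attached to a call, used to explain discordance."""

    GERMLINE_OVERLAP = "germline_overlap"
    SPLICE_SITE = "splice_site"
    PROMOTER = "promoter"
    REPORTED_AS_SV = "reported_as_SV"
    ANNOTATION_MERGED = "annotation_merged"
    INTRONIC = "intronic"
    POLYMORPHISM = "polymorphism"
    LOH_EVENT = "LOH_event"
    HOMOLOGOUS_REGION = "homologous_region"


# --------------------------------------------------------------------------
# Genome model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome catalogue over which base-level comparisons run.

    ``included_chromosomes`` is the subset entering base-level copy-number
    comparison; by default analyses include autosomes plus chrX and exclude
    chrY.
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]
    included_chromosomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("chromosome names must be unique")
        for name in self.names:
            if self.lengths.get(name, 0) <= 0:
                raise ValidationError(f"chromosome {name!r} needs a positive length")
        extra = set(self.included_chromosomes) - set(self.names)
        if extra:
            raise ValidationError(f"included chromosomes not in genome: {sorted(extra)}")

    @property
    def included_length(self) -> int:
        return sum(self.lengths[c] for c in self.included_chromosomes)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "lengths": dict(self.lengths),
            "included_chromosomes": list(self.included_chromosomes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenomeModel":
        return cls(
            names=tuple(d["names"]),
            lengths=dict(d["lengths"]),
            included_chromosomes=tuple(d["included_chromosomes"]),
        )


# --------------------------------------------------------------------------
# Variant identity and normalization
# --------------------------------------------------------------------------

_DNA_RE = re.compile(r"^[ACGTN]+$")


def _classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VariantClass.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantClass.DELETION
    return VariantClass.DELINS


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a somatic alteration at the DNA level.

    Two calls refer to the same variant iff their keys compare equal
    (exact-match semantics on chromosome, position and REF/ALT strings
    after normalization).
    """

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not _DNA_RE.match(allele):
                raise ValidationError(f"invalid DNA string: {allele!r}")
        if self.position < 1:
            raise ValidationError("position must be >= 1")

    @property
    def variant_class(self) -> VariantClass:
        return _classify(self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


def normalize_variant(
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    context: str | None = None,
    context_start: int | None = None,
) -> VariantKey:
    """Return the canonical :class:`VariantKey` for a (pos, ref, alt) record.

    Shared suffix bases are trimmed first, then shared prefix bases are
    trimmed with the position advanced, always retaining one anchor base
    for indels.  When ``context`` (a reference sub-sequence whose first base
    sits at 1-based ``context_start``) is supplied, indels are additionally
    left-aligned against it, so that every representation of the same
    haplotype edit maps to one key.  Without a context only prefix/suffix
    trimming is applied.  The operation is idempotent.
    """

    ref = ref.upper()
    alt = alt.upper()
    if not ref and not alt:
        raise ValidationError("ref and alt must not both be empty")
    for allele in (ref, alt):
        if allele and not _DNA_RE.match(allele):
            raise ValidationError(f"invalid DNA string: {allele!r}")
    if position < 1:
        raise ValidationError("position must be >= 1")

    def context_base(pos: int) -> str | None:
        if context is None or context_start is None:
            return None
        idx = pos - context_start
        if 0 <= idx < len(context):
            return context[idx].upper()
        return None

    # Suffix trimming with optional left extension (classical left-align loop).
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        else:
            base = context_base(position - 1)
            if base is None:
                break
            ref = base + ref[:-1]
            alt = base + alt[:-1]
            position -= 1
    # Prefix trimming, keeping one anchor base.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1

    if not ref or not alt:
        # Alleles without an anchor base (e.g. "A" -> "" deletions); anchor
        # with the preceding context base when available.
        base = context_base(position - 1)
        if base is None:
            raise ValidationError(
                "allele trimmed to empty and no reference context available "
                f"to anchor {chromosome}:{position}"
            )
        ref = base + ref
        alt = base + alt
        position -= 1

    return VariantKey(chromosome=chromosome, position=position, ref=ref, alt=alt)


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One institution's observation of one variant in one case."""

    case_id: str
    institution_id: str
    key: VariantKey
    vaf: float
    depth: int
    filter_status: FilterStatus = FilterStatus.PASS
    gene: str = ""
    flags: frozenset[Flag] = frozenset()
    evidence_reads: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if self.evidence_reads is not None:
            if self.evidence_reads < 0:
                raise ValidationError("evidence_reads must be >= 0")
            if self.depth < self.evidence_reads:
                raise ValidationError("depth must be >= evidence_reads")


@dataclass(frozen=True)
class CNSegment:
    """Genomic interval of constant copy number, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    total_cn: int
    major_cn: int | None = None
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )
        if self.total_cn < 0:
            raise ValidationError("total_cn must be >= 0")
        if (self.major_cn is None) != (self.minor_cn is None):
            raise ValidationError("major_cn and minor_cn must be given together")
        if self.major_cn is not None and self.minor_cn is not None:
            if self.major_cn < 0 or self.minor_cn < 0:
                raise ValidationError("allele-specific CN must be >= 0")
            if self.major_cn + self.minor_cn != self.total_cn:
                raise ValidationError("major_cn + minor_cn must equal total_cn")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BiomarkerRecord:
    """Complex biomarker scores reported by one institution for one case.

    Any score may be missing (``None``), e.g. when an institution is unable
    to determine tumor purity for a sample.
    """

    case_id: str
    institution_id: str
    hrd_sum: float | None = None
    tmb: float | None = None
    msi: float | None = None
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        if self.hrd_sum is not None and self.hrd_sum < 0:
            raise ValidationError("hrd_sum must be >= 0")
        if self.tmb is not None and self.tmb < 0:
            raise ValidationError("tmb must be >= 0")
        if self.msi is not None and not 0 <= self.msi <= 100:
            raise ValidationError(f"msi {self.msi} outside [0, 100]")
        if self.purity is not None and not 0 <= self.purity <= 1:
            raise ValidationError("purity must lie in [0, 1]")
        if self.ploidy is not None and self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")


@dataclass(frozen=True)
class TherapeuticAnnotation:
    gene: str
    alteration: str  # "*" matches any alteration in the gene
    level: int
    treatment: str

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValidationError(f"evidence level must be 1-4, got {self.level}")


@dataclass
class AnnotationTable:
    """Static therapeutic-annotation input.

    ``variant_rows`` map gene (+ optional alteration matcher) to an evidence
    level 1-4 and a treatment label; ``cn_genes`` lists genes whose
    amplification and/or deletion is considered oncogenic.
    """

    variant_rows: list[TherapeuticAnnotation] = field(default_factory=list)
    cn_genes: dict[str, set[str]] = field(default_factory=dict)  # gene -> {"amplification","deletion"}

    def match(self, gene: str, alteration: str) -> TherapeuticAnnotation | None:
        """Best (lowest-level) annotation matching a gene/alteration pair."""
        hits = [
            row
            for row in self.variant_rows
            if row.gene == gene and row.alteration in ("*", alteration)
        ]
        return min(hits, key=lambda r: r.level) if hits else None


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chromosome: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(f"invalid gene interval for {self.gene}")


# --------------------------------------------------------------------------
# Variant call I/O
# --------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "case_id", "institution_id", "chrom", "pos", "ref", "alt",
    "vaf", "depth", "filter", "gene", "flags",
]

_QUALITY_FILTER_RE = re.compile(r"^q\d*$|qual|^lowqual$", re.IGNORECASE)


def map_filter_string(raw: str) -> FilterStatus:
    """Map a VCF/TSV FILTER string onto the three-way filter status.

    ``PASS``/``.``/empty pass through; quality-style names (``q20``,
    ``LowQual`` ...) become ``quality_filtered``; anything else is
    ``other_filtered``.
    """
    raw = raw.strip()
    if raw in ("", ".", "PASS"):
        return FilterStatus.PASS
    if raw == "quality_filtered":
        return FilterStatus.QUALITY_FILTERED
    if raw == "other_filtered":
        return FilterStatus.OTHER_FILTERED
    if _QUALITY_FILTER_RE.search(raw):
        return FilterStatus.QUALITY_FILTERED
    return FilterStatus.OTHER_FILTERED


def _parse_flags(raw: str) -> frozenset[Flag]:
    raw = raw.strip()
    if not raw or raw == ".":
        return frozenset()
    out = set()
    for token in raw.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            out.add(Flag(token))
        except ValueError as exc:
            raise ValidationError(f"unknown flag {token!r}") from exc
    return frozenset(out)


def read_variant_calls(
    path: str | Path,
    dialect: str = "tsv",
    case_id: str | None = None,
    institution_id: str | None = None,
    normalize: bool = True,
) -> list[VariantCall]:
    """Read somatic variant calls from a TSV dialect or a VCF 4.x file.

    The TSV dialect carries explicit ``case_id``/``institution_id`` columns;
    for VCF those identities come from the ``case_id``/``institution_id``
    arguments.  Every record is normalized through :func:`normalize_variant`
    unless ``normalize=False`` (strict-match mode, which reproduces literal
    per-caller representations).  Unparseable rows raise with their line
    number.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variant_tsv(path, normalize=normalize)
    if dialect == "vcf":
        if case_id is None or institution_id is None:
            raise ValidationError("VCF input requires case_id and institution_id")
        return _read_variant_vcf(path, case_id, institution_id, normalize=normalize)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _maybe_normalize(chrom: str, pos: int, ref: str, alt: str, normalize: bool) -> VariantKey:
    if normalize:
        return normalize_variant(chrom, pos, ref, alt)
    return VariantKey(chromosome=chrom, position=pos, ref=ref.upper(), alt=alt.upper())


def _read_variant_tsv(path: Path, normalize: bool) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _VARIANT_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {missing}")
        idx = {name: header.index(name) for name in header}
        has_evidence = "evidence_reads" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                key = _maybe_normalize(
                    fields[idx["chrom"]], int(fields[idx["pos"]]),
                    fields[idx["ref"]], fields[idx["alt"]], normalize,
                )
                evidence = None
                if has_evidence and fields[idx["evidence_reads"]].strip() not in ("", "."):
                    evidence = int(fields[idx["evidence_reads"]])
                calls.append(VariantCall(
                    case_id=fields[idx["case_id"]],
                    institution_id=fields[idx["institution_id"]],
                    key=key,
                    vaf=float(fields[idx["vaf"]]),
                    depth=int(fields[idx["depth"]]),
                    filter_status=map_filter_string(fields[idx["filter"]]),
                    gene=fields[idx["gene"]].strip(),
                    flags=_parse_flags(fields[idx["flags"]]),
                    evidence_reads=evidence,
                ))
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return calls


def _read_variant_vcf(
    path: Path, case_id: str, institution_id: str, normalize: bool
) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            status = FilterStatus.PASS if not filters else map_filter_string(filters[0])
            for alt in rec.alts or ():
                vaf, depth = _vcf_af_dp(rec)
                key = _maybe_normalize(rec.chrom, rec.pos, rec.ref, alt, normalize)
                gene = rec.info.get("GENE", "")
                if isinstance(gene, tuple):
                    gene = gene[0] if gene else ""
                try:
                    calls.append(VariantCall(
                        case_id=case_id, institution_id=institution_id, key=key,
                        vaf=vaf, depth=depth, filter_status=status, gene=str(gene),
                    ))
                except ValidationError as exc:
                    raise ValidationError(f"{path}: record {rec.chrom}:{rec.pos}: {exc}") from exc
    return calls


def _vcf_af_dp(rec) -> tuple[float, int]:
    vaf, depth = 0.0, 0
    if rec.samples:
        sample = rec.samples[0]
        af = sample.get("AF")
        if af is not None:
            vaf = float(af[0] if isinstance(af, tuple) else af)
        dp = sample.get("DP")
        if dp is not None:
            depth = int(dp)
    if vaf == 0.0 and "AF" in rec.info:
        info_af = rec.info["AF"]
        vaf = float(info_af[0] if isinstance(info_af, tuple) else info_af)
    if depth == 0 and "DP" in rec.info:
        depth = int(rec.info["DP"])
    return vaf, depth


def write_variant_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls in the TSV variant dialect (round-trips through the reader)."""
    columns = _VARIANT_COLUMNS + ["evidence_reads"]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for c in sorted(calls, key=lambda c: (c.case_id, c.institution_id, c.key)):
            fh.write("\t".join([
                c.case_id, c.institution_id, c.key.chromosome, str(c.key.position),
                c.key.ref, c.key.alt, repr(c.vaf), str(c.depth),
                c.filter_status.value, c.gene,
                ";".join(sorted(f.value for f in c.flags)) or ".",
                "." if c.evidence_reads is None else str(c.evidence_reads),
            ]) + "\n")


# --------------------------------------------------------------------------
# Copy-number segment I/O
# --------------------------------------------------------------------------

_SEG_COLUMNS = ["case_id", "institution_id", "chrom", "start", "end", "total_cn"]


def read_cn_segments(
    path: str | Path, dialect: str = "bed"
) -> dict[tuple[str, str], list[CNSegment]]:
    """Read a SEG-style TSV into per-(case, institution) segment lists.

    ``dialect="bed"`` expects 0-based half-open coordinates (stored as-is);
    ``dialect="seg1"`` expects 1-based inclusive coordinates and converts
    them, so (1, 100) becomes [0, 100).  Overlapping segments within one
    profile are rejected.
    """
    if dialect not in ("bed", "seg1"):
        raise FormatError(f"unknown segment dialect {dialect!r}")
    path = Path(path)
    profiles: dict[tuple[str, str], list[CNSegment]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _SEG_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {missing}")
        idx = {name: header.index(name) for name in header}
        allele = "major_cn" in idx and "minor_cn" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                start = int(fields[idx["start"]])
                end = int(fields[idx["end"]])
                if dialect == "seg1":
                    start -= 1  # 1-based inclusive -> 0-based half-open
                major = minor = None
                if allele:
                    raw_major = fields[idx["major_cn"]].strip()
                    raw_minor = fields[idx["minor_cn"]].strip()
                    if raw_major not in ("", ".") and raw_minor not in ("", "."):
                        major, minor = int(raw_major), int(raw_minor)
                seg = CNSegment(
                    chromosome=fields[idx["chrom"]], start=start, end=end,
                    total_cn=int(fields[idx["total_cn"]]),
                    major_cn=major, minor_cn=minor,
                )
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            key = (fields[idx["case_id"]], fields[idx["institution_id"]])
            profiles.setdefault(key, []).append(seg)
    for key, segs in profiles.items():
        overlaps = find_overlaps(segs)
        if overlaps:
            raise ValidationError(
                f"{path}: overlapping segments for {key}: "
                + "; ".join(f"{a.chromosome}:[{a.start},{a.end}) vs [{b.start},{b.end})"
                            for a, b in overlaps)
            )
        segs.sort(key=lambda s: (s.chromosome, s.start))
    return profiles


def find_overlaps(segments: Sequence[CNSegment]) -> list[tuple[CNSegment, CNSegment]]:
    """Pairs of overlapping segments within one profile (empty if valid)."""
    out = []
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                out.append((a, b))
    return out


def write_cn_segments(
    profiles: Mapping[tuple[str, str], Sequence[CNSegment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SEG_COLUMNS + ["major_cn", "minor_cn"]) + "\n")
        for (case, inst) in sorted(profiles):
            for s in sorted(profiles[(case, inst)], key=lambda s: (s.chromosome, s.start)):
                fh.write("\t".join([
                    case, inst, s.chromosome, str(s.start), str(s.end), str(s.total_cn),
                    "." if s.major_cn is None else str(s.major_cn),
                    "." if s.minor_cn is None else str(s.minor_cn),
                ]) + "\n")


# --------------------------------------------------------------------------
# Biomarker table I/O
# --------------------------------------------------------------------------

_BIOMARKER_COLUMNS = ["case_id", "institution_id", "hrd_sum", "tmb", "msi", "purity", "ploidy"]


def read_biomarker_table(path: str | Path) -> list[BiomarkerRecord]:
    """Read per-(case, institution) biomarker scores; empty cells are missing."""
    path = Path(path)
    records: list[BiomarkerRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _BIOMARKER_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {missing}")
        idx = {name: header.index(name) for name in header}

        def parse(fields: list[str], col: str) -> float | None:
            raw = fields[idx[col]].strip()
            return None if raw in ("", ".", "NA") else float(raw)

        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            key = (fields[idx["case_id"]], fields[idx["institution_id"]])
            if key in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate record for {key}")
            seen.add(key)
            try:
                records.append(BiomarkerRecord(
                    case_id=key[0], institution_id=key[1],
                    hrd_sum=parse(fields, "hrd_sum"), tmb=parse(fields, "tmb"),
                    msi=parse(fields, "msi"), purity=parse(fields, "purity"),
                    ploidy=parse(fields, "ploidy"),
                ))
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_biomarker_table(records: Iterable[BiomarkerRecord], path: str | Path) -> None:
    def fmt(x: float | None) -> str:
        return "" if x is None else repr(x)

    with open(path, "w") as fh:
        fh.write("\t".join(_BIOMARKER_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.case_id, r.institution_id)):
            fh.write("\t".join([
                r.case_id, r.institution_id, fmt(r.hrd_sum), fmt(r.tmb),
                fmt(r.msi), fmt(r.purity), fmt(r.ploidy),
            ]) + "\n")


# --------------------------------------------------------------------------
# BED gene intervals and annotation tables
# --------------------------------------------------------------------------

def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """BED (chrom, start, end, name) -> gene intervals, 0-based half-open."""
    out: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs 4 columns (chrom,start,end,name)")
            try:
                out.append(GeneInterval(
                    gene=fields[3], chromosome=fields[0],
                    start=int(fields[1]), end=int(fields[2]),
                ))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_intervals(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gi in sorted(intervals, key=lambda g: (g.chromosome, g.start)):
            fh.write(f"{gi.chromosome}\t{gi.start}\t{gi.end}\t{gi.gene}\n")


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """TSV with columns type/gene/alteration/level/treatment.

    ``type`` is ``variant`` (therapeutic variant row, level 1-4 required),
    ``amplification`` or ``deletion`` (oncogenic CN event genes).
    """
    table = AnnotationTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["type", "gene", "alteration", "level", "treatment"]
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            kind = fields[idx["type"]].strip()
            gene = fields[idx["gene"]].strip()
            if kind == "variant":
                try:
                    table.variant_rows.append(TherapeuticAnnotation(
                        gene=gene,
                        alteration=fields[idx["alteration"]].strip() or "*",
                        level=int(fields[idx["level"]]),
                        treatment=fields[idx["treatment"]].strip(),
                    ))
                except (ValueError, ValidationError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            elif kind in ("amplification", "deletion"):
                table.cn_genes.setdefault(gene, set()).add(kind)
            else:
                raise ValidationError(f"{path}:{lineno}: unknown row type {kind!r}")
    return table
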