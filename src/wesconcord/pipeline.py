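"""Pipeline orchestration: run all analysis stages over a cohort directory.

The cohort directory layout matches what :func:`wesconcord.synthetic_data.
simulate_cohort` writes (and what a real multi-center comparison would be
exported to): variants.tsv, optional evidence.tsv, segments.tsv,
biomarkers.tsv, genome.json, genes.bed, optional annotations.tsv and
variability.tsv.  Every number in the emitted report tables is produced by
the module operations; this layer only formats and assembles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from wesconcord import biomarker_concordance as bm
from wesconcord import cna_concordance as cna
from wesconcord import variance_decomposition as vd
from wesconcord import variant_concordance as vc
from wesconcord.core_io import (
    GenomeModel,
    read_annotation_table,
    read_biomarker_table,
    read_cn_segments,
    read_gene_intervals,
    read_variant_calls,
)

log = logging.getLogger("wesconcord")


@dataclass
class RunConfig:
    """Thresholds and options for a full pipeline run."""

    cohort_dir: Path
    out_dir: Path
    vaf_threshold: float = 0.10
    cov_threshold: int = 100
    consensus_k: tuple[int, ...] = (2, 3)
    amp_delta: int = 5
    duplication_rule: str = "ratio"  # or "delta"
    cutoffs: bm.CutoffConfig = field(default_factory=bm.CutoffConfig)
    wilcoxon_alternative: str = "two-sided"
    strict_match: bool = False  # disable indel normalization on read
    reference_replicate_bioinf: str = "pipeline1"
    reference_replicate_wetlab: str = "lab1"

    def __post_init__(self) -> None:
        self.cohort_dir = Path(self.cohort_dir)
        self.out_dir = Path(self.out_dir)


def _float(x) -> str:
    return "" if x is None else f"{x:.6f}"


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def run_variant_stage(config: RunConfig) -> dict:
    calls = read_variant_calls(
        config.cohort_dir / "variants.tsv", normalize=not config.strict_match
    )
    roster = None
    manifest_path = config.cohort_dir / "manifest.json"
    if manifest_path.exists():
        roster = json.loads(manifest_path.read_text()).get("roster")
    collection = vc.CallSetCollection.from_calls(calls, roster=roster)
    evidence_lookup = {}
    evidence_path = config.cohort_dir / "evidence.tsv"
    if evidence_path.exists():
        for ev in read_variant_calls(evidence_path, normalize=not config.strict_match):
            evidence_lookup[(ev.case_id, ev.institution_id, ev.key)] = ev

    hist = vc.support_histogram(collection)
    hist_summary = {
        "n_unique_variants": hist.total,
        "counts_by_support": {str(k): v for k, v in sorted(hist.counts.items())},
        "buckets": hist.buckets,
        "bucket_percent": {},
    }
    for name, count in hist.buckets.items():
        frac = hist.bucket_fractions[name]
        lo, hi = (
            vc.clopper_pearson(count, hist.total) if hist.total else (0.0, 0.0)
        )
        hist_summary["bucket_percent"][name] = {
            "percent": round(100 * frac, 2),
            "ci_low": round(100 * lo, 2),
            "ci_high": round(100 * hi, 2),
        }

    rows = []
    pooled = {}
    for k in config.consensus_k:
        references = {
            case: vc.build_consensus(collection, case, k) for case in collection.cases
        }
        for inst in collection.roster:
            results = [
                vc.score_against_reference(collection, ref, inst)
                for ref in references.values()
            ]
            for r in results:
                rows.append({
                    "reference": r.reference_label, "case_id": r.case_id,
                    "institution_id": inst, "tp": r.tp, "fp": r.fp, "fn": r.fn,
                    "ppa": _float(r.ppa), "ppv": _float(r.ppv),
                })
            agg = vc.aggregate_concordance(results, mode="pooled")
            agg_mean = vc.aggregate_concordance(results, mode="per_case_mean")
            pooled[f"consensus_{k}x::{inst}"] = {
                "ppa_pooled": agg["ppa"], "ppv_pooled": agg["ppv"],
                "tp": agg["tp"], "fp": agg["fp"], "fn": agg["fn"],
                "ppa_per_case_mean": agg_mean["ppa"],
                "ppv_per_case_mean": agg_mean["ppv"],
            }
    columns = ["reference", "case_id", "institution_id", "tp", "fp", "fn", "ppa", "ppv"]
    concordance = pd.DataFrame(rows, columns=columns).sort_values(
        ["reference", "case_id", "institution_id"], kind="mergesort"
    )

    discordance = vc.classify_all_discordant(
        collection, evidence_lookup or None,
        vaf_threshold=config.vaf_threshold, cov_threshold=config.cov_threshold,
    )
    discordance_frame = pd.DataFrame(
        [
            {
                "case_id": d.case_id, "variant": str(d.variant),
                "institution_id": d.institution_id,
                "direction": d.direction.value, "cause": d.cause.value,
            }
            for d in discordance
        ],
        columns=["case_id", "variant", "institution_id", "direction", "cause"],
    )
    cause_counts: dict[str, dict[str, int]] = {}
    for d in discordance:
        bucket = cause_counts.setdefault(d.direction.value, {})
        bucket[d.cause.value] = bucket.get(d.cause.value, 0) + 1

    annotation_path = config.cohort_dir / "annotations.tsv"
    therapeutic = None
    if annotation_path.exists():
        table = read_annotation_table(annotation_path)
        therapeutic = vc.therapeutic_concordance_matrix(collection, table)

    return {
        "collection": collection,
        "support_histogram": hist_summary,
        "concordance": concordance,
        "pooled": pooled,
        "discordance": discordance_frame,
        "cause_counts": cause_counts,
        "therapeutic": therapeutic,
    }


def run_cna_stage(config: RunConfig) -> dict:
    genome = GenomeModel.from_dict(
        json.loads((config.cohort_dir / "genome.json").read_text())
    )
    profiles_raw = read_cn_segments(config.cohort_dir / "segments.tsv")
    filled = {
        (case, inst): cna.fill_profile(segs, genome, case_id=case, institution_id=inst)
        for (case, inst), segs in profiles_raw.items()
    }
    cases = sorted({case for case, _ in filled})
    insts = sorted({inst for _, inst in filled})

    comparisons = []
    rows = []
    for case in cases:
        for i, a in enumerate(insts):
            for b in insts[i + 1:]:
                if (case, a) not in filled or (case, b) not in filled:
                    continue
                cmp = cna.compare_profiles(
                    filled[(case, a)], filled[(case, b)], rule=config.duplication_rule
                )
                comparisons.append(cmp)
                fr = cmp.fractions
                rows.append({
                    "case_id": case, "institution_a": a, "institution_b": b,
                    "ploidy_a": cmp.ploidy_a, "ploidy_b": cmp.ploidy_b,
                    "exact_bp": cmp.exact_match_bp,
                    "duplication_bp": cmp.duplication_match_bp,
                    "mismatch_bp": cmp.mismatch_bp,
                    "exact_fraction": _float(fr["exact"]),
                    "duplication_fraction": _float(fr["duplication"]),
                    "mismatch_fraction": _float(fr["mismatch"]),
                })
    pairwise = pd.DataFrame(rows)
    match = cna.aggregate_match_fraction(comparisons)
    diff_hist = cna.cn_diff_summary(comparisons)

    gene_intervals = read_gene_intervals(config.cohort_dir / "genes.bed")
    annotation_path = config.cohort_dir / "annotations.tsv"
    cn_genes = None
    if annotation_path.exists():
        cn_genes = set(read_annotation_table(annotation_path).cn_genes)
    event_rows = []
    for case in cases:
        per_inst = {
            inst: filled[(case, inst)] for inst in insts if (case, inst) in filled
        }
        if len(per_inst) < 2:
            continue
        intervals = [
            gi for gi in gene_intervals if cn_genes is None or gi.gene in cn_genes
        ]
        matrix, agreement = cna.gene_event_matrix(
            per_inst, intervals, amp_delta=config.amp_delta
        )
        for gene, events in matrix.items():
            classes = {e.classification for e in events.values()}
            if classes == {cna.CNEventClass.NEUTRAL}:
                continue  # report only genes with an event somewhere
            row = {"case_id": case, "gene": gene, "agreement": agreement[gene].value}
            for inst, event in events.items():
                row[f"{inst}_class"] = event.classification.value
                row[f"{inst}_min_cn"] = event.min_cn
                row[f"{inst}_max_cn"] = event.max_cn
            event_rows.append(row)
    return {
        "pairwise": pairwise,
        "match_fraction": match,
        "cn_diff_histogram": {str(k): v for k, v in diff_hist.items()},
        "gene_events": pd.DataFrame(event_rows),
    }


def run_biomarker_stage(config: RunConfig) -> dict:
    records = read_biomarker_table(config.cohort_dir / "biomarkers.tsv")
    panel = bm.biomarker_panel(
        records, cutoffs=config.cutoffs, alternative=config.wilcoxon_alternative
    )
    return {"records": records, "panel": panel}


def run_variance_stage(config: RunConfig) -> dict:
    path = config.cohort_dir / "variability.tsv"
    frame = pd.read_csv(path, sep="\t")
    summaries = {}
    for biomarker in sorted(frame["biomarker"].unique()):
        bio = vd.ReplicateMatrix.from_long(
            frame, biomarker, vd.BIOINFORMATIC, config.reference_replicate_bioinf
        )
        wet = vd.ReplicateMatrix.from_long(
            frame, biomarker, vd.WETLAB, config.reference_replicate_wetlab
        )
        summaries[biomarker] = vd.compare_sources(bio, wet)
    return {"summaries": summaries}


# --------------------------------------------------------------------------
# Full run and report emission
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; report partial failures.

    Returns the results bundle.  A stage whose input file is absent or
    unparseable is recorded under ``skipped`` and the remaining stages still
    run; output artifacts are written into ``config.out_dir``.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"stages": {}, "skipped": {}}
    stage_fns = {
        "variants": run_variant_stage,
        "cna": run_cna_stage,
        "biomarkers": run_biomarker_stage,
        "variance": run_variance_stage,
    }
    for name, fn in stage_fns.items():
        try:
            bundle["stages"][name] = fn(config)
        except FileNotFoundError as exc:
            log.warning("stage %s skipped: missing input %s", name, exc)
            bundle["skipped"][name] = f"missing input: {exc}"
        except Exception as exc:  # keep other stages alive
            log.warning("stage %s failed: %s", name, exc)
            bundle["skipped"][name] = str(exc)
    _write_outputs(bundle, config)
    return bundle


def _write_outputs(bundle: dict, config: RunConfig) -> None:
    out = config.out_dir
    stages = bundle["stages"]
    if "variants" in stages:
        stage = stages["variants"]
        stage["concordance"].to_csv(out / "variant_concordance.tsv", sep="\t", index=False)
        stage["discordance"].to_csv(out / "variant_discordance.tsv", sep="\t", index=False)
        with open(out / "variant_summary.json", "w") as fh:
            json.dump({
                "support_histogram": stage["support_histogram"],
                "pooled": stage["pooled"],
                "cause_counts": stage["cause_counts"],
            }, fh, indent=1, sort_keys=True)
        if stage["therapeutic"] is not None and len(stage["therapeutic"]):
            stage["therapeutic"].to_csv(out / "therapeutic_matrix.tsv", sep="\t", index=False)
    if "cna" in stages:
        stage = stages["cna"]
        stage["pairwise"].to_csv(out / "cna_pairwise.tsv", sep="\t", index=False)
        if len(stage["gene_events"]):
            stage["gene_events"].to_csv(out / "cna_gene_events.tsv", sep="\t", index=False)
        with open(out / "cna_summary.json", "w") as fh:
            json.dump({
                "match_fraction": stage["match_fraction"],
                "cn_diff_histogram": stage["cn_diff_histogram"],
            }, fh, indent=1, sort_keys=True)
    if "biomarkers" in stages:
        panel = stages["biomarkers"]["panel"]
        summary = {}
        for biomarker, entry in panel.items():
            entry["pearson"].to_csv(out / f"{biomarker}_pearson.tsv", sep="\t")
            entry["deviation_pct"].to_csv(out / f"{biomarker}_deviation.tsv", sep="\t")
            if "status" in entry:
                entry["status"].to_csv(out / f"{biomarker}_status.tsv", sep="\t")
                counts = entry["agreement"]["category"].value_counts(dropna=True)
                summary[biomarker] = {str(k): int(v) for k, v in counts.items()}
        with open(out / "biomarker_summary.json", "w") as fh:
            json.dump({"status_agreement": summary}, fh, indent=1, sort_keys=True)
    if "variance" in stages:
        summaries = stages["variance"]["summaries"]
        rows = []
        payload = {}
        for biomarker, s in summaries.items():
            payload[biomarker] = {
                "median_sd_bioinformatic": s.median_sd_bioinformatic,
                "median_sd_wetlab": s.median_sd_wetlab,
                "sd_ratio": s.sd_ratio,
                "wilcoxon_p": s.wilcoxon_p,
                "outliers_bioinformatic": s.outliers_bioinformatic,
                "outliers_wetlab": s.outliers_wetlab,
            }
            for sample in s.sd_bioinformatic.index:
                rows.append({
                    "biomarker": biomarker, "sample": sample,
                    "sd_bioinformatic": _float(float(s.sd_bioinformatic[sample])),
                    "sd_wetlab": _float(float(s.sd_wetlab[sample])),
                })
        pd.DataFrame(rows).to_csv(out / "variance_per_sample.tsv", sep="\t", index=False)
        with open(out / "variance_summary.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    (out / "summary.md").write_text(emit_report(bundle))


def emit_report(bundle: dict) -> str:
    """Render the cohort-level markdown summary from the results bundle."""
    lines = ["# Multi-institution WES concordance summary", ""]
    stages = bundle["stages"]
    for name, reason in bundle["skipped"].items():
        lines.append(f"*Stage `{name}` skipped: {reason}*")
    if bundle["skipped"]:
        lines.append("")

    if "variants" in stages:
        stage = stages["variants"]
        hist = stage["support_histogram"]
        lines.append("## Somatic variant concordance")
        if hist["n_unique_variants"] == 0:
            lines.append("No variants detected in this cohort.")
        else:
            lines.append(
                f"{hist['n_unique_variants']} unique variants; detection support "
                "(percent of unique variants, Clopper-Pearson 95% CI):"
            )
            for bucket in ("all", "some", "single"):
                entry = hist["bucket_percent"][bucket]
                lines.append(
                    f"- {bucket}: {entry['percent']}% "
                    f"(CI {entry['ci_low']}-{entry['ci_high']}%)"
                )
            lines.append("")
            lines.append("Pooled PPA / PPV per institution and reference:")
            lines.append("")
            lines.append("| reference | institution | PPA | PPV |")
            lines.append("|---|---|---|---|")
            for label in sorted(stage["pooled"]):
                entry = stage["pooled"][label]
                ref, inst = label.split("::")
                ppa = entry["ppa_pooled"]
                ppv = entry["ppv_pooled"]
                lines.append(
                    f"| {ref} | {inst} | "
                    f"{'NA' if ppa is None else f'{100 * ppa:.1f}%'} | "
                    f"{'NA' if ppv is None else f'{100 * ppv:.1f}%'} |"
                )
        lines.append("")

    if "cna" in stages:
        stage = stages["cna"]
        match = stage["match_fraction"]
        lines.append("## Copy-number concordance")
        lines.append(
            f"Matching (exact or duplication-explained) genome fraction: "
            f"{100 * match['pooled']:.1f}% pooled, "
            f"{100 * match['per_pair_mean']:.1f}% per-pair mean."
        )
        if stage["cn_diff_histogram"]:
            parts = ", ".join(
                f"|dCN|={k}: {100 * v:.0f}%"
                for k, v in stage["cn_diff_histogram"].items()
            )
            lines.append(f"CN differences over mismatched bases: {parts}.")
        lines.append("")

    if "biomarkers" in stages:
        lines.append("## Complex biomarkers")
        for biomarker, entry in stages["biomarkers"]["panel"].items():
            r = entry["pearson"]
            tri = [
                r.iloc[i, j]
                for i in range(len(r)) for j in range(i + 1, len(r))
                if pd.notna(r.iloc[i, j])
            ]
            if tri:
                lines.append(
                    f"- {biomarker}: Pearson r {min(tri):.2f}-{max(tri):.2f}"
                )
        lines.append("")

    if "variance" in stages:
        lines.append("## Wet-lab vs bioinformatic variability")
        for biomarker, s in stages["variance"]["summaries"].items():
            lines.append(
                f"- {biomarker}: median SD wet-lab {s.median_sd_wetlab:.3g}, "
                f"bioinformatic {s.median_sd_bioinformatic:.3g} "
                f"(one-sided Wilcoxon p = {s.wilcoxon_p:.3g})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
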