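# Methods

## Setting and model

A cohort of cases (tumor/normal pairs) is analyzed by a roster of
institutions, each combining its own wet-lab protocol and bioinformatic
pipeline. For every case each institution reports (i) a somatic variant
call set, (ii) a copy-number segmentation with optional allele-specific
copy numbers and a tumor-purity estimate, and (iii) complex biomarker
scores: HRDsum (homologous recombination deficiency sum score), TMB
(tumor mutational burden, mutations per megabase) and MSI (microsatellite
instability, percent unstable sites). The package quantifies agreement
between institutions on each layer and attributes disagreement to causes.
No ground truth exists for clinical tissue, so agreement is always measured
against surrogate references (consensus call sets, pairwise comparison, or
a designated reference pipeline).

## Variant identity and normalization

Variants are compared by exact match on (chromosome, position, REF, ALT)
after normalization: shared suffix bases are trimmed, then shared prefix
bases are trimmed with the position advanced, always keeping one anchor
base for indels; when a reference context is available, indels are
additionally left-aligned by the classical trim-and-extend loop. The
normalized key is provably representation-invariant: the test suite
enumerates every (pos, ref, alt) encoding of an edit on a printed context,
checks equality of the edited haplotype strings (the oracle), and asserts
that all encodings map to one key that itself reproduces the haplotype.
A `--strict-match` mode disables normalization to reproduce literal
per-caller representation matching, which inflates indel discordance —
useful for studying exactly that effect.

## Consensus references, PPA and PPV

The consensus-k reference for a case is the set of variants called by at
least k distinct institutions (k = 2 and 3 by default; references nest:
consensus-(k+1) ⊆ consensus-k). Against a reference, an institution's
TP/FP/FN are exact set counts; PPA = TP/(TP+FN) and PPV = TP/(TP+FP).
Ratios with empty denominators (e.g. a case where nothing was detected)
are reported as missing, never as zero, and excluded from aggregates.
Cohort aggregation is *pooled* (summing counts before forming ratios) as
the primary mode and per-case mean as a secondary output, since the two
can differ when case sizes vary. All proportions carry exact
Clopper–Pearson intervals, computed from Beta quantiles
(lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k)) and verified
against an independent binomial tail-bisection oracle.

## Discordance taxonomy

Each discordant (variant, institution) pair — a miss of a variant seen by
at least two others, or a call made by a single institution — receives
exactly one cause. Because a variant can satisfy several mechanisms at
once, causes are tested in a fixed documented precedence order:
low VAF (< 0.10) or coverage (< 100) in the institution's evidence →
removed by a quality/other filter → merged into another annotation →
germline branch (mislabeled as germline / germline variant missed by the
others) → reported as structural variant → intron/polymorphism filtering →
no supporting reads or off target → remaining flag-driven causes (splice
classification, promoter region, somatic LOH, homologous region), then
singleton-indel representation → unexplained. The VAF and coverage
thresholds are configuration defaults and overridable. The "evidence"
record is the institution's pre-filter observation of the variant (from
raw-data re-inspection, or the simulator's evidence channel); without
evidence the cause is *unexplained* rather than guessed.

## Copy-number comparison

Segmentations are completed to a gap-free tiling per chromosome — regions
without a reported change are set to CN 2 (major 1 / minor 1 in
allele-specific mode) — and adjacent equal-CN segments are merged. The
predominant ploidy is the CN covering the largest base fraction, ties
broken toward the lower CN (a deterministic, conservative choice). The
default comparison covers autosomes plus chrX and excludes chrY
(configurable through the genome model).

Profiles are compared pairwise over the union of their breakpoints, which
is exactly equivalent to a per-base loop (asserted against a brute-force
oracle in the tests) at O(segments) cost. Each base is *exact* when total
CNs agree; otherwise *duplication-explained* when the discrepancy is
accounted for by a discordant genome-duplication call; otherwise a
*mismatch* contributing |ΔCN| to a histogram. Concordance uses total CN;
allele-specific values are carried through but not compared.

Two duplication rules are provided. The default is the ratio rule,
cn_a/ploidy_a = cn_b/ploidy_b: a profile compared with its exact doubling
(one institution calls a genome duplication, the other does not) is then
fully duplication-explained, which is the defining behavior of this
category. The delta rule, cn_a − ploidy_a = cn_b − ploidy_b, is available
behind `--dup-rule delta`; it treats CN offsets as additive and explains
only ploidy-level bases after a doubling, so it is strictly more
conservative. Match fractions are aggregated both bp-weighted over all
pairs pooled and as a per-pair mean.

Gene-level events intersect the tiling with gene intervals. The
representative CN is the minimum over the gene for deletion calling and
the maximum for amplification calling (both are reported). Deletions use
fixed absolute thresholds — deep at CN 0, monoallelic at CN 1 — a
deliberate asymmetry to the ploidy-relative amplification rule
(high-level at CN ≥ ploidy + 5; above ploidy but below that is
low-level). Per gene, institutions either all agree, disagree only between
high- and low-level amplification (threshold disagreement), or disagree in
any other way (presence disagreement, which includes deep- vs
monoallelic-deletion splits).

## Biomarker statistics

Scores form case × institution matrices with missing-value support
(e.g. an undeterminable purity). Pairwise statistics use
pairwise-complete observations; the per-case status summary is listwise.
For each institution pair: Pearson r (undefined — not NaN-propagated —
under zero variance or fewer than three complete pairs); the zero-intercept
least-squares slope b = Σxy/Σx², whose systematic deviation is
(b − 1)·100 %; and a paired Wilcoxon signed-rank test. The Wilcoxon
direction is a required configuration choice, not inferred from the data;
zero differences are dropped, the exact null distribution is used up to 25
non-zero differences and a continuity-corrected normal approximation
above (exactness is cheap and deterministic at cohort scale n = 30, and
the branches agree to < 0.01 at the switch point). No multiple-testing
correction is applied; p-values are reported raw.

Status calls use score ≥ cutoff (the boundary counts positive, consistent
with a TMB of 10.19 being high and 9.95 low at a cutoff of 10). Default
cutoffs: HRDsum 42, TMB 10 mut/MB, MSI 10 % with per-institution overrides
(a pipeline using a different MSI tool may call high at 40 %). Per case the
roster is *all positive*, *all negative*, or *discordant* with the minority
institutions listed.

## Wet-lab vs bioinformatic variability

Two replicate designs: the data of one sequencing lab evaluated by several
pipelines (per-sample spread = bioinformatic variability) and the data of
several labs evaluated by one pipeline (spread = wet-lab variability).
Before computing spreads, each replicate column is divided by its
zero-intercept slope against a reference replicate — division is the
natural inverse of a multiplicative scale model and makes the operation
idempotent — so systematic scale offsets do not masquerade as scatter.
Per-sample SDs use the unbiased (n−1) estimator; samples with fewer than
two observed replicates are skipped, not imputed. The two axes are
contrasted on shared samples by their median SDs and a one-sided paired
Wilcoxon test (default direction: wet-lab exceeds bioinformatic); samples
beyond the 1.5×IQR whiskers of either SD distribution are flagged as
outliers. A full mixed-effects variance-component model is deliberately
out of scope; the two-matrix SD design answers the operational question
directly.

## Synthetic cohort generator

The generator emulates the statistical structure of a multi-center WES
comparison so that every statistic has a known generative truth.

Per case it draws a truth: somatic variants (count ~ Poisson(9) per case,
84 % SNVs, positions inside a deterministic 200-gene panel) with VAFs from
a clonal/subclonal Beta mixture (86 % Beta(7,13), mean ≈ 0.35; 14 %
Beta(2,25), mean ≈ 0.07); a copy-number tiling around a baseline ploidy
(tetraploid with probability 0.2, the longest span per chromosome held at
baseline so the predominant ploidy reflects the intended state); tumor
purity uniform on [0.46, 0.90]; and independent biomarker truths
(HRDsum ~ N(30, 18) clipped to [0, 100], TMB log-normal with median
≈ 4 mut/MB, MSI exponential with scale 2 %). The joint distribution of
biomarker truths in real tumors is unknown; independence is a documented
simplification. Optionally TMB can be tied to the simulated variant count
per panel megabase (off by default, since in practice biomarker scores are
independent pipeline outputs).

Each institution then observes the truth through explicit channels.
Detection is two-regime — confident variants (VAF ≥ 0.10 and depth ≥ 100,
depth ~ negative binomial around the institution's mean coverage) are
detected with probability 0.965–0.985 depending on the institution,
low-evidence variants with 0.50–0.65 — rather than a continuous logistic
curve, matching the binary VAF/coverage taxonomy used in the discordance
analysis. Detected confident variants can be filter-removed (~2 %) or
merged into another annotation (~1.5 %); false positives arrive at 0.3–0.6
per case with a low-VAF Beta(1.3, 12) spectrum. Every miss records an
evidence entry (the variant-level VAF, the institution's local depth and
supporting-read count, filter status, flags) plus a mechanism label, which
is what the discordance classifier is validated against. CN observations
double the whole profile with probability 0.06 (WGD misclassification),
shift each segment's CN by ±1 with probability 0.08 scaled by
0.68/purity (noisier calls at low purity), and jitter interior breakpoints
by up to 50 kb. Biomarkers are observed as bias × truth + Gaussian noise;
the default biases span 0.85–1.09 for HRDsum and one institution reports
TMB 12 % low, mirroring realistic systematic deviations; one institution
uses the 40 % MSI cutoff.

These defaults were fixed once so that the default cohort reproduces the
canonical structure of such comparisons — detection-support buckets of
roughly 52 / 22 / 26 % (all / some / single) and pooled PPA of 91–95 %
against the three-institution consensus — and are not tuned per run.

Randomness is fully deterministic: a master seed expands into independent
PCG64 sub-streams per (channel, case, institution) via seed sequences, so
regenerating one institution leaves all other outputs byte-identical.
The toy genome is five included chromosomes (chr1–chr4 + chrX, 100 Mb
total; chrY present but excluded), small enough for fast exact interval
arithmetic while exercising multi-chromosome bookkeeping.

What the generator does *not* model: read-level data (no FASTQ/BAM),
FFPE artifacts (fresh-frozen samples are assumed), real gene annotation,
structural variants beyond a flag, correlated biomarker truths, and
per-exon coverage structure. Passing tests therefore demonstrate that the
analysis stack measures what it claims on data with known structure — not
that any particular laboratory achieves these numbers on tissue.

## Numerical and degenerate-input choices

- Predominant-ploidy ties break toward the lower CN.
- Undefined ratios (empty references, zero-variance scores, all-zero
  Wilcoxon differences) are explicit missing values or p = 1 with a
  warning, never silent zeros or NaNs.
- Gene intervals touching a segment boundary intersect by half-open
  overlap; variants are matched to intervals by 1-based position within
  the half-open interval.
- A gene whose interval contains both a deletion (min CN ≤ 1) and an
  amplification is classified by the deletion first (deep/monoallelic
  take precedence over amplification classes).
- Coordinates: variants 1-based (VCF convention), segments 0-based
  half-open (BED convention); the 1-based inclusive segment dialect is
  converted on read.
- Unknown FILTER strings map to `other_filtered`; quality-style names
  (`q20`, `LowQual`) to `quality_filtered`.
- Writers emit full-precision floats (`repr`) so write→read round-trips
  are exact.

## Problem sizes

Default simulated cohorts are 30 cases × 5 institutions on the 100 Mb toy
genome. The test suite validates the interval comparison against the
per-base oracle on 100 kb genomes (50 random pairs), detection-probability
recovery on 10,000 confident variants, bias recovery over 500 replicates
of 30 cases, and noise-ratio recovery over 200 replicates of 30 samples —
sizes chosen to make sampling error a small fraction of the tested
tolerances while keeping the full suite under a minute of compute.

## Known limitations

- Consensus references are biased surrogates: a variant systematically
  missed by most institutions never enters the reference, so PPA against
  consensus overstates sensitivity relative to an oracle truth. This is a
  property of the design being reproduced, not of the implementation.
- The discordance classifier is only as good as the evidence records it
  is given; on real cohorts assembling pre-filter evidence is the
  labor-intensive step.
- MSI is treated as a generic percentage score; tool-specific score
  semantics beyond the cutoff override are not modeled.
- The annotation table is a pre-resolved static input; no entity/ontology
  matching is performed.
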