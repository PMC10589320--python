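"""Separation of wet-lab and bioinformatic variability.

Two replicate designs feed this module: (i) the sequencing data of one
laboratory evaluated by several bioinformatic pipelines (the replicate axis
is the pipeline, so the per-sample spread reflects bioinformatic
variability) and (ii) the data of several laboratories evaluated by one
pipeline (spread reflects wet-lab variability).  Before computing spreads,
every replicate column is normalized onto a reference replicate by a
zero-intercept linear fit, removing systematic scale offsets so the
residual per-sample standard deviations measure irreducible scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from wesconcord.biomarker_concordance import paired_wilcoxon, zero_intercept_slope
from wesconcord.core_io import ValidationError

BIOINFORMATIC = "bioinformatic_pipelines"
WETLAB = "sequencing_labs"


@dataclass
class ReplicateMatrix:
    """Samples x replicates matrix of one biomarker on one variability axis."""

    biomarker: str
    data: pd.DataFrame  # index: sample id, columns: replicate id
    axis: str  # BIOINFORMATIC or WETLAB
    reference: str  # replicate id columns are normalized against

    def __post_init__(self) -> None:
        if self.axis not in (BIOINFORMATIC, WETLAB):
            raise ValidationError(f"unknown replicate axis {self.axis!r}")
        if self.data.shape[1] < 2:
            raise ValidationError("need at least 2 replicates")
        if self.data.shape[0] < 3:
            raise ValidationError("need at least 3 samples")
        if self.reference not in self.data.columns:
            raise ValidationError(f"reference replicate {self.reference!r} not present")

    @classmethod
    def from_long(
        cls, frame: pd.DataFrame, biomarker: str, axis: str, reference: str
    ) -> "ReplicateMatrix":
        """Build from long format (sample, replicate_id, axis, biomarker, value)."""
        sub = frame[(frame["axis"] == axis) & (frame["biomarker"] == biomarker)]
        matrix = sub.pivot(index="sample", columns="replicate_id", values="value")
        return cls(biomarker=biomarker, data=matrix.sort_index(), axis=axis, reference=reference)


def normalize_to_reference(matrix: ReplicateMatrix) -> ReplicateMatrix:
    """Scale every replicate column onto the reference replicate.

    Each non-reference column is divided by its zero-intercept slope fitted
    against the reference over jointly observed samples; the reference
    column is unchanged.  Idempotent: re-normalizing is a no-op (up to
    floating point) because the fitted slope of an already-normalized
    column is 1.
    """
    ref = matrix.data[matrix.reference]
    if ref.isna().any():
        used = matrix.data.dropna(how="all").index
        if ref.loc[used].isna().any():
            raise ValidationError("reference replicate has missing values")
    out = matrix.data.copy()
    for col in matrix.data.columns:
        if col == matrix.reference:
            continue
        both = matrix.data[[matrix.reference, col]].dropna()
        if len(both) < 2:
            raise ValidationError(f"replicate {col!r} shares <2 samples with reference")
        slope = zero_intercept_slope(
            both[matrix.reference].to_numpy(), both[col].to_numpy()
        )
        if slope == 0:
            raise ValidationError(f"zero fitted slope for replicate {col!r}")
        out[col] = matrix.data[col] / slope
    return replace(matrix, data=out)


def per_sample_sd(matrix: ReplicateMatrix, min_replicates: int = 2) -> pd.Series:
    """Unbiased (n-1) standard deviation across replicates, per sample.

    Samples with fewer than ``min_replicates`` non-missing replicates are
    skipped rather than imputed.
    """
    sds = matrix.data.std(axis=1, ddof=1)
    enough = matrix.data.notna().sum(axis=1) >= max(min_replicates, 2)
    return sds[enough]


def median_sd(matrix: ReplicateMatrix) -> float:
    """Median of the per-sample SDs over retained samples."""
    sds = per_sample_sd(matrix)
    if len(sds) < 3:
        raise ValidationError("fewer than 3 samples with enough replicates")
    return float(sds.median())


def iqr_outliers(values: pd.Series) -> list:
    """Sample ids beyond the 1.5 x IQR whiskers (boxplot rule)."""
    q1, q3 = values.quantile(0.25), values.quantile(0.75)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return sorted(values[(values < lower) | (values > upper)].index.tolist())


@dataclass
class DecompositionSummary:
    biomarker: str
    sd_bioinformatic: pd.Series
    sd_wetlab: pd.Series
    median_sd_bioinformatic: float
    median_sd_wetlab: float
    outliers_bioinformatic: list
    outliers_wetlab: list
    wilcoxon_p: float  # one-sided: wet-lab SDs exceed bioinformatic SDs

    @property
    def sd_ratio(self) -> float:
        """Median wet-lab SD over median bioinformatic SD."""
        if self.median_sd_bioinformatic == 0:
            return float("inf") if self.median_sd_wetlab > 0 else 1.0
        return self.median_sd_wetlab / self.median_sd_bioinformatic


def compare_sources(
    bioinf: ReplicateMatrix,
    wetlab: ReplicateMatrix,
    alternative: str = "greater",
    normalize: bool = True,
) -> DecompositionSummary:
    """Contrast bioinformatic and wet-lab variability on shared samples.

    Both matrices are reference-normalized (unless ``normalize=False``),
    per-sample SDs are computed on the intersection of retained samples,
    and a one-sided paired Wilcoxon test (default: wet-lab > bioinformatic)
    compares the two SD vectors.  Outliers are flagged per axis with the
    1.5 x IQR boxplot rule.
    """
    if bioinf.biomarker != wetlab.biomarker:
        raise ValidationError("matrices must describe the same biomarker")
    if normalize:
        bioinf = normalize_to_reference(bioinf)
        wetlab = normalize_to_reference(wetlab)
    sd_bio = per_sample_sd(bioinf)
    sd_wet = per_sample_sd(wetlab)
    shared = sd_bio.index.intersection(sd_wet.index)
    if len(shared) == 0:
        raise ValidationError("no shared samples between the two designs")
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared samples")
    sd_bio, sd_wet = sd_bio.loc[shared], sd_wet.loc[shared]
    return DecompositionSummary(
        biomarker=bioinf.biomarker,
        sd_bioinformatic=sd_bio,
        sd_wetlab=sd_wet,
        median_sd_bioinformatic=float(sd_bio.median()),
        median_sd_wetlab=float(sd_wet.median()),
        outliers_bioinformatic=iqr_outliers(sd_bio),
        outliers_wetlab=iqr_outliers(sd_wet),
        wilcoxon_p=paired_wilcoxon(sd_wet.to_numpy(), sd_bio.to_numpy(), alternative=alternative),
    )
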