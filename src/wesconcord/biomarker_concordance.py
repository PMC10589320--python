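"""Pairwise concordance of complex biomarker scores (HRDsum, TMB, MSI).

Scores reported by different institutions for the same cases are compared
pairwise by Pearson correlation and by a zero-intercept linear fit
y = b*x, whose slope measures the systematic deviation between two
institutions as (b - 1) x 100 percent.  Clinical status calls (HRD-positive,
TMB-high, MSI-high) are derived from per-institution cutoffs and summarized
per case.  Paired one-sided Wilcoxon signed-rank tests assess whether one
institution's scores run systematically higher.

Missing scores (e.g. an undeterminable tumor purity) are handled
pairwise-complete for correlations and fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wesconcord.core_io import BiomarkerRecord, ValidationError

BIOMARKERS = ("hrd_sum", "tmb", "msi", "purity", "ploidy")


@dataclass
class ScoreMatrix:
    """Case x institution matrix of one biomarker, with missing support."""

    biomarker: str
    data: pd.DataFrame  # index: case_id, columns: institution_id, NaN = missing

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError("a score matrix needs at least 2 institutions")

    @classmethod
    def from_records(
        cls, records: Iterable[BiomarkerRecord], biomarker: str
    ) -> "ScoreMatrix":
        if biomarker not in BIOMARKERS:
            raise ValidationError(f"unknown biomarker {biomarker!r}")
        rows = [
            (r.case_id, r.institution_id, getattr(r, biomarker)) for r in records
        ]
        frame = pd.DataFrame(rows, columns=["case_id", "institution_id", "value"])
        matrix = frame.pivot(index="case_id", columns="institution_id", values="value")
        return cls(biomarker=biomarker, data=matrix.sort_index())

    @property
    def institutions(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def pair(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete observations for an institution pair (missing dropped)."""
        sub = self.data[[a, b]].dropna()
        return sub[a].to_numpy(float), sub[b].to_numpy(float)


@dataclass(frozen=True)
class PairwiseBiomarkerStats:
    institution_a: str
    institution_b: str
    n_complete: int
    pearson_r: float | None  # None when undefined (zero variance)
    slope: float  # zero-intercept fit of b on a
    deviation_pct: float
    wilcoxon_p: float


@dataclass
class CutoffConfig:
    """Clinical positivity cutoffs: HRDsum 42, TMB 10 mut/MB, MSI 10 percent.

    MSI cutoffs may differ per institution (a pipeline using a different
    MSI tool may call high at e.g. 40 percent); ``msi_overrides`` maps
    institution ids to their cutoff.
    """

    hrd_cutoff: float = 42.0
    tmb_cutoff: float = 10.0
    msi_cutoff: float = 10.0
    msi_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [self.hrd_cutoff, self.tmb_cutoff, self.msi_cutoff, *self.msi_overrides.values()]
        if any(v <= 0 for v in values):
            raise ValidationError("cutoffs must be positive")

    def cutoff_for(self, biomarker: str, institution_id: str) -> float:
        if biomarker == "hrd_sum":
            return self.hrd_cutoff
        if biomarker == "tmb":
            return self.tmb_cutoff
        if biomarker == "msi":
            return self.msi_overrides.get(institution_id, self.msi_cutoff)
        raise ValidationError(f"no cutoff defined for biomarker {biomarker!r}")


# --------------------------------------------------------------------------
# Correlation and systematic deviation
# --------------------------------------------------------------------------

def pearson_pairwise(matrix: ScoreMatrix, min_n: int = 3) -> pd.DataFrame:
    """Pairwise Pearson r over complete observations.

    Pairs with fewer than ``min_n`` complete cases or zero variance in
    either vector are reported as NaN (undefined), never propagated from a
    degenerate division.
    """
    insts = matrix.institutions
    out = pd.DataFrame(np.nan, index=list(insts), columns=list(insts))
    for a in insts:
        out.loc[a, a] = 1.0
        for b in insts:
            if b <= a:
                continue
            x, y = matrix.pair(a, b)
            if len(x) < min_n or np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(stats.pearsonr(x, y).statistic)
            out.loc[a, b] = out.loc[b, a] = r
    return out


def zero_intercept_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Least-squares slope of the through-origin model y = b*x: sum(xy)/sum(x^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("x and y must have equal length >= 2")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValidationError("all-zero x: zero-intercept slope undefined")
    return float(np.dot(x, y) / sxx)


def systematic_deviation(x: Sequence[float], y: Sequence[float]) -> float:
    """Systematic deviation of y relative to x in percent: (slope - 1) x 100."""
    return (zero_intercept_slope(x, y) - 1.0) * 100.0


def pairwise_stats(
    matrix: ScoreMatrix,
    alternative: str = "two-sided",
    min_n: int = 3,
) -> list[PairwiseBiomarkerStats]:
    """Full pairwise panel: r, zero-intercept slope, deviation, Wilcoxon p.

    ``alternative`` fixes the Wilcoxon direction (testing institution b's
    scores against institution a's); it must be chosen a priori.
    """
    out = []
    for i, a in enumerate(matrix.institutions):
        for b in matrix.institutions[i + 1:]:
            x, y = matrix.pair(a, b)
            if len(x) < min_n:
                continue
            r = None
            if np.std(x) > 0 and np.std(y) > 0:
                r = float(stats.pearsonr(x, y).statistic)
            slope = zero_intercept_slope(x, y)
            out.append(PairwiseBiomarkerStats(
                institution_a=a, institution_b=b, n_complete=len(x),
                pearson_r=r, slope=slope, deviation_pct=(slope - 1.0) * 100.0,
                wilcoxon_p=paired_wilcoxon(y, x, alternative=alternative),
            ))
    return out


def deviation_matrix(matrix: ScoreMatrix, min_n: int = 3) -> pd.DataFrame:
    """Systematic deviation (%) of column institution relative to row institution."""
    insts = matrix.institutions
    out = pd.DataFrame(np.nan, index=list(insts), columns=list(insts))
    for a in insts:
        out.loc[a, a] = 0.0
        for b in insts:
            if b == a:
                continue
            x, y = matrix.pair(a, b)
            if len(x) < min_n:
                continue
            try:
                out.loc[a, b] = systematic_deviation(x, y)
            except ValidationError:
                pass
    return out


# --------------------------------------------------------------------------
# Cutoff status classification
# --------------------------------------------------------------------------

def classify_status(
    matrix: ScoreMatrix, cutoffs: CutoffConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positive/negative status per (case, institution) plus per-case agreement.

    A score is positive iff it is >= the institution's cutoff (boundary
    counts positive).  Per case the agreement category is ``all_positive``,
    ``all_negative`` or ``discordant``; cases with any missing score are
    summarized listwise (category NA) while the status matrix still shows
    the available calls.  Discordant institutions are the minority side.
    """
    status = pd.DataFrame("", index=matrix.data.index, columns=matrix.data.columns, dtype=object)
    for inst in matrix.institutions:
        cutoff = cutoffs.cutoff_for(matrix.biomarker, inst)
        col = matrix.data[inst]
        status[inst] = np.where(col.isna(), None, np.where(col >= cutoff, "positive", "negative"))

    rows = []
    for case in matrix.data.index:
        calls = [status.loc[case, inst] for inst in matrix.institutions]
        if any(c is None for c in calls):
            rows.append({"case_id": case, "category": None, "discordant_institutions": ""})
            continue
        positives = [i for i, c in zip(matrix.institutions, calls) if c == "positive"]
        negatives = [i for i, c in zip(matrix.institutions, calls) if c == "negative"]
        if not negatives:
            category, minority = "all_positive", []
        elif not positives:
            category, minority = "all_negative", []
        else:
            category = "discordant"
            minority = positives if len(positives) <= len(negatives) else negatives
        rows.append({
            "case_id": case, "category": category,
            "discordant_institutions": ";".join(sorted(minority)),
        })
    return status, pd.DataFrame(rows).set_index("case_id")


# --------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def paired_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    exact_threshold: int = 25,
) -> float:
    """One-sided (by default) paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; the null distribution is exact for up to
    ``exact_threshold`` non-zero differences and a normal approximation with
    continuity correction above.  All-zero differences give p = 1 with a
    warning (no evidence of any shift).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if diffs.size <= exact_threshold else "approx"
    try:
        res = stats.wilcoxon(
            diffs, alternative=alternative, method=method, correction=(method == "approx")
        )
    except ValueError:
        # exact method can reject tied ranks; fall back to the approximation
        res = stats.wilcoxon(diffs, alternative=alternative, method="approx", correction=True)
    return float(res.pvalue)


# --------------------------------------------------------------------------
# Convenience: full panel over all biomarkers
# --------------------------------------------------------------------------

def biomarker_panel(
    records: Iterable[BiomarkerRecord],
    cutoffs: CutoffConfig | None = None,
    alternative: str = "two-sided",
) -> dict[str, dict]:
    """Run correlations, deviations and (where defined) status per biomarker."""
    records = list(records)
    cutoffs = cutoffs or CutoffConfig()
    out: dict[str, dict] = {}
    for biomarker in BIOMARKERS:
        matrix = ScoreMatrix.from_records(records, biomarker)
        if matrix.data.notna().sum().sum() == 0:
            continue
        entry: dict = {
            "pearson": pearson_pairwise(matrix),
            "deviation_pct": deviation_matrix(matrix),
            "pairwise": pairwise_stats(matrix, alternative=alternative),
        }
        if biomarker in ("hrd_sum", "tmb", "msi"):
            entry["status"], entry["agreement"] = classify_status(matrix, cutoffs)
        out[biomarker] = entry
    return out
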