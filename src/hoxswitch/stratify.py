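"""HOXA9-bimodality patient stratification.

The pipeline mirrors a standard expression-cohort analysis of a bulk
RNA-seq cohort on the log2(TPM+1) scale:

1. drop lowly expressed genes (a gene is dropped when more than a fixed
   number — or fraction — of samples have TPM < 1);
2. test the marker gene (HOXA9) for bimodality with the excess-mass /
   critical-bandwidth test;
3. split samples into a low cohort (expression in (0, 1]), a high cohort
   ([4, 5.5]) and an excluded remainder; samples with exactly zero
   expression are always excluded — a null measurement is not evidence of
   a low-but-active promoter;
4. compare cohort survival (Kaplan-Meier curves, log-rank test,
   proportional-hazards hazard ratio of low vs high);
5. rank genes by the absolute difference of cohort mean expression (or
   fold change of means) and keep the top 30.

Expression matrices are pandas DataFrames (genes x samples); clinical
tables are DataFrames indexed by sample with columns time_days / event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .bimodality import multimodality_test
from .survival import HazardRatio, hazard_ratio, km_estimator, logrank_test

LOW_LABEL = "low"
HIGH_LABEL = "high"
EXCLUDED_LABEL = "excluded"

#: Default cohort intervals on the log2(TPM+1) scale: low (0, 1], high [4, 5.5].
DEFAULT_LOW_INTERVAL = (0.0, 1.0)
DEFAULT_HIGH_INTERVAL = (4.0, 5.5)


def low_expression_filter(
    matrix: pd.DataFrame,
    tpm_threshold: float = 1.0,
    low_fraction: Optional[float] = None,
    max_low_samples: Optional[int] = 50,
) -> pd.DataFrame:
    """Drop genes whose TPM is below `tpm_threshold` in too many samples.

    TPM is recovered from the stored log2(TPM+1) values.  The absolute
    rule keeps a gene unless *more than* `max_low_samples` samples fall
    below the threshold (the historical ">50 of 173" rule); passing
    `low_fraction` switches to a fractional cutoff, which scales to any
    cohort size.
    """
    if tpm_threshold <= 0:
        raise ValueError("tpm_threshold must be positive")
    tpm = np.power(2.0, matrix.to_numpy()) - 1.0
    n_low = (tpm < tpm_threshold).sum(axis=1)
    if low_fraction is not None:
        if not 0 < low_fraction <= 1:
            raise ValueError("low_fraction must be in (0, 1]")
        keep = n_low <= low_fraction * matrix.shape[1]
    else:
        keep = n_low <= int(max_low_samples)
    out = matrix.loc[keep]
    if out.empty:
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return out


@dataclass(frozen=True)
class CohortAssignment:
    """Per-sample cohort labels plus the thresholds that produced them."""

    labels: pd.Series  # sample -> low / high / excluded
    gene: str
    low_interval: Tuple[float, float]
    high_interval: Tuple[float, float]
    n_zero: int  # samples excluded for exactly-zero expression

    @property
    def low_samples(self) -> pd.Index:
        return self.labels.index[self.labels == LOW_LABEL]

    @property
    def high_samples(self) -> pd.Index:
        return self.labels.index[self.labels == HIGH_LABEL]

    @property
    def n_low(self) -> int:
        return int((self.labels == LOW_LABEL).sum())

    @property
    def n_high(self) -> int:
        return int((self.labels == HIGH_LABEL).sum())

    @property
    def n_low_raw(self) -> int:
        """Low-interval count before zero-exclusion (both readings of the
        low-peak size are reported: raw interval occupancy and the cohort
        actually analysed)."""
        return self.n_low + self.n_zero


def split_cohorts(
    matrix: pd.DataFrame,
    gene: str = "HOXA9",
    low_interval: Tuple[float, float] = DEFAULT_LOW_INTERVAL,
    high_interval: Tuple[float, float] = DEFAULT_HIGH_INTERVAL,
) -> CohortAssignment:
    """Assign samples to expression cohorts of `gene`.

    Zero-expression samples are excluded; values in (low_min, low_max] go
    to the low cohort, values in [high_min, high_max] to the high cohort,
    everything else is excluded.  The intervals must be disjoint.
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not present in expression matrix")
    if low_interval[1] > high_interval[0]:
        raise ValueError("low and high intervals must be disjoint")
    x = matrix.loc[gene]
    labels = pd.Series(EXCLUDED_LABEL, index=matrix.columns, name="cohort", dtype=object)
    labels[(x > low_interval[0]) & (x <= low_interval[1])] = LOW_LABEL
    labels[(x >= high_interval[0]) & (x <= high_interval[1])] = HIGH_LABEL
    labels[x == 0] = EXCLUDED_LABEL
    n_zero = int(((x == 0) & (low_interval[0] <= 0)).sum())
    return CohortAssignment(
        labels=labels,
        gene=gene,
        low_interval=tuple(low_interval),
        high_interval=tuple(high_interval),
        n_zero=n_zero,
    )


def rank_differential_genes(
    matrix: pd.DataFrame,
    cohorts: CohortAssignment,
    method: str = "abs_mean_diff",
    top_n: int = 30,
) -> pd.DataFrame:
    """Genes most differentially expressed between the two cohorts.

    abs_mean_diff scores |mean(low) - mean(high)|; fold_change scores the
    ratio of cohort means (pseudocount 1 keeps zero means finite).  Sorted
    descending, ties broken by gene id for determinism.
    """
    low = cohorts.low_samples
    high = cohorts.high_samples
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both cohorts must be non-empty to rank genes")
    mean_low = matrix[low].mean(axis=1)
    mean_high = matrix[high].mean(axis=1)
    if method == "abs_mean_diff":
        score = (mean_low - mean_high).abs()
    elif method == "fold_change":
        score = (mean_high + 1.0) / (mean_low + 1.0)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    df = pd.DataFrame(
        {"score": score, "mean_low": mean_low, "mean_high": mean_high}
    ).rename_axis("gene")
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df.head(top_n)


@dataclass(frozen=True)
class StratificationReport:
    """End-to-end result of the bimodality stratification pipeline."""

    cohorts: CohortAssignment
    bimodality_statistic: float
    bimodality_p: float
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    logrank_chi2: float
    logrank_p: float
    hazard: HazardRatio  # low relative to high; < 1 means low expression protects
    ranked_genes: pd.DataFrame
    seed: int

    def summary(self) -> Dict[str, float]:
        return {
            "n_low": self.cohorts.n_low,
            "n_high": self.cohorts.n_high,
            "n_low_raw": self.cohorts.n_low_raw,
            "n_zero_excluded": self.cohorts.n_zero,
            "bimodality_statistic": self.bimodality_statistic,
            "bimodality_p": self.bimodality_p,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hazard_ratio_low_vs_high": self.hazard.hr,
            "hazard_ratio_ci_low": self.hazard.ci_low,
            "hazard_ratio_ci_high": self.hazard.ci_high,
            "seed": self.seed,
        }


def run_stratification(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    gene: str = "HOXA9",
    low_interval: Tuple[float, float] = DEFAULT_LOW_INTERVAL,
    high_interval: Tuple[float, float] = DEFAULT_HIGH_INTERVAL,
    n_boot: int = 500,
    seed: int = 0,
    top_n: int = 30,
    filter_low_expression: bool = True,
) -> StratificationReport:
    """Run the full marker-gene stratification pipeline.

    The marker gene itself is always retained even if the low-expression
    filter would drop it (its low cohort is low by definition).
    """
    work = matrix
    if filter_low_expression:
        filtered = low_expression_filter(matrix)
        if gene not in filtered.index and gene in matrix.index:
            filtered = pd.concat([filtered, matrix.loc[[gene]]])
        work = filtered
    if gene not in work.index:
        raise KeyError(f"gene {gene!r} not present in expression matrix")
    nonzero = work.loc[gene][work.loc[gene] > 0]
    stat, p = multimodality_test(nonzero.to_numpy(), n_boot=n_boot, seed=seed)
    cohorts = split_cohorts(work, gene, low_interval, high_interval)
    missing = [s for s in cohorts.labels.index if s not in clinical.index]
    if missing:
        raise KeyError(f"samples without clinical data: {missing[:5]}")
    lo = clinical.loc[cohorts.low_samples]
    hi = clinical.loc[cohorts.high_samples]
    chi2, logrank_p = logrank_test(
        lo["time_days"], lo["event"], hi["time_days"], hi["event"]
    )
    hr = hazard_ratio(lo["time_days"], lo["event"], hi["time_days"], hi["event"])
    return StratificationReport(
        cohorts=cohorts,
        bimodality_statistic=stat,
        bimodality_p=p,
        km_low=km_estimator(lo["time_days"], lo["event"]),
        km_high=km_estimator(hi["time_days"], hi["event"]),
        logrank_chi2=chi2,
        logrank_p=logrank_p,
        hazard=hr,
        ranked_genes=rank_differential_genes(work, cohorts, top_n=top_n),
        seed=seed,
    )
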