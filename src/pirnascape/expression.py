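"""TPM normalisation and differential expression of piRNA count matrices.

Expression is quantified as TPM in the small-RNA sense: reads per million
mapped reads, with no length normalisation (a piRNA is sequenced end to end,
so read counts are already proportional to molecule counts).  Differential
expression between the breeding-season (BSB) and non-breeding-season (NBS)
groups is called with a Welch two-sample t-test on log2(TPM + pseudo), and a
piRNA is labelled up/down when |log2FC| exceeds the fold-change threshold and
the p-value is below the significance threshold.  Positive log2FC means
higher expression in BSB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Floor applied to degenerate p-values (zero variance, unequal means).
P_FLOOR = 1e-12


@dataclass
class DEThresholds:
    """|log2FC| and p-value cutoffs for calling differential expression."""

    min_abs_log2fc: float = 1.0
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")


@dataclass
class ExpressionMatrix:
    """piRNAs x samples expression values with per-sample condition labels.

    ``values``: DataFrame indexed by piRNA id with sample columns.
    ``conditions``: Series mapping sample id -> condition label.
    ``value_kind``: "count" for raw integer counts, "tpm" after normalisation.
    """

    values: pd.DataFrame
    conditions: pd.Series
    value_kind: Literal["count", "tpm"] = "count"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class DEResult:
    pirna_id: str
    log2fc: float
    p: float
    status: Literal["up", "down", "ns"]


class DECounts(NamedTuple):
    n_total_de: int
    n_up: int
    n_down: int


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample reads-per-million normalisation (columns sum to 1e6)."""
    if counts.value_kind != "count":
        raise ValueError("compute_tpm expects a count matrix")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    tpm = counts.values / totals * 1e6
    return ExpressionMatrix(tpm, counts.conditions, "tpm")


def de_test(
    tpm: ExpressionMatrix,
    thresholds: DEThresholds | None = None,
    pseudo: float = 1.0,
    numerator: str = "BSB",
    denominator: str = "NBS",
    fdr: bool = False,
) -> list[DEResult]:
    """Welch t-test on log2(TPM + pseudo) with threshold-based status calls.

    ``log2fc = log2((mean TPM in numerator + pseudo) / (mean TPM in
    denominator + pseudo))``.  When both groups have zero variance the test
    is degenerate: p = 1 if the group means are equal, otherwise the p-value
    is floored at ``P_FLOOR``.  With ``fdr=True`` p-values are
    Benjamini-Hochberg adjusted before thresholding.
    """
    if thresholds is None:
        thresholds = DEThresholds()
    if tpm.value_kind != "tpm":
        raise ValueError("de_test expects a TPM matrix; run compute_tpm first")
    groups = {}
    for condition in (numerator, denominator):
        samples = tpm.samples_of(condition)
        if len(samples) < 2:
            raise ValueError(
                f"condition {condition!r} has {len(samples)} sample(s); need >= 2"
            )
        groups[condition] = tpm.values[samples].to_numpy(dtype=float)

    a, b = groups[numerator], groups[denominator]
    log_a, log_b = np.log2(a + pseudo), np.log2(b + pseudo)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))

    # degenerate rows: both groups constant
    var_zero = (log_a.var(axis=1) == 0) & (log_b.var(axis=1) == 0)
    equal_means = log_a.mean(axis=1) == log_b.mean(axis=1)
    p = np.where(var_zero & equal_means, 1.0, p)
    p = np.where(var_zero & ~equal_means, P_FLOOR, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)

    if fdr:
        p = stats.false_discovery_control(p, method="bh")

    results = []
    for pid, fc, pval in zip(tpm.values.index, log2fc, p):
        if pval < thresholds.max_p and fc > thresholds.min_abs_log2fc:
            status = "up"
        elif pval < thresholds.max_p and fc < -thresholds.min_abs_log2fc:
            status = "down"
        else:
            status = "ns"
        results.append(DEResult(str(pid), float(fc), float(pval), status))
    return results


def de_counts(results: Sequence[DEResult]) -> DECounts:
    """(total DE, up, down) over a list of DE results."""
    n_up = sum(1 for r in results if r.status == "up")
    n_down = sum(1 for r in results if r.status == "down")
    return DECounts(n_up + n_down, n_up, n_down)


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Tabular view of DE results (columns id, log2fc, p, status)."""
    return pd.DataFrame(
        {
            "id": [r.pirna_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "status": [r.status for r in results],
        }
    ).set_index("id")
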