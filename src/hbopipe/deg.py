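"""Expression filtering, threshold-based DEG calling, and z-score matrices.

The differential-expression convention here is the threshold conjunction
used in desktop transcriptomics workflows rather than a count-model fit:
a gene is differentially expressed between two groups when all three hold —

* absolute difference of linear-TPM group means > 4,
* fold change (larger mean over smaller mean) > 2,
* two-tailed unpaired t-test on log2(TPM + 1) gives p < 0.05.

No multiple-testing correction is applied at this stage; the conjunction
with the effect-size thresholds is the false-positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st


@dataclass
class ExpressionMatrix:
    """TPM expression values (genes x samples) with a sample -> group map."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("TPM matrix contains negative values")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        cols = [s for s, g in self.groups.items() if g == group]
        if not cols:
            raise KeyError(f"group {group!r} not present in group map")
        return cols


def filter_low_expression(
    m: ExpressionMatrix, min_valid: int = 7, min_value: float = 0.1
) -> ExpressionMatrix:
    """Drop low-expression genes.

    A gene is retained iff at least ``min_valid`` of its samples have
    TPM > ``min_value`` (default: 7 valid values out of 20 samples above
    0.1).  Idempotent by construction.
    """
    if min_valid > m.n_samples:
        raise ValueError(f"min_valid={min_valid} exceeds sample count {m.n_samples}")
    keep = (m.values > min_value).sum(axis=1) >= min_valid
    return ExpressionMatrix(values=m.values.loc[keep].copy(), groups=m.groups)


def call_degs(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    min_diff: float = 4.0,
    min_fc: float = 2.0,
    alpha: float = 0.05,
    log_offset: float = 1.0,
    mean_floor: float = 0.01,
) -> pd.DataFrame:
    """Call DEGs for the contrast ``group_a`` vs ``group_b``.

    Returns a per-gene table with columns ``mean_a``, ``mean_b`` (linear
    TPM), ``diff`` (mean_a - mean_b), ``fc`` (ratio >= 1), ``log2_fc``
    (signed, a over b), ``p`` (two-tailed unpaired t on
    log2(TPM + log_offset)) and ``deg_class`` in {"up", "down", "ns"} —
    up meaning higher in ``group_a``.  All three criteria are strict
    inequalities; group means are floored at ``mean_floor`` TPM before the
    ratio to keep the fold change finite.
    """
    cols_a = m.group_samples(group_a)
    cols_b = m.group_samples(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = m.values[cols_a].to_numpy(float)
    b = m.values[cols_b].to_numpy(float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    diff = mean_a - mean_b
    fa = np.maximum(mean_a, mean_floor)
    fb = np.maximum(mean_b, mean_floor)
    fc = np.maximum(fa, fb) / np.minimum(fa, fb)
    log2_fc = np.log2(fa / fb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = _st.ttest_ind(
            np.log2(a + log_offset), np.log2(b + log_offset), axis=1, equal_var=True
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups

    sig = (np.abs(diff) > min_diff) & (fc > min_fc) & (p < alpha)
    deg_class = np.where(sig & (diff > 0), "up", np.where(sig, "down", "ns"))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": diff,
            "fc": fc,
            "log2_fc": log2_fc,
            "p": p,
            "deg_class": deg_class,
        },
        index=m.values.index,
    )


def deg_lists(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(up, down) gene-id lists from a :func:`call_degs` table."""
    up = table.index[table["deg_class"] == "up"].tolist()
    down = table.index[table["deg_class"] == "down"].tolist()
    return up, down


def zscore_matrix(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Per-gene z-scores across samples for a gene subset (heatmap input).

    Each selected row is centred to mean 0 and scaled to unit sample SD
    (ddof=1, the usual heatmap convention).  A constant gene has no
    z-score; it is reported by name.
    """
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    sub = m.values.loc[genes].astype(float)
    sd = sub.std(axis=1, ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"constant gene(s) cannot be z-scored: {zero}")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
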