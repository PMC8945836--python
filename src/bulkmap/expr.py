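"""Simplified differential expression and qPCR relative quantification.

Counts are normalized by median-of-ratios size factors and tested per gene
with a Welch two-sample test on log2(normalized + 1); significance uses a
Benjamini-Hochberg FDR < 0.05 together with |log2 fold change| >= 1. This
deliberately replaces a negative-binomial DE model with a transparent
stand-in — the thresholding and up/down accounting are the point, not the
dispersion machinery — so DEG counts from real libraries are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegThresholds",
    "DegSummary",
    "size_factors",
    "de_test",
    "bh_fdr",
    "deg_summary",
    "ddct",
]

FDR_MAX = 0.05
LOG2FC_MIN = 1.0


class DegSummary(NamedTuple):
    n_up: int
    n_down: int
    pct_up: float | None
    pct_down: float | None


def _check_matrix(counts: pd.DataFrame) -> None:
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample column).

    Genes with a zero in any sample are excluded from the reference
    geometric mean, as usual for this estimator.
    """
    _check_matrix(counts)
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logx = np.log(x[all_pos])
    log_geomean = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_test(counts: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene Welch test of MUT vs WT on log2(normalized count + 1).

    ``groups`` maps each sample column to 'WT' or 'MUT'; each group needs at
    least two replicates. Genes constant across all samples get p = 1.
    Returns a DataFrame with log2fc, pvalue, fdr, is_deg, direction.
    """
    _check_matrix(counts)
    unknown = set(groups.values()) - {"WT", "MUT"}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    missing = [c for c in counts.columns if c not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    wt = [c for c in counts.columns if groups[c] == "WT"]
    mut = [c for c in counts.columns if groups[c] == "MUT"]
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 replicates per group")

    sf = size_factors(counts)
    norm = counts / sf
    logn = np.log2(norm.to_numpy(dtype=float) + 1.0)
    iw = [counts.columns.get_loc(c) for c in wt]
    im = [counts.columns.get_loc(c) for c in mut]
    a, b = logn[:, im], logn[:, iw]

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    constant = counts.nunique(axis=1).to_numpy() == 1
    pvals[constant | np.isnan(pvals)] = 1.0

    mean_mut = norm[mut].mean(axis=1).to_numpy()
    mean_wt = norm[wt].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_mut + 1.0) - np.log2(mean_wt + 1.0)

    fdr = bh_fdr(pvals)
    is_deg = (fdr < FDR_MAX) & (np.abs(log2fc) >= LOG2FC_MIN)
    direction = np.where(
        ~is_deg, "none", np.where(log2fc > 0, "up", "down")
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=counts.index,
    )


def deg_summary(results: pd.DataFrame) -> DegSummary:
    """Up/down DEG counts and their percentages of the DEG total.

    Percentages are rounded to 2 decimals; with zero DEGs they are None
    rather than 0/0.
    """
    deg = results[results["is_deg"]]
    n_up = int((deg["direction"] == "up").sum())
    n_down = int((deg["direction"] == "down").sum())
    total = n_up + n_down
    if total == 0:
        return DegSummary(0, 0, None, None)
    return DegSummary(
        n_up,
        n_down,
        round(100.0 * n_up / total, 2),
        round(100.0 * n_down / total, 2),
    )


def ddct(test: pd.DataFrame, calibrator: pd.DataFrame) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    Each frame holds replicate rows with ``ct_target`` and ``ct_reference``
    columns; ΔCt is the difference of replicate-mean Cts per condition and
    the result is 2^-(ΔCt_test - ΔCt_calibrator).
    """
    for name, frame in (("test", test), ("calibrator", calibrator)):
        for col in ("ct_target", "ct_reference"):
            if col not in frame.columns or frame[col].dropna().empty:
                raise ValueError(f"{name} table lacks {col} values")
    dct_test = test["ct_target"].mean() - test["ct_reference"].mean()
    dct_cal = calibrator["ct_target"].mean() - calibrator["ct_reference"].mean()
    return float(2.0 ** -(dct_test - dct_cal))
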