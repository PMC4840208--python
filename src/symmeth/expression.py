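"""Two-condition differential expression from a replicate intensity matrix.

The protocol mirrors standard two-colour microarray practice: per-array
median-centering, quantile normalisation across arrays, spot-to-gene
averaging, then a per-gene two-sample t statistic on log2 intensities with
Benjamini-Hochberg adjustment.  By default each gene's variance is shrunk
toward the genome-wide mean residual variance with a fixed prior weight
(d0 = 4 pseudo-degrees of freedom), a lightweight stand-in for fully
estimated empirical-Bayes moderation that stabilises inference at 2-3 arrays
per condition; set d0 = 0 for the plain pooled-variance t.

Sign convention: log_fc = mean(A) - mean(B), positive when expression is
higher in condition A (the free-living state in the symbiosis pipeline).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Significance convention for the adjusted p-value.
DE_ALPHA = 0.001

#: Default prior weight for variance shrinkage (pseudo degrees of freedom).
DEFAULT_D0 = 4.0


@dataclass(frozen=True)
class ExpressionMatrix:
    """log2 intensities, rows indexed by (gene_id, spot_id) or gene_id,
    one column per array, each array assigned to exactly one condition."""

    values: pd.DataFrame
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [a for a in self.values.columns if a not in self.conditions]
        if missing:
            raise ValueError(f"arrays without condition assignment: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def arrays_for(self, condition: str) -> list[str]:
        return [a for a in self.values.columns if self.conditions[a] == condition]


def read_expression(
    tsv_path: str | Path, conditions: Mapping[str, str]
) -> ExpressionMatrix:
    """TSV with gene_id, spot_id, then one column per array."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str, "spot_id": str})
    for col in ("gene_id", "spot_id"):
        if col not in df.columns:
            raise ValueError(f"{tsv_path}: missing column {col!r}")
    df = df.set_index(["gene_id", "spot_id"])
    return ExpressionMatrix(values=df.astype(float), conditions=dict(conditions))


def write_expression(matrix: ExpressionMatrix, tsv_path: str | Path) -> None:
    matrix.values.reset_index().to_csv(tsv_path, sep="\t", index=False)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Within-array normalisation: subtract each array's median, then restore
    the grand median so the intensity scale is preserved."""
    vals = matrix.values
    centered = vals - vals.median(axis=0) + float(np.median(vals.values))
    return ExpressionMatrix(values=centered, conditions=matrix.conditions)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standard quantile normalisation: every array's value distribution is
    replaced by the mean of the per-rank sorted columns; ties share the mean
    of their rank range (rank-average interpolation)."""
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 arrays")
    n = len(vals)
    sorted_means = np.sort(vals.values, axis=0).mean(axis=1)
    ranks = vals.rank(method="average").values
    normed = np.interp(ranks, np.arange(1, n + 1), sorted_means)
    out = pd.DataFrame(normed, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(values=out, conditions=matrix.conditions)


def collapse_spots(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate spots to one row per gene."""
    vals = matrix.values
    if "gene_id" in (vals.index.names or []):
        collapsed = vals.groupby(level="gene_id", sort=True).mean()
    else:
        collapsed = vals.groupby(vals.index, sort=True).mean()
        collapsed.index.name = "gene_id"
    return ExpressionMatrix(values=collapsed, conditions=matrix.conditions)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    alpha: float = DE_ALPHA,
    d0: float = DEFAULT_D0,
) -> pd.DataFrame:
    """Per-gene log2 fold change, (optionally moderated) t test, BH adjustment.

    Returns a DataFrame with columns gene_id, log_fc, p_value, adj_p,
    significant.  Requires a collapsed (one row per gene) matrix and at least
    two arrays per condition.
    """
    cols_a = matrix.arrays_for(condition_a)
    cols_b = matrix.arrays_for(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each condition needs at least 2 arrays")
    vals = matrix.values
    if vals.index.nlevels != 1:
        raise ValueError("collapse spots before testing (one row per gene)")
    a = vals[cols_a].values
    b = vals[cols_b].values
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log_fc = mean_a - mean_b
    df_resid = na + nb - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if d0 > 0:
        s2_prior = float(s2.mean())
        s2_used = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
        df_used = d0 + df_resid
    else:
        s2_used, df_used = s2, df_resid
    se = np.sqrt(s2_used * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, np.where(log_fc == 0, 0.0, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df_used)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": vals.index.astype(str),
            "log_fc": log_fc,
            "p_value": p,
            "adj_p": adj,
            "significant": adj < alpha,
        }
    ).reset_index(drop=True)
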