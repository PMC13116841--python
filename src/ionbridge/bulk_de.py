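"""Bulk RNA-seq differential expression.

Normalization to log2(CPM + 1), a deterministic location/scale batch
adjustment that preserves the condition effect, and Welch's t-test with
Benjamini-Hochberg correction and the dual DEG thresholds
(FDR < 0.05 and |log2FC| > log2(1.5), both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class BulkCohort:
    """Gene x sample count matrix with per-sample condition and batch labels."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    condition: pd.Series  # per sample: "tumor" / "normal"
    batch: pd.Series  # per sample batch label

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        for name, labels in (("condition", self.condition), ("batch", self.batch)):
            missing = self.counts.columns.difference(labels.index)
            if len(missing):
                raise ValueError(f"samples without {name} label: {list(missing[:5])}")
        self.condition = self.condition.loc[self.counts.columns]
        self.batch = self.batch.loc[self.counts.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def drop_unmapped(self, mapping: pd.Series | None) -> "BulkCohort":
        """Drop genes absent from a symbol mapping table (identity if None)."""
        if mapping is None:
            return self
        keep = self.counts.index.intersection(mapping.index)
        return BulkCohort(self.counts.loc[keep], self.condition, self.batch)


@dataclass
class DEResult:
    """Per-gene Welch DE statistics with the dual-threshold DEG call."""

    table: pd.DataFrame  # columns: log2FC, p, padj, is_DEG, direction
    fdr: float = 0.05
    fc: float = 1.5

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_DEG"]]

    def log2fc(self, gene: str) -> float:
        return float(self.table.loc[gene, "log2FC"])


def cpm_log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1): scale each sample column to one million, then log."""
    libsize = counts.sum(axis=0)
    zero = libsize.index[libsize <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero)}")
    cpm = counts.div(libsize, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def batch_correct(
    x: pd.DataFrame,
    batch: pd.Series,
    condition: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene location/scale batch adjustment preserving the condition effect.

    The condition effect is removed via a two-group mean model, batch-specific
    residual means and standard deviations are equalized to the pooled values,
    and the condition means are added back. A single batch is a no-op; a
    design fully confounded with condition is left uncorrected with a warning.
    """
    batch = batch.loc[x.columns]
    levels = batch.unique()
    if len(levels) < 2:
        return x.copy()
    small = [b for b in levels if (batch == b).sum() < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    if condition is not None:
        condition = condition.loc[x.columns]
        per_batch_conditions = condition.groupby(batch, observed=True).nunique()
        if (per_batch_conditions == 1).all() and condition.nunique() > 1:
            warnings.warn(
                "batch is fully confounded with condition; correction skipped",
                stacklevel=2,
            )
            return x.copy()
        group_means = x.T.groupby(condition, observed=True).mean().T
        fitted = group_means[condition.values].set_axis(x.columns, axis=1)
    else:
        fitted = pd.DataFrame(
            np.tile(x.mean(axis=1).values[:, None], (1, x.shape[1])),
            index=x.index,
            columns=x.columns,
        )

    resid = x - fitted
    pooled_sd = resid.std(axis=1, ddof=1)
    corrected = resid.copy()
    for b in levels:
        cols = batch.index[batch == b]
        sub = resid[cols]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        scale = pooled_sd / sd.replace(0.0, np.nan)
        scale = scale.fillna(1.0).clip(upper=1e6)
        corrected[cols] = sub.sub(mu, axis=0).mul(scale, axis=0)
    out = corrected + fitted
    return out.astype(float)


def welch_de(
    x: pd.DataFrame,
    condition: pd.Series,
    fdr: float = 0.05,
    fc: float = 1.5,
) -> DEResult:
    """Two-sided Welch's t-test per gene on the log scale, BH-adjusted.

    log2FC is the tumor-minus-normal difference of group means. Genes with
    zero variance in both groups and equal means get p = 1. A DEG satisfies
    padj < fdr AND |log2FC| > log2(fc), both strict.
    """
    condition = condition.loc[x.columns]
    t_cols = condition.index[condition == TUMOR]
    n_cols = condition.index[condition == NORMAL]
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >=2 samples per condition for Welch's t-test")

    a = x[t_cols].to_numpy(float)
    b = x[n_cols].to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & np.isclose(lfc, 0.0), 1.0, p)
    lfc = np.where(degenerate & np.isclose(lfc, 0.0), 0.0, lfc)
    if not np.isfinite(p).all():
        # zero variance in both groups but unequal means: call with p -> 0
        p = np.where(np.isfinite(p), p, 0.0)

    padj = bh_adjust(p)
    cut = np.log2(fc)
    is_deg = (padj < fdr) & (np.abs(lfc) > cut)
    direction = np.where(~is_deg, "none", np.where(lfc > 0, "up", "down"))
    table = pd.DataFrame(
        {"log2FC": lfc, "p": p, "padj": padj, "is_DEG": is_deg, "direction": direction},
        index=x.index,
    )
    return DEResult(table=table, fdr=fdr, fc=fc)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]
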