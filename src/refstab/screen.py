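"""Genome-wide CV screening of candidate reference genes from FPKM.

A reference-gene candidate must be constitutively expressed (FPKM
strictly greater than a floor, default 1, in every sample) and vary
little across conditions. Variation is summarised per gene by the
coefficient of variation CV% = 100 * SD / mean, with the sample SD
(n - 1 denominator). Candidates are shortlisted by a strict CV%
threshold (20% for functional follow-up, 16% for the RT-qPCR panel in
the motivating study design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, RefstabError

STATS_COLUMNS = ["gene_id", "mean_fpkm", "sd_fpkm", "cv_pct"]


@dataclass
class FilterResult:
    """Constitutive-filter output: retained matrix plus bookkeeping counts."""

    matrix: ExpressionMatrix
    n_input: int
    n_retained: int
    n_dropped: int
    dropped_gene_ids: list[str]


def filter_constitutive(expr: ExpressionMatrix, min_fpkm: float = 1.0) -> FilterResult:
    """Keep genes with FPKM strictly greater than ``min_fpkm`` in every sample."""
    if min_fpkm < 0:
        raise RefstabError("min_fpkm must be >= 0")
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise RefstabError("expression matrix is empty")
    keep_mask = np.all(expr.values > min_fpkm, axis=1)
    kept = [g for g, k in zip(expr.gene_ids, keep_mask) if k]
    dropped = [g for g, k in zip(expr.gene_ids, keep_mask) if not k]
    return FilterResult(
        matrix=expr.subset_genes(kept),
        n_input=len(expr.gene_ids),
        n_retained=len(kept),
        n_dropped=len(dropped),
        dropped_gene_ids=dropped,
    )


def gene_stats(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean, sample SD (n-1) and CV% of FPKM.

    Returns a DataFrame with columns ``gene_id, mean_fpkm, sd_fpkm,
    cv_pct`` in the matrix's gene order. CV is undefined for a zero-mean
    gene (domain error).
    """
    if expr.shape[1] < 2:
        raise RefstabError("gene_stats requires >= 2 samples per gene")
    mean = expr.values.mean(axis=1)
    if np.any(mean == 0):
        bad = [g for g, m in zip(expr.gene_ids, mean) if m == 0]
        raise RefstabError(f"CV undefined for zero-mean genes: {bad}")
    sd = expr.values.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "mean_fpkm": mean,
            "sd_fpkm": sd,
            "cv_pct": 100.0 * sd / mean,
        }
    )


def cv_stats_from_summary(mean: np.ndarray | pd.Series, sd: np.ndarray | pd.Series) -> np.ndarray:
    """CV% = 100 * SD / mean from already-summarised per-gene mean and SD.

    The same statistic :func:`gene_stats` computes, applied to printed or
    precomputed summary columns (e.g. mean Cq and SD of a qPCR panel).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean == 0):
        raise RefstabError("CV undefined at zero mean")
    return 100.0 * sd / mean


def shortlist(stats: pd.DataFrame, cv_threshold_pct: float) -> pd.DataFrame:
    """Genes with CV% strictly below the threshold, most stable first.

    Sorted ascending by ``cv_pct``; ties broken by ``gene_id`` so
    shortlists are reproducible.
    """
    if stats.empty:
        raise RefstabError("stats table is empty")
    out = stats.loc[stats["cv_pct"] < cv_threshold_pct]
    return out.sort_values(["cv_pct", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def cv_scatter(stats: pd.DataFrame, cv_threshold_pct: float = 20.0) -> pd.DataFrame:
    """Per-gene (log10 mean FPKM, CV%) table with a shortlist flag.

    The flag marks exactly the genes :func:`shortlist` would return at
    the same threshold.
    """
    if np.any(stats["mean_fpkm"].to_numpy() <= 0):
        raise RefstabError("cv_scatter requires positive means")
    return pd.DataFrame(
        {
            "gene_id": stats["gene_id"],
            "log10_mean_fpkm": np.log10(stats["mean_fpkm"].to_numpy()),
            "cv_pct": stats["cv_pct"],
            "shortlisted": stats["cv_pct"].to_numpy() < cv_threshold_pct,
        }
    )
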