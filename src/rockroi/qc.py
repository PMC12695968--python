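"""Per-cell QC, filtering, species assignment and summary statistics.

Covers the descriptive layer of the workflow: mitochondrial-percentage and
library-size filtering, mouse-vs-human style species calls in mixing
experiments, the positive-cell rate on targeted regions, detection
efficiency against an imaging-based absolute transcript count, pseudobulk
Pearson correlations between conditions, and region-level fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quant import CountMatrix, FeatureModel


@dataclass
class FilterSpec:
    """Per-cell and per-gene retention bounds; unset bounds do not filter."""

    min_umis: Optional[float] = None
    max_umis: Optional[float] = None
    min_genes: Optional[int] = None
    max_genes: Optional[int] = None
    min_mito_percent: Optional[float] = None
    max_mito_percent: Optional[float] = None
    min_gene_total: Optional[float] = None

    def __post_init__(self) -> None:
        for lo, hi in ((self.min_umis, self.max_umis),
                       (self.min_genes, self.max_genes),
                       (self.min_mito_percent, self.max_mito_percent)):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError("min bound exceeds max bound")


def per_cell_qc(m: CountMatrix, mito_ids: Sequence[str]) -> pd.DataFrame:
    """Barcode-level QC table: n_umis, n_genes, mito_percent.

    ``mito_percent`` sums over all mitochondrial features present — with two
    species in the matrix this is the sum over both species' mito genes. A
    zero-total cell gets mito_percent 0 and is flagged.
    """
    dense = m.matrix
    totals = np.asarray(dense.sum(axis=1)).ravel()
    n_genes = np.asarray((dense > 0).sum(axis=1)).ravel()
    mito_cols = [i for i, f in enumerate(m.features) if f in set(mito_ids)]
    mito = (np.asarray(dense[:, mito_cols].sum(axis=1)).ravel()
            if mito_cols else np.zeros_like(totals))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(totals > 0, 100.0 * mito / np.maximum(totals, 1e-12),
                       0.0)
    return pd.DataFrame({"barcode": m.barcodes, "n_umis": totals,
                         "n_genes": n_genes, "mito_percent": pct,
                         "zero_total": totals == 0})


def per_cell_qc_and_filter(m: CountMatrix, fm: FeatureModel,
                           spec: FilterSpec
                           ) -> tuple[pd.DataFrame, CountMatrix]:
    """Compute QC, drop cells outside bounds and genes below the total floor."""
    qc = per_cell_qc(m, sorted(fm.mito_ids()))
    keep = np.ones(len(m.barcodes), dtype=bool)

    def bound(col, lo, hi, strict_lo=True, strict_hi=True):
        nonlocal keep
        v = qc[col].values
        if lo is not None:
            keep &= (v > lo) if strict_lo else (v >= lo)
        if hi is not None:
            keep &= (v < hi) if strict_hi else (v <= hi)

    bound("n_umis", spec.min_umis, spec.max_umis)
    bound("n_genes", spec.min_genes, spec.max_genes)
    bound("mito_percent", spec.min_mito_percent, spec.max_mito_percent)
    qc["retained"] = keep
    retained_bcs = [b for b, k in zip(m.barcodes, keep) if k]
    sub = m.subset_barcodes(retained_bcs)
    if spec.min_gene_total is not None:
        gene_totals = np.asarray(sub.matrix.sum(axis=0)).ravel()
        cols = np.flatnonzero(gene_totals >= spec.min_gene_total)
        sub = CountMatrix(sub.matrix[:, cols],
                          sub.barcodes,
                          [sub.features[i] for i in cols],
                          sub.modality, sub.mode)
    return qc, sub


def assign_species(m: CountMatrix,
                   species_map: dict[str, str]) -> pd.Series:
    """Majority-vote species call per cell.

    A cell is species A when strictly more than 50% of its counts map to
    A-features (symmetrically for B); anything else — including an exact
    50/50 split and zero-count cells — is ``unknown`` and flagged for
    removal downstream.
    """
    unmapped = [f for f in m.features if f not in species_map]
    if unmapped:
        raise ValueError(f"features without species mapping: {unmapped[:5]}")
    species = sorted(set(species_map.values()))
    totals = m.total_counts()
    calls = np.full(len(m.barcodes), "unknown", dtype=object)
    for sp in species:
        cols = [i for i, f in enumerate(m.features) if species_map[f] == sp]
        sp_counts = np.asarray(m.matrix[:, cols].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            frac = np.where(totals > 0, sp_counts / np.maximum(totals, 1e-12),
                            0.0)
        calls[frac > 0.5] = sp
    return pd.Series(calls, index=m.barcodes, name="species")


def positive_cell_rate(m: CountMatrix,
                       target_features: Sequence[str]) -> float:
    """Percent of cells with non-zero summed (possibly fractional) target counts.

    The matrix must already be restricted to retained cells; that set is the
    denominator.
    """
    if not m.barcodes:
        raise ValueError("empty cell set")
    cols = [i for i, f in enumerate(m.features) if f in set(target_features)]
    if not cols:
        return 0.0
    sums = np.asarray(m.matrix[:, cols].sum(axis=1)).ravel()
    return 100.0 * float(np.sum(sums > 0)) / len(m.barcodes)


def detection_efficiency(mean_counts_per_cell: float,
                         replicate_means: Sequence[float]) -> float:
    """Sequencing-detected transcripts as a percentage of the imaging truth.

    The denominator is the mean of absolute per-cell transcript counts from
    replicate imaging experiments (e.g. RNAscope spot counts); the result is
    rounded to 2 decimals.
    """
    if not replicate_means:
        raise ValueError("replicate_means must be nonempty")
    if any(r <= 0 for r in replicate_means):
        raise ValueError("replicate means must be positive")
    denom = float(np.mean(replicate_means))
    return round(100.0 * mean_counts_per_cell / denom, 2)


def _log_normalize(m: CountMatrix) -> np.ndarray:
    """log1p of counts scaled by median-normalized library-size factors."""
    totals = m.total_counts().astype(float)
    med = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    factors = np.where(totals > 0, totals / med, 1.0)
    dense = np.asarray(m.matrix.todense(), dtype=float)
    return np.log1p(dense / factors[:, None])


def _log_cpm(agg: np.ndarray, prior_count: float = 1.0) -> np.ndarray:
    lib = agg.sum(axis=0, keepdims=True)
    return np.log2((agg + prior_count) / (lib + 2 * prior_count) * 1e6)


def pseudobulk_correlation(m1: CountMatrix, m2: CountMatrix,
                           grouping1: pd.Series, grouping2: pd.Series,
                           min_mean_logcount: float = 0.1,
                           min_variance: float = 0.5,
                           method: str = "mean_logcount") -> pd.DataFrame:
    """Pairwise Pearson correlation of per-group aggregated gene vectors.

    ``method='mean_logcount'`` aggregates mean log1p-normalized counts per
    gene per group and keeps genes whose mean logcount across all cells
    exceeds ``min_mean_logcount`` with variance above ``min_variance``;
    ``method='logcpm'`` aggregates total counts per group into log-CPM
    (prior count 1) and keeps genes with any count, matching the
    mixing-experiment variant.
    """
    if list(m1.features) != list(m2.features):
        raise ValueError("matrices must share one feature space")

    def aggregate(m: CountMatrix, grouping: pd.Series) -> pd.DataFrame:
        groups = grouping.reindex(m.barcodes)
        if method == "mean_logcount":
            logn = _log_normalize(m)
            df = pd.DataFrame(logn, index=m.barcodes, columns=m.features)
            return df.groupby(groups).mean().T  # genes x groups
        raw = pd.DataFrame(np.asarray(m.matrix.todense()), index=m.barcodes,
                           columns=m.features)
        agg = raw.groupby(groups).sum().T.values.astype(float)
        out = pd.DataFrame(_log_cpm(agg), index=m1.features,
                           columns=raw.groupby(groups).sum().T.columns)
        return out

    a1, a2 = aggregate(m1, grouping1), aggregate(m2, grouping2)
    if method == "mean_logcount":
        logn_all = np.vstack([_log_normalize(m1), _log_normalize(m2)])
        mean_lc = logn_all.mean(axis=0)
        var_lc = logn_all.var(axis=0, ddof=1)
        keep = (mean_lc > min_mean_logcount) & (var_lc > min_variance)
    else:
        totals = (np.asarray(m1.matrix.sum(axis=0)).ravel()
                  + np.asarray(m2.matrix.sum(axis=0)).ravel())
        keep = totals > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes survive the filter")
    a1k, a2k = a1.loc[a1.index[keep]], a2.loc[a2.index[keep]]
    rows = []
    for g1 in a1k.columns:
        for g2 in a2k.columns:
            r = float(np.corrcoef(a1k[g1].values, a2k[g2].values)[0, 1])
            rows.append((g1, g2, r))
    return pd.DataFrame(rows, columns=["group1", "group2", "pearson_r"])


def fold_enrichment(counts_a: float, counts_b: float
                    ) -> tuple[float, Optional[str]]:
    """Region-level count ratio between two conditions.

    Returns (ratio, flag); flag is ``'infinite'`` when the denominator is
    zero with a positive numerator, ``'undefined'`` when both are zero.
    """
    if counts_a < 0 or counts_b < 0:
        raise ValueError("counts must be non-negative")
    if counts_b == 0:
        if counts_a == 0:
            return float("nan"), "undefined"
        return float("inf"), "infinite"
    return counts_a / counts_b, None
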