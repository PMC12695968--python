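"""Empty-droplet detection on the WTA matrix, EmptyDrops-style.

Droplet assays produce many barcodes that captured only ambient RNA. Cells
are called on the untargeted (WTA) matrix in two ways that are OR-combined:

* knee retention — barcodes above the knee of the log-log barcode-rank curve
  are kept unconditionally;
* a Monte-Carlo significance test — each barcode's counts are compared
  against a Dirichlet-multinomial model of the pooled ambient profile
  estimated from low-count barcodes, and deviating barcodes are kept at a
  Benjamini-Hochberg FDR threshold.

The targeted (TSO) matrix is never tested itself: targeted transcriptional
complexity carries no usable signal for emptiness, so the WTA-retained cell
set is borrowed for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .quant import CountMatrix

DEFAULT_LOWER = 100     # ambient totals at or below this are pooled
DEFAULT_ALPHA_FDR = 0.01
DEFAULT_N_ITER = 10_000
DEFAULT_CONCENTRATION = 100.0


@dataclass
class AmbientProfile:
    """Pooled per-feature ambient proportions (pseudo-count smoothed)."""

    proportions: np.ndarray
    low_count_threshold: int
    n_contributing_barcodes: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p <= 0):
            raise ValueError("ambient proportions must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("ambient proportions must sum to 1")
        self.proportions = p


def knee_point(totals: np.ndarray,
               min_total: Optional[float] = None) -> tuple[float, float]:
    """Locate the knee and inflection of the barcode-rank curve.

    The curve is the descending log-total vs log-rank step curve over
    distinct totals (rank = number of barcodes with at least that total;
    deduplication keeps the tail of singleton totals from dominating the
    log-rank axis). The inflection is the point of steepest descent; the
    knee is the point with the largest perpendicular distance below the
    chord joining the curve's start to the inflection. On a pure
    shelf-and-cliff curve no interior point dips below that chord and the
    knee coincides with the inflection. Returns the UMI totals at the two
    points. Permutation-invariant by construction.

    ``min_total`` restricts the curve to barcodes above that total before
    locating either point (ranks are still counted within the restricted
    curve); the cell-calling driver passes the ambient threshold here so the
    near-singleton far tail of the rank curve cannot masquerade as a cliff.
    """
    totals = np.asarray(totals, dtype=float)
    totals = totals[totals > 0]
    if min_total is not None:
        totals = totals[totals > min_total]
    if totals.size < 3 or np.unique(totals).size < 2:
        raise ValueError("need >= 3 barcodes with >= 2 distinct positive totals")
    distinct = np.unique(totals)[::-1]
    # rank of each distinct total = barcodes with total >= it
    ranks = np.searchsorted(-totals[np.argsort(-totals)], -distinct,
                            side="right")
    x = np.log10(ranks.astype(float))
    y = np.log10(distinct)
    slopes = np.diff(y) / np.maximum(np.diff(x), 1e-12)
    infl_idx = int(np.argmin(slopes)) + 1  # lower point of steepest segment
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[infl_idx], y[infl_idx]])
    chord = p1 - p0
    chord_len = np.hypot(*chord)
    if chord_len == 0:
        return float(distinct[infl_idx]), float(distinct[infl_idx])
    xs, ys = x[:infl_idx + 1], y[:infl_idx + 1]
    # signed cross product: negative = below the chord
    signed = (chord[0] * (ys - p0[1]) - chord[1] * (xs - p0[0])) / chord_len
    knee_idx = int(np.argmin(signed))
    if signed[knee_idx] >= -1e-12:
        knee_idx = infl_idx  # shelf-and-cliff: fall back to the inflection
    return float(distinct[knee_idx]), float(distinct[infl_idx])


def estimate_ambient(matrix: CountMatrix,
                     low_count_threshold: int = DEFAULT_LOWER
                     ) -> AmbientProfile:
    """Pool counts of barcodes with totals <= threshold; smooth with +0.5."""
    totals = matrix.total_counts()
    low = totals <= low_count_threshold
    if not low.any():
        raise ValueError(
            f"no barcode has total <= {low_count_threshold}; cannot "
            "estimate an ambient profile")
    pooled = np.asarray(matrix.matrix[low, :].sum(axis=0)).ravel() + 0.5
    return AmbientProfile(pooled / pooled.sum(), low_count_threshold,
                          int(low.sum()))


def _dirmult_loglik(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log-pmf, rows of ``counts`` vs concentration ``alpha``."""
    counts = np.atleast_2d(counts)
    n = counts.sum(axis=1)
    a0 = alpha.sum()
    return (gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
            + gammaln(a0) - gammaln(n + a0)
            + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1))


def _sample_dirmult(total: int, alpha: np.ndarray, n_iter: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_iter`` Dirichlet-multinomial count vectors at a fixed total."""
    p = rng.dirichlet(alpha, size=n_iter)
    out = np.zeros((n_iter, alpha.size), dtype=np.int64)
    remaining = np.full(n_iter, total, dtype=np.int64)
    remaining_p = np.ones(n_iter)
    for g in range(alpha.size - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(remaining_p > 0, p[:, g] / remaining_p, 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        draw = rng.binomial(remaining, frac)
        out[:, g] = draw
        remaining -= draw
        remaining_p -= p[:, g]
    out[:, -1] = remaining
    return out


def empty_drops_pvalues(matrix: CountMatrix, ambient: AmbientProfile,
                        n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                        concentration: float = DEFAULT_CONCENTRATION
                        ) -> pd.DataFrame:
    """Monte-Carlo p-values for barcodes above the ambient total threshold.

    For each tested barcode the Dirichlet-multinomial log-likelihood of its
    counts under the ambient profile is compared against ``n_iter`` simulated
    draws at the same total; p = (1 + #{draws <= observed}) / (n_iter + 1),
    so p is never exactly zero. Draws are grouped by total for efficiency.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = concentration * ambient.proportions
    totals = matrix.total_counts()
    tested = np.flatnonzero(totals > ambient.low_count_threshold)
    rows = []
    dense = np.asarray(matrix.matrix[tested, :].todense())
    obs_ll = _dirmult_loglik(dense, alpha)
    by_total: dict[int, list[int]] = {}
    for pos, i in enumerate(tested):
        by_total.setdefault(int(round(totals[i])), []).append(pos)
    for total in sorted(by_total):
        sims = _sample_dirmult(total, alpha, n_iter, rng)
        sim_ll = _dirmult_loglik(sims, alpha)
        for pos in by_total[total]:
            n_le = int(np.sum(sim_ll <= obs_ll[pos]))
            rows.append((matrix.barcodes[tested[pos]], totals[tested[pos]],
                         obs_ll[pos], (1 + n_le) / (n_iter + 1)))
    return pd.DataFrame(rows, columns=["barcode", "total", "loglik",
                                       "p_value"])


def call_cells(pvalues: pd.DataFrame, totals: pd.Series, knee: float,
               alpha_fdr: float = DEFAULT_ALPHA_FDR) -> pd.DataFrame:
    """Combine knee retention with the BH-corrected Monte-Carlo test.

    ``totals`` indexes every barcode (tested or not) by its UMI total;
    barcodes absent from ``pvalues`` can only be retained by the knee rule.
    """
    if totals.empty:
        raise ValueError("no barcodes to call")
    df = pd.DataFrame({"barcode": totals.index, "total": totals.values})
    df = df.merge(pvalues[["barcode", "p_value"]], on="barcode", how="left")
    tested = df["p_value"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh")[1]
    by_knee = df["total"] >= knee
    by_test = df["fdr"] <= alpha_fdr
    df["retained"] = by_knee | by_test.fillna(False)
    df["retained_by"] = np.select(
        [by_knee & by_test.fillna(False), by_knee, by_test.fillna(False)],
        ["both", "knee", "test"], default="none")
    return df


def run_empty_drops(matrix: CountMatrix,
                    low_count_threshold: int = DEFAULT_LOWER,
                    alpha_fdr: float = DEFAULT_ALPHA_FDR,
                    n_iter: int = DEFAULT_N_ITER, seed: int = 0,
                    concentration: float = DEFAULT_CONCENTRATION
                    ) -> pd.DataFrame:
    """Full WTA cell-calling pass: knee + ambient + Monte-Carlo + BH."""
    totals = pd.Series(matrix.total_counts(), index=matrix.barcodes)
    knee, _ = knee_point(totals.values, min_total=low_count_threshold)
    ambient = estimate_ambient(matrix, low_count_threshold)
    pvals = empty_drops_pvalues(matrix, ambient, n_iter, seed, concentration)
    return call_cells(pvals, totals, knee, alpha_fdr)


def borrow_cells(tso_matrix: CountMatrix,
                 wta_calls: pd.DataFrame) -> CountMatrix:
    """Restrict the TSO matrix to WTA-retained barcodes."""
    retained = wta_calls.loc[wta_calls["retained"], "barcode"].tolist()
    out = tso_matrix.subset_barcodes(retained)
    if not out.barcodes:
        import warnings
        warnings.warn("no TSO barcode is WTA-retained; TSO matrix is empty")
    return out
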