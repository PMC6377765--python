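"""Expression correlation of LCPs, FDR adjustment, per-lncRNA outliers,
the poly-/mono-correlation frequency matrix, and cross-dataset overlap.

Spearman rank correlation (midranks for ties, two-sided p) measures
coexpression of each pair; Benjamini-Hochberg adjustment is applied once
over all pairs of a dataset (one family per run). A per-lncRNA Z-score of
the rho values flags the coding gene whose correlation stands apart from
the rest of that lncRNA's neighbourhood (|z| > 1).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import LCP

log = logging.getLogger("plaidoh")

ALPHA_MATRIX = 0.01   # frequency-matrix significance
ALPHA_QUADRANT = 0.05  # conservation / downstream significance


def spearman_lcp(x: Sequence[float], y: Sequence[float]):
    """Spearman rho and two-sided p for one pair of expression vectors.

    Returns (nan, nan) when n < 3 or either vector is constant, in which
    case the pair is excluded from the BH family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are excluded
    from the family and restored as NaN."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def zscore_per_lncrna(rhos: Sequence[float]):
    """Standardise one lncRNA's rho values: z = (rho - mean) / sd with
    sample (n-1) sd; |z| > 1 flags the outlier gene. All-NaN output when
    fewer than 2 defined rho or sd == 0."""
    r = np.asarray(rhos, dtype=float)
    z = np.full(r.shape, np.nan)
    finite = np.isfinite(r)
    if finite.sum() < 2:
        return z, np.zeros(r.shape, dtype=bool)
    sd = np.std(r[finite], ddof=1)
    if sd == 0:
        return z, np.zeros(r.shape, dtype=bool)
    z[finite] = (r[finite] - np.mean(r[finite])) / sd
    flags = np.zeros(r.shape, dtype=bool)
    flags[finite] = np.abs(z[finite]) > 1
    return z, flags


def annotate_correlations(lcps: List[LCP]) -> None:
    """Fill rho/p/adj_p/zscore/outlier on every LCP in place.

    BH spans all pairs of the run jointly; Z-scores are computed within
    each lncRNA's pair set.
    """
    for lcp in lcps:
        lcp.rho, lcp.p = spearman_lcp(lcp.lnc.expression, lcp.gene.expression)
    adj = adjust_bh([lcp.p for lcp in lcps])
    for lcp, a in zip(lcps, adj):
        lcp.adj_p = float(a) if np.isfinite(a) else None
        if lcp.p is not None and not np.isfinite(lcp.p):
            lcp.p = None
            lcp.rho = None

    by_lnc: Dict[str, List[LCP]] = {}
    for lcp in lcps:
        by_lnc.setdefault(lcp.lnc.name, []).append(lcp)
    for group in by_lnc.values():
        z, flags = zscore_per_lncrna(
            [lcp.rho if lcp.rho is not None else float("nan") for lcp in group]
        )
        for lcp, zi, fi in zip(group, z, flags):
            lcp.zscore = float(zi) if np.isfinite(zi) else None
            lcp.outlier = bool(fi)


@dataclass
class FrequencyMatrix:
    """Tally of lncRNAs by (total coding neighbours, significant
    neighbours); the mono-/poly-correlation landscape of a dataset."""

    cells: Dict[tuple, int]
    alpha_sig: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "TOTAL_GENES": x,
                "SIGNIFICANT_GENES": y,
                "FREQUENCY": n,
                "LOG10_FREQUENCY": float(np.log10(n)),
            }
            for (x, y), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["TOTAL_GENES", "SIGNIFICANT_GENES", "FREQUENCY", "LOG10_FREQUENCY"]
        )


def frequency_matrix(lcps: Sequence[LCP], alpha: float = ALPHA_MATRIX) -> FrequencyMatrix:
    """Per lncRNA: x = number of paired coding genes, y = number with
    adj_p < alpha; tally lncRNA counts per (x, y) cell."""
    totals: Counter = Counter()
    sig: Counter = Counter()
    for lcp in lcps:
        totals[lcp.lnc.name] += 1
        if lcp.adj_p is not None and lcp.adj_p < alpha:
            sig[lcp.lnc.name] += 1
    cells: Counter = Counter()
    for name, x in totals.items():
        cells[(x, sig.get(name, 0))] += 1
    return FrequencyMatrix(dict(cells), alpha)


def cross_dataset_conservation(
    results: Dict[str, pd.DataFrame], alpha: float = ALPHA_QUADRANT
):
    """Binary LCP-significance matrix across datasets.

    ``results`` maps dataset name to an LCP table (columns LNC_NAME,
    GENE_NAME, ADJUSTED_SPEARMAN, SPEARMAN_RHO). Rows are the union of
    pairs significant (adj p < alpha) in at least one dataset; entries
    are 1 iff significant in that dataset. Also returns sharing-pattern
    counts (how many pairs are significant in exactly k datasets) and the
    same counts split by correlation sign.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 datasets to compare")
    sig_sets: Dict[str, set] = {}
    signs: Dict[tuple, float] = {}
    for ds, df in results.items():
        mask = df["ADJUSTED_SPEARMAN"].notna() & (df["ADJUSTED_SPEARMAN"] < alpha)
        sig_sets[ds] = set()
        for _, row in df[mask].iterrows():
            key = (row["LNC_NAME"], row["GENE_NAME"])
            sig_sets[ds].add(key)
            signs.setdefault(key, float(row["SPEARMAN_RHO"]))
    union = sorted(set().union(*sig_sets.values()))
    datasets = list(results)
    matrix = pd.DataFrame(
        [[int(key in sig_sets[ds]) for ds in datasets] for key in union],
        index=pd.MultiIndex.from_tuples(union, names=["LNC_NAME", "GENE_NAME"])
        if union
        else None,
        columns=datasets,
        dtype=int,
    )
    n_shared = matrix.sum(axis=1) if len(matrix) else pd.Series(dtype=int)
    pattern_counts = Counter(n_shared.tolist())
    sign_split = {
        "positive": Counter(n_shared[[signs[k] > 0 for k in union]].tolist()),
        "negative": Counter(n_shared[[signs[k] < 0 for k in union]].tolist()),
    } if union else {"positive": Counter(), "negative": Counter()}
    return matrix, dict(pattern_counts), {k: dict(v) for k, v in sign_split.items()}
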