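"""The two cis-regulatory scores, ranking, inflection cutoffs, scaling
and quadrant assignment.

The transcript cis-regulatory score weights evidence tied to the lncRNA
transcript itself (correlation significance, promoter-associated H3K4me3,
nuclear retention):

    10 * |−log10(adj_p + 0.001)| * (H3K4me3 + 0.1) * (fraction + 0.01)

The enhancer score weights enhancer-element evidence (H3K4me1, H3K27ac,
chromatin looping):

    ((H3K4me1 + 1) + (H3K27ac + 1)) * (1 + ChIA/100)

The small offsets act as floors so that a missing annotation (substituted
as 0) never zeroes the product. Each score vector is ranked (missing
lowest, random tie-break under the run seed) and cut at the geometric
inflection point, the uppermost crossing of the ranked-score curve with
its own least-squares line; the two cutoffs partition LCPs into four
mechanism quadrants.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np

from .types import LCP, ScoreCutoffs

log = logging.getLogger("plaidoh")


def _as_zero(value: Optional[float]) -> float:
    if value is None:
        return 0.0
    v = float(value)
    return 0.0 if math.isnan(v) else v


def transcript_cis_score(
    adj_p: Optional[float],
    h3k4me3: Optional[float],
    fraction: Optional[float],
    log_base: float = 10.0,
) -> Optional[float]:
    """LncRNA transcript cis-regulatory score; None when adj_p undefined
    (no correlation could be computed). Missing h3k4me3 / fraction enter
    as 0, floored by the formula's +0.1 / +0.01 offsets."""
    if adj_p is None or (isinstance(adj_p, float) and math.isnan(adj_p)):
        return None
    if not 0.0 <= adj_p <= 1.0:
        raise ValueError(f"adjusted p must lie in [0, 1], got {adj_p}")
    h = _as_zero(h3k4me3)
    f = _as_zero(fraction)
    return 10.0 * abs(-math.log(adj_p + 0.001, log_base)) * ((h + 0.1) * (f + 0.01))


def enhancer_score(
    h3k4me1: Optional[float], h3k27ac: Optional[float], chia: Optional[float]
) -> float:
    """Enhancer score; minimum 2 at all-zero inputs. Missing values enter
    as 0."""
    m1, ac, c = _as_zero(h3k4me1), _as_zero(h3k27ac), _as_zero(chia)
    if m1 < 0 or ac < 0 or c < 0:
        raise ValueError("enhancer-score inputs must be non-negative")
    return ((m1 + 1.0) + (ac + 1.0)) * (1.0 + c / 100.0)


def rank_scores(scores: Sequence[Optional[float]], seed: int = 0) -> np.ndarray:
    """Integer ranks 1..n: missing values take the lowest ranks (in input
    order); ties among finite values break uniformly at random under
    ``seed``."""
    vals = np.array(
        [float("nan") if s is None else float(s) for s in scores], dtype=float
    )
    n = vals.size
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(n)
    missing = ~np.isfinite(vals)
    finite_idx = np.nonzero(~missing)[0]
    missing_idx = np.nonzero(missing)[0]
    # missing first (input order), then finite by (value, random tie-break)
    finite_order = finite_idx[np.lexsort((tiebreak[finite_idx], vals[finite_idx]))]
    order = np.concatenate([missing_idx, finite_order])
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def inflection_cutoff(scores: Sequence[Optional[float]]) -> Optional[float]:
    """Geometric inflection point of a ranked score curve.

    Sort finite scores ascending, fit an ordinary least-squares line of
    score against rank, and locate the uppermost crossing where the
    empirical curve passes the line from below (residual sign change
    − → +). The cutoff is the score at the last point still below the
    line there, so every point beyond the crossing — the high-score
    tail — exceeds it. A degenerate (near-linear or never-crossing)
    curve yields max(scores): nothing passes, logged loudly. None when
    fewer than 3 finite scores.
    """
    vals = np.sort(
        np.array([s for s in scores if s is not None and math.isfinite(s)], dtype=float)
    )
    n = vals.size
    if n < 3:
        return None
    ranks = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(ranks, vals, 1)
    resid = vals - (slope * ranks + intercept)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(vals))))
    signif = np.nonzero(np.abs(resid) > tol)[0]
    if signif.size == 0:
        log.warning("inflection cutoff degenerate (linear curve); using max score")
        return float(vals[-1])
    signs = np.sign(resid[signif])
    crossings = np.nonzero((signs[:-1] < 0) & (signs[1:] > 0))[0]
    if crossings.size == 0:
        log.warning("ranked-score curve never crosses its regression line "
                    "from below; using max score")
        return float(vals[-1])
    upper = crossings[-1]  # last below-line point of the upper crossing
    return float(vals[signif[upper]])


def scale_to_100(scores: Sequence[Optional[float]]) -> np.ndarray:
    """scaled = 100 * score / max(score); all-zero input stays zero with
    a warning. Missing values propagate as NaN."""
    vals = np.array(
        [float("nan") if s is None else float(s) for s in scores], dtype=float
    )
    finite = np.isfinite(vals)
    if not finite.any():
        return vals
    top = np.max(vals[finite])
    if top <= 0:
        log.warning("all scores <= 0; scaled scores left at 0")
        return np.where(finite, 0.0, vals)
    return np.where(finite, 100.0 * vals / top, vals)


def assign_quadrant(
    enh: Optional[float], cis: Optional[float], cutoffs: ScoreCutoffs
) -> Optional[str]:
    """Mechanism quadrant from the two scores and their cutoffs.

    Q1 low/low; Q2 enhancer-high only; Q3 both high; Q4 transcript-high
    only. Scores exactly at a cutoff count as low. None when either score
    or cutoff is undefined.
    """
    if (
        enh is None
        or cis is None
        or cutoffs.enhancer_cutoff is None
        or cutoffs.transcript_cutoff is None
    ):
        return None
    e_high = enh > cutoffs.enhancer_cutoff
    c_high = cis > cutoffs.transcript_cutoff
    if e_high and c_high:
        return "Q3"
    if e_high:
        return "Q2"
    if c_high:
        return "Q4"
    return "Q1"


def score_lcps(
    lcps: Sequence[LCP], seed: int = 0, log_base: float = 10.0
) -> ScoreCutoffs:
    """Compute both scores, scaled versions, inflection cutoffs and
    quadrants for a run's LCPs in place; returns the cutoffs."""
    for lcp in lcps:
        lcp.enhancer_score = enhancer_score(lcp.h3k4me1, lcp.h3k27ac, lcp.chia_score)
        lcp.transcript_cis_score = transcript_cis_score(
            lcp.adj_p, lcp.h3k4me3, lcp.nuclear_fraction, log_base=log_base
        )
    enh = [lcp.enhancer_score for lcp in lcps]
    cis = [lcp.transcript_cis_score for lcp in lcps]
    cutoffs = ScoreCutoffs(
        enhancer_cutoff=inflection_cutoff(enh),
        transcript_cutoff=inflection_cutoff(cis),
        seed=seed,
    )
    enh_scaled = scale_to_100(enh)
    cis_scaled = scale_to_100(cis)
    for lcp, es, cs in zip(lcps, enh_scaled, cis_scaled):
        lcp.enhancer_score_scaled = float(es) if math.isfinite(es) else None
        lcp.transcript_cis_score_scaled = float(cs) if math.isfinite(cs) else None
        lcp.quadrant = assign_quadrant(
            lcp.enhancer_score, lcp.transcript_cis_score, cutoffs
        )
    return cutoffs
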