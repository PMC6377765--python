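"""Attach chromatin and localization evidence to lncRNAs and LCPs.

ChIP-seq peak significance (-log10 p) over the lncRNA locus serves as a
normalized activity measure per histone mark; ChIA-PET interactions whose
two anchors bridge the lncRNA and its paired gene contribute looping
evidence; nuclear/cytoplasmic FPKM gives the nuclear fraction and a
three-way localization class.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .intervals import GenomeIndex
from .types import (
    AnnotationBundle,
    ChiaInteraction,
    ChipPeak,
    FractionExpression,
    LCP,
    Transcript,
)

log = logging.getLogger("plaidoh")


def assign_chip_signal(
    lnc: Transcript,
    peaks: Sequence[ChipPeak],
    mark: str,
    index: Optional[GenomeIndex] = None,
) -> float:
    """Maximum -log10 peak p of ``mark`` over peaks overlapping the
    lncRNA interval; 0 when none overlap. Multiple overlapping peaks are
    combined by max, which stays on the -log10 scale and is robust to
    peak fragmentation."""
    if index is None:
        index = GenomeIndex(
            (p.chrom, p.start, p.stop, p) for p in peaks if p.mark == mark
        )
    hits = index.overlapping(lnc.chrom, lnc.start, lnc.stop)
    return max((p.neg_log10_p for p in hits if p.mark == mark), default=0.0)


def chip_indexes(peaks: Sequence[ChipPeak]) -> dict:
    """One overlap index per histone mark."""
    marks = {}
    for p in peaks:
        marks.setdefault(p.mark, GenomeIndex()).add(p.chrom, p.start, p.stop, p)
    return marks


def assign_chia_score(
    lcp: LCP,
    interactions: Sequence[ChiaInteraction],
    index: Optional[GenomeIndex] = None,
) -> float:
    """Maximum score over interactions bridging the pair: one anchor
    overlaps the lncRNA and the other overlaps the gene, in either anchor
    order. 0 when no interaction bridges."""
    lnc, gene = lcp.lnc, lcp.gene
    if index is not None:
        candidates = index.overlapping(lnc.chrom, lnc.start, lnc.stop)
    else:
        candidates = interactions
    best = 0.0
    for ia in candidates:
        a1, a2 = ia.anchor1, ia.anchor2
        bridges = (a1.overlaps(lnc.interval) and a2.overlaps(gene.interval)) or (
            a2.overlaps(lnc.interval) and a1.overlaps(gene.interval)
        )
        if bridges and ia.score > best:
            best = ia.score
    return best


def chia_index(interactions: Sequence[ChiaInteraction]) -> GenomeIndex:
    """Index interactions by both anchors so a lncRNA-interval query
    retrieves every candidate."""
    idx = GenomeIndex()
    for ia in interactions:
        idx.add(ia.anchor1.chrom, ia.anchor1.start, ia.anchor1.stop, ia)
        idx.add(ia.anchor2.chrom, ia.anchor2.start, ia.anchor2.stop, ia)
    return idx


def nuclear_fraction(fr: Optional[FractionExpression]) -> Optional[float]:
    """nuclear / (nuclear + cytoplasmic) FPKM; None when the transcript
    is absent from the fraction table or both compartments are zero."""
    if fr is None:
        return None
    total = fr.nuclear_fpkm + fr.cytoplasmic_fpkm
    if total <= 0:
        return None
    return fr.nuclear_fpkm / total


def classify_localization(fraction: Optional[float]) -> Optional[str]:
    """Three-way localization class from the nuclear fraction.

    Nuclear at fraction >= 0.7, Cytoplasmic at <= 0.3, Both between the
    two; boundaries inclusive on the single-compartment side. None in,
    None out.
    """
    if fraction is None:
        return None
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"nuclear fraction must lie in [0, 1], got {fraction}")
    if fraction >= 0.7:
        return "Nuclear"
    if fraction <= 0.3:
        return "Cytoplasmic"
    return "Both"


def annotate_epigenome(lcps: Sequence[LCP], bundle: AnnotationBundle) -> None:
    """Fill ChIP marks, ChIA score, nuclear fraction/localization and TAD
    overlap on every LCP in place."""
    marks = chip_indexes(bundle.chip_peaks)
    c_index = chia_index(bundle.chia_interactions)
    tad_index = GenomeIndex(
        (t.chrom, t.start, t.stop, t) for t in bundle.tad_boundaries
    )
    cache: dict = {}
    for lcp in lcps:
        lnc = lcp.lnc
        if lnc.name not in cache:
            frac = nuclear_fraction(bundle.fractions.get(lnc.name))
            cache[lnc.name] = (
                {
                    m: assign_chip_signal(lnc, (), m, index=idx)
                    for m, idx in marks.items()
                },
                frac,
                classify_localization(frac),
                tad_index.any_overlap(lnc.chrom, lnc.start, lnc.stop),
            )
        chip, frac, loc, tad = cache[lnc.name]
        lcp.h3k4me1 = chip.get("H3K4me1", 0.0)
        lcp.h3k27ac = chip.get("H3K27ac", 0.0)
        lcp.h3k4me3 = chip.get("H3K4me3", 0.0)
        lcp.nuclear_fraction = frac
        lcp.localization = loc
        lcp.tad_overlap = tad
        lcp.chia_score = assign_chia_score(lcp, bundle.chia_interactions, index=c_index)
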