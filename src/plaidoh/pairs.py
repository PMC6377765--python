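"""Enumerate lncRNA-coding-gene pairs and classify lncRNA genomic context.

A pair (LCP) is any lncRNA or antisense transcript and any protein-coding
gene on the same chromosome whose nearest-edge distance is at most the
flanking window (default 400 kb, so the searched region spans 800 kb total
around the lncRNA). Overlapping pairs count at distance 0.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np

from .intervals import GenomeIndex, edge_distance
from .types import LCP, EnhancerRegion, PositionClass, Transcript

log = logging.getLogger("plaidoh")

DEFAULT_WINDOW = 400_000


def find_lcps(transcripts: Sequence[Transcript], window: int = DEFAULT_WINDOW) -> List[LCP]:
    """All (lncRNA-or-antisense, coding gene) pairs within ``window`` bp.

    Each unordered pair appears exactly once; misc transcripts never
    participate. Complexity is O(L * G_c) per chromosome via a vectorised
    distance scan, ample for genome-scale inputs.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    lncs = [t for t in transcripts if t.is_lnc]
    genes = [t for t in transcripts if t.is_coding]
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    lcps: List[LCP] = []
    for lnc in lncs:
        chrom_genes = by_chrom.get(lnc.chrom)
        if not chrom_genes:
            continue
        starts = np.array([g.start for g in chrom_genes])
        stops = np.array([g.stop for g in chrom_genes])
        dist = np.maximum(np.maximum(starts - lnc.stop, lnc.start - stops), 0)
        for idx in np.nonzero(dist <= window)[0]:
            lcps.append(LCP(lnc=lnc, gene=chrom_genes[idx], distance=int(dist[idx])))
    return lcps


def classify_position(
    lnc: Transcript,
    genes: Sequence[Transcript],
    enhancers: Sequence[EnhancerRegion],
    gene_index: Optional[GenomeIndex] = None,
    enhancer_index: Optional[GenomeIndex] = None,
) -> PositionClass:
    """Genomic relationship of one lncRNA to coding genes and enhancers.

    intragenic iff >=1 bp overlap with any coding gene; orientation is
    antisense when the TYPE says so or when the lncRNA overlaps a coding
    gene on the opposite known strand; overlapping for same-/unknown-strand
    overlap; distal otherwise. Super-enhancer overlap takes precedence
    over conventional.
    """
    if gene_index is None:
        gene_index = GenomeIndex((g.chrom, g.start, g.stop, g) for g in genes if g.is_coding)
    if enhancer_index is None:
        enhancer_index = GenomeIndex((e.chrom, e.start, e.stop, e) for e in enhancers)

    hits = gene_index.overlapping(lnc.chrom, lnc.start, lnc.stop)
    geniality = "intragenic" if hits else "intergenic"

    if lnc.ttype == "antisense_rna":
        orientation = "antisense"
    elif hits:
        opposite = any(
            lnc.strand in ("+", "-")
            and g.strand in ("+", "-")
            and g.strand != lnc.strand
            for g in hits
        )
        orientation = "antisense" if opposite else "overlapping"
    else:
        orientation = "distal"

    ehits = enhancer_index.overlapping(lnc.chrom, lnc.start, lnc.stop)
    if any(e.kind == "super" for e in ehits):
        enhancer_class = "super"
    elif ehits:
        enhancer_class = "conventional"
    else:
        enhancer_class = "none"
    return PositionClass(orientation, geniality, enhancer_class)


def lncrnas_per_kb(
    enhancers: Sequence[EnhancerRegion], lncs: Sequence[Transcript]
) -> List[tuple]:
    """Per-enhancer lncRNA overlap density: count / (length in kb).

    Returns (enhancer, count, density) triples; zero-length enhancers are
    excluded with a warning.
    """
    lnc_index = GenomeIndex((t.chrom, t.start, t.stop, t) for t in lncs if t.is_lnc)
    out = []
    for enh in enhancers:
        if enh.length <= 0:
            log.warning(
                "zero-length enhancer %s:%d-%d excluded from density",
                enh.chrom, enh.start, enh.stop,
            )
            continue
        count = len(lnc_index.overlapping(enh.chrom, enh.start, enh.stop))
        out.append((enh, count, count / (enh.length / 1000.0)))
    return out
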