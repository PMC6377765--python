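"""lncRNA x RBP interactome from eCLIP binding evidence.

Binding evidence comes from ENCODE-style eCLIP tracks in two cell lines
(K562, HepG2) with two replicates each; only records carrying the maximal
score encoding (1000) count as binding calls. An RBP binds a lncRNA when
both cell lines show binding, or both replicates of either single line
do. Bound pairs receive a localization concordance score in
{-2,-1,1,2,3} comparing the lncRNA's fractionation class with the RBP's
immunofluorescence compartments; unbound pairs score 0.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import classify_localization, nuclear_fraction
from .intervals import GenomeIndex
from .types import (
    AnnotationBundle,
    EclipRecord,
    InteractomeEntry,
    RbpLocalization,
    Transcript,
)

log = logging.getLogger("plaidoh")

BINDING_SCORE = 1000.0


def binding_call(records: Sequence[EclipRecord], strict: bool = False) -> int:
    """1 iff the eCLIP evidence meets the binding rule.

    ``records`` must already be restricted to sites overlapping the
    lncRNA. A cell line "shows binding" when any replicate carries a
    score-1000 record (``strict`` demands both replicates for the
    cross-line clause). Returns 1 iff both cell lines show binding, or
    both replicates of either one line do.
    """
    present = {("K562", 1): False, ("K562", 2): False,
               ("HepG2", 1): False, ("HepG2", 2): False}
    for r in records:
        if r.score == BINDING_SCORE:
            present[(r.cell_line, r.replicate)] = True
    k1, k2 = present[("K562", 1)], present[("K562", 2)]
    h1, h2 = present[("HepG2", 1)], present[("HepG2", 2)]
    if strict:
        cross = (k1 and k2) and (h1 and h2)
    else:
        cross = (k1 or k2) and (h1 or h2)
    return int(cross or (k1 and k2) or (h1 and h2))


def concordance_score(
    bound: int,
    lnc_class: Optional[str],
    rbp_compartments: frozenset,
) -> Optional[int]:
    """Localization concordance of a lncRNA-RBP pair.

    0 when unbound. For bound pairs: 3 when both molecules are present in
    both compartments; +/-2 when the lncRNA's compartment (Nuclear +,
    Cytoplasmic -) is shared by the RBP; +/-1 when it is not. A lncRNA
    classed Both facing a single-compartment RBP scores +/-1 by the
    shared compartment (extended rule, see :func:`is_extended_rule`).
    None for a bound pair whose lncRNA localization is unknown.
    """
    if not bound:
        return 0
    if lnc_class is None:
        return None
    rbp = frozenset(rbp_compartments)
    if lnc_class == "Both":
        if {"Nuclear", "Cytoplasmic"} <= rbp:
            return 3
        if "Cytoplasmic" in rbp:
            return -1
        # Nuclear-only RBP, or none recorded: nuclear-side sign anchor
        return 1
    if lnc_class == "Nuclear":
        return 2 if "Nuclear" in rbp else 1
    if lnc_class == "Cytoplasmic":
        return -2 if "Cytoplasmic" in rbp else -1
    raise ValueError(f"unknown localization class {lnc_class!r}")


def is_extended_rule(bound: int, lnc_class: Optional[str], rbp_compartments) -> bool:
    """True when the pair falls outside the printed concordance rules
    (lncRNA classed Both with a single-compartment or unannotated RBP)."""
    return bool(bound) and lnc_class == "Both" and not (
        {"Nuclear", "Cytoplasmic"} <= frozenset(rbp_compartments)
    )


def merge_sites(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals into distinct
    binding sites."""
    merged: List[Tuple[int, int]] = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
        else:
            merged.append((start, stop))
    return merged


def binding_density(n_sites: int, lnc_length_bp: int) -> float:
    """Distinct binding sites per kb of lncRNA span."""
    if lnc_length_bp <= 0:
        raise ValueError(f"lncRNA length must be positive, got {lnc_length_bp}")
    return n_sites / (lnc_length_bp / 1000.0)


def build_interaction_matrix(
    lncs: Sequence[Transcript],
    bundle: AnnotationBundle,
    strict: bool = False,
) -> List[InteractomeEntry]:
    """One entry per (lncRNA, RBP) with at least one overlapping eCLIP
    record. Binding, merged-site density and concordance are computed per
    entry; RBP compartments default to empty (with a warning) when the
    RBP is absent from the immunofluorescence table.
    """
    eclip_index = GenomeIndex(
        (r.chrom, r.start, r.stop, r) for r in bundle.eclip_records
    )
    warned: set = set()
    entries: List[InteractomeEntry] = []
    expr_by_name = {t.name: float(np.mean(t.expression)) for t in lncs}
    for lnc in lncs:
        if not lnc.is_lnc:
            continue
        frac = nuclear_fraction(bundle.fractions.get(lnc.name))
        lnc_class = classify_localization(frac)
        by_rbp: Dict[str, List[EclipRecord]] = {}
        for rec in eclip_index.overlapping(lnc.chrom, lnc.start, lnc.stop):
            by_rbp.setdefault(rec.rbp_name, []).append(rec)
        for rbp, recs in sorted(by_rbp.items()):
            bound = binding_call(recs, strict=strict)
            sites = merge_sites(
                [(r.start, r.stop) for r in recs if r.score == BINDING_SCORE]
            )
            loc = bundle.rbp_localizations.get(rbp)
            if loc is None and rbp not in warned:
                log.warning("RBP %s absent from localization table", rbp)
                warned.add(rbp)
            comps = loc.compartments if loc else frozenset()
            entries.append(
                InteractomeEntry(
                    lnc_name=lnc.name,
                    rbp_name=rbp,
                    bound=bound,
                    n_sites=len(sites),
                    density=binding_density(len(sites), lnc.length) if bound else None,
                    concordance=concordance_score(bound, lnc_class, comps),
                    lnc_class=lnc_class,
                    rbp_compartments=comps,
                    lnc_expression=expr_by_name.get(lnc.name),
                    rbp_expression=expr_by_name.get(rbp),
                    extended_rule=is_extended_rule(bound, lnc_class, comps),
                )
            )
    return entries


def interactome_dataframe(entries: Sequence[InteractomeEntry]) -> pd.DataFrame:
    rows = [
        {
            "LNC_NAME": e.lnc_name,
            "RBP_NAME": e.rbp_name,
            "BOUND": e.bound,
            "N_SITES": e.n_sites,
            "DENSITY_PER_KB": e.density,
            "CONCORDANCE": e.concordance,
            "LNC_CLASS": e.lnc_class,
            "RBP_COMPARTMENTS": ",".join(sorted(e.rbp_compartments)),
            "LNC_EXPRESSION": e.lnc_expression,
            "RBP_EXPRESSION": e.rbp_expression,
            "EXTENDED_RULE": int(e.extended_rule),
        }
        for e in entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "LNC_NAME", "RBP_NAME", "BOUND", "N_SITES", "DENSITY_PER_KB",
            "CONCORDANCE", "LNC_CLASS", "RBP_COMPARTMENTS",
            "LNC_EXPRESSION", "RBP_EXPRESSION", "EXTENDED_RULE",
        ],
    )


def concordance_matrix(entries: Sequence[InteractomeEntry]) -> pd.DataFrame:
    """lncRNA x RBP matrix of concordance scores (0 where no entry)."""
    df = interactome_dataframe(entries)
    if df.empty:
        return pd.DataFrame()
    return (
        df.pivot_table(
            index="LNC_NAME", columns="RBP_NAME", values="CONCORDANCE",
            aggfunc="first", fill_value=0,
        )
        .astype(int)
    )


def specificity_counts(entries: Sequence[InteractomeEntry]):
    """(per-lncRNA bound-RBP counts, per-RBP bound-lncRNA counts)."""
    per_lnc: Dict[str, int] = {}
    per_rbp: Dict[str, int] = {}
    for e in entries:
        if e.bound:
            per_lnc[e.lnc_name] = per_lnc.get(e.lnc_name, 0) + 1
            per_rbp[e.rbp_name] = per_rbp.get(e.rbp_name, 0) + 1
    return per_lnc, per_rbp
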