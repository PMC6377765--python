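"""Readers and writers for the expression table and annotation tracks.

The expression table is a bed-like TSV whose header line must begin with
``#``: columns CHR, START, STOP, NAME, TYPE, then one column per sample.
TYPE values other than protein_coding / lncRNA / antisense_rna are routed
to ``misc`` and excluded from pair building. All annotation tracks are
BED3-plus dialects documented per parser below; every track is optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    CHIP_MARKS,
    COMPARTMENTS,
    ECLIP_CELL_LINES,
    AnnotationBundle,
    ChiaInteraction,
    ChipPeak,
    EclipRecord,
    EnhancerRegion,
    FractionExpression,
    Interval,
    LCP,
    RbpLocalization,
    Transcript,
)

log = logging.getLogger("plaidoh")

_KNOWN_TYPES = {"protein_coding", "lncRNA", "antisense_rna"}


class FormatError(ValueError):
    """Malformed file structure (header, column count)."""


class SortOrderError(ValueError):
    """Input table not sorted by (CHR, START)."""


@dataclass
class RejectedRow:
    line_no: int
    reason: str
    text: str


@dataclass
class ExpressionTable:
    transcripts: List[Transcript]
    sample_names: List[str]
    rejected: List[RejectedRow] = field(default_factory=list)

    @property
    def misc(self) -> List[Transcript]:
        return [t for t in self.transcripts if t.ttype == "misc"]

    @property
    def active(self) -> List[Transcript]:
        """Transcripts that participate in pair building."""
        return [t for t in self.transcripts if t.ttype != "misc"]


def parse_expression_table(path, swap_malformed: bool = False) -> ExpressionTable:
    """Parse the user expression table.

    Rows with START >= STOP are rejected with a per-row diagnostic unless
    ``swap_malformed`` is set, in which case the coordinates are swapped
    and a warning logged. Sort order by (CHR lexicographic, START) is
    verified over the accepted rows and a :class:`SortOrderError` raised
    on violation.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(
                f"{path}: header line must begin with '#', got {header[:40]!r}"
            )
        cols = header.lstrip("#").split("\t")
        if len(cols) < 6:
            raise FormatError(
                f"{path}: expected >=6 columns (CHR START STOP NAME TYPE "
                f"SAMPLE...), found {len(cols)}"
            )
        sample_names = [c for c in cols[5:] if c]

        transcripts: List[Transcript] = []
        rejected: List[RejectedRow] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5 + len(sample_names):
                rejected.append(
                    RejectedRow(line_no, f"expected {5 + len(sample_names)} fields, got {len(fields)}", line)
                )
                continue
            chrom, start_s, stop_s, name, ttype = fields[:5]
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError:
                rejected.append(RejectedRow(line_no, "non-integer coordinate", line))
                continue
            if start >= stop:
                if swap_malformed:
                    log.warning(
                        "line %d (%s): START %d >= STOP %d, swapping", line_no, name, start, stop
                    )
                    start, stop = stop, start
                else:
                    rejected.append(
                        RejectedRow(line_no, f"START {start} >= STOP {stop}", line)
                    )
                    continue
            expr = np.empty(len(sample_names))
            bad_cell = None
            for j, cell in enumerate(fields[5:]):
                try:
                    expr[j] = float(cell)
                except ValueError:
                    bad_cell = j
                    break
            if bad_cell is not None:
                raise ValueError(
                    f"{path}: non-numeric expression value {fields[5 + bad_cell]!r} "
                    f"at line {line_no}, column {sample_names[bad_cell]}"
                )
            if ttype not in _KNOWN_TYPES:
                ttype = "misc"
            transcripts.append(Transcript(chrom, start, stop, name, ttype, expr))

    _check_sorted(transcripts, path)
    log.info(
        "%s: %d transcripts parsed, %d rows rejected",
        path.name, len(transcripts), len(rejected),
    )
    return ExpressionTable(transcripts, sample_names, rejected)


def _check_sorted(transcripts: Sequence[Transcript], path) -> None:
    prev = None
    for t in transcripts:
        key = (t.chrom, t.start)
        if prev is not None and key < prev:
            raise SortOrderError(
                f"{path}: input not sorted by (CHR, START) near {t.name} "
                f"({t.chrom}:{t.start}); sort with `sort -k1,1 -k2,2n`"
            )
        prev = key


# ---------------------------------------------------------------------------
# annotation tracks


def _iter_rows(path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line_no, line.split("\t")


def _coords_ok(start: int, stop: int) -> bool:
    return start < stop


def parse_chip_peaks(path) -> List[ChipPeak]:
    """BED3+3: chrom start stop cell_line mark neg_log10_p."""
    peaks, dropped = [], 0
    for line_no, f in _iter_rows(path):
        try:
            chrom, start, stop, cell, mark, nlp = f[0], int(f[1]), int(f[2]), f[3], f[4], float(f[5])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if not _coords_ok(start, stop) or mark not in CHIP_MARKS or nlp < 0:
            dropped += 1
            continue
        peaks.append(ChipPeak(chrom, start, stop, cell, mark, nlp))
    if dropped:
        log.warning("%s: %d ChIP peak records rejected", path, dropped)
    return peaks


def parse_enhancers(path, kind: str) -> List[EnhancerRegion]:
    """BED3; ``kind`` is fixed per file (conventional vs super)."""
    regions, dropped = [], 0
    for line_no, f in _iter_rows(path):
        try:
            chrom, start, stop = f[0], int(f[1]), int(f[2])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if not _coords_ok(start, stop):
            dropped += 1
            continue
        regions.append(EnhancerRegion(chrom, start, stop, kind))
    if dropped:
        log.warning("%s: %d enhancer records rejected", path, dropped)
    return regions


def parse_chia(path) -> List[ChiaInteraction]:
    """Paired-anchor 7-column: chrom1 start1 stop1 chrom2 start2 stop2 score."""
    out, dropped = [], 0
    for line_no, f in _iter_rows(path):
        try:
            a1 = Interval(f[0], int(f[1]), int(f[2]))
            a2 = Interval(f[3], int(f[4]), int(f[5]))
            score = float(f[6])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if not (_coords_ok(a1.start, a1.stop) and _coords_ok(a2.start, a2.stop)) or score < 0:
            dropped += 1
            continue
        out.append(ChiaInteraction(a1, a2, score))
    if dropped:
        log.warning("%s: %d ChIA-PET records rejected", path, dropped)
    return out


def parse_eclip(path) -> List[EclipRecord]:
    """BED3+4: chrom start stop rbp_name cell_line replicate score.

    Only K562 and HepG2 are defined cell lines; records from any other
    line are rejected (logged), as are replicates outside {1, 2}.
    """
    out, dropped = [], 0
    for line_no, f in _iter_rows(path):
        try:
            chrom, start, stop = f[0], int(f[1]), int(f[2])
            rbp, cell, rep, score = f[3], f[4], int(f[5]), float(f[6])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if not _coords_ok(start, stop) or cell not in ECLIP_CELL_LINES or rep not in (1, 2):
            dropped += 1
            continue
        out.append(EclipRecord(chrom, start, stop, rbp, cell, rep, score))
    if dropped:
        log.warning("%s: %d eCLIP records rejected", path, dropped)
    return out


def parse_fractions(path) -> dict:
    """TSV: name nuclear_fpkm cytoplasmic_fpkm (optional # header)."""
    out, dropped = {}, 0
    for line_no, f in _iter_rows(path):
        try:
            name, nuc, cyt = f[0], float(f[1]), float(f[2])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if nuc < 0 or cyt < 0:
            dropped += 1
            continue
        out[name] = FractionExpression(name, nuc, cyt)
    if dropped:
        log.warning("%s: %d fraction records rejected", path, dropped)
    return out


def parse_rbp_localizations(path) -> dict:
    """TSV: rbp_name compartments (comma-separated subset of Nuclear,Cytoplasmic)."""
    out, dropped = {}, 0
    for line_no, f in _iter_rows(path):
        if len(f) < 2:
            dropped += 1
            continue
        comps = frozenset(c.strip() for c in f[1].split(",") if c.strip())
        if not comps or not comps <= set(COMPARTMENTS):
            dropped += 1
            continue
        out[f[0]] = RbpLocalization(f[0], comps)
    if dropped:
        log.warning("%s: %d RBP localization records rejected", path, dropped)
    return out


def parse_tads(path) -> List[Interval]:
    out, dropped = [], 0
    for line_no, f in _iter_rows(path):
        try:
            chrom, start, stop = f[0], int(f[1]), int(f[2])
        except (IndexError, ValueError):
            dropped += 1
            continue
        if not _coords_ok(start, stop):
            dropped += 1
            continue
        out.append(Interval(chrom, start, stop))
    if dropped:
        log.warning("%s: %d TAD records rejected", path, dropped)
    return out


def parse_gene_annotation(path) -> dict:
    """TSV: name strand [description]. Strand in {+, -}; others -> unknown."""
    out = {}
    for line_no, f in _iter_rows(path):
        if len(f) < 2:
            continue
        strand = f[1] if f[1] in ("+", "-") else "unknown"
        out[f[0]] = (strand, f[2] if len(f) > 2 else "")
    return out


_TRACK_PARSERS = {
    "chip": ("chip_peaks", parse_chip_peaks),
    "enhancers": ("enhancers", lambda p: parse_enhancers(p, "conventional")),
    "super_enhancers": ("enhancers", lambda p: parse_enhancers(p, "super")),
    "chia": ("chia_interactions", parse_chia),
    "eclip": ("eclip_records", parse_eclip),
    "fractions": ("fractions", parse_fractions),
    "rbp_localizations": ("rbp_localizations", parse_rbp_localizations),
    "tads": ("tad_boundaries", parse_tads),
    "gene_annotation": ("gene_annotation", parse_gene_annotation),
}


def parse_annotation_bundle(config: dict) -> AnnotationBundle:
    """Assemble an :class:`AnnotationBundle` from a {track: path} mapping.

    Any track may be absent or ``None``; absent tracks yield empty
    collections and contribute zero downstream. Unknown track keys raise.
    """
    unknown = set(config) - set(_TRACK_PARSERS)
    if unknown:
        raise KeyError(f"unknown annotation tracks: {sorted(unknown)}")
    bundle = AnnotationBundle()
    for key, path in config.items():
        if path is None:
            continue
        attr, parser = _TRACK_PARSERS[key]
        parsed = parser(path)
        current = getattr(bundle, attr)
        if isinstance(current, list):
            current.extend(parsed)
        else:
            current.update(parsed)
    return bundle


# ---------------------------------------------------------------------------
# output


OUTPUT_COLUMNS = [
    "LNC_NAME", "LNC_CHR", "LNC_START", "LNC_STOP", "LNC_STRAND",
    "GENE_NAME", "GENE_CHR", "GENE_START", "GENE_STOP", "GENE_STRAND",
    "DISTANCE", "SPEARMAN_RHO", "SPEARMAN_P", "ADJUSTED_SPEARMAN",
    "ZSCORE", "OUTLIER",
    "H3K4ME1", "H3K27AC", "H3K4ME3", "CHIA_SCORE",
    "NUCLEAR_FRACTION", "LOCALIZATION",
    "ENHANCER_CLASS", "ORIENTATION", "GENIALITY", "TAD_OVERLAP",
    "ENHANCER_SCORE", "TRANSCRIPT_CIS_SCORE",
    "ENHANCER_SCORE_SCALED", "TRANSCRIPT_CIS_SCORE_SCALED",
    "ENHANCER_CUTOFF", "TRANSCRIPT_CUTOFF", "QUADRANT", "N_RBPS_BOUND",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return repr(value)  # shortest round-trippable form
    return str(value)


def lcp_row(lcp: LCP, cutoffs=None) -> dict:
    pos = lcp.position
    return {
        "LNC_NAME": lcp.lnc.name,
        "LNC_CHR": lcp.lnc.chrom,
        "LNC_START": lcp.lnc.start,
        "LNC_STOP": lcp.lnc.stop,
        "LNC_STRAND": lcp.lnc.strand,
        "GENE_NAME": lcp.gene.name,
        "GENE_CHR": lcp.gene.chrom,
        "GENE_START": lcp.gene.start,
        "GENE_STOP": lcp.gene.stop,
        "GENE_STRAND": lcp.gene.strand,
        "DISTANCE": lcp.distance,
        "SPEARMAN_RHO": lcp.rho,
        "SPEARMAN_P": lcp.p,
        "ADJUSTED_SPEARMAN": lcp.adj_p,
        "ZSCORE": lcp.zscore,
        "OUTLIER": lcp.outlier,
        "H3K4ME1": lcp.h3k4me1,
        "H3K27AC": lcp.h3k27ac,
        "H3K4ME3": lcp.h3k4me3,
        "CHIA_SCORE": lcp.chia_score,
        "NUCLEAR_FRACTION": lcp.nuclear_fraction,
        "LOCALIZATION": lcp.localization,
        "ENHANCER_CLASS": pos.enhancer_class if pos else None,
        "ORIENTATION": pos.orientation if pos else None,
        "GENIALITY": pos.geniality if pos else None,
        "TAD_OVERLAP": lcp.tad_overlap,
        "ENHANCER_SCORE": lcp.enhancer_score,
        "TRANSCRIPT_CIS_SCORE": lcp.transcript_cis_score,
        "ENHANCER_SCORE_SCALED": lcp.enhancer_score_scaled,
        "TRANSCRIPT_CIS_SCORE_SCALED": lcp.transcript_cis_score_scaled,
        "ENHANCER_CUTOFF": cutoffs.enhancer_cutoff if cutoffs else None,
        "TRANSCRIPT_CUTOFF": cutoffs.transcript_cutoff if cutoffs else None,
        "QUADRANT": lcp.quadrant,
        "N_RBPS_BOUND": lcp.n_rbps_bound,
    }


def write_output_table(lcps: Sequence[LCP], path, cutoffs=None) -> None:
    """Write the main LCP table: one TSV row per pair, fixed 34-column
    schema (:data:`OUTPUT_COLUMNS`), NA for undefined values."""
    with open(path, "w") as fh:
        fh.write("\t".join(OUTPUT_COLUMNS) + "\n")
        for lcp in lcps:
            row = lcp_row(lcp, cutoffs)
            fh.write("\t".join(_fmt(row[c]) for c in OUTPUT_COLUMNS) + "\n")


def read_output_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_misc_table(misc: Sequence[Transcript], sample_names, path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHR\tSTART\tSTOP\tNAME\tTYPE\t" + "\t".join(sample_names) + "\n")
        for t in misc:
            expr = "\t".join(repr(float(v)) for v in t.expression)
            fh.write(f"{t.chrom}\t{t.start}\t{t.stop}\t{t.name}\t{t.ttype}\t{expr}\n")
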