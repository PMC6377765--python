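"""Core domain types.

Coordinates throughout the package are 0-based, half-open ([start, stop)),
the BED convention; two intervals overlap iff their intersection is at
least 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

TRANSCRIPT_TYPES = ("protein_coding", "lncRNA", "antisense_rna", "misc")
LNC_TYPES = ("lncRNA", "antisense_rna")
CHIP_MARKS = ("H3K4me1", "H3K27ac", "H3K4me3")
ECLIP_CELL_LINES = ("K562", "HepG2")
COMPARTMENTS = ("Nuclear", "Cytoplasmic")


@dataclass
class Interval:
    chrom: str
    start: int
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.stop
            and other.start < self.stop
        )


@dataclass
class Transcript:
    """One row of the user expression table.

    ``expression`` holds one non-negative value per sample, in whatever
    units the user supplied (FPKM, CPM, probe intensity, ...). ``strand``
    comes from the gene-annotation track, never from the input table, and
    defaults to "unknown".
    """

    chrom: str
    start: int
    stop: int
    name: str
    ttype: str
    expression: np.ndarray
    strand: str = "unknown"

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.stop)

    @property
    def length(self) -> int:
        return self.stop - self.start

    @property
    def is_lnc(self) -> bool:
        return self.ttype in LNC_TYPES

    @property
    def is_coding(self) -> bool:
        return self.ttype == "protein_coding"


@dataclass
class ChipPeak:
    chrom: str
    start: int
    stop: int
    cell_line: str
    mark: str
    neg_log10_p: float


@dataclass
class ChiaInteraction:
    anchor1: Interval
    anchor2: Interval
    score: float


@dataclass
class EclipRecord:
    chrom: str
    start: int
    stop: int
    rbp_name: str
    cell_line: str
    replicate: int
    score: float


@dataclass
class FractionExpression:
    name: str
    nuclear_fpkm: float
    cytoplasmic_fpkm: float


@dataclass
class RbpLocalization:
    rbp_name: str
    compartments: frozenset


@dataclass
class EnhancerRegion:
    chrom: str
    start: int
    stop: int
    kind: str  # "conventional" | "super"

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class PositionClass:
    orientation: str  # overlapping | antisense | distal
    geniality: str  # intergenic | intragenic
    enhancer_class: str  # conventional | super | none


@dataclass
class ScoreCutoffs:
    enhancer_cutoff: Optional[float]
    transcript_cutoff: Optional[float]
    method: str = "inflection"
    seed: Optional[int] = None


@dataclass
class LCP:
    """A lncRNA x coding-gene pair: the unit the pipeline scores.

    Annotation and score fields are filled in stage by stage; ``None``
    means not yet computed or undefined (e.g. a constant expression
    vector makes the correlation undefined).
    """

    lnc: Transcript
    gene: Transcript
    distance: int
    rho: Optional[float] = None
    p: Optional[float] = None
    adj_p: Optional[float] = None
    zscore: Optional[float] = None
    outlier: bool = False
    chia_score: float = 0.0
    h3k4me1: float = 0.0
    h3k27ac: float = 0.0
    h3k4me3: float = 0.0
    nuclear_fraction: Optional[float] = None
    localization: Optional[str] = None
    position: Optional[PositionClass] = None
    tad_overlap: bool = False
    enhancer_score: Optional[float] = None
    transcript_cis_score: Optional[float] = None
    enhancer_score_scaled: Optional[float] = None
    transcript_cis_score_scaled: Optional[float] = None
    quadrant: Optional[str] = None
    n_rbps_bound: int = 0


@dataclass
class InteractomeEntry:
    """One lncRNA x RBP cell of the eCLIP interactome."""

    lnc_name: str
    rbp_name: str
    bound: int
    n_sites: int
    density: Optional[float]
    concordance: Optional[int]
    lnc_class: Optional[str]
    rbp_compartments: frozenset
    lnc_expression: Optional[float] = None
    rbp_expression: Optional[float] = None
    extended_rule: bool = False


@dataclass
class AnnotationBundle:
    """All optional annotation tracks; absent tracks are empty lists and
    contribute zero to every downstream score."""

    chip_peaks: list = field(default_factory=list)
    enhancers: list = field(default_factory=list)
    chia_interactions: list = field(default_factory=list)
    eclip_records: list = field(default_factory=list)
    fractions: dict = field(default_factory=dict)  # name -> FractionExpression
    rbp_localizations: dict = field(default_factory=dict)  # rbp -> RbpLocalization
    tad_boundaries: list = field(default_factory=list)  # Interval
    gene_annotation: dict = field(default_factory=dict)  # name -> (strand, description)
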