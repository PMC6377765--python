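"""End-to-end orchestration: parse -> pair -> correlate -> annotate ->
score -> interactome -> write.

Every stage logs record counts so a run is auditable; with a fixed seed
the whole output set is byte-identical across re-runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotation, correlation, interactome, io, pairs, scoring
from .types import LCP

log = logging.getLogger("plaidoh")


@dataclass
class RunConfig:
    input_path: str
    tracks: Dict[str, str] = field(default_factory=dict)
    outdir: str = "plaidoh_out"
    window_bp: int = pairs.DEFAULT_WINDOW
    alpha_quadrant: float = correlation.ALPHA_QUADRANT
    alpha_matrix: float = correlation.ALPHA_MATRIX
    seed: int = 0
    log_base: float = 10.0
    strict_binding: bool = False
    swap_malformed: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha_quadrant < 1 or not 0 < self.alpha_matrix < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window must be positive")


@dataclass
class RunResult:
    lcps: List[LCP]
    cutoffs: scoring.ScoreCutoffs
    interactome_entries: list
    outputs: Dict[str, Path]


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = io.parse_expression_table(config.input_path, swap_malformed=config.swap_malformed)
    bundle = io.parse_annotation_bundle(config.tracks)
    for t in table.transcripts:
        ann = bundle.gene_annotation.get(t.name)
        if ann:
            t.strand = ann[0]
    log.info(
        "stage parse: %d transcripts (%d misc), %d rejected rows",
        len(table.transcripts), len(table.misc), len(table.rejected),
    )

    lcps = pairs.find_lcps(table.active, window=config.window_bp)
    log.info("stage pair: %d LCPs within %d bp", len(lcps), config.window_bp)

    correlation.annotate_correlations(lcps)
    annotation.annotate_epigenome(lcps, bundle)

    coding = [t for t in table.active if t.is_coding]
    gene_index = None
    enh_index = None
    pos_cache: dict = {}
    for lcp in lcps:
        if lcp.lnc.name not in pos_cache:
            pos_cache[lcp.lnc.name] = pairs.classify_position(
                lcp.lnc, coding, bundle.enhancers
            )
        lcp.position = pos_cache[lcp.lnc.name]

    cutoffs = scoring.score_lcps(lcps, seed=config.seed, log_base=config.log_base)
    log.info(
        "stage score: cutoffs enhancer=%s transcript=%s",
        cutoffs.enhancer_cutoff, cutoffs.transcript_cutoff,
    )

    lnc_transcripts = [t for t in table.active if t.is_lnc]
    entries = interactome.build_interaction_matrix(
        lnc_transcripts + coding, bundle, strict=config.strict_binding
    )
    per_lnc, _ = interactome.specificity_counts(entries)
    for lcp in lcps:
        lcp.n_rbps_bound = per_lnc.get(lcp.lnc.name, 0)
    log.info("stage interactome: %d entries, %d bound", len(entries),
             sum(e.bound for e in entries))

    outputs = _write_outputs(config, outdir, table, lcps, cutoffs, entries, bundle)
    return RunResult(lcps, cutoffs, entries, outputs)


def _write_outputs(config, outdir, table, lcps, cutoffs, entries, bundle) -> Dict[str, Path]:
    out: Dict[str, Path] = {}

    out["lcps"] = outdir / "lcps.tsv"
    io.write_output_table(lcps, out["lcps"], cutoffs)

    out["misc"] = outdir / "misc.tsv"
    io.write_misc_table(table.misc, table.sample_names, out["misc"])

    out["interactome"] = outdir / "interactome.tsv"
    interactome.interactome_dataframe(entries).to_csv(
        out["interactome"], sep="\t", index=False, na_rep="NA"
    )
    out["interactome_matrix"] = outdir / "interactome_matrix.tsv"
    mat = interactome.concordance_matrix(entries)
    mat.to_csv(out["interactome_matrix"], sep="\t", na_rep="NA")

    out["frequency_matrix"] = outdir / "frequency_matrix.tsv"
    correlation.frequency_matrix(lcps, alpha=config.alpha_matrix).to_dataframe().to_csv(
        out["frequency_matrix"], sep="\t", index=False
    )

    out["zscore_distance"] = outdir / "zscore_distance.tsv"
    pd.DataFrame(
        [
            {
                "LNC_NAME": l.lnc.name,
                "GENE_NAME": l.gene.name,
                "DISTANCE": l.distance,
                "SPEARMAN_RHO": l.rho,
                "ZSCORE": l.zscore,
                "OUTLIER": int(l.outlier),
            }
            for l in lcps
        ],
        columns=["LNC_NAME", "GENE_NAME", "DISTANCE", "SPEARMAN_RHO", "ZSCORE", "OUTLIER"],
    ).to_csv(out["zscore_distance"], sep="\t", index=False, na_rep="NA")

    for label, attr in (("enhancer", "enhancer_score"), ("transcript", "transcript_cis_score")):
        path = outdir / f"ranked_{label}_scores.tsv"
        scores = [getattr(l, attr) for l in lcps]
        ranks = scoring.rank_scores(scores, seed=config.seed)
        cutoff = cutoffs.enhancer_cutoff if label == "enhancer" else cutoffs.transcript_cutoff
        scaled = scoring.scale_to_100(scores)
        pd.DataFrame(
            {
                "LNC_NAME": [l.lnc.name for l in lcps],
                "GENE_NAME": [l.gene.name for l in lcps],
                "RANK": ranks,
                "SCORE": [s if s is not None else np.nan for s in scores],
                "SCORE_SCALED": scaled,
                "ABOVE_CUTOFF": [
                    int(s is not None and cutoff is not None and s > cutoff) for s in scores
                ],
            }
        ).sort_values("RANK").to_csv(path, sep="\t", index=False, na_rep="NA")
        out[f"ranked_{label}"] = path

    out["enhancer_density"] = outdir / "enhancer_lncrna_density.tsv"
    dens = pairs.lncrnas_per_kb(bundle.enhancers, [t for t in table.active if t.is_lnc])
    pd.DataFrame(
        [
            {
                "CHR": e.chrom, "START": e.start, "STOP": e.stop, "KIND": e.kind,
                "N_LNCRNAS": n, "PER_KB": d,
            }
            for e, n, d in dens
        ],
        columns=["CHR", "START", "STOP", "KIND", "N_LNCRNAS", "PER_KB"],
    ).to_csv(out["enhancer_density"], sep="\t", index=False)
    return out


def compare_datasets(
    lcp_tables: Dict[str, str], outdir, alpha: float = correlation.ALPHA_QUADRANT
):
    """Cross-dataset conservation from previously written LCP tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {name: io.read_output_table(path) for name, path in lcp_tables.items()}
    matrix, patterns, sign_split = correlation.cross_dataset_conservation(frames, alpha=alpha)
    matrix_path = outdir / "conservation_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    counts_path = outdir / "conservation_counts.tsv"
    with open(counts_path, "w") as fh:
        fh.write("N_DATASETS\tN_LCPS\tN_POSITIVE\tN_NEGATIVE\n")
        for k in sorted(patterns):
            fh.write(
                f"{k}\t{patterns[k]}\t{sign_split['positive'].get(k, 0)}\t"
                f"{sign_split['negative'].get(k, 0)}\n"
            )
    return matrix, patterns, sign_split
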