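"""Synthetic toy datasets with planted ground truth.

Generates a complete miniature input set — expression table plus every
annotation track — on a toy genome, with a manifest recording each
planted fact so tests can assert recovery. Defaults emulate one study
dataset: 48 expression samples, 2 chromosomes of 5 Mb, 20 lncRNAs and 60
coding genes arranged in blocks so every lncRNA has several coding
neighbours inside the 400 kb flanking window.

Planted expression correlations are drawn from a bivariate Gaussian at
the target rho and exponentiated; the monotone transform preserves rank
correlation, so planted Spearman signal survives the positivity
transform exactly in expectation. Everything is driven by one seed:
identical spec + seed gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic dataset."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_lncs: int = 20
    n_genes: int = 60
    n_samples: int = 48
    window_bp: int = 400_000
    # (lnc_name, gene_name, rho_target in (-1, 1))
    planted_correlations: List[Tuple[str, str, float]] = field(default_factory=list)
    # (lnc_name, gene_name, chia_score)
    planted_loops: List[Tuple[str, str, float]] = field(default_factory=list)
    # lnc_name -> (h3k4me1, h3k27ac, h3k4me3) -log10 peak p
    planted_marks: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    # (lnc_name, rbp_name, [(cell_line, replicate), ...]) score-1000 records
    planted_bindings: List[Tuple[str, str, List[Tuple[str, int]]]] = field(
        default_factory=list
    )
    # lnc_name -> nuclear fraction in [0, 1]
    lnc_fractions: Dict[str, float] = field(default_factory=dict)
    # rbp_name -> compartments subset of {Nuclear, Cytoplasmic}
    rbp_compartments: Dict[str, List[str]] = field(default_factory=dict)
    # lnc_name -> enhancer kind ("conventional" | "super")
    planted_enhancers: Dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def lnc_name(self, i: int) -> str:
        return f"LNC{i + 1:03d}"

    def gene_name(self, i: int) -> str:
        return f"GENE{i + 1:03d}"


BLOCK_SPACING = 200_000  # between lncRNA anchors on one chromosome
LNC_LENGTH = 2_000
GENE_LENGTH = 2_000
GENE_OFFSETS = (20_000, 60_000, 100_000)  # gene starts relative to block base


def _layout(spec: FixtureSpec) -> List[dict]:
    """Deterministic placement: blocks of 1 lncRNA + up to 3 coding genes,
    round-robin across chromosomes; all block members sit well inside the
    window of their lncRNA."""
    per_chrom_blocks = -(-spec.n_lncs // spec.n_chroms)
    if (per_chrom_blocks * BLOCK_SPACING + max(GENE_OFFSETS) + GENE_LENGTH) > spec.chrom_length:
        raise ValueError("fixture spec infeasible: blocks exceed chromosome length")
    rows = []
    gene_i = 0
    for i in range(spec.n_lncs):
        chrom = f"chr{i % spec.n_chroms + 1}"
        base = (i // spec.n_chroms) * BLOCK_SPACING + 10_000
        rows.append(
            {
                "name": spec.lnc_name(i),
                "chrom": chrom,
                "start": base,
                "stop": base + LNC_LENGTH,
                "ttype": "lncRNA" if i % 5 else "antisense_rna",
            }
        )
        for off in GENE_OFFSETS:
            if gene_i >= spec.n_genes:
                break
            rows.append(
                {
                    "name": spec.gene_name(gene_i),
                    "chrom": chrom,
                    "start": base + off,
                    "stop": base + off + GENE_LENGTH,
                    "ttype": "protein_coding",
                }
            )
            gene_i += 1
    while gene_i < spec.n_genes:  # spill extra genes onto trailing blocks
        chrom = f"chr{gene_i % spec.n_chroms + 1}"
        base = (per_chrom_blocks + gene_i // spec.n_chroms) * BLOCK_SPACING + 10_000
        rows.append(
            {
                "name": spec.gene_name(gene_i),
                "chrom": chrom,
                "start": base,
                "stop": base + GENE_LENGTH,
                "ttype": "protein_coding",
            }
        )
        gene_i += 1
    return rows


def _expression(spec: FixtureSpec, names: List[str], rng) -> np.ndarray:
    """Log-normal expression; planted pairs share a Gaussian copula at
    the target rho before exponentiation."""
    n = len(names)
    z = rng.standard_normal((n, spec.n_samples))
    idx = {name: i for i, name in enumerate(names)}
    for lnc, gene, rho in spec.planted_correlations:
        if not -1 < rho < 1:
            raise ValueError(f"rho_target must lie in (-1, 1), got {rho}")
        a = rng.standard_normal(spec.n_samples)
        eps = rng.standard_normal(spec.n_samples)
        z[idx[lnc]] = a
        z[idx[gene]] = rho * a + np.sqrt(1 - rho * rho) * eps
    return np.exp(1.0 + z)


def generate_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write the dataset to ``outdir``; returns a manifest dict that is
    also saved as manifest.yaml. The manifest's ``tracks`` sub-dict plugs
    straight into :func:`plaidoh.io.parse_annotation_bundle`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = _layout(spec)
    known = {r["name"] for r in rows}
    for lnc, gene, _ in spec.planted_correlations + spec.planted_loops:
        if lnc not in known or gene not in known:
            raise ValueError(f"planted pair ({lnc}, {gene}) references unknown transcripts")

    names = [r["name"] for r in rows]
    expr = _expression(spec, names, rng)

    # expression table, sorted by (CHR, START) as the parser requires
    order = sorted(range(len(rows)), key=lambda i: (rows[i]["chrom"], rows[i]["start"]))
    sample_names = [f"SAMPLE_{j + 1}" for j in range(spec.n_samples)]
    input_path = outdir / "expression.tsv"
    with open(input_path, "w") as fh:
        fh.write("#CHR\tSTART\tSTOP\tNAME\tTYPE\t" + "\t".join(sample_names) + "\n")
        for i in order:
            r = rows[i]
            vals = "\t".join(repr(float(v)) for v in expr[i])
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['stop']}\t{r['name']}\t{r['ttype']}\t{vals}\n")

    by_name = {r["name"]: r for r in rows}

    # ChIP peaks: planted marks as single peaks spanning the lncRNA
    chip_path = outdir / "chip_peaks.bed"
    mark_names = ("H3K4me1", "H3K27ac", "H3K4me3")
    with open(chip_path, "w") as fh:
        for lnc, intensities in sorted(spec.planted_marks.items()):
            r = by_name[lnc]
            for mark, val in zip(mark_names, intensities):
                if val > 0:
                    fh.write(
                        f"{r['chrom']}\t{r['start'] - 200}\t{r['stop'] + 200}\t"
                        f"K562\t{mark}\t{val}\n"
                    )

    # enhancer tracks
    enh_path = outdir / "enhancers.bed"
    super_path = outdir / "super_enhancers.bed"
    with open(enh_path, "w") as fe, open(super_path, "w") as fs:
        for lnc, kind in sorted(spec.planted_enhancers.items()):
            r = by_name[lnc]
            line = f"{r['chrom']}\t{r['start'] - 500}\t{r['stop'] + 500}\n"
            (fs if kind == "super" else fe).write(line)

    # ChIA-PET loops: anchors on the lncRNA and its target gene
    chia_path = outdir / "chia.tsv"
    with open(chia_path, "w") as fh:
        for lnc, gene, score in spec.planted_loops:
            a, b = by_name[lnc], by_name[gene]
            fh.write(
                f"{a['chrom']}\t{a['start']}\t{a['stop']}\t"
                f"{b['chrom']}\t{b['start']}\t{b['stop']}\t{score}\n"
            )

    # eCLIP: planted score-1000 records per replicate pattern, plus one
    # sub-threshold background record per lncRNA-RBP pair
    eclip_path = outdir / "eclip.bed"
    with open(eclip_path, "w") as fh:
        for lnc, rbp, pattern in spec.planted_bindings:
            r = by_name[lnc]
            mid = (r["start"] + r["stop"]) // 2
            for cell, rep in pattern:
                fh.write(f"{r['chrom']}\t{mid - 50}\t{mid + 50}\t{rbp}\t{cell}\t{rep}\t1000\n")
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['start'] + 40}\t{rbp}\tK562\t1\t200\n")

    # nuclear / cytoplasmic fractionation
    frac_path = outdir / "fractions.tsv"
    with open(frac_path, "w") as fh:
        fh.write("#NAME\tNUCLEAR_FPKM\tCYTOPLASMIC_FPKM\n")
        for lnc, f in sorted(spec.lnc_fractions.items()):
            fh.write(f"{lnc}\t{round(f * 100, 6)}\t{round((1 - f) * 100, 6)}\n")

    # RBP immunofluorescence compartments
    loc_path = outdir / "rbp_localizations.tsv"
    with open(loc_path, "w") as fh:
        fh.write("#RBP\tCOMPARTMENTS\n")
        for rbp, comps in sorted(spec.rbp_compartments.items()):
            fh.write(f"{rbp}\t{','.join(sorted(comps))}\n")

    # one TAD spanning each chromosome's populated region
    tad_path = outdir / "tads.bed"
    with open(tad_path, "w") as fh:
        for c in range(spec.n_chroms):
            fh.write(f"chr{c + 1}\t0\t{spec.chrom_length}\n")

    # gene annotation: deterministic alternating strand
    ann_path = outdir / "gene_annotation.tsv"
    with open(ann_path, "w") as fh:
        fh.write("#NAME\tSTRAND\tDESCRIPTION\n")
        for i, r in enumerate(rows):
            fh.write(f"{r['name']}\t{'+' if i % 2 == 0 else '-'}\tsynthetic {r['ttype']}\n")

    manifest = {
        "seed": spec.seed,
        "n_samples": spec.n_samples,
        "window_bp": spec.window_bp,
        "input": str(input_path),
        "tracks": {
            "chip": str(chip_path),
            "enhancers": str(enh_path),
            "super_enhancers": str(super_path),
            "chia": str(chia_path),
            "eclip": str(eclip_path),
            "fractions": str(frac_path),
            "rbp_localizations": str(loc_path),
            "tads": str(tad_path),
            "gene_annotation": str(ann_path),
        },
        "planted": {
            "correlations": [list(t) for t in spec.planted_correlations],
            "loops": [list(t) for t in spec.planted_loops],
            "marks": {k: list(v) for k, v in spec.planted_marks.items()},
            "bindings": [
                [lnc, rbp, [list(p) for p in pattern]]
                for lnc, rbp, pattern in spec.planted_bindings
            ],
            "lnc_fractions": dict(spec.lnc_fractions),
            "rbp_compartments": {k: sorted(v) for k, v in spec.rbp_compartments.items()},
            "enhancers": dict(spec.planted_enhancers),
        },
        "transcripts": [
            {k: r[k] for k in ("name", "chrom", "start", "stop", "ttype")} for r in rows
        ],
    }
    # on disk the manifest stays location-independent (file names only),
    # so identical spec+seed gives byte-identical output anywhere
    portable = dict(manifest)
    portable["input"] = Path(manifest["input"]).name
    portable["tracks"] = {k: Path(v).name for k, v in manifest["tracks"].items()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(portable, fh, sort_keys=True)
    return manifest


def demo_spec(seed: int = 0) -> FixtureSpec:
    """A fully planted dataset exercising every pipeline stage.

    Plants two enhancer-driven lncRNAs (strong H3K4me1/H3K27ac and a
    90-unit loop to a neighbour gene, null correlation), two
    transcript-driven lncRNAs (rho 0.95 to a neighbour, strong H3K4me3,
    nuclear), and one highly expressed nuclear lncRNA bound by two
    nuclear RBPs — the classic paraspeckle pattern.
    """
    spec = FixtureSpec(seed=seed)
    # block layout pairs LNC00k with GENE{3k-2, 3k-1, 3k} (1-based)
    spec.planted_marks = {
        "LNC002": (9.0, 10.0, 0.0),
        "LNC004": (8.5, 9.5, 0.0),
        "LNC006": (0.0, 0.0, 8.0),
        "LNC008": (0.0, 0.0, 9.0),
    }
    spec.planted_loops = [("LNC002", "GENE004", 90.0), ("LNC004", "GENE010", 85.0)]
    spec.planted_correlations = [
        ("LNC006", "GENE016", 0.95),
        ("LNC008", "GENE022", 0.95),
    ]
    spec.lnc_fractions = {
        "LNC002": 0.2,
        "LNC004": 0.25,
        "LNC006": 0.9,
        "LNC008": 0.85,
        "LNC010": 0.95,
        "LNC012": 0.5,
    }
    spec.planted_bindings = [
        ("LNC010", "NONO", [("K562", 1), ("K562", 2)]),
        ("LNC010", "SFPQ", [("K562", 1), ("HepG2", 1)]),
        ("LNC012", "PUM2", [("HepG2", 1)]),  # single replicate: not bound
    ]
    spec.rbp_compartments = {
        "NONO": ["Nuclear"],
        "SFPQ": ["Nuclear"],
        "PUM2": ["Cytoplasmic"],
    }
    spec.planted_enhancers = {"LNC002": "super", "LNC004": "conventional"}
    return spec
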