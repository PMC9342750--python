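"""Gene-locus mapping and per-chromosome / per-arm summaries.

Genes are placed on a chromosome model (length, centromere midpoint,
acrocentric flag) using 1-based inclusive Ensembl-style coordinates.  Arm
assignment compares the gene start to the centromere midpoint; genes that
span the centromere go to the arm of their start.  Summaries report coding,
membrane and detected counts per (chromosome, arm) along with per-hallmark
percentages, and export Circos-style whitespace-delimited text tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hallmark_db import HallmarkDB

logger = logging.getLogger(__name__)

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"{self.gene}: chromosome {self.chromosome!r} not in 1-22/X/Y")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene}: invalid span {self.start}-{self.end}")


@dataclass(frozen=True)
class ChromosomeModel:
    chromosome: str
    length: int
    centromere_mid: int
    acrocentric: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.centromere_mid < self.length):
            raise ValueError(f"chr{self.chromosome}: centromere outside (0, length)")


def load_chromosome_model(path: str | Path | None = None) -> dict[str, ChromosomeModel]:
    """Load the chromosome model table (the shipped default when path=None)."""
    if path is None:
        with resources.as_file(
            resources.files("hallmarkmap.data").joinpath("chromosomes.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return {
        r.chromosome: ChromosomeModel(
            chromosome=r.chromosome,
            length=int(r.length),
            centromere_mid=int(r.centromere_mid),
            acrocentric=bool(int(r.acrocentric)),
        )
        for r in df.itertuples(index=False)
    }


def assign_arm(locus: GeneLocus, model: ChromosomeModel) -> str:
    """Return "p" or "q" for a locus: p iff gene start precedes the centromere."""
    if locus.chromosome != model.chromosome:
        raise ValueError(f"{locus.gene}: locus on chr{locus.chromosome}, model is chr{model.chromosome}")
    if locus.end > model.length:
        raise ValueError(f"{locus.gene}: end {locus.end} beyond chr{model.chromosome} length {model.length}")
    return "p" if locus.start < model.centromere_mid else "q"


def read_loci(path: str | Path) -> dict[str, GeneLocus]:
    """Read a gene-locus TSV (gene, chromosome, start, end).

    Duplicate identical rows are a validation error; a symbol mapped to
    several distinct loci resolves to the first by (chromosome, start) with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    missing = {"gene", "chromosome", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing locus columns {sorted(missing)}")
    if df.duplicated().any():
        dup = df.loc[df.duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene→locus row for {dup!r}")
    loci: dict[str, GeneLocus] = {}
    multi = 0
    order = df.sort_values(["chromosome", "start"], kind="mergesort")
    for r in order.itertuples(index=False):
        if r.gene in loci:
            multi += 1
            continue
        loci[r.gene] = GeneLocus(gene=r.gene, chromosome=r.chromosome, start=int(r.start), end=int(r.end))
    if multi:
        logger.warning("read_loci: %d multi-locus symbol(s) resolved to first by (chromosome, start)", multi)
    return loci


def chromosome_summary(
    loci: Mapping[str, GeneLocus],
    db: HallmarkDB | None,
    detected_genes: set[str],
    membrane_genes: set[str],
    models: Mapping[str, ChromosomeModel],
    gene_of_accession: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(chromosome, arm) counts and percentages.

    Returns the summary table and the sorted list of detected genes with no
    locus (the "unmapped sidecar") — nothing is silently dropped.  Hallmark
    membership percentages are per-hallmark fractions of coding genes on the
    arm and may sum above 100 because of multi-membership.
    """
    unmapped = sorted(g for g in detected_genes if g not in loci)

    hall_genes: dict[int, set[str]] = {}
    if db is not None:
        acc2gene = gene_of_accession or {}
        for h, accs in db.by_hallmark.items():
            hall_genes[h] = {acc2gene.get(a, a) for a in accs}

    rows = []
    for chrom in CHROMOSOMES:
        model = models[chrom]
        for arm in ("p", "q"):
            genes = [
                g for g, loc in loci.items()
                if loc.chromosome == chrom and assign_arm(loc, model) == arm
            ]
            n_coding = len(genes)
            gene_set = set(genes)
            n_membrane = len(gene_set & membrane_genes)
            n_detected = len(gene_set & detected_genes)
            row = {
                "chromosome": chrom,
                "arm": arm,
                "n_coding": n_coding,
                "n_membrane": n_membrane,
                "n_detected": n_detected,
                "pct_membrane_of_coding": round(100 * n_membrane / n_coding, 4) if n_coding else 0.0,
                "pct_detected_of_coding": round(100 * n_detected / n_coding, 4) if n_coding else 0.0,
            }
            for h in sorted(hall_genes):
                n_h = len(gene_set & hall_genes[h])
                row[f"pct_hallmark_{h}"] = round(100 * n_h / n_coding, 4) if n_coding else 0.0
            rows.append(row)
    return pd.DataFrame(rows), unmapped


def circos_track_export(
    entries: Iterable[tuple[GeneLocus, float]],
    path: str | Path | None = None,
) -> str:
    """Emit a Circos-style text track: ``chromosome start end value`` lines.

    Rows are ordered by (chromosome, start) for deterministic output; the
    first line is a header comment.  Returns the track text (and writes it to
    ``path`` when given).
    """
    chrom_rank = {c: i for i, c in enumerate(CHROMOSOMES)}
    ordered = sorted(entries, key=lambda e: (chrom_rank[e[0].chromosome], e[0].start, e[0].gene))
    lines = ["# chromosome start end value"]
    for loc, value in ordered:
        lines.append(f"{loc.chromosome} {loc.start} {loc.end} {value:g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
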