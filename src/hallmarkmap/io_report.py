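"""Pipeline configuration, orchestration and the report bundle.

``run_pipeline`` chains the stages — hallmark assignment, evidence
filtering, genome summaries, catalogue cross-referencing and PPI network
analysis — into one deterministic report bundle: fixed column orders, UNIX
newlines, JSON with sorted keys, and a run manifest carrying input
checksums, parameters and the tool version so identical manifests imply
identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .hallmark_db import (
    assign_hallmarks,
    hallmark_counts,
    load_hallmark_definitions,
    membership_table,
    read_annotations,
)
from .evidence_filter import detected_table, filter_high_quality, read_evidence
from .genome_map import (
    chromosome_summary,
    circos_track_export,
    load_chromosome_model,
    read_loci,
)
from .cancer_crossref import (
    build_representative_set,
    crossref_cgc,
    overlap_report,
    read_cgc,
    read_drug_targets,
)
from . import ppi_network as ppi

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    annotations: str
    evidence: str
    loci: str
    cgc: str
    drug_targets: str
    literature: str
    ppi_edges: str
    out_dir: str
    hallmark_definitions: str | None = None
    chromosome_model: str | None = None
    min_unique: int = 2
    max_fdr: float = 0.03
    ppi_threshold: float = 0.9
    degree_cutoff: int = 6
    node_scope: str = "all"
    approved_only: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "annotations": self.annotations,
            "evidence": self.evidence,
            "loci": self.loci,
            "cgc": self.cgc,
            "drug_targets": self.drug_targets,
            "literature": self.literature,
            "ppi_edges": self.ppi_edges,
        }
        if self.hallmark_definitions:
            paths["hallmark_definitions"] = self.hallmark_definitions
        if self.chromosome_model:
            paths["chromosome_model"] = self.chromosome_model
        return paths

    def validate(self) -> None:
        if not (1 <= self.min_unique):
            raise PipelineError("config: min_unique must be >= 1")
        if self.max_fdr not in (0.01, 0.03):
            raise PipelineError("config: max_fdr must be 0.01 or 0.03")
        if not (0.0 <= self.ppi_threshold <= 1.0):
            raise PipelineError("config: ppi_threshold must lie in [0, 1]")
        missing = [p for p in self.input_paths().values() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"config: missing input file(s): {missing}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``cfg.out_dir``.

    Returns a summary dict of the headline counts.  Any stage failure aborts
    with the stage name; inputs are validated before the first output is
    written.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: hallmark database -------------------------------------
    try:
        defs = load_hallmark_definitions(cfg.hallmark_definitions)
        annotations = read_annotations(cfg.annotations)
        db = assign_hallmarks(annotations, defs)
    except Exception as exc:
        raise PipelineError(f"hallmark_db: {exc}") from exc
    gene_of_acc = {a.accession: a.gene for a in annotations}
    membrane_accs = {a.accession for a in annotations if a.membrane_flag}

    _write_tsv(membership_table(db), out / "protein_hallmarks.tsv")
    _write_tsv(hallmark_counts(db), out / "hallmark_counts.tsv")

    # -- stage 2: evidence filter ----------------------------------------
    try:
        evidence = read_evidence(cfg.evidence)
        detected = filter_high_quality(
            evidence,
            min_unique=cfg.min_unique,
            max_fdr=cfg.max_fdr,
            membrane_flags={a: a in membrane_accs for a in gene_of_acc},
        )
    except Exception as exc:
        raise PipelineError(f"evidence_filter: {exc}") from exc
    _write_tsv(detected_table(detected), out / "detected_proteins.tsv")
    detected_accs = {d.accession for d in detected}

    # -- stage 3: genome map ----------------------------------------------
    try:
        loci = read_loci(cfg.loci)
        models = load_chromosome_model(cfg.chromosome_model)
        detected_genes = {gene_of_acc.get(a, a) for a in detected_accs}
        membrane_genes = {gene_of_acc[a] for a in membrane_accs if a in gene_of_acc}
        summary, unmapped = chromosome_summary(
            loci, db, detected_genes, membrane_genes, models, gene_of_acc
        )
    except Exception as exc:
        raise PipelineError(f"genome_map: {exc}") from exc
    _write_tsv(summary, out / "chromosome_summary.tsv")
    (out / "unmapped_genes.txt").write_text("\n".join(unmapped) + ("\n" if unmapped else ""))
    abundance_entries = [
        (loci[g], d.log_abundance)
        for d in detected
        for g in [gene_of_acc.get(d.accession, d.accession)]
        if g in loci
    ]
    circos_track_export(abundance_entries, out / "circos_abundance.txt")

    # -- stage 4: cancer crossref -----------------------------------------
    try:
        cgc = read_cgc(cfg.cgc)
        drug_targets = read_drug_targets(cfg.drug_targets)
        if cfg.approved_only:
            drug_targets = [t for t in drug_targets if t.status == "approved"]
        literature = [
            g.strip() for g in Path(cfg.literature).read_text().splitlines() if g.strip()
        ]
        hallmark_accs = set(db.by_protein)
        detected_membrane_hallmark = {
            gene_of_acc[a]
            for a in detected_accs & membrane_accs & hallmark_accs
            if a in gene_of_acc
        }
        matched, crossref_summary = crossref_cgc(detected_membrane_hallmark, cgc)
        rep = build_representative_set({r.gene for r in matched}, literature)
        onco = {r.gene for r in matched if r.role == "oncogene"}
        supp = {r.gene for r in matched if r.role == "suppressor"}
        dual = {r.gene for r in matched if r.role == "dual"}
        target_genes = {t.gene for t in drug_targets}
        regions = overlap_report(onco, supp, dual, target_genes & rep.members)
    except Exception as exc:
        raise PipelineError(f"cancer_crossref: {exc}") from exc
    _write_tsv(crossref_summary, out / "crossref_summary.tsv")
    rep_df = pd.DataFrame(
        [{"gene": g, "provenance": rep.provenance[g]} for g in sorted(rep.members)],
        columns=["gene", "provenance"],
    )
    _write_tsv(rep_df, out / "representative_set.tsv")
    _write_json(regions, out / "overlap_report.json")

    # -- stage 5: PPI network ---------------------------------------------
    try:
        edges = ppi.read_edges(cfg.ppi_edges)
        node_universe = sorted(rep.members | {e.a for e in edges} | {e.b for e in edges})
        graph = ppi.build_graph(node_universe, edges, threshold=cfg.ppi_threshold)
        records = ppi.centrality_table(graph)
        stats = ppi.network_stats(graph, node_scope=cfg.node_scope)
        report = ppi.prioritize_targets(
            records, target_genes & set(node_universe), degree_cutoff=cfg.degree_cutoff
        )
        order = ppi.attribute_circle_order({r.node: r.degree for r in records})
    except Exception as exc:
        raise PipelineError(f"ppi_network: {exc}") from exc
    cent_df = pd.DataFrame(
        [
            {
                "node": r.node,
                "degree": r.degree,
                "betweenness": round(r.betweenness, 9),
                "clustering": round(r.clustering, 9),
            }
            for r in records
        ],
        columns=["node", "degree", "betweenness", "clustering"],
    )
    _write_tsv(cent_df, out / "centrality.tsv")
    _write_json(stats.as_dict(), out / "network_stats.json")
    _write_json(report, out / "prioritization.json")
    _write_tsv(
        pd.DataFrame({"rank": range(1, len(order) + 1), "node": order}),
        out / "circle_order_degree.tsv",
    )

    # -- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": {
            k: getattr(cfg, k)
            for k in (
                "min_unique", "max_fdr", "ppi_threshold", "degree_cutoff",
                "node_scope", "approved_only", "seed",
            )
        },
        "input_checksums": {k: _sha256(p) for k, p in sorted(cfg.input_paths().items())},
    }
    _write_json(manifest, out / "manifest.json")

    headline = {
        "n_annotated": len(annotations),
        "n_hallmark_mapped": len(db.by_protein),
        "n_detected": len(detected),
        "n_detected_membrane_hallmark": len(detected_membrane_hallmark),
        "n_cgc_matched": int(crossref_summary.loc[0, "n_matched"]),
        "representative_set_size": len(rep.members),
        "n_edges_kept": graph.number_of_edges(),
        "n_targets_degree_ge_1": report["n_targets_degree_ge_1"],
    }
    logger.info("run_pipeline: %s", headline)
    return headline
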