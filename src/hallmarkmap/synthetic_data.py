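"""Synthetic input generator with known ground truth.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage is testable without external downloads: proteins carry 0-10
hallmark memberships drawn from a configurable multiplicity distribution
(GO terms sampled from the hallmark term lists, plus decoy terms matching
nothing); detection follows a logistic curve on a latent log10 abundance;
spectral counts are negative-binomial per (method, replicate, injection)
cell; the PPI topology is preferential-attachment growth with planted
high-degree hubs enriched among drug targets; gene loci avoid centromeres
and acrocentric p-arms.  One global seed drives independent per-module
substreams, so any table can be regenerated in isolation and identical
seeds give byte-identical output.

Because hallmark definitions share terms (autophagy, hypoxia response, p53
signaling each appear under two hallmarks), the ground-truth hallmark set
recorded for a protein is the membership implied by its emitted terms,
recomputed here with a brute-force double loop that is independent of the
assignment code it is later used to check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hallmark_db import (
    HallmarkDefinition,
    expand_terms,
    load_hallmark_definitions,
    normalize_label,
)
from .genome_map import ChromosomeModel, load_chromosome_model

#: Decoy GO-process labels guaranteed to match no hallmark definition.
DECOY_TERMS = (
    "cilium assembly",
    "mRNA splicing via spliceosome",
    "ribosome biogenesis",
    "tRNA aminoacylation",
    "visual perception",
    "sensory perception of smell",
    "keratinization",
    "bone mineralization",
    "synaptic vesicle cycle",
    "melanin biosynthetic process",
)

METHODS = ("biotin", "glycan", "shave")


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults model a 5,000-protein proteome with mean hallmark multiplicity
    around 1.7, a 40% membrane fraction (membrane proteins are ~35-40% of
    the genes coded per chromosome), logistic detection on latent log10
    abundance, and a 200-node preferential-attachment PPI with five planted
    hubs boosted past the expected natural maximum degree (~2*sqrt(n)).
    """

    n_proteins: int = 5000
    multiplicity_probs: tuple[float, ...] = (
        0.25, 0.25, 0.20, 0.12, 0.08, 0.05, 0.03, 0.01, 0.005, 0.003, 0.002,
    )
    membrane_fraction: float = 0.4
    disease_variant_fraction: float = 0.05
    decoy_rate: float = 1.0  # Poisson mean of decoy terms per protein

    # evidence model
    abundance_mean: float = 1.5  # latent log10(SC) scale
    abundance_sd: float = 0.8
    detect_slope: float = 2.0
    detect_mid: float = 1.5
    n_replicates: int = 2
    n_injections: int = 2
    nb_dispersion: float = 2.0
    relaxed_fraction: float = 0.15
    rank1_fraction: float = 0.97

    # PPI model
    ppi_n_nodes: int = 200
    ppi_attachment: int = 2
    n_planted_hubs: int = 5
    hub_boost: int = 30
    score_high_fraction: float = 0.5  # mass of the score mixture at >= 0.9

    # catalogue model
    cancer_fraction: float = 0.10
    tier1_fraction: float = 0.8
    role_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # onco, supp, dual
    hub_target_prob: float = 0.8
    background_target_prob: float = 0.05
    n_literature: int = 31

    seed: int = None  # type: ignore[assignment]  # mandatory

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if len(self.multiplicity_probs) > 11:
            raise ValueError("multiplicity distribution puts mass on >10 hallmarks")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("multiplicity probabilities must sum to 1")
        if abs(sum(self.role_probs) - 1.0) > 1e-9:
            raise ValueError("role probabilities must sum to 1")
        if self.ppi_n_nodes < self.ppi_attachment + 1:
            raise ValueError("ppi_n_nodes must exceed the attachment parameter")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream ``stream`` of the global seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    hallmark_sets: dict[str, list[int]] = field(default_factory=dict)  # accession -> ids
    membrane: dict[str, bool] = field(default_factory=dict)
    detected: list[str] = field(default_factory=list)
    planted_hubs: list[str] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)
    tiers: dict[str, int] = field(default_factory=dict)
    drug_targets: list[str] = field(default_factory=list)
    gene_of_accession: dict[str, str] = field(default_factory=dict)
    loci: dict[str, list] = field(default_factory=dict)  # gene -> [chrom, start, end]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _implied_hallmarks(labels: set[str], defs: list[HallmarkDefinition]) -> set[int]:
    """Brute-force membership scan, independent of hallmark_db.assign_hallmarks."""
    out = set()
    for d in defs:
        for t in expand_terms(d):
            if t in labels:
                out.add(d.hallmark_id)
                break
    return out


def gen_proteome(cfg: SimConfig, defs: list[HallmarkDefinition] | None = None):
    """Annotation table plus ground truth for the synthetic proteome.

    Returns ``(DataFrame, GroundTruth)``; the frame has the annotation-table
    layout (accession, gene, go_terms, membrane_flag, disease_variant).
    """
    defs = defs or load_hallmark_definitions()
    rng = cfg.rng(1)
    probs = np.asarray(cfg.multiplicity_probs, dtype=float)
    hallmark_ids = [d.hallmark_id for d in defs]
    term_pool = {
        d.hallmark_id: sorted(expand_terms(d)) for d in defs
    }

    truth = GroundTruth()
    rows = []
    for i in range(cfg.n_proteins):
        acc = f"P{i:05d}"
        gene = f"G{i:04d}"
        k = int(rng.choice(len(probs), p=probs))
        chosen = sorted(rng.choice(hallmark_ids, size=min(k, len(hallmark_ids)), replace=False).tolist())
        labels: list[str] = []
        for h in chosen:
            pool = term_pool[h]
            n_terms = int(rng.integers(1, 3))  # 1 or 2 terms per planted hallmark
            idx = rng.choice(len(pool), size=min(n_terms, len(pool)), replace=False)
            labels.extend(pool[j] for j in sorted(idx.tolist()))
        n_decoys = int(rng.poisson(cfg.decoy_rate))
        if n_decoys:
            idx = rng.choice(len(DECOY_TERMS), size=min(n_decoys, len(DECOY_TERMS)), replace=False)
            labels.extend(DECOY_TERMS[j] for j in sorted(idx.tolist()))
        membrane = bool(rng.random() < cfg.membrane_fraction)
        disease = bool(rng.random() < cfg.disease_variant_fraction)

        label_set = {normalize_label(t) for t in labels}
        implied = _implied_hallmarks(label_set, defs)
        truth.hallmark_sets[acc] = sorted(implied)
        truth.membrane[acc] = membrane
        truth.gene_of_accession[acc] = gene
        rows.append(
            {
                "accession": acc,
                "gene": gene,
                "go_terms": ";".join(dict.fromkeys(labels)),
                "membrane_flag": int(membrane),
                "disease_variant": int(disease),
            }
        )
    df = pd.DataFrame(rows, columns=["accession", "gene", "go_terms", "membrane_flag", "disease_variant"])
    return df, truth


def gen_evidence(proteome: pd.DataFrame, cfg: SimConfig, truth: GroundTruth | None = None) -> pd.DataFrame:
    """Detection + spectral-count evidence for the synthetic proteome.

    Latent log10 abundance is normal; detection probability is
    ``logistic(slope * (abundance - midpoint))``; detected proteins get a
    zero-truncated unique-peptide count and negative-binomial spectral
    counts per (method, replicate, injection) cell.  Undetected proteins are
    absent from the table.
    """
    rng = cfg.rng(2)
    cells = [
        (m, f"r{r+1}", f"i{j+1}")
        for m in METHODS
        for r in range(cfg.n_replicates)
        for j in range(cfg.n_injections)
    ]
    n_cells = len(cells)
    r_disp = cfg.nb_dispersion

    rows = []
    detected_accs = []
    for row in proteome.itertuples(index=False):
        x = rng.normal(cfg.abundance_mean, cfg.abundance_sd)
        z = np.clip(cfg.detect_slope * (x - cfg.detect_mid), -700.0, 700.0)
        p_detect = 1.0 / (1.0 + np.exp(-z))
        if rng.random() >= p_detect:
            continue
        mu_total = 10.0 ** max(x, 0.0)
        mu_cell = mu_total / n_cells
        p_nb = r_disp / (r_disp + mu_cell)
        sc = rng.negative_binomial(r_disp, p_nb, size=n_cells).astype(int)
        if sc.sum() == 0:
            sc[0] = 1  # a detected protein must have at least one spectrum
        upep = 1 + int(rng.poisson(1.0 + 1.5 * max(x, 0.0)))
        fdr_class = "relaxed" if rng.random() < cfg.relaxed_fraction else "strict"
        rank1 = bool(rng.random() < cfg.rank1_fraction)
        rec = {
            "accession": row.accession,
            "unique_peptides": upep,
            "rank1_only": int(rank1),
            "fdr_class": fdr_class,
        }
        rec.update({".".join(c): int(v) for c, v in zip(cells, sc)})
        rows.append(rec)
        detected_accs.append(row.accession)
    cols = ["accession", "unique_peptides", "rank1_only", "fdr_class"] + [".".join(c) for c in cells]
    df = pd.DataFrame(rows, columns=cols)
    if truth is not None:
        truth.detected = detected_accs
    return df


def gen_ppi(cfg: SimConfig, genes: list[str], truth: GroundTruth | None = None) -> pd.DataFrame:
    """Preferential-attachment PPI edge list with planted hubs.

    Hubs are drawn from the late-arriving (ordinarily low-degree) nodes and
    receive ``hub_boost`` extra random attachments each.  Scores come from a
    two-component uniform mixture, so thresholding at 0.9 retains on average
    ``score_high_fraction`` of the edges.  Node identifiers are the first
    ``ppi_n_nodes`` proteome genes; the table uses the STRING-style header
    (protein1, protein2, combined_score) with integer 0-1000 scores.
    """
    import networkx as nx

    if len(genes) < cfg.ppi_n_nodes:
        raise ValueError("not enough genes for the requested PPI size")
    rng = cfg.rng(3)
    n = cfg.ppi_n_nodes
    g = nx.barabasi_albert_graph(n, cfg.ppi_attachment, seed=int(rng.integers(2**31 - 1)))

    # plant hubs among the late half of the growth order, where natural
    # degree is low, so recovery is a statement about the boost
    candidates = np.arange(n // 2, n)
    hubs = sorted(rng.choice(candidates, size=cfg.n_planted_hubs, replace=False).tolist())
    for h in hubs:
        others = np.array([v for v in range(n) if v != h and not g.has_edge(h, v)])
        extra = rng.choice(others, size=min(cfg.hub_boost, len(others)), replace=False)
        for v in extra.tolist():
            g.add_edge(h, v)

    node_gene = {i: genes[i] for i in range(n)}
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    rows = []
    for a, b in edges:
        if rng.random() < cfg.score_high_fraction:
            score = rng.uniform(0.9, 1.0)
        else:
            score = rng.uniform(0.3, 0.9)
        rows.append(
            {
                "protein1": node_gene[a],
                "protein2": node_gene[b],
                "combined_score": int(round(score * 1000)),
            }
        )
    if truth is not None:
        truth.planted_hubs = sorted(node_gene[h] for h in hubs)
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def gen_tables(
    proteome: pd.DataFrame,
    cfg: SimConfig,
    truth: GroundTruth,
    models: dict[str, ChromosomeModel] | None = None,
):
    """Gene loci, cancer-gene catalogue, drug targets and literature list.

    Loci are uniform over non-centromeric regions (1 Mb exclusion either
    side of the centromere midpoint), never on acrocentric p-arms, and never
    on chromosome Y (female-derived cell line).  Roles and tiers follow the
    configured fractions; planted hubs are enriched among drug targets.
    """
    models = models or load_chromosome_model()
    rng = cfg.rng(4)
    genes = proteome["gene"].tolist()

    usable = [m for c, m in sorted(models.items()) if c != "Y"]
    weights = np.array([m.length for m in usable], dtype=float)
    weights /= weights.sum()
    margin = 1_000_000
    gene_len = 10_000

    loci_rows = []
    for gene in genes:
        m = usable[int(rng.choice(len(usable), p=weights))]
        intervals = []
        if not m.acrocentric:
            lo, hi = 1, m.centromere_mid - margin - gene_len
            if hi > lo:
                intervals.append((lo, hi))
        lo, hi = m.centromere_mid + margin, m.length - gene_len
        if hi > lo:
            intervals.append((lo, hi))
        lens = np.array([hi - lo for lo, hi in intervals], dtype=float)
        lo, hi = intervals[int(rng.choice(len(intervals), p=lens / lens.sum()))]
        start = int(rng.integers(lo, hi))
        end = start + gene_len - 1
        loci_rows.append({"gene": gene, "chromosome": m.chromosome, "start": start, "end": end})
        truth.loci[gene] = [m.chromosome, start, end]
    loci_df = pd.DataFrame(loci_rows, columns=["gene", "chromosome", "start", "end"])

    # cancer-gene catalogue: a random slice of the proteome plus every hub
    n_cancer = int(round(cfg.cancer_fraction * len(genes)))
    chosen = set(rng.choice(genes, size=n_cancer, replace=False).tolist()) | set(truth.planted_hubs)
    cgc_rows = []
    for gene in sorted(chosen):
        role = ("oncogene", "suppressor", "dual")[int(rng.choice(3, p=list(cfg.role_probs)))]
        tier = 1 if rng.random() < cfg.tier1_fraction else 2
        truth.roles[gene] = role
        truth.tiers[gene] = tier
        cgc_rows.append(
            {"gene": gene, "tier": tier, "role": role, "hallmark_annotated": int(rng.random() < 0.7)}
        )
    cgc_df = pd.DataFrame(cgc_rows, columns=["gene", "tier", "role", "hallmark_annotated"])

    # drug targets: hubs enriched, background drawn from the catalogue
    target_rows = []
    targets = []
    for gene in sorted(chosen):
        p = cfg.hub_target_prob if gene in truth.planted_hubs else cfg.background_target_prob
        if rng.random() < p:
            targets.append(gene)
            for _ in range(int(rng.integers(1, 4))):
                target_rows.append(
                    {
                        "gene": gene,
                        "drug": f"DRUG{int(rng.integers(0, 10000)):04d}",
                        "status": "approved" if rng.random() < 0.6 else "investigational",
                    }
                )
    targets_df = pd.DataFrame(target_rows, columns=["gene", "drug", "status"])
    truth.drug_targets = sorted(set(targets))

    # literature additions: hallmark-positive genes, some outside the catalogue
    hallmark_pos = sorted(
        truth.gene_of_accession[a] for a, hs in truth.hallmark_sets.items() if hs
    )
    lit = sorted(
        rng.choice(hallmark_pos, size=min(cfg.n_literature, len(hallmark_pos)), replace=False).tolist()
    )
    return loci_df, cgc_df, targets_df, lit


def simulate_bundle(cfg: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Generate every pipeline input table plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    defs = load_hallmark_definitions()
    proteome, truth = gen_proteome(cfg, defs)
    evidence = gen_evidence(proteome, cfg, truth)
    ppi = gen_ppi(cfg, proteome["gene"].tolist(), truth)
    loci, cgc, targets, lit = gen_tables(proteome, cfg, truth)

    proteome.to_csv(out / "annotations.tsv", sep="\t", index=False, lineterminator="\n")
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False, lineterminator="\n")
    ppi.to_csv(out / "ppi_edges.tsv", sep="\t", index=False, lineterminator="\n")
    loci.to_csv(out / "loci.tsv", sep="\t", index=False, lineterminator="\n")
    cgc.to_csv(out / "cgc.csv", index=False, lineterminator="\n")
    targets.to_csv(out / "drug_targets.csv", index=False, lineterminator="\n")
    (out / "literature.txt").write_text("\n".join(lit) + "\n")
    truth.to_json(out / "ground_truth.json")
    return truth
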