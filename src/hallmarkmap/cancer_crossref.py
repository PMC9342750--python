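"""Cross-reference detected membrane hallmark proteins with cancer-gene and
drug-target catalogues.

Detected genes are intersected with a Cancer Gene Census-style catalogue
(tier 1/2; oncogene, suppressor or dual role — dual is its own class, never
double-counted), supplemented with literature-reported hallmark proteins to
form the representative analysis set, and overlapped with drug targets to
produce Venn-region counts.  Gene symbols match exactly after upper-casing;
an optional two-column alias table reconciles synonyms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("oncogene", "suppressor", "dual")


@dataclass(frozen=True)
class CancerGeneRecord:
    gene: str
    tier: int  # 1 | 2
    role: str  # oncogene | suppressor | dual
    hallmark_annotated: bool = False

    def __post_init__(self) -> None:
        if self.tier not in (1, 2):
            raise ValueError(f"{self.gene}: tier must be 1 or 2")
        if self.role not in ROLES:
            raise ValueError(f"{self.gene}: role must be one of {ROLES}")


@dataclass(frozen=True)
class DrugTargetRecord:
    gene: str
    drugs: tuple[str, ...]
    status: str  # approved | investigational

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"{self.gene}: drug list must be non-empty")
        if self.status not in ("approved", "investigational"):
            raise ValueError(f"{self.gene}: unknown status {self.status!r}")


@dataclass(frozen=True)
class RepresentativeSet:
    """The combined analysis set: CGC-matched genes plus literature additions."""

    members: frozenset[str]
    provenance: Mapping[str, str]  # gene -> "cgc" | "literature"

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.members):
            raise ValueError("provenance must cover exactly the member set")


def normalize_symbol(gene: str, aliases: Mapping[str, str] | None = None) -> str:
    g = gene.strip().upper()
    return (aliases or {}).get(g, g)


def read_cgc(path: str | Path) -> list[CancerGeneRecord]:
    """Read a CGC-style CSV: gene, tier, role, hallmark_annotated."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"gene", "tier", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CGC columns {sorted(missing)}")
    if df["gene"].str.upper().duplicated().any():
        dup = df.loc[df["gene"].str.upper().duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r} in cancer-gene table")
    return [
        CancerGeneRecord(
            gene=r.gene.upper(),
            tier=int(r.tier),
            role=r.role,
            hallmark_annotated=str(getattr(r, "hallmark_annotated", "0")) == "1",
        )
        for r in df.itertuples(index=False)
    ]


def read_drug_targets(path: str | Path) -> list[DrugTargetRecord]:
    """Read a drug-target CSV (gene, drug, status), one row per gene-drug pair."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"gene", "drug", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing drug-target columns {sorted(missing)}")
    grouped: dict[str, dict[str, list[str] | str]] = {}
    for r in df.itertuples(index=False):
        g = r.gene.upper()
        entry = grouped.setdefault(g, {"drugs": [], "status": r.status})
        entry["drugs"].append(r.drug)
        # approved dominates if any pair is approved
        if r.status == "approved":
            entry["status"] = "approved"
    return [
        DrugTargetRecord(gene=g, drugs=tuple(sorted(set(e["drugs"]))), status=e["status"])
        for g, e in sorted(grouped.items())
    ]


def crossref_cgc(
    detected_membrane: set[str],
    cgc: Sequence[CancerGeneRecord],
    aliases: Mapping[str, str] | None = None,
) -> tuple[list[CancerGeneRecord], pd.DataFrame]:
    """Intersect detected membrane genes with the cancer-gene catalogue.

    Returns the matched records plus a one-row summary with per-tier and
    per-role counts; the three role counts partition the matched set.
    """
    seen: set[str] = set()
    for rec in cgc:
        if rec.gene in seen:
            raise ValueError(f"duplicate gene {rec.gene!r} in cancer-gene catalogue")
        seen.add(rec.gene)
    detected_norm = {normalize_symbol(g, aliases) for g in detected_membrane}
    matched = [rec for rec in cgc if rec.gene in detected_norm]
    summary = pd.DataFrame(
        [
            {
                "n_matched": len(matched),
                "tier1": sum(r.tier == 1 for r in matched),
                "tier2": sum(r.tier == 2 for r in matched),
                "oncogene": sum(r.role == "oncogene" for r in matched),
                "suppressor": sum(r.role == "suppressor" for r in matched),
                "dual": sum(r.role == "dual" for r in matched),
            }
        ]
    )
    return matched, summary


def build_representative_set(
    cgc_matched: set[str], literature: Iterable[str]
) -> RepresentativeSet:
    """Union of CGC-matched genes and literature-reported hallmark proteins.

    Genes present in both sources keep CGC provenance (with a logged note);
    the result size is |cgc| + |literature \\ cgc|.
    """
    lit = {normalize_symbol(g) for g in literature}
    cgc_norm = {normalize_symbol(g) for g in cgc_matched}
    both = lit & cgc_norm
    if both:
        logger.info("build_representative_set: %d literature gene(s) already CGC-matched", len(both))
    provenance = {g: "cgc" for g in cgc_norm}
    provenance.update({g: "literature" for g in lit - cgc_norm})
    return RepresentativeSet(members=frozenset(provenance), provenance=provenance)


def overlap_report(
    onco: set[str], supp: set[str], dual: set[str], targets: set[str]
) -> dict[str, int]:
    """Venn-region counts for oncogenes, suppressors, dual-role genes and
    drug targets.

    The three role classes must be pairwise disjoint (dual role is its own
    class).  Every region is reported, including the empty ones; region
    counts sum to the size of the union.
    """
    for a, b, la, lb in (
        (onco, supp, "oncogene", "suppressor"),
        (onco, dual, "oncogene", "dual"),
        (supp, dual, "suppressor", "dual"),
    ):
        overlap = a & b
        if overlap:
            raise ValueError(f"{la}/{lb} role classes overlap: {sorted(overlap)[:5]}")

    regions = {
        "onco_only": onco - targets,
        "supp_only": supp - targets,
        "dual_only": dual - targets,
        "onco_and_target": onco & targets,
        "supp_and_target": supp & targets,
        "dual_and_target": dual & targets,
        "target_only": targets - (onco | supp | dual),
    }
    counts = {k: len(v) for k, v in regions.items()}
    counts["union"] = len(onco | supp | dual | targets)
    assert sum(v for k, v in counts.items() if k != "union") == counts["union"]
    return counts
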