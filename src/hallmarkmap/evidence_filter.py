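"""Protein-identification quality filtering and spectral-count abundances.

Mass-spectrometry evidence is reduced to one record per protein carrying the
unique-peptide count, the FDR class applied by the upstream search (strict =
0.01, relaxed = 0.03), a rank-1-only flag, and spectral counts (SC) per
(enrichment method, replicate, injection) cell.  High-quality identifications
require at least two unique peptides, rank-1 peptides only, and FDR within
the requested ceiling; abundance is log10 of the summed spectral counts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Numeric FDR ceilings for the two categorical classes.
FDR_CLASSES = {"strict": 0.01, "relaxed": 0.03}

_SC_COL = re.compile(r"^[^.\t]+\.[^.\t]+\.[^.\t]+$")  # method.rep.inj


@dataclass(frozen=True)
class ProteinEvidence:
    accession: str
    unique_peptides: int
    rank1_only: bool
    fdr_class: str  # "strict" | "relaxed"
    spectral_counts: Mapping[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        if self.unique_peptides < 0:
            raise ValueError("unique_peptides must be >= 0")
        if self.fdr_class not in FDR_CLASSES:
            raise ValueError(f"unknown fdr_class {self.fdr_class!r}")
        if any(v < 0 for v in self.spectral_counts.values()):
            raise ValueError("spectral counts must be non-negative")

    @property
    def fdr(self) -> float:
        return FDR_CLASSES[self.fdr_class]

    @property
    def summed_sc(self) -> int:
        return int(sum(self.spectral_counts.values()))


@dataclass(frozen=True)
class DetectedProtein:
    """A protein surviving the quality filter, with log10(SC) abundance."""

    accession: str
    summed_sc: int
    log_abundance: float
    membrane_flag: bool = False

    @classmethod
    def from_evidence(cls, ev: ProteinEvidence, membrane_flag: bool = False) -> "DetectedProtein":
        sc = ev.summed_sc
        return cls(
            accession=ev.accession,
            summed_sc=sc,
            log_abundance=math.log10(sc),
            membrane_flag=membrane_flag,
        )


class EvidenceInconsistencyError(ValueError):
    """A protein passed identification filters but has zero spectra."""


def filter_high_quality(
    evidence: Iterable[ProteinEvidence],
    min_unique: int = 2,
    max_fdr: float = 0.03,
    membrane_flags: Mapping[str, bool] | None = None,
) -> list[DetectedProtein]:
    """Apply the identification quality rules and compute abundances.

    Keeps proteins with ``unique_peptides >= min_unique``, rank-1-only
    identifications, FDR class within ``max_fdr``, and at least one spectrum.
    A protein passing the identification filters with a zero spectral-count
    sum is a data inconsistency and raises.
    """
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    membrane_flags = membrane_flags or {}
    out: list[DetectedProtein] = []
    n_seen = 0
    for ev in evidence:
        n_seen += 1
        if ev.unique_peptides < min_unique or not ev.rank1_only or ev.fdr > max_fdr:
            continue
        if ev.summed_sc == 0:
            raise EvidenceInconsistencyError(
                f"{ev.accession}: passes identification filters but has no spectra"
            )
        out.append(DetectedProtein.from_evidence(ev, membrane_flags.get(ev.accession, False)))
    logger.info(
        "filter_high_quality: %d/%d proteins retained (min_unique=%d, max_fdr=%.2f)",
        len(out), n_seen, min_unique, max_fdr,
    )
    return out


def per_method_sums(evidence: Iterable[ProteinEvidence]) -> pd.DataFrame:
    """Optional per-enrichment-method spectral-count summary.

    One row per protein, one column per method, each cell the SC sum over
    that method's replicates and injections (the default abundance pools all
    methods into one value).
    """
    rows: dict[str, dict[str, int]] = {}
    methods: set[str] = set()
    for ev in evidence:
        acc = rows.setdefault(ev.accession, {})
        for (method, _, _), v in ev.spectral_counts.items():
            methods.add(method)
            acc[method] = acc.get(method, 0) + int(v)
    cols = sorted(methods)
    return pd.DataFrame(
        [{"accession": a, **{m: r.get(m, 0) for m in cols}} for a, r in sorted(rows.items())],
        columns=["accession"] + cols,
    )


def abundance_scale(
    detected: Iterable[DetectedProtein], lo: float = 0.0, hi: float = 5.0
) -> dict[str, float]:
    """Display sizes for abundance dots: log10(SC) clamped to [lo, hi]."""
    if hi <= lo:
        raise ValueError("hi must be > lo")
    return {d.accession: min(max(d.log_abundance, lo), hi) for d in detected}


# ---------------------------------------------------------------------------
# Tabular I/O
#
# Evidence TSV layout: accession, unique_peptides, rank1_only, fdr_class,
# then one spectral-count column per (method, replicate, injection) named
# "method.rep.inj".


def read_evidence(path: str | Path) -> list[ProteinEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["accession", "unique_peptides", "rank1_only", "fdr_class"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing evidence columns {sorted(missing)}")
    sc_cols = [c for c in df.columns if c not in fixed]
    bad = [c for c in sc_cols if not _SC_COL.match(c)]
    if bad:
        raise ValueError(f"{path}: spectral-count columns must be named method.rep.inj: {bad}")
    records = []
    for _, row in df.iterrows():
        sc = {tuple(c.split(".")): int(row[c] or 0) for c in sc_cols}
        records.append(
            ProteinEvidence(
                accession=row["accession"],
                unique_peptides=int(row["unique_peptides"]),
                rank1_only=str(row["rank1_only"]) == "1",
                fdr_class=row["fdr_class"],
                spectral_counts=sc,
            )
        )
    return records


def write_evidence(path: str | Path, evidence: list[ProteinEvidence]) -> None:
    cells = sorted({c for ev in evidence for c in ev.spectral_counts})
    cols = ["accession", "unique_peptides", "rank1_only", "fdr_class"] + [
        ".".join(c) for c in cells
    ]
    rows = []
    for ev in evidence:
        row = [ev.accession, ev.unique_peptides, int(ev.rank1_only), ev.fdr_class]
        row += [int(ev.spectral_counts.get(c, 0)) for c in cells]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def detected_table(detected: Iterable[DetectedProtein]) -> pd.DataFrame:
    rows = [
        {
            "accession": d.accession,
            "summed_sc": d.summed_sc,
            "log_abundance": round(d.log_abundance, 6),
            "membrane_flag": int(d.membrane_flag),
        }
        for d in detected
    ]
    return pd.DataFrame(rows, columns=["accession", "summed_sc", "log_abundance", "membrane_flag"])
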