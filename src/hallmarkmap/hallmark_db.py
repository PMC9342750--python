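"""Hallmark-supportive protein database.

Ten cancer-hallmark categories are each defined by a flat list of GO
biological-process term labels.  A protein belongs to a hallmark when any of
its GO annotations matches one of the hallmark's terms (after label
normalization and optional expansion with the three standard regulation
forms).  Matching is by exact normalized label — never substring — so that
e.g. "cell death" does not capture "programmed cell death"; when both the
definition and the annotation carry a GO identifier, identifiers take
precedence over labels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: Regulation forms generated for a term flagged "(& regulation)".
REGULATION_FORMS = ("regulation of {}", "positive regulation of {}", "negative regulation of {}")


def normalize_label(label: str) -> str:
    """Case-fold and collapse internal whitespace for exact-label matching."""
    return _WS.sub(" ", label.strip()).casefold()


class HallmarkDefinitionError(ValueError):
    """Raised for malformed or inconsistent hallmark definition files."""


@dataclass(frozen=True)
class GOTermRef:
    """A GO biological-process term referenced by name (optionally by ID)."""

    term_label: str
    term_id: str | None = None

    def __post_init__(self) -> None:
        if not self.term_label or not self.term_label.strip():
            raise ValueError("term_label must be non-empty")


@dataclass(frozen=True)
class HallmarkDefinition:
    """One hallmark category: an id (1-10), a label, and its GO term list."""

    hallmark_id: int
    name: str
    terms: tuple[GOTermRef, ...]
    include_regulation: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise HallmarkDefinitionError(f"hallmark {self.name!r}: empty term list")
        if len(self.terms) != len(self.include_regulation):
            raise HallmarkDefinitionError(
                f"hallmark {self.name!r}: terms and regulation flags differ in length"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein annotation: accession, gene symbol, GO terms, membrane flag."""

    accession: str
    gene: str
    go_terms: frozenset[GOTermRef]
    membrane_flag: bool = False
    disease_variant: bool = False


@dataclass
class HallmarkDB:
    """Bidirectional protein <-> hallmark membership map.

    ``by_protein`` and ``by_hallmark`` are kept mutually consistent; a protein
    may belong to anywhere between 0 and 10 hallmarks (multi-membership is the
    norm, not the exception).
    """

    by_protein: dict[str, set[int]] = field(default_factory=dict)
    by_hallmark: dict[int, set[str]] = field(default_factory=dict)
    hallmark_names: dict[int, str] = field(default_factory=dict)

    def add(self, accession: str, hallmark_id: int) -> None:
        self.by_protein.setdefault(accession, set()).add(hallmark_id)
        self.by_hallmark.setdefault(hallmark_id, set()).add(accession)

    def check_consistent(self) -> None:
        """Full cross-walk of both maps; raises on any asymmetry."""
        for acc, hids in self.by_protein.items():
            for h in hids:
                if acc not in self.by_hallmark.get(h, set()):
                    raise AssertionError(f"{acc} in by_protein[{h}] but not by_hallmark")
        for h, accs in self.by_hallmark.items():
            for acc in accs:
                if h not in self.by_protein.get(acc, set()):
                    raise AssertionError(f"{acc} in by_hallmark[{h}] but not by_protein")

    def hallmarks_of(self, accession: str) -> set[int]:
        return set(self.by_protein.get(accession, set()))


def load_hallmark_definitions(path: str | Path | None = None) -> list[HallmarkDefinition]:
    """Load hallmark definitions from a YAML file.

    With ``path=None`` the shipped default file is used; it encodes the ten
    standard hallmark/term sets.  Entries must carry a unique name and at
    least one term.
    """
    if path is None:
        text = resources.files("hallmarkmap.data").joinpath("hallmarks.yaml").read_text()
        source = "<default>"
    else:
        source = str(path)
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise HallmarkDefinitionError(f"{source}: YAML parse error: {exc}") from exc
    if not doc or "hallmarks" not in doc or not doc["hallmarks"]:
        raise HallmarkDefinitionError(f"{source}: no hallmark definitions found")

    defs: list[HallmarkDefinition] = []
    seen_names: set[str] = set()
    for i, entry in enumerate(doc["hallmarks"], start=1):
        if not isinstance(entry, dict) or "name" not in entry or "terms" not in entry:
            raise HallmarkDefinitionError(f"{source}: malformed hallmark entry #{i}: {entry!r}")
        name = str(entry["name"])
        if normalize_label(name) in seen_names:
            raise HallmarkDefinitionError(f"{source}: duplicate hallmark name {name!r}")
        seen_names.add(normalize_label(name))
        terms: list[GOTermRef] = []
        flags: list[bool] = []
        if not entry["terms"]:
            raise HallmarkDefinitionError(f"{source}: hallmark {name!r} has no terms")
        for j, t in enumerate(entry["terms"], start=1):
            if isinstance(t, str):
                label, reg, tid = t, False, None
            elif isinstance(t, dict) and "label" in t:
                label = str(t["label"])
                reg = bool(t.get("regulation", False))
                tid = t.get("id")
            else:
                raise HallmarkDefinitionError(
                    f"{source}: hallmark {name!r}, term #{j}: malformed entry {t!r}"
                )
            terms.append(GOTermRef(term_label=label, term_id=tid))
            flags.append(reg)
        defs.append(
            HallmarkDefinition(
                hallmark_id=int(entry.get("id", i)),
                name=name,
                terms=tuple(terms),
                include_regulation=tuple(flags),
            )
        )
    return defs


def expand_terms(defn: HallmarkDefinition) -> set[str]:
    """Expanded normalized label set for one hallmark definition.

    Terms flagged for regulation contribute the base label plus
    "regulation of X", "positive regulation of X" and "negative regulation
    of X"; other terms contribute only the base label.
    """
    out: set[str] = set()
    for term, reg in zip(defn.terms, defn.include_regulation):
        base = normalize_label(term.term_label)
        out.add(base)
        if reg:
            for form in REGULATION_FORMS:
                out.add(normalize_label(form.format(term.term_label)))
    return out


def _expanded_ids(defn: HallmarkDefinition) -> set[str]:
    return {t.term_id for t in defn.terms if t.term_id}


def assign_hallmarks(
    annotations: Iterable[AnnotationRecord],
    defs: Sequence[HallmarkDefinition],
) -> HallmarkDB:
    """Assign each protein to every hallmark whose term set it intersects.

    A protein lands in hallmark *h* iff one of its GO annotations matches a
    term of *h*: by GO identifier when both sides carry one, otherwise by
    exact normalized label.  Proteins matching nothing simply stay out of the
    map (an empty hallmark set is not an error).
    """
    db = HallmarkDB(hallmark_names={d.hallmark_id: d.name for d in defs})
    expanded = [(d.hallmark_id, expand_terms(d), _expanded_ids(d)) for d in defs]
    for rec in annotations:
        labels = {normalize_label(t.term_label) for t in rec.go_terms}
        ids = {t.term_id for t in rec.go_terms if t.term_id}
        for hid, terms, term_ids in expanded:
            if (ids and term_ids & ids) or (labels & terms):
                db.add(rec.accession, hid)
    db.check_consistent()
    return db


def hallmark_counts(
    db: HallmarkDB,
    subset: set[str] | None = None,
    hallmark_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-hallmark protein counts, optionally restricted to ``subset``.

    Because of multi-membership the counts may sum to more than the number of
    distinct proteins.  Accessions in ``subset`` unknown to the database are
    ignored with a warning.
    """
    db.check_consistent()
    if hallmark_ids is None:
        hallmark_ids = sorted(set(db.by_hallmark) | set(db.hallmark_names))
    if subset is not None:
        unknown = subset - set(db.by_protein)
        if unknown:
            logger.warning("hallmark_counts: %d accession(s) not in database, ignored", len(unknown))
    rows = []
    for h in hallmark_ids:
        members = db.by_hallmark.get(h, set())
        n = len(members if subset is None else members & subset)
        rows.append({"hallmark_id": h, "hallmark_name": db.hallmark_names.get(h, ""), "count": n})
    return pd.DataFrame(rows, columns=["hallmark_id", "hallmark_name", "count"])


# ---------------------------------------------------------------------------
# Tabular I/O


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a protein annotation table.

    TSV columns: accession, gene, go_terms (semicolon-separated labels),
    membrane_flag (0/1), optional disease_variant (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", "gene", "go_terms", "membrane_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["accession"].duplicated().any():
        dup = df.loc[df["accession"].duplicated(), "accession"].iloc[0]
        raise ValueError(f"{path}: duplicate accession {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        terms = frozenset(
            GOTermRef(term_label=t.strip()) for t in str(row.go_terms).split(";") if t.strip()
        )
        records.append(
            AnnotationRecord(
                accession=row.accession,
                gene=row.gene,
                go_terms=terms,
                membrane_flag=str(row.membrane_flag) == "1",
                disease_variant=str(getattr(row, "disease_variant", "0")) == "1",
            )
        )
    return records


def membership_table(db: HallmarkDB) -> pd.DataFrame:
    """Long protein→hallmark table (accession, hallmark_id, hallmark_name)."""
    rows = [
        {"accession": acc, "hallmark_id": h, "hallmark_name": db.hallmark_names.get(h, "")}
        for acc in sorted(db.by_protein)
        for h in sorted(db.by_protein[acc])
    ]
    return pd.DataFrame(rows, columns=["accession", "hallmark_id", "hallmark_name"])
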