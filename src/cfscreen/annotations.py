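"""Cofactor annotation tables: loading, validation and summary statistics.

A cofactor (CF) annotation table describes one transcriptional cofactor per
row: functional categories (chromatin-modifier classes, reader domains,
Mediator, ...), protein-complex memberships, WormBase-style phenotype
strings, tissue-expression flags and RNAi-library clone provenance.  This
module parses that table into :class:`CofactorRecord` objects, derives
essentiality from phenotypes, and computes the category/complex/library
summaries that characterise the screened gene set.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cfscreen._util import percent

__all__ = [
    "ESSENTIAL_PHENOTYPES",
    "GENOME_PROTEIN_CODING_GENES",
    "CF_COMPLEXES",
    "CLONE_SOURCES",
    "CofactorRecord",
    "GenomeBackground",
    "SchemaError",
    "ValidationError",
    "load_cofactor_table",
    "records_to_frame",
    "flag_essential",
    "category_counts",
    "complex_members",
    "library_summary",
    "write_summary_json",
    "write_category_counts_tsv",
]

#: Phenotype annotations that mark a gene as essential.  Any gene carrying
#: at least one of these is flagged ``essential``.
ESSENTIAL_PHENOTYPES: frozenset[str] = frozenset(
    {
        "lethal",
        "larval lethal",
        "larval arrest",
        "embryonic lethal",
        "embryonic arrest",
        "sterile",
    }
)

#: Protein-coding genes in the C. elegans genome background (WormBase WS284).
GENOME_PROTEIN_CODING_GENES: int = 19_987

#: Curated C. elegans cofactor complexes and their subunits.  Several genes
#: sit in more than one complex (ekl-4, ruvb-1/2, swsn-6, trr-1), which is
#: why complex membership is set-valued on records.
CF_COMPLEXES: dict[str, frozenset[str]] = {
    "CAF-1": frozenset({"chaf-1", "chaf-2", "rba-1"}),
    "CCR4-NOT": frozenset(
        {"ccf-1", "ccr-4", "let-711", "ntl-2", "ntl-3", "ntl-4", "ntl-9", "ntl-11", "tag-153"}
    ),
    "DRM": frozenset(
        {"dpl-1", "efl-1", "lin-9", "lin-35", "lin-37", "lin-52", "lin-53", "lin-54"}
    ),
    "Mediator": frozenset(
        {
            "cdk-4", "cdk-8", "cic-1", "dpy-22", "dyf-18", "let-19", "let-49",
            "lin-25", "mdt-4", "mdt-6", "mdt-8", "mdt-10", "mdt-11", "mdt-15",
            "mdt-17", "mdt-18", "mdt-19", "mdt-20", "mdt-21", "mdt-22",
            "mdt-27", "mdt-29", "mdt-31", "R09F10.3", "rgr-1", "sna-1",
            "sop-3", "sur-2",
        }
    ),
    "NuA4": frozenset(
        {
            "B0025.4", "cec-7", "ekl-4", "epc-1", "F59E12.1", "gfl-1", "ing-3",
            "mrg-1", "mys-1", "ruvb-1", "ruvb-2", "swsn-6", "trr-1",
            "Y43H11AL.1", "ZK1127.3",
        }
    ),
    "NuRD": frozenset({"dcp-66", "egl-27", "hda-1", "let-418", "lin-40"}),
    "SAGA": frozenset(
        {
            "ada-2", "pcaf-1", "T22B7.4", "taf-6.1", "taf-6.2", "taf-9",
            "taf-10", "taf-12", "trr-1", "Y17G9B.8",
        }
    ),
    "Set1C/COMPASS": frozenset(
        {
            "ash-2", "cfp-1", "dpy-30", "hcf-1", "rbbp-5", "set-2",
            "swd-2.1", "swd-2.2", "wdr-5.1",
        }
    ),
    "SWI/SNF/BAF": frozenset(
        {
            "C52B9.8", "dpff-1", "ham-3", "let-526", "snfc-5", "swsn-1",
            "swsn-2.2", "swsn-3", "swsn-4", "swsn-6", "swsn-7", "ZK973.9",
        }
    ),
    "SWR1": frozenset(
        {"arp-6", "C17E4.6", "ekl-4", "F13C5.2", "ruvb-1", "ruvb-2", "ssl-1", "zhit-1"}
    ),
}

CLONE_SOURCES = ("orfeome", "ahringer", "de_novo", "none")

#: Internal delimiter for set-valued cells; commas occur inside phenotype
#: names, so a pipe is used instead.
SET_DELIMITER = "|"

REQUIRED_COLUMNS = (
    "gene_id",
    "name",
    "categories",
    "complexes",
    "phenotypes",
    "tissues",
    "clone_source",
)


class SchemaError(ValueError):
    """The annotation table header does not declare a required column."""


class ValidationError(ValueError):
    """The annotation table content violates an invariant."""


@dataclass(frozen=True)
class CofactorRecord:
    """Annotations for one regulator (transcriptional cofactor)."""

    gene_id: str
    name: str
    categories: frozenset[str] = frozenset()
    complexes: frozenset[str] = frozenset()
    phenotypes: frozenset[str] = frozenset()
    tissues: frozenset[str] = frozenset()
    clone_source: str = "none"
    essential: bool = False

    def __post_init__(self) -> None:
        if self.clone_source not in CLONE_SOURCES:
            raise ValidationError(
                f"{self.gene_id}: unknown clone_source {self.clone_source!r}; "
                f"expected one of {CLONE_SOURCES}"
            )
        if not self.categories and not self.complexes:
            raise ValidationError(
                f"{self.gene_id}: record has neither a functional category nor "
                "a complex membership"
            )

    @property
    def in_library(self) -> bool:
        """True iff an RNAi clone for this gene is in the screened library."""
        return self.clone_source != "none"


@dataclass(frozen=True)
class GenomeBackground:
    """Genome-wide background for essentiality enrichment."""

    n_genes: int = GENOME_PROTEIN_CODING_GENES
    n_essential: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_essential <= self.n_genes:
            raise ValidationError(
                f"n_essential must lie in [0, n_genes]; got "
                f"{self.n_essential} of {self.n_genes}"
            )


def _parse_set(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(p.strip() for p in text.split(SET_DELIMITER) if p.strip())


def load_cofactor_table(
    path: str | Path,
    *,
    known_categories: Iterable[str] | None = None,
    permissive: bool = False,
    essential_set: Iterable[str] = ESSENTIAL_PHENOTYPES,
) -> list[CofactorRecord]:
    """Read a tab-separated cofactor annotation table.

    Parameters
    ----------
    path
        TSV file with a header row declaring at least the columns
        ``gene_id, name, categories, complexes, phenotypes, tissues,
        clone_source``.  Set-valued cells are ``|``-delimited.
    known_categories
        Optional controlled vocabulary.  Category labels outside it are
        rejected unless ``permissive`` is set.
    permissive
        Accept category labels outside ``known_categories``.
    essential_set
        Phenotype labels that confer essentiality (exact string match).

    Raises
    ------
    SchemaError
        A required column is missing from the header.
    ValidationError
        Duplicated gene ids, unknown clone source or category labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table is missing required column(s): {missing}")

    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicated gene_id value(s): {sorted(set(dup))}")

    vocabulary = frozenset(known_categories) if known_categories is not None else None
    records: list[CofactorRecord] = []
    for row in df.itertuples(index=False):
        categories = _parse_set(row.categories)
        if vocabulary is not None and not permissive:
            unknown = categories - vocabulary
            if unknown:
                raise ValidationError(
                    f"{row.gene_id}: unknown category label(s) {sorted(unknown)}"
                )
        records.append(
            CofactorRecord(
                gene_id=row.gene_id,
                name=row.name,
                categories=categories,
                complexes=_parse_set(row.complexes),
                phenotypes=_parse_set(row.phenotypes),
                tissues=_parse_set(row.tissues),
                clone_source=(row.clone_source or "none").strip(),
            )
        )
    return flag_essential(records, essential_set)


def records_to_frame(records: Sequence[CofactorRecord]) -> pd.DataFrame:
    """Serialise records back to the tabular schema (round-trip of load)."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "name": r.name,
                "categories": SET_DELIMITER.join(sorted(r.categories)),
                "complexes": SET_DELIMITER.join(sorted(r.complexes)),
                "phenotypes": SET_DELIMITER.join(sorted(r.phenotypes)),
                "tissues": SET_DELIMITER.join(sorted(r.tissues)),
                "clone_source": r.clone_source,
                "essential": r.essential,
            }
        )
    return pd.DataFrame(rows)


def flag_essential(
    records: Sequence[CofactorRecord],
    essential_set: Iterable[str] = ESSENTIAL_PHENOTYPES,
) -> list[CofactorRecord]:
    """Set each record's ``essential`` flag from its phenotype annotations.

    A record is essential iff its phenotype set intersects ``essential_set``
    (exact string match).  Order-preserving and idempotent.
    """
    labels = frozenset(essential_set)
    if not labels:
        raise ValueError("essential_set must be non-empty")
    return [replace(r, essential=bool(r.phenotypes & labels)) for r in records]


def category_counts(records: Sequence[CofactorRecord]) -> dict[str, int]:
    """Count records per functional category.

    A gene annotated with k categories contributes one count to each of
    them (e.g. a methyltransferase that also carries a plant homeodomain is
    counted in both categories), so the total count mass equals the sum of
    per-record category set sizes.
    """
    counter: Counter[str] = Counter()
    for r in records:
        counter.update(r.categories)
    return dict(counter)


def complex_members(records: Sequence[CofactorRecord], complex_label: str) -> set[str]:
    """Gene ids of all records annotated as members of ``complex_label``.

    Shared subunits are returned for every complex they belong to.
    Raises :class:`LookupError` if no record mentions the label.
    """
    known = set().union(*(r.complexes for r in records)) if records else set()
    if complex_label not in known:
        raise LookupError(f"unknown complex label: {complex_label!r}")
    return {r.gene_id for r in records if complex_label in r.complexes}


@dataclass(frozen=True)
class LibrarySummary:
    """RNAi-library composition of an annotated gene set."""

    counts_by_source: dict[str, int]
    total_clones: int
    n_records: int
    coverage_pct: int


def library_summary(records: Sequence[CofactorRecord]) -> LibrarySummary:
    """Summarise clone provenance and library coverage.

    ``total_clones`` counts in-library records; ``coverage_pct`` is the
    in-library fraction of all records as an integer percent (half-up).
    """
    counts = Counter(r.clone_source for r in records if r.in_library)
    by_source = {src: counts.get(src, 0) for src in CLONE_SOURCES if src != "none"}
    total = sum(by_source.values())
    n = len(records)
    cov = percent(total, n) if n else 0
    return LibrarySummary(
        counts_by_source=by_source, total_clones=total, n_records=n, coverage_pct=cov
    )


def write_summary_json(records: Sequence[CofactorRecord], path: str | Path) -> None:
    """Write the library/essentiality summary as a JSON report."""
    summ = library_summary(records)
    payload = {
        "n_records": summ.n_records,
        "total_clones": summ.total_clones,
        "coverage_pct": summ.coverage_pct,
        "counts_by_source": summ.counts_by_source,
        "n_essential": sum(r.essential for r in records),
        "category_counts": category_counts(records),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_category_counts_tsv(
    records: Sequence[CofactorRecord], path: str | Path
) -> None:
    counts = category_counts(records)
    df = pd.DataFrame(
        sorted(counts.items()), columns=["category", "count"]
    )
    df.to_csv(path, sep="\t", index=False)


def table1_records(complexes: Mapping[str, frozenset[str]] = CF_COMPLEXES) -> list[CofactorRecord]:
    """Build annotation records for the curated complex table alone.

    Each gene carries its complex memberships and no category label; useful
    as a minimal fixture for complex-membership queries.
    """
    membership: dict[str, set[str]] = {}
    for cx, genes in complexes.items():
        for g in genes:
            membership.setdefault(g, set()).add(cx)
    return [
        CofactorRecord(gene_id=g, name=g, complexes=frozenset(cxs))
        for g, cxs in sorted(membership.items())
    ]
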