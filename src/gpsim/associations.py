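"""Integration of disease-gene and disease-phenotype associations (the DGP store).

Heterogeneous mapping sources are merged onto Disease Ontology term ids:

* HPO monthly-build annotation files
  (``diseases_to_genes_to_phenotypes`` dialect) keyed by OMIM/ORPHA/DOID
  accessions,
* id -> gene tables ("OMIM:nnnn <tab> GENE", SIDD/HPO style),
* name -> gene tables ("disease name <tab> GENE", Dancer style), matched
  against DO names and synonyms.

Resolution is deterministic: ids resolve through DOID identity or unique
xref lookup, names through exact equality after case-folding and whitespace
normalization. Ambiguous matches (two or more candidate DO terms) are
dropped and logged, never picked heuristically. Associations are not
propagated up the DO hierarchy unless explicitly requested.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .errors import GPSimError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

GENE = "gene"
PHENOTYPE = "phenotype"

SOURCE_HPO = "hpo_annot"
SOURCE_SIDD = "sidd_style"
SOURCE_DANCER = "dancer_style"


@dataclass(frozen=True)
class MappingRecord:
    """One raw disease -> item assertion from a source file.

    ``record_kind`` is ``"by_id"`` when ``source_id`` is a prefixed accession
    (OMIM:/ORPHA:/DOID:) and ``"by_name"`` when it is a raw disease name.
    """

    source_id: str
    target: str
    record_kind: str  # by_id | by_name
    target_kind: str  # gene | phenotype


@dataclass
class SourceFile:
    """A parsed mapping source: a provenance tag plus its records."""

    tag: str
    records: List[MappingRecord]


@dataclass
class IntegrationReport:
    """Counts from one build: how many records resolved, and why the rest did not."""

    resolved: int = 0
    unresolved: int = 0
    ambiguous: int = 0
    invalid_phenotypes: int = 0

    def __str__(self) -> str:
        return (
            f"resolved={self.resolved} unresolved={self.unresolved} "
            f"ambiguous={self.ambiguous} invalid_phenotypes={self.invalid_phenotypes}"
        )


@dataclass
class DGPStore:
    """Integrated disease -> gene-set and disease -> phenotype-set associations.

    Keys are active DO term ids. ``provenance`` maps (disease, item) to the
    set of source tags asserting that association.
    """

    gene_sets: Dict[str, Set[str]] = field(default_factory=dict)
    phenotype_sets: Dict[str, Set[str]] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)
    report: IntegrationReport = field(default_factory=IntegrationReport)

    @property
    def diseases(self) -> Set[str]:
        return set(self.gene_sets) | set(self.phenotype_sets)

    def gene_set(self, disease: str) -> Set[str]:
        return self.gene_sets.get(disease, set())

    def phenotype_set(self, disease: str) -> Set[str]:
        return self.phenotype_sets.get(disease, set())

    def add(self, disease: str, kind: str, item: str, source: str) -> None:
        table = self.gene_sets if kind == GENE else self.phenotype_sets
        table.setdefault(disease, set()).add(item)
        self.provenance.setdefault((disease, item), set()).add(source)

    def to_tsv(self, path) -> None:
        """Export as TSV rows: disease_id, kind, item_id, sources (comma-joined)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["disease_id", "kind", "item_id", "sources"])
            for kind, table in ((GENE, self.gene_sets), (PHENOTYPE, self.phenotype_sets)):
                for disease in sorted(table):
                    for item in sorted(table[disease]):
                        tags = sorted(self.provenance.get((disease, item), ()))
                        w.writerow([disease, kind, item, ",".join(tags)])

    @classmethod
    def from_tsv(cls, path) -> "DGPStore":
        store = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            for row in reader:
                if len(row) < 3:
                    continue
                disease, kind, item = row[0], row[1], row[2]
                tags = row[3].split(",") if len(row) > 3 and row[3] else []
                for tag in tags or ["unknown"]:
                    store.add(disease, kind, item, tag)
        return store


# -- parsing ------------------------------------------------------------


def parse_hpo_annotation_file(
    path, columns: Sequence[int] = (0, 1, 3)
) -> List[Tuple[str, str, str]]:
    """Parse a ``diseases_to_genes_to_phenotypes`` file into triples.

    Returns (disease accession, gene id, HPO term id) per data row, with the
    accession prefix (OMIM:/ORPHA:/DOID:) retained. *columns* gives the
    indices of the disease, gene and HPO columns; the default matches the
    HPO monthly-build layout. Rows with too few columns are skipped with a
    logged line number.
    """
    need = max(columns) + 1
    triples: List[Tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < need or not all(row[c].strip() for c in columns):
                logger.warning("%s line %d: malformed row skipped", path, i)
                continue
            d, g, p = (row[c].strip() for c in columns)
            triples.append((d, g, p))
    return triples


def hpo_source(triples: Iterable[Tuple[str, str, str]]) -> SourceFile:
    """Turn HPO annotation triples into gene and phenotype mapping records."""
    records: List[MappingRecord] = []
    for disease, gene, hp in triples:
        records.append(MappingRecord(disease, gene, "by_id", GENE))
        records.append(MappingRecord(disease, hp, "by_id", PHENOTYPE))
    return SourceFile(SOURCE_HPO, records)


def _parse_two_column(path, record_kind: str, tag: str) -> SourceFile:
    records: List[MappingRecord] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                logger.warning("%s line %d: malformed row skipped", path, i)
                continue
            records.append(MappingRecord(row[0].strip(), row[1].strip(), record_kind, GENE))
    return SourceFile(tag, records)


def parse_id_gene_file(path, tag: str = SOURCE_SIDD) -> SourceFile:
    """Parse an "OMIM/ORPHA/DOID <tab> gene" table (SIDD/HPO style)."""
    return _parse_two_column(path, "by_id", tag)


def parse_name_gene_file(path, tag: str = SOURCE_DANCER) -> SourceFile:
    """Parse a "disease name <tab> gene" table (Dancer style)."""
    return _parse_two_column(path, "by_name", tag)


# -- resolution ---------------------------------------------------------


def resolve_disease(do: OntologyGraph, rec: MappingRecord) -> Optional[str]:
    """Map a record's disease reference to an active DO term id, or None.

    * ``by_id`` with a DOID prefix: that term if active (alt ids resolve).
    * ``by_id`` with another prefix: the unique DO term carrying it as xref.
    * ``by_name``: the unique DO term whose name or synonym matches exactly
      after case-folding and whitespace normalization.

    Ambiguous matches (>= 2 candidate terms) return None and are logged as
    ambiguities; resolution never silently picks one.
    """
    if rec.record_kind == "by_id":
        acc = rec.source_id.strip()
        if acc.upper().startswith("DOID:"):
            tid = do.resolve_id(acc)
            return tid if do.is_active(tid) else None
        hits = do.find_by_xref(acc)
    else:
        hits = do.find_by_label(rec.source_id)
    if len(hits) == 1:
        return next(iter(hits))
    if len(hits) > 1:
        logger.warning(
            "ambiguous disease reference %r matches %d DO terms; dropped",
            rec.source_id,
            len(hits),
        )
    return None


def build_dgp(
    do: OntologyGraph,
    hpo: OntologyGraph,
    sources: Iterable[SourceFile],
) -> DGPStore:
    """Integrate all sources into one de-duplicated DGP store with provenance.

    Phenotype targets must be active HPO terms (alt ids resolve to
    primaries); others are counted as invalid. Unresolved and ambiguous
    disease references are counted in ``store.report``. Rebuilding from the
    same sources yields an identical store.
    """
    store = DGPStore()
    for src in sources:
        for rec in src.records:
            hits = _candidates(do, rec)
            if len(hits) != 1:
                if len(hits) > 1:
                    store.report.ambiguous += 1
                    logger.warning(
                        "ambiguous disease reference %r (%d DO terms); dropped",
                        rec.source_id,
                        len(hits),
                    )
                else:
                    store.report.unresolved += 1
                continue
            disease = next(iter(hits))
            if rec.target_kind == PHENOTYPE:
                if not hpo.is_active(rec.target):
                    store.report.invalid_phenotypes += 1
                    continue
                target = hpo.resolve_id(rec.target)
            else:
                target = rec.target
            store.add(disease, rec.target_kind, target, src.tag)
            store.report.resolved += 1
    if not store.diseases:
        logger.warning("integration produced an empty DGP store")
    return store


def _candidates(do: OntologyGraph, rec: MappingRecord) -> Set[str]:
    if rec.record_kind == "by_id":
        acc = rec.source_id.strip()
        if acc.upper().startswith("DOID:"):
            tid = do.resolve_id(acc)
            return {tid} if do.is_active(tid) else set()
        return do.find_by_xref(acc)
    return do.find_by_label(rec.source_id)


def propagate_up(store: DGPStore, do: OntologyGraph) -> DGPStore:
    """Opt-in: copy each disease's associations to all its DO ancestors.

    Off by default — the integration itself never propagates.
    """
    out = DGPStore(report=store.report)
    for kind, table in ((GENE, store.gene_sets), (PHENOTYPE, store.phenotype_sets)):
        for disease, items in table.items():
            targets = do.ancestors(disease) if disease in do else {disease}
            for d in targets:
                for item in items:
                    for tag in store.provenance.get((disease, item), {"propagated"}):
                        out.add(d, kind, item, tag)
    return out


def filter_phenotypes(
    store: DGPStore,
    hpo: OntologyGraph,
    min_depth: int = 0,
    min_count: int = 0,
) -> DGPStore:
    """Restrict phenotype sets by HPO term depth and per-disease count.

    Keeps only HPO terms at depth >= *min_depth*; diseases whose filtered
    phenotype set has fewer than *min_count* members lose their phenotype
    entry entirely. Gene sets are untouched. ``(0, 0)`` is the identity.
    """
    if min_depth < 0 or min_count < 0:
        raise ValueError("min_depth and min_count must be non-negative")
    out = DGPStore(
        gene_sets={d: set(s) for d, s in store.gene_sets.items()},
        report=store.report,
    )
    for disease, terms in store.phenotype_sets.items():
        kept = {t for t in terms if hpo.depth(t) >= min_depth}
        if len(kept) >= min_count:
            out.phenotype_sets[disease] = kept
    for (disease, item), tags in store.provenance.items():
        if item in out.gene_sets.get(disease, ()) or item in out.phenotype_sets.get(
            disease, ()
        ):
            out.provenance[(disease, item)] = set(tags)
    return out
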