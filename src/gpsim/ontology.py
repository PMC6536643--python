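"""Ontology loading and structural queries over is-a DAGs.

Wraps an OBO 1.2 flat file (Disease Ontology, Human Phenotype Ontology or a
synthetic stand-in) as a rooted directed acyclic graph and provides the
structural primitives the similarity measures need: shortest-path depth,
ancestor sets, annotation-propagated information content (IC) and the most
informative common ancestor (MICA).

Conventions
-----------
* Edges run child -> parent along ``is_a`` only; other relation types are
  ignored.
* The root has depth 0 by default (``depth_convention="root0"``); a
  ``"root1"`` convention is available for tools that count the root as
  level 1.
* Obsolete terms are loaded and retrievable but excluded from every
  structural query; alternate (merged) ids resolve to their primary id.
* If the file has several top-level terms, a virtual root is inserted above
  them so that depth and MICA are total functions.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import networkx as nx
import obonet

from .errors import (
    AnnotationError,
    OboParseError,
    OntologyStructureError,
    TermNotFoundError,
)

logger = logging.getLogger(__name__)

VIRTUAL_ROOT = "VIRTUAL:ROOT"

_SYNONYM_RE = re.compile(r'"(.*?)"')


def normalize_label(s: str) -> str:
    """Case-fold, trim and collapse internal whitespace for label matching."""
    return " ".join(s.split()).casefold()


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    synonyms: frozenset = frozenset()
    xrefs: frozenset = frozenset()
    parents: frozenset = frozenset()
    is_obsolete: bool = False


class OntologyGraph:
    """A rooted is-a DAG of ontology terms with structural queries.

    Parameters
    ----------
    terms:
        Mapping of primary term id to :class:`Term`. Parents referenced by a
        term must exist among the active (non-obsolete) terms.
    alt_ids:
        Mapping of alternate/merged id to primary id.
    depth_convention:
        ``"root0"`` (default) counts the root as depth 0, ``"root1"`` as 1.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        alt_ids: Optional[Mapping[str, str]] = None,
        depth_convention: str = "root0",
    ) -> None:
        if depth_convention not in ("root0", "root1"):
            raise ValueError(f"unknown depth convention: {depth_convention!r}")
        self._terms: Dict[str, Term] = dict(terms)
        self._alt: Dict[str, str] = dict(alt_ids or {})
        self.depth_convention = depth_convention

        active = {t.id for t in self._terms.values() if not t.is_obsolete}
        if not active:
            raise OntologyStructureError("ontology has no active terms (no root)")

        # child -> parent graph over active terms only
        g = nx.DiGraph()
        g.add_nodes_from(active)
        for t in self._terms.values():
            if t.is_obsolete:
                continue
            for p in t.parents:
                if p in active:
                    g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(f"cyclic is-a relation involving {cycle[0][0]}")

        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) == 1:
            self.root = roots[0]
        else:
            logger.warning(
                "ontology has %d top-level terms; inserting virtual root", len(roots)
            )
            self.root = VIRTUAL_ROOT
            g.add_node(VIRTUAL_ROOT)
            for r in roots:
                g.add_edge(r, VIRTUAL_ROOT)
            self._terms[VIRTUAL_ROOT] = Term(id=VIRTUAL_ROOT, name="virtual root")

        for n in g.nodes:
            if n != self.root and not nx.has_path(g, n, self.root):
                raise OntologyStructureError(f"term {n} cannot reach the root")

        self._dag = g
        self._depths: Dict[str, int] = nx.single_source_shortest_path_length(
            g.reverse(copy=False), self.root
        )
        self._name_index: Optional[Dict[str, Set[str]]] = None
        self._xref_index: Optional[Dict[str, Set[str]]] = None

    # -- term access ---------------------------------------------------

    def resolve_id(self, term_id: str) -> str:
        """Map an alternate id to its primary id (identity for primaries)."""
        return self._alt.get(term_id, term_id)

    def term(self, term_id: str) -> Term:
        tid = self.resolve_id(term_id)
        try:
            return self._terms[tid]
        except KeyError:
            raise TermNotFoundError(term_id) from None

    def __contains__(self, term_id: str) -> bool:
        return self.resolve_id(term_id) in self._terms

    def is_active(self, term_id: str) -> bool:
        tid = self.resolve_id(term_id)
        t = self._terms.get(tid)
        return t is not None and not t.is_obsolete

    @property
    def active_terms(self) -> Set[str]:
        return set(self._dag.nodes)

    def __len__(self) -> int:
        return len(self._terms)

    def _require_active(self, term_id: str) -> str:
        tid = self.resolve_id(term_id)
        if tid not in self._dag:
            raise TermNotFoundError(f"unknown or obsolete term: {term_id}")
        return tid

    # -- label / xref lookup -------------------------------------------

    def find_by_label(self, label: str) -> Set[str]:
        """Active term ids whose name or synonym equals *label*.

        Matching is exact after case-folding and whitespace normalization;
        no fuzzy matching.
        """
        if self._name_index is None:
            idx: Dict[str, Set[str]] = {}
            for t in self._terms.values():
                if t.is_obsolete or t.id == VIRTUAL_ROOT:
                    continue
                for lab in {t.name, *t.synonyms}:
                    if lab:
                        idx.setdefault(normalize_label(lab), set()).add(t.id)
            self._name_index = idx
        return set(self._name_index.get(normalize_label(label), set()))

    def find_by_xref(self, xref: str) -> Set[str]:
        """Active term ids carrying *xref* (e.g. ``OMIM:104300``) as a cross-reference."""
        if self._xref_index is None:
            idx: Dict[str, Set[str]] = {}
            for t in self._terms.values():
                if t.is_obsolete:
                    continue
                for x in t.xrefs:
                    idx.setdefault(x.strip().upper(), set()).add(t.id)
            self._xref_index = idx
        return set(self._xref_index.get(xref.strip().upper(), set()))

    # -- structural queries --------------------------------------------

    def depth(self, term_id: str) -> int:
        """Shortest is-a path length from *term_id* up to the root."""
        tid = self._require_active(term_id)
        d = self._depths[tid]
        return d + (1 if self.depth_convention == "root1" else 0)

    def ancestors(self, term_id: str) -> Set[str]:
        """All terms reachable via parent edges, including the term itself."""
        tid = self._require_active(term_id)
        anc = nx.descendants(self._dag, tid)  # child->parent edges: up is forward
        anc.add(tid)
        return anc

    def descendants(self, term_id: str) -> Set[str]:
        """All terms whose ancestor set contains *term_id*, including itself."""
        tid = self._require_active(term_id)
        desc = nx.ancestors(self._dag, tid)
        desc.add(tid)
        return desc

    def link_distance(self, t1: str, t2: str) -> int:
        """Length of the shortest undirected is-a path between two terms."""
        a = self._require_active(t1)
        b = self._require_active(t2)
        try:
            return nx.shortest_path_length(self._dag.to_undirected(as_view=True), a, b)
        except nx.NetworkXNoPath:
            raise OntologyStructureError(f"no is-a path between {t1} and {t2}") from None

    def information_content(
        self, annotations: Mapping[str, float], log_base: Optional[float] = None
    ) -> Dict[str, float]:
        """IC(t) = -log p(t) with descendant-propagated annotation counts.

        A term's effective count is the sum of the raw counts of itself and
        all of its (distinct) descendants, so p(root) = 1 and IC(root) = 0.
        Natural log by default; *log_base* overrides.

        Raises
        ------
        AnnotationError
            If no annotation mass reaches the root (all counts zero/missing).
        """
        prop: Dict[str, float] = {t: 0.0 for t in self._dag.nodes}
        for term_id, count in annotations.items():
            if count < 0:
                raise AnnotationError(f"negative annotation count for {term_id}")
            if count == 0:
                continue
            tid = self.resolve_id(term_id)
            if tid not in self._dag:
                logger.warning("ignoring annotations on unknown/obsolete term %s", term_id)
                continue
            for anc in self.ancestors(tid):
                prop[anc] += count
        total = prop[self.root]
        if total <= 0:
            raise AnnotationError("no annotations propagate to the root")
        scale = 1.0 if log_base is None else math.log(log_base)
        # +0.0 folds IEEE -0.0 (from p = 1) to 0.0
        return {
            t: (-math.log(c / total) / scale + 0.0 if c > 0 else math.inf)
            for t, c in prop.items()
        }

    def mica(self, ic: Mapping[str, float], t1: str, t2: str) -> str:
        """Most informative common ancestor of *t1* and *t2*.

        Ties on IC are broken by greater depth, then lexicographically
        smaller id. Terms without an IC entry count as IC 0.
        """
        common = self.ancestors(t1) & self.ancestors(t2)
        if not common:
            raise OntologyStructureError(f"{t1} and {t2} have no common ancestor")

        def finite_ic(t: str) -> float:
            v = ic.get(t, 0.0)
            return v if math.isfinite(v) else 0.0

        return min(common, key=lambda t: (-finite_ic(t), -self._depths[t], t))


def load_obo(path, depth_convention: str = "root0") -> OntologyGraph:
    """Load an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Recognized tags: ``id``, ``name``, ``synonym``, ``xref``, ``is_a``,
    ``alt_id``, ``is_obsolete``. Obsolete terms are retained but flagged and
    excluded from structural queries; alternate ids resolve to primaries.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except (ValueError, KeyError) as exc:
        raise OboParseError(f"malformed OBO file {path}: {exc}") from exc

    terms: Dict[str, Term] = {}
    alt: Dict[str, str] = {}
    for node, data in g.nodes(data=True):
        synonyms = set()
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            synonyms.add(m.group(1) if m else raw)
        # obonet turns is_a lines into typed edges; obsolete stanzas may keep
        # the raw attribute instead
        parents = {v for _, v, k in g.out_edges(node, keys=True) if k == "is_a"}
        parents.update(data.get("is_a", []))
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            synonyms=frozenset(synonyms),
            xrefs=frozenset(data.get("xref", [])),
            parents=frozenset(parents),
            is_obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
        for a in data.get("alt_id", []):
            alt[a] = node
    return OntologyGraph(terms, alt_ids=alt, depth_convention=depth_convention)
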