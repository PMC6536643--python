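"""Functional gene network and best-match-average gene-set similarity.

The network is a weighted undirected graph in the HumanNet style: each edge
carries a log-likelihood score (LLS) for a true functional linkage between
two genes. Pairwise gene similarity is the globally min-max normalized LLS
(LLSN); two identical genes have similarity 1 and unlinked genes 0. Gene-set
similarity is the best-match average (BMA): every gene contributes its best
match in the opposite set, summed in both directions and divided by the
total set size.
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

from .errors import UndefinedSimilarityError

logger = logging.getLogger(__name__)

Pair = FrozenSet[str]


def _pair(g1: str, g2: str) -> Pair:
    return frozenset((g1, g2))


class GeneNetwork:
    """Weighted undirected gene graph with raw and normalized edge weights.

    Self-edges are dropped. Duplicate or reciprocal edges are collapsed by
    keeping the maximum LLS (logged). The normalization extremes
    ``lls_min``/``lls_max`` are computed once over the whole network.

    A degenerate network in which every edge carries the same LLS would make
    the min-max normalization 0/0; existing edges are then given normalized
    weight 1.0 (with a warning), preserving the ordering "edge present >
    edge absent".
    """

    def __init__(self, edges: Mapping[Pair, float]) -> None:
        self._edges: Dict[Pair, float] = {}
        for pair, lls in edges.items():
            if len(pair) != 2:
                continue  # self-edge
            self._edges[frozenset(pair)] = float(lls)
        if self._edges:
            values = self._edges.values()
            self.lls_min = min(values)
            self.lls_max = max(values)
        else:
            self.lls_min = self.lls_max = 0.0
        self._degenerate = bool(self._edges) and self.lls_max == self.lls_min
        if self._degenerate:
            logger.warning(
                "degenerate network: all %d edges share LLS %g; "
                "normalized weight defined as 1.0",
                len(self._edges),
                self.lls_max,
            )

    @classmethod
    def from_edges(cls, triples: Iterable[Tuple[str, str, float]]) -> "GeneNetwork":
        edges: Dict[Pair, float] = {}
        n_dup = n_self = 0
        for g1, g2, lls in triples:
            if g1 == g2:
                n_self += 1
                continue
            p = _pair(g1, g2)
            if p in edges:
                n_dup += 1
                edges[p] = max(edges[p], float(lls))
            else:
                edges[p] = float(lls)
        if n_dup or n_self:
            logger.info(
                "collapsed %d duplicate edges (kept max LLS), dropped %d self-edges",
                n_dup,
                n_self,
            )
        return cls(edges)

    @classmethod
    def from_tsv(cls, path) -> "GeneNetwork":
        """Read a HumanNet-style edge list: gene1 <tab> gene2 <tab> LLS."""

        def rows():
            with open(path, newline="") as fh:
                for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                    if not row or row[0].startswith("#"):
                        continue
                    if len(row) < 3:
                        logger.warning("%s line %d: expected 3 columns, skipped", path, i)
                        continue
                    try:
                        yield row[0].strip(), row[1].strip(), float(row[2])
                    except ValueError:
                        logger.warning("%s line %d: non-numeric LLS, skipped", path, i)

        return cls.from_edges(rows())

    def __len__(self) -> int:
        return len(self._edges)

    @property
    def genes(self) -> Set[str]:
        return {g for pair in self._edges for g in pair}

    def has_edge(self, g1: str, g2: str) -> bool:
        return _pair(g1, g2) in self._edges

    def lls(self, g1: str, g2: str) -> float:
        return self._edges[_pair(g1, g2)]

    def normalized_lls(self, g1: str, g2: str) -> float:
        """Min-max normalized LLS of an existing edge, in [0, 1]."""
        raw = self._edges[_pair(g1, g2)]
        if self._degenerate:
            return 1.0
        return (raw - self.lls_min) / (self.lls_max - self.lls_min)


def sim_gene(net: GeneNetwork, g1: str, g2: str) -> float:
    """Pairwise gene similarity: identity 1, linked LLSN, unlinked 0.

    Genes absent from the network participate only through the identity
    case; nothing is imputed for them.
    """
    if g1 == g2:
        return 1.0
    if net.has_edge(g1, g2):
        return net.normalized_lls(g1, g2)
    return 0.0


def sim_max(net: GeneNetwork, k: str, gene_set: Iterable[str]) -> float:
    """Best match: max similarity between gene *k* and any member of *gene_set*."""
    gene_set = set(gene_set)
    if not gene_set:
        raise UndefinedSimilarityError("sim_max over an empty gene set")
    return max(sim_gene(net, k, ki) for ki in gene_set)


def sim_gene_set(net: GeneNetwork, set1: Iterable[str], set2: Iterable[str]) -> float:
    """Best-match-average similarity of two gene sets, in [0, 1].

    With |set1| = m and |set2| = n:

        (sum_{g in set1} max-match(g, set2)
         + sum_{g' in set2} max-match(g', set1)) / (m + n)

    Symmetric by construction; equals 1 for identical sets.

    Raises
    ------
    UndefinedSimilarityError
        If either set is empty — the caller decides the fallback.
    """
    s1, s2 = set(set1), set(set2)
    if not s1 or not s2:
        raise UndefinedSimilarityError("gene-set similarity of an empty set")
    total = sum(sim_max(net, g, s2) for g in s1)
    total += sum(sim_max(net, g, s1) for g in s2)
    return total / (len(s1) + len(s2))
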