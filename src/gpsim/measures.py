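"""Combined disease similarity (GPSim) and literature baselines.

GPSim scores a disease pair as a convex combination of its gene-set
similarity over the functional network and its phenotype-set Dice overlap:

    sim(d1, d2) = beta * simGeneSet(G1, G2) + (1 - beta) * simHPOSet(P1, P2)

with beta in [0, 1] weighting the genetic against the phenotypic channel
(default 0.9, the reported optimum on real data). When exactly one channel
is undefined — a disease with no gene or no phenotype associations — the
combined score falls back to the defined component alone, so diseases with
sparse genetic annotation are still scored; the alternative policy of
treating a missing component as 0 is available via ``policy="zero"``.

Baselines implemented from their one-line literature definitions: Resnik
(IC of the MICA), Lin (IC ratio), Kim (reciprocal shortest DAG distance)
and BOG (gene-set overlap, as a Dice variant).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

from .associations import DGPStore
from .errors import NoDataError, UndefinedSimilarityError
from .gene_network import GeneNetwork, sim_gene_set
from .ontology import OntologyGraph
from .phenotype_sim import sim_hpo_set

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.9


@dataclass(frozen=True)
class SimilarityResult:
    """A scored disease pair with its component and combined similarities.

    ``gene_sim`` / ``pheno_sim`` are None when the corresponding sets were
    empty for either disease; ``combined`` always lies in [0, 1].
    """

    d1: str
    d2: str
    gene_sim: Optional[float]
    pheno_sim: Optional[float]
    combined: float
    beta: float
    method: str = "gpsim"


def combine(
    gene_sim: Optional[float],
    pheno_sim: Optional[float],
    beta: float = DEFAULT_BETA,
    policy: str = "defined_component",
) -> float:
    """Weighted combination of component similarities with fallback policy.

    ``policy="defined_component"`` (default): if exactly one component is
    defined, return it alone. ``policy="zero"``: treat the undefined
    component as 0 in the weighted sum.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if policy not in ("defined_component", "zero"):
        raise ValueError(f"unknown fallback policy: {policy!r}")
    if gene_sim is None and pheno_sim is None:
        raise NoDataError("neither gene nor phenotype similarity is defined")
    if gene_sim is None:
        return (1.0 - beta) * pheno_sim if policy == "zero" else pheno_sim
    if pheno_sim is None:
        return beta * gene_sim if policy == "zero" else gene_sim
    return beta * gene_sim + (1.0 - beta) * pheno_sim


def gpsim(
    store: DGPStore,
    net: GeneNetwork,
    d1: str,
    d2: str,
    beta: float = DEFAULT_BETA,
    policy: str = "defined_component",
) -> SimilarityResult:
    """Score one disease pair; symmetric in (d1, d2).

    Raises :class:`NoDataError` when either disease carries neither gene nor
    phenotype associations (so no component is computable).
    """
    g1, g2 = store.gene_set(d1), store.gene_set(d2)
    p1, p2 = store.phenotype_set(d1), store.phenotype_set(d2)
    gene_sim = sim_gene_set(net, g1, g2) if g1 and g2 else None
    pheno_sim = sim_hpo_set(p1, p2) if p1 and p2 else None
    if gene_sim is None and pheno_sim is None:
        raise NoDataError(
            f"no commensurable associations for pair ({d1}, {d2})"
        )
    return SimilarityResult(
        d1=d1,
        d2=d2,
        gene_sim=gene_sim,
        pheno_sim=pheno_sim,
        combined=combine(gene_sim, pheno_sim, beta, policy),
        beta=beta,
    )


def all_pairs(
    store: DGPStore,
    net: GeneNetwork,
    beta: float = DEFAULT_BETA,
    policy: str = "defined_component",
) -> List[SimilarityResult]:
    """Score every unordered disease pair in the store (self-pairs excluded).

    Cost is O(N^2 * (K^2 + L)) for N diseases with gene sets of size K and
    phenotype sets of size L: N^2 pairs, a K x K best-match scan and an
    O(L) set intersection per pair. Pairs where no component is defined are
    skipped with a logged count.
    """
    results: List[SimilarityResult] = []
    skipped = 0
    for d1, d2 in itertools.combinations(sorted(store.diseases), 2):
        try:
            results.append(gpsim(store, net, d1, d2, beta, policy))
        except NoDataError:
            skipped += 1
    if skipped:
        logger.info("all_pairs: %d pairs had no scorable associations", skipped)
    return results


def results_to_tsv(results: List[SimilarityResult], path) -> None:
    """Write pairwise results as TSV: d1, d2, gene_sim, pheno_sim, combined, method, beta."""
    with open(path, "w") as fh:
        fh.write("d1\td2\tgene_sim\tpheno_sim\tcombined\tmethod\tbeta\n")
        for r in results:
            gs = "" if r.gene_sim is None else repr(r.gene_sim)
            ps = "" if r.pheno_sim is None else repr(r.pheno_sim)
            fh.write(f"{r.d1}\t{r.d2}\t{gs}\t{ps}\t{r.combined!r}\t{r.method}\t{r.beta}\n")


# -- baselines ----------------------------------------------------------


def baseline_resnik(
    do: OntologyGraph, ic: Mapping[str, float], d1: str, d2: str
) -> float:
    """IC of the most informative common ancestor."""
    mica = do.mica(ic, d1, d2)
    v = ic.get(mica, 0.0)
    return v if v != float("inf") else 0.0


def baseline_lin(do: OntologyGraph, ic: Mapping[str, float], d1: str, d2: str) -> float:
    """Lin ratio 2*IC(MICA) / (IC(d1) + IC(d2)); 0 when the denominator is 0."""
    denom = ic.get(d1, 0.0) + ic.get(d2, 0.0)
    if denom == 0.0 or denom == float("inf"):
        return 0.0
    return 2.0 * baseline_resnik(do, ic, d1, d2) / denom


def baseline_kim(do: OntologyGraph, d1: str, d2: str) -> float:
    """Reciprocal of the shortest undirected is-a distance between two terms.

    A self-pair has distance 0; its similarity is capped at 1 rather than
    dividing by zero.
    """
    if do.resolve_id(d1) == do.resolve_id(d2):
        return 1.0
    return 1.0 / do.link_distance(d1, d2)


def baseline_bog(store: DGPStore, d1: str, d2: str) -> float:
    """Gene-set overlap similarity (Dice variant of the BOG idea).

    Raises :class:`UndefinedSimilarityError` if either gene set is empty.
    """
    g1, g2 = store.gene_set(d1), store.gene_set(d2)
    if not g1 or not g2:
        raise UndefinedSimilarityError("BOG with an empty gene set")
    return 2.0 * len(g1 & g2) / (len(g1) + len(g2))


def ic_from_gene_annotations(do: OntologyGraph, store: DGPStore) -> Dict[str, float]:
    """Information content over DO terms using gene-association counts.

    Each disease term's raw count is the size of its gene set; counts
    propagate to ancestors inside ``information_content``.
    """
    counts = {d: len(gs) for d, gs in store.gene_sets.items() if d in do}
    return do.information_content(counts)
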