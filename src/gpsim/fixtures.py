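"""Synthetic ontologies, gene networks, annotation files and benchmarks.

Everything the pipeline consumes can be generated here in the exact
dialects the readers expect (OBO 1.2, HumanNet-style edge lists, HPO
annotation triples, two-column mapping tables, positive-pair TSVs), so the
package builds and tests with no downloads.

The planted-signal benchmark is the core device: designated positive
disease pairs share a controlled fraction (``signal_strength``) of their
gene and phenotype associations, while all other pairs share only
background overlap. At signal 1 a positive pair has identical gene and
phenotype sets; at signal 0 positives are statistically indistinguishable
from random pairs. Signal is planted symmetrically in both channels so
beta sweeps remain meaningful.

Default condition sizes: a 100-disease universe, 300 genes, 200 phenotype
terms, 50 positive pairs, around 5 genes and 6 phenotypes per disease —
small enough to benchmark in seconds yet large enough that 500 random
negative pairs can be drawn per replicate, matching the reference
evaluation protocol.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .evaluation import Pair, as_pair

OBO_HEADER = "format-version: 1.2\nontology: {name}\n"


@dataclass
class FixtureConfig:
    """Knobs for the synthetic world; deterministic given ``seed``."""

    n_diseases: int = 100
    n_genes: int = 300
    n_phenotypes: int = 200
    ontology_depth: int = 6
    mean_genes_per_disease: float = 5.0
    mean_phenotypes_per_disease: float = 6.0
    edge_density: float = 0.05
    lls_range: Tuple[float, float] = (0.5, 5.0)
    lls_distribution: str = "uniform"  # uniform | lognormal
    signal_strength: float = 0.8
    indirect_gene_fraction: float = 0.5
    n_positive_pairs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_diseases", "n_genes", "n_phenotypes", "ontology_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_genes_per_disease <= 0 or self.mean_phenotypes_per_disease <= 0:
            raise ValueError("mean set sizes must be positive")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        low, high = self.lls_range
        if not low < high:
            raise ValueError("lls_range must satisfy low < high")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0 <= self.indirect_gene_fraction <= 1:
            raise ValueError("indirect_gene_fraction must lie in [0, 1]")
        if 2 * self.n_positive_pairs > self.n_diseases:
            raise ValueError("need at least 2 * n_positive_pairs diseases")


@dataclass
class BenchmarkFixture:
    """Paths and ground truth for one generated benchmark world."""

    do_obo: str
    hpo_obo: str
    network: str
    hpo_annotations: str
    id_gene: str
    name_gene: str
    positive_pairs: str
    diseases: List[str]
    positives: List[Pair]
    gene_sets: Dict[str, Set[str]] = field(default_factory=dict)
    phenotype_sets: Dict[str, Set[str]] = field(default_factory=dict)


def _term_ids(kind: str, n: int) -> List[str]:
    prefix = "DOID" if kind.upper() == "DO" else "HP"
    return [f"{prefix}:{i:07d}" for i in range(1, n + 1)]


def make_ontology(cfg: FixtureConfig, kind: str, path, n_terms: int = None) -> str:
    """Write a random rooted single-root DAG as an OBO 1.2 file.

    Term 1 is the root. A chain guarantees at least one term at the
    requested ``ontology_depth``; every other term is assigned a level in
    [1, depth] and draws one or two parents from the level directly above,
    so a term's shortest-path depth equals its level exactly. DO terms get
    unique OMIM and ORPHA xrefs; both kinds get a synonym.
    """
    if n_terms is None:
        n_terms = (cfg.n_diseases if kind.upper() == "DO" else cfg.n_phenotypes) + 1
    depth = cfg.ontology_depth
    if n_terms < depth + 1:
        raise ValueError(
            f"cannot place a depth-{depth} chain in {n_terms} terms"
        )
    rng = np.random.default_rng(cfg.seed + (11 if kind.upper() == "DO" else 13))
    ids = _term_ids(kind, n_terms)
    root = ids[0]
    levels: Dict[str, int] = {root: 0}
    by_level: Dict[int, List[str]] = {0: [root]}
    parents: Dict[str, List[str]] = {root: []}

    # guaranteed-depth chain
    for lvl, tid in enumerate(ids[1 : depth + 1], start=1):
        parents[tid] = [by_level[lvl - 1][0]]
        levels[tid] = lvl
        by_level.setdefault(lvl, []).append(tid)

    for tid in ids[depth + 1 :]:
        lvl = int(rng.integers(1, depth + 1))
        pool = by_level[lvl - 1]
        chosen = [pool[int(rng.integers(len(pool)))]]
        if len(pool) > 1 and rng.random() < 0.3:
            other = pool[int(rng.integers(len(pool)))]
            if other not in chosen:
                chosen.append(other)
        parents[tid] = chosen
        levels[tid] = lvl
        by_level.setdefault(lvl, []).append(tid)

    noun = "disease" if kind.upper() == "DO" else "phenotype"
    with open(path, "w") as fh:
        fh.write(OBO_HEADER.format(name=f"synthetic-{kind.lower()}"))
        for i, tid in enumerate(ids):
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\n")
            if tid == root:
                fh.write(f"name: synthetic {noun} root\n")
            else:
                fh.write(f"name: synthetic {noun} {i}\n")
                fh.write(f'synonym: "S{noun[0].upper()}{i} syndrome" EXACT []\n')
            if kind.upper() == "DO" and tid != root:
                fh.write(f"xref: OMIM:{600000 + i}\n")
                fh.write(f"xref: ORPHA:{10000 + i}\n")
            for p in parents[tid]:
                fh.write(f"is_a: {p}\n")
    return str(path)


def _gene_ids(n: int) -> List[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def make_network(
    cfg: FixtureConfig,
    path,
    genes: Sequence[str] = None,
    planted_edges: Sequence[Tuple[str, str]] = (),
) -> str:
    """Write a HumanNet-style weighted edge list.

    Each unordered gene pair becomes an edge with probability
    ``edge_density``; weights are drawn from ``lls_range`` (uniform by
    default, truncated log-normal optionally). *planted_edges* are written
    additionally with scores in the top decile of the range — these are the
    functional links behind indirectly planted gene sharing. Byte-identical
    for a given config.
    """
    if genes is None:
        genes = _gene_ids(cfg.n_genes)
    rng = np.random.default_rng(cfg.seed + 17)
    low, high = cfg.lls_range
    with open(path, "w") as fh:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() >= cfg.edge_density:
                    continue
                if cfg.lls_distribution == "lognormal":
                    w = low + (high - low) * min(1.0, rng.lognormal(0.0, 0.5) / 4.0)
                else:
                    w = rng.uniform(low, high)
                fh.write(f"{genes[i]}\t{genes[j]}\t{w:.6f}\n")
        for g1, g2 in planted_edges:
            w = rng.uniform(low + 0.9 * (high - low), high)
            fh.write(f"{g1}\t{g2}\t{w:.6f}\n")
    return str(path)


def _planted_sets(
    rng: np.random.Generator,
    pool: Sequence[str],
    mean_size: float,
    diseases: Sequence[str],
    positives: Sequence[Pair],
    signal: float,
    indirect_fraction: float = 0.0,
) -> Tuple[Dict[str, Set[str]], List[Tuple[str, str]]]:
    """Per-disease item sets where positive pairs share a planted fraction.

    Set sizes are 1 + Poisson(mean - 1), drawn independently for every
    disease (so positive pairs are not coupled through their sizes); a
    positive pair's planted budget is round(signal * min(sizes)) items.
    Of that budget, *indirect_fraction* is planted as item pairs — one
    distinct item placed in each set, returned as a linked pair — and the
    rest as literally shared items; indirect planting models diseases whose
    causal genes interact rather than coincide, and a strong network edge
    is later written for each linked pair. At signal 1 the two sets are
    made literally identical (and nothing is planted indirectly).
    """
    sets: Dict[str, Set[str]] = {}
    links: List[Tuple[str, str]] = []
    paired = {d for p in positives for d in p}

    def draw_size() -> int:
        return 1 + int(rng.poisson(max(mean_size - 1.0, 0.0)))

    def sample(n: int, exclude: Set[str] = frozenset()) -> Set[str]:
        avail = [x for x in pool if x not in exclude]
        n = min(n, len(avail))
        idx = rng.choice(len(avail), size=n, replace=False)
        return {avail[i] for i in idx}

    for a, b in positives:
        size_a, size_b = draw_size(), draw_size()
        if signal == 1.0:
            sets[a] = sets[b] = sample(size_a)
            continue
        budget = int(round(signal * min(size_a, size_b)))
        n_indirect = int(round(indirect_fraction * budget))
        shared = sample(budget - n_indirect)
        only_a: Set[str] = set()
        only_b: Set[str] = set()
        for _ in range(n_indirect):
            ga, gb = sorted(sample(2, exclude=shared | only_a | only_b))
            only_a.add(ga)
            only_b.add(gb)
            links.append((ga, gb))
        sets[a] = shared | only_a | sample(
            size_a - budget, exclude=shared | only_a | only_b
        )
        sets[b] = shared | only_b | sample(
            size_b - budget, exclude=shared | only_a | only_b
        )
    for d in diseases:
        if d not in paired:
            sets[d] = sample(draw_size())
    return sets, links


def make_benchmark(cfg: FixtureConfig, outdir) -> BenchmarkFixture:
    """Generate a full benchmark world under *outdir*.

    Emits the DO and HPO ontologies, the gene network, an HPO-style
    disease-gene-phenotype annotation file (mixing OMIM- and DOID-keyed
    rows), SIDD-style id->gene and Dancer-style name->gene tables, and the
    positive-pair file. Returns paths plus the ground-truth sets for
    verification.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    do_path = make_ontology(cfg, "DO", os.path.join(outdir, "do.obo"))
    hpo_path = make_ontology(cfg, "HPO", os.path.join(outdir, "hpo.obo"))

    do_ids = _term_ids("DO", cfg.n_diseases + 1)
    diseases = do_ids[1:]  # every non-root DO term is a disease
    hp_ids = _term_ids("HPO", cfg.n_phenotypes + 1)[1:]
    genes = _gene_ids(cfg.n_genes)

    # disjoint positive pairs
    order = rng.permutation(len(diseases))
    positives = [
        as_pair(diseases[order[2 * i]], diseases[order[2 * i + 1]])
        for i in range(cfg.n_positive_pairs)
    ]

    gene_sets, linked = _planted_sets(
        rng, genes, cfg.mean_genes_per_disease, diseases, positives,
        cfg.signal_strength, cfg.indirect_gene_fraction,
    )
    pheno_sets, _ = _planted_sets(
        rng, hp_ids, cfg.mean_phenotypes_per_disease, diseases, positives, cfg.signal_strength
    )
    net_path = make_network(
        cfg, os.path.join(outdir, "network.tsv"), genes, planted_edges=linked
    )

    # accession per disease: even-index diseases keyed by their OMIM xref,
    # odd by DOID, to exercise both resolution paths
    accession = {
        d: (f"OMIM:{600000 + i + 1}" if i % 2 == 0 else d)
        for i, d in enumerate(diseases)
    }

    annot_path = os.path.join(outdir, "diseases_to_genes_to_phenotypes.tsv")
    with open(annot_path, "w") as fh:
        fh.write("#disease-id\tgene-symbol\tgene-id\tHPO-ID\tHPO-term-name\n")
        for d in diseases:
            gs, ps = sorted(gene_sets[d]), sorted(pheno_sets[d])
            for k in range(max(len(gs), len(ps))):
                g = gs[k % len(gs)]
                p = ps[k % len(ps)]
                fh.write(f"{accession[d]}\t{g}\t{g[1:]}\t{p}\tsynthetic phenotype\n")

    # SIDD-style: every disease-gene association by accession
    sidd_path = os.path.join(outdir, "id_gene.tsv")
    with open(sidd_path, "w") as fh:
        for d in diseases:
            for g in sorted(gene_sets[d]):
                fh.write(f"{accession[d]}\t{g}\n")

    # Dancer-style: a third of the diseases again, keyed by name/synonym
    dancer_path = os.path.join(outdir, "name_gene.tsv")
    with open(dancer_path, "w") as fh:
        for i, d in enumerate(diseases):
            if i % 3:
                continue
            name = f"synthetic disease {i + 1}"
            for g in sorted(gene_sets[d]):
                fh.write(f"{name}\t{g}\n")

    pos_path = os.path.join(outdir, "positive_pairs.tsv")
    with open(pos_path, "w") as fh:
        for a, b in positives:
            fh.write(f"{a}\t{b}\n")

    return BenchmarkFixture(
        do_obo=do_path,
        hpo_obo=hpo_path,
        network=net_path,
        hpo_annotations=annot_path,
        id_gene=sidd_path,
        name_gene=dancer_path,
        positive_pairs=pos_path,
        diseases=list(diseases),
        positives=positives,
        gene_sets=gene_sets,
        phenotype_sets=pheno_sets,
    )


def planted_signal_aucs(
    signal: float,
    n_replicates: int,
    base_seed: int,
    n_neg: int = 500,
    beta: float = 0.9,
    **cfg_kwargs,
) -> List[float]:
    """GPSim AUC over independent synthetic worlds at one signal level.

    Each replicate generates a fresh benchmark world (seed ``base_seed + r``),
    integrates it through the full file pipeline, scores the planted
    positives against *n_neg* freshly sampled negatives and records the AUC.
    Independent worlds (rather than a fixed world with redrawn negatives)
    are used so the replicate mean is an unbiased, low-variance estimate of
    the recovery rate at that signal level.
    """
    import tempfile

    from .associations import build_dgp, hpo_source, parse_hpo_annotation_file
    from .errors import GPSimError
    from .evaluation import BenchmarkSet, evaluate_methods, sample_negatives
    from .gene_network import GeneNetwork
    from .measures import gpsim
    from .ontology import load_obo

    aucs: List[float] = []
    for r in range(n_replicates):
        cfg = FixtureConfig(signal_strength=signal, seed=base_seed + r, **cfg_kwargs)
        with tempfile.TemporaryDirectory() as tmp:
            fx = make_benchmark(cfg, tmp)
            g_do, g_hpo = load_obo(fx.do_obo), load_obo(fx.hpo_obo)
            store = build_dgp(
                g_do, g_hpo, [hpo_source(parse_hpo_annotation_file(fx.hpo_annotations))]
            )
            net = GeneNetwork.from_tsv(fx.network)
        universe = sorted(store.diseases)
        rep = BenchmarkSet(
            positives=tuple(fx.positives),
            negatives=tuple(
                sample_negatives(universe, fx.positives, n_neg, cfg.seed + 1)
            ),
            replicate_index=r,
            seed=cfg.seed,
        )

        def scorer(pair):
            try:
                return gpsim(store, net, *pair, beta=beta).combined
            except GPSimError:
                return None

        aucs.append(evaluate_methods({"gpsim": scorer}, [rep])["gpsim"].aucs[0])
    return aucs


def read_positive_pairs(path) -> List[Pair]:
    """Read a TSV of positive disease pairs (one pair per line)."""
    pairs: List[Pair] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, *_ = line.split("\t")
            pairs.append(as_pair(a, b))
    return pairs
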