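# Methods

## Model

GPSim scores a pair of Disease Ontology terms as a convex combination of
two channels:

* a **genetic channel**: best-match-average (BMA) similarity of the two
  disease gene sets, where pairwise gene similarity is 1 for identical
  genes, the globally min–max normalised log-likelihood score (LLSN) for
  genes joined by an edge of the functional network, and 0 otherwise;
* a **phenotypic channel**: Dice overlap of the two HPO term sets, by
  literal term identity.

The combination weight β defaults to 0.9, the value reported as optimal
on real corpora; it is a parameter everywhere, never a constant. The
measure is symmetric, bounded in [0, 1], and equals 1 for a self-pair with
any non-empty annotation.

Assumptions worth stating explicitly:

* The network's LLS extremes are global properties of the loaded network,
  computed once, so LLSN is comparable across pairs. A degenerate network
  (all edge scores equal) makes the normalisation 0/0; existing edges then
  get weight 1.0, preserving "linked > unlinked" ordering, with a warning.
* Phenotype overlap carries no ontology structure: a parent and child HPO
  term do not match. An ancestor-closure variant exists as an opt-in flag
  (`sim_hpo_set(..., ancestor_closure=True)`) but is off by default,
  keeping the published small-example arithmetic.
* When exactly one channel is undefined (a disease with no gene or no
  phenotype associations) the combined score is the defined channel alone.
  This scores sparsely annotated diseases — the measure's motivating case —
  without inventing a penalty. `policy="zero"` instead treats the missing
  channel as 0. A pair with neither channel raises a no-data error and is
  excluded (and counted) in benchmarks, never imputed.

Scoring all pairs of N diseases costs O(N²·(K² + L)) with gene-set size K
and phenotype-set size L: N² pairs, a K×K best-match scan and an O(L)
intersection each.

## Data integration

Associations are merged onto active DO term ids from three source shapes:
HPO monthly-build disease→gene→phenotype triples (OMIM:/ORPHA:/DOID:
accessions retained), id→gene tables, and name→gene tables. Resolution
rules, in order of precedence:

1. DOID accessions resolve by identity (alternate/merged ids map to their
   primary; obsolete terms never resolve).
2. Other accessions resolve through a unique DO xref.
3. Names resolve by exact equality with a DO name or synonym after
   case-folding, trimming and collapsing internal whitespace. No fuzzy
   matching.

A reference matching two or more DO terms is dropped and logged as an
ambiguity — integration is deterministic, never heuristic. Associations
are not propagated up the DO hierarchy by default (`propagate_up` is the
opt-in). Phenotype filtering keeps HPO terms at depth ≥ `min_depth` and
drops a disease's phenotype entry when fewer than `min_count` survive;
gene sets are never touched by the phenotype filter.

## Ontology conventions

* Depth is the shortest is-a path to the root, with the root at depth 0
  (`depth_convention="root0"`). The alternative root-at-1 convention is a
  constructor flag, since depth-threshold filters are sometimes quoted
  against either convention. Shortest-path is the conservative reading for
  minimum-specificity cutoffs.
* Information content is −log p with natural log by default (`log_base`
  overrides); p(t) is the descendant-propagated annotation count of t over
  the root's. Terms with zero propagated mass get IC = ∞ and are treated
  as IC 0 inside MICA selection.
* MICA ties on IC break by greater depth, then lexicographically smaller
  id, so results are reproducible across runs and platforms.
* Files with several top-level terms get a virtual root inserted above
  them so depth and MICA are total functions.

## Baselines

Implemented from their standard one-line definitions: Resnik (IC of the
MICA), Lin (2·IC(MICA)/(IC(d₁)+IC(d₂)), 0 on a zero denominator), Kim
(reciprocal shortest undirected is-a distance; the self-pair, distance 0,
is capped at similarity 1), and BOG as Dice overlap of gene sets. The
original BOG and Zhang publications use more elaborate parameterisations
that are not reproduced here; the gene-only GPSim configuration (β = 1)
serves as the SemFunSim-like comparator. These are comparison points, not
re-implementations of record.

## Benchmark protocol

A benchmark set is a fixed list of positive disease pairs plus `n_neg`
negative pairs sampled uniformly without replacement from all unordered
pairs over the disease universe (default: diseases present in the store),
excluding self-pairs and positives. The reference protocol uses 500
negatives and 100 replicates; replicate *i* draws with seed
`base_seed + i`, so the whole experiment is one reproducible artifact.
Whether a sampled negative coincides with a true but unlisted association
is not controlled for — this is what makes mean AUCs float by a couple of
percent across draws, so the dispersion is always reported.

The ROC sweeps thresholds descending and the AUC is the trapezoidal
integral, which equals the normalised Mann–Whitney U statistic with
half-credit for ties (the suite asserts this identity against a
pair-counting oracle to 1e-12). The curve itself comes from
scikit-learn's `roc_curve` with no intermediate-point dropping.

## Synthetic data generator

The generator emulates the full input universe in the exact dialects the
readers consume: OBO 1.2 ontologies (single root, guaranteed maximum
depth via a chain, random 1–2 parents per term from the level above so
depth equals level, unique names/synonyms, unique OMIM/ORPHA xrefs on DO
terms), a HumanNet-style edge list (Bernoulli edges at `edge_density`,
uniform LLS in `lls_range` by default, log-normal optional), HPO-style
annotation triples (alternating OMIM- and DOID-keyed rows to exercise
both resolution paths), SIDD-style and Dancer-style gene tables, and a
positive-pair file.

Planted signal: `n_positive_pairs` disjoint disease pairs share a fraction
`signal_strength` of their annotation budget in both channels. Set sizes
are 1 + Poisson(mean − 1), drawn independently per disease so positive
pairs are not coupled through size. Of a pair's shared-gene budget,
`indirect_gene_fraction` (default 0.5) is planted as *distinct* genes
joined by a top-decile network edge rather than as identical genes —
modelling diseases whose causal genes interact rather than coincide,
which is precisely the regime where network-aware similarity should beat
plain gene-overlap counting. At `signal_strength = 1` the two sets are
made literally identical (and nothing is planted indirectly), so a fully
planted pair scores exactly 1.

Default condition sizes — 100 diseases, 300 genes, 200 phenotype terms,
50 positive pairs, ~5 genes and ~6 phenotypes per disease, edge density
0.05, LLS in (0.5, 5.0) — keep every disease in the sparse-genetic-
annotation regime the measure targets while leaving enough pair space to
draw 500 negatives per replicate.

What the generator does **not** emulate: real DO/HPO topology statistics
(term fan-out, depth distributions), HumanNet's actual LLS distribution,
annotation biases (shared "popular" genes across unrelated diseases), or
noisy/partial name matching. Passing the planted-signal tests therefore
shows the pipeline recovers known structure under controlled conditions —
it does not certify performance numbers on the real corpora, which depend
on specific database releases. The harness accepts the real files
directly (`gpsim build --do doid.obo --hpo hp.obo --hpo-annotations
ALL_SOURCES_ALL_FREQUENCIES_diseases_to_genes_to_phenotypes.txt ...`) for
anyone who has them.

For recovery experiments, replicates are *independent worlds* (fresh
generator seed per replicate) rather than one world with redrawn
negatives: with a single world the fixed positives' scores put an
irreducible floor (~0.04 AUC s.d. at 50 positives) under the replicate
mean, while independent worlds shrink it by √n_replicates. The suite's
recovery check uses 20 worlds per signal level and 500 negatives each.

## Numerical choices and degenerate inputs

* Duplicate or reciprocal network edges collapse to the maximum LLS
  (configurable in principle; max is the loader's behaviour, logged);
  self-edges are dropped.
* Empty gene or phenotype sets raise an undefined-similarity signal; the
  combination layer, not the kernels, owns the fallback.
* Malformed annotation or network rows are skipped with a logged line
  number, never silently.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; equal seeds give byte-identical generator output
  and bit-identical benchmark replicates.

## Known limitations

* Name matching is exact-after-normalisation; typos or lexical variants in
  name-keyed sources simply fail to resolve (counted, logged).
* IC-based baselines depend on the annotation corpus supplied for IC; the
  CLI derives IC from the store's gene counts, which is one defensible
  choice among several.
* The phenotype channel ignores HPO term frequency and negation.
* `all_pairs` is quadratic in diseases; it is meant for thousands, not
  millions, of terms.
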