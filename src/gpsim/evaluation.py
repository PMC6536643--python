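"""Benchmarking protocol: replicate test sets, ROC curves and averaged AUC.

The protocol mirrors the standard disease-similarity evaluation: a fixed
set of positive disease pairs is combined with randomly sampled negative
pairs (500 per test set in the reference protocol), the scorer under test
ranks all pairs, and the ROC/AUC is computed; the experiment is repeated
over independently seeded replicates (100 in the reference protocol) and
the AUCs averaged. Because negatives are random, mean AUCs fluctuate by a
couple of percent across draws — the dispersion is reported alongside the
mean.

Negative pairs are sampled uniformly without replacement from all unordered
pairs over a caller-supplied disease universe (by default the diseases in
the DGP store), excluding self-pairs and known positives. Every source of
randomness derives deterministically from a base seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import BenchmarkError

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]

POS = "pos"
NEG = "neg"


def as_pair(d1: str, d2: str) -> Pair:
    """Canonical unordered pair representation (sorted tuple)."""
    return (d1, d2) if d1 <= d2 else (d2, d1)


@dataclass(frozen=True)
class BenchmarkSet:
    """Labeled disease pairs for one replicate."""

    positives: Tuple[Pair, ...]
    negatives: Tuple[Pair, ...]
    replicate_index: int
    seed: int

    def __post_init__(self) -> None:
        pos, neg = set(self.positives), set(self.negatives)
        if pos & neg:
            raise BenchmarkError("positives and negatives overlap")
        if any(a == b for a, b in pos | neg):
            raise BenchmarkError("self-pairs are not allowed")
        if len(pos) != len(self.positives) or len(neg) != len(self.negatives):
            raise BenchmarkError("duplicate pairs within a class")

    @property
    def pairs(self) -> List[Pair]:
        return list(self.positives) + list(self.negatives)

    def label(self, pair: Pair) -> str:
        return POS if pair in set(self.positives) else NEG


@dataclass
class RocResult:
    """An ROC curve with its trapezoidal area.

    ``thresholds`` are descending score cutpoints; ``fpr``/``tpr`` run from
    (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def sample_negatives(
    universe: Sequence[str],
    positives: Iterable[Pair],
    n: int,
    seed: int,
) -> List[Pair]:
    """Draw *n* negative pairs uniformly without replacement.

    The candidate space is all unordered pairs over *universe* excluding
    self-pairs and *positives*. Deterministic given *seed*.
    """
    pos = {as_pair(*p) for p in positives}
    candidates = [
        p
        for p in itertools.combinations(sorted(set(universe)), 2)
        if p not in pos
    ]
    if n > len(candidates):
        raise BenchmarkError(
            f"requested {n} negatives but only {len(candidates)} candidate pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def build_replicates(
    universe: Sequence[str],
    positives: Iterable[Pair],
    n_neg: int,
    n_reps: int,
    base_seed: int,
) -> List[BenchmarkSet]:
    """Build *n_reps* benchmark sets sharing positives, with fresh negatives.

    Replicate *i* draws its negatives with seed ``base_seed + i``, so the
    whole experiment is reproducible from one base seed.
    """
    pos = tuple(sorted({as_pair(*p) for p in positives}))
    return [
        BenchmarkSet(
            positives=pos,
            negatives=tuple(sample_negatives(universe, pos, n_neg, base_seed + i)),
            replicate_index=i,
            seed=base_seed + i,
        )
        for i in range(n_reps)
    ]


def roc_auc(scores: Mapping[Pair, float], labels: Mapping[Pair, str]) -> RocResult:
    """ROC curve and area for a scored, labeled pair collection.

    Thresholds are swept descending; the area is the trapezoidal integral,
    which on tied scores is equivalent to the half-credit (Mann-Whitney)
    convention. Requires at least one positive and one negative.
    """
    pairs = list(scores)
    y = np.array([1 if labels[p] == POS else 0 for p in pairs])
    s = np.array([scores[p] for p in pairs], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise BenchmarkError("ROC needs both a positive and a negative example")
    fpr, tpr, thresholds = _roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


Scorer = Callable[[Pair], Optional[float]]


@dataclass
class MethodEvaluation:
    """Per-method benchmark outcome: replicate AUCs plus summaries."""

    aucs: List[float]
    n_undefined: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs))


def evaluate_methods(
    methods: Mapping[str, Scorer],
    replicates: Sequence[BenchmarkSet],
) -> Dict[str, MethodEvaluation]:
    """Score every method on the identical replicates and average the AUCs.

    A scorer returns a similarity for an unordered pair, or None when the
    similarity is undefined for that pair (e.g. a disease with no usable
    associations); undefined pairs are excluded from that method's ROC with
    a logged count, never imputed as 0.
    """
    out: Dict[str, MethodEvaluation] = {
        name: MethodEvaluation(aucs=[]) for name in methods
    }
    for rep in replicates:
        label_map = {p: POS for p in rep.positives}
        label_map.update({p: NEG for p in rep.negatives})
        for name, scorer in methods.items():
            scores: Dict[Pair, float] = {}
            for pair in rep.pairs:
                val = scorer(pair)
                if val is None:
                    out[name].n_undefined += 1
                else:
                    scores[pair] = val
            result = roc_auc(scores, label_map)
            out[name].aucs.append(result.auc)
    for name, ev in out.items():
        if ev.n_undefined:
            logger.info(
                "method %s: %d pair scores undefined and excluded", name, ev.n_undefined
            )
    return out
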