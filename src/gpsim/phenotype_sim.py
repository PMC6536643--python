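"""Phenotype-set similarity as Dice overlap of HPO term sets.

Overlap is by literal term identity: a parent and a child HPO term do not
match, and no information-content weighting is applied. An opt-in ancestor
closure is available for callers who want each set replaced by its is-a
closure before the overlap is taken; it is off by default.
"""

from __future__ import annotations

from typing import Iterable, Optional, Set

from .errors import UndefinedSimilarityError
from .ontology import OntologyGraph


def sim_hpo_set(
    set1: Iterable[str],
    set2: Iterable[str],
    hpo: Optional[OntologyGraph] = None,
    ancestor_closure: bool = False,
) -> float:
    """Dice coefficient of two phenotype term sets: 2|P1 ∩ P2| / (|P1| + |P2|).

    Parameters
    ----------
    set1, set2:
        HPO term id collections; duplicates are ignored.
    hpo, ancestor_closure:
        When *ancestor_closure* is true, each set is replaced by the union of
        its terms' ancestors in *hpo* before the overlap is computed.

    Raises
    ------
    UndefinedSimilarityError
        If either set is empty — the caller decides the fallback.
    """
    p1: Set[str] = set(set1)
    p2: Set[str] = set(set2)
    if not p1 or not p2:
        raise UndefinedSimilarityError("phenotype-set similarity of an empty set")
    if ancestor_closure:
        if hpo is None:
            raise ValueError("ancestor_closure requires the HPO graph")
        p1 = set().union(*(hpo.ancestors(t) for t in p1))
        p2 = set().union(*(hpo.ancestors(t) for t in p2))
    return 2.0 * len(p1 & p2) / (len(p1) + len(p2))
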