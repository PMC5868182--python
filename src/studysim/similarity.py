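"""Similarity measures over annotation profiles.

Three base measures are provided -- Resnik best-match-average, cosine and
Jaccard -- each usable on unweighted (merged) and weighted profiles, plus the
study-wise meta-measure that matches each query study against the best item
study and averages.

Profiles enter the vector measures after ancestor propagation
(:func:`propagate`).  When one ancestor covers several annotated descendants
with different counts, its entry is the **maximum** of those counts (this
reduces to all-ones in the unweighted case); a ``rule="sum"`` variant is
available.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set, Union

from studysim.corpus import StudyCorpus, to_merged, to_weighted
from studysim.ontology import ICTable, Ontology, mica

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileVector",
    "propagate",
    "resnik_bma",
    "cosine",
    "jaccard",
    "studywise_sim",
    "score",
    "MEASURES",
    "MODELS",
]

#: class id -> positive count after ancestor propagation (the q / i vectors)
ProfileVector = Dict[str, float]

#: multiset of class ids: mapping id -> count, or iterable with repetitions
Multiset = Union[Mapping[str, float], Iterable[str]]

MEASURES = ("resnik", "cosine", "jaccard")
MODELS = ("merged", "weighted", "studywise", "studywise_shuffled")


def _as_counts(classes: Multiset) -> Dict[str, float]:
    if isinstance(classes, Mapping):
        return {c: float(m) for c, m in classes.items() if m > 0}
    counts: Dict[str, float] = {}
    for c in classes:
        counts[c] = counts.get(c, 0.0) + 1.0
    return counts


def propagate(classes: Multiset, ont: Ontology, rule: str = "max") -> ProfileVector:
    """Turn a (multi)set of class ids into a propagated profile vector.

    Every ancestor of an annotated class enters the support.  Under the
    default ``rule="max"`` an entry is the maximum multiplicity over the
    annotated classes in its descendant-or-self set; ``rule="sum"`` adds them
    instead.  Passing a plain set yields the unweighted all-ones vector.
    """
    if rule not in ("max", "sum"):
        raise ValueError(f"unknown propagation rule {rule!r}")
    counts = _as_counts(classes)
    vec: ProfileVector = {}
    for c, m in counts.items():
        for a in ont.ancestors(c):  # raises KeyError on unknown class
            if rule == "max":
                if vec.get(a, 0.0) < m:
                    vec[a] = m
            else:
                vec[a] = vec.get(a, 0.0) + m
    return vec


def _default_pair_ic(ont: Ontology, ic: ICTable) -> Callable[[str, str], float]:
    def pair_ic(c1: str, c2: str) -> float:
        return mica(ont, ic, c1, c2)[1]

    return pair_ic


def resnik_bma(
    Q: Multiset,
    I: Multiset,
    ont: Ontology,
    ic: ICTable,
    pair_ic: Callable[[str, str], float] | None = None,
) -> float:
    """Query-directed Resnik best-match-average.

    ``(1/|Q|) * sum over c1 in Q of max over c2 in I of IC(MICA(c1, c2))``
    where ``|Q|`` counts multiplicity.  An empty item profile scores 0 by
    convention; an empty query is an error (undefined normalisation).  Not
    symmetric in its arguments.
    """
    q_counts = _as_counts(Q)
    i_counts = _as_counts(I)
    if not q_counts:
        raise ValueError("empty query profile: Resnik BMA is undefined")
    if not i_counts:
        return 0.0
    if pair_ic is None:
        pair_ic = _default_pair_ic(ont, ic)
    total = 0.0
    size = 0.0
    for c1, m in q_counts.items():
        best = max(pair_ic(c1, c2) for c2 in i_counts)
        total += m * best
        size += m
    return total / size


def cosine(q: ProfileVector, i: ProfileVector) -> float:
    """Cosine of the angle between two propagated profile vectors.

    Returns 0 if either vector is empty (documented convention); the result
    lies in [0, 1] since all entries are non-negative.
    """
    if not q or not i:
        return 0.0
    if len(i) < len(q):
        q, i = i, q
    dot = sum(v * i[c] for c, v in q.items() if c in i)
    nq = math.sqrt(sum(v * v for v in q.values()))
    ni = math.sqrt(sum(v * v for v in i.values()))
    return dot / (nq * ni)


def jaccard(q: ProfileVector, i: ProfileVector) -> float:
    """Weighted Jaccard index: sum of entrywise minima over entrywise maxima.

    Two empty vectors score 0 with a warning (the degenerate 0/0 case never
    arises for filtered corpora).
    """
    if not q and not i:
        logger.warning("jaccard of two empty profiles; returning 0")
        return 0.0
    min_sum = 0.0
    max_sum = 0.0
    for c in q.keys() | i.keys():
        a = q.get(c, 0.0)
        b = i.get(c, 0.0)
        if a < b:
            min_sum += a
            max_sum += b
        else:
            min_sum += b
            max_sum += a
    return min_sum / max_sum if max_sum > 0 else 0.0


def _base_measure(
    name: str,
    sq: Set[str],
    si: Set[str],
    ont: Ontology,
    ic: ICTable,
    pair_ic: Callable[[str, str], float] | None,
) -> float:
    if name in ("resnik", "resnik_bma"):
        if not sq:
            raise ValueError("empty query study")
        return resnik_bma(sq, si, ont, ic, pair_ic=pair_ic)
    if name == "cosine":
        return cosine(propagate(sq, ont), propagate(si, ont))
    if name == "jaccard":
        return jaccard(propagate(sq, ont), propagate(si, ont))
    raise ValueError(f"unknown measure {name!r}")


def studywise_sim(
    Qs: Sequence[Iterable[str]],
    Is: Sequence[Iterable[str]],
    base: str,
    ont: Ontology,
    ic: ICTable,
    pair_ic: Callable[[str, str], float] | None = None,
) -> float:
    """Study-wise meta-measure: best-matching item study per query study.

    ``(1/|Qs|) * sum over s_q in Qs of max over s_i in Is of base(s_q, s_i)``.
    Each study's class list is read as an unweighted set.  Empty ``Is``
    scores 0; empty ``Qs`` is an error.
    """
    study_sets_q = [set(s) for s in Qs]
    study_sets_i = [set(s) for s in Is]
    if not study_sets_q:
        raise ValueError("empty query study list")
    if not study_sets_i:
        return 0.0
    total = 0.0
    for sq in study_sets_q:
        total += max(
            _base_measure(base, sq, si, ont, ic, pair_ic)
            for si in study_sets_i
        )
    return total / len(study_sets_q)


def score(
    query_item: str,
    target_item: str,
    corpus: StudyCorpus,
    model: str,
    measure: str,
    ont: Ontology,
    ic: ICTable,
) -> float:
    """Similarity of ``target_item`` to ``query_item`` under a model/measure.

    ``model`` is one of ``merged`` (unweighted flat profiles), ``weighted``
    (study-occurrence counts), ``studywise`` or ``studywise_shuffled`` (the
    study-wise meta-measure with unweighted base; for the shuffled model the
    corpus must already be shuffled).  ``measure`` is one of ``resnik``,
    ``cosine``, ``jaccard``.
    """
    if measure not in ("resnik", "resnik_bma", "cosine", "jaccard"):
        raise ValueError(f"unknown measure {measure!r}")
    if model in ("studywise", "studywise_shuffled", "shuffled"):
        return studywise_sim(
            corpus.study_lists(query_item),
            corpus.study_lists(target_item),
            measure,
            ont,
            ic,
        )
    if model == "merged":
        q: Multiset = to_merged(corpus, query_item)
        i: Multiset = to_merged(corpus, target_item)
    elif model == "weighted":
        q = to_weighted(corpus, query_item)
        i = to_weighted(corpus, target_item)
    else:
        raise ValueError(f"unknown model {model!r}")
    if measure in ("resnik", "resnik_bma"):
        return resnik_bma(q, i, ont, ic)
    qv = propagate(q, ont)
    iv = propagate(i, ont)
    return cosine(qv, iv) if measure == "cosine" else jaccard(qv, iv)
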