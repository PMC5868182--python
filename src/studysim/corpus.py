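"""Study-structured annotation corpora and the four derived annotation models.

An item (a disease or a gene) is represented as an ordered list of studies,
each study being an ordered list of ontology class ids.  From this structure
four views are derived:

* *merged* -- the flat unique set of classes (:func:`to_merged`);
* *weighted* -- a multiset counting in how many studies each class occurs
  (:func:`to_weighted`);
* *study-wise* -- the study lists themselves;
* *study-wise shuffled* -- a null model that randomly exchanges classes
  between an item's studies while keeping the number of studies and each
  study's length fixed (:func:`shuffle_studywise`).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

from studysim.ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "Study",
    "StudyCorpus",
    "load_corpus",
    "write_corpus",
    "to_merged",
    "to_weighted",
    "shuffle_studywise",
    "filter_items",
]

#: A study: (study id, ordered list of class ids).
Study = Tuple[str, List[str]]


@dataclass
class StudyCorpus:
    """Map from item id to its ordered list of studies.

    Within one study class ids are unique after loading (duplicate mentions
    collapse), but the same class may occur in several studies of one item.
    After :func:`shuffle_studywise` a study list may contain duplicates; they
    are collapsed only where a measure reads the list as a set.
    """

    items: Dict[str, List[Study]] = field(default_factory=dict)
    #: number of input rows dropped because their class id was unknown
    dropped_rows: int = 0

    def __contains__(self, item: str) -> bool:
        return item in self.items

    def __len__(self) -> int:
        return len(self.items)

    def studies(self, item: str) -> List[Study]:
        if item not in self.items:
            raise KeyError(f"unknown item {item!r}")
        return self.items[item]

    def study_lists(self, item: str) -> List[List[str]]:
        """The per-study class lists of ``item`` (without study ids)."""
        return [classes for _, classes in self.studies(item)]

    def item_class_sets(self) -> Dict[str, Set[str]]:
        """Merged (item-level) class sets for all items; used for IC."""
        return {item: to_merged(self, item) for item in self.items}

    def n_mentions(self, item: str) -> int:
        return sum(len(classes) for _, classes in self.studies(item))

    def to_json_models(self) -> Dict[str, dict]:
        """Export all four annotation models per item (for docs and tests)."""
        out: Dict[str, dict] = {}
        for item in sorted(self.items):
            out[item] = {
                "merged": sorted(to_merged(self, item)),
                "weighted": dict(sorted(to_weighted(self, item).items())),
                "studywise": [
                    {"study": sid, "classes": list(classes)}
                    for sid, classes in self.studies(item)
                ],
            }
        return out


class CorpusFormatError(ValueError):
    """A malformed row in a corpus TSV file."""


def load_corpus(path, ont: Ontology) -> StudyCorpus:
    """Load a 3-column TSV corpus (``item_id  study_id  class_id``).

    One mention per row; ``#`` starts a comment line.  Rows whose class id is
    not inside the ontology (root subgraph) are dropped and counted in
    ``dropped_rows``; duplicate mentions within one (item, study) collapse.

    Raises
    ------
    CorpusFormatError
        On a row with fewer than three columns, naming the line number.
    """
    items: Dict[str, Dict[str, List[str]]] = {}
    order: Dict[str, List[str]] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            item, study, cls = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if cls not in ont:
                dropped += 1
                continue
            studies = items.setdefault(item, {})
            if study not in studies:
                studies[study] = []
                order.setdefault(item, []).append(study)
            if cls not in studies[study]:
                studies[study].append(cls)
    if dropped:
        logger.warning("dropped %d rows with class ids outside the ontology",
                       dropped)
    corpus = StudyCorpus(dropped_rows=dropped)
    for item, studies in items.items():
        corpus.items[item] = [(sid, studies[sid]) for sid in order[item]]
    return corpus


def write_corpus(corpus: StudyCorpus, path) -> None:
    """Write a corpus as a 3-column mention TSV (inverse of :func:`load_corpus`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# item_id\tstudy_id\tclass_id\n")
        for item in sorted(corpus.items):
            for sid, classes in corpus.items[item]:
                for cls in classes:
                    fh.write(f"{item}\t{sid}\t{cls}\n")


def write_models_json(corpus: StudyCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(corpus.to_json_models(), fh, indent=2)


def to_merged(corpus: StudyCorpus, item: str) -> Set[str]:
    """Flat unique class set of ``item`` (union over its studies)."""
    merged: Set[str] = set()
    for _, classes in corpus.studies(item):
        merged.update(classes)
    return merged


def to_weighted(corpus: StudyCorpus, item: str) -> Dict[str, int]:
    """Class -> number of distinct studies of ``item`` mentioning it."""
    counts: Dict[str, int] = {}
    for _, classes in corpus.studies(item):
        for cls in set(classes):
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def shuffle_studywise(
    corpus: StudyCorpus,
    n_swaps_per_item: int = 1000,
    seed: int = 0,
) -> StudyCorpus:
    """Return a shuffled copy of ``corpus`` (the null annotation model).

    Per item, ``n_swaps_per_item`` iterations each draw two studies uniformly
    with replacement and one random position in each, then exchange the two
    classes.  Drawing the same study twice is a counted no-op.  The number of
    studies, each study's list length and the item's total mention multiset
    are invariant.  Items with fewer than two studies are left unchanged.
    Deterministic given ``seed``; items are processed in sorted id order.
    """
    rng = random.Random(seed)
    shuffled = StudyCorpus(dropped_rows=corpus.dropped_rows)
    for item in sorted(corpus.items):
        studies = [(sid, list(classes)) for sid, classes in corpus.items[item]]
        if len(studies) >= 2:
            for _ in range(n_swaps_per_item):
                a = rng.randrange(len(studies))
                b = rng.randrange(len(studies))
                if a == b:
                    continue
                la, lb = studies[a][1], studies[b][1]
                ia = rng.randrange(len(la))
                ib = rng.randrange(len(lb))
                la[ia], lb[ib] = lb[ib], la[ia]
        shuffled.items[item] = studies
    return shuffled


def filter_items(
    corpus: StudyCorpus,
    min_annotations: int = 5,
    min_studies: int = 4,
    policy: str = "strict",
) -> StudyCorpus:
    """Filter items by merged annotation count and study count.

    ``policy="strict"`` (default) keeps an item only if it has at least
    ``min_annotations`` merged classes AND at least ``min_studies`` studies.
    ``policy="literal"`` removes an item only when it fails both thresholds
    (the weaker reading of removing items with too few annotations *and* too
    few studies).
    """
    if policy not in ("strict", "literal"):
        raise ValueError(f"unknown filter policy {policy!r}")
    kept = StudyCorpus(dropped_rows=corpus.dropped_rows)
    for item, studies in corpus.items.items():
        n_ann = len(to_merged(corpus, item))
        n_stu = len(studies)
        ok_ann = n_ann >= min_annotations
        ok_stu = n_stu >= min_studies
        keep = (ok_ann and ok_stu) if policy == "strict" else (ok_ann or ok_stu)
        if keep:
            kept.items[item] = [(sid, list(classes)) for sid, classes in studies]
    return kept
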