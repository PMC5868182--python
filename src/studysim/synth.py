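"""Deterministic generators for toy ontologies, corpora and group tables.

Every other module is testable offline with these fixtures.  Generated
corpora have a tunable *within-study coherence*: each group of items owns a
topic block (a subtree of the ontology) and each study of a member draws all
its classes from that block with probability ``coherence``, from the whole
ontology otherwise.  Group members therefore share signal exactly to the
degree that studies are topically pure, which is what the study-wise
annotation model is designed to exploit.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from studysim.benchmark import GroupTable
from studysim.corpus import StudyCorpus
from studysim.ontology import ICTable, Ontology, OntologyClass, compute_ic

__all__ = [
    "GeneratorConfig",
    "generate_ontology",
    "generate_corpus",
    "make_toy",
    "toy_ic",
    "write_obo",
]


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic ontology/corpus generators."""

    n_classes: int = 120
    max_children: int = 6
    depth: int = 3
    n_items: int = 30  # background items, in addition to group members
    n_groups: int = 5
    items_per_group: int = 4
    studies_per_item: Tuple[int, int] = (2, 5)
    classes_per_study: Tuple[int, int] = (2, 5)
    #: probability that a study draws all its classes from one topic block
    #: (its item's core or a private topic); the rest are uniform junk studies
    coherence: float = 0.8
    #: per-class probability of replacement by a uniformly random class
    noise_rate: float = 0.0
    #: probability that a topical study covers the core topic rather than a
    #: private one
    core_topic_rate: float = 0.65
    #: item-specific side topics (random class bundles unique to the item)
    n_private_topics: int = 2
    #: number of classes in each private topic bundle
    private_topic_size: int = 8
    #: concentration of within-block class frequencies (0 = uniform)
    zipf: float = 0.8
    #: fraction of classes receiving a second (shallower) parent
    multi_parent_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "max_children", "depth", "n_groups",
                     "items_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_items < 0:
            raise ValueError("n_items must be non-negative")
        if self.n_private_topics < 0:
            raise ValueError("n_private_topics must be non-negative")
        if self.private_topic_size < 1:
            raise ValueError("private_topic_size must be positive")
        for name in ("coherence", "noise_rate", "core_topic_rate",
                     "multi_parent_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.zipf < 0:
            raise ValueError("zipf must be non-negative")
        for name in ("studies_per_item", "classes_per_study"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a valid positive range")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("studies_per_item", "classes_per_study"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


ROOT_ID = "C:0000000"


def _class_id(i: int) -> str:
    return f"C:{i:07d}"


def generate_ontology(cfg: GeneratorConfig) -> Ontology:
    """Generate a rooted DAG, deterministic per seed.

    Classes are attached level by level (``depth=1`` yields a star); a
    fraction of classes at level >= 2 receives a second parent at a strictly
    shallower level, exercising multi-parent MICA paths without risking
    cycles.
    """
    rng = random.Random(f"ontology-{cfg.seed}")
    classes: Dict[str, OntologyClass] = {
        ROOT_ID: OntologyClass(id=ROOT_ID, name="root term")
    }
    levels: Dict[str, int] = {ROOT_ID: 0}
    n_children: Dict[str, int] = {ROOT_ID: 0}
    by_level: List[List[str]] = [[ROOT_ID]]
    for i in range(1, cfg.n_classes):
        cid = _class_id(i)
        candidates = [
            p for p in classes
            if levels[p] < cfg.depth and n_children[p] < cfg.max_children
        ]
        if not candidates:  # all full: ignore the fan-out cap
            candidates = [p for p in classes if levels[p] < cfg.depth]
        parent = rng.choice(sorted(candidates))
        level = levels[parent] + 1
        parents = [parent]
        if level >= 2 and rng.random() < cfg.multi_parent_fraction:
            shallower = [
                c for lv in range(1, level) for c in by_level[lv]
                if c != parent
            ]
            if shallower:
                parents.append(rng.choice(sorted(shallower)))
        classes[cid] = OntologyClass(
            id=cid,
            name=f"term {i:07d}",
            synonyms=[f"synonym {i:07d}"],
            parents=parents,
        )
        levels[cid] = level
        n_children[cid] = 0
        for p in parents:
            n_children[p] += 1
        while len(by_level) <= level:
            by_level.append([])
        by_level[level].append(cid)
    return Ontology(classes, ROOT_ID)


def _subtree(ont: Ontology, root: str) -> List[str]:
    children: Dict[str, List[str]] = {cid: [] for cid in ont.classes}
    for cid, cls in ont.classes.items():
        for p in cls.parents:
            children[p].append(cid)
    out: List[str] = []
    stack = [root]
    seen: Set[str] = set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        out.append(node)
        stack.extend(children[node])
    return sorted(out)


def _topic_blocks(ont: Ontology, min_size: int = 3) -> List[List[str]]:
    """Subtrees rooted at depth-2 classes (depth-1 if the DAG is shallow)."""
    depth2 = [cid for cid in ont.classes if _min_depth(ont, cid) == 2]
    if not depth2:
        depth2 = [cid for cid in ont.classes if _min_depth(ont, cid) == 1]
    blocks = [_subtree(ont, cid) for cid in sorted(depth2)]
    sized = [b for b in blocks if len(b) >= min_size]
    return sized or blocks


def _min_depth(ont: Ontology, cid: str) -> int:
    if cid == ont.root:
        return 0
    return 1 + min(_min_depth(ont, p) for p in ont.classes[cid].parents)


def generate_corpus(
    ont: Ontology, cfg: GeneratorConfig
) -> Tuple[StudyCorpus, GroupTable]:
    """Generate a study corpus plus a matching group table.

    Every item has a *core* topic block (a subtree shared by its group) and
    ``n_private_topics`` private topics of its own -- random class bundles
    unique to the item, standing in for study-specific aspects that no other
    item repeats.  With probability ``coherence`` a study draws all its
    classes from one topic -- the core with probability ``core_topic_rate``,
    a private topic otherwise; the remaining studies are uniform junk.
    Group members share their group's core block; background items get a
    random core.  Within a topic, class frequencies fall off as a power law
    (``zipf``), so studies of the same topic repeat its common classes --
    the structure the weighted and study-wise models exploit.  Private and
    junk mentions pollute the merged profile but stay confined to single
    studies, which is exactly what best-match study pairing can ignore and
    study-shuffling spreads.

    Deterministic per seed (integer/str-seeded ``random.Random`` only).
    """
    rng = random.Random(f"corpus-{cfg.seed}")
    blocks = _topic_blocks(ont)
    all_classes = sorted(c for c in ont.classes if c != ont.root)
    groups = GroupTable()
    corpus = StudyCorpus()

    # assign topic blocks to groups, without replacement while possible
    block_order = list(range(len(blocks)))
    rng.shuffle(block_order)
    group_blocks = [
        blocks[block_order[g % len(blocks)]] for g in range(cfg.n_groups)
    ]

    def sample_block(block: List[str], k: int) -> List[str]:
        weights = [1.0 / (j + 1) ** cfg.zipf for j in range(len(block))]
        chosen = rng.choices(block, weights=weights, k=k)
        return list(dict.fromkeys(chosen))  # study-level uniqueness

    def make_item(item: str, core: List[str]) -> None:
        privates = [
            rng.sample(all_classes, min(cfg.private_topic_size,
                                        len(all_classes)))
            for _ in range(cfg.n_private_topics)
        ]
        n_studies = rng.randint(*cfg.studies_per_item)
        studies = []
        for s in range(n_studies):
            k = rng.randint(*cfg.classes_per_study)
            if rng.random() < cfg.coherence:
                if privates and rng.random() >= cfg.core_topic_rate:
                    chosen = sample_block(rng.choice(privates), k)
                else:
                    chosen = sample_block(core, k)
            else:
                chosen = list(dict.fromkeys(rng.choices(all_classes, k=k)))
            if cfg.noise_rate > 0:
                chosen = list(dict.fromkeys(
                    rng.choice(all_classes)
                    if rng.random() < cfg.noise_rate else c
                    for c in chosen
                ))
            studies.append((f"s{s + 1}", chosen))
        corpus.items[item] = studies

    idx = 0
    for g in range(cfg.n_groups):
        gid = f"G{g + 1:04d}"
        groups.groups[gid] = set()
        for _ in range(cfg.items_per_group):
            item = f"I{idx:05d}"
            idx += 1
            groups.groups[gid].add(item)
            make_item(item, group_blocks[g])
    for _ in range(cfg.n_items):
        item = f"I{idx:05d}"
        idx += 1
        make_item(item, rng.choice(blocks))
    return corpus, groups


# ---------------------------------------------------------------------------
# Fixed toy fixture used by the worked examples
# ---------------------------------------------------------------------------

def make_toy() -> Tuple[Ontology, StudyCorpus]:
    """The fixed six-class toy ontology and its reference corpus.

    Ontology: root R with children A and B; A1, A2 under A; B1 under B.
    Corpus: three single-study reference items I1 {A1, A2}, I2 {A1, B1},
    I3 {B} (these drive the IC table, see :func:`toy_ic`) and the
    three-study item D1 with studies [A1], [A1, A2], [B1].
    """
    classes = {
        "R": OntologyClass(id="R", name="root"),
        "A": OntologyClass(id="A", name="branch a", parents=["R"]),
        "B": OntologyClass(id="B", name="branch b", parents=["R"]),
        "A1": OntologyClass(id="A1", name="leaf a1", parents=["A"]),
        "A2": OntologyClass(id="A2", name="leaf a2", parents=["A"]),
        "B1": OntologyClass(id="B1", name="leaf b1", parents=["B"]),
    }
    ont = Ontology(classes, "R")
    corpus = StudyCorpus()
    corpus.items["I1"] = [("s1", ["A1", "A2"])]
    corpus.items["I2"] = [("s1", ["A1", "B1"])]
    corpus.items["I3"] = [("s1", ["B"])]
    corpus.items["D1"] = [("s1", ["A1"]), ("s2", ["A1", "A2"]),
                          ("s3", ["B1"])]
    return ont, corpus


TOY_IC_ITEMS = ("I1", "I2", "I3")


def toy_ic(ont: Optional[Ontology] = None,
           corpus: Optional[StudyCorpus] = None) -> ICTable:
    """IC table of the toy fixture, computed from the reference items only.

    D1 is the example query item and is excluded from the frequency counts,
    which keeps the worked IC values (e.g. ``ic[A] = -ln(2/3)``) intact.
    """
    if ont is None or corpus is None:
        ont, corpus = make_toy()
    sets = {
        item: classes
        for item, classes in corpus.item_class_sets().items()
        if item in TOY_IC_ITEMS
    }
    return compute_ic(ont, sets)


def write_obo(ont: Ontology, path) -> None:
    """Serialise an ontology as a minimal OBO 1.2 flat file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for cid in sorted(ont.classes):
            cls = ont.classes[cid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {cls.id}\n")
            if cls.name:
                fh.write(f"name: {cls.name}\n")
            for syn in cls.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for p in cls.parents:
                fh.write(f"is_a: {p} ! {ont.classes[p].name}\n")
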