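"""Ontology loading, ancestor queries, information content and MICA.

Only ``is_a`` edges are considered (the go-basic convention); classes that are
not descendants of the chosen root are discarded at load time, as are obsolete
terms.  Information content is computed from item-level annotation frequencies
under the true-path rule: an item annotated to a class counts for every
ancestor of that class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Set, Tuple

__all__ = [
    "OntologyClass",
    "Ontology",
    "ICTable",
    "CycleError",
    "parse_obo",
    "ancestors",
    "compute_ic",
    "mica",
]


class CycleError(ValueError):
    """Raised when the ``is_a`` graph contains a cycle.

    The offending cycle (a list of class ids, first == last) is available as
    the ``cycle`` attribute.
    """

    def __init__(self, cycle: List[str]):
        self.cycle = list(cycle)
        super().__init__("is_a cycle detected: " + " -> ".join(self.cycle))


@dataclass
class OntologyClass:
    """A single ontology class with its ``is_a`` parents."""

    id: str
    name: str = ""
    synonyms: List[str] = field(default_factory=list)
    parents: List[str] = field(default_factory=list)
    obsolete: bool = False


class Ontology:
    """A rooted DAG of :class:`OntologyClass` objects connected by ``is_a``.

    Parameters
    ----------
    classes:
        Mapping from class id to :class:`OntologyClass`.  Parent references
        must stay inside the mapping.
    root:
        Id of the designated root class.  Every retained class must reach the
        root via ``is_a`` edges.

    Raises
    ------
    KeyError
        If ``root`` is not among ``classes``.
    CycleError
        If the ``is_a`` graph is cyclic.
    ValueError
        If some class cannot reach the root.
    """

    def __init__(self, classes: Mapping[str, OntologyClass], root: str):
        if root not in classes:
            raise KeyError(f"root class {root!r} not found in ontology")
        self.classes: Dict[str, OntologyClass] = dict(classes)
        self.root = root
        self._ancestor_cache: Dict[str, frozenset] = {}
        _check_acyclic(self.classes)
        for cid in self.classes:
            if root not in self.ancestors(cid):
                raise ValueError(
                    f"class {cid!r} does not reach the root {root!r}"
                )

    def __contains__(self, cid: str) -> bool:
        return cid in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def parents(self, cid: str) -> List[str]:
        return self.classes[cid].parents

    def ancestors(self, cid: str) -> frozenset:
        """Reflexive-transitive ``is_a`` closure of ``cid`` (includes itself)."""
        cached = self._ancestor_cache.get(cid)
        if cached is not None:
            return cached
        if cid not in self.classes:
            raise KeyError(f"unknown class id {cid!r}")
        # iterative DFS; memoizes every class on the way up
        result: Set[str] = {cid}
        stack = list(self.classes[cid].parents)
        while stack:
            p = stack.pop()
            if p in result:
                continue
            cached_p = self._ancestor_cache.get(p)
            if cached_p is not None:
                result |= cached_p
            else:
                result.add(p)
                stack.extend(self.classes[p].parents)
        frozen = frozenset(result)
        self._ancestor_cache[cid] = frozen
        return frozen

    def surface_forms(self) -> Iterable[Tuple[str, str]]:
        """Yield ``(surface form, class id)`` pairs for names and synonyms."""
        for cid, cls in self.classes.items():
            if cls.name:
                yield cls.name, cid
            for syn in cls.synonyms:
                yield syn, cid


def _check_acyclic(classes: Mapping[str, OntologyClass]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {cid: WHITE for cid in classes}
    for start in classes:
        if color[start] != WHITE:
            continue
        # path-tracking iterative DFS over parent edges
        stack: List[Tuple[str, int]] = [(start, 0)]
        path: List[str] = []
        while stack:
            node, idx = stack.pop()
            if idx == 0:
                color[node] = GREY
                path.append(node)
            parents = classes[node].parents
            advanced = False
            while idx < len(parents):
                p = parents[idx]
                idx += 1
                if p not in classes:
                    continue
                if color[p] == GREY:
                    cycle = path[path.index(p):] + [p]
                    raise CycleError(cycle)
                if color[p] == WHITE:
                    stack.append((node, idx))
                    stack.append((p, 0))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                path.pop()


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------

def _parse_obo_stanzas(lines: Iterable[str]) -> Dict[str, OntologyClass]:
    classes: Dict[str, OntologyClass] = {}
    current: OntologyClass | None = None
    in_term = False
    for raw in lines:
        line = raw.strip()
        if line.startswith("["):
            if current is not None and current.id:
                classes[current.id] = current
            in_term = line == "[Term]"
            current = OntologyClass(id="") if in_term else None
            continue
        if not in_term or current is None or not line or line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            current.id = value
        elif tag == "name":
            current.name = value
        elif tag == "is_a":
            target = value.split("!")[0].split("{")[0].strip()
            if target:
                current.parents.append(target)
        elif tag == "synonym":
            # synonym: "some text" EXACT []
            if value.startswith('"'):
                end = value.find('"', 1)
                if end > 0:
                    current.synonyms.append(value[1:end])
        elif tag == "is_obsolete":
            current.obsolete = value.lower().startswith("true")
    if current is not None and current.id:
        classes[current.id] = current
    return classes


def parse_obo(path, root: str) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file and restrict it to the subgraph of
    ``root``.

    Only the tags ``id``, ``name``, ``is_a``, ``synonym`` and ``is_obsolete``
    are honoured.  Obsolete terms and classes that do not reach ``root`` via
    ``is_a`` are dropped; synonyms are retained for dictionary building.

    Raises
    ------
    KeyError
        If ``root`` does not occur in the file.
    CycleError
        If the ``is_a`` graph is cyclic.
    """
    with open(path, encoding="utf-8") as fh:
        parsed = _parse_obo_stanzas(fh)
    parsed = {cid: c for cid, c in parsed.items() if not c.obsolete}
    if root not in parsed:
        raise KeyError(f"root class {root!r} not found in {path}")
    _check_acyclic(parsed)
    # keep classes whose upward closure contains root
    keep: Dict[str, bool] = {}

    def reaches_root(cid: str) -> bool:
        if cid in keep:
            return keep[cid]
        if cid == root:
            keep[cid] = True
            return True
        keep[cid] = False  # placeholder; graph is acyclic so no live cycle
        result = any(
            p in parsed and reaches_root(p) for p in parsed[cid].parents
        )
        keep[cid] = result
        return result

    retained: Dict[str, OntologyClass] = {}
    for cid, cls in parsed.items():
        if reaches_root(cid):
            retained[cid] = OntologyClass(
                id=cls.id,
                name=cls.name,
                synonyms=list(cls.synonyms),
                parents=[],  # filled below with retained parents only
                obsolete=False,
            )
    for cid, cls in parsed.items():
        if cid in retained and cid != root:
            retained[cid].parents = [p for p in cls.parents if p in retained]
    retained[root].parents = []
    return Ontology(retained, root)


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Per-class information content computed from annotated items.

    ``ic[c] = -log(n_c / n_items)`` where ``n_c`` counts the items annotated
    with ``c`` or any of its descendants.  Classes never annotated (directly
    or via descendants) carry ``math.inf`` and are excluded from MICA results.
    """

    ic: Dict[str, float]
    n_items: int

    def __getitem__(self, cid: str) -> float:
        return self.ic.get(cid, math.inf)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for cid in sorted(self.ic):
                fh.write(f"{cid}\t{self.ic[cid]:.10g}\n")

    @classmethod
    def from_tsv(cls, path, n_items: int = 0) -> "ICTable":
        table: Dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cid, value = line.split("\t")
                table[cid] = float(value)
        return cls(ic=table, n_items=n_items)


def _item_class_sets(corpus) -> Dict[str, Set[str]]:
    """Accept a StudyCorpus-like object or a plain ``{item: classes}`` map."""
    if hasattr(corpus, "item_class_sets"):
        return corpus.item_class_sets()
    return {item: set(classes) for item, classes in corpus.items()}


def compute_ic(ont: Ontology, corpus, log_base: float = math.e) -> ICTable:
    """Compute the :class:`ICTable` for ``ont`` from item-level annotations.

    Study multiplicity is ignored: each item contributes at most once to the
    count of any class.  Annotations are propagated to all ancestors before
    counting (true-path rule).  The logarithm defaults to the natural log;
    pass e.g. ``log_base=2`` for bits.
    """
    sets = _item_class_sets(corpus)
    counts: Dict[str, int] = {cid: 0 for cid in ont.classes}
    n_items = 0
    for _, classes in sorted(sets.items()):
        propagated: Set[str] = set()
        for c in classes:
            if c in ont:
                propagated |= ont.ancestors(c)
        if not propagated:
            continue
        n_items += 1
        for c in propagated:
            counts[c] += 1
    if n_items == 0:
        raise ValueError("empty corpus: no item has annotations under the root")
    log = math.log if log_base == math.e else (lambda x: math.log(x, log_base))
    table = {
        cid: (-log(cnt / n_items) if cnt > 0 else math.inf)
        for cid, cnt in counts.items()
    }
    # guard against -0.0 for fully annotated classes
    table = {cid: (0.0 if v == 0 else v) for cid, v in table.items()}
    return ICTable(ic=table, n_items=n_items)


def ancestors(ont: Ontology, cid: str) -> Set[str]:
    """Reflexive-transitive ``is_a`` closure of ``cid`` as a plain set."""
    return set(ont.ancestors(cid))


def mica(ont: Ontology, ic: ICTable, c1: str, c2: str) -> Tuple[str, float]:
    """Most informative common ancestor of ``c1`` and ``c2``.

    Common ancestry is reflexive (a class subsumes itself).  Classes with
    infinite IC (never annotated) are skipped; the root always qualifies, so a
    result always exists.  Ties are broken deterministically: the most
    specific class wins (largest ancestor closure, so ``mica(c, c) == c``
    even when an ancestor has equal IC), then the lexicographically smallest
    id.
    """
    common = ont.ancestors(c1) & ont.ancestors(c2)
    best: Tuple[float, float, str] | None = None
    for c in common:
        value = ic[c]
        if math.isinf(value):
            continue
        key = (-value, -len(ont.ancestors(c)), c)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(
            f"no common ancestor of {c1!r} and {c2!r} has finite IC"
        )
    return best[2], -best[0]
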