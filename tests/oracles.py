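"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive -- repeated edge relaxation, exhaustive
pair tables, full enumeration of sign assignments -- and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
import random
from typing import Dict, Iterable, List, Sequence, Set, Tuple

# ---------------------------------------------------------------------------
# graph / IC / MICA oracles
# ---------------------------------------------------------------------------

def brute_ancestors(edges: Dict[str, List[str]], c: str) -> Set[str]:
    """Reflexive-transitive closure by repeated edge relaxation."""
    closure = {c}
    changed = True
    while changed:
        changed = False
        for node in list(closure):
            for parent in edges.get(node, []):
                if parent not in closure:
                    closure.add(parent)
                    changed = True
    return closure


def brute_ic(
    edges: Dict[str, List[str]], item_sets: Dict[str, Set[str]]
) -> Dict[str, float]:
    """Per class: count items annotated with it or any descendant, -ln."""
    annotated = {
        item: set().union(*(brute_ancestors(edges, c) for c in classes))
        for item, classes in item_sets.items()
        if classes
    }
    n = len(annotated)
    all_classes = set(edges)
    for parents in edges.values():
        all_classes.update(parents)
    out = {}
    for c in all_classes:
        count = sum(1 for s in annotated.values() if c in s)
        out[c] = -math.log(count / n) if count else math.inf
    return out


def brute_mica(
    edges: Dict[str, List[str]],
    ic: Dict[str, float],
    c1: str,
    c2: str,
) -> Tuple[str, float]:
    """Enumerate the ancestor-set intersection; argmax IC, most-specific then
    smallest-id ties."""
    common = brute_ancestors(edges, c1) & brute_ancestors(edges, c2)
    finite = [c for c in common if math.isfinite(ic.get(c, math.inf))]
    best = sorted(
        finite, key=lambda c: (-ic[c], -len(brute_ancestors(edges, c)), c)
    )[0]
    return best, ic[best]


def random_dag(
    rng: random.Random, n_nodes: int, extra_parent_p: float = 0.25
) -> Dict[str, List[str]]:
    """Random rooted DAG as a parent-edge map; node 0 is the root."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    edges: Dict[str, List[str]] = {names[0]: []}
    for i in range(1, n_nodes):
        parents = [names[rng.randrange(i)]]
        if i >= 2 and rng.random() < extra_parent_p:
            second = names[rng.randrange(i)]
            if second != parents[0]:
                parents.append(second)
        edges[names[i]] = parents
    return edges


# ---------------------------------------------------------------------------
# similarity oracles
# ---------------------------------------------------------------------------

def brute_propagate(
    edges: Dict[str, List[str]], counts: Dict[str, float], rule: str = "max"
) -> Dict[str, float]:
    vec: Dict[str, float] = {}
    for c, m in counts.items():
        for a in brute_ancestors(edges, c):
            if rule == "max":
                vec[a] = max(vec.get(a, 0.0), m)
            else:
                vec[a] = vec.get(a, 0.0) + m
    return vec


def brute_resnik_bma(
    edges: Dict[str, List[str]],
    ic: Dict[str, float],
    Q: Sequence[str],
    I: Sequence[str],
) -> float:
    """Exhaustive pair table over all (c1, c2), multiplicities included."""
    if not list(Q):
        raise ValueError("empty query")
    if not list(I):
        return 0.0
    total = 0.0
    for c1 in Q:
        total += max(brute_mica(edges, ic, c1, c2)[1] for c2 in I)
    return total / len(list(Q))


def brute_cosine(q: Dict[str, float], i: Dict[str, float]) -> float:
    if not q or not i:
        return 0.0
    keys = set(q) | set(i)
    dot = sum(q.get(k, 0.0) * i.get(k, 0.0) for k in keys)
    nq = math.sqrt(sum(v * v for v in q.values()))
    ni = math.sqrt(sum(v * v for v in i.values()))
    return dot / (nq * ni)


def brute_jaccard(q: Dict[str, float], i: Dict[str, float]) -> float:
    keys = set(q) | set(i)
    if not keys:
        return 0.0
    mins = sum(min(q.get(k, 0.0), i.get(k, 0.0)) for k in keys)
    maxs = sum(max(q.get(k, 0.0), i.get(k, 0.0)) for k in keys)
    return mins / maxs if maxs else 0.0


def brute_studywise(
    edges: Dict[str, List[str]],
    ic: Dict[str, float],
    Qs: Sequence[Iterable[str]],
    Is: Sequence[Iterable[str]],
    base: str,
) -> float:
    """Exhaustive study-pair matrix, unweighted base measure."""
    def base_sim(sq: Set[str], si: Set[str]) -> float:
        if base == "resnik":
            return brute_resnik_bma(edges, ic, sorted(sq), sorted(si))
        qv = brute_propagate(edges, {c: 1.0 for c in sq})
        iv = brute_propagate(edges, {c: 1.0 for c in si})
        return brute_cosine(qv, iv) if base == "cosine" else brute_jaccard(qv, iv)

    Qsets = [set(s) for s in Qs]
    Isets = [set(s) for s in Is]
    if not Qsets:
        raise ValueError("empty query study list")
    if not Isets:
        return 0.0
    return sum(max(base_sim(sq, si) for si in Isets) for sq in Qsets) / len(Qsets)


# ---------------------------------------------------------------------------
# benchmark oracles
# ---------------------------------------------------------------------------

def brute_auprc(pairs: Sequence[Tuple[float, int]]) -> float:
    """Hand-rolled trapezoid over threshold points, leading recall-0 anchor."""
    ordered = sorted(pairs, key=lambda p: -p[0])
    n_pos = sum(label for _, label in ordered)
    points: List[Tuple[float, float]] = []
    tp = fp = 0
    idx = 0
    while idx < len(ordered):
        threshold = ordered[idx][0]
        while idx < len(ordered) and ordered[idx][0] == threshold:
            if ordered[idx][1]:
                tp += 1
            else:
                fp += 1
            idx += 1
        points.append((tp / n_pos, tp / (tp + fp)))
    points = [(0.0, points[0][1])] + points
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2.0
    return area


def brute_wilcoxon_less(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact one-sided p by enumerating all 2^n sign assignments.

    Tie-averaged ranks; zero differences dropped.  Usable for n <= ~14.
    """
    d = [a - b for a, b in zip(x, y) if a != b]
    n = len(d)
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1..j
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2 ** n


def quantile_type7(values: Sequence[float], p: float) -> float:
    """R's default (type 7) quantile by closed-form linear interpolation."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
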