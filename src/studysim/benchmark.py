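"""Group-recovery evaluation of annotation models and similarity measures.

Every retained member of every retained group serves once as query; all other
filtered items are ranked by similarity to the query and the ranks of the
remaining group members are recorded.  Pooled (score, label) pairs feed a
precision-recall curve; rank lists from two configurations are compared with
a one-sided paired Wilcoxon signed-rank test matching R's ``wilcox.test``
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from studysim.corpus import (
    StudyCorpus,
    filter_items,
    shuffle_studywise,
    to_merged,
    to_weighted,
)
from studysim.ontology import ICTable, Ontology, mica
from studysim.similarity import cosine, jaccard, propagate, resnik_bma

__all__ = [
    "GroupTable",
    "RankRecord",
    "PRCurve",
    "BenchmarkConfig",
    "Scorer",
    "load_groups",
    "write_groups",
    "rank_candidates",
    "candidate_ranks",
    "run_group_recovery",
    "precision_recall",
    "wilcoxon_signed_rank",
    "summarize_corpus",
]


@dataclass
class GroupTable:
    """Map from group id to its set of member item ids."""

    groups: Dict[str, Set[str]] = field(default_factory=dict)

    def restrict(self, items: Iterable[str]) -> "GroupTable":
        """Intersect every group with ``items``; empty groups are dropped."""
        keep = set(items)
        out = GroupTable()
        for gid, members in self.groups.items():
            retained = members & keep
            if retained:
                out.groups[gid] = retained
        return out


def load_groups(path) -> GroupTable:
    """Read a 2-column TSV (``group_id  item_id``); '#' starts a comment."""
    table = GroupTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            table.groups.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return table


def write_groups(table: GroupTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# group_id\titem_id\n")
        for gid in sorted(table.groups):
            for item in sorted(table.groups[gid]):
                fh.write(f"{gid}\t{item}\n")


@dataclass(frozen=True)
class RankRecord:
    """Rank of one sought group member in one query's candidate list."""

    query: str
    sought: str
    rank: float  # fractional under tie-averaging
    n_candidates: int


@dataclass
class PRCurve:
    """Precision-recall points (one per distinct score threshold) and AU-PRC.

    ``points[0]`` is the leading anchor at recall 0 with the precision of the
    first threshold block, so that the trapezoidal integral of the stored
    points equals ``auprc``.
    """

    points: List[Tuple[float, float]]
    auprc: float


@dataclass
class BenchmarkConfig:
    """Filters and policies for a group-recovery run."""

    min_annotations: int = 5
    min_studies: int = 4
    filter_policy: str = "strict"
    max_group_size: Optional[int] = None
    tie: str = "mean"  # or "worst"
    n_swaps: int = 1000
    seed: int = 0


class Scorer:
    """Memoising pairwise scorer over a fixed corpus/model/measure.

    Produces scores identical to :func:`studysim.similarity.score`; caches
    propagated profiles, per-study vectors, MICA pair ICs and study-pair
    similarities so that all-against-all ranking stays fast.
    """

    def __init__(
        self,
        corpus: StudyCorpus,
        model: str,
        measure: str,
        ont: Ontology,
        ic: ICTable,
    ):
        if model not in ("merged", "weighted", "studywise",
                         "studywise_shuffled", "shuffled"):
            raise ValueError(f"unknown model {model!r}")
        if measure not in ("resnik", "resnik_bma", "cosine", "jaccard"):
            raise ValueError(f"unknown measure {measure!r}")
        self.corpus = corpus
        self.model = model
        self.measure = "resnik" if measure == "resnik_bma" else measure
        self.ont = ont
        self.ic = ic
        self._pair_ic_cache: Dict[Tuple[str, str], float] = {}
        self._profiles: Dict[str, dict] = {}
        self._study_sets: Dict[str, List[Set[str]]] = {}
        self._study_vecs: Dict[str, List[dict]] = {}
        self._study_sim_cache: Dict[Tuple, float] = {}

    # -- cached primitives ------------------------------------------------
    def pair_ic(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        value = self._pair_ic_cache.get(key)
        if value is None:
            value = mica(self.ont, self.ic, c1, c2)[1]
            self._pair_ic_cache[key] = value
        return value

    def _profile(self, item: str) -> dict:
        prof = self._profiles.get(item)
        if prof is None:
            if self.model == "merged":
                raw = to_merged(self.corpus, item)
            else:
                raw = to_weighted(self.corpus, item)
            prof = {
                "raw": raw,
                "vec": propagate(raw, self.ont)
                if self.measure in ("cosine", "jaccard") else None,
            }
            self._profiles[item] = prof
        return prof

    def _studies(self, item: str) -> Tuple[List[Set[str]], List[dict]]:
        if item not in self._study_sets:
            sets = [set(s) for s in self.corpus.study_lists(item)]
            self._study_sets[item] = sets
            if self.measure in ("cosine", "jaccard"):
                self._study_vecs[item] = [propagate(s, self.ont) for s in sets]
        return self._study_sets[item], self._study_vecs.get(item, [])

    def _study_sim(self, q_item: str, qi: int, i_item: str, ii: int) -> float:
        if self.measure == "resnik":
            key = ("r", q_item, qi, i_item, ii)  # BMA is query-directed
        else:
            a, b = (q_item, qi), (i_item, ii)
            key = ("s",) + (a + b if a <= b else b + a)
        value = self._study_sim_cache.get(key)
        if value is not None:
            return value
        q_sets, q_vecs = self._studies(q_item)
        i_sets, i_vecs = self._studies(i_item)
        if self.measure == "resnik":
            value = resnik_bma(q_sets[qi], i_sets[ii], self.ont, self.ic,
                               pair_ic=self.pair_ic)
        elif self.measure == "cosine":
            value = cosine(q_vecs[qi], i_vecs[ii])
        else:
            value = jaccard(q_vecs[qi], i_vecs[ii])
        self._study_sim_cache[key] = value
        return value

    # -- public scoring ---------------------------------------------------
    def score(self, query_item: str, target_item: str) -> float:
        if self.model in ("studywise", "studywise_shuffled", "shuffled"):
            q_sets, _ = self._studies(query_item)
            i_sets, _ = self._studies(target_item)
            if not q_sets:
                raise ValueError("empty query study list")
            if not i_sets:
                return 0.0
            total = 0.0
            for qi in range(len(q_sets)):
                total += max(
                    self._study_sim(query_item, qi, target_item, ii)
                    for ii in range(len(i_sets))
                )
            return total / len(q_sets)
        qp = self._profile(query_item)
        ip = self._profile(target_item)
        if self.measure == "resnik":
            return resnik_bma(qp["raw"], ip["raw"], self.ont, self.ic,
                              pair_ic=self.pair_ic)
        if self.measure == "cosine":
            return cosine(qp["vec"], ip["vec"])
        return jaccard(qp["vec"], ip["vec"])


def _check_query_filters(
    corpus: StudyCorpus, query: str, config: BenchmarkConfig
) -> None:
    if query not in corpus:
        raise KeyError(f"unknown query item {query!r}")
    n_ann = len(to_merged(corpus, query))
    n_stu = len(corpus.studies(query))
    failures = []
    if n_ann < config.min_annotations:
        failures.append(
            f"min_annotations ({n_ann} < {config.min_annotations})"
        )
    if n_stu < config.min_studies:
        failures.append(f"min_studies ({n_stu} < {config.min_studies})")
    if config.filter_policy == "strict":
        if failures:
            raise ValueError(
                f"query {query!r} removed by filter: " + ", ".join(failures)
            )
    elif len(failures) == 2:
        raise ValueError(
            f"query {query!r} removed by filter: " + ", ".join(failures)
        )


def rank_candidates(
    query: str,
    corpus: StudyCorpus,
    model: str,
    measure: str,
    ont: Ontology,
    ic: ICTable,
    config: Optional[BenchmarkConfig] = None,
    scorer: Optional[Scorer] = None,
) -> List[Tuple[str, float]]:
    """Score all items except ``query`` and sort by descending score.

    If ``config`` is given, the item filter is applied first and a query that
    fails it raises an error naming the failing filter.  Ties keep a
    deterministic item-id order in the returned list; fractional tie ranks
    come from :func:`candidate_ranks`.
    """
    if config is not None:
        _check_query_filters(corpus, query, config)
        corpus = filter_items(corpus, config.min_annotations,
                              config.min_studies, config.filter_policy)
    if query not in corpus:
        raise KeyError(f"unknown query item {query!r}")
    if scorer is None:
        scorer = Scorer(corpus, model, measure, ont, ic)
    scored = [
        (item, scorer.score(query, item))
        for item in sorted(corpus.items)
        if item != query
    ]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return scored


def candidate_ranks(
    scored: Sequence[Tuple[str, float]], tie: str = "mean"
) -> Dict[str, float]:
    """Item -> rank (1 = best) with tied blocks averaged (or worst-ranked)."""
    if tie not in ("mean", "worst"):
        raise ValueError(f"unknown tie policy {tie!r}")
    scores = np.array([s for _, s in scored], dtype=float)
    method = "average" if tie == "mean" else "max"
    ranks = rankdata(-scores, method=method)
    return {item: float(r) for (item, _), r in zip(scored, ranks)}


def run_group_recovery(
    corpus: StudyCorpus,
    groups: GroupTable,
    model: str,
    measure: str,
    ont: Ontology,
    ic: ICTable,
    config: Optional[BenchmarkConfig] = None,
) -> Tuple[List[RankRecord], List[Tuple[float, int]]]:
    """Run the full group-recovery benchmark.

    Applies the item filter, shuffles the corpus first for the
    ``studywise_shuffled`` model, drops groups with fewer than two retained
    members (and larger than ``max_group_size`` if set), and uses every
    retained member of every retained group as query once.

    Returns the rank records of all sought members and the pooled
    ``(score, label)`` pairs over all (query, candidate) scorings.
    """
    config = config or BenchmarkConfig()
    filtered = filter_items(corpus, config.min_annotations,
                            config.min_studies, config.filter_policy)
    if model in ("studywise_shuffled", "shuffled"):
        filtered = shuffle_studywise(filtered, config.n_swaps, config.seed)
    retained_groups = {}
    for gid in sorted(groups.groups):
        members = groups.groups[gid] & set(filtered.items)
        if len(members) < 2:
            continue
        if config.max_group_size is not None and len(members) > config.max_group_size:
            continue
        retained_groups[gid] = members
    scorer = Scorer(filtered, model, measure, ont, ic)
    records: List[RankRecord] = []
    pooled: List[Tuple[float, int]] = []
    for gid, members in retained_groups.items():
        for query in sorted(members):
            scored = rank_candidates(query, filtered, model, measure, ont, ic,
                                     scorer=scorer)
            ranks = candidate_ranks(scored, tie=config.tie)
            n_candidates = len(scored)
            for item, s in scored:
                label = 1 if item in members else 0
                pooled.append((s, label))
                if label:
                    records.append(
                        RankRecord(query, item, ranks[item], n_candidates)
                    )
    return records, pooled


def precision_recall(pairs: Sequence[Tuple[float, int]]) -> PRCurve:
    """Precision-recall curve over pooled (score, label) pairs.

    Pairs are sorted by descending score; one point is emitted after each
    distinct score threshold.  The area is the trapezoidal integral including
    a leading anchor at recall 0 with the first block's precision.
    """
    labels = np.array([l for _, l in pairs], dtype=int)
    scores = np.array([s for s, _ in pairs], dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision_recall requires at least one positive label")
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    labels = labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    # indices closing each distinct-score block
    last_of_block = np.nonzero(np.append(scores[1:] != scores[:-1], True))[0]
    precision = tp[last_of_block] / (tp[last_of_block] + fp[last_of_block])
    recall = tp[last_of_block] / n_pos
    points = [(0.0, float(precision[0]))]
    points += [(float(r), float(p)) for r, p in zip(recall, precision)]
    rs = np.array([r for r, _ in points])
    ps = np.array([p for _, p in points])
    auprc = float(np.trapezoid(ps, rs))
    return PRCurve(points=points, auprc=auprc)


def _exact_signed_rank_cdf(ranks: Sequence[int], w: float) -> float:
    """P(W+ <= w) for the exact null over 2^n sign assignments."""
    total = sum(ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    threshold = int(math.floor(w + 1e-9))
    return float(counts[: threshold + 1].sum() / counts.sum())


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "less",
) -> float:
    """One-sided paired Wilcoxon signed-rank p-value (R conventions).

    Zero differences are dropped.  With at most 25 remaining pairs and no
    ties among the absolute differences the exact null distribution is
    enumerated; otherwise the normal approximation with continuity correction
    and tie correction is used.  ``alternative="less"`` tests whether ``x``
    is stochastically smaller than ``y``.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equal-length non-empty 1-d sequences")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # tie-averaged ranks are multiples of 1/2: double them to stay integral
        int_ranks = [int(round(2 * r)) for r in ranks]
        if alternative == "less":
            return _exact_signed_rank_cdf(int_ranks, 2 * w_plus)
        # P(W+ >= w) = 1 - P(W+ <= w - eps); doubled ranks step by 1
        return 1.0 - _exact_signed_rank_cdf(int_ranks, 2 * w_plus - 1)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts) / 48.0).sum()
    )
    sigma = math.sqrt(sigma2)
    correction = -0.5 if alternative == "less" else 0.5
    z = (w_plus - mu - correction) / sigma
    return float(norm.cdf(z) if alternative == "less" else norm.sf(z))


def summarize_corpus(corpus: StudyCorpus, model: str = "merged") -> Dict[str, float]:
    """Corpus summary statistics under one annotation model.

    Annotation-set size per item is the merged set size under ``merged`` and
    the total study-mention count under ``studywise``/``weighted``.  The 5%
    and 95% quantiles use linear interpolation (R's default type-7).
    """
    if not corpus.items:
        raise ValueError("empty corpus")
    if model == "merged":
        sizes = [len(to_merged(corpus, item)) for item in corpus.items]
    elif model in ("studywise", "weighted", "studywise_shuffled", "shuffled"):
        sizes = [corpus.n_mentions(item) for item in corpus.items]
    else:
        raise ValueError(f"unknown model {model!r}")
    n_studies = [len(corpus.studies(item)) for item in corpus.items]
    total_mentions = sum(corpus.n_mentions(item) for item in corpus.items)
    study_sizes = np.array(
        [len(classes) for item in corpus.items
         for _, classes in corpus.studies(item)],
        dtype=float,
    )
    sizes_arr = np.array(sizes, dtype=float)
    return {
        "q05_study": float(np.percentile(study_sizes, 5)),
        "q95_study": float(np.percentile(study_sizes, 95)),
        "n_items": float(len(corpus.items)),
        "n_studies": float(sum(n_studies)),
        "mean_annotations_per_item": float(sizes_arr.mean()),
        "mean_studies_per_item": float(np.mean(n_studies)),
        "mean_annotations_per_study": float(total_mentions / sum(n_studies)),
        "q05": float(np.percentile(sizes_arr, 5)),
        "q95": float(np.percentile(sizes_arr, 95)),
    }
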