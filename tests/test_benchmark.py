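import math
import random

import numpy as np
import pytest
import scipy.stats

from studysim.benchmark import (
    BenchmarkConfig,
    GroupTable,
    Scorer,
    candidate_ranks,
    load_groups,
    precision_recall,
    rank_candidates,
    run_group_recovery,
    summarize_corpus,
    wilcoxon_signed_rank,
    write_groups,
)
from studysim.corpus import StudyCorpus
from studysim.ontology import compute_ic
from studysim.similarity import score
from studysim.synth import GeneratorConfig, generate_corpus, generate_ontology

from oracles import brute_auprc, brute_wilcoxon_less, quantile_type7


def corpus_of(items):
    c = StudyCorpus()
    for item, studies in items.items():
        c.items[item] = [(f"s{i + 1}", list(s)) for i, s in enumerate(studies)]
    return c


class TestCandidateRanks:
    def test_tie_mean_rank(self):
        scored = [("X", 0.9), ("Y", 0.5), ("Z", 0.5), ("W", 0.1)]
        ranks = candidate_ranks(scored)
        assert ranks["Y"] == 2.5
        assert ranks["Z"] == 2.5
        assert ranks["X"] == 1.0

    def test_unique_top_rank_one(self):
        assert candidate_ranks([("A", 0.7), ("B", 0.2)])["A"] == 1.0

    def test_full_tie(self):
        scored = [(f"C{i}", 0.5) for i in range(5)]
        ranks = candidate_ranks(scored)
        assert all(r == 3.0 for r in ranks.values())  # (n+1)/2

    def test_worst_policy(self):
        scored = [("X", 0.9), ("Y", 0.5), ("Z", 0.5)]
        ranks = candidate_ranks(scored, tie="worst")
        assert ranks["Y"] == ranks["Z"] == 3.0


class TestRankCandidates:
    def test_scores_sorted_descending(self, toy):
        ont, corpus, ic = toy
        scored = rank_candidates("D1", corpus, "merged", "jaccard", ont, ic)
        values = [s for _, s in scored]
        assert values == sorted(values, reverse=True)
        assert "D1" not in {item for item, _ in scored}

    def test_query_filter_error_names_filter(self, toy):
        ont, corpus, ic = toy
        config = BenchmarkConfig(min_annotations=5, min_studies=4)
        with pytest.raises(ValueError, match="min_annotations"):
            rank_candidates("D1", corpus, "merged", "jaccard", ont, ic,
                            config=config)

    def test_matches_plain_score(self, toy):
        ont, corpus, ic = toy
        for model in ("merged", "weighted", "studywise"):
            for measure in ("resnik", "cosine", "jaccard"):
                scored = dict(
                    rank_candidates("D1", corpus, model, measure, ont, ic)
                )
                for item, value in scored.items():
                    assert value == pytest.approx(
                        score("D1", item, corpus, model, measure, ont, ic),
                        abs=1e-12,
                    )


class TestScorerEquivalence:
    """The memoising scorer must reproduce the reference dispatcher exactly."""

    @pytest.mark.parametrize("model",
                             ["merged", "weighted", "studywise"])
    @pytest.mark.parametrize("measure", ["resnik", "cosine", "jaccard"])
    def test_synthetic_corpus(self, model, measure):
        cfg = GeneratorConfig(n_classes=40, depth=3, n_groups=2,
                              items_per_group=3, n_items=6, seed=42)
        ont = generate_ontology(cfg)
        corpus, _ = generate_corpus(ont, cfg)
        ic = compute_ic(ont, corpus)
        scorer = Scorer(corpus, model, measure, ont, ic)
        items = sorted(corpus.items)
        rng = random.Random(0)
        for _ in range(30):
            q, t = rng.choice(items), rng.choice(items)
            assert scorer.score(q, t) == pytest.approx(
                score(q, t, corpus, model, measure, ont, ic), abs=1e-12
            )


class TestGroupRecovery:
    def test_perfect_pair(self, toy):
        ont, corpus, ic = toy
        groups = GroupTable(groups={"G1": {"I1", "I2"}})
        config = BenchmarkConfig(min_annotations=1, min_studies=1)
        records, pooled = run_group_recovery(
            corpus, groups, "merged", "jaccard", ont, ic, config
        )
        assert {(r.query, r.sought) for r in records} == {
            ("I1", "I2"), ("I2", "I1")
        }
        assert all(1 <= r.rank <= r.n_candidates for r in records)
        assert len(pooled) == 2 * 3  # two queries x three candidates

    def test_group_reduced_to_one_dropped(self, toy):
        ont, corpus, ic = toy
        # I3 fails a 2-annotation filter, leaving G1 with one member
        groups = GroupTable(groups={"G1": {"I1", "I3"}})
        config = BenchmarkConfig(min_annotations=2, min_studies=1)
        records, pooled = run_group_recovery(
            corpus, groups, "merged", "jaccard", ont, ic, config
        )
        assert records == []

    def test_oversized_group_dropped(self, toy):
        ont, corpus, ic = toy
        groups = GroupTable(groups={"G1": {"I1", "I2", "I3", "D1"}})
        config = BenchmarkConfig(min_annotations=1, min_studies=1,
                                 max_group_size=3)
        records, _ = run_group_recovery(
            corpus, groups, "merged", "jaccard", ont, ic, config
        )
        assert records == []

    def test_oracle_measure_gives_rank_one_and_auprc_one(self):
        # construct a corpus where group members are identical and unique
        c = corpus_of({
            "A1x": [["A1", "A2"], ["A1"]],
            "A2x": [["A1", "A2"], ["A2"]],
            "B1x": [["B1", "B"], ["B1"]],
            "B2x": [["B1", "B"], ["B"]],
        })
        from studysim.synth import make_toy
        ont, _ = make_toy()
        ic = compute_ic(ont, c)
        groups = GroupTable(groups={"GA": {"A1x", "A2x"},
                                    "GB": {"B1x", "B2x"}})
        config = BenchmarkConfig(min_annotations=1, min_studies=1)
        records, pooled = run_group_recovery(
            c, groups, "merged", "jaccard", ont, ic, config
        )
        assert all(r.rank == 1.0 for r in records)
        assert precision_recall(pooled).auprc == pytest.approx(1.0)

    def test_shuffled_model_is_deterministic(self, toy):
        ont, corpus, ic = toy
        groups = GroupTable(groups={"G1": {"I1", "I2"}})
        config = BenchmarkConfig(min_annotations=1, min_studies=1, seed=9)
        first = run_group_recovery(corpus, groups, "studywise_shuffled",
                                   "jaccard", ont, ic, config)
        second = run_group_recovery(corpus, groups, "studywise_shuffled",
                                    "jaccard", ont, ic, config)
        assert first == second


class TestPrecisionRecall:
    def test_worked_example(self):
        curve = precision_recall([(0.9, 1), (0.8, 0), (0.7, 1)])
        assert curve.points[1:] == [
            (0.5, 1.0),
            (0.5, 0.5),
            (1.0, pytest.approx(2 / 3)),
        ]
        assert curve.auprc == pytest.approx(0.7917, abs=1e-4)
        assert curve.auprc == pytest.approx(
            brute_auprc([(0.9, 1), (0.8, 0), (0.7, 1)]), abs=1e-12
        )

    def test_perfect_separation(self):
        pairs = [(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]
        assert precision_recall(pairs).auprc == pytest.approx(1.0)

    def test_all_positive(self):
        curve = precision_recall([(0.5, 1), (0.4, 1)])
        assert all(p == 1.0 for _, p in curve.points)
        assert curve.auprc == pytest.approx(1.0)

    def test_zero_positives_error(self):
        with pytest.raises(ValueError):
            precision_recall([(0.5, 0)])

    def test_recall_non_decreasing_and_area_consistent(self):
        rng = random.Random(3)
        pairs = [(rng.random(), rng.randint(0, 1)) for _ in range(200)]
        pairs.append((0.5, 1))
        curve = precision_recall(pairs)
        recalls = [r for r, _ in curve.points]
        assert recalls == sorted(recalls)
        assert curve.auprc == pytest.approx(brute_auprc(pairs), abs=1e-12)
        # trapezoid of the stored points reproduces the stored area
        rs = np.array(recalls)
        ps = np.array([p for _, p in curve.points])
        assert curve.auprc == pytest.approx(float(np.trapezoid(ps, rs)))

    def test_label_shuffle_drives_auprc_to_prevalence(self):
        rng = random.Random(4)
        scores = [rng.random() for _ in range(4000)]
        labels = [1 if rng.random() < 0.2 else 0 for _ in range(4000)]
        curve = precision_recall(list(zip(scores, labels)))
        assert curve.auprc == pytest.approx(0.2, abs=0.05)


class TestWilcoxon:
    def test_worked_example_exact(self):
        assert wilcoxon_signed_rank([1, 2, 3], [2, 3, 4]) == pytest.approx(
            0.125, abs=1e-12
        )

    def test_wrong_direction_near_one(self):
        x = [5, 6, 7, 8, 9]
        y = [1, 2, 3, 4, 5]
        assert wilcoxon_signed_rank(x, y) > 0.9

    @pytest.mark.parametrize("n", range(2, 13))
    def test_exact_matches_enumeration_oracle(self, n):
        rng = random.Random(n)
        while True:
            x = [rng.random() for _ in range(n)]
            y = [rng.random() for _ in range(n)]
            d = [a - b for a, b in zip(x, y)]
            if all(v != 0 for v in d) and len({abs(v) for v in d}) == n:
                break
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            brute_wilcoxon_less(x, y), abs=1e-6
        )

    def test_exact_matches_scipy(self):
        rng = random.Random(10)
        for _ in range(10):
            n = rng.randint(3, 20)
            x = [rng.random() for _ in range(n)]
            y = [rng.random() for _ in range(n)]
            mine = wilcoxon_signed_rank(x, y)
            ref = scipy.stats.wilcoxon(
                x, y, alternative="less", method="exact"
            ).pvalue
            assert mine == pytest.approx(float(ref), abs=1e-12)

    def test_approx_matches_r_golden_values(self):
        # frozen from R 4.3.3:
        # wilcox.test(x, y, paired=TRUE, alternative=..., exact=FALSE)
        x = [0.304717, -1.039984, 0.750451, 0.940565, -1.951035, -1.30218,
             0.12784, -0.316243, -0.016801, -0.853044, 0.879398, 0.777792,
             0.066031, 1.127241, 0.467509, -0.859292, 0.368751, -0.958883,
             0.87845, -0.049926, -0.184862, -0.68093, 1.222541, -0.154529,
             -0.428328, -0.352134, 0.532309, 0.365444, 0.412733, 0.430821]
        y = [2.846365, -1.046399, 0.638208, 0.526792, -0.935056, 0.226792,
             0.413893, -0.756399, -0.441282, 0.197549, 2.022652, 1.720946,
             -0.199479, 1.759402, 0.984195, -0.240603, 1.64018, -0.335287,
             1.957364, 0.417653, 0.504257, 0.350358, 0.165385, -0.0742,
             -0.498701, -0.591012, 0.657167, 2.260385, -0.053098, 1.799099]
        assert wilcoxon_signed_rank(x, y, "less") == pytest.approx(
            0.00124915569646781, rel=1e-10
        )
        assert wilcoxon_signed_rank(x, y, "greater") == pytest.approx(
            0.998833167417923, rel=1e-10
        )

    def test_approx_matches_scipy_on_simulated_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(26, 80))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.2, 1, n)
            mine = wilcoxon_signed_rank(x, y)
            ref = scipy.stats.wilcoxon(
                x, y, alternative="less", correction=True, method="approx"
            ).pvalue
            assert mine == pytest.approx(float(ref), rel=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2])

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1])


class TestSummarizeCorpus:
    def test_toy_counts(self):
        c = corpus_of({"D1": [["A1"], ["A1", "A2"], ["B1"]]})
        merged = summarize_corpus(c, model="merged")
        studywise = summarize_corpus(c, model="studywise")
        assert merged["mean_annotations_per_item"] == 3.0
        assert studywise["mean_annotations_per_item"] == 4.0
        assert merged["mean_studies_per_item"] == 3.0
        assert merged["mean_annotations_per_study"] == pytest.approx(4 / 3)

    def test_single_study_items_equal(self, toy):
        _, corpus, _ = toy
        single = corpus_of(
            {i: [list(s) for s in corpus.study_lists(i)]
             for i in ("I1", "I2", "I3")}
        )
        m = summarize_corpus(single, "merged")
        s = summarize_corpus(single, "studywise")
        assert m["mean_annotations_per_item"] == s["mean_annotations_per_item"]

    def test_type7_quantiles(self):
        c = corpus_of({
            f"D{i}": [[f"C{j}" for j in range(i)]] for i in range(1, 101)
        })
        summary = summarize_corpus(c, "merged")
        assert summary["q05"] == pytest.approx(5.95)
        assert summary["q95"] == pytest.approx(95.05)
        values = list(range(1, 101))
        assert summary["q05"] == pytest.approx(quantile_type7(values, 0.05))
        assert summary["q95"] == pytest.approx(quantile_type7(values, 0.95))

    def test_empty_corpus_error(self):
        with pytest.raises(ValueError):
            summarize_corpus(StudyCorpus(), "merged")


class TestGroupTableIO:
    def test_round_trip(self, tmp_path):
        table = GroupTable(groups={"G1": {"a", "b"}, "G2": {"c"}})
        path = tmp_path / "groups.tsv"
        write_groups(table, path)
        assert load_groups(path).groups == table.groups

    def test_malformed_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("G1 only-one-column\n")
        with pytest.raises(ValueError):
            load_groups(path)
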