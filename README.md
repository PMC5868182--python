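# studysim

Study-wise annotation models and ontology-based semantic similarity.

Items (diseases, genes) are usually described by a flat list of ontology
classes. `studysim` keeps the *study* structure behind those annotations —
which publication or text paragraph each class was mentioned in — and
implements similarity measures that exploit it, together with the tooling to
derive such corpora from text and to benchmark the annotation models against
each other.

## What's inside

| module | contents |
| --- | --- |
| `studysim.ontology` | OBO flat-file parser (`is_a` only, sub-ontology root filter), ancestor closure, information content (−log item frequency with true-path propagation), most informative common ancestor (MICA) |
| `studysim.corpus` | study-structured corpora (TSV: `item  study  class`), the four annotation models — **merged** (flat set), **weighted** (study-occurrence counts), **study-wise** (per-study class lists), **shuffled** (null model exchanging classes between an item's studies, sizes preserved) — plus item filters |
| `studysim.similarity` | Resnik best-match-average, cosine and Jaccard on ancestor-propagated profile vectors (unweighted and weighted), and the study-wise meta-measure (best-matching study per query study, averaged) |
| `studysim.mining` | dictionary concept recognition over sectioned plain text: `## section` headers, blank-line paragraphs, six-section whitelist, longest-match scan over class names/synonyms; each matched paragraph becomes one study |
| `studysim.benchmark` | group-recovery evaluation: per-query candidate ranking (mean-rank ties), pooled precision–recall with trapezoidal AU-PRC, paired one-sided Wilcoxon signed-rank (exact ≤ 25 pairs, continuity-corrected normal approximation above, R conventions), corpus summaries (type-7 quantiles) |
| `studysim.synth` | deterministic generators for rooted DAG ontologies, study corpora with tunable within-study coherence, and group tables, so everything is testable offline |

Conventions worth knowing:

* Information content uses the natural logarithm (configurable) and is always
  computed from item-level presence, regardless of the model used later.
* Ancestor propagation assigns each ancestor the **maximum** multiplicity over
  the annotated classes it subsumes (`rule="sum"` available).
* Resnik BMA is query-directed and not symmetric; study lists entering the
  study-wise measure are read as unweighted sets.
* Empty profiles score 0 by convention; filtered corpora never produce them.

## CLI

```sh
# synthetic data: ontology.obo + corpus.tsv + groups.tsv
studysim generate --seed 1 --out data/

# concept recognition over a directory of *.txt documents
studysim mine --obo hp.obo --root HP:0000118 --docs docs/ \
    --out mentions.tsv --corpus-out corpus.tsv

# group-recovery benchmark for one model/measure combination
studysim benchmark --obo data/ontology.obo --root C:0000000 \
    --annotations data/corpus.tsv --groups data/groups.tsv \
    --model studywise --measure jaccard \
    --min-annotations 2 --min-studies 1 --out results/
```

`benchmark` writes `ranks.tsv` (rank of every sought group member),
`prcurve.tsv` and `summary.json`; `--plots` adds rank and PR plots (needs
matplotlib).

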