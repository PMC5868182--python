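"""Dictionary-based concept recognition over sectioned plain-text documents.

Documents use a simple dialect: section headers are lines of the form
``## <name>``, paragraphs are separated by blank lines, and any text before
the first header forms the unnamed introductory section.  Recognition is a
deterministic, offline longest-match dictionary scan over ontology class
names and exact synonyms (a stand-in for web-service annotators); each
paragraph of a retained section becomes one candidate study.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from studysim.corpus import StudyCorpus
from studysim.ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "MentionRow",
    "DEFAULT_SECTIONS",
    "parse_document",
    "filter_sections",
    "build_dictionary",
    "annotate_paragraph",
    "mine_document",
    "mine_corpus",
    "write_mentions",
]

#: Sections retained by default (the unnamed introductory section is always kept).
DEFAULT_SECTIONS = frozenset({
    "description",
    "other features",
    "biochemical features",
    "diagnosis",
    "clinical features",
})


@dataclass
class Document:
    """A sectioned full-text description of one item."""

    item: str
    #: ordered (section name, paragraphs); the intro section has name ""
    sections: List[Tuple[str, List[str]]] = field(default_factory=list)

    def paragraphs(self) -> List[str]:
        """All paragraphs in reading order (1-based global indexing applies)."""
        out: List[str] = []
        for _, paras in self.sections:
            out.extend(paras)
        return out


@dataclass(frozen=True)
class MentionRow:
    """One recognised concept mention: the 4-column output unit."""

    item: str
    class_id: str
    matched_text: str  # uppercased, whitespace removed
    paragraph: int  # 1-based global index

    def as_tsv(self) -> str:
        return f"{self.item}\t{self.class_id}\t{self.matched_text}\t{self.paragraph}"


_HEADER_RE = re.compile(r"^##\s*(.*\S)?\s*$")


def parse_document(text: str, item: str) -> Document:
    """Split plain text into sections and paragraphs.

    Section names are normalised to lowercase; empty paragraphs are dropped.
    Empty input yields a document with zero sections.
    """
    sections: List[Tuple[str, List[str]]] = []
    current_name = ""
    current_paras: List[str] = []
    buf: List[str] = []
    started = False  # becomes True once any content or header was seen

    def flush_paragraph() -> None:
        para = "\n".join(buf).strip()
        buf.clear()
        if para:
            current_paras.append(para)

    def flush_section() -> None:
        nonlocal current_paras
        flush_paragraph()
        if started:
            sections.append((current_name, current_paras))
        current_paras = []

    for line in text.splitlines():
        m = _HEADER_RE.match(line)
        if m:
            flush_section()
            current_name = (m.group(1) or "").lower()
            started = True
            continue
        if line.strip():
            started = True
            buf.append(line)
        else:
            flush_paragraph()
    flush_section()
    return Document(item=item, sections=sections)


def filter_sections(
    doc: Document, whitelist: Iterable[str] = DEFAULT_SECTIONS
) -> Document:
    """Keep only whitelisted sections plus the unnamed introductory section."""
    allowed = {name.lower() for name in whitelist}
    kept = [
        (name, list(paras))
        for name, paras in doc.sections
        if name == "" or name in allowed
    ]
    return Document(item=doc.item, sections=kept)


_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*")


def _normalize(form: str) -> str:
    return " ".join(form.lower().split())


class DictionaryMatcher:
    """Case-insensitive longest-match dictionary over names and synonyms.

    Surface forms are whitespace-normalised token sequences; forms shorter
    than 3 characters are dropped.  Two classes sharing a surface form are
    both reported (ambiguity is preserved and logged once at build time).
    """

    def __init__(self, forms: Dict[str, Set[str]]):
        #: normalised surface form -> set of class ids
        self.forms = forms
        self.max_tokens = max(
            (len(f.split()) for f in forms), default=0
        )
        ambiguous = {f: ids for f, ids in forms.items() if len(ids) > 1}
        if ambiguous:
            logger.info(
                "%d ambiguous surface forms map to multiple classes", len(ambiguous)
            )

    def scan(self, text: str) -> List[Tuple[str, str]]:
        """Longest-match, non-overlapping, left-to-right scan on word boundaries.

        Returns ``(class id, matched text)`` pairs in match order; the matched
        text is the original span uppercased with whitespace removed.
        """
        tokens = list(_TOKEN_RE.finditer(text))
        hits: List[Tuple[str, str]] = []
        pos = 0
        while pos < len(tokens):
            matched = False
            upper = min(self.max_tokens, len(tokens) - pos)
            for length in range(upper, 0, -1):
                span = tokens[pos:pos + length]
                phrase = _normalize(" ".join(t.group(0) for t in span))
                ids = self.forms.get(phrase)
                if ids:
                    raw = text[span[0].start():span[-1].end()]
                    surface = re.sub(r"\s+", "", raw).upper()
                    for cid in sorted(ids):
                        hits.append((cid, surface))
                    pos += length
                    matched = True
                    break
            if not matched:
                pos += 1
        return hits


def build_dictionary(ont: Ontology) -> DictionaryMatcher:
    """Build the matcher from ontology class names and exact synonyms."""
    forms: Dict[str, Set[str]] = {}
    for surface, cid in ont.surface_forms():
        norm = _normalize(surface)
        if len(norm) < 3:
            continue
        forms.setdefault(norm, set()).add(cid)
    return DictionaryMatcher(forms)


def annotate_paragraph(
    text: str,
    matcher: DictionaryMatcher,
    item: str,
    paragraph_index: int,
) -> List[MentionRow]:
    """Recognise concepts in one paragraph.

    Each (class, paragraph) pair is emitted at most once, keeping the first
    matched surface text.
    """
    if paragraph_index < 1:
        raise ValueError("paragraph indices are 1-based")
    rows: List[MentionRow] = []
    seen: Set[str] = set()
    for cid, surface in matcher.scan(text):
        if cid in seen:
            continue
        seen.add(cid)
        rows.append(MentionRow(item, cid, surface, paragraph_index))
    return rows


def mine_document(doc: Document, matcher: DictionaryMatcher) -> List[MentionRow]:
    """Mention rows for all paragraphs of a (section-filtered) document."""
    rows: List[MentionRow] = []
    for idx, para in enumerate(doc.paragraphs(), start=1):
        rows.extend(annotate_paragraph(para, matcher, doc.item, idx))
    return rows


def mine_corpus(
    docs: Sequence[Document], matcher: DictionaryMatcher
) -> StudyCorpus:
    """Turn documents into a study corpus, one study per matched paragraph.

    Study ids are the 1-based global paragraph indices (as strings); only
    paragraphs with at least one mention become studies, and items without
    any mention are absent from the corpus.
    """
    corpus = StudyCorpus()
    for doc in docs:
        studies: Dict[int, List[str]] = {}
        for row in mine_document(doc, matcher):
            studies.setdefault(row.paragraph, [])
            if row.class_id not in studies[row.paragraph]:
                studies[row.paragraph].append(row.class_id)
        if studies:
            corpus.items[doc.item] = [
                (str(idx), studies[idx]) for idx in sorted(studies)
            ]
    return corpus


def write_mentions(rows: Iterable[MentionRow], path) -> None:
    """Write mention rows as 4-column TSV (item, class, matched text, paragraph)."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(row.as_tsv() + "\n")
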