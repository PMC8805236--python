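"""Input artifacts: MEDLINE corpus, qrels gold standard, MeSH vocabulary, concept lexicon.

Four plain-text formats feed the pipeline:

* a MEDLINE tagged-field corpus (``PMID``/``TI``/``AB``/``MH``), parsed with
  :mod:`Bio.Medline`;
* a TREC-style qrels file (``topic  0  pmid  score``) giving graded
  topic-document relevance;
* a two-column TSV MeSH vocabulary (term name -> semicolon-joined tree numbers);
* a two-column TSV concept lexicon (CUI -> surface string).

Only *major* MeSH terms (marked with ``*`` in the MH field) are kept, and
subheadings (``/qualifier``) are stripped: major headings carry the thematic
content of an article and are what the similarity network is built from.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Medline

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*(\.[A-Za-z0-9]+)*$")


class CorpusError(ValueError):
    """Raised on malformed or inconsistent input artifacts."""


@dataclass
class Document:
    """A MEDLINE citation reduced to the fields the similarity methods use."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    topics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise CorpusError("Document requires a non-empty PMID")


@dataclass
class Corpus:
    """An ordered collection of documents with unique PMIDs."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.pmid in seen:
                raise CorpusError(f"duplicate PMID {doc.pmid!r} in corpus")
            seen.add(doc.pmid)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def get(self, pmid: str) -> Document:
        for doc in self.documents:
            if doc.pmid == pmid:
                return doc
        raise KeyError(pmid)

    @property
    def pmids(self) -> list[str]:
        return [d.pmid for d in self.documents]


@dataclass
class GoldStandard:
    """Graded topic-document relevance and the derived topic membership sets.

    ``topic_members[t]`` holds exactly the pmids with a nonzero relevance
    score for topic ``t``; a pmid may belong to several topics.
    """

    relevance: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def topic_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for (topic, pmid), score in self.relevance.items():
            members.setdefault(topic, set())
            if score > 0:
                members[topic].add(pmid)
        return members

    def topics_of(self, pmid: str) -> set[str]:
        return {t for (t, p), s in self.relevance.items() if p == pmid and s > 0}

    @property
    def judged_pmids(self) -> set[str]:
        return {p for (_, p) in self.relevance}


@dataclass
class MeshVocabulary:
    """Term name -> set of dotted tree numbers."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, numbers in self.entries.items():
            if not numbers:
                raise CorpusError(f"MeSH term {term!r} has no tree numbers")
            for code in numbers:
                validate_tree_number(code)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def tree_numbers(self, term: str) -> set[str]:
        try:
            return self.entries[term]
        except KeyError:
            raise KeyError(f"MeSH term {term!r} not in vocabulary") from None


@dataclass
class ConceptLexicon:
    """CUI -> set of lower-cased surface strings (single words or phrases)."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            cui: {s.lower() for s in strings} for cui, strings in self.entries.items()
        }
        for cui, strings in self.entries.items():
            if not strings or any(not s.strip() for s in strings):
                raise CorpusError(f"concept {cui!r} has an empty surface string")


def validate_tree_number(code: str) -> str:
    """Check a dotted tree-number code; return it unchanged if valid."""
    if not code or not _TREE_NUMBER_RE.match(code):
        raise CorpusError(f"malformed tree number {code!r}")
    return code


def _major_mesh(mh_entries: Iterable[str]) -> list[str]:
    """Keep only major-topic MH entries; strip subheadings and the marker.

    MEDLINE marks major topics with an asterisk either on the heading
    (``*Breast Neoplasms``) or on a subheading (``Breast Neoplasms/*genetics``);
    both flag the heading as major here.
    """
    terms: list[str] = []
    for entry in mh_entries:
        if "*" not in entry:
            continue
        heading = entry.split("/", 1)[0].replace("*", "").strip()
        if heading and heading not in terms:
            terms.append(heading)
    return terms


def read_medline(path: str | Path) -> Corpus:
    """Parse a MEDLINE tagged-field file into a :class:`Corpus`.

    Records without a PMID are rejected with a logged warning; duplicate
    PMIDs raise :class:`CorpusError`.
    """
    path = Path(path)
    documents: list[Document] = []
    with path.open(encoding="utf-8") as handle:
        for record in Medline.parse(handle):
            pmid = record.get("PMID", "").strip()
            if not pmid:
                logger.warning("skipping MEDLINE record without PMID in %s", path)
                continue
            documents.append(
                Document(
                    pmid=pmid,
                    title=record.get("TI", "").strip(),
                    abstract=record.get("AB", "").strip(),
                    mesh_terms=_major_mesh(record.get("MH", [])),
                )
            )
    return Corpus(documents=documents, provenance=str(path))


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back out in MEDLINE tagged format (round-trips with
    :func:`read_medline`; all MeSH terms are written as major topics)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for doc in corpus:
            handle.write(f"PMID- {doc.pmid}\n")
            if doc.title:
                handle.write(f"TI  - {doc.title}\n")
            if doc.abstract:
                handle.write(f"AB  - {doc.abstract}\n")
            for term in doc.mesh_terms:
                handle.write(f"MH  - *{term}\n")
            handle.write("\n")


def read_qrels(path: str | Path) -> GoldStandard:
    """Parse TREC qrels lines ``topic  iter  pmid  score`` (whitespace-split).

    Scores are integers (0 not relevant, 1 possibly, 2 definitely relevant).
    """
    path = Path(path)
    relevance: dict[tuple[str, str], int] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CorpusError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            topic, _, pmid, score_str = parts
            try:
                score = int(score_str)
            except ValueError:
                raise CorpusError(
                    f"{path}:{lineno}: non-integer relevance score {score_str!r}"
                ) from None
            relevance[(topic, pmid)] = score
    return GoldStandard(relevance=relevance)


def write_qrels(gold: GoldStandard, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for (topic, pmid), score in sorted(gold.relevance.items()):
            handle.write(f"{topic} 0 {pmid} {score}\n")


def read_mesh_vocabulary(path: str | Path) -> MeshVocabulary:
    """Parse a two-column TSV: term name TAB semicolon-joined tree numbers.

    Duplicate term lines union their tree-number sets.
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                term, numbers = line.split("\t")
            except ValueError:
                raise CorpusError(f"{path}:{lineno}: expected 2 tab-separated columns")
            codes = {c.strip() for c in numbers.split(";") if c.strip()}
            if not codes:
                raise CorpusError(f"{path}:{lineno}: no tree numbers for {term!r}")
            for code in codes:
                try:
                    validate_tree_number(code)
                except CorpusError:
                    raise CorpusError(f"{path}:{lineno}: malformed tree number {code!r}")
            entries.setdefault(term.strip(), set()).update(codes)
    return MeshVocabulary(entries=entries)


def write_mesh_vocabulary(vocab: MeshVocabulary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for term in sorted(vocab.entries):
            handle.write(f"{term}\t{';'.join(sorted(vocab.entries[term]))}\n")


def read_concept_lexicon(path: str | Path) -> ConceptLexicon:
    """Parse a two-column TSV: CUI TAB surface string (one string per line).

    Surface strings are lower-cased; blank strings are rejected with a warning.
    """
    path = Path(path)
    entries: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                cui, surface = line.split("\t")
            except ValueError:
                raise CorpusError(f"{path}:{lineno}: expected 2 tab-separated columns")
            surface = surface.strip().lower()
            if not surface:
                logger.warning("%s:%d: blank surface string for %s, skipped", path, lineno, cui)
                continue
            entries.setdefault(cui.strip(), set()).add(surface)
    return ConceptLexicon(entries=entries)


def write_concept_lexicon(lexicon: ConceptLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for cui in sorted(lexicon.entries):
            for surface in sorted(lexicon.entries[cui]):
                handle.write(f"{cui}\t{surface}\n")


def attach_topics(corpus: Corpus, gold: GoldStandard) -> None:
    """Fill each document's ``topics`` list from the gold standard, in place.

    Documents absent from the qrels keep an empty topic list and are later
    excluded from evaluation.
    """
    for doc in corpus:
        doc.topics = sorted(gold.topics_of(doc.pmid))


def pair_is_relevant(d1: Document, d2: Document, gold: GoldStandard) -> bool:
    """Two documents are relevant iff they share at least one topic.

    A document compared with itself is relevant (it shares its own topics).
    """
    for doc in (d1, d2):
        if doc.pmid not in gold.judged_pmids:
            raise CorpusError(f"PMID {doc.pmid!r} absent from gold standard")
    t1, t2 = gold.topics_of(d1.pmid), gold.topics_of(d2.pmid)
    if d1.pmid == d2.pmid:
        return True
    return bool(t1 & t2)
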