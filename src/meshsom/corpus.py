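"""Controlled vocabularies and sparse binary article corpora.

A literature corpus is encoded the way Medline encodes it: each article
carries a small set of controlled-vocabulary annotations (MeSH-style terms
organized in a dot-numbered tree), and becomes one row of an N x D sparse
binary matrix whose columns are the D retained vocabulary terms.  Column
order is the vocabulary file order and is never sorted, so codebooks trained
on the matrix are reproducible across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "VocabularyTerm",
    "Vocabulary",
    "ArticleRecord",
    "AnnotatedCorpus",
    "FilterSummary",
    "load_vocabulary",
    "write_vocabulary",
    "vectorize",
    "filter_rare_terms",
    "read_corpus",
    "write_corpus",
]


@dataclass(frozen=True)
class VocabularyTerm:
    """A single controlled-vocabulary term.

    ``tree_paths`` are dot-separated tree numbers (e.g. ``"F03.600.300"``);
    ``is_domain`` marks membership of the configured domain subtree (for the
    psychiatric-literature use case, the subtree rooted at the
    "Psychiatry and Psychology" branch).
    """

    term_id: str
    label: str
    tree_paths: tuple[str, ...]
    is_domain: bool = False
    annotation_count: int = 0


def _is_domain(tree_paths: Sequence[str], prefixes: Sequence[str]) -> bool:
    return any(p.startswith(pre) for p in tree_paths for pre in prefixes)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered list of retained terms defining the binary-vector columns."""

    terms: tuple[VocabularyTerm, ...]
    index_of: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index_of:
            object.__setattr__(
                self, "index_of", {t.term_id: i for i, t in enumerate(self.terms)}
            )
        if len(self.index_of) != len(self.terms):
            seen: set[str] = set()
            for t in self.terms:
                if t.term_id in seen:
                    raise ValueError(f"duplicate term_id: {t.term_id!r}")
                seen.add(t.term_id)

    @property
    def D(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    @property
    def domain_mask(self) -> np.ndarray:
        """Boolean column mask of domain-subtree terms."""
        return np.array([t.is_domain for t in self.terms], dtype=bool)

    def digest(self) -> str:
        """Stable hash of the column layout, stored in codebook provenance."""
        h = hashlib.sha256()
        for t in self.terms:
            h.update(t.term_id.encode())
            h.update(b"\x00")
        return h.hexdigest()

    def subset(self, keep: np.ndarray) -> "Vocabulary":
        """New vocabulary retaining terms where ``keep`` is True (order kept)."""
        return Vocabulary(tuple(t for t, k in zip(self.terms, keep) if k))


@dataclass(frozen=True)
class ArticleRecord:
    """One annotated article: an opaque id plus its term-id set.

    ``term_ids`` is stored as a deduplicated tuple in first-occurrence order
    so that serialization round-trips are byte-stable.
    """

    article_id: str
    term_ids: tuple[str, ...]

    @property
    def D_a(self) -> int:
        return len(self.term_ids)


def _dedup(term_ids: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for t in term_ids:
        seen.setdefault(t, None)
    return tuple(seen)


@dataclass(frozen=True)
class AnnotatedCorpus:
    """N article records plus their N x D sparse binary matrix."""

    records: tuple[ArticleRecord, ...]
    matrix: sp.csr_matrix = field(repr=False, compare=False)
    vocabulary: Vocabulary = field(repr=False, compare=False)

    @property
    def N(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def article_ids(self) -> list[str]:
        return [r.article_id for r in self.records]

    def subset(self, indices: Sequence[int]) -> "AnnotatedCorpus":
        idx = list(indices)
        return AnnotatedCorpus(
            records=tuple(self.records[i] for i in idx),
            matrix=self.matrix[idx],
            vocabulary=self.vocabulary,
        )


# ---------------------------------------------------------------------------
# vocabulary I/O

_VOCAB_COLUMNS = ("term_id", "label", "tree_paths")


def load_vocabulary(
    path: str | Path, domain_prefixes: Sequence[str] = ()
) -> Vocabulary:
    """Read a vocabulary TSV.

    Expected columns: ``term_id``, ``label``, ``tree_paths``
    (semicolon-separated dot paths) and an optional ``admin`` flag column;
    admin-flagged terms are administrative codes and are excluded from the
    vector space.  ``is_domain`` is set for terms with any tree path starting
    with one of ``domain_prefixes``.
    """
    path = Path(path)
    terms: list[VocabularyTerm] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _VOCAB_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing vocabulary columns {missing}")
        col = {c: i for i, c in enumerate(header)}
        admin_col = col.get("admin")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(_VOCAB_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            term_id = fields[col["term_id"]]
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            seen.add(term_id)
            if admin_col is not None and len(fields) > admin_col:
                flag = fields[admin_col].strip().lower()
                if flag in ("1", "true", "yes", "y"):
                    continue  # administrative code: not a vector column
            paths = tuple(p for p in fields[col["tree_paths"]].split(";") if p)
            terms.append(
                VocabularyTerm(
                    term_id=term_id,
                    label=fields[col["label"]],
                    tree_paths=paths,
                    is_domain=_is_domain(paths, domain_prefixes),
                )
            )
    return Vocabulary(tuple(terms))


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("term_id\tlabel\ttree_paths\tadmin\n")
        for t in vocab.terms:
            fh.write(f"{t.term_id}\t{t.label}\t{';'.join(t.tree_paths)}\t0\n")


# ---------------------------------------------------------------------------
# vectorization

def vectorize(
    records: Iterable[ArticleRecord | tuple[str, Iterable[str]]],
    vocab: Vocabulary,
    strict: bool = False,
) -> AnnotatedCorpus:
    """Encode records as an N x D sparse binary matrix.

    Unknown terms are dropped (lenient, default) or raise (``strict=True``).
    Records left without any known term are dropped with a warning — a SOM is
    never trained on all-zero vectors.
    """
    kept: list[ArticleRecord] = []
    indptr = [0]
    indices: list[int] = []
    for rec in records:
        if not isinstance(rec, ArticleRecord):
            article_id, term_ids = rec
            rec = ArticleRecord(article_id=str(article_id), term_ids=_dedup(term_ids))
        cols = []
        for t in rec.term_ids:
            j = vocab.index_of.get(t)
            if j is None:
                if strict:
                    raise KeyError(
                        f"record {rec.article_id!r}: unknown term {t!r}"
                    )
                continue
            cols.append(j)
        if not cols:
            logger.warning(
                "dropping record %s: no annotations in vocabulary", rec.article_id
            )
            continue
        kept.append(
            ArticleRecord(
                article_id=rec.article_id,
                term_ids=tuple(t for t in rec.term_ids if t in vocab.index_of),
            )
        )
        indices.extend(cols)
        indptr.append(len(indices))
    matrix = sp.csr_matrix(
        (
            np.ones(len(indices), dtype=np.float64),
            np.asarray(indices, dtype=np.int32),
            np.asarray(indptr, dtype=np.int64),
        ),
        shape=(len(kept), vocab.D),
    )
    return AnnotatedCorpus(records=tuple(kept), matrix=matrix, vocabulary=vocab)


@dataclass(frozen=True)
class FilterSummary:
    """Bookkeeping from :func:`filter_rare_terms`."""

    removed_term_ids: tuple[str, ...]
    dropped_record_ids: tuple[str, ...]


def filter_rare_terms(
    vocab: Vocabulary, corpus: AnnotatedCorpus, min_count: int
) -> tuple[Vocabulary, AnnotatedCorpus, FilterSummary]:
    """Drop terms annotating fewer than ``min_count`` articles and re-vectorize.

    Mirrors the corpus-preparation rule of excluding rarely used headings
    (the full-scale analysis used ``min_count=100``).  Records left with no
    annotations are dropped and their ids reported in the summary.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = np.asarray(corpus.matrix.sum(axis=0)).ravel()
    keep = counts >= min_count
    new_terms = tuple(
        replace(t, annotation_count=int(c))
        for t, c, k in zip(vocab.terms, counts, keep)
        if k
    )
    removed = tuple(t.term_id for t, k in zip(vocab.terms, keep) if not k)
    new_vocab = Vocabulary(new_terms)
    new_corpus = vectorize(corpus.records, new_vocab, strict=False)
    surviving = set(new_corpus.article_ids)
    dropped = tuple(
        r.article_id for r in corpus.records if r.article_id not in surviving
    )
    return new_vocab, new_corpus, FilterSummary(removed, dropped)


# ---------------------------------------------------------------------------
# corpus I/O (JSONL / TSV)

def write_corpus(corpus_or_records, path: str | Path) -> None:
    """Write records as JSONL (``.jsonl``/``.json``) or 2-column TSV.

    JSONL lines are ``{"article_id": ..., "mesh": [...]}``; the TSV second
    column joins term ids with semicolons.  Output is deterministic given the
    record order, so write-then-read-then-write is byte-stable.
    """
    records = getattr(corpus_or_records, "records", corpus_or_records)
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {"article_id": r.article_id, "mesh": list(r.term_ids)},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        with path.open("w", encoding="utf-8") as fh:
            fh.write("article_id\tmesh\n")
            for r in records:
                fh.write(f"{r.article_id}\t{';'.join(r.term_ids)}\n")


def read_corpus(path: str | Path) -> list[ArticleRecord]:
    """Read article records from JSONL or TSV (formats of :func:`write_corpus`).

    Duplicate terms within a record are deduplicated with a warning.
    Malformed lines raise with the line number.
    """
    path = Path(path)
    records: list[ArticleRecord] = []
    if path.suffix in (".jsonl", ".json"):
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    article_id = obj["article_id"]
                    mesh = obj["mesh"]
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record ({exc})")
                terms = _dedup(str(t) for t in mesh)
                if len(terms) != len(mesh):
                    logger.warning(
                        "%s:%d: duplicate terms in record %s deduplicated",
                        path, lineno, article_id,
                    )
                records.append(ArticleRecord(str(article_id), terms))
    else:
        with path.open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["article_id", "mesh"]:
                raise ValueError(f"{path}:1: expected header 'article_id\\tmesh'")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                article_id, mesh = fields
                terms = _dedup(t for t in mesh.split(";") if t)
                records.append(ArticleRecord(article_id, terms))
    return records
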