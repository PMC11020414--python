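"""Offline matching of free-text references against a bibliographic record set.

Stands in for submitting reference strings to a Medline search and manually
verifying first author, title and journal: candidates are indexed by the
first author's surname and accepted only when both the normalized title and
journal clear configurable fuzzy-similarity thresholds, uniquely.  Rejects
(no author hit, field mismatch, ambiguity) are data, not errors — an
edition's matched/unmatched counts are exactly the indexed/non-indexed
bookkeeping of the projection pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib

from .corpus import AnnotatedCorpus, Vocabulary, vectorize

__all__ = [
    "ReferenceString",
    "BibRecord",
    "MatchOutcome",
    "MatchReport",
    "parse_reference",
    "normalized_similarity",
    "match",
    "match_all",
    "build_edition_corpora",
    "read_references_tsv",
    "read_records",
]

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Lower-case, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", text.lower())).strip()


def normalized_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein ratio: 1 - distance / max(len); 1.0 for equal strings."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


@dataclass(frozen=True)
class ReferenceString:
    """A raw reference plus its best-effort parsed fields (normalized)."""

    edition_id: str
    raw_text: str
    first_author_surname: str = ""
    title: str = ""
    journal: str = ""
    parse_ok: bool = False


@dataclass(frozen=True)
class BibRecord:
    """A local bibliographic record (the offline stand-in for a Medline entry)."""

    article_id: str
    first_author_surname: str
    title: str
    journal: str
    term_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class MatchOutcome:
    reference: ReferenceString
    article_id: str | None
    reason: str  # "matched" or a reject reason

    @property
    def matched(self) -> bool:
        return self.article_id is not None


@dataclass(frozen=True)
class MatchReport:
    """Per-edition matched/unmatched bookkeeping."""

    outcomes: tuple[MatchOutcome, ...]

    def per_edition(self) -> dict[str, dict[str, int]]:
        stats: dict[str, dict[str, int]] = {}
        for o in self.outcomes:
            s = stats.setdefault(
                o.reference.edition_id,
                {"n_total": 0, "n_matched": 0, "n_unmatched": 0},
            )
            s["n_total"] += 1
            s["n_matched" if o.matched else "n_unmatched"] += 1
        return stats

    def matched_ids(self, edition_id: str) -> list[str]:
        """Matched article ids of one edition, deduplicated, input order."""
        seen: dict[str, None] = {}
        for o in self.outcomes:
            if o.reference.edition_id == edition_id and o.matched:
                seen.setdefault(o.article_id, None)
        return list(seen)


_YEARISH = re.compile(r"^[\d\s:;,\-–()]+$")


def parse_reference(raw_text: str, edition_id: str = "") -> ReferenceString:
    """Heuristic split of ``"Authors. Title. Journal. year;vol:pages"``.

    The first sentence-like segment is the author block (first surname kept),
    the second the title, the third the journal; trailing purely numeric
    segments (year/volume/pages) are ignored.  Failures leave fields empty
    and the record flagged, never raise.
    """
    if not raw_text or not raw_text.strip():
        raise ValueError("reference text is empty")
    segments = [s.strip() for s in raw_text.split(". ") if s.strip()]
    if segments and segments[-1].endswith("."):
        segments[-1] = segments[-1][:-1]
    segments = [s for s in segments if not _YEARISH.match(s)]
    if len(segments) < 3:
        return ReferenceString(edition_id=edition_id, raw_text=raw_text)
    author_block, title, journal = segments[0], segments[1], segments[2]
    first_author = author_block.split(",")[0].strip()
    surname = first_author.split()[0] if first_author.split() else ""
    return ReferenceString(
        edition_id=edition_id,
        raw_text=raw_text,
        first_author_surname=normalize(surname),
        title=normalize(title),
        journal=normalize(journal),
        parse_ok=bool(surname),
    )


def _surname_index(records: Sequence[BibRecord]) -> dict[str, list[BibRecord]]:
    index: dict[str, list[BibRecord]] = {}
    for rec in records:
        index.setdefault(normalize(rec.first_author_surname), []).append(rec)
    return index


def match(
    ref: ReferenceString,
    records: Sequence[BibRecord] | dict[str, list[BibRecord]],
    title_threshold: float = 0.90,
    journal_threshold: float = 0.80,
) -> MatchOutcome:
    """Accept the unique surname-sharing record whose title and journal both
    clear their thresholds; otherwise reject with a reason.

    Reject reasons: ``"unparsed"``, ``"author"`` (no surname candidates),
    ``"title"`` / ``"journal"`` (best candidate fails that field),
    ``"ambiguous"`` (two or more candidates pass).  Candidate order never
    affects the outcome: passing candidates are compared as a set and the
    best-failing candidate is chosen by similarity, ties by article_id.
    """
    if not ref.parse_ok:
        return MatchOutcome(ref, None, "unparsed")
    index = records if isinstance(records, dict) else _surname_index(records)
    candidates = index.get(ref.first_author_surname, [])
    if not candidates:
        return MatchOutcome(ref, None, "author")
    scored = sorted(
        (
            (
                normalized_similarity(ref.title, normalize(rec.title)),
                normalized_similarity(ref.journal, normalize(rec.journal)),
                rec,
            )
            for rec in candidates
        ),
        key=lambda t: (-t[0], -t[1], t[2].article_id),
    )
    passing = [
        rec for ts, js, rec in scored
        if ts >= title_threshold and js >= journal_threshold
    ]
    if len(passing) == 1:
        return MatchOutcome(ref, passing[0].article_id, "matched")
    if len(passing) >= 2:
        return MatchOutcome(ref, None, "ambiguous")
    best_ts, best_js, _ = scored[0]
    return MatchOutcome(ref, None, "title" if best_ts < title_threshold else "journal")


def match_all(
    refs: Iterable[ReferenceString],
    records: Sequence[BibRecord],
    title_threshold: float = 0.90,
    journal_threshold: float = 0.80,
) -> MatchReport:
    index = _surname_index(records)
    return MatchReport(
        tuple(
            match(r, index, title_threshold, journal_threshold) for r in refs
        )
    )


def build_edition_corpora(
    report: MatchReport,
    records: Sequence[BibRecord],
    vocab: Vocabulary,
) -> dict[str, AnnotatedCorpus]:
    """Per-edition corpora of matched records (deduplicated within an edition),
    vectorized and ready for projection.  Only matched — i.e. locally indexed —
    references enter the analysis."""
    by_id = {r.article_id: r for r in records}
    editions = sorted({o.reference.edition_id for o in report.outcomes})
    out: dict[str, AnnotatedCorpus] = {}
    for ed in editions:
        ids = report.matched_ids(ed)
        recs = [(i, by_id[i].term_ids) for i in ids if i in by_id]
        out[ed] = vectorize(recs, vocab, strict=False)
    return out


# ---------------------------------------------------------------------------
# file I/O

def read_references_tsv(path: str | Path) -> list[ReferenceString]:
    """Read (edition_id, raw_text) TSV and parse each reference."""
    refs = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["edition_id", "raw_text"]:
            raise ValueError(f"{path}: expected header 'edition_id\\traw_text'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            refs.append(parse_reference(fields[1], edition_id=fields[0]))
    return refs


def read_records(path: str | Path) -> list[BibRecord]:
    """Read bibliographic records from TSV
    (article_id, first_author, title, journal, mesh)."""
    recs = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["article_id", "first_author", "title", "journal", "mesh"]
        if header[: len(expected)] != expected:
            raise ValueError(f"{path}: expected header {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            mesh = tuple(
                t for t in (fields[4].split(";") if len(fields) > 4 else []) if t
            )
            recs.append(
                BibRecord(
                    article_id=fields[0],
                    first_author_surname=fields[1],
                    title=fields[2],
                    journal=fields[3],
                    term_ids=mesh,
                )
            )
    return recs


def export_match_report_tsv(report: MatchReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("edition_id\traw_text\tarticle_id\treason\n")
        for o in report.outcomes:
            fh.write(
                f"{o.reference.edition_id}\t{o.reference.raw_text}\t"
                f"{o.article_id or ''}\t{o.reason}\n"
            )
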