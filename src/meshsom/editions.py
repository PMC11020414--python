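"""Edition-level organizational statistics of a multi-edition reference work.

Given per-edition metadata (year, pages, chapters, chapter turnover, citation
counts) and per-edition sets of indexed citations, computes citations per
chapter, the citation-persistence percentage between consecutive editions,
and the cross-edition aggregates.  Rounding is half-up to match the
conventional one-decimal / whole-percent presentation of such tables.

The packaged dataset ``data/textbook_editions.tsv`` carries the published
organizational features of the ten editions (1967-2017) of Kaplan & Sadock's
Comprehensive Textbook of Psychiatry, the reference work used to validate
the literature map.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "EditionMeta",
    "EditionStatsReport",
    "citations_per_chapter",
    "persistence",
    "aggregate",
    "load_edition_metadata",
    "packaged_edition_metadata",
]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EditionMeta:
    """One edition's organizational metadata.

    ``new_chapters`` / ``removed_chapters`` / ``persistence_pct`` are None for
    the first edition, where they are undefined.
    """

    edition_id: str
    year: int
    pages: int
    chapters: int
    citations_total: int
    citations_indexed: int
    new_chapters: int | None = None
    removed_chapters: int | None = None
    persistence_pct: int | None = None

    def __post_init__(self) -> None:
        if self.chapters <= 0:
            raise ValueError(f"edition {self.edition_id}: chapters must be > 0")
        for name in ("pages", "citations_total", "citations_indexed"):
            if getattr(self, name) < 0:
                raise ValueError(f"edition {self.edition_id}: {name} negative")


@dataclass(frozen=True)
class EditionStatsReport:
    """Per-edition derived columns plus cross-edition aggregates."""

    citations_per_chapter: dict[str, float]
    persistence_pct: dict[str, int]
    mean_new_chapters: float
    mean_removed_chapters: float
    mean_persistence_pct: int


def citations_per_chapter(meta: EditionMeta) -> float:
    """Total citations divided by chapters, rounded half-up to one decimal."""
    return _round_half_up(meta.citations_total / meta.chapters, 1)


def persistence(prev_ids: set[str], curr_ids: set[str]) -> int:
    """Percentage of the current edition's citations already present in the
    previous edition, rounded half-up to a whole percent."""
    if not curr_ids:
        raise ValueError("persistence undefined for an empty current edition")
    frac = len(curr_ids & prev_ids) / len(curr_ids)
    return int(_round_half_up(100.0 * frac, 0))


def persistence_percentages(
    edition_ids: Sequence[str], id_sets: dict[str, set[str]]
) -> dict[str, int]:
    """Consecutive-edition persistence for every edition after the first."""
    out: dict[str, int] = {}
    for prev, curr in zip(edition_ids, edition_ids[1:]):
        if id_sets.get(curr):
            out[curr] = persistence(id_sets.get(prev, set()), id_sets[curr])
    return out


def aggregate(metas: Sequence[EditionMeta]) -> EditionStatsReport:
    """Derived per-edition columns and means over the editions after the first
    where each quantity is defined (a first edition has no predecessor, so its
    turnover and persistence are excluded even when a value is printed for it)."""
    if len(metas) < 2:
        raise ValueError("aggregation needs at least two editions")
    cpc = {m.edition_id: citations_per_chapter(m) for m in metas}
    later = metas[1:]
    pers = {
        m.edition_id: m.persistence_pct
        for m in later
        if m.persistence_pct is not None
    }
    new = [m.new_chapters for m in later if m.new_chapters is not None]
    rem = [m.removed_chapters for m in later if m.removed_chapters is not None]
    return EditionStatsReport(
        citations_per_chapter=cpc,
        persistence_pct=pers,
        mean_new_chapters=_round_half_up(sum(new) / len(new), 1) if new else float("nan"),
        mean_removed_chapters=_round_half_up(sum(rem) / len(rem), 1) if rem else float("nan"),
        mean_persistence_pct=int(_round_half_up(sum(pers.values()) / len(pers), 0))
        if pers
        else 0,
    )


# ---------------------------------------------------------------------------
# metadata I/O

_INT_COLS = ("year", "pages", "chapters", "citations_total", "citations_indexed")
_OPT_COLS = ("new_chapters", "removed_chapters", "persistence_pct")


def load_edition_metadata(path: str | Path) -> list[EditionMeta]:
    """Read an edition-metadata TSV; empty/NA optional cells become None."""
    df = pd.read_csv(path, sep="\t", dtype={"edition_id": str})
    missing = [c for c in ("edition_id",) + _INT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    metas = []
    for _, row in df.iterrows():
        kwargs = {c: int(row[c]) for c in _INT_COLS}
        for c in _OPT_COLS:
            v = row.get(c)
            kwargs[c] = None if v is None or pd.isna(v) else int(v)
        metas.append(EditionMeta(edition_id=str(row["edition_id"]), **kwargs))
    return metas


def packaged_edition_metadata() -> list[EditionMeta]:
    """The shipped ten-edition textbook metadata table."""
    ref = resources.files("meshsom.data").joinpath("textbook_editions.tsv")
    with resources.as_file(ref) as path:
        return load_edition_metadata(path)


def export_report_tsv(
    metas: Sequence[EditionMeta], report: EditionStatsReport, path: str | Path
) -> None:
    rows = []
    for m in metas:
        rows.append(
            dict(
                edition_id=m.edition_id,
                year=m.year,
                citations_per_chapter=report.citations_per_chapter[m.edition_id],
                persistence_pct=report.persistence_pct.get(m.edition_id, ""),
            )
        )
    rows.append(
        dict(
            edition_id="mean(2nd+)",
            year="",
            citations_per_chapter="",
            persistence_pct=report.mean_persistence_pct,
        )
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
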