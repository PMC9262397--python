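"""Year-stamped document corpora: reading, writing, validation, and time binning.

A corpus is an ordered collection of documents, each carrying a unique id, a
journal label, a publication year, and plain text.  Corpora are stored as
JSON-lines files (one object per line with keys ``id``, ``journal``, ``year``,
``text``), a format that is streamable and diff-able.  Text is normalised to
Unicode NFC on read so that downstream tokenisation is deterministic.

Time binning supports calendar decades, the quarter-century scheme anchored at
1900 (1900-1924, 1925-1949, ... with the final bin running to the corpus's
last year), and arbitrary custom bins.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Corpus",
    "TimeBinning",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "assign_time_bins",
    "make_binning",
    "read_targets",
]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus records or invalid binnings."""


@dataclass(frozen=True)
class Document:
    """One article: unique id, journal label, calendar year, plain text."""

    id: str
    journal: str
    year: int
    text: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusFormatError("document id must be non-empty")
        if not isinstance(self.year, int) or isinstance(self.year, bool):
            raise CorpusFormatError(f"document {self.id!r}: year must be an integer")
        if self.year <= 0:
            raise CorpusFormatError(f"document {self.id!r}: year must be positive")


@dataclass
class Corpus:
    """An ordered, id-unique sequence of documents."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise CorpusFormatError(f"duplicate document id {doc.id!r}")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    @property
    def year_min(self) -> int:
        if not self.documents:
            raise ValueError("empty corpus has no year range")
        return min(d.year for d in self.documents)

    @property
    def year_max(self) -> int:
        if not self.documents:
            raise ValueError("empty corpus has no year range")
        return max(d.year for d in self.documents)

    def article_counts(self) -> dict[int, int]:
        """Number of documents per year (the per-article denominator)."""
        counts: dict[int, int] = {}
        for d in self.documents:
            counts[d.year] = counts.get(d.year, 0) + 1
        return counts


@dataclass(frozen=True)
class TimeBinning:
    """Ordered, non-overlapping inclusive year intervals covering a year range.

    Labels use the ASCII hyphen ("1880-1889"); :meth:`display_labels` swaps in
    an en dash for presentation.
    """

    scheme: str
    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.bins:
            if start > end:
                raise CorpusFormatError(f"bin {start}-{end}: start exceeds end")
            if prev_end is not None and start != prev_end + 1:
                kind = "overlapping" if start <= prev_end else "gapped"
                raise CorpusFormatError(
                    f"{kind} bins: [{start}, {end}] follows a bin ending {prev_end}"
                )
            prev_end = end

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{s}-{e}" for s, e in self.bins)

    def display_labels(self) -> tuple[str, ...]:
        return tuple(f"{s}–{e}" for s, e in self.bins)

    def label_of(self, year: int) -> str:
        """Label of the bin containing ``year``; KeyError if uncovered."""
        for (s, e), lab in zip(self.bins, self.labels):
            if s <= year <= e:
                return lab
        raise KeyError(f"year {year} not covered by binning {self.scheme!r}")

    def covers(self, year: int) -> bool:
        return any(s <= year <= e for s, e in self.bins)


# Quarter-century grid anchor: the scheme used for concept evolution starts
# its columns at 1900 (1900-1924, 1925-1949, 1950-1974, 1975-1999, 2000-...).
_QC_ANCHOR = 1900
_QC_WIDTH = 25


def make_binning(
    year_min: int,
    year_max: int,
    scheme: str = "decade",
    custom_bins: Sequence[Sequence[int]] | None = None,
) -> TimeBinning:
    """Build a :class:`TimeBinning` covering ``[year_min, year_max]``.

    decade
        Full calendar decades (1880-1889, 1890-1899, ...).
    quarter_century
        25-year bins on the 1900-anchored grid; the final bin is clamped to
        ``year_max`` (so a corpus ending in 2020 gets 2000-2020).
    custom
        Caller-supplied inclusive ``[start, end]`` intervals, validated for
        order, overlap and coverage.
    """
    if year_min > year_max:
        raise ValueError("year_min exceeds year_max")
    if scheme == "decade":
        start = (year_min // 10) * 10
        bins = []
        while start <= year_max:
            bins.append((start, start + 9))
            start += 10
        return TimeBinning("decade", tuple(bins))
    if scheme == "quarter_century":
        # First anchored 25-year period containing year_min (anchors extend
        # backwards from 1900 for earlier corpora).
        offset = (year_min - _QC_ANCHOR) // _QC_WIDTH
        start = _QC_ANCHOR + offset * _QC_WIDTH
        bins = []
        while start <= year_max:
            bins.append((start, start + _QC_WIDTH - 1))
            start += _QC_WIDTH
        # Final bin runs to the corpus end.
        s_last, e_last = bins[-1]
        bins[-1] = (s_last, max(year_max, s_last))
        return TimeBinning("quarter_century", tuple(bins))
    if scheme == "custom":
        if not custom_bins:
            raise CorpusFormatError("custom scheme requires bins")
        bins = tuple((int(s), int(e)) for s, e in custom_bins)
        binning = TimeBinning("custom", bins)
        if not (binning.covers(year_min) and binning.covers(year_max)):
            raise CorpusFormatError("custom bins do not cover the corpus year range")
        return binning
    raise ValueError(f"unknown binning scheme {scheme!r}")


def assign_time_bins(corpus: Corpus, scheme: str = "decade",
                     custom_bins: Sequence[Sequence[int]] | None = None) -> TimeBinning:
    """Binning for a non-empty corpus; every document year maps to one bin."""
    if len(corpus) == 0:
        raise ValueError("cannot bin an empty corpus")
    return make_binning(corpus.year_min, corpus.year_max, scheme, custom_bins)


_REQUIRED_KEYS = ("id", "journal", "year", "text")


def _parse_record(line: str, lineno: int) -> Document:
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise CorpusFormatError(f"line {lineno}: record is not an object")
    missing = [k for k in _REQUIRED_KEYS if k not in obj]
    if missing:
        raise CorpusFormatError(f"line {lineno}: missing fields {missing}")
    year = obj["year"]
    if not isinstance(year, int) or isinstance(year, bool):
        raise CorpusFormatError(f"line {lineno}: year {year!r} is not an integer")
    text = unicodedata.normalize("NFC", str(obj["text"]))
    return Document(id=str(obj["id"]), journal=str(obj["journal"]), year=year, text=text)


def read_corpus(path: str | Path, strict: bool = True) -> Corpus:
    """Read a JSON-lines corpus.

    In strict mode any malformed record aborts the read.  In non-strict mode
    malformed records are skipped and counted in the log (a small, random
    fraction of unreadable records leaves year-level statistics essentially
    unchanged).  Duplicate ids are always an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    documents: list[Document] = []
    seen: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                doc = _parse_record(line, lineno)
            except CorpusFormatError:
                if strict:
                    raise
                skipped += 1
                continue
            if doc.id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate document id {doc.id!r}")
            seen.add(doc.id)
            documents.append(doc)
    if skipped:
        logger.warning("read_corpus(%s): skipped %d malformed record(s)", path, skipped)
    return Corpus(documents)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON-lines; round-trips record-for-record."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for doc in corpus:
            rec = {"id": doc.id, "journal": doc.journal, "year": doc.year,
                   "text": unicodedata.normalize("NFC", doc.text)}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path


def read_targets(path: str | Path) -> set[str]:
    """Read a target word list: one token per line, '#' comments allowed."""
    words: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                words.add(line)
    return words
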