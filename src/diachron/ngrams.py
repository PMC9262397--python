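"""Tokenisation, per-year ngram counting, and normalised frequency series.

The tokenizer produces letters-only tokens: each whitespace-delimited chunk is
stripped of every non-letter character (so hyphenated and apostrophised forms
concatenate — "self-identified" becomes "selfidentified"), digit-only chunks
vanish, and tokens are lowercased unless case-sensitive mode is on.  No
misspelling or stop-word filtering is applied: historical corpora carry OCR
forms and archaic spellings that are themselves signal.

Frequencies are normalised against corpus growth: the per-100k frequency of a
term in a year is its count divided by the total number of same-order ngrams
published that year, times 100,000.  Years in which nothing was published
yield no frequency point at all (the denominator is undefined), mirroring the
gaps in early journal runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Corpus

__all__ = [
    "TokenSequence",
    "NgramCountTable",
    "FrequencySeries",
    "tokenize",
    "tokenize_corpus",
    "extract_ngrams",
    "count_ngrams",
    "frequency_series",
    "smooth_series",
    "cumulative_series",
    "export_series_csv",
]

PER_100K_BASIS = 100_000


def tokenize(text: str, case_sensitive: bool = False) -> list[str]:
    """Split ``text`` into letters-only tokens.

    Non-letter characters inside a whitespace-delimited chunk are deleted by
    concatenation; chunks left empty (punctuation- or digit-only) are dropped.
    """
    tokens: list[str] = []
    for chunk in text.split():
        word = "".join(ch for ch in chunk if ch.isalpha())
        if word:
            tokens.append(word if case_sensitive else word.lower())
    return tokens


@dataclass(frozen=True)
class TokenSequence:
    """A tokenised document: id, year, and its ordered tokens."""

    doc_id: str
    year: int
    tokens: tuple[str, ...]


def tokenize_corpus(corpus: Corpus, case_sensitive: bool = False) -> list[TokenSequence]:
    return [
        TokenSequence(doc.id, doc.year, tuple(tokenize(doc.text, case_sensitive)))
        for doc in corpus
    ]


def extract_ngrams(tokens: Sequence[str], n: int) -> list[str]:
    """All ``max(0, m - n + 1)`` consecutive space-joined n-token windows."""
    if n < 1:
        raise ValueError(f"ngram order must be >= 1, got {n}")
    m = len(tokens)
    if m < n:
        return []
    if n == 1:
        return list(tokens)
    return [" ".join(tokens[i : i + n]) for i in range(m - n + 1)]


@dataclass
class NgramCountTable:
    """Per-year ngram counts plus the all-ngrams denominator per year.

    ``totals[y]`` is the total number of order-``n`` ngrams published in year
    ``y`` — the denominator of every normalised frequency for that year.
    """

    n: int
    counts: dict[int, Counter] = field(default_factory=dict)
    totals: dict[int, int] = field(default_factory=dict)

    def years(self) -> list[int]:
        return sorted(self.totals)


def count_ngrams(corpus: Corpus, n: int = 1, case_sensitive: bool = False) -> NgramCountTable:
    """Count order-``n`` ngrams per year across the whole corpus.

    Ngram windows run across sentence boundaries within a document (documents
    are the only windowing unit).  Years with no documents are absent.
    """
    if len(corpus) == 0:
        raise ValueError("cannot count ngrams of an empty corpus")
    table = NgramCountTable(n=n)
    for doc in corpus:
        grams = extract_ngrams(tokenize(doc.text, case_sensitive), n)
        year_counts = table.counts.setdefault(doc.year, Counter())
        year_counts.update(grams)
        table.totals[doc.year] = table.totals.get(doc.year, 0) + len(grams)
    return table


@dataclass
class FrequencySeries:
    """A single term's yearly frequency in one of three scale modes.

    raw
        integer occurrence counts.
    per_article
        occurrences divided by the number of articles that year.
    per_100k
        occurrences per 100,000 same-order ngrams that year.
    """

    term: str
    mode: str
    values: dict[int, float]
    basis: int | None = None

    def years(self) -> list[int]:
        return sorted(self.values)


def frequency_series(
    table: NgramCountTable,
    term: str,
    mode: str = "per_100k",
    article_counts: Mapping[int, int] | None = None,
) -> FrequencySeries:
    """Yearly frequency series for ``term`` from a count table.

    Years absent from the table are absent from the series; a term absent in
    a present year gets an explicit 0.
    """
    order = len(term.split(" "))
    if order != table.n:
        raise ValueError(
            f"term {term!r} has order {order} but table holds {table.n}-grams"
        )
    if mode not in ("raw", "per_article", "per_100k"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "per_article" and article_counts is None:
        raise ValueError("per_article mode requires article counts")
    values: dict[int, float] = {}
    for year in table.years():
        count = table.counts[year].get(term, 0)
        if mode == "raw":
            values[year] = float(count)
        elif mode == "per_article":
            n_articles = article_counts.get(year, 0)
            if n_articles == 0:
                continue
            values[year] = count / n_articles
        else:
            total = table.totals[year]
            if total == 0:
                continue  # nothing published: frequency undefined, not zero
            values[year] = PER_100K_BASIS * count / total
    basis = PER_100K_BASIS if mode == "per_100k" else None
    return FrequencySeries(term=term, mode=mode, values=values, basis=basis)


def smooth_series(series: FrequencySeries, window: int = 1) -> FrequencySeries:
    """Centered moving average over the year grid.

    The window is truncated at the series boundaries (the mean is taken over
    the years actually present within the half-window), so window=1 is the
    identity and a constant series stays constant.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and positive, got {window}")
    if window == 1:
        return FrequencySeries(series.term, series.mode, dict(series.values), series.basis)
    half = window // 2
    years = series.years()
    values = series.values
    smoothed: dict[int, float] = {}
    for y in years:
        present = [values[yy] for yy in range(y - half, y + half + 1) if yy in values]
        smoothed[y] = sum(present) / len(present)
    return FrequencySeries(series.term, series.mode, smoothed, series.basis)


def cumulative_series(series: FrequencySeries) -> FrequencySeries:
    """Running sum over years ascending (raw or per_100k series)."""
    if series.mode == "per_article":
        raise ValueError("cumulative series are defined for raw or per_100k modes")
    acc = 0.0
    values: dict[int, float] = {}
    for y in series.years():
        acc += series.values[y]
        values[y] = acc
    return FrequencySeries(series.term, series.mode, values, series.basis)


def export_series_csv(
    series_set: Iterable[FrequencySeries],
    path: str | Path,
    year_window: tuple[int, int] | None = None,
) -> Path:
    """Export one or more same-mode series as CSV: year column + one per term.

    Rows are sorted by year ascending and restricted to ``year_window`` when
    given.  A year missing from every series is omitted; a year present in
    some series is written with 0 for the others.
    """
    series_list = list(series_set)
    if not series_list:
        raise ValueError("no series to export")
    modes = {s.mode for s in series_list}
    if len(modes) > 1:
        raise ValueError(f"mixed series modes {sorted(modes)} cannot share one CSV")
    years = sorted(set().union(*(s.values.keys() for s in series_list)))
    if year_window is not None:
        lo, hi = year_window
        years = [y for y in years if lo <= y <= hi]
    frame = pd.DataFrame(
        {"year": years}
        | {s.term: [s.values.get(y, 0.0) for y in years] for s in series_list}
    )
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path
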