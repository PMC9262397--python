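"""Synthetic diachronic corpora with planted trends, topics, and drift.

Real multi-decade journal archives are rarely shareable, so every stage of
the pipeline is exercised against generated corpora whose ground truth is
known exactly.  The generator emulates the statistical features the analyses
rely on:

* per-year token totals that grow over time (the corpus keeps expanding);
* terms following planted frequency trajectories — constant, logistic rise,
  or rise-and-fall bumps — expressed as target per-100k frequencies;
* topic-structured co-occurrence: each document is drawn from exactly one
  named topic, so words sharing a topic genuinely share contexts and a
  skip-gram model can recover the neighbourhoods;
* designated drift words that belong to one topic's co-occurrence pool before
  a known change year and a different topic's pool afterwards — the synthetic
  analogue of a word whose dominant sense shifts.

Document lengths are drawn from a negative-binomial distribution (Poisson
with gamma-distributed rate), giving realistic over-dispersion.  Everything
is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import Corpus, Document
from .ngrams import PER_100K_BASIS

__all__ = [
    "Trajectory",
    "SyntheticSpec",
    "PlantedTruth",
    "default_spec",
    "generate_corpus",
    "truth_report",
    "load_truth",
]


def _letter_suffix(i: int) -> str:
    """Fixed-width three-letter suffix (aaa, aab, ...) — survives the
    letters-only tokenizer unchanged; supports 17,576 distinct words."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    if not (0 <= i < 26 ** 3):
        raise ValueError("suffix index out of range")
    return letters[i // 676] + letters[(i // 26) % 26] + letters[i % 26]


@dataclass(frozen=True)
class Trajectory:
    """A planted per-100k frequency trajectory for one term.

    kind = "constant": ``level`` per 100k every year.
    kind = "logistic": floor + (ceiling - floor) / (1 + exp(-steepness*(y - midpoint))).
    kind = "bump": Gaussian rise-and-fall, ``height * exp(-((y-peak)/width)^2 / 2)``.
    """

    kind: str
    level: float = 0.0
    floor: float = 0.0
    ceiling: float = 0.0
    midpoint: int = 0
    steepness: float = 0.0
    peak: int = 0
    width: float = 1.0
    height: float = 0.0

    def value(self, year: int) -> float:
        if self.kind == "constant":
            v = self.level
        elif self.kind == "logistic":
            v = self.floor + (self.ceiling - self.floor) / (
                1.0 + math.exp(-self.steepness * (year - self.midpoint))
            )
        elif self.kind == "bump":
            v = self.height * math.exp(-0.5 * ((year - self.peak) / self.width) ** 2)
        else:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if not (0.0 <= v <= PER_100K_BASIS):
            raise ValueError(f"trajectory value {v} outside [0, {PER_100K_BASIS}]")
        return v


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic diachronic corpus."""

    year_start: int = 1940
    year_end: int = 1999
    docs_per_year: int = 30
    docs_growth: float = 0.0            # extra docs per elapsed year (linear growth)
    doc_length_mean: float = 120.0      # tokens per document
    doc_length_dispersion: float = 10.0 # negative-binomial shape; larger = tighter
    topics: dict[str, list[str]] = field(default_factory=dict)
    topic_weights: dict[str, float] | None = None
    background_vocab_size: int = 400
    background_zipf_exponent: float = 1.2
    background_fraction: float = 0.35   # share of tokens drawn from background
    trend_terms: dict[str, Trajectory] = field(default_factory=dict)
    drift_words: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    journal: str = "SYNTH"
    seed: int = 0

    def validate(self) -> None:
        if self.year_start > self.year_end:
            raise ValueError("year range inverted")
        all_topic_words: set[str] = set()
        for name, words in self.topics.items():
            overlap = all_topic_words.intersection(words)
            if overlap:
                raise ValueError(f"topics are not disjoint: {sorted(overlap)}")
            all_topic_words.update(words)
        for word, (pre, post, change_year) in self.drift_words.items():
            for t in (pre, post):
                if t not in self.topics:
                    raise ValueError(f"drift word {word!r} references unknown topic {t!r}")
            # a change year outside the corpus window is allowed: the word
            # then stays in one topic for the whole generated period
        # Total trend mass must leave room for topic/background tokens.
        for year in range(self.year_start, self.year_end + 1):
            mass = sum(t.value(year) for t in self.trend_terms.values())
            if mass >= PER_100K_BASIS:
                raise ValueError(f"trend trajectories sum to >= 100k per 100k in {year}")

    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def docs_in_year(self, year: int) -> int:
        return max(0, int(round(self.docs_per_year + self.docs_growth * (year - self.year_start))))


@dataclass
class PlantedTruth:
    """The recoverable ground truth behind a generated corpus.

    ``trend_expected`` maps term -> year -> planted per-100k frequency;
    ``drift_words`` maps word -> (pre topic, post topic, change year);
    ``topic_members`` maps word -> year -> topic name (drift words switch at
    their change year, stable topic words never do).
    """

    trend_expected: dict[str, dict[int, float]]
    drift_words: dict[str, tuple[str, str, int]]
    topic_members: dict[str, dict[int, str]]
    topics: dict[str, list[str]]
    seed: int


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The reference study conditions: a 60-year, 3-topic corpus.

    Sixty years (1940-1999) of 30 documents per year averaging 120 tokens,
    three disjoint 30-word topics, two drift words switching topics in 1970,
    and three trend terms (constant, logistic rise, rise-and-fall bump).
    """
    def topic(prefix: str) -> list[str]:
        return [f"{prefix}{_letter_suffix(i)}" for i in range(30)]

    topics = {
        "cardiology": topic("cardio"),
        "infection": topic("infect"),
        "genetics": topic("gene"),
    }
    trend_terms = {
        "steady": Trajectory(kind="constant", level=80.0),
        "risingterm": Trajectory(kind="logistic", floor=0.0, ceiling=200.0,
                                 midpoint=1970, steepness=0.25),
        "fadterm": Trajectory(kind="bump", peak=1980, width=8.0, height=150.0),
    }
    drift_words = {
        "driftalpha": ("cardiology", "genetics", 1970),
        "driftbeta": ("infection", "cardiology", 1970),
    }
    return SyntheticSpec(topics=topics, trend_terms=trend_terms,
                         drift_words=drift_words, seed=seed)


def _topic_pool(spec: SyntheticSpec, topic: str, year: int) -> list[str]:
    """A topic's co-occurrence pool in a given year, including current drift words."""
    pool = list(spec.topics[topic])
    for word, (pre, post, change_year) in sorted(spec.drift_words.items()):
        current = pre if year < change_year else post
        if current == topic:
            pool.append(word)
    return pool


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, PlantedTruth]:
    """Generate a corpus and its ground truth from a spec, deterministically.

    Per document: a topic is sampled once (single-membership mixture); each
    token position is, independently, a trend term with probability equal to
    its trajectory value / 100k that year, otherwise a background word
    (power-law weighted) with probability ``background_fraction``, otherwise a
    uniform draw from the document topic's current pool.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    topic_names = sorted(spec.topics)
    if spec.topic_weights:
        weights = np.array([spec.topic_weights.get(t, 0.0) for t in topic_names], float)
    else:
        weights = np.ones(len(topic_names))
    if topic_names:
        weights = weights / weights.sum()

    background = [f"bg{_letter_suffix(i)}" for i in range(spec.background_vocab_size)]
    bg_w = 1.0 / np.arange(1, spec.background_vocab_size + 1) ** spec.background_zipf_exponent
    bg_w /= bg_w.sum()
    bg_cum = np.cumsum(bg_w)

    trend_names = sorted(spec.trend_terms)

    documents: list[Document] = []
    doc_counter = 0
    for year in spec.years():
        trend_p = np.array([spec.trend_terms[t].value(year) / PER_100K_BASIS
                            for t in trend_names])
        trend_cum = np.cumsum(trend_p)
        trend_mass = float(trend_cum[-1]) if trend_names else 0.0
        pools = {t: _topic_pool(spec, t, year) for t in topic_names}
        for _ in range(spec.docs_in_year(year)):
            topic = (topic_names[int(rng.choice(len(topic_names), p=weights))]
                     if topic_names else None)
            # Negative binomial as gamma-mixed Poisson for over-dispersed lengths.
            lam = rng.gamma(spec.doc_length_dispersion,
                            spec.doc_length_mean / spec.doc_length_dispersion)
            m = max(1, int(rng.poisson(lam)))
            u = rng.random(m)
            tokens: list[str] = []
            pool = pools[topic] if topic is not None else background
            for ui in u:
                if ui < trend_mass:
                    tokens.append(trend_names[int(np.searchsorted(trend_cum, ui, side="right"))])
                elif (ui - trend_mass) / max(1e-300, 1.0 - trend_mass) < spec.background_fraction:
                    tokens.append(background[int(np.searchsorted(bg_cum, rng.random(), side="right"))])
                else:
                    tokens.append(pool[int(rng.integers(0, len(pool)))])
            documents.append(Document(
                id=f"{spec.journal.lower()}-{doc_counter:06d}",
                journal=spec.journal, year=year, text=" ".join(tokens)))
            doc_counter += 1

    trend_expected = {
        t: {y: spec.trend_terms[t].value(y) for y in spec.years()} for t in trend_names
    }
    topic_members: dict[str, dict[int, str]] = {}
    for t, words in spec.topics.items():
        for w in words:
            topic_members[w] = {y: t for y in spec.years()}
    for w, (pre, post, cy) in spec.drift_words.items():
        topic_members[w] = {y: (pre if y < cy else post) for y in spec.years()}
    truth = PlantedTruth(trend_expected=trend_expected,
                         drift_words=dict(spec.drift_words),
                         topic_members=topic_members,
                         topics={t: list(ws) for t, ws in spec.topics.items()},
                         seed=spec.seed)
    return Corpus(documents), truth


def truth_report(truth: PlantedTruth, path: str | Path) -> Path:
    """Dump the planted ground truth as JSON for test-harness consumption."""
    payload = {
        "seed": truth.seed,
        "trend_expected": {t: {str(y): v for y, v in ys.items()}
                           for t, ys in truth.trend_expected.items()},
        "drift_words": {w: {"topic_pre": pre, "topic_post": post, "change_year": cy}
                        for w, (pre, post, cy) in truth.drift_words.items()},
        "topic_members": {w: {str(y): t for y, t in ys.items()}
                          for w, ys in truth.topic_members.items()},
        "topics": truth.topics,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def load_truth(path: str | Path) -> PlantedTruth:
    """Inverse of :func:`truth_report`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PlantedTruth(
        trend_expected={t: {int(y): v for y, v in ys.items()}
                        for t, ys in payload["trend_expected"].items()},
        drift_words={w: (d["topic_pre"], d["topic_post"], int(d["change_year"]))
                     for w, d in payload["drift_words"].items()},
        topic_members={w: {int(y): t for y, t in ys.items()}
                       for w, ys in payload["topic_members"].items()},
        topics=payload["topics"],
        seed=int(payload["seed"]),
    )
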