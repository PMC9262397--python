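"""Shared fixtures: synthetic corpora and trained embedding models.

Model training is the expensive step, so trained models are session-scoped
and shared across test modules.  All corpora are generated programmatically
from seeded specs — no stored data files.
"""

from __future__ import annotations

import pytest

import diachron as dc


def control_words(truth: dc.PlantedTruth) -> list[str]:
    """One stable (never-drifting) word per planted topic."""
    return [words[0] for _, words in sorted(truth.topics.items())]


def decade_targets(truth: dc.PlantedTruth) -> set[str]:
    """Target list for decade-bin runs: drift words, trend terms, controls."""
    return set(truth.drift_words) | set(truth.trend_expected) | set(control_words(truth))


def train_decade_model(seed: int) -> tuple[dc.Corpus, dc.PlantedTruth, dc.EmbeddingModel]:
    spec = dc.default_spec(seed=seed)
    corpus, truth = dc.generate_corpus(spec)
    binning = dc.assign_time_bins(corpus, "decade")
    cfg = dc.TrainingConfig(dim=16, min_count=1, seed=seed)
    model = dc.train_temporal_model(corpus, decade_targets(truth), binning, cfg)
    return corpus, truth, model


@pytest.fixture(scope="session")
def default_corpus_truth() -> tuple[dc.Corpus, dc.PlantedTruth]:
    return dc.generate_corpus(dc.default_spec(seed=7))


@pytest.fixture(scope="session")
def decade_run() -> tuple[dc.Corpus, dc.PlantedTruth, dc.EmbeddingModel]:
    """Default-spec corpus (seed 7) with a decade-bin temporal model."""
    return train_decade_model(7)


@pytest.fixture(scope="session")
def qc_run() -> tuple[dc.Corpus, dc.PlantedTruth, dc.EmbeddingModel]:
    """Default-spec corpus (seed 7) with a quarter-century temporal model
    whose targets are all topic words plus drift words (the clustering setup)."""
    spec = dc.default_spec(seed=7)
    corpus, truth = dc.generate_corpus(spec)
    binning = dc.make_binning(corpus.year_min, corpus.year_max, "quarter_century")
    targets = {w for ws in truth.topics.values() for w in ws} | set(truth.drift_words)
    cfg = dc.TrainingConfig(dim=16, min_count=1, seed=7)
    model = dc.train_temporal_model(corpus, targets, binning, cfg)
    return corpus, truth, model


def small_spec(seed: int) -> dc.SyntheticSpec:
    """A reduced spec for tests that train several models: 24 years,
    two topics, one drift word switching in 1972."""
    topics = {
        "heart": [f"heart{s}" for s in ("aaa", "aab", "aac", "aad", "aae",
                                        "aaf", "aag", "aah", "aai", "aaj")],
        "germ": [f"germ{s}" for s in ("aaa", "aab", "aac", "aad", "aae",
                                      "aaf", "aag", "aah", "aai", "aaj")],
    }
    return dc.SyntheticSpec(
        year_start=1960, year_end=1983, docs_per_year=25,
        doc_length_mean=90.0, topics=topics,
        background_vocab_size=150,
        drift_words={"shifty": ("heart", "germ", 1972)},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_corpus_truth() -> tuple[dc.Corpus, dc.PlantedTruth]:
    return dc.generate_corpus(small_spec(3))
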