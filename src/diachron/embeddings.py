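"""Temporal-referencing word embeddings via skip-gram with negative sampling.

To compare a word's meaning across time periods without aligning separately
trained vector spaces, every occurrence of a *target* word in a document
dated within time bin ``b`` is rewritten to a time-specific token
``word@LABEL`` (e.g. ``patent@1880-1889``) before training.  A single
skip-gram-negative-sampling (SGNS) model is then trained over the whole
rewritten stream: non-target words keep one vector (their "numerical address"
is fixed), while each target word acquires one vector per bin, all living in
one space so cosine similarities across periods are directly comparable.

The trainer is a plain-numpy SGNS implementation.  For each (center c,
context o) pair within a per-position reduced window it ascends

    log sigma(u_o . v_c) + sum_{n ~ P_n} log sigma(-u_n . v_c)

with k noise words drawn from the unigram distribution raised to 3/4.
Updates are applied in deterministic chunked minibatches on a single thread,
so identical inputs and seed give bit-identical vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, TimeBinning
from .ngrams import TokenSequence, tokenize_corpus

__all__ = [
    "TrainingConfig",
    "EmbeddingModel",
    "NeighborTable",
    "apply_temporal_referencing",
    "build_vocabulary",
    "train_sgns",
    "train_temporal_model",
    "train_per_period_models",
    "cosine_similarity",
    "top_related_terms",
    "export_neighbors_tsv",
    "save_model",
    "load_model",
]

TIME_SEP = "@"  # cannot appear in tokenizer output, so never collides


@dataclass(frozen=True)
class TrainingConfig:
    """SGNS hyperparameters.

    dim
        vector dimension (canonical default 100; tests use 16 for speed).
    window
        maximum context offset; each position uses a reduced window drawn
        uniformly from [1, window], the standard variance-reduction trick.
    negatives
        noise samples per positive pair, from the unigram^0.75 distribution.
    alpha
        initial learning rate, decayed linearly to alpha / 10000.
    subsample_t
        optional frequent-word subsampling threshold; None disables it.
    """

    dim: int = 100
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    alpha: float = 0.025
    min_count: int = 5
    subsample_t: float | None = None
    seed: int = 0
    # Chunk of pairs updated together.  Small chunks keep the accumulated
    # step for high-frequency tokens (which recur many times per chunk)
    # close to sequential SGD; large chunks can destabilise training.
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1 or self.negatives < 1 or self.min_count < 1:
            raise ValueError("window, negatives and min_count must be >= 1")


def apply_temporal_referencing(
    stream: Sequence[TokenSequence],
    targets: Iterable[str],
    binning: TimeBinning,
) -> list[TokenSequence]:
    """Rewrite each target-word occurrence to its time-specific token.

    A target word in a document dated within bin ``b`` becomes
    ``word@LABEL(b)``; all other tokens pass through unchanged, so the stream
    length is preserved exactly.
    """
    target_set = set(targets)
    out: list[TokenSequence] = []
    for seq in stream:
        if not binning.covers(seq.year):
            raise ValueError(
                f"document {seq.doc_id!r} year {seq.year} outside binning"
            )
        if not target_set:
            out.append(seq)
            continue
        label = binning.label_of(seq.year)
        tokens = tuple(
            f"{tok}{TIME_SEP}{label}" if tok in target_set else tok
            for tok in seq.tokens
        )
        out.append(TokenSequence(seq.doc_id, seq.year, tokens))
    return out


def build_vocabulary(stream: Sequence[TokenSequence], min_count: int = 1) -> dict[str, int]:
    """Token counts for tokens occurring at least ``min_count`` times."""
    counts: dict[str, int] = {}
    for seq in stream:
        for tok in seq.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    return {t: c for t, c in counts.items() if c >= min_count}


@dataclass
class EmbeddingModel:
    """A trained SGNS vector space, possibly containing time-indexed tokens."""

    vocab: list[str]
    counts: dict[str, int]
    vectors: np.ndarray            # input/center vectors, shape (V, dim)
    context_vectors: np.ndarray    # output/context vectors, shape (V, dim)
    config: TrainingConfig
    binning: TimeBinning | None = None
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.vocab)}
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("model contains non-finite vectors")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def time_token(self, word: str, bin_label: str) -> str:
        return f"{word}{TIME_SEP}{bin_label}"


def _pairs_for_doc(ids: np.ndarray, window: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs with per-position reduced windows."""
    m = ids.shape[0]
    if m < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    b = rng.integers(1, window + 1, size=m)
    lo = np.maximum(0, np.arange(m) - b)
    hi = np.minimum(m - 1, np.arange(m) + b)
    reps = hi - lo  # context count per position (center excluded)
    centers = np.repeat(np.arange(m), reps)
    total = int(reps.sum())
    # offsets within each position's context run
    starts = np.concatenate(([0], np.cumsum(reps)[:-1]))
    within = np.arange(total) - np.repeat(starts, reps)
    ctx = np.repeat(lo, reps) + within
    # skip the center itself inside the window
    ctx = np.where(ctx >= centers, ctx + 1, ctx)
    return ids[centers], ids[ctx]


def train_sgns(stream: Sequence[TokenSequence], config: TrainingConfig,
               binning: TimeBinning | None = None) -> EmbeddingModel:
    """Train an SGNS model over a token stream.

    Deterministic: identical stream + config (including seed) give
    bit-identical vectors (single-threaded, fixed chunk order).
    """
    counts = build_vocabulary(stream, config.min_count)
    if not counts:
        raise ValueError("empty vocabulary: nothing meets min_count")
    vocab = sorted(counts)
    index = {t: i for i, t in enumerate(vocab)}
    V, d = len(vocab), config.dim
    rng = np.random.default_rng(config.seed)

    # Noise distribution: unigram counts ^ 0.75.
    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()
    noise_cum = np.cumsum(noise)

    keep_p = None
    if config.subsample_t is not None:
        rel = freq / freq.sum()
        keep_p = np.minimum(1.0, np.sqrt(config.subsample_t / rel)
                            + config.subsample_t / rel)

    # word2vec-style init: centers uniform small, contexts zero.
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    docs = [np.array([index[t] for t in seq.tokens if t in index], dtype=np.int64)
            for seq in stream]
    docs = [ids for ids in docs if ids.size > 1]

    # Pre-count pairs for the linear learning-rate schedule (one generation
    # per epoch keeps the schedule exact without storing all epochs).
    alpha0, alpha_min = config.alpha, config.alpha / 10_000.0
    k = config.negatives
    B = config.batch_size

    # total expected updates: estimated from epoch 0's realised pair count
    processed = 0
    total_pairs = None
    for epoch in range(config.epochs):
        epoch_centers: list[np.ndarray] = []
        epoch_ctx: list[np.ndarray] = []
        for ids in docs:
            if keep_p is not None:
                ids = ids[rng.random(ids.size) < keep_p[ids]]
                if ids.size < 2:
                    continue
            c, o = _pairs_for_doc(ids, config.window, rng)
            if c.size:
                epoch_centers.append(c)
                epoch_ctx.append(o)
        if not epoch_centers:
            continue
        centers = np.concatenate(epoch_centers)
        contexts = np.concatenate(epoch_ctx)
        if total_pairs is None:
            total_pairs = centers.size * config.epochs
        for start in range(0, centers.size, B):
            c = centers[start : start + B]
            o = contexts[start : start + B]
            n = np.searchsorted(noise_cum, rng.random((c.size, k)), side="right")
            n = np.minimum(n, V - 1)
            alpha = max(alpha_min,
                        alpha0 * (1.0 - processed / max(1, total_pairs)))
            v_c = W_in[c]                      # (B, d)
            u_o = W_out[o]                     # (B, d)
            u_n = W_out[n]                     # (B, k, d)
            # logits clipped at +-30: sigma saturates there in float64
            z_pos = np.clip((u_o * v_c).sum(1), -30.0, 30.0)
            z_neg = np.clip((u_n * v_c[:, None, :]).sum(2), -30.0, 30.0)
            g_pos = 1.0 / (1.0 + np.exp(-z_pos)) - 1.0   # sigma - label
            g_neg = 1.0 / (1.0 + np.exp(-z_neg))
            grad_c = g_pos[:, None] * u_o + (g_neg[:, :, None] * u_n).sum(1)
            grad_o = g_pos[:, None] * v_c
            grad_n = g_neg[:, :, None] * v_c[:, None, :]
            np.add.at(W_in, c, -alpha * grad_c)
            np.add.at(W_out, o, -alpha * grad_o)
            np.add.at(W_out, n.reshape(-1), -alpha * grad_n.reshape(-1, d))
            processed += c.size
            if not np.isfinite(W_in[c]).all():
                raise FloatingPointError(
                    f"non-finite parameters at epoch {epoch}, pair {processed}: "
                    "lower alpha or check the input stream"
                )

    return EmbeddingModel(vocab=vocab, counts=counts, vectors=W_in,
                          context_vectors=W_out, config=config, binning=binning)


def train_temporal_model(
    corpus: Corpus,
    targets: Iterable[str],
    binning: TimeBinning,
    config: TrainingConfig,
    case_sensitive: bool = False,
) -> EmbeddingModel:
    """Tokenise, temporally reference, and train in one step."""
    stream = tokenize_corpus(corpus, case_sensitive)
    stream = apply_temporal_referencing(stream, targets, binning)
    return train_sgns(stream, config, binning=binning)


def train_per_period_models(
    corpus: Corpus,
    binning: TimeBinning,
    config: TrainingConfig,
    case_sensitive: bool = False,
) -> dict[str, EmbeddingModel]:
    """The classical sensitivity-analysis variant: one model per time slice.

    The corpus is sub-divided into per-bin corpora and an independent SGNS
    model is trained on each (no target list, no time tokens).  Vectors from
    different slices are NOT comparable across models; the variant exists to
    check that within-period neighbourhoods agree with temporal referencing.
    """
    stream = tokenize_corpus(corpus, case_sensitive)
    models: dict[str, EmbeddingModel] = {}
    for (s, e), label in zip(binning.bins, binning.labels):
        slice_stream = [seq for seq in stream if s <= seq.year <= e]
        if not slice_stream:
            continue
        models[label] = train_sgns(slice_stream, config)
    return models


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); raises on zero vectors."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class NeighborTable:
    """Ranked related terms for one (word, bin) query."""

    word: str
    bin_label: str
    neighbors: tuple[tuple[str, float], ...]  # (term, cosine), cosine non-increasing


def top_related_terms(model: EmbeddingModel, word: str, bin_label: str,
                      k: int = 200) -> NeighborTable:
    """The top-k most-correlated terms for a target word in a time bin.

    Candidates are all plain (non-time-indexed) tokens plus other words'
    time tokens at the same bin, reported with the time suffix stripped
    (keeping the maximum cosine if stripping creates duplicates).  The query
    word and all of its own time variants are excluded.  Ranking is by cosine
    descending, ties broken lexicographically.
    """
    query_tok = model.time_token(word, bin_label)
    if query_tok not in model:
        raise KeyError(
            f"{query_tok!r} not in model (word below min_count in that bin?)"
        )
    q = model.vector(query_tok)
    qn = np.linalg.norm(q)
    suffix = TIME_SEP + bin_label
    best: dict[str, float] = {}
    norms = np.linalg.norm(model.vectors, axis=1)
    sims = model.vectors @ q / np.where(norms == 0, 1.0, norms) / qn
    for tok, i in model.index.items():
        if TIME_SEP in tok:
            if not tok.endswith(suffix):
                continue
            term = tok[: -len(suffix)]
        else:
            term = tok
        if term == word:
            continue
        cos = float(sims[i])
        if term not in best or cos > best[term]:
            best[term] = cos
    ranked = sorted(best.items(), key=lambda tc: (-tc[1], tc[0]))[: max(0, k)]
    return NeighborTable(word=word, bin_label=bin_label, neighbors=tuple(ranked))


def export_neighbors_tsv(table: NeighborTable, path: str | Path) -> Path:
    """TSV export: rank, term, cosine — one file per (word, bin)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tterm\tcosine\n")
        for rank, (term, cos) in enumerate(table.neighbors, start=1):
            fh.write(f"{rank}\t{term}\t{cos:.6f}\n")
    return path


_FMT = "%.17g"  # round-trips float64 exactly in decimal text


def save_model(model: EmbeddingModel, path: str | Path) -> Path:
    """Persist a model as text: one JSON header line, then token/vector rows."""
    path = Path(path)
    header = {
        "format": "diachron-sgns-1",
        "dim": model.dim,
        "vocab_size": len(model.vocab),
        "config": asdict(model.config),
        "binning": None if model.binning is None else
                   {"scheme": model.binning.scheme,
                    "bins": [list(b) for b in model.binning.bins]},
    }
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for i, tok in enumerate(model.vocab):
            vin = " ".join(_FMT % x for x in model.vectors[i])
            vout = " ".join(_FMT % x for x in model.context_vectors[i])
            fh.write(f"{tok}\t{model.counts[tok]}\t{vin}\t{vout}\n")
    return path


def load_model(path: str | Path) -> EmbeddingModel:
    """Inverse of :func:`save_model`; validates dimension and vocabulary size."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "diachron-sgns-1":
            raise ValueError(f"{path}: not a diachron model file")
        dim = header["dim"]
        vocab: list[str] = []
        counts: dict[str, int] = {}
        vin_rows: list[list[float]] = []
        vout_rows: list[list[float]] = []
        for line in fh:
            tok, cnt, vin, vout = line.rstrip("\n").split("\t")
            vin_vals = [float(x) for x in vin.split(" ")]
            vout_vals = [float(x) for x in vout.split(" ")]
            if len(vin_vals) != dim or len(vout_vals) != dim:
                raise ValueError(f"{path}: vector for {tok!r} has wrong dimension")
            vocab.append(tok)
            counts[tok] = int(cnt)
            vin_rows.append(vin_vals)
            vout_rows.append(vout_vals)
    if len(vocab) != header["vocab_size"]:
        raise ValueError(f"{path}: vocabulary size mismatch")
    cfg = TrainingConfig(**header["config"])
    binning = None
    if header["binning"] is not None:
        binning = TimeBinning(header["binning"]["scheme"],
                              tuple(tuple(b) for b in header["binning"]["bins"]))
    return EmbeddingModel(vocab=vocab, counts=counts,
                          vectors=np.array(vin_rows, dtype=np.float64),
                          context_vectors=np.array(vout_rows, dtype=np.float64),
                          config=cfg, binning=binning)
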