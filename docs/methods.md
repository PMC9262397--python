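# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data generator does and
does not emulate, and the numerical choices that affect results.

## Corpus model and time binning

A corpus is an ordered sequence of documents `(id, journal, year, text)`;
the year is the only dating information used (documents spanning volume
boundaries are dated by their single year field). Corpora are stored as
UTF-8 JSON lines; text is normalized to Unicode NFC on read so that
tokenization is byte-deterministic. Non-strict reading skips and counts
malformed records: when a small fraction of records is unreadable at random,
year-level statistics are essentially unaffected, which is the regime this
mode is intended for.

Two standard binnings are built in. Decade bins are full calendar decades
(1880–1889, …). Quarter-century bins lie on a 1900-anchored 25-year grid
(1900–1924, 1925–1949, …); the final bin is clamped to the corpus's last
year, so a corpus ending in 2020 gets 2000–2020 as its last period. Custom
bins are validated to be sorted, non-overlapping, and to cover the corpus
range. Bin labels use the ASCII hyphen internally ("1880-1889"); the en-dash
form is display-only.

## Tokenization and ngram statistics

Tokens are letters-only: each whitespace-delimited chunk has every
non-letter character deleted (so hyphenated/apostrophized forms concatenate:
"self-identified" → "selfidentified"), digit-only chunks vanish, and tokens
are lowercased unless case-sensitive mode is requested. No vocabulary
filtering of any kind is applied — in historical corpora, misspellings and
OCR forms are data. Ngram windows run across sentence boundaries within a
document (no sentence segmentation is assumed); a document of *m* tokens
yields exactly `max(0, m − n + 1)` order-*n* ngrams.

Frequencies are normalized against the total number of same-order ngrams
published per year, produced by the same tokenizer (so the numerator and
denominator are always consistent). A year with no published tokens yields
no frequency point rather than a zero — the quantity is undefined, and early
journal runs genuinely have such gaps. The per-article mode divides by the
number of corpus documents in that year.

Smoothing is a centered moving average truncated at the series boundaries
(the mean over the years actually present in the half-window); window 1 is
the identity. This is the simplest defensible kernel; it is stated here
because smoothed peak locations depend mildly on it.

## Temporal-referencing embeddings

Target words are rewritten, per occurrence, to `word@BIN` using the bin of
the containing document's year; all other words keep a single token. One
SGNS model is then trained over the rewritten stream, so every word-period
vector lives in the same space and cosines are directly comparable across
periods — no per-period model alignment (e.g. Procrustes) is needed, and
none is performed. The `@` separator cannot appear in tokenizer output, so
time tokens never collide with real words.

The trainer optimizes, for each (center c, context o) pair within a
per-position reduced window drawn uniformly from [1, w],

    log σ(u_o · v_c) + Σ_{i=1..k, n_i ~ P_n} log σ(−u_{n_i} · v_c),

with noise distribution `P_n ∝ unigram_count^0.75`. Defaults: dimension 100,
window 5, 5 negatives, 5 epochs, initial learning rate 0.025 decayed
linearly to 1/10000 of itself, min_count 5, frequent-word subsampling off.
These are the canonical SGNS settings; all are exposed in `TrainingConfig`.
The test suite and the acceptance script use dimension 16 and min_count 1 —
the synthetic vocabulary is small and topic structure is recoverable at low
dimension, which keeps a full training run around twenty seconds on one CPU.

Numerical choices that matter:

- Updates are applied in deterministic chunks of 64 (center, context) pairs:
  within a chunk gradients are computed at the same parameter values and
  scatter-added. Small chunks keep the accumulated step for high-frequency
  tokens (which recur many times per chunk) close to sequential SGD; large
  chunks were observed to destabilize training. Chunk size is a config
  field.
- Logits are clipped at ±30 before the sigmoid (σ saturates there in
  float64), and training aborts with a diagnostic on any non-finite
  parameter.
- Training is single-threaded numpy throughout, so identical inputs and seed
  give bit-identical vectors. This determinism contract is tested and is
  the basis of the manifest-reproducibility guarantee in the CLI.
- Negative draws are not filtered against the positive context; with
  realistic vocabulary sizes the collision probability is negligible.

Related-term queries rank candidates by cosine against the query's
time-specific vector. Candidates are all plain tokens plus other target
words' time tokens *of the same bin*, reported with the suffix stripped
(duplicates keep the maximum cosine); the query word and all its own time
variants are excluded; ties break lexicographically. Ranking is invariant
to vector scaling. The alternative convention — ranking against every time
token of every bin — is not used because printed related-term tables contain
plain words; the convention is configurable at the API level by querying the
model's vocabulary directly.

The classical sensitivity variant (`train_per_period_models`) slices the
corpus by bin and trains an independent model per slice, with no target
list. Its vectors are not comparable across slices; it exists to check that
within-period neighbourhoods agree with temporal referencing, which the test
suite does on synthetic drift words.

## Affinity propagation and concept flow

Word vectors of a period are clustered with affinity propagation on the
pairwise cosine matrix (negative squared Euclidean distance is available as
an alternative). The preference (diagonal) defaults to the median
off-diagonal similarity — the standard moderate-granularity choice given
that neither the number nor the size of clusters is fixed a priori. Damped
responsibility/availability messages are iterated until the exemplar set is
stable for 50 iterations (max 1000); each non-exemplar then joins the
exemplar it is most similar to.

Tiny symmetric seeded noise (scale 1e-12) is added to the similarities to
break exemplar ties deterministically. Non-convergence is never silent: the
returned partition carries `converged=False`. At the default damping 0.5,
affinity propagation can oscillate on dense embedding-derived similarity
matrices (scikit-learn's implementation fails identically on the same
input); `cluster_time_bins` therefore escalates damping 0.5 → 0.7 → 0.9 on
non-convergence before accepting a flagged partial result. The per-bin
robustness report — mean pairwise adjusted Rand index across repeat runs at
dampings {0.5, 0.7, 0.9} with distinct tie-break seeds — quantifies whether
the partition depends on the parameterization.

Concept flow between consecutive periods is defined purely by shared
membership: tracking the members of a chosen latest-period cluster, an edge
connects an earlier-period cluster to a later-period cluster with weight
equal to the number of tracked words in both. Cluster identity is never
inferred from labels or exemplars across periods; zero shared words means no
edge. Consequently the edge weights between two consecutive periods always
sum to the number of tracked words present in both partitions (tested as an
invariant).

## OCR character error rate

CER = (Σ per-line Levenshtein distance) / (Σ gold characters), with lines
paired positionally. The rate is gold-denominated, reportable as a percent
or as "1 in N characters" with `N = round(1/CER)`, and can exceed 1 when the
OCR inserts more characters than the gold line contains (it is reported, not
clamped). Leading/trailing whitespace is stripped per line (line extraction
is not under evaluation); interior whitespace and punctuation count as
characters, since punctuation recognition is a real OCR failure mode. A
letters-only variant restricts both sides to alphabetic characters,
separating punctuation failures from misread letters.

Edit distances are computed with edlib (bit-vector Myers algorithm); the
test suite property-checks it against a quadratic dynamic-programming
oracle.

Uncertainty: lines are resampled with replacement (default 1000 replicates,
explicit seed required in the CLI), the CER is recomputed per replicate, and
the standard deviation across replicates is reported. Whole lines are the
resampling unit because errors within a line are correlated (print quality,
typeface). The point CER is exactly invariant to line order; the bootstrap
standard deviation is deterministic given the seed and invariant to line
order only in distribution, not bitwise.

The error-planting helper substitutes exactly k characters (never to the
same letter) at positions sampled without replacement, and verifies that the
realized summed edit distance equals k — several substitutions in one line
can otherwise admit a cheaper shift alignment — so the expected CER of a
planted pair is exactly k/N.

## Synthetic corpus generator

The generator is the package's stand-in for multi-decade journal archives,
which are typically not redistributable. Per document: one topic is sampled
(single-membership mixture); the length is negative-binomial (gamma-mixed
Poisson, mean 120, shape 10 by default) for realistic over-dispersion; each
token position is independently a trend term with probability equal to its
trajectory value /100k for that year, otherwise a background word
(power-law weights, exponent 1.2 over 400 words, 35% of tokens), otherwise a
uniform draw from the document topic's pool. Drift words belong to their
pre-change topic's pool strictly before the change year and to the
post-change pool from that year on. Yearly document counts grow linearly
when a growth rate is set, emulating corpus expansion.

The reference conditions (`default_spec`): 60 years (1940–1999), 30
documents/year, 120-token mean length, three disjoint 30-word topics, two
drift words switching topic in 1970, and three trend terms — constant 80 per
100k, logistic rise (floor 0, ceiling 200, midpoint 1970, steepness 0.25),
and a Gaussian bump (peak 1980, width 8, height 150 per 100k). This trains
in about twenty seconds per model on one CPU, small enough that the
acceptance script can train several seeded models.

Because trend terms are injected per token position, the recoverable truth
is exact: the empirical frequency of a trend term is a binomial draw around
its trajectory, so recovery is asserted within 3 binomial standard errors at
decade midpoints, and planted OCR errors and topic labels are known exactly.

What the generator does *not* emulate — and hence what passing tests do not
show about real archives: OCR noise in the corpus text (the OCR module has
its own planted-error generator), genre/section structure, vocabulary
growth and spelling change over time, topic mixtures within a document,
polysemy beyond a single hard topic switch, and bursty term usage. Results
on real corpora additionally depend on tokenizer fit to the source material.

## Known limitations

- The tokenizer's letters-only rule discards numerals entirely; terms like
  "covid19" reduce to "covid". This matches the printed-vocabulary style of
  historical full-text studies but is a real modelling choice.
- Whether a corpus's published totals count all tokens or letter-tokens only
  is a convention; this package normalizes by its own tokenizer's totals and
  states so.
- SGNS at dimension 16 on synthetic topics is easy; real corpora need the
  default dimension 100 and benefit from min_count ≥ 5, at proportionally
  higher training cost.
- Affinity propagation's cluster granularity is controlled entirely by the
  preference; the median heuristic is a default, not an estimate.
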