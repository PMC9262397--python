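"""OCR transcription quality: character error rate with bootstrapped spread.

The character error rate (CER) of an OCR transcription against a manually
verified gold standard is the summed per-line character edit distance divided
by the total number of gold characters.  The rate is gold-denominated — a
"1 in N characters" error rate means N = round(1/CER) — and can exceed 1 when
OCR inserts more characters than the gold text contains (it is reported, not
clamped).  Whitespace inside a line counts as characters; leading and trailing
whitespace is stripped per line before comparison, since line extraction
itself is not under evaluation.

Uncertainty is estimated by bootstrap over whole lines (the sampling unit of
typical transcription studies), preserving within-line error correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

__all__ = [
    "TranscriptionPair",
    "CerEstimate",
    "char_edit_distance",
    "character_error_rate",
    "bootstrap_cer_std",
    "plant_ocr_errors",
    "read_transcription_pair",
]


def char_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance: minimum single-character edits from ``a`` to ``b``."""
    if a == b:
        return 0
    return edlib.align(a, b)["editDistance"]


@dataclass(frozen=True)
class TranscriptionPair:
    """Positionally aligned gold and OCR lines (line i versus line i)."""

    gold_lines: tuple[str, ...]
    ocr_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gold_lines) != len(self.ocr_lines):
            raise ValueError(
                f"gold has {len(self.gold_lines)} lines but OCR has "
                f"{len(self.ocr_lines)}; pairing is positional"
            )

    def stripped(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (
            tuple(g.strip() for g in self.gold_lines),
            tuple(o.strip() for o in self.ocr_lines),
        )


def _letters_only(s: str) -> str:
    return "".join(ch for ch in s if ch.isalpha())


def _line_stats(pair: TranscriptionPair, letters_only: bool) -> tuple[np.ndarray, np.ndarray]:
    gold, ocr = pair.stripped()
    if letters_only:
        gold = tuple(_letters_only(g) for g in gold)
        ocr = tuple(_letters_only(o) for o in ocr)
    dists = np.array([char_edit_distance(g, o) for g, o in zip(gold, ocr)], dtype=np.int64)
    lens = np.array([len(g) for g in gold], dtype=np.int64)
    return dists, lens


def character_error_rate(pair: TranscriptionPair, letters_only: bool = False) -> float:
    """Summed per-line edit distance over summed gold character count.

    ``letters_only`` restricts both texts to alphabetic characters before
    comparison, separating typography/punctuation failures from misread
    letters.
    """
    dists, lens = _line_stats(pair, letters_only)
    n_chars = int(lens.sum())
    if n_chars == 0:
        raise ValueError("gold text contains no characters; CER undefined")
    return float(dists.sum()) / n_chars


@dataclass(frozen=True)
class CerEstimate:
    """A CER point estimate with its bootstrap standard deviation."""

    cer: float
    std: float
    n_chars: int
    n_lines: int
    n_boot: int
    seed: int

    @property
    def one_in_n(self) -> int | None:
        """The '1 error in N characters' reading; None for a perfect transcript."""
        return round(1.0 / self.cer) if self.cer > 0 else None

    def report(self) -> str:
        pct = 100.0 * self.cer
        spd = 100.0 * self.std
        tail = f"; 1 in {self.one_in_n} characters" if self.one_in_n else ""
        return (
            f"CER {pct:.4g}% (± std {spd:.2g}%{tail}) "
            f"over {self.n_chars} gold characters in {self.n_lines} lines "
            f"[{self.n_boot} bootstrap replicates, seed {self.seed}]"
        )


def bootstrap_cer_std(
    pair: TranscriptionPair,
    n_boot: int = 1000,
    seed: int = 0,
    letters_only: bool = False,
) -> CerEstimate:
    """Bootstrap the CER standard deviation by resampling whole lines.

    Lines are resampled with replacement ``n_boot`` times; the CER is
    recomputed per replicate and the standard deviation is taken across
    replicates.  Deterministic given ``seed``.
    """
    n_lines = len(pair.gold_lines)
    if n_lines < 2:
        raise ValueError("bootstrap requires at least 2 lines")
    dists, lens = _line_stats(pair, letters_only)
    n_chars = int(lens.sum())
    if n_chars == 0:
        raise ValueError("gold text contains no characters; CER undefined")
    cer = float(dists.sum()) / n_chars
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_lines, size=(n_boot, n_lines))
    rep_err = dists[idx].sum(axis=1).astype(np.float64)
    rep_len = lens[idx].sum(axis=1).astype(np.float64)
    # A replicate of only empty gold lines contributes nothing estimable.
    ok = rep_len > 0
    reps = rep_err[ok] / rep_len[ok]
    std = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return CerEstimate(cer=cer, std=std, n_chars=n_chars, n_lines=n_lines,
                       n_boot=n_boot, seed=seed)


def plant_ocr_errors(
    gold_lines: list[str] | tuple[str, ...],
    n_errors: int,
    seed: int = 0,
) -> tuple[TranscriptionPair, int, int]:
    """Corrupt gold lines with exactly ``n_errors`` character substitutions.

    Each planted error replaces one character with a different letter, at
    positions sampled without replacement across the concatenated (stripped)
    gold text; at most one substitution lands per character.  Returns the
    gold/OCR pair plus the planted error count and the total gold character
    count, so the exact expected CER ``k/N`` is known.
    """
    stripped = [g.strip() for g in gold_lines]
    char_owner = [(i, j) for i, line in enumerate(stripped) for j in range(len(line))]
    n_chars = len(char_owner)
    if n_errors > n_chars:
        raise ValueError(f"cannot plant {n_errors} errors in {n_chars} characters")
    rng = np.random.default_rng(seed)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # Several substitutions in one line can occasionally admit a cheaper
    # shift alignment than n substitutions; redraw until the realised edit
    # distance equals the planted count so the expected CER is exactly k/N.
    for _ in range(100):
        hit = rng.choice(n_chars, size=n_errors, replace=False)
        ocr = [list(line) for line in stripped]
        for flat in hit:
            i, j = char_owner[flat]
            old = ocr[i][j]
            choices = [c for c in alphabet if c != old.lower()]
            ocr[i][j] = choices[int(rng.integers(0, len(choices)))]
        pair = TranscriptionPair(tuple(stripped), tuple("".join(l) for l in ocr))
        realised = sum(
            char_edit_distance(g, o) for g, o in zip(pair.gold_lines, pair.ocr_lines)
        )
        if realised == n_errors:
            return pair, n_errors, n_chars
    raise RuntimeError("could not plant exactly countable substitutions")


def read_transcription_pair(gold_path: str | Path, ocr_path: str | Path) -> TranscriptionPair:
    """Load positionally aligned gold and OCR line files."""
    gold = Path(gold_path).read_text(encoding="utf-8").splitlines()
    ocr = Path(ocr_path).read_text(encoding="utf-8").splitlines()
    return TranscriptionPair(tuple(gold), tuple(ocr))
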