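"""Transcript-based segmentation and metrics for the counting exercises.

The count-to-50 and single-breath-count exercises are located inside a
word-level ASR transcript by parsing number tokens (digits, number words,
adjacent-word compounds like "twenty one", and common counting homophones)
and finding the longest strictly increasing run starting at 1 or 2, tolerant
of a bounded number of missing or misrecognized values. Breath pauses are
inter-token silences (next onset minus previous offset) longer than a
threshold; the single-breath count is the value reached before the first
such pause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from .data import TranscriptWords
from .errors import InsufficientDataError, SegmentNotFoundError

_UNITS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9,
}
_TEENS = {
    "ten": 10, "eleven": 11, "twelve": 12, "thirteen": 13, "fourteen": 14,
    "fifteen": 15, "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS = {"twenty": 20, "thirty": 30, "forty": 40, "fifty": 50}
#: ASR homophones accepted only when adjacent to another number token.
_HOMOPHONES = {"to": 2, "too": 2, "for": 4, "ate": 8, "won": 1}

MAX_VALUE = 50


@dataclass(frozen=True)
class NumberToken:
    value: int          # 1..50
    start: float
    end: float
    raw_text: str

    def __post_init__(self):
        if not (1 <= self.value <= MAX_VALUE):
            raise ValueError(f"number token value {self.value} outside 1..{MAX_VALUE}")
        if self.start > self.end:
            raise ValueError("token start > end")


@dataclass(frozen=True)
class CountSegment:
    tokens: tuple[NumberToken, ...]
    elapsed: float                       # last end - first start
    intervals: tuple[float, ...]         # successive onset differences
    max_value: int
    breath_pauses: tuple[tuple[float, float], ...]  # (gap_start, gap_len)


def _clean(text: str) -> str:
    return "".join(ch for ch in text.lower() if ch.isalnum() or ch == "-")


def _word_value(text: str) -> Optional[int]:
    """Definite number value of a single cleaned word, else None."""
    if text.isdigit():
        v = int(text)
        return v if 1 <= v <= MAX_VALUE else None
    if text in _UNITS:
        return _UNITS[text]
    if text in _TEENS:
        return _TEENS[text]
    if text in _TENS:
        return _TENS[text]
    if "-" in text:
        parts = text.split("-")
        if len(parts) == 2 and parts[0] in _TENS and parts[1] in _UNITS:
            v = _TENS[parts[0]] + _UNITS[parts[1]]
            return v if v <= MAX_VALUE else None
    return None


def parse_number_words(transcript: TranscriptWords) -> list[NumberToken]:
    """Number tokens 1..50 from a transcript; non-numbers are skipped.

    Adjacent tens+unit words compound ("twenty" "one" -> 21, spanning both
    words). Counting homophones ("for" -> 4, ...) are accepted only when an
    adjacent transcript word is itself a number token.
    """
    words = transcript.words
    cleaned = [_clean(w.text) for w in words]
    definite = [_word_value(c) for c in cleaned]

    tokens: list[NumberToken] = []
    consumed = [False] * len(words)
    i = 0
    while i < len(words):
        v = definite[i]
        if v in _TENS.values() and v < 50 and i + 1 < len(words):
            nxt = definite[i + 1]
            if nxt is not None and 1 <= nxt <= 9:
                tokens.append(NumberToken(
                    value=v + nxt, start=words[i].start, end=words[i + 1].end,
                    raw_text=f"{words[i].text} {words[i + 1].text}",
                ))
                consumed[i] = consumed[i + 1] = True
                i += 2
                continue
        if v is not None:
            tokens.append(NumberToken(value=v, start=words[i].start, end=words[i].end,
                                      raw_text=words[i].text))
            consumed[i] = True
        i += 1

    # second pass: contextual homophones
    for i, c in enumerate(cleaned):
        if consumed[i] or c not in _HOMOPHONES:
            continue
        neighbor_is_number = (i > 0 and consumed[i - 1]) or (
            i + 1 < len(words) and consumed[i + 1]
        )
        if neighbor_is_number:
            tokens.append(NumberToken(value=_HOMOPHONES[c], start=words[i].start,
                                      end=words[i].end, raw_text=words[i].text))
    tokens.sort(key=lambda tk: (tk.start, tk.end))
    return tokens


def _pauses(tokens: Sequence[NumberToken], pause_gap_s: float) -> tuple[tuple[float, float], ...]:
    out = []
    for a, b in zip(tokens, tokens[1:]):
        gap = b.start - a.end
        if gap > pause_gap_s:
            out.append((a.end, gap))
    return tuple(out)


def locate_count_segment(
    tokens: Sequence[NumberToken],
    target: int = 50,
    max_skips: int = 3,
    min_run: int = 5,
    pause_gap_s: float = 1.0,
) -> CountSegment:
    """Longest strictly increasing counting run starting at value <= 2.

    Missing values (a jump of k skips k-1 values) and interleaved
    misrecognized tokens each consume skip budget, up to ``max_skips`` in
    total. Exact search by memoized recursion; ties broken toward the
    lexicographically earliest token indices. Values above ``target`` never
    enter the run.
    """
    if not tokens:
        raise SegmentNotFoundError("empty token sequence")
    values = [tk.value for tk in tokens]
    n = len(values)

    @lru_cache(maxsize=None)
    def best_from(i: int, budget: int) -> tuple[int, tuple[int, ...]]:
        """(chain length, index chain) of the best run whose first accepted token is i."""
        best_len, best_chain = 1, (i,)
        for j in range(i + 1, n):
            if values[j] <= values[i] or values[j] > target:
                continue
            cost = (j - i - 1) + (values[j] - values[i] - 1)
            if cost > budget:
                continue
            ln, chain = best_from(j, budget - cost)
            if 1 + ln > best_len:
                best_len, best_chain = 1 + ln, (i,) + chain
        return best_len, best_chain

    best: tuple[int, tuple[int, ...]] | None = None
    for i in range(n):
        if values[i] <= 2:
            ln, chain = best_from(i, max_skips)
            if best is None or ln > best[0]:
                best = (ln, chain)
    best_from.cache_clear()
    if best is None or best[0] < min_run:
        raise SegmentNotFoundError(
            f"no increasing counting run of length >= {min_run} starting at <= 2"
        )
    run = tuple(tokens[i] for i in best[1])
    starts = [tk.start for tk in run]
    return CountSegment(
        tokens=run,
        elapsed=float(run[-1].end - run[0].start),
        intervals=tuple(b - a for a, b in zip(starts, starts[1:])),
        max_value=max(tk.value for tk in run),
        breath_pauses=_pauses(run, pause_gap_s),
    )


def count_rate_metrics(segment: CountSegment) -> tuple[float, float]:
    """(mean, coefficient of variation) of successive onset intervals."""
    if len(segment.tokens) < 2:
        raise InsufficientDataError("rate metrics need at least 2 tokens")
    iv = segment.intervals
    mean = sum(iv) / len(iv)
    if mean == 0:
        raise InsufficientDataError("zero mean interval")
    var = sum((x - mean) ** 2 for x in iv) / len(iv)  # population variance
    return float(mean), float(var ** 0.5 / mean)


def single_breath_metrics(
    tokens: Sequence[NumberToken],
    pause_gap_s: float = 1.0,
) -> tuple[int, float, int]:
    """(count_reached, counting_time, breath_pauses) for the one-breath count.

    A breath pause is an inter-token gap (next start - previous end) longer
    than ``pause_gap_s``. ``count_reached`` is the value of the last token
    before the first pause (the overall maximum when there is none) and
    ``counting_time`` runs from the first token's start to that token's end.
    ``breath_pauses`` counts all gaps over threshold in the full segment.
    """
    if not tokens:
        raise InsufficientDataError("empty token sequence")
    pauses = _pauses(tokens, pause_gap_s)
    n_pauses = len(pauses)
    if n_pauses == 0:
        last = max(tokens, key=lambda tk: tk.value)
        return int(last.value), float(last.end - tokens[0].start), 0
    first_pause_start = pauses[0][0]
    before = [tk for tk in tokens if tk.end <= first_pause_start + 1e-12]
    last = before[-1]
    return int(last.value), float(last.end - tokens[0].start), n_pauses
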