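"""Text normalization and tokenization for free-text pathology reports."""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass


class TextError(ValueError):
    pass


#: Characters that end a sentence for negation/context scoping.
SENTENCE_BOUNDARIES = frozenset({".", ";", "\n"})

#: Punctuation stripped from token edges (never from the middle).
_EDGE_PUNCT = ".,;:!?()[]'\"“”‘’"

#: Characters that separate tokens.  Hyphens separate so that compounds such
#: as "hyperplasia-adenomatous" expose their components to gazetteer matching.
_SEPARATORS = frozenset({" ", "-", "–", "—", "/", "\n"})


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Lowercase, NFKC-fold and whitespace-collapse a report text.

    Returns the normalized text plus an offset map: for each normalized
    character, the index of the original character it came from.  Whitespace
    runs collapse to a single space, except that runs containing a newline
    collapse to a single newline (kept because newlines scope sentences).
    Idempotent on its own output.
    """
    if text is None or not text.strip():
        raise TextError("report text is empty or whitespace-only")
    out: list[str] = []
    offsets: list[int] = []
    pending: str | None = None  # collapsed whitespace char awaiting emission
    pending_at = 0
    for i, ch in enumerate(text):
        for nch in unicodedata.normalize("NFKC", ch).lower():
            if nch.isspace():
                if pending != "\n":
                    pending = "\n" if nch == "\n" else " "
                    pending_at = i
            else:
                if pending is not None and out:
                    out.append(pending)
                    offsets.append(pending_at)
                pending = None
                out.append(nch)
                offsets.append(i)
    return "".join(out), offsets


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # into the normalized text, half-open [start, end)
    end: int
    sentence: int


def tokenize(normalized: str) -> list[Token]:
    """Split normalized text into tokens with spans and sentence indices.

    Hyphens and slashes act as separators; edge punctuation is stripped.
    Sentence index increments at '.', ';' and newline.
    """
    tokens: list[Token] = []
    sentence = 0
    i = 0
    n = len(normalized)
    while i < n:
        ch = normalized[i]
        if ch in SENTENCE_BOUNDARIES:
            sentence += 1
            i += 1
            continue
        if ch in _SEPARATORS or ch in _EDGE_PUNCT:
            i += 1
            continue
        j = i
        while j < n and normalized[j] not in _SEPARATORS and normalized[j] not in SENTENCE_BOUNDARIES:
            j += 1
        start, end = i, j
        while start < end and normalized[start] in _EDGE_PUNCT:
            start += 1
        while end > start and normalized[end - 1] in _EDGE_PUNCT:
            end -= 1
        if end > start:
            tokens.append(Token(normalized[start:end], start, end, sentence))
        i = j
    return tokens


def term_tokens(term: str) -> tuple[str, ...]:
    """Canonical token tuple of a gazetteer term or candidate surface."""
    normalized, _ = normalize_text(term)
    return tuple(t.text for t in tokenize(normalized))
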