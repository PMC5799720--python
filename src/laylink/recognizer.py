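"""Candidate medical-term span recognition.

Two routes produce :class:`ConceptMatch` lists: a deterministic
dictionary tagger (greedy leftmost-longest token-window matching against
the concept table), and an import path for precomputed spans from an
external concept tagger.  Both emit non-overlapping matches sorted by
start offset, with 0-based half-open character spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .errors import FormatError
from .lexicon import ConceptRecord, ConceptTable, normalize_surface

__all__ = ["Token", "ConceptMatch", "tokenize", "recognize", "import_external_matches"]

logger = logging.getLogger(__name__)

# letters/digits runs; an apostrophe only joins when flanked by word chars;
# hyphen and underscore split
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class ConceptMatch:
    start: int
    end: int
    surface: str
    concept: ConceptRecord


def tokenize(text: str) -> list[Token]:
    """Split text into word tokens with character offsets.

    Maximal runs of letters/digits form tokens; internal apostrophes are
    retained (``Cushing's`` is one token); punctuation, whitespace, and
    hyphens separate tokens.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _window_key(text: str, tokens: list[Token], i: int, j: int) -> str | None:
    """Normalized lookup key for tokens[i:j], or None if the window spans
    non-whitespace separators (no dictionary surface crosses punctuation)."""
    for a, b in zip(tokens[i : j - 1], tokens[i + 1 : j]):
        if text[a.end : b.start].strip():
            return None
    return normalize_surface(" ".join(t.text for t in tokens[i:j]))


def recognize(text: str, concepts: ConceptTable, max_ngram: int = 6) -> list[ConceptMatch]:
    """Greedy leftmost-longest dictionary matching over token windows.

    At each token position the longest window (up to ``max_ngram``
    tokens) whose normalized form is a known surface is accepted; an
    accepted match consumes its tokens, so output spans never overlap or
    nest.  Deterministic for fixed inputs.
    """
    if max_ngram < 1:
        raise ValueError("max_ngram must be >= 1")
    tokens = tokenize(text)
    matches: list[ConceptMatch] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for j in range(min(n, i + max_ngram), i, -1):
            key = _window_key(text, tokens, i, j)
            if key is None:
                continue
            rec = concepts.get(key)
            if rec is not None:
                hit = (j, rec)
                break
        if hit is None:
            i += 1
        else:
            j, rec = hit
            start, end = tokens[i].start, tokens[j - 1].end
            matches.append(ConceptMatch(start, end, text[start:end], rec))
            i = j
    return matches


def import_external_matches(path: str | Path, text: str) -> list[ConceptMatch]:
    """Read precomputed span records and validate them against the text.

    Rows are ``start<TAB>end<TAB>concept_id<TAB>preferred_name<TAB>
    semantic_types``.  Out-of-bounds spans raise :class:`FormatError`;
    overlapping rows are resolved leftmost-longest, dropped rows are
    logged.
    """
    path = Path(path)
    rows: list[ConceptMatch] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            try:
                start, end = int(fields[0]), int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer span") from None
            if not (0 <= start < end <= len(text)):
                raise FormatError(
                    f"{path}:{lineno}: span ({start},{end}) out of bounds for text of "
                    f"length {len(text)}"
                )
            types = frozenset(t for t in fields[4].split("|") if t)
            if not types:
                raise FormatError(f"{path}:{lineno}: row with empty semantic_types")
            surface = text[start:end]
            rows.append(
                ConceptMatch(
                    start,
                    end,
                    surface,
                    ConceptRecord(
                        surface_form=normalize_surface(surface),
                        concept_id=fields[2],
                        preferred_name=fields[3],
                        semantic_types=types,
                    ),
                )
            )
    rows.sort(key=lambda m: (m.start, -(m.end - m.start)))
    kept: list[ConceptMatch] = []
    for m in rows:
        if kept and m.start < kept[-1].end:
            logger.warning(
                "dropping overlapping external match (%d,%d) %r", m.start, m.end, m.surface
            )
            continue
        kept.append(m)
    return kept
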