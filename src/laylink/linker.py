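"""The linking engine: semantic-type gating, four-stage definition
lookup with modifier trimming and per-word fallback, memoization, and
annotated-note assembly / serialization / HTML rendering.

Lookup stages for a recognized term:

1. exact match of the normalized surface form in the lexicon;
2. match of the concept's preferred name;
3. match of the surface with common modifier words removed (only when
   the trimmed string differs from the surface);
4. per-word fallback — each distinct word of the trimmed term is looked
   up and every hit is shown with a bracketed word label (a *partial*
   match: the full span is highlighted but only component words are
   defined).

Gating by semantic type decides how deep the search goes: terms with any
prioritized type run all four stages (FULL); terms whose types are all
deprioritized are ignored (SKIP); everything else stops after stage 2
(SHALLOW).
"""

from __future__ import annotations

import enum
import hashlib
import html
import json
import logging
from dataclasses import dataclass, field

from .errors import IntegrityError
from .lexicon import (
    ConceptRecord,
    ConceptTable,
    Lexicon,
    ModifierList,
    Provenance,
    SemanticTypeConfig,
    normalize_key,
    normalize_surface,
    resolve_definitions,
)
from .recognizer import ConceptMatch, recognize

__all__ = [
    "LookupPolicy",
    "LinkItem",
    "LinkResult",
    "AnnotatedNote",
    "classify_policy",
    "trim_modifiers",
    "lookup",
    "annotate",
    "serialize_annotations",
    "parse_annotations",
    "render_html",
]

logger = logging.getLogger(__name__)


class LookupPolicy(enum.Enum):
    FULL = "FULL"  # stages 1-4
    SHALLOW = "SHALLOW"  # stages 1-2
    SKIP = "SKIP"  # not looked up at all


@dataclass(frozen=True)
class LinkItem:
    label: str
    definition_text: str
    provenance: Provenance


@dataclass(frozen=True)
class LinkResult:
    match: ConceptMatch
    stage: int
    partial: bool
    items: tuple[LinkItem, ...]

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3, 4):
            raise ValueError(f"stage must be 1..4, got {self.stage}")
        if not self.items:
            raise ValueError("LinkResult.items must be non-empty")
        if self.partial != (self.stage == 4):
            raise ValueError("partial flag must hold exactly at stage 4")


@dataclass
class AnnotatedNote:
    text: str
    results: list[LinkResult]
    provenance: dict[str, str] = field(default_factory=dict)


def classify_policy(match: ConceptMatch, config: SemanticTypeConfig) -> LookupPolicy:
    """ANY prioritized type → FULL; else ALL deprioritized → SKIP; else
    SHALLOW."""
    types = match.concept.semantic_types
    if any(config.is_prioritized(t) for t in types):
        return LookupPolicy.FULL
    if types and all(config.is_deprioritized(t) for t in types):
        return LookupPolicy.SKIP
    return LookupPolicy.SHALLOW


def trim_modifiers(term: str, modifiers: ModifierList) -> str:
    """Drop every modifier word, preserving the order of the rest; may
    return the empty string."""
    return " ".join(w for w in term.split() if w not in modifiers)


# cache values are (stage, partial, items) or None for a miss
_CacheValue = tuple[int, bool, tuple[LinkItem, ...]] | None
LookupCache = dict[tuple[str, str, LookupPolicy], _CacheValue]


def _run_stages(
    surface_key: str,
    preferred_key: str,
    lexicon: Lexicon,
    policy: LookupPolicy,
    modifiers: ModifierList,
) -> _CacheValue:
    # stage 1: exact surface
    defs = resolve_definitions(surface_key, lexicon)
    if defs:
        return 1, False, tuple(LinkItem(surface_key, d, p) for d, p in defs)
    # stage 2: preferred name
    defs = resolve_definitions(preferred_key, lexicon)
    if defs:
        return 2, False, tuple(LinkItem(preferred_key, d, p) for d, p in defs)
    if policy is LookupPolicy.SHALLOW:
        return None
    # stage 3: modifier-trimmed surface (only when trimming changed it)
    trimmed = trim_modifiers(surface_key, modifiers)
    if trimmed and trimmed != surface_key:
        defs = resolve_definitions(trimmed, lexicon)
        if defs:
            return 3, False, tuple(LinkItem(trimmed, d, p) for d, p in defs)
    # stage 4: per-word fallback over the trimmed term, one labeled item
    # per defined word in word order (top-ranked sense per word)
    items = []
    for word in dict.fromkeys(trimmed.split()):
        defs = resolve_definitions(word, lexicon)
        if defs:
            items.append(LinkItem(word, defs[0][0], defs[0][1]))
    if items:
        return 4, True, tuple(items)
    return None


def lookup(
    match: ConceptMatch,
    lexicon: Lexicon,
    policy: LookupPolicy,
    modifiers: ModifierList,
    cache: LookupCache | None = None,
) -> LinkResult | None:
    """Run the staged lookup for one match; returns None on a miss.

    ``cache`` memoizes interim results keyed by (surface, preferred name,
    policy); passing the same dict across calls reuses them.  Callers
    must not invoke lookup for SKIP matches.
    """
    if policy is LookupPolicy.SKIP:
        raise ValueError("lookup must not be called with SKIP policy")
    surface_key = normalize_surface(match.surface)
    preferred_key = normalize_key(match.concept.preferred_name)
    cache_key = (surface_key, preferred_key, policy)
    if cache is not None and cache_key in cache:
        value = cache[cache_key]
    else:
        value = _run_stages(surface_key, preferred_key, lexicon, policy, modifiers)
        if cache is not None:
            cache[cache_key] = value
    if value is None:
        return None
    stage, partial, items = value
    return LinkResult(match=match, stage=stage, partial=partial, items=items)


def annotate(
    text: str,
    concepts: ConceptTable,
    lexicon: Lexicon,
    config: SemanticTypeConfig,
    modifiers: ModifierList,
    *,
    matches: list[ConceptMatch] | None = None,
    max_ngram: int = 6,
    use_cache: bool = True,
    cache: LookupCache | None = None,
    provenance: dict[str, str] | None = None,
) -> AnnotatedNote:
    """Recognize (or accept imported) matches, gate them by semantic
    type, and attach definitions.  Output is deterministic and identical
    with or without the memoization cache.
    """
    if matches is None:
        matches = recognize(text, concepts, max_ngram=max_ngram)
    if cache is None and use_cache:
        cache = {}
    policy_counts = {p: 0 for p in LookupPolicy}
    stage_counts = {s: 0 for s in (1, 2, 3, 4)}
    results: list[LinkResult] = []
    for match in matches:
        policy = classify_policy(match, config)
        policy_counts[policy] += 1
        if policy is LookupPolicy.SKIP:
            continue
        result = lookup(match, lexicon, policy, modifiers, cache=cache)
        if result is not None:
            stage_counts[result.stage] += 1
            results.append(result)
    logger.info(
        "matches by policy: %s; linked by stage: %s",
        {p.value: c for p, c in policy_counts.items()},
        stage_counts,
    )
    return AnnotatedNote(text=text, results=results, provenance=dict(provenance or {}))


# --------------------------------------------------------------------------
# serialization


def _text_hash(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def serialize_annotations(note: AnnotatedNote) -> str:
    record = {
        "text_hash": _text_hash(note.text),
        "provenance": note.provenance,
        "results": [
            {
                "start": r.match.start,
                "end": r.match.end,
                "surface": r.match.surface,
                "concept": {
                    "surface_form": r.match.concept.surface_form,
                    "concept_id": r.match.concept.concept_id,
                    "preferred_name": r.match.concept.preferred_name,
                    "semantic_types": sorted(r.match.concept.semantic_types),
                },
                "stage": r.stage,
                "partial": r.partial,
                "items": [
                    [item.label, item.definition_text, item.provenance.value]
                    for item in r.items
                ],
            }
            for r in note.results
        ],
    }
    return json.dumps(record, ensure_ascii=False, sort_keys=True, indent=2)


def parse_annotations(record: str, text: str) -> AnnotatedNote:
    """Inverse of :func:`serialize_annotations`; validates the record
    against the note text (hash and span bounds)."""
    try:
        data = json.loads(record)
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"unparseable annotation record: {exc}") from None
    if data.get("text_hash") != _text_hash(text):
        raise IntegrityError("annotation record does not match the supplied text")
    results = []
    for row in data.get("results", []):
        start, end = row["start"], row["end"]
        if not (0 <= start < end <= len(text)):
            raise IntegrityError(f"span ({start},{end}) out of bounds")
        if text[start:end] != row["surface"]:
            raise IntegrityError(f"span ({start},{end}) does not slice to recorded surface")
        concept = ConceptRecord(
            surface_form=row["concept"]["surface_form"],
            concept_id=row["concept"]["concept_id"],
            preferred_name=row["concept"]["preferred_name"],
            semantic_types=frozenset(row["concept"]["semantic_types"]),
        )
        results.append(
            LinkResult(
                match=ConceptMatch(start, end, row["surface"], concept),
                stage=row["stage"],
                partial=row["partial"],
                items=tuple(
                    LinkItem(label, definition, Provenance(prov))
                    for label, definition, prov in row["items"]
                ),
            )
        )
    return AnnotatedNote(text=text, results=results, provenance=dict(data.get("provenance", {})))


# --------------------------------------------------------------------------
# rendering


def _title_text(result: LinkResult) -> str:
    if result.stage == 4:
        lines = [f"[{i.label}]: {i.definition_text}" for i in result.items]
    else:
        lines = [i.definition_text for i in result.items]
    return "\n".join(lines)


def render_html(note: AnnotatedNote) -> str:
    """Render the note with each linked span wrapped in a highlight
    element whose ``title`` attribute carries the definitions (hover
    text).  All text is entity-escaped; no anchor elements are emitted.
    """
    parts: list[str] = []
    pos = 0
    for result in note.results:
        parts.append(html.escape(note.text[pos : result.match.start]))
        parts.append(
            '<span class="laylink-term" data-stage="{stage}" title="{title}">{surface}</span>'.format(
                stage=result.stage,
                title=html.escape(_title_text(result), quote=True).replace("\n", "&#10;"),
                surface=html.escape(note.text[result.match.start : result.match.end]),
            )
        )
        pos = result.match.end
    parts.append(html.escape(note.text[pos:]))
    return "".join(parts)
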