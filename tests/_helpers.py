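"""Shared test utilities: random instance generators and independent
brute-force oracles (deliberately written without reusing the package's
production code paths)."""

from __future__ import annotations

import numpy as np

from laylink.lexicon import (
    ConceptRecord,
    ConceptTable,
    DefinitionEntry,
    DrugClassEntry,
    EntryClass,
    Lexicon,
    ModifierList,
    Sense,
)
from laylink.recognizer import tokenize

VOCAB = [
    "ax", "bor", "cul", "dem", "eft", "fos", "gid", "hap", "ilk", "jot",
    "kex", "lum", "mop", "nub", "orc", "pyx", "quod", "rix", "sev", "tog",
]


def random_term(rng: np.random.Generator, max_words: int = 3) -> str:
    k = int(rng.integers(1, max_words + 1))
    return " ".join(rng.choice(VOCAB, size=k))


def random_lexicon(rng: np.random.Generator, n_entries: int = 8) -> Lexicon:
    """A random valid lexicon over the small shared vocabulary."""
    entries: dict[str, DefinitionEntry] = {}
    drug_classes: dict[str, DrugClassEntry] = {}
    while len(entries) < n_entries:
        key = random_term(rng)
        if key in entries:
            continue
        cls = [EntryClass.TERM, EntryClass.ACRONYM, EntryClass.DRUG][int(rng.integers(3))]
        n_senses = int(rng.integers(1, 4))
        class_key = None
        if cls is EntryClass.DRUG and rng.random() < 0.5:
            n_senses = 0
            class_key = f"class {random_term(rng, 1)}"
            if class_key not in drug_classes:
                drug_classes[class_key] = DrugClassEntry(class_key, f"Drugs like {key}.")
        senses = tuple(
            Sense(f"Definition {i + 1} of {key}.", i + 1, "t") for i in range(n_senses)
        )
        entries[key] = DefinitionEntry(key, cls, senses, drug_class_key=class_key)
    lex = Lexicon(entries=entries, drug_classes=drug_classes)
    lex.validate()
    return lex


def oracle_resolve(key: str, lexicon: Lexicon) -> list[str]:
    """Definition texts for a key, re-deriving the display rules from the
    entry fields (independent of lexicon.resolve_definitions)."""
    entry = lexicon.entries.get(key)
    if entry is None:
        return []
    senses = sorted(entry.senses, key=lambda s: s.sense_rank)
    if entry.entry_class is EntryClass.ACRONYM:
        return [senses[0].definition_text] if senses else []
    if senses:
        return [s.definition_text for s in senses]
    if entry.entry_class is EntryClass.DRUG and entry.drug_class_key:
        return [lexicon.drug_classes[entry.drug_class_key].definition_text]
    return []


def oracle_stage(
    surface: str,
    preferred: str,
    lexicon: Lexicon,
    modifiers: ModifierList,
    shallow: bool,
) -> tuple[int, list[str]] | None:
    """Brute-force evaluation of all four stages: each stage is computed
    independently, then the first hit wins (subject to the policy depth)."""
    stage_hits: dict[int, list[str]] = {}
    stage_hits[1] = oracle_resolve(surface, lexicon)
    stage_hits[2] = oracle_resolve(preferred, lexicon)
    trimmed = " ".join(w for w in surface.split() if w not in modifiers.words)
    if trimmed and trimmed != surface:
        stage_hits[3] = oracle_resolve(trimmed, lexicon)
    else:
        stage_hits[3] = []
    seen: list[str] = []
    for w in trimmed.split():
        if w not in seen:
            seen.append(w)
    stage_hits[4] = [w for w in seen if oracle_resolve(w, lexicon)]
    depth = 2 if shallow else 4
    for stage in range(1, depth + 1):
        if stage_hits[stage]:
            return stage, stage_hits[stage]
    return None


def oracle_recognize(text: str, concepts: ConceptTable, max_ngram: int = 6):
    """Exhaustive window scan: score every token window against the
    table, then replay the leftmost-longest consumption rule over the
    full candidate set."""
    from laylink.lexicon import normalize_surface

    tokens = tokenize(text)
    candidates = []
    for i in range(len(tokens)):
        for j in range(i + 1, min(len(tokens), i + max_ngram) + 1):
            gap_ok = all(
                not text[tokens[a].end : tokens[a + 1].start].strip()
                for a in range(i, j - 1)
            )
            if not gap_ok:
                continue
            key = normalize_surface(" ".join(t.text for t in tokens[i:j]))
            rec = concepts.get(key)
            if rec is not None:
                candidates.append((i, j, tokens[i].start, tokens[j - 1].end, rec))
    chosen = []
    consumed_until = -1
    # leftmost-longest: among candidates starting at the earliest free
    # token, prefer the longest window
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    for i, j, start, end, rec in candidates:
        if i <= consumed_until:
            continue
        chosen.append((start, end, rec.concept_id))
        consumed_until = j - 1
    return chosen


def random_concept_table(rng: np.random.Generator, n_surfaces: int = 10) -> ConceptTable:
    table = ConceptTable()
    surfaces: set[str] = set()
    while len(surfaces) < n_surfaces:
        s = random_term(rng)
        if s in surfaces:
            continue
        surfaces.add(s)
        table.add(
            ConceptRecord(
                surface_form=s,
                concept_id=f"C{len(surfaces):03d}",
                preferred_name=random_term(rng),
                semantic_types=frozenset({"Disease or Syndrome"}),
            )
        )
    return table


def random_text(rng: np.random.Generator, n_tokens: int = 30) -> str:
    seps = [" ", " ", " ", ", ", ". ", "; ", " - "]
    parts = []
    for _ in range(n_tokens):
        parts.append(str(rng.choice(VOCAB)))
        parts.append(str(rng.choice(seps)))
    return "".join(parts).strip()
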