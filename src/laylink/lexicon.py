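"""Data model and I/O for the lay-definition lexicon, the concept table,
the semantic-type configuration, and the modifier list.

The lexicon maps normalized term keys to lay definitions.  An entry is one
of three classes: plain terms (all senses shown in rank order), acronyms
(only the top-ranked sense is shown), and drugs (all senses, or a
class-level fallback definition when no term-level sense exists).

File dialects (all UTF-8, tab-separated, one header line):

* lexicon:       ``term_key  entry_class  sense_rank  definition_text
                 source_tag  drug_class_key``
* drug classes:  ``class_key  definition_text``
* concept table: ``surface_form  concept_id  preferred_name
                 semantic_types`` with semantic types ``|``-joined
* semantic-type config / modifier list: plain text with
  ``[prioritized]`` / ``[deprioritized]`` / ``[modifiers]`` sections,
  one item per line, ``#`` comments.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "EntryClass",
    "Provenance",
    "Sense",
    "DefinitionEntry",
    "DrugClassEntry",
    "Lexicon",
    "ConceptRecord",
    "ConceptTable",
    "SemanticTypeConfig",
    "ModifierList",
    "normalize_key",
    "normalize_surface",
    "load_lexicon",
    "write_lexicon",
    "resolve_definitions",
    "load_concept_table",
    "write_concept_table",
    "load_semantic_config",
    "load_modifier_list",
    "default_semantic_config",
    "default_modifier_list",
]

_WS_RE = re.compile(r"\s+")

LEXICON_HEADER = "term_key\tentry_class\tsense_rank\tdefinition_text\tsource_tag\tdrug_class_key"
DRUG_CLASS_HEADER = "class_key\tdefinition_text"
CONCEPT_HEADER = "surface_form\tconcept_id\tpreferred_name\tsemantic_types"


def normalize_key(text: str) -> str:
    """Canonical stored-key form: NFC, lowercase, outer strip, inner
    whitespace collapsed to single spaces."""
    text = unicodedata.normalize("NFC", text)
    return _WS_RE.sub(" ", text.strip()).lower()


def normalize_surface(text: str) -> str:
    """Surface-matching form: :func:`normalize_key` plus stripping a
    trailing possessive ``'s`` (applied at match time only, never to
    stored keys)."""
    key = normalize_key(text)
    for suffix in ("'s", "’s"):
        if key.endswith(suffix) and len(key) > len(suffix):
            return key[: -len(suffix)]
    return key


class EntryClass(enum.Enum):
    TERM = "TERM"
    ACRONYM = "ACRONYM"
    DRUG = "DRUG"


class Provenance(enum.Enum):
    SENSE = "SENSE"
    DRUG_CLASS = "DRUG_CLASS"


@dataclass(frozen=True)
class Sense:
    definition_text: str
    sense_rank: int
    source_tag: str = ""


@dataclass(frozen=True)
class DefinitionEntry:
    term_key: str
    entry_class: EntryClass
    senses: tuple[Sense, ...] = ()
    drug_class_key: str | None = None

    def __post_init__(self) -> None:
        if self.term_key != normalize_key(self.term_key):
            raise ValueError(f"term_key not normalized: {self.term_key!r}")
        ranks = [s.sense_rank for s in self.senses]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"sense ranks for {self.term_key!r} must be contiguous from 1, got {ranks}"
            )
        for s in self.senses:
            if not s.definition_text:
                raise ValueError(f"empty definition_text in entry {self.term_key!r}")
        if self.drug_class_key is not None and self.entry_class is not EntryClass.DRUG:
            raise ValueError(
                f"drug_class_key only valid for DRUG entries, found on {self.term_key!r}"
            )


@dataclass(frozen=True)
class DrugClassEntry:
    class_key: str
    definition_text: str

    def __post_init__(self) -> None:
        if not self.definition_text:
            raise ValueError(f"empty drug-class definition for {self.class_key!r}")


@dataclass
class Lexicon:
    entries: dict[str, DefinitionEntry] = field(default_factory=dict)
    drug_classes: dict[str, DrugClassEntry] = field(default_factory=dict)

    def validate(self) -> None:
        for key, entry in self.entries.items():
            if key != entry.term_key:
                raise IntegrityError(f"entry keyed {key!r} has term_key {entry.term_key!r}")
            if entry.drug_class_key is not None and entry.drug_class_key not in self.drug_classes:
                raise IntegrityError(
                    f"entry {key!r} references unknown drug class {entry.drug_class_key!r}"
                )


@dataclass(frozen=True)
class ConceptRecord:
    surface_form: str
    concept_id: str
    preferred_name: str
    semantic_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.semantic_types:
            raise ValueError(f"concept {self.concept_id!r} has no semantic types")


class ConceptTable(Mapping[str, ConceptRecord]):
    """Surface-form → concept lookup with possessive-tolerant aliases.

    Primary keys are :func:`normalize_key` forms; each key ending in a
    possessive also registers its stripped alias so that matching by
    :func:`normalize_surface` still lands on the record.
    """

    def __init__(self, records: dict[str, ConceptRecord] | None = None):
        self._records: dict[str, ConceptRecord] = {}
        self._aliases: dict[str, ConceptRecord] = {}
        for rec in (records or {}).values():
            self.add(rec)

    def add(self, record: ConceptRecord) -> None:
        key = normalize_key(record.surface_form)
        existing = self._records.get(key)
        if existing is not None and existing.concept_id != record.concept_id:
            raise FormatError(
                f"surface form {key!r} mapped to two concepts: "
                f"{existing.concept_id!r} and {record.concept_id!r}"
            )
        self._records[key] = record
        alias = normalize_surface(record.surface_form)
        if alias != key and alias not in self._records:
            self._aliases.setdefault(alias, record)

    def get(self, surface: str, default=None):  # type: ignore[override]
        key = normalize_key(surface)
        if key in self._records:
            return self._records[key]
        key = normalize_surface(surface)
        if key in self._records:
            return self._records[key]
        return self._aliases.get(key, default)

    def __getitem__(self, surface: str) -> ConceptRecord:
        rec = self.get(surface)
        if rec is None:
            raise KeyError(surface)
        return rec

    def __contains__(self, surface: object) -> bool:
        return isinstance(surface, str) and self.get(surface) is not None

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def max_surface_words(self) -> int:
        return max((len(k.split()) for k in self._records), default=1)


@dataclass(frozen=True)
class SemanticTypeConfig:
    prioritized: frozenset[str]
    deprioritized: frozenset[str]

    def __post_init__(self) -> None:
        overlap = {p.lower() for p in self.prioritized} & {d.lower() for d in self.deprioritized}
        if overlap:
            raise ConfigError(f"semantic types in both sections: {sorted(overlap)}")

    def is_prioritized(self, semantic_type: str) -> bool:
        return semantic_type.lower() in {t.lower() for t in self.prioritized}

    def is_deprioritized(self, semantic_type: str) -> bool:
        return semantic_type.lower() in {t.lower() for t in self.deprioritized}


@dataclass(frozen=True)
class ModifierList:
    words: frozenset[str]

    def __post_init__(self) -> None:
        for w in self.words:
            if not w:
                raise ValueError("empty modifier word")
            if " " in w or w != w.lower():
                raise ValueError(f"modifiers must be single lowercase words, got {w!r}")

    def __contains__(self, word: str) -> bool:
        return word in self.words


# --------------------------------------------------------------------------
# defaults
#
# Only a handful of types are fixed by the published behavior; the full
# prioritized/deprioritized lists are deployment configuration.  These
# defaults seed the documented examples plus common clinical categories.

_DEFAULT_PRIORITIZED = (
    "Disease or Syndrome",
    "Pharmacologic Substance",
    "Laboratory or Test Result",
    "Sign or Symptom",
    "Finding",
    "Diagnostic Procedure",
    "Therapeutic or Preventive Procedure",
    "Laboratory Procedure",
    "Body Part, Organ, or Organ Component",
    "Clinical Drug",
    "Antibiotic",
    "Neoplastic Process",
    "Pathologic Function",
    "Injury or Poisoning",
    "Mental or Behavioral Dysfunction",
    "Congenital Abnormality",
    "Anatomical Abnormality",
    "Acquired Abnormality",
    "Virus",
    "Bacterium",
    "Medical Device",
)

_DEFAULT_DEPRIORITIZED = (
    "Geographic Area",
    "Temporal Concept",
    "Quantitative Concept",
)

_DEFAULT_MODIFIERS = ("chronic", "severe", "left", "right", "acute", "mild")


def default_semantic_config() -> SemanticTypeConfig:
    return SemanticTypeConfig(
        prioritized=frozenset(_DEFAULT_PRIORITIZED),
        deprioritized=frozenset(_DEFAULT_DEPRIORITIZED),
    )


def default_modifier_list() -> ModifierList:
    return ModifierList(words=frozenset(_DEFAULT_MODIFIERS))


# --------------------------------------------------------------------------
# lexicon I/O


def _split_row(line: str, n_fields: int, path: Path, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != n_fields:
        raise FormatError(f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}")
    return fields


def load_drug_classes(path: str | Path) -> dict[str, DrugClassEntry]:
    path = Path(path)
    classes: dict[str, DrugClassEntry] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.rstrip("\n") == DRUG_CLASS_HEADER:
                continue
            if not line.strip():
                continue
            class_key, definition = _split_row(line, 2, path, lineno)
            class_key = normalize_key(class_key)
            if not definition:
                raise FormatError(f"{path}:{lineno}: empty drug-class definition")
            if class_key in classes:
                raise FormatError(f"{path}:{lineno}: duplicate drug class {class_key!r}")
            classes[class_key] = DrugClassEntry(class_key, definition)
    return classes


def write_drug_classes(classes: dict[str, DrugClassEntry], path: str | Path) -> None:
    lines = [DRUG_CLASS_HEADER]
    for key in sorted(classes):
        lines.append(f"{key}\t{classes[key].definition_text}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_lexicon(path: str | Path, drug_class_path: str | Path | None = None) -> Lexicon:
    """Load a lexicon file (and optionally its drug-class companion file).

    Raises :class:`FormatError` on malformed rows or duplicate
    (term_key, sense_rank) pairs, and :class:`IntegrityError` when an
    entry references a drug class that does not exist.
    """
    path = Path(path)
    drug_classes = load_drug_classes(drug_class_path) if drug_class_path else {}

    rows: dict[str, list[tuple[int, str, EntryClass, int | None, str, str, str | None]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.rstrip("\n") == LEXICON_HEADER:
                continue
            if not line.strip():
                continue
            term_key, cls_s, rank_s, definition, source, class_key = _split_row(
                line, 6, path, lineno
            )
            term_key = normalize_key(term_key)
            try:
                entry_class = EntryClass(cls_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unknown entry_class {cls_s!r}") from None
            rank: int | None = None
            if rank_s:
                try:
                    rank = int(rank_s)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad sense_rank {rank_s!r}") from None
                if rank < 1:
                    raise FormatError(f"{path}:{lineno}: sense_rank must be >= 1")
                if not definition:
                    raise FormatError(f"{path}:{lineno}: sense row with empty definition_text")
            elif definition:
                raise FormatError(f"{path}:{lineno}: definition_text without sense_rank")
            rows.setdefault(term_key, []).append(
                (lineno, term_key, entry_class, rank, definition, source, class_key or None)
            )

    entries: dict[str, DefinitionEntry] = {}
    for term_key, group in rows.items():
        classes = {g[2] for g in group}
        if len(classes) > 1:
            raise FormatError(
                f"{path}:{group[0][0]}: conflicting entry_class values for {term_key!r}"
            )
        class_keys = {g[6] for g in group if g[6] is not None}
        if len(class_keys) > 1:
            raise FormatError(
                f"{path}:{group[0][0]}: conflicting drug_class_key values for {term_key!r}"
            )
        seen_ranks: set[int] = set()
        senses = []
        for lineno, _, _, rank, definition, source, _ in group:
            if rank is None:
                continue
            if rank in seen_ranks:
                raise FormatError(
                    f"{path}:{lineno}: duplicate sense_rank {rank} for term {term_key!r}"
                )
            seen_ranks.add(rank)
            senses.append(Sense(definition, rank, source))
        senses.sort(key=lambda s: s.sense_rank)
        try:
            entry = DefinitionEntry(
                term_key=term_key,
                entry_class=classes.pop(),
                senses=tuple(senses),
                drug_class_key=normalize_key(class_keys.pop()) if class_keys else None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: term {term_key!r}: {exc}") from None
        entries[term_key] = entry

    lexicon = Lexicon(entries=entries, drug_classes=drug_classes)
    lexicon.validate()
    return lexicon


def write_lexicon(
    lexicon: Lexicon, path: str | Path, drug_class_path: str | Path | None = None
) -> None:
    """Write the canonical tab-separated form (rows sorted by term_key then
    sense_rank; deterministic byte-for-byte)."""
    lexicon.validate()
    lines = [LEXICON_HEADER]
    for term_key in sorted(lexicon.entries):
        entry = lexicon.entries[term_key]
        class_key = entry.drug_class_key or ""
        if not entry.senses:
            lines.append(f"{term_key}\t{entry.entry_class.value}\t\t\t\t{class_key}")
        for sense in entry.senses:
            lines.append(
                f"{term_key}\t{entry.entry_class.value}\t{sense.sense_rank}"
                f"\t{sense.definition_text}\t{sense.source_tag}\t{class_key}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if drug_class_path is not None:
        write_drug_classes(lexicon.drug_classes, drug_class_path)


def resolve_definitions(term_key: str, lexicon: Lexicon) -> list[tuple[str, Provenance]]:
    """Definitions for a normalized key, per entry-class display rules.

    ACRONYM entries yield only the rank-1 (most frequent) sense; TERM and
    DRUG entries yield all senses in rank order; a sense-less DRUG entry
    falls back to its drug-class definition.  An unknown key yields [].
    """
    entry = lexicon.entries.get(term_key)
    if entry is None:
        return []
    if entry.entry_class is EntryClass.ACRONYM:
        return [(entry.senses[0].definition_text, Provenance.SENSE)] if entry.senses else []
    if entry.senses:
        return [(s.definition_text, Provenance.SENSE) for s in entry.senses]
    if entry.entry_class is EntryClass.DRUG and entry.drug_class_key is not None:
        cls = lexicon.drug_classes[entry.drug_class_key]
        return [(cls.definition_text, Provenance.DRUG_CLASS)]
    return []


# --------------------------------------------------------------------------
# concept table I/O


def load_concept_table(path: str | Path) -> ConceptTable:
    path = Path(path)
    table = ConceptTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and line.rstrip("\n") == CONCEPT_HEADER:
                continue
            if not line.strip():
                continue
            surface, cid, preferred, types_s = _split_row(line, 4, path, lineno)
            types = frozenset(t for t in types_s.split("|") if t)
            if not types:
                raise FormatError(f"{path}:{lineno}: row with empty semantic_types")
            try:
                table.add(
                    ConceptRecord(
                        surface_form=normalize_key(surface),
                        concept_id=cid,
                        preferred_name=preferred,
                        semantic_types=types,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return table


def write_concept_table(table: ConceptTable, path: str | Path) -> None:
    lines = [CONCEPT_HEADER]
    for key in sorted(table):
        rec = table[key]
        lines.append(
            f"{rec.surface_form}\t{rec.concept_id}\t{rec.preferred_name}"
            f"\t{'|'.join(sorted(rec.semantic_types))}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# sectioned config files


def _read_sections(path: str | Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                sections.setdefault(current, [])
                continue
            if current is None:
                raise ConfigError(f"{path}:{lineno}: item before any [section] header")
            sections[current].append(line)
    return sections


def load_semantic_config(path: str | Path) -> SemanticTypeConfig:
    sections = _read_sections(path)
    return SemanticTypeConfig(
        prioritized=frozenset(sections.get("prioritized", ())),
        deprioritized=frozenset(sections.get("deprioritized", ())),
    )


def load_modifier_list(path: str | Path) -> ModifierList:
    sections = _read_sections(path)
    return ModifierList(words=frozenset(w.lower() for w in sections.get("modifiers", ())))


def write_config(
    config: SemanticTypeConfig, modifiers: ModifierList, path: str | Path
) -> None:
    lines = ["[prioritized]"]
    lines += sorted(config.prioritized)
    lines.append("[deprioritized]")
    lines += sorted(config.deprioritized)
    lines.append("[modifiers]")
    lines += sorted(modifiers.words)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
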