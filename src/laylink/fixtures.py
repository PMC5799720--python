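"""Seeded generators for synthetic test inputs.

Everything the rest of the package consumes can be generated here with a
fixed seed: mini-lexicons with matching concept tables and gold-annotated
notes (``gen_bundle``), distant-supervision simulation worlds
(``gen_importance_world``), and clustered embedding spaces
(``gen_embedding_world``).  All generators are pure functions of their
parameters and seed.

``demo_resources`` builds a tiny hand-written lexicon/concept-table pair
whose entries exercise every display rule (acronym most-frequent-sense,
drug-class fallback, word-level partial matches) with runnable
micro-examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lexicon import (
    ConceptRecord,
    ConceptTable,
    DefinitionEntry,
    DrugClassEntry,
    EntryClass,
    Lexicon,
    ModifierList,
    SemanticTypeConfig,
    Sense,
    default_modifier_list,
    resolve_definitions,
    write_concept_table,
    write_config,
    write_lexicon,
)
from .importance import CandidateTerm, LabeledItem, LabeledSet, Label, Origin, feature_names
from .linker import LookupPolicy, classify_policy, trim_modifiers
from .recognizer import ConceptMatch
from .synmine import VectorTable

__all__ = [
    "GoldResult",
    "FixtureBundle",
    "ImportanceWorld",
    "EmbeddingWorld",
    "gen_bundle",
    "gen_importance_world",
    "gen_embedding_world",
    "demo_resources",
    "average_precision",
    "EMBEDDING_SIGMA_THRESHOLD",
]

# --------------------------------------------------------------------------
# annotated-note bundles

_PRIORITIZED_TYPE = "Disease or Syndrome"
_DEPRIORITIZED_TYPE = "Temporal Concept"
_NEUTRAL_TYPE = "Functional Concept"

_FILLERS = (
    "the", "patient", "was", "seen", "and", "stable", "today", "plan",
    "continue", "monitor", "daily", "with", "for", "followup", "status",
    "review", "remains", "improving", "tolerating", "well",
)

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class GoldResult:
    start: int
    end: int
    stage: int
    partial: bool


@dataclass
class FixtureBundle:
    lexicon: Lexicon
    concepts: ConceptTable
    config: SemanticTypeConfig
    modifiers: ModifierList
    notes: list[tuple[str, list[GoldResult]]]
    seed: int

    def write_to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_lexicon(self.lexicon, directory / "lexicon.tsv", directory / "drug_classes.tsv")
        write_concept_table(self.concepts, directory / "concepts.tsv")
        write_config(self.config, self.modifiers, directory / "config.txt")
        notes_dir = directory / "notes"
        notes_dir.mkdir(exist_ok=True)
        gold = {}
        for i, (text, results) in enumerate(self.notes):
            name = f"note_{i:03d}.txt"
            (notes_dir / name).write_text(text, encoding="utf-8")
            gold[name] = [
                {"start": g.start, "end": g.end, "stage": g.stage, "partial": g.partial}
                for g in results
            ]
        (directory / "gold.json").write_text(
            json.dumps(gold, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _word(rng: np.random.Generator, used: set[str], syllables: int = 3) -> str:
    forbidden = set(_FILLERS) | set(default_modifier_list().words)
    while True:
        w = "".join(
            rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
            for _ in range(syllables)
        )
        if w not in used and w not in forbidden:
            used.add(w)
            return w


@dataclass
class _TermSpec:
    surface: str
    preferred: str
    semantic_type: str
    expected: tuple[int, bool] | None  # (stage, partial) or no-result


def _slow_expected(
    spec: _TermSpec,
    lexicon: Lexicon,
    config: SemanticTypeConfig,
    modifiers: ModifierList,
) -> tuple[int, bool] | None:
    """Independent re-derivation of the expected link outcome: every
    stage is evaluated exhaustively, then the policy filter is applied.
    Used only to verify generated gold; deliberately avoids linker.lookup.
    """
    match = ConceptMatch(
        0,
        len(spec.surface),
        spec.surface,
        ConceptRecord(spec.surface, "X", spec.preferred, frozenset({spec.semantic_type})),
    )
    policy = classify_policy(match, config)
    if policy is LookupPolicy.SKIP:
        return None
    hits: dict[int, bool] = {}
    hits[1] = bool(resolve_definitions(spec.surface, lexicon))
    hits[2] = bool(resolve_definitions(spec.preferred, lexicon))
    trimmed = trim_modifiers(spec.surface, modifiers)
    hits[3] = bool(
        trimmed and trimmed != spec.surface and resolve_definitions(trimmed, lexicon)
    )
    hits[4] = any(resolve_definitions(w, lexicon) for w in trimmed.split())
    last = 2 if policy is LookupPolicy.SHALLOW else 4
    for stage in range(1, last + 1):
        if hits[stage]:
            return stage, stage == 4
    return None


def _build_terms(n_terms: int, rng: np.random.Generator) -> tuple[list[_TermSpec], Lexicon, ConceptTable]:
    used: set[str] = set()
    entries: dict[str, DefinitionEntry] = {}
    drug_classes: dict[str, DrugClassEntry] = {}
    concepts = ConceptTable()
    specs: list[_TermSpec] = []

    def define(word: str) -> None:
        entries[word] = DefinitionEntry(
            word, EntryClass.TERM, (Sense(f"A lay explanation of {word}.", 1, "gen"),)
        )

    def add(spec: _TermSpec) -> None:
        concepts.add(
            ConceptRecord(
                surface_form=spec.surface,
                concept_id=f"C{len(specs):04d}",
                preferred_name=spec.preferred,
                semantic_types=frozenset({spec.semantic_type}),
            )
        )
        specs.append(spec)

    # core scenarios: every stage × every policy outcome is represented
    def scn_full_stage1() -> None:
        w = _word(rng, used)
        define(w)
        add(_TermSpec(w, _word(rng, used), _PRIORITIZED_TYPE, (1, False)))

    def scn_full_stage2() -> None:
        w, pref = _word(rng, used), _word(rng, used)
        define(pref)
        add(_TermSpec(w, pref, _PRIORITIZED_TYPE, (2, False)))

    def scn_full_stage3() -> None:
        base = _word(rng, used)
        define(base)
        add(_TermSpec(f"chronic {base}", _word(rng, used), _PRIORITIZED_TYPE, (3, False)))

    def scn_full_stage4() -> None:
        w1, w2 = _word(rng, used), _word(rng, used)
        define(w2)
        add(_TermSpec(f"{w1} {w2}", _word(rng, used), _PRIORITIZED_TYPE, (4, True)))

    def scn_full_miss() -> None:
        add(_TermSpec(_word(rng, used), _word(rng, used), _PRIORITIZED_TYPE, None))

    def scn_shallow_stage1() -> None:
        w = _word(rng, used)
        define(w)
        add(_TermSpec(w, _word(rng, used), _NEUTRAL_TYPE, (1, False)))

    def scn_shallow_stage2() -> None:
        w, pref = _word(rng, used), _word(rng, used)
        define(pref)
        add(_TermSpec(w, pref, _NEUTRAL_TYPE, (2, False)))

    def scn_shallow_blocked() -> None:
        # reachable only at stage 3, which SHALLOW never runs
        base = _word(rng, used)
        define(base)
        add(_TermSpec(f"chronic {base}", _word(rng, used), _NEUTRAL_TYPE, None))

    def scn_skip() -> None:
        w = _word(rng, used)
        define(w)
        add(_TermSpec(w, _word(rng, used), _DEPRIORITIZED_TYPE, None))

    def scn_acronym() -> None:
        w = _word(rng, used, syllables=1)
        entries[w] = DefinitionEntry(
            w,
            EntryClass.ACRONYM,
            (
                Sense(f"The most frequent sense of {w}.", 1, "gen"),
                Sense(f"A rarer sense of {w}.", 2, "gen"),
            ),
        )
        add(_TermSpec(w, _word(rng, used), _PRIORITIZED_TYPE, (1, False)))

    def scn_drug_class() -> None:
        w = _word(rng, used)
        cls = f"{_word(rng, used)} inhibitors"
        drug_classes[cls] = DrugClassEntry(cls, f"A drug of the {cls} class.")
        entries[w] = DefinitionEntry(w, EntryClass.DRUG, (), drug_class_key=cls)
        add(_TermSpec(w, _word(rng, used), _PRIORITIZED_TYPE, (1, False)))

    core = [
        scn_full_stage1,
        scn_full_stage2,
        scn_full_stage3,
        scn_full_stage4,
        scn_full_miss,
        scn_shallow_stage1,
        scn_shallow_stage2,
        scn_shallow_blocked,
        scn_skip,
        scn_acronym,
        scn_drug_class,
    ]
    if n_terms < len(core):
        raise ValueError(
            f"n_terms must be >= {len(core)} to cover every stage and policy"
        )
    for i in range(n_terms):
        core[i % len(core)]()
    lexicon = Lexicon(entries=entries, drug_classes=drug_classes)
    lexicon.validate()
    return specs, lexicon, concepts


def gen_bundle(
    n_terms: int = 22, n_notes: int = 10, jargon_density: float = 0.3, seed: int = 0
) -> FixtureBundle:
    """Generate a lexicon + concept table + notes with gold annotations.

    Every lookup stage and every gating policy is exercised by at least
    one term.  Gold spans/stages are verified at generation time by an
    independent exhaustive stage evaluation; output is deterministic for
    a fixed seed.
    """
    if not (0.0 < jargon_density <= 1.0):
        raise ValueError(f"jargon_density must be in (0, 1], got {jargon_density}")
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    rng = np.random.default_rng(seed)
    specs, lexicon, concepts = _build_terms(n_terms, rng)
    config = SemanticTypeConfig(
        prioritized=frozenset({_PRIORITIZED_TYPE}),
        deprioritized=frozenset({_DEPRIORITIZED_TYPE}),
    )
    modifiers = default_modifier_list()

    for spec in specs:
        assert _slow_expected(spec, lexicon, config, modifiers) == spec.expected, (
            f"generator/stage-rule disagreement for {spec}"
        )

    # every term is planted at least once; extra slots follow the density
    notes: list[tuple[str, list[GoldResult]]] = []
    assigned: dict[int, list[_TermSpec]] = {i: [] for i in range(n_notes)}
    for i, spec in enumerate(specs):
        assigned[i % n_notes].append(spec)
    for i in range(n_notes):
        mandatory = assigned[i]
        n_slots = max(10, math.ceil(len(mandatory) / jargon_density))
        slots: list[_TermSpec | str] = list(mandatory)
        while len(slots) < n_slots:
            if rng.random() < jargon_density:
                slots.append(specs[int(rng.integers(len(specs)))])
            else:
                slots.append(str(rng.choice(_FILLERS)))
        order = rng.permutation(len(slots))
        text = ""
        gold: list[GoldResult] = []
        for idx in order:
            slot = slots[int(idx)]
            if text:
                text += " "
            piece = slot.surface if isinstance(slot, _TermSpec) else slot
            start = len(text)
            text += piece
            if isinstance(slot, _TermSpec) and slot.expected is not None:
                stage, partial = slot.expected
                gold.append(GoldResult(start, len(text), stage, partial))
        text += "."
        gold.sort(key=lambda g: g.start)
        for g in gold:  # slice-check invariant
            assert text[g.start : g.end] in {s.surface for s in specs}
        notes.append((text, gold))

    return FixtureBundle(
        lexicon=lexicon,
        concepts=concepts,
        config=config,
        modifiers=modifiers,
        notes=notes,
        seed=seed,
    )


# --------------------------------------------------------------------------
# distant-supervision simulation world

_WORLD_DIM = 8
_WORLD_BASE_RATE = 0.25


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ImportanceWorld:
    candidates: list[CandidateTerm]
    true_labels: dict[str, int]
    consumer_vocab: set[str]
    manual: LabeledSet
    weights: np.ndarray
    intercept: float
    rho: float
    seed: int
    train_candidates: list[CandidateTerm] = field(default_factory=list)
    test_candidates: list[CandidateTerm] = field(default_factory=list)

    def distant_train_set(self) -> LabeledSet:
        """Distant labels (vocabulary membership) over the train split."""
        return LabeledSet(
            [
                LabeledItem(
                    c,
                    Label.POSITIVE if c.term in self.consumer_vocab else Label.NEGATIVE,
                    Origin.DISTANT,
                )
                for c in self.train_candidates
            ]
        )


def gen_importance_world(n: int = 2000, rho: float = 1.0, seed: int = 0) -> ImportanceWorld:
    """Simulated candidate-term world with known generative weights.

    Features are standard normal; the true label is
    Bernoulli(logistic(w·x + b)) with ``b`` calibrated so the positive
    base rate is ≈ 0.25.  The consumer vocabulary misses true positives
    with mean recall ``rho``, and the missingness is *feature-dependent*
    (retention probability follows a logistic of a random feature
    direction, calibrated to mean rho): whole regions of term space are
    systematically absent from the vocabulary and get distantly labeled
    negative, which biases the base model — the failure mode that
    adaptation on a small manual set corrects.  The manual set carries
    true labels and is drawn from the train split.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n, _WORLD_DIM))
    w = rng.normal(0.0, 1.0, size=_WORLD_DIM)
    w *= 5.0 / np.linalg.norm(w)  # strong signal: Bayes-optimal AUC well above 0.9
    scores = X @ w
    lo, hi = -20.0, 20.0  # calibrate intercept to the target base rate
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if _sigmoid(scores + mid).mean() > _WORLD_BASE_RATE:
            hi = mid
        else:
            lo = mid
    b = (lo + hi) / 2.0
    y = rng.binomial(1, _sigmoid(scores + b))

    # pad synthetic feature rows to the package's fixed feature length so
    # CandidateTerm vectors stay interchangeable with extracted ones
    n_features = len(feature_names())
    pad = np.zeros((n, n_features - _WORLD_DIM))
    feats = np.hstack([X, pad])
    candidates = [
        CandidateTerm(f"term{i:05d}", tuple(feats[i])) for i in range(n)
    ]
    true_labels = {c.term: int(y[i]) for i, c in enumerate(candidates)}
    if rho >= 1.0:
        keep = np.ones(n, dtype=bool)
    else:
        # retention depends on a random feature direction; calibrate the
        # offset so the mean retention over true positives equals rho
        v = rng.normal(0.0, 1.0, size=_WORLD_DIM)
        v /= np.linalg.norm(v)
        u = X @ v
        pos = y == 1
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = (lo + hi) / 2.0
            if _sigmoid(2.0 * u[pos] + mid).mean() > rho:
                hi = mid
            else:
                lo = mid
        keep = rng.random(n) < _sigmoid(2.0 * u + (lo + hi) / 2.0)
    vocab = {c.term for i, c in enumerate(candidates) if y[i] == 1 and keep[i]}

    split = int(0.75 * n)
    perm = rng.permutation(n)
    train = [candidates[i] for i in perm[:split]]
    test = [candidates[i] for i in perm[split:]]
    manual_idx = rng.choice(split, size=min(120, split), replace=False)
    manual = LabeledSet(
        [
            LabeledItem(
                train[i],
                Label.POSITIVE if true_labels[train[i].term] else Label.NEGATIVE,
                Origin.MANUAL,
            )
            for i in sorted(manual_idx)
        ]
    )
    return ImportanceWorld(
        candidates=candidates,
        true_labels=true_labels,
        consumer_vocab=vocab,
        manual=manual,
        weights=w,
        intercept=b,
        rho=rho,
        seed=seed,
        train_candidates=train,
        test_candidates=test,
    )


# --------------------------------------------------------------------------
# clustered embedding world

# below this noise level (relative to unit-norm cluster centers) the PRF
# improvement property is asserted by the benchmark
EMBEDDING_SIGMA_THRESHOLD = 0.35


@dataclass
class EmbeddingWorld:
    vectors: VectorTable
    targets: list[str]
    true_synonyms: dict[str, set[str]]
    candidates: dict[str, list[str]]
    sigma: float
    seed: int


def gen_embedding_world(
    n_clusters: int = 50,
    syn_per_cluster: int = 5,
    d: int = 16,
    sigma: float = 0.25,
    seed: int = 0,
) -> EmbeddingWorld:
    """Clustered vector space: each cluster has one target term and
    ``syn_per_cluster`` true synonyms, all equal to the cluster center
    plus isotropic Gaussian noise of scale ``sigma``.  Candidate pools
    mix the true synonyms with distractors drawn from other clusters.
    At ``sigma=0`` every synonym vector equals its target's center.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters for distractors")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, size=(n_clusters, d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    vectors: dict[str, np.ndarray] = {}
    targets: list[str] = []
    synonyms: dict[str, set[str]] = {}
    for i in range(n_clusters):
        target = f"targ{i:03d}"
        targets.append(target)
        vectors[target] = centers[i] + rng.normal(0.0, sigma, d)
        syns = set()
        for j in range(syn_per_cluster):
            name = f"syn{i:03d}x{j:02d}"
            vectors[name] = centers[i] + rng.normal(0.0, sigma, d)
            syns.add(name)
        synonyms[target] = syns
    candidates: dict[str, list[str]] = {}
    all_syns = sorted(set().union(*synonyms.values()))
    for i, target in enumerate(targets):
        others = [s for s in all_syns if s not in synonyms[target]]
        n_distract = min(3 * syn_per_cluster, len(others))
        picks = rng.choice(len(others), size=n_distract, replace=False)
        pool = sorted(synonyms[target] | {others[int(p)] for p in picks})
        candidates[target] = pool
    return EmbeddingWorld(
        vectors=VectorTable(vectors),
        targets=targets,
        true_synonyms=synonyms,
        candidates=candidates,
        sigma=sigma,
        seed=seed,
    )


def average_precision(order: list[str], truth: set[str]) -> float:
    """Mean of precision-at-hit over the relevant items in ``order``."""
    if not truth:
        return 0.0
    hits = 0
    total = 0.0
    for i, item in enumerate(order, start=1):
        if item in truth:
            hits += 1
            total += hits / i
    return total / len(truth)


# --------------------------------------------------------------------------
# worked micro-examples


def demo_resources() -> tuple[Lexicon, ConceptTable, SemanticTypeConfig, ModifierList]:
    """Tiny hand-authored resources exercising every display rule:
    direct lookup, per-word partial matches, acronym most-frequent-sense,
    and drug-class fallback."""
    entries = {
        "bacteremia": DefinitionEntry(
            "bacteremia",
            EntryClass.TERM,
            (Sense("The presence of bacteria, a type of germ, in the blood", 1, "demo"),),
        ),
        "community": DefinitionEntry(
            "community", EntryClass.TERM, (Sense("A group of people.", 1, "demo"),)
        ),
        "pneumonia": DefinitionEntry(
            "pneumonia",
            EntryClass.TERM,
            (
                Sense(
                    "An infection of the lungs, usually caused by viruses or bacteria.",
                    1,
                    "demo",
                ),
            ),
        ),
        "rhythm": DefinitionEntry(
            "rhythm",
            EntryClass.TERM,
            (Sense("The pattern of the heartbeat.", 1, "demo"),),
        ),
        "ac": DefinitionEntry(
            "ac",
            EntryClass.ACRONYM,
            (
                Sense(
                    "a short-hand name for a chemotherapy combination used to treat "
                    "breast cancer",
                    1,
                    "demo",
                ),
                Sense("assist control, a way a breathing machine helps you breathe", 2, "demo"),
            ),
        ),
        "hecoria": DefinitionEntry(
            "hecoria", EntryClass.DRUG, (), drug_class_key="calcineurin inhibitors"
        ),
    }
    drug_classes = {
        "calcineurin inhibitors": DrugClassEntry(
            "calcineurin inhibitors", "A drug used to reduce immune response."
        )
    }
    lexicon = Lexicon(entries=entries, drug_classes=drug_classes)
    lexicon.validate()

    concepts = ConceptTable()
    for surface, cid, preferred, stype in [
        ("bacteremia", "C0004610", "Bacteremia", "Disease or Syndrome"),
        (
            "community acquired pneumonia",
            "C0694549",
            "Community-Acquired Pneumonia",
            "Disease or Syndrome",
        ),
        ("normal sinus rhythm", "C0232202", "Normal Sinus Rhythm", "Finding"),
        ("ac", "C0281462", "AC Chemotherapy Regimen", "Pharmacologic Substance"),
        ("hecoria", "C3234538", "Hecoria", "Pharmacologic Substance"),
    ]:
        concepts.add(
            ConceptRecord(
                surface_form=surface,
                concept_id=cid,
                preferred_name=preferred,
                semantic_types=frozenset({stype}),
            )
        )
    config = SemanticTypeConfig(
        prioritized=frozenset({"Disease or Syndrome", "Pharmacologic Substance", "Finding"}),
        deprioritized=frozenset({"Temporal Concept", "Geographic Area"}),
    )
    return lexicon, concepts, config, default_modifier_list()
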