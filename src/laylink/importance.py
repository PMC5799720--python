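"""Term-importance ranking by adapted distant supervision.

Candidate terms are extracted from a note corpus, distantly labeled
against a consumer vocabulary (a term present in the vocabulary is
assumed important), and scored by a regularized logistic model.  Because
important terms missing from the vocabulary get wrongly labeled
negative, a second, small model is fit on manually labeled examples over
the original features augmented with the base model's score (stacked
transfer), which recovers ranking quality lost to the label noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import TrainingError
from .lexicon import ConceptTable, normalize_surface
from .recognizer import recognize

__all__ = [
    "Label",
    "Origin",
    "CandidateTerm",
    "LabeledItem",
    "LabeledSet",
    "ImportanceModel",
    "feature_names",
    "term_features",
    "extract_candidates",
    "distant_label",
    "train_base",
    "adapt",
    "rank_terms",
]

# suffix trigrams typical of medical morphology; fixed block, fixed order
SUFFIX_TRIGRAMS = ("mia", "tis", "sis", "oma", "thy", "omy", "ion", "ous", "ary", "gic", "lar", "ase")

_BUCKET_EDGES = (100, 250, 500, 1000)  # word-frequency rank → bucket 0..4


def _load_english_ranks() -> dict[str, int]:
    text = resources.files("laylink.data").joinpath("english_freq.txt").read_text("utf-8")
    return {w: i for i, w in enumerate(text.split())}


_ENGLISH_RANKS = _load_english_ranks()


class Label(enum.Enum):
    POSITIVE = 1
    NEGATIVE = 0


class Origin(enum.Enum):
    DISTANT = "DISTANT"
    MANUAL = "MANUAL"


@dataclass(frozen=True)
class CandidateTerm:
    term: str
    features: tuple[float, ...]


@dataclass(frozen=True)
class LabeledItem:
    candidate: CandidateTerm
    label: Label
    origin: Origin


@dataclass
class LabeledSet:
    items: list[LabeledItem]

    def __len__(self) -> int:
        return len(self.items)


def feature_names() -> tuple[str, ...]:
    return (
        "term_frequency",
        "doc_frequency",
        "word_count",
        "char_length",
        "mean_word_length",
        "english_rank_bucket",
    ) + tuple(f"suffix_{t}" for t in SUFFIX_TRIGRAMS)


def _rank_bucket(word: str) -> int:
    rank = _ENGLISH_RANKS.get(word)
    if rank is None:
        return len(_BUCKET_EDGES)
    for bucket, edge in enumerate(_BUCKET_EDGES):
        if rank < edge:
            return bucket
    return len(_BUCKET_EDGES)


def term_features(term: str, term_frequency: int, doc_frequency: int) -> tuple[float, ...]:
    """Deterministic fixed-order feature vector for one candidate term."""
    words = term.split()
    mean_bucket = float(np.mean([_rank_bucket(w) for w in words])) if words else 0.0
    mean_len = float(np.mean([len(w) for w in words])) if words else 0.0
    suffix = tuple(1.0 if term.endswith(t) else 0.0 for t in SUFFIX_TRIGRAMS)
    return (
        float(term_frequency),
        float(doc_frequency),
        float(len(words)),
        float(len(term)),
        mean_len,
        mean_bucket,
    ) + suffix


def extract_candidates(corpus: list[str], concepts: ConceptTable) -> list[CandidateTerm]:
    """Distinct recognized term surfaces across the corpus, with corpus
    counts folded into the feature vector.  Sorted by term."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    tf: dict[str, int] = {}
    df: dict[str, int] = {}
    for note in corpus:
        seen: set[str] = set()
        for match in recognize(note, concepts):
            key = normalize_surface(match.surface)
            tf[key] = tf.get(key, 0) + 1
            seen.add(key)
        for key in seen:
            df[key] = df.get(key, 0) + 1
    return [
        CandidateTerm(term, term_features(term, tf[term], df[term])) for term in sorted(tf)
    ]


def distant_label(candidates: list[CandidateTerm], consumer_vocab: set[str]) -> LabeledSet:
    """Label every candidate by vocabulary membership (noisy by design:
    important terms absent from the vocabulary come out NEGATIVE)."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    return LabeledSet(
        [
            LabeledItem(
                c,
                Label.POSITIVE if c.term in consumer_vocab else Label.NEGATIVE,
                Origin.DISTANT,
            )
            for c in candidates
        ]
    )


@dataclass(frozen=True)
class ImportanceModel:
    """Linear-logistic scorer with optional stacked adaptation layer.

    ``base_weights``/``base_intercept`` act on standardized features;
    the adapted layer, when present, acts on standardized features plus
    the base model's probability as one extra input.
    """

    feature_mean: tuple[float, ...]
    feature_scale: tuple[float, ...]
    base_weights: tuple[float, ...]
    base_intercept: float
    adapted_weights: tuple[float, ...] | None = None
    adapted_intercept: float | None = None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - np.asarray(self.feature_mean)) / np.asarray(self.feature_scale)

    def base_score(self, X: np.ndarray) -> np.ndarray:
        z = self._standardize(np.atleast_2d(np.asarray(X, dtype=float)))
        logit = z @ np.asarray(self.base_weights) + self.base_intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def score(self, X: np.ndarray) -> np.ndarray:
        """Probability of being an important term, in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p_base = self.base_score(X)
        if self.adapted_weights is None:
            return p_base
        z = np.column_stack([self._standardize(X), p_base])
        logit = z @ np.asarray(self.adapted_weights) + self.adapted_intercept
        return 1.0 / (1.0 + np.exp(-logit))


def _design(items: list[LabeledItem]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([item.candidate.features for item in items], dtype=float)
    y = np.array([item.label.value for item in items], dtype=int)
    return X, y


def train_base(labeled: LabeledSet, *, C: float = 1.0, tol: float = 1e-6) -> ImportanceModel:
    """Fit the L2-regularized logistic base model on the DISTANT items.

    Deterministic for fixed inputs (lbfgs with fixed tolerance).  Raises
    :class:`TrainingError` when only one class is present.
    """
    items = [i for i in labeled.items if i.origin is Origin.DISTANT]
    if not items:
        raise TrainingError("no DISTANT items to train on")
    X, y = _design(items)
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both POSITIVE and NEGATIVE examples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=tol)
    clf.fit((X - mean) / scale, y)
    return ImportanceModel(
        feature_mean=tuple(mean),
        feature_scale=tuple(scale),
        base_weights=tuple(clf.coef_[0]),
        base_intercept=float(clf.intercept_[0]),
    )


def adapt(
    model: ImportanceModel, manual: LabeledSet, *, C: float = 1.0, tol: float = 1e-6
) -> ImportanceModel:
    """Stacked transfer: fit a second logistic layer on MANUAL items over
    standardized features plus the base model's score.  The base weights
    are left untouched.  Raises :class:`TrainingError` on an empty or
    single-class manual set.
    """
    items = [i for i in manual.items if i.origin is Origin.MANUAL]
    if not items:
        raise TrainingError("no MANUAL items to adapt on")
    X, y = _design(items)
    if len(np.unique(y)) < 2:
        raise TrainingError("adaptation requires both POSITIVE and NEGATIVE examples")
    Z = np.column_stack([model._standardize(X), model.base_score(X)])
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=tol)
    clf.fit(Z, y)
    return replace(
        model,
        adapted_weights=tuple(clf.coef_[0]),
        adapted_intercept=float(clf.intercept_[0]),
    )


def rank_terms(
    model: ImportanceModel, candidates: list[CandidateTerm]
) -> list[tuple[str, float]]:
    """Candidates sorted by importance probability (descending), ties
    broken lexicographically by term."""
    if not candidates:
        return []
    X = np.array([c.features for c in candidates], dtype=float)
    probs = model.score(X)
    order = sorted(range(len(candidates)), key=lambda i: (-probs[i], candidates[i].term))
    return [(candidates[i].term, float(probs[i])) for i in order]
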