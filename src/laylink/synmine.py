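"""Synonym candidate mining and two-pass ranking.

Candidates for a target term are its neighbors in an interwiki-link
edge list.  A first pass ranks them by cosine similarity between term
embeddings (multi-word terms embed as the mean of their word vectors);
a second pass re-represents the target as a Rocchio-style combination
of its own embedding and the centroid of the top-k first-pass
candidates (pseudo-relevance feedback) and reranks.  Candidates with no
embedding sink deterministically to the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import FormatError
from .lexicon import normalize_key

__all__ = [
    "LinkGraph",
    "VectorTable",
    "SynCandidate",
    "load_edge_list",
    "load_vectors",
    "write_vectors",
    "extract_candidates",
    "embed_term",
    "rank_by_similarity",
    "prf_rerank",
]

logger = logging.getLogger(__name__)


@dataclass
class LinkGraph:
    """Undirected edges between normalized terms; self-edges excluded."""

    edges: set[frozenset[str]]

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise ValueError(f"edge must join two distinct terms: {set(edge)}")

    def neighbors(self, term: str) -> set[str]:
        return {next(iter(e - {term})) for e in self.edges if term in e}


class VectorTable:
    """Fixed-dimension word/term vectors keyed by normalized token."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("vector table must contain at least one vector")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        self._vectors = {normalize_key(k): np.asarray(v, dtype=float) for k, v in vectors.items()}
        self.dim = next(iter(self._vectors.values())).shape[0]

    def get(self, word: str) -> np.ndarray | None:
        return self._vectors.get(normalize_key(word))

    def __len__(self) -> int:
        return len(self._vectors)

    def __iter__(self):
        return iter(self._vectors)

    def items(self):
        return self._vectors.items()


@dataclass(frozen=True)
class SynCandidate:
    target: str
    candidate: str
    sim_plain: float | None  # None means no embedding (MISSING)
    rank_plain: int
    sim_prf: float | None = None
    rank_prf: int | None = None


def load_edge_list(path: str | Path) -> LinkGraph:
    path = Path(path)
    edges: set[frozenset[str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            a, b = normalize_key(fields[0]), normalize_key(fields[1])
            if a == b:
                logger.warning("%s:%d: skipping self-edge %r", path, lineno, a)
                continue
            edges.add(frozenset((a, b)))
    return LinkGraph(edges=edges)


def load_vectors(path: str | Path) -> VectorTable:
    """Read the text vector format: header line ``n d``, then one
    ``token v1 … vd`` line per vector (space-separated)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: header must be 'n d'")
        try:
            n, d = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer header") from None
        vectors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != d + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected 1 token + {d} values, got {len(fields)} fields"
                )
            vectors[fields[0]] = np.array([float(x) for x in fields[1:]], dtype=float)
    if len(vectors) != n:
        raise FormatError(f"{path}: header declares {n} vectors, found {len(vectors)}")
    return VectorTable(vectors)


def write_vectors(table: VectorTable, path: str | Path) -> None:
    lines = [f"{len(table)} {table.dim}"]
    for token, vec in sorted(table.items()):
        lines.append(token + " " + " ".join(repr(float(x)) for x in vec))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def extract_candidates(graph: LinkGraph, target: str) -> list[str]:
    """Deduplicated graph neighbors of the target, lexicographically
    ordered (pre-ranking order); the target itself is excluded."""
    return sorted(graph.neighbors(target))


def embed_term(term: str, vectors: VectorTable) -> np.ndarray | None:
    """Single word → its vector; multi-word → mean of the available word
    vectors; None when every word is out of vocabulary."""
    whole = vectors.get(term)
    if whole is not None:
        return whole
    found = [v for w in normalize_key(term).split() if (v := vectors.get(w)) is not None]
    if not found:
        return None
    return np.mean(found, axis=0)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _sort_and_rank(
    scored: list[tuple[str, float]], missing: list[str]
) -> list[tuple[str, float | None, int]]:
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    ordered: list[tuple[str, float | None, int]] = [
        (c, s, i + 1) for i, (c, s) in enumerate(scored)
    ]
    base = len(ordered)
    ordered += [(c, None, base + i + 1) for i, c in enumerate(sorted(missing))]
    return ordered


def rank_by_similarity(
    target: str, candidates: list[str], vectors: VectorTable
) -> list[SynCandidate]:
    """First-pass ranking by cosine similarity to the target embedding.

    Raises ``ValueError`` when the target itself has no embedding (the
    caller should skip such targets).
    """
    t_vec = embed_term(target, vectors)
    if t_vec is None:
        raise ValueError(
            f"target {target!r} has no embedding; skip this target"
        )
    scored: list[tuple[str, float]] = []
    missing: list[str] = []
    for cand in candidates:
        c_vec = embed_term(cand, vectors)
        if c_vec is None:
            missing.append(cand)
        else:
            scored.append((cand, _cosine(t_vec, c_vec)))
    return [
        SynCandidate(target=target, candidate=c, sim_plain=s, rank_plain=r)
        for c, s, r in _sort_and_rank(scored, missing)
    ]


def prf_rerank(
    target: str,
    ranked: list[SynCandidate],
    vectors: VectorTable,
    k: int = 5,
    alpha: float = 1.0,
    beta: float = 0.75,
) -> list[SynCandidate]:
    """Pseudo-relevance-feedback rerank (Rocchio combination).

    The feedback vector is ``alpha * embed(target) + beta * centroid of
    the top-k scored candidates``; candidates are re-scored by cosine to
    it.  MISSING candidates keep sinking to the bottom.  With no scored
    candidate the input ranking is returned unchanged (warning logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [c for c in sorted(ranked, key=lambda c: c.rank_plain) if c.sim_plain is not None]
    if not scored:
        logger.warning("prf_rerank: no scored candidates for %r; returning input", target)
        return [
            replace(c, sim_prf=c.sim_plain, rank_prf=c.rank_plain)
            for c in sorted(ranked, key=lambda c: c.rank_plain)
        ]
    top_vecs = [embed_term(c.candidate, vectors) for c in scored[:k]]
    feedback = alpha * embed_term(target, vectors) + beta * np.mean(top_vecs, axis=0)
    rescored: list[tuple[str, float]] = []
    missing: list[str] = []
    for c in ranked:
        if c.sim_plain is None:
            missing.append(c.candidate)
        else:
            rescored.append((c.candidate, _cosine(feedback, embed_term(c.candidate, vectors))))
    plain = {c.candidate: c for c in ranked}
    out = []
    for cand, sim, rank in _sort_and_rank(rescored, missing):
        prev = plain[cand]
        out.append(replace(prev, sim_prf=sim, rank_prf=rank))
    return out
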