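"""Phase-1 entity resolution: blocking notices by manufacturer similarity.

Two interchangeable strategies are provided.  The primary one vectorizes
canonical manufacturer names with TF-IDF and admits every registry name
whose cosine similarity with the notice's name reaches a threshold (default
0.90).  The alternative extracts a named entity from each raw name and
requires exact equality of the extracted entities; when extraction fails
and returns an empty string, the block degenerates to the whole registry
(an un-blocked search).

Devices whose manufacturers fall outside the block are never compared in
phase 2, so the quality of this step bounds the quality of the whole
linkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import sparse

from .textprep import DEFAULT_LEGAL_SUFFIXES, normalize, strip_company_suffix

__all__ = [
    "TfidfModel",
    "ManufacturerBlock",
    "build_tfidf",
    "cosine_similarity",
    "block_by_cosine",
    "extract_named_entity",
    "block_by_ner",
    "preprocess_manufacturer",
    "DEFAULT_COS_THRESHOLD",
]

DEFAULT_COS_THRESHOLD = 0.90


def preprocess_manufacturer(name: str) -> str:
    """Canonical form used on both sides of the cosine comparison."""
    return strip_company_suffix(normalize(name))


@dataclass
class TfidfModel:
    """Deterministic TF-IDF vectorizer over a fixed name corpus.

    Term frequency is the raw in-document count; the inverse document
    frequency is the smoothed ``ln((1 + N) / (1 + df)) + 1`` so that no
    term receives a zero or undefined weight.  Vectors are L2-normalized
    (a vector with no in-vocabulary term stays the zero vector).  The
    vocabulary is ordered by first occurrence, which makes the model — and
    everything downstream — bit-stable across runs.
    """

    vocabulary: dict[str, int]
    doc_count: int
    doc_freq: np.ndarray
    idf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n, df = self.doc_count, self.doc_freq
        self.idf = np.log((1.0 + n) / (1.0 + df)) + 1.0

    def vectorize(self, text: str) -> np.ndarray:
        """Dense L2-normalized TF-IDF vector for one preprocessed name."""
        vec = np.zeros(len(self.vocabulary))
        for token in text.split():
            idx = self.vocabulary.get(token)
            if idx is not None:
                vec[idx] += self.idf[idx]
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def matrix(self, texts: Sequence[str]) -> sparse.csr_matrix:
        """Row-stacked normalized vectors for many names (sparse, for speed)."""
        data: list[float] = []
        indices: list[int] = []
        indptr = [0]
        for text in texts:
            counts: dict[int, int] = {}
            for token in text.split():
                idx = self.vocabulary.get(token)
                if idx is not None:
                    counts[idx] = counts.get(idx, 0) + 1
            row = {idx: cnt * self.idf[idx] for idx, cnt in counts.items()}
            norm = math.sqrt(sum(w * w for w in row.values()))
            for idx in sorted(row):
                indices.append(idx)
                data.append(row[idx] / norm if norm > 0 else 0.0)
            indptr.append(len(indices))
        return sparse.csr_matrix(
            (data, indices, indptr), shape=(len(texts), len(self.vocabulary))
        )


def build_tfidf(names: Sequence[str]) -> TfidfModel:
    """Fit a :class:`TfidfModel` on preprocessed manufacturer names.

    Each name is one document.  Raises ``ValueError`` on an empty corpus.
    """
    if not names:
        raise ValueError("cannot build a TF-IDF model from an empty corpus")
    vocabulary: dict[str, int] = {}
    doc_freq: list[int] = []
    for name in names:
        seen: set[str] = set()
        for token in name.split():
            if token in seen:
                continue
            seen.add(token)
            idx = vocabulary.get(token)
            if idx is None:
                vocabulary[token] = len(doc_freq)
                doc_freq.append(1)
            else:
                doc_freq[idx] += 1
    return TfidfModel(
        vocabulary=vocabulary,
        doc_count=len(names),
        doc_freq=np.asarray(doc_freq, dtype=float),
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between nonnegative vectors; 0 if either is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class ManufacturerBlock:
    """Result of phase-1 blocking for one notice."""

    notice_manufacturer: str
    matched: set[str]
    method: str
    scores: dict[str, float] = field(default_factory=dict)
    reason: Optional[str] = None  # set when the block is empty


def block_by_cosine(
    notice_name: str,
    model: TfidfModel,
    registry_names: Sequence[str],
    threshold: float = DEFAULT_COS_THRESHOLD,
    registry_matrix: Optional[sparse.csr_matrix] = None,
) -> ManufacturerBlock:
    """All registry names with cosine similarity >= *threshold* to the notice.

    *notice_name* and *registry_names* must be preprocessed identically
    (``preprocess_manufacturer``).  A query with no in-vocabulary term yields
    an empty block with reason ``"oov"``.  *registry_matrix* may carry the
    pre-vectorized registry names to avoid re-vectorizing per call.
    """
    query = model.vectorize(notice_name)
    if not np.any(query):
        return ManufacturerBlock(notice_name, set(), "cos", reason="oov")
    if registry_matrix is None:
        registry_matrix = model.matrix(registry_names)
    scores = registry_matrix.dot(query)
    matched: set[str] = set()
    score_map: dict[str, float] = {}
    for name, score in zip(registry_names, scores):
        if score >= threshold:
            matched.add(name)
            score_map[name] = float(score)
    if not matched:
        return ManufacturerBlock(notice_name, set(), "cos", reason="below_threshold")
    return ManufacturerBlock(notice_name, matched, "cos", scores=score_map)


def _default_ner(name: str) -> str:
    """Longest run of capitalized tokens, excluding legal-suffix tokens.

    Mimics what a real NER backend extracts from a well-formed company
    string; all-lowercase or otherwise ambiguous input yields "".
    """
    runs: list[list[str]] = [[]]
    for token in name.split():
        bare = "".join(ch for ch in token if ch.isalnum())
        if bare and token[:1].isupper() and bare.lower() not in DEFAULT_LEGAL_SUFFIXES:
            runs[-1].append(token)
        else:
            runs.append([])
    best = max(runs, key=len)
    return " ".join(best)


def extract_named_entity(
    name: str, backend: Optional[Callable[[str], str]] = None
) -> str:
    """Extract a single canonical entity string from a raw manufacturer name.

    The raw (suffix-bearing) name is passed to the backend: the legal suffix
    is informative for entity extraction even though it is stripped for the
    cosine route.  Returns "" when extraction fails.
    """
    if backend is None:
        backend = _default_ner
    if not callable(backend):
        raise TypeError("NER backend must be callable")
    return backend(name)


def block_by_ner(
    notice_name: str,
    registry_names: Sequence[str],
    backend: Optional[Callable[[str], str]] = None,
    registry_entities: Optional[Sequence[str]] = None,
) -> ManufacturerBlock:
    """Registry names whose extracted entity equals the notice's entity.

    Equality is tested on normalized entity strings.  When the notice's
    entity is empty the block is the whole registry (un-blocked search),
    which is the expensive failure mode of this method.
    """
    notice_entity = normalize(extract_named_entity(notice_name, backend))
    if not notice_entity:
        return ManufacturerBlock(notice_name, set(registry_names), "ner")
    if registry_entities is None:
        registry_entities = [
            normalize(extract_named_entity(n, backend)) for n in registry_names
        ]
    matched = {
        name
        for name, entity in zip(registry_names, registry_entities)
        if entity == notice_entity
    }
    if not matched:
        return ManufacturerBlock(notice_name, set(), "ner", reason="no_entity_match")
    return ManufacturerBlock(notice_name, matched, "ner")
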