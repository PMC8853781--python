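"""Top-N syndrome recommendation by dismantling and score-and-vote.

A test record is dismantled into tail-missing queries, one per resolvable
symptom token: (symptom, "{field}-syndrome", ?).  Every query row is scored
against every candidate syndrome, each row's top-k shortlist is taken, and
syndromes are ranked by how often they appear across shortlists (frequency
voting), with summed score as tie-break.  A single high-scoring query is
therefore never decisive on its own — the judgment aggregates all symptoms,
which is what makes overlapping symptom vocabularies tolerable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import DEFAULT_PUNCTUATION, EMRecord, FieldType, tokenize_record
from .embedding import ComplexEmbeddings, score_triples
from .kg import KnowledgeGraph, syndrome_relation

__all__ = [
    "Query",
    "CandidateMatrix",
    "Recommendation",
    "RecordNotDiagnosableError",
    "dismantle_record",
    "build_candidate_matrix",
    "score_and_vote",
    "recommend",
]

logger = logging.getLogger(__name__)


class RecordNotDiagnosableError(ValueError):
    """No token of the record resolved to a known symptom entity."""


@dataclass(frozen=True)
class Query:
    """A tail-missing triple (h, l, ?) for one resolved symptom token."""

    h: int  # symptom entity id
    l: int  # "{t}-syndrome" relation id
    token: str = ""
    field_type: FieldType | None = None


@dataclass
class CandidateMatrix:
    """m queries x n candidate syndromes of raw triple scores."""

    queries: list[Query]
    candidates: list[int]
    scores: np.ndarray  # (m, n) float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        m, n = len(self.queries), len(self.candidates)
        if self.scores.shape != (m, n):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({m}, {n})")
        if not np.isfinite(self.scores).all():
            raise ValueError("candidate matrix contains non-finite scores")


@dataclass
class RecommendationItem:
    syndrome_id: int
    votes: int
    summed_score: float


@dataclass
class Recommendation:
    """Ordered top-N list plus a per-query audit trail."""

    items: list[RecommendationItem]
    m: int = 0  # number of queries
    n: int = 0  # number of candidates
    shortlists: list[list[tuple[int, float]]] = field(default_factory=list)

    def syndrome_ids(self) -> list[int]:
        return [it.syndrome_id for it in self.items]

    def __len__(self) -> int:
        return len(self.items)


def dismantle_record(
    record: EMRecord,
    kg: KnowledgeGraph,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> list[Query]:
    """Turn a record into tail-missing queries against known symptoms.

    Nursing-precaution text is never used for diagnosis.  Tokens missing
    from the graph vocabulary are skipped with a logged warning; if nothing
    resolves, :class:`RecordNotDiagnosableError` is raised.
    """
    tokens = tokenize_record(record, punctuation, include_nursing=False)
    queries: list[Query] = []
    any_token = False
    for tok in tokens:
        any_token = True
        rid = kg.relation_id(syndrome_relation(tok.field_type))
        eid = kg.entity_id(tok.text, tok.field_type)
        if rid is None or eid is None:
            logger.warning(
                "record %s: unknown symptom %r (%s); skipped",
                record.record_id, tok.text, tok.field_type.value,
            )
            continue
        queries.append(Query(h=eid, l=rid, token=tok.text, field_type=tok.field_type))
    if not queries:
        msg = (
            f"record {record.record_id!r} is not diagnosable: "
            + ("no token resolved to a known symptom" if any_token else "no diagnostic text")
        )
        raise RecordNotDiagnosableError(msg)
    return queries


def build_candidate_matrix(
    queries: Sequence[Query],
    candidates: Sequence[int],
    emb: ComplexEmbeddings,
) -> CandidateMatrix:
    """Dense score matrix: row per query, column per candidate syndrome."""
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    if len(queries) == 0:
        raise ValueError("query list must be non-empty")
    cand = np.asarray(candidates, dtype=np.int64)
    hs = np.asarray([q.h for q in queries], dtype=np.int64)
    ls = np.asarray([q.l for q in queries], dtype=np.int64)
    scores = score_triples(hs[:, None], ls[:, None], cand[None, :], emb)
    return CandidateMatrix(list(queries), [int(c) for c in cand], scores)


def score_and_vote(matrix: CandidateMatrix, k: int = 10, top_n: int = 5) -> Recommendation:
    """Aggregate per-query shortlists into a ranked recommendation.

    Each query row contributes its ``k`` best-scoring candidates (ties by
    ascending entity id).  Syndromes are then ranked by shortlist
    occurrence count, tie-broken by summed score over appearances, then by
    ascending id, and the first ``top_n`` are returned.
    """
    m, n = matrix.scores.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")

    votes: dict[int, int] = {}
    sums: dict[int, float] = {}
    shortlists: list[list[tuple[int, float]]] = []
    cand = matrix.candidates
    for i in range(m):
        row = matrix.scores[i]
        order = sorted(range(n), key=lambda j: (-row[j], cand[j]))[:k]
        shortlist = [(cand[j], float(row[j])) for j in order]
        shortlists.append(shortlist)
        for sid, sc in shortlist:
            votes[sid] = votes.get(sid, 0) + 1
            sums[sid] = sums.get(sid, 0.0) + sc

    ranked = sorted(votes, key=lambda sid: (-votes[sid], -sums[sid], sid))
    items = [
        RecommendationItem(sid, votes[sid], sums[sid]) for sid in ranked[:top_n]
    ]
    return Recommendation(items=items, m=m, n=n, shortlists=shortlists)


def recommend(
    record: EMRecord,
    kg: KnowledgeGraph,
    emb: ComplexEmbeddings,
    k: int = 10,
    top_n: int = 5,
    candidates: Sequence[int] | None = None,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> Recommendation:
    """dismantle -> score matrix -> vote, returning the top-N syndromes.

    ``candidates`` defaults to every syndrome entity in the graph; a
    restricted syndrome-group list may be supplied instead.
    """
    queries = dismantle_record(record, kg, punctuation)
    if candidates is None:
        candidates = kg.syndrome_ids
    if len(candidates) == 0:
        raise ValueError("knowledge graph has no syndrome entities")
    matrix = build_candidate_matrix(queries, candidates, emb)
    k_eff = min(k, len(candidates))
    rec = score_and_vote(matrix, k=k_eff, top_n=top_n)
    logger.debug(
        "record %s: m=%d queries, n=%d candidates, %d recommended",
        record.record_id, rec.m, rec.n, len(rec),
    )
    return rec
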