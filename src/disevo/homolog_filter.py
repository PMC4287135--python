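"""Homolog-candidate filtering: self-score cutoff and redundancy clustering.

A candidate set (e.g. database hits for a query protein) is filtered by the
scale-free rule "keep candidates scoring at least ``fraction`` of the query's
self-alignment score" (default 10%), then collapsed by greedy longest-first
clustering at a sequence-identity threshold (default 90%), keeping one
representative per cluster. Scoring uses exact affine-gap global alignment
rather than a database heuristic, which leaves the score-ratio rule unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment import global_align
from .errors import ParameterError
from .records import ProteinRecord


@dataclass(frozen=True)
class PairwiseScore:
    query_id: str
    subject_id: str
    score: float
    identity: float
    coverage: float
    ratio: float = float("nan")  # score / query self-score, filled by the filter


@dataclass(frozen=True)
class Cluster:
    representative: ProteinRecord
    members: tuple[ProteinRecord, ...]


def score_candidates(
    query: ProteinRecord,
    candidates: Sequence[ProteinRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> list[PairwiseScore]:
    """Align every candidate to the query and report score/identity/coverage."""
    out = []
    for cand in candidates:
        res = global_align(query, cand, matrix, gap_open, gap_extend)
        out.append(
            PairwiseScore(
                query_id=query.id,
                subject_id=cand.id,
                score=res.score,
                identity=res.identity,
                coverage=res.coverage,
            )
        )
    return out


def self_score_filter(
    query: ProteinRecord,
    candidates: Sequence[ProteinRecord] | Sequence[PairwiseScore],
    fraction: float = 0.10,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> tuple[list[PairwiseScore], pd.DataFrame]:
    """Retain candidates scoring >= ``fraction`` of the query self-score.

    ``candidates`` may be records (aligned here) or precomputed
    :class:`PairwiseScore` rows from an external search. Returns the retained
    scores (each annotated with its ratio) and the full report table.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    self_score = global_align(query, query, matrix, gap_open, gap_extend).score
    if candidates and isinstance(candidates[0], PairwiseScore):
        scores = list(candidates)  # type: ignore[arg-type]
    else:
        scores = score_candidates(query, candidates, matrix, gap_open, gap_extend)  # type: ignore[arg-type]
    annotated = [
        PairwiseScore(
            s.query_id, s.subject_id, s.score, s.identity, s.coverage,
            ratio=s.score / self_score,
        )
        for s in scores
    ]
    retained = [s for s in annotated if s.score >= fraction * self_score]
    table = pd.DataFrame(
        [
            {
                "query": s.query_id,
                "subject": s.subject_id,
                "score": s.score,
                "ratio": s.ratio,
                "identity": s.identity,
                "coverage": s.coverage,
                "retained": s.score >= fraction * self_score,
            }
            for s in annotated
        ]
    )
    return retained, table


def redundancy_cluster(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.90,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> list[Cluster]:
    """Greedy longest-first clustering at a global-identity threshold.

    Records are processed longest first (ties by id); each joins the first
    existing cluster whose representative it matches at >= the threshold
    (identity = matches / alignment length, gap columns included), otherwise
    it founds a new cluster. The representative is the longest member, i.e.
    the founder. The result is a partition of the input.
    """
    if not 0 < identity_threshold <= 1:
        raise ParameterError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[list[ProteinRecord]] = []
    for rec in ordered:
        placed = False
        for cl in clusters:
            rep = cl[0]
            res = global_align(rep, rec, matrix, gap_open, gap_extend)
            if res.identity >= identity_threshold:
                cl.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])
    return [Cluster(representative=cl[0], members=tuple(cl)) for cl in clusters]


def cluster_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": k,
            "representative": cl.representative.id,
            "member": m.id,
            "member_length": len(m),
        }
        for k, cl in enumerate(clusters)
        for m in cl.members
    ]
    return pd.DataFrame(rows)
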