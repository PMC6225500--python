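"""Best Match / Best Close Match species discrimination.

Every sequence is in turn treated as a query against all others
(leave-one-out).  Best Match (BM) assigns the query the species of its
nearest sequence(s); the outcome is *correct* if all nearest sequences are
conspecific, *ambiguous* if mixed, *incorrect* if all heterospecific.  Best
Close Match (BCM) first discards candidates farther than a threshold set at
the 95th percentile of all intraspecific distances; a query with no
candidate left is *no_match*.

Ties are exact: the nearest set contains every sequence whose distance
equals the minimum with no epsilon.  The threshold is rank-based (the value
at the 95% cumulative rank of the sorted intraspecific distances), not an
interpolated percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .distances import DEFAULT_MIN_OVERLAP, DistanceMatrix, pairwise_matrix
from .seqio import AlignedMatrix

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_match")


@dataclass
class QueryOutcome:
    query_id: str
    category: str
    nearest_ids: list[str] = field(default_factory=list)
    nearest_distance: float = math.nan


@dataclass
class DiscriminationReport:
    outcomes: list[QueryOutcome]
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    pct_no_match: float
    method: str
    threshold: float | None = None
    n_unmatchable: int = 0


def intraspecific_threshold(
    matrix: DistanceMatrix, label_map: dict[str, str], percentile: float = 95.0
) -> float:
    """Smallest intraspecific distance v with >= percentile% of values <= v."""
    from .distances import partition_intra_inter

    intra, _ = partition_intra_inter(matrix, label_map)
    if not intra:
        raise ValueError("no defined intraspecific distances to rank")
    ranked = sorted(intra)
    k = math.ceil(percentile / 100.0 * len(ranked))
    k = max(k, 1)
    return ranked[k - 1]


def _nearest_set(
    query_id: str,
    matrix: DistanceMatrix,
    threshold: float | None,
) -> tuple[list[str], float]:
    qi = matrix.ids.index(query_id)
    best = math.inf
    nearest: list[str] = []
    for j, other in enumerate(matrix.ids):
        if j == qi:
            continue
        d = matrix.values[qi, j]
        if math.isnan(d):
            continue
        if threshold is not None and d > threshold:
            continue
        if d < best:
            best = d
            nearest = [other]
        elif d == best:
            nearest.append(other)
    return nearest, best


def _categorize(
    query_id: str,
    nearest: list[str],
    best: float,
    label_map: dict[str, str],
) -> QueryOutcome:
    if not nearest:
        return QueryOutcome(query_id=query_id, category="no_match")
    species = label_map[query_id]
    kinds = {label_map[n] == species for n in nearest}
    if kinds == {True}:
        category = "correct"
    elif kinds == {False}:
        category = "incorrect"
    else:
        category = "ambiguous"
    return QueryOutcome(
        query_id=query_id,
        category=category,
        nearest_ids=sorted(nearest),
        nearest_distance=best,
    )


def best_match(
    query_id: str, matrix: DistanceMatrix, label_map: dict[str, str]
) -> QueryOutcome:
    """BM outcome for one query; no_match only if it has no defined distance."""
    nearest, best = _nearest_set(query_id, matrix, threshold=None)
    return _categorize(query_id, nearest, best, label_map)


def best_close_match(
    query_id: str,
    matrix: DistanceMatrix,
    label_map: dict[str, str],
    threshold: float,
) -> QueryOutcome:
    """BCM outcome: BM restricted to candidates at distance <= threshold."""
    nearest, best = _nearest_set(query_id, matrix, threshold=threshold)
    return _categorize(query_id, nearest, best, label_map)


def discriminate_matrix(
    matrix: DistanceMatrix,
    label_map: dict[str, str],
    method: str = "best_close_match",
    percentile: float = 95.0,
    threshold: float | None = None,
) -> DiscriminationReport:
    """Leave-one-out discrimination over a precomputed distance matrix.

    Queries with zero defined distances (overlap filter) are counted as
    ``unmatchable`` and excluded from the percentage denominators under BM;
    under BCM they fall in the no_match class like any thresholded-out query.
    """
    if method not in ("best_match", "best_close_match"):
        raise ValueError(f"unknown method {method!r}")
    if method == "best_close_match" and threshold is None:
        threshold = intraspecific_threshold(matrix, label_map, percentile)
    outcomes = []
    n_unmatchable = 0
    for query_id in matrix.ids:
        if method == "best_match":
            out = best_match(query_id, matrix, label_map)
            if out.category == "no_match":
                n_unmatchable += 1
        else:
            out = best_close_match(query_id, matrix, label_map, threshold)
        outcomes.append(out)

    if method == "best_match":
        scored = [o for o in outcomes if o.category != "no_match"]
    else:
        scored = outcomes
    n = len(scored)

    def pct(cat: str) -> float:
        if n == 0:
            return 0.0
        return 100.0 * sum(o.category == cat for o in scored) / n

    return DiscriminationReport(
        outcomes=outcomes,
        pct_correct=pct("correct"),
        pct_ambiguous=pct("ambiguous"),
        pct_incorrect=pct("incorrect"),
        pct_no_match=pct("no_match") if method == "best_close_match" else 0.0,
        method=method,
        threshold=threshold,
        n_unmatchable=n_unmatchable,
    )


def discriminate_all(
    alignment: AlignedMatrix,
    model: str = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    method: str = "best_close_match",
    percentile: float = 95.0,
) -> DiscriminationReport:
    """End-to-end: distance matrix + leave-one-out discrimination."""
    label_map = {r.id: r.species for r in alignment.records}
    unlabeled = [i for i, s in label_map.items() if not s]
    if unlabeled:
        raise ValueError(f"unlabeled sequences: {unlabeled}")
    matrix = pairwise_matrix(alignment, model=model, min_overlap=min_overlap)
    return discriminate_matrix(
        matrix, label_map, method=method, percentile=percentile
    )
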