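"""Tracing clonal relatives of expressed monoclonal antibody sequences.

Given the heavy chain of an in vitro characterized monoclonal antibody,
find every clonally related sequence in a target repertoire: records
sharing a V gene, a J gene and the junction length are pre-filtered into
a mini-repertoire, the query is appended, and clonal clustering groups
the relatives around it.  The distance threshold is detected on the full
target repertoire unless supplied.  The pre-filter is an exact
optimization: clustering partitions on V/J/length anyway, so the
mini-repertoire shortcut returns the identical member set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .airr_io import Rearrangement, Repertoire
from .clonal_clustering import (
    define_clones,
    detect_threshold,
    gene_set,
    nearest_neighbor_distances,
)

logger = logging.getLogger(__name__)

__all__ = ["QueryClone", "TraceResult", "trace_relatives", "summarize_descendants"]

_QUERY_ID_PREFIX = "__query__"


@dataclass
class QueryClone:
    """One expressed monoclonal heavy chain to trace."""

    query_id: str
    rearrangement: Rearrangement
    polyreactive: bool | None = None

    def __post_init__(self):
        r = self.rearrangement
        if not r.junction:
            raise ValueError(f"query {self.query_id}: junction required")
        if not r.v_call or not r.j_call:
            raise ValueError(f"query {self.query_id}: v_call and j_call required")


@dataclass
class TraceResult:
    """Relatives of one query with their compartmental distribution."""

    query_id: str
    threshold: float
    threshold_method: str = ""
    members: list[Rearrangement] = field(default_factory=list)
    #: sequence_ids grouped by (compartment, timepoint)
    by_compartment: dict = field(default_factory=dict)
    #: number of distinct relative sequences per compartment
    descendant_count: dict = field(default_factory=dict)
    #: matched copies / total repertoire copies per compartment
    contribution: dict = field(default_factory=dict)

    @property
    def n_descendants(self) -> int:
        return len(self.members)


def trace_relatives(
    query: QueryClone,
    rep: Repertoire,
    tau: float | None = None,
    **threshold_kwargs,
) -> TraceResult:
    """Recover all clonal relatives of a query in a corrected repertoire.

    When ``tau`` is None, the threshold is detected on the full
    repertoire's nearest-neighbor distance distribution; a fallback there
    is propagated through ``threshold_method``.
    """
    method = "manual"
    if tau is None:
        profile = detect_threshold(nearest_neighbor_distances(rep), **threshold_kwargs)
        tau = profile.threshold
        method = profile.method

    q = query.rearrangement
    qv, qj = gene_set(q.v_call), gene_set(q.j_call)
    mini = [
        r
        for r in rep.records
        if r.junction_length == q.junction_length
        and gene_set(r.v_call) & qv
        and gene_set(r.j_call) & qj
    ]
    result = TraceResult(query_id=query.query_id, threshold=tau, threshold_method=method)
    if not mini:
        return result

    # the query is not a repertoire observation: unit copies, excluded later
    qrec = q.copy(sequence_id=f"{_QUERY_ID_PREFIX}{query.query_id}", duplicate_count=1)
    combined = Repertoire(records=mini + [qrec])
    clones = define_clones(combined, tau)
    for clone in clones:
        if qrec.sequence_id in clone.sequence_ids:
            result.members = [m for m in clone.members if m.sequence_id != qrec.sequence_id]
            break

    totals: dict[str, int] = {}
    for r in rep.records:
        totals[r.compartment] = totals.get(r.compartment, 0) + r.duplicate_count
    matched: dict[str, int] = {}
    for m in result.members:
        key = (m.compartment, m.timepoint)
        result.by_compartment.setdefault(key, []).append(m.sequence_id)
        result.descendant_count[m.compartment] = (
            result.descendant_count.get(m.compartment, 0) + 1
        )
        matched[m.compartment] = matched.get(m.compartment, 0) + m.duplicate_count
    result.contribution = {
        comp: matched.get(comp, 0) / totals[comp] for comp in totals
    }
    return result


def summarize_descendants(results: list[TraceResult]) -> dict:
    """Summary across queries traced against one repertoire set.

    Reports the number of queries with at least one descendant, the
    per-query per-compartment contribution fractions, and flags queries
    whose descendants appear at two or more timepoints as persistent.
    """
    with_hits = [r for r in results if r.n_descendants > 0]
    per_query = {}
    for r in results:
        timepoints = sorted({tp for (_, tp) in r.by_compartment})
        per_query[r.query_id] = {
            "n_descendants": r.n_descendants,
            "contribution": dict(r.contribution),
            "descendant_count": dict(r.descendant_count),
            "timepoints": timepoints,
            "persistent": len(timepoints) >= 2,
        }
    return {
        "n_queries": len(results),
        "n_queries_with_descendants": len(with_hits),
        "queries": per_query,
    }
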