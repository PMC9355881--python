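"""Copy-number-based error correction of bulk BCR repertoires.

Reverse transcription, PCR and sequencing introduce low-copy artefact
reads that sit within one substitution of a genuine, abundant sequence.
The correction used here: collapse identical sequences summing copies,
split the pool at a copy threshold (default 5), merge each low-copy read
into its closest high-copy neighbor when the Hamming distance is at most
one, and discard unmatched low-copy reads together with non-functional
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

from .airr_io import Rearrangement, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionParams",
    "CorrectionReport",
    "collapse_identical",
    "merge_low_copy",
    "correct_repertoire",
    "hamming",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Knobs of the correction step.

    copy_threshold
        Reads with fewer copies than this form the low-copy pool
        (default 5).
    max_merge_distance
        Largest Hamming distance at which a low-copy read is absorbed by
        a high-copy sequence (default 1).
    drop_nonproductive
        Remove out-of-frame / stop-containing rearrangements at the end
        (default True).
    """

    copy_threshold: int = 5
    max_merge_distance: int = 1
    drop_nonproductive: bool = True

    def __post_init__(self):
        if self.copy_threshold < 1:
            raise ValueError("copy_threshold must be >= 1")
        if self.max_merge_distance < 0:
            raise ValueError("max_merge_distance must be >= 0")


@dataclass
class CorrectionReport:
    """Audit trail of a correction run.  Copies are conserved:
    ``copies_in == copies_out + copies_discarded``."""

    n_input: int = 0
    n_collapsed: int = 0
    n_high: int = 0
    n_low: int = 0
    n_merged: int = 0
    n_discarded_low: int = 0
    n_dropped_nonproductive: int = 0
    copies_in: int = 0
    copies_out: int = 0
    copies_discarded: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def hamming(a: str, b: str) -> int | None:
    """Hamming distance over gapped alignment strings.

    Positions where either string carries N are ignored (D-masked
    germlines and ambiguity codes must not inflate distances).  Unequal
    lengths are incomparable and return None.
    """
    if len(a) != len(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def collapse_identical(rep: Repertoire) -> Repertoire:
    """Collapse records with identical ``sequence_alignment`` into one
    unique record each, summing their copy numbers.

    The representative is the merged record with the highest input
    duplicate_count (ties: lexicographically smallest sequence_id).
    Input order of first appearance is preserved.
    """
    groups: dict[str, list[Rearrangement]] = {}
    order: list[str] = []
    for r in rep.records:
        key = r.sequence_alignment
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    out: list[Rearrangement] = []
    for key in order:
        members = groups[key]
        rep_rec = min(members, key=lambda r: (-r.duplicate_count, r.sequence_id))
        total = sum(r.duplicate_count for r in members)
        out.append(rep_rec.copy(duplicate_count=total))
    res = Repertoire(records=out, donor_id=rep.donor_id,
                     compartment=rep.compartment, timepoint=rep.timepoint)
    return res


def merge_low_copy(
    rep: Repertoire, params: CorrectionParams = CorrectionParams()
) -> tuple[Repertoire, CorrectionReport]:
    """Absorb low-copy reads into Hamming-neighboring high-copy sequences.

    Every read with ``duplicate_count < copy_threshold`` is compared to
    every high-copy sequence of equal alignment length; if its distance
    to the closest one is at most ``max_merge_distance`` its copies are
    added there, otherwise it is discarded.  The high/low split uses
    pre-merge copy counts only — a low-copy read can never be promoted
    by receiving merges.

    Tie-break among equally close high-copy candidates: highest
    duplicate_count, then lexicographically smallest alignment string.
    """
    report = CorrectionReport(n_input=len(rep.records),
                              copies_in=rep.total_copies())
    high = [r for r in rep.records if r.duplicate_count >= params.copy_threshold]
    low = [r for r in rep.records if r.duplicate_count < params.copy_threshold]
    report.n_high = len(high)
    report.n_low = len(low)

    if low and not high:
        logger.warning("empty high-copy pool: discarding all %d low-copy reads", len(low))

    # group highs by alignment length; Hamming is only defined there
    by_len: dict[int, list[int]] = {}
    for idx, r in enumerate(high):
        by_len.setdefault(len(r.sequence_alignment), []).append(idx)

    added = [0] * len(high)
    for r in low:
        candidates = by_len.get(len(r.sequence_alignment), ())
        best: tuple[int, int, str] | None = None  # (distance, -copies, alignment)
        best_idx = -1
        for idx in candidates:
            h = high[idx]
            d = hamming(r.sequence_alignment, h.sequence_alignment)
            if d is None or d > params.max_merge_distance:
                continue
            key = (d, -h.duplicate_count, h.sequence_alignment)
            if best is None or key < best:
                best = key
                best_idx = idx
        if best is None:
            report.n_discarded_low += 1
            report.copies_discarded += r.duplicate_count
        else:
            added[best_idx] += r.duplicate_count
            report.n_merged += 1

    out = [
        h.copy(duplicate_count=h.duplicate_count + extra) if extra else h
        for h, extra in zip(high, added)
    ]
    res = Repertoire(records=out, donor_id=rep.donor_id,
                     compartment=rep.compartment, timepoint=rep.timepoint)
    report.copies_out = res.total_copies()
    return res, report


def correct_repertoire(
    rep: Repertoire, params: CorrectionParams = CorrectionParams()
) -> tuple[Repertoire, CorrectionReport]:
    """Full correction pipeline: collapse identical sequences, merge
    low-copy reads, drop non-functional sequences.

    The report aggregates all stages and preserves copy conservation
    (non-productive copies count as discarded).
    """
    n_input = len(rep.records)
    copies_in = rep.total_copies()

    collapsed = collapse_identical(rep)
    merged, report = merge_low_copy(collapsed, params)
    report.n_input = n_input
    report.copies_in = copies_in
    report.n_collapsed = n_input - len(collapsed.records)

    if params.drop_nonproductive:
        kept = [r for r in merged.records if r.productive]
        dropped = [r for r in merged.records if not r.productive]
        report.n_dropped_nonproductive = len(dropped)
        report.copies_discarded += sum(r.duplicate_count for r in dropped)
        merged = Repertoire(records=kept, donor_id=rep.donor_id,
                            compartment=rep.compartment, timepoint=rep.timepoint)

    report.copies_out = merged.total_copies()
    return merged, report
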