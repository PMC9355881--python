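"""Reading, writing and validation of AIRR Rearrangement TSV files.

Field names follow the AIRR Rearrangement schema verbatim; the project's
metadata (``donor_id``, ``compartment``, ``timepoint``) travel as extra
columns with exactly those names so files stay interoperable with
community tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Rearrangement",
    "Repertoire",
    "read_rearrangements",
    "write_rearrangements",
    "validate_records",
]

#: columns written for every repertoire, in this order
AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_length",
    "productive",
    "duplicate_count",
    "sequence_alignment",
    "germline_alignment",
    "c_call",
    "donor_id",
    "compartment",
    "timepoint",
    "clone_id",
]

ALIGNMENT_ALPHABET = set("ACGTN.")

ISOTYPES = {
    "IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHG4",
    "IGHA1", "IGHA2", "IGHE", "unknown",
}


@dataclass
class Rearrangement:
    """One annotated heavy-chain sequence observation.

    ``sequence_alignment`` and ``germline_alignment`` are IMGT-gapped
    nucleotide strings restricted to the CDR1–FWR4 analysis region; the
    germline carries the D segment masked with N.  Alignment coordinates
    used elsewhere in the package are 1-based inclusive over the gapped
    string, matching IMGT numbering.
    """

    sequence_id: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    junction: str = ""
    junction_length: int = 0
    productive: bool = True
    duplicate_count: int = 1
    sequence_alignment: str = ""
    germline_alignment: str = ""
    c_call: str = "unknown"
    donor_id: str = ""
    compartment: str = "other"
    timepoint: int = 0
    clone_id: str = ""

    def copy(self, **changes) -> "Rearrangement":
        d = asdict(self)
        d.update(changes)
        return Rearrangement(**d)


@dataclass
class Repertoire:
    """Ordered collection of rearrangements with a (donor, compartment,
    timepoint) label."""

    records: list[Rearrangement] = field(default_factory=list)
    donor_id: str = ""
    compartment: str = ""
    timepoint: int = 0

    @property
    def label(self) -> tuple[str, str, int]:
        return (self.donor_id, self.compartment, self.timepoint)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Rearrangement]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def total_copies(self) -> int:
        return sum(r.duplicate_count for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
        # AIRR serializes booleans as T/F
        df["productive"] = df["productive"].map({True: "T", False: "F"})
        return df


_BOOL_MAP = {
    "T": True, "TRUE": True, "True": True, "true": True, "1": True,
    "F": False, "FALSE": False, "False": False, "false": False, "0": False,
}


def _parse_bool(value, row: int, col: str) -> bool:
    s = str(value).strip()
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"row {row}: unparseable boolean in {col!r}: {value!r}")


def _parse_int(value, row: int, col: str, default=None) -> int:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        if default is not None:
            return default
        raise ValueError(f"row {row}: missing integer in {col!r}")
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: unparseable integer in {col!r}: {value!r}") from None


def read_rearrangements(
    path: str | Path,
    required_fields: Sequence[str] = ("sequence_id", "v_call", "j_call", "junction"),
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Missing ``duplicate_count`` defaults to 1 (a sequence observed once);
    missing ``c_call`` defaults to ``unknown``.  Row order is preserved.

    Raises
    ------
    ValueError
        If a required field is absent from the header, or an integer or
        boolean cell cannot be parsed (the message carries the row number).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for f in required_fields:
        if f not in df.columns:
            raise ValueError(f"missing field: {f}")

    records: list[Rearrangement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()

        def get(col: str, default: str = "") -> str:
            v = row.get(col, default)
            return default if v == "" else v

        records.append(
            Rearrangement(
                sequence_id=get("sequence_id"),
                v_call=get("v_call"),
                d_call=get("d_call"),
                j_call=get("j_call"),
                junction=get("junction"),
                junction_length=_parse_int(get("junction_length", ""), i, "junction_length", default=len(get("junction"))),
                productive=_parse_bool(get("productive", "T"), i, "productive"),
                duplicate_count=_parse_int(get("duplicate_count", ""), i, "duplicate_count", default=1),
                sequence_alignment=get("sequence_alignment"),
                germline_alignment=get("germline_alignment"),
                c_call=get("c_call", "unknown") or "unknown",
                donor_id=get("donor_id"),
                compartment=get("compartment", "other") or "other",
                timepoint=_parse_int(get("timepoint", ""), i, "timepoint", default=0),
                clone_id=get("clone_id"),
            )
        )

    rep = Repertoire(records=records)
    if records:
        rep.donor_id = records[0].donor_id
        rep.compartment = records[0].compartment
        rep.timepoint = records[0].timepoint
    return rep


def write_rearrangements(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (UTF-8, header row).

    Round-trips bit-exactly through :func:`read_rearrangements` on every
    field, including ambiguous comma-separated gene calls.
    """
    df = rep.to_frame()
    df.to_csv(path, sep="\t", index=False)


def validate_records(rep: Repertoire) -> list[dict]:
    """Check type invariants; return a list of violations (empty = valid).

    Each violation is a dict with ``sequence_id`` and ``rule`` keys.
    Reporting, not raising: callers decide severity.
    """
    violations: list[dict] = []
    seen: set[str] = set()

    def flag(sid: str, rule: str) -> None:
        violations.append({"sequence_id": sid, "rule": rule})

    for r in rep.records:
        if r.sequence_id in seen:
            flag(r.sequence_id, "duplicate sequence_id")
        seen.add(r.sequence_id)
        if r.junction_length != len(r.junction):
            flag(r.sequence_id, "junction_length mismatch")
        if r.duplicate_count < 1:
            flag(r.sequence_id, "duplicate_count < 1")
        if r.sequence_alignment and r.germline_alignment:
            if len(r.sequence_alignment) != len(r.germline_alignment):
                flag(r.sequence_id, "alignment length mismatch")
        for name, aln in (("sequence_alignment", r.sequence_alignment),
                          ("germline_alignment", r.germline_alignment)):
            bad = set(aln) - ALIGNMENT_ALPHABET
            if bad:
                flag(r.sequence_id, f"{name} has characters outside ACGTN.: {sorted(bad)}")
    return violations


def concat_repertoires(reps: Iterable[Repertoire]) -> Repertoire:
    """Pool several repertoires into one (label cleared)."""
    out = Repertoire()
    for rep in reps:
        out.records.extend(rep.records)
    return out
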