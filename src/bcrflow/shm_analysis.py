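"""Somatic hypermutation quantification against clonal germlines.

Mutations are counted over the V region (IMGT gapped positions 1–312,
through FR3; the junction is clone-defining, not a mutation track),
split by IMGT region and replacement/silent status, and profiled for
AID-hotspot (WRCY/RGYW) context and a 5-mer mutability model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .airr_io import Rearrangement, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "MutationProfile",
    "MutabilityModel",
    "IMGT_REGIONS",
    "count_mutations",
    "region_rs_profile",
    "hotspot_fraction",
    "is_hotspot_context",
    "build_mutability_model",
]

#: IMGT region boundaries on the gapped alignment, 1-based inclusive
IMGT_REGIONS = {
    "FR1": (1, 78),
    "CDR1": (79, 114),
    "FR2": (115, 165),
    "CDR2": (166, 195),
    "FR3": (196, 312),
}

V_REGION_END = 312

BASES = set("ACGT")

CODON_TABLE = {}


def _init_codon_table():
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_init_codon_table()


@dataclass
class MutationProfile:
    """Mutation counts for one sequence: totals over the V region and a
    region-by-type split."""

    sequence_id: str
    n_mutations: int = 0
    n_informative_positions: int = 0
    frequency: float = float("nan")
    by_region_type: dict = field(default_factory=dict)  # (region, type) -> count
    skipped_codons: int = 0
    flagged: bool = False

    def region_total(self, region: str) -> int:
        return sum(v for (r, _), v in self.by_region_type.items() if r == region)


@dataclass
class MutabilityModel:
    """Normalized per-5-mer mutability with AID-hotspot flags."""

    mutability: dict  # 5-mer -> probability
    observed: dict  # 5-mer -> mutation count at center
    background: dict  # 5-mer -> occurrences across germlines
    n_mutations: int


def _region_of(pos1: int) -> str | None:
    for name, (a, b) in IMGT_REGIONS.items():
        if a <= pos1 <= b:
            return name
    return None


def count_mutations(seq: Rearrangement) -> MutationProfile:
    """Count V-region point mutations of a sequence against its germline.

    A mutation is a position (gapped 1..312) where both bases are in
    {A,C,G,T} and differ; positions with N or '.' in either string are
    excluded from the informative count.
    """
    prof = MutationProfile(sequence_id=seq.sequence_id)
    s, g = seq.sequence_alignment, seq.germline_alignment
    end = min(len(s), len(g), V_REGION_END)
    informative = 0
    muts = 0
    for i in range(end):
        a, b = s[i], g[i]
        if a in BASES and b in BASES:
            informative += 1
            if a != b:
                muts += 1
    prof.n_mutations = muts
    prof.n_informative_positions = informative
    if informative == 0:
        prof.flagged = True
        logger.warning("sequence %s has no informative V positions", seq.sequence_id)
    else:
        prof.frequency = muts / informative
    return prof


def region_rs_profile(seq: Rearrangement) -> MutationProfile:
    """Full region x replacement/silent mutation profile.

    Each mutation is evaluated independently against the germline codon
    background: the germline codon is translated with and without the
    single mutation; an amino-acid change makes it a replacement,
    otherwise silent.  Codons containing gaps or N are skipped and
    tallied.
    """
    prof = count_mutations(seq)
    s, g = seq.sequence_alignment, seq.germline_alignment
    end = min(len(s), len(g), V_REGION_END)
    counts: dict = {}
    skipped = 0
    for codon_start in range(0, end - 2, 3):
        gc = g[codon_start : codon_start + 3]
        sc = s[codon_start : codon_start + 3]
        mut_offsets = [
            k
            for k in range(3)
            if sc[k] in BASES and gc[k] in BASES and sc[k] != gc[k]
        ]
        if not mut_offsets:
            continue
        if any(c not in BASES for c in gc):
            skipped += 1
            continue
        aa_germ = CODON_TABLE[gc]
        for k in mut_offsets:
            mutated = gc[:k] + sc[k] + gc[k + 1 :]
            aa_mut = CODON_TABLE[mutated]
            mtype = "replacement" if aa_mut != aa_germ else "silent"
            region = _region_of(codon_start + k + 1)
            if region is None:
                continue
            counts[(region, mtype)] = counts.get((region, mtype), 0) + 1
    prof.by_region_type = counts
    prof.skipped_codons = skipped
    return prof


def _ungapped_with_map(g: str):
    """Ungapped V-region germline and a gapped-index -> ungapped-index map.

    Restricted to the V region so junction and FR4 bases never enter
    motif contexts or 5-mer backgrounds.
    """
    ug = []
    gap_to_ung = {}
    for i, c in enumerate(g[:V_REGION_END]):
        if c != ".":
            gap_to_ung[i] = len(ug)
            ug.append(c)
    return "".join(ug), gap_to_ung


_W = set("AT")
_R = set("AG")
_Y = set("CT")


def is_hotspot_context(germline: str, pos: int) -> bool | None:
    """Whether the ungapped germline position sits in a WRCY C or RGYW G.

    Returns None when the motif window around the position is incomplete.
    """
    c = germline[pos]
    if c == "C":
        # W R C Y with the mutation at C (needs pos-2 .. pos+1)
        if pos - 2 < 0 or pos + 1 >= len(germline):
            return None
        return (
            germline[pos - 2] in _W
            and germline[pos - 1] in _R
            and germline[pos + 1] in _Y
        )
    if c == "G":
        # R G Y W with the mutation at G (needs pos-1 .. pos+2)
        if pos - 1 < 0 or pos + 2 >= len(germline):
            return None
        return (
            germline[pos - 1] in _R
            and germline[pos + 1] in _Y
            and germline[pos + 2] in _W
        )
    return False


def hotspot_fraction(rep: Repertoire) -> tuple[float, list[dict]]:
    """Fraction of V-region mutations falling in AID WRCY/RGYW hotspots.

    Contexts are computed on the ungapped germline (AID targets the
    pre-mutation motif).  Mutations whose context window runs past the
    sequence ends are excluded from the denominator.
    """
    n_hot = 0
    n_eval = 0
    flags: list[dict] = []
    for r in rep.records:
        s, g = r.sequence_alignment, r.germline_alignment
        if not g:
            continue
        ug, gmap = _ungapped_with_map(g)
        end = min(len(s), len(g), V_REGION_END)
        for i in range(end):
            if s[i] in BASES and g[i] in BASES and s[i] != g[i]:
                hot = is_hotspot_context(ug, gmap[i])
                if hot is None:
                    continue
                n_eval += 1
                n_hot += int(hot)
                flags.append(
                    {"sequence_id": r.sequence_id, "position": i + 1, "hotspot": hot}
                )
    frac = n_hot / n_eval if n_eval else float("nan")
    return frac, flags


def build_mutability_model(rep: Repertoire, min_mutations: int = 50) -> MutabilityModel:
    """Estimate a 5-mer mutability model from observed mutations.

    For every V-region mutation the germline-centered 5-mer is counted;
    the background is the number of occurrences of each 5-mer across the
    ungapped germlines; mutability is count/background normalized to sum
    to 1 over 5-mers with nonzero background.

    Raises
    ------
    ValueError
        If fewer than ``min_mutations`` mutations are available — pool
        repertoires before modelling.
    """
    observed: dict[str, int] = {}
    background: dict[str, int] = {}
    n_mut = 0
    for r in rep.records:
        s, g = r.sequence_alignment, r.germline_alignment
        if not g:
            continue
        ug, gmap = _ungapped_with_map(g)
        for start in range(len(ug) - 4):
            k = ug[start : start + 5]
            if set(k) <= BASES:
                background[k] = background.get(k, 0) + 1
        end = min(len(s), len(g), V_REGION_END)
        for i in range(end):
            if s[i] in BASES and g[i] in BASES and s[i] != g[i]:
                p = gmap[i]
                if p - 2 < 0 or p + 2 >= len(ug):
                    continue
                k = ug[p - 2 : p + 3]
                if set(k) <= BASES:
                    observed[k] = observed.get(k, 0) + 1
                    n_mut += 1
    if n_mut < min_mutations:
        raise ValueError(
            f"only {n_mut} usable mutations (< {min_mutations}); pool repertoires"
        )
    raw = {
        k: observed.get(k, 0) / background[k]
        for k in background
        if background[k] > 0
    }
    total = sum(raw.values())
    mutability = {k: v / total for k, v in raw.items()} if total else raw
    return MutabilityModel(
        mutability=mutability, observed=observed, background=background, n_mutations=n_mut
    )


def model_hotspot_flags(model: MutabilityModel) -> dict[str, bool]:
    """Hotspot flag per 5-mer of a mutability model (center C in WRCY or
    center G in RGYW)."""
    flags = {}
    for k in model.mutability:
        flags[k] = bool(is_hotspot_context(k, 2))
    return flags
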