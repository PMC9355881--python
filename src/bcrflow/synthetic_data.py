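"""Synthetic AIRR repertoires and ELISA panels with known ground truth.

The generator emulates the statistical structure the analysis assumes:
clonal lineages sharing V/J/junction length whose members diverge by
hotspot-biased point mutations, heavy-tailed copy numbers, low-copy
sequencing-error satellites at Hamming distance 1 from true sequences,
irreversible isotype switching along lineage edges, and lineage sharing
across sorted B cell compartments and timepoints.  It does not emulate
V(D)J recombination machinery, indels, or allele-level variation: all
distances in the analysis are Hamming distances over substitutions.

A toy germline reference is bundled (deterministically generated
synthetic sequences carrying real IMGT-style gene labels such as
IGHV4-34 and IGHJ1..6) so no external database is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .airr_io import Rearrangement, Repertoire
from .reactivity import ANTIGENS, CONCENTRATIONS, HEP2_CONCENTRATION, ElisaPanel
from .shm_analysis import V_REGION_END, is_hotspot_context

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "GermlineReference",
    "builtin_reference",
    "simulate_lineage",
    "inject_errors",
    "generate_repertoires",
    "simulate_elisa",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
FR4_LENGTH = 33
COMPARTMENTS = ("CD38int", "CD38neg", "CD27pos")
SWITCHED_CLASSES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE")
JUNCTION_LENGTHS = (36, 45, 48, 51, 54, 60)

#: fixed seed of the bundled reference — part of the reference, not a knob
_REFERENCE_SEED = 20190427


@dataclass(frozen=True)
class GermlineReference:
    """Toy germline set: V genes are gapped-length-312 nucleotide strings,
    J genes contribute the FR4 tail."""

    v_genes: dict
    j_genes: dict


@lru_cache(maxsize=1)
def builtin_reference() -> GermlineReference:
    rng = np.random.default_rng(_REFERENCE_SEED)
    v_names = [
        "IGHV1-2", "IGHV1-46", "IGHV1-69", "IGHV2-5", "IGHV3-7", "IGHV3-23",
        "IGHV3-30", "IGHV3-48", "IGHV4-34", "IGHV4-59", "IGHV5-51", "IGHV6-1",
    ]
    j_names = [f"IGHJ{i}" for i in range(1, 7)]
    v_genes = {
        name: "".join(rng.choice(list("ACGT"), size=V_REGION_END))
        for name in v_names
    }
    j_genes = {
        name: "".join(rng.choice(list("ACGT"), size=FR4_LENGTH))
        for name in j_names
    }
    return GermlineReference(v_genes=v_genes, j_genes=j_genes)


@dataclass
class SimConfig:
    """Study conditions of the synthetic repertoires.

    Defaults describe an antigen-experienced repertoire with clonal
    expansion: geometric lineage sizes (mean 3), per-site SHM rate 0.02,
    fivefold AID-hotspot bias, Zipf copy numbers on top of a floor of 5
    copies per true sequence, error satellites at roughly one per ten
    true copies with 1–4 copies each, and a 10% chance for a lineage to
    span more than one compartment.
    """

    seed: int = 0
    n_lineages: int = 100
    lineage_size_mean: float = 3.0
    mu: float = 0.02                      # per-site substitution rate per lineage edge
    hotspot_bias: float = 5.0             # multiplier at WRCY/RGYW germline contexts
    zipf_a: float = 2.0                   # copy-number tail exponent
    copy_min: int = 5                     # floor of true-sequence copies
    error_rate: float = 0.1               # expected satellites per true copy / 10
    satellite_copy_max: int = 4
    compartments: tuple = COMPARTMENTS
    sharing_prob: float = 0.1             # lineage spans >1 compartment
    isotype_switch_prob: float = 0.2      # per lineage edge, IgM -> switched
    vh434_fraction: float = 0.1           # lineages forced to IGHV4-34
    timepoints: int = 1
    persistence_prob: float = 0.5         # lineage also present at later timepoints
    junction_divergence: float = 0.05     # max within-lineage normalized junction distance
    nonproductive_fraction: float = 0.0

    def __post_init__(self):
        for name in ("sharing_prob", "isotype_switch_prob", "vh434_fraction",
                     "persistence_prob", "nonproductive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mu >= 0.3:
            logger.warning("per-site SHM rate %.3f approaches saturation", self.mu)


def _mutate(
    rng: np.random.Generator,
    seq: str,
    n: int,
    weights: np.ndarray,
) -> tuple[str, list[int]]:
    """Apply n substitutions at positions drawn with the given weights.

    Returns the mutated string and the 0-based positions used.
    """
    if n == 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    p = weights / weights.sum()
    pos = rng.choice(len(seq), size=min(n, len(seq)), replace=False, p=p)
    for i in pos:
        current = arr[i]
        choices = _BASES[_BASES != current]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), sorted(int(i) for i in pos)


def _hotspot_weights(germline_v: str, bias: float) -> np.ndarray:
    """Per-position mutation weights over the V region: ``bias`` at
    AID-hotspot germline contexts, 1 elsewhere."""
    w = np.ones(len(germline_v))
    for i in range(len(germline_v)):
        if is_hotspot_context(germline_v, i):
            w[i] = bias
    return w


def simulate_lineage(
    config: SimConfig,
    rng: np.random.Generator,
    v_name: str,
    j_name: str,
    junction: str,
    size: int,
    seen: set | None = None,
) -> list[dict]:
    """Grow one clonal lineage as a branching process from the germline.

    Each new member derives from a random earlier member with
    Poisson(mu * 312) fresh V-region substitutions at positions weighted
    by the hotspot bias, plus at most
    floor(junction_divergence * L / 2) junction substitutions relative
    to the founder junction (so pairwise junction divergence stays within
    the configured bound).  IgM may switch irreversibly to a switched
    class along each edge.  Returns member dicts with V sequence,
    junction, isotype and mutation positions.
    """
    ref = builtin_reference()
    germ_v = ref.v_genes[v_name]
    weights = _hotspot_weights(germ_v, config.hotspot_bias)
    L = len(junction)
    max_jmut = int(config.junction_divergence * L / 2)
    if seen is None:
        seen = set()

    members: list[dict] = []
    for k in range(size):
        for _attempt in range(50):
            if k == 0:
                parent_v, parent_iso = germ_v, "IGHM"
                n_new = 0 if _attempt == 0 else int(rng.poisson(config.mu * len(germ_v))) + 1
            else:
                parent = members[int(rng.integers(len(members)))]
                parent_v, parent_iso = parent["v_seq"], parent["isotype"]
                n_new = int(rng.poisson(config.mu * len(germ_v)))
                if _attempt > 0:
                    n_new += 1
            v_seq, _ = _mutate(rng, parent_v, n_new, weights)
            n_jmut = int(rng.integers(0, max_jmut + 1)) if max_jmut else 0
            jseq, _ = _mutate(rng, junction, n_jmut, np.ones(L))
            key = v_seq + jseq
            if key not in seen:
                seen.add(key)
                break
        else:
            continue  # could not produce a fresh sequence; shrink the lineage
        isotype = parent_iso if k else "IGHM"
        if isotype == "IGHM" and rng.random() < config.isotype_switch_prob:
            isotype = str(rng.choice(SWITCHED_CLASSES))
        mut_positions = [
            i + 1 for i in range(len(germ_v)) if v_seq[i] != germ_v[i]
        ]
        members.append(
            {
                "v_seq": v_seq,
                "junction": jseq,
                "isotype": isotype,
                "mutation_positions": mut_positions,
            }
        )
    return members


def inject_errors(
    true_records: list[Rearrangement],
    error_rate: float,
    satellite_copy_max: int,
    rng: np.random.Generator,
    seen: set | None = None,
) -> tuple[list[Rearrangement], list[dict]]:
    """Spawn sequencing-error satellites around true records.

    Each true record spawns Poisson(error_rate * copies / 10) satellites,
    each a single random substitution away (Hamming distance exactly 1)
    with 1..satellite_copy_max copies — below the correction threshold by
    construction.  Satellites colliding with an existing sequence are
    redrawn.
    """
    if seen is None:
        seen = {r.sequence_alignment for r in true_records}
    satellites: list[Rearrangement] = []
    truth: list[dict] = []
    counter = 0
    for parent in true_records:
        n_sat = int(rng.poisson(error_rate * parent.duplicate_count / 10.0))
        for _ in range(n_sat):
            for _attempt in range(20):
                aln = parent.sequence_alignment
                i = int(rng.integers(len(aln)))
                if aln[i] == ".":
                    continue
                base = str(rng.choice([b for b in "ACGT" if b != aln[i]]))
                new_aln = aln[:i] + base + aln[i + 1 :]
                if new_aln not in seen:
                    seen.add(new_aln)
                    break
            else:
                continue
            counter += 1
            jstart = V_REGION_END
            junction = parent.junction
            if jstart <= i < jstart + parent.junction_length:
                junction = new_aln[jstart : jstart + parent.junction_length]
            sat = parent.copy(
                sequence_id=f"{parent.sequence_id}.e{counter}",
                sequence_alignment=new_aln,
                junction=junction,
                duplicate_count=int(rng.integers(1, satellite_copy_max + 1)),
            )
            satellites.append(sat)
            truth.append(
                {
                    "sequence_id": sat.sequence_id,
                    "parent_id": parent.sequence_id,
                    "error_position": i + 1,
                }
            )
    return satellites, truth


def generate_repertoires(
    config: SimConfig,
) -> tuple[dict, pd.DataFrame]:
    """Generate per-(compartment, timepoint) repertoires plus ground truth.

    Returns (repertoires, ground_truth) where ``repertoires`` maps
    (compartment, timepoint) to a :class:`Repertoire` and the ground
    truth table maps every emitted sequence_id to its lineage, true
    sequence, satellite flag, planted mutation positions, compartment,
    timepoint and isotype.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ref = builtin_reference()
    v_names = sorted(ref.v_genes)
    j_names = sorted(ref.j_genes)

    records_by_key: dict[tuple, list[Rearrangement]] = {}
    truth_rows: list[dict] = []
    seen: set[str] = set()
    seq_counter = 0

    n_vh434 = int(round(config.vh434_fraction * config.n_lineages))

    for lineage_idx in range(config.n_lineages):
        lid = f"L{lineage_idx:04d}"
        if lineage_idx < n_vh434:
            v_name = "IGHV4-34"
        else:
            v_name = str(rng.choice(v_names))
        j_name = str(rng.choice(j_names))
        L = int(rng.choice(JUNCTION_LENGTHS))
        inner = "".join(rng.choice(list("ACGT"), size=L - 6))
        junction = "TGT" + inner + "TGG"

        # geometric sizes with the configured mean (support {1, 2, ...})
        p = min(1.0, 1.0 / config.lineage_size_mean)
        size = int(rng.geometric(p))

        members = simulate_lineage(config, rng, v_name, j_name, junction, size, seen=seen)
        if not members:
            continue

        home = str(rng.choice(config.compartments))
        comps = [home]
        if len(config.compartments) > 1 and rng.random() < config.sharing_prob:
            others = [c for c in config.compartments if c != home]
            extra = 1 + int(rng.random() < 0.5 and len(others) > 1)
            comps += [str(c) for c in rng.choice(others, size=extra, replace=False)]
        tps = [0]
        for t in range(1, config.timepoints):
            if rng.random() < config.persistence_prob:
                tps.append(t)

        germ_v = ref.v_genes[v_name]
        fr4 = ref.j_genes[j_name]
        germline_alignment = germ_v + "N" * L + fr4

        for m_idx, m in enumerate(members):
            seq_counter += 1
            # guarantee each declared compartment holds >= 1 member
            if m_idx < len(comps):
                comp = comps[m_idx]
            else:
                comp = str(rng.choice(comps))
            tp = int(rng.choice(tps))
            copies = config.copy_min + min(int(rng.zipf(config.zipf_a)), 10_000) - 1
            productive = bool(rng.random() >= config.nonproductive_fraction)
            rec = Rearrangement(
                sequence_id=f"S{seq_counter:06d}",
                v_call=f"{v_name}*01",
                d_call="IGHD3-10*01",
                j_call=f"{j_name}*01",
                junction=m["junction"],
                junction_length=L,
                productive=productive,
                duplicate_count=copies,
                sequence_alignment=m["v_seq"] + m["junction"] + fr4,
                germline_alignment=germline_alignment,
                c_call=m["isotype"],
                donor_id="sim",
                compartment=comp,
                timepoint=tp,
            )
            records_by_key.setdefault((comp, tp), []).append(rec)
            truth_rows.append(
                {
                    "sequence_id": rec.sequence_id,
                    "lineage_id": lid,
                    "is_error_satellite": False,
                    "parent_id": "",
                    "true_sequence": rec.sequence_alignment,
                    "mutation_positions": ";".join(map(str, m["mutation_positions"])),
                    "compartment": comp,
                    "timepoint": tp,
                    "isotype": m["isotype"],
                    "v_call": rec.v_call,
                }
            )

    # sequencing-error satellites, per (compartment, timepoint) pool
    truth_idx = {row["sequence_id"]: row for row in truth_rows}
    for key, recs in records_by_key.items():
        sats, sat_truth = inject_errors(
            recs, config.error_rate, config.satellite_copy_max, rng, seen=seen
        )
        recs.extend(sats)
        for st in sat_truth:
            parent_row = truth_idx[st["parent_id"]]
            truth_rows.append(
                {
                    "sequence_id": st["sequence_id"],
                    "lineage_id": parent_row["lineage_id"],
                    "is_error_satellite": True,
                    "parent_id": st["parent_id"],
                    "true_sequence": parent_row["true_sequence"],
                    "mutation_positions": "",
                    "compartment": key[0],
                    "timepoint": key[1],
                    "isotype": parent_row["isotype"],
                    "v_call": parent_row["v_call"],
                }
            )

    repertoires = {
        key: Repertoire(records=recs, donor_id="sim", compartment=key[0], timepoint=key[1])
        for key, recs in sorted(records_by_key.items())
    }
    ground_truth = pd.DataFrame(truth_rows)
    return repertoires, ground_truth


def simulate_elisa(
    n_clones: int,
    fraction_polyreactive: float,
    noise_sd: float,
    seed: int,
) -> tuple[ElisaPanel, pd.DataFrame]:
    """Generate an ELISA panel with known polyreactivity labels.

    Two positive controls bracket OD 1.5 at the top concentration, giving
    a positivity threshold near 1.36; positive clone/antigen pairs sit
    about 0.5 above it, negative pairs near 0.2.  Gaussian noise of the
    given sd is added to clone ODs (controls are noise-free by design —
    they define the threshold).  HEp-2 reactivity follows the
    polyreactivity label.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    dilution = {1.0: 1.0, 0.25: 0.7, 0.0625: 0.4, 0.0156: 0.2}

    for ctrl, offset in (("ctrl1", -0.05), ("ctrl2", 0.05)):
        for ag in list(ANTIGENS):
            for conc in CONCENTRATIONS:
                rows.append(
                    {"clone_id": ctrl, "antigen": ag, "concentration": conc,
                     "od": (1.5 + offset) * dilution[conc], "is_control": True}
                )
        rows.append(
            {"clone_id": ctrl, "antigen": "HEp-2",
             "concentration": HEP2_CONCENTRATION,
             "od": 1.5 + offset, "is_control": True}
        )

    truth_rows = []
    n_poly = int(round(fraction_polyreactive * n_clones))
    for i in range(n_clones):
        cid = f"clone{i:03d}"
        poly = i < n_poly
        if poly:
            n_pos = 2 + int(rng.random() < 0.5)
            positive_ags = set(rng.choice(list(ANTIGENS), size=n_pos, replace=False))
        else:
            positive_ags = set()
            if rng.random() < 0.3:
                positive_ags = {str(rng.choice(list(ANTIGENS)))}
        for ag in ANTIGENS:
            top = 1.9 if ag in positive_ags else 0.2
            for conc in CONCENTRATIONS:
                od = top * dilution[conc] + rng.normal(0.0, noise_sd)
                rows.append(
                    {"clone_id": cid, "antigen": ag, "concentration": conc,
                     "od": max(od, 0.0), "is_control": False}
                )
        hep2 = poly
        rows.append(
            {"clone_id": cid, "antigen": "HEp-2",
             "concentration": HEP2_CONCENTRATION,
             "od": max((1.9 if hep2 else 0.2) + rng.normal(0.0, noise_sd), 0.0),
             "is_control": False}
        )
        truth_rows.append(
            {"clone_id": cid, "polyreactive": poly,
             "positive_antigens": ";".join(sorted(positive_ags)), "hep2": hep2}
        )

    panel = ElisaPanel(data=pd.DataFrame(rows))
    return panel, pd.DataFrame(truth_rows)
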