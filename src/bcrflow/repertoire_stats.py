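"""Descriptive repertoire statistics: diversity indices, clonal
abundance, gene segment usage and isotype distribution.

Diversity is computed over clone frequencies p_i = clone copies / total
copies by default (copy weighting); clone-level weighting is exposed
because statements about the fraction of clones carrying a particular V
gene are about clones, not reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .airr_io import Rearrangement, Repertoire
from .clonal_clustering import CloneCluster, gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityResult",
    "clone_abundance",
    "diversity_indices",
    "top_clones_cumulative",
    "gene_usage",
    "isotype_distribution",
    "downsample_unique",
    "treemap_table",
]

UNSWITCHED = {"IGHM", "IGHD"}
SWITCHED = {"IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE"}


@dataclass
class DiversityResult:
    """Shannon's H (natural log), Gini–Simpson 1 - sum p_i^2, D50 as a
    percentage of ranked clones, and the unique/total sequence ratio."""

    shannon_H: float
    gini_simpson: float
    d50: float
    unique_total_ratio: float
    n_clones: int
    n_unique_sequences: int
    total_copies: int

    def as_dict(self) -> dict:
        return asdict(self)


def clone_abundance(clones: list[CloneCluster]) -> pd.DataFrame:
    """Per-clone relative frequency table, ranked descending.

    Frequencies are clone_copies over total copies; ties in copies are
    broken by clone_id so the ranking is stable.
    """
    if not clones:
        raise ValueError("no clones")
    total = sum(c.clone_copies for c in clones)
    rows = [
        {
            "clone_id": c.clone_id,
            "v_group": c.v_group,
            "clone_copies": c.clone_copies,
            "clone_size": c.clone_size,
            "frequency": c.clone_copies / total,
        }
        for c in clones
    ]
    df = pd.DataFrame(rows).sort_values(
        ["clone_copies", "clone_id"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def diversity_indices(clones: list[CloneCluster]) -> DiversityResult:
    """Compute Shannon's H, Gini–Simpson and D50 over clone frequencies."""
    ab = clone_abundance(clones)
    p = ab["frequency"].to_numpy()
    H = float(-(p * np.log(p)).sum())
    gini = float(1.0 - (p**2).sum())
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, 0.5 - 1e-12) + 1)
    d50 = 100.0 * k / len(p)
    n_unique = sum(c.clone_size for c in clones)
    total = int(ab["clone_copies"].sum())
    return DiversityResult(
        shannon_H=H,
        gini_simpson=gini,
        d50=d50,
        unique_total_ratio=n_unique / total,
        n_clones=len(clones),
        n_unique_sequences=n_unique,
        total_copies=total,
    )


def top_clones_cumulative(clones: list[CloneCluster], n: int) -> float:
    """Cumulative frequency of the N most abundant clones (all clones if
    fewer than N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ab = clone_abundance(clones)
    return float(ab["frequency"].head(n).sum())


_DISTAL = {
    "heavy": ("IGHJ5", "IGHJ6"),
    "kappa": ("IGKJ4", "IGKJ5"),
    "lambda": ("IGLJ3",),
}


def gene_usage(
    rep: Repertoire,
    segment: str = "V",
    level: str = "gene",
    weighting: str = "copies",
) -> pd.DataFrame:
    """Gene segment usage frequencies.

    Ambiguous multi-gene calls contribute 1/k weight to each of their k
    genes.  ``weighting='clones'`` counts each record once;
    ``'copies'`` weights by duplicate_count.  The result carries an
    attrs entry ``distal_j`` with the aggregate distal-J fractions
    (IGHJ5+IGHJ6, IGKJ4+IGKJ5, IGLJ3) when J usage is requested.
    """
    if segment not in ("V", "D", "J"):
        raise ValueError("segment must be V, D or J")
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    weights: dict[str, float] = {}
    for r in rep.records:
        call = getattr(r, col)
        genes = sorted(gene_set(call, level=level))
        if not genes:
            continue
        w = (r.duplicate_count if weighting == "copies" else 1) / len(genes)
        for g in genes:
            if not g.startswith(("IGH", "IGK", "IGL")):
                logger.info("unrecognized %s segment %r binned as 'other'", segment, g)
                g = "other"
            weights[g] = weights.get(g, 0.0) + w
    total = sum(weights.values())
    if total == 0:
        return pd.DataFrame(columns=["gene", "frequency"])
    df = pd.DataFrame(
        sorted(weights.items()), columns=["gene", "frequency"]
    )
    df["frequency"] /= total
    if segment == "J":
        distal = {
            locus: float(df.loc[df["gene"].isin(genes), "frequency"].sum())
            for locus, genes in _DISTAL.items()
        }
        df.attrs["distal_j"] = distal
    return df


def isotype_distribution(rep: Repertoire, weighting: str = "copies") -> dict:
    """Per-isotype fractions and the switched/unswitched split.

    Fractions sum to 1 over known classes; records with unknown c_call
    are reported separately as ``unknown_fraction``.  Unswitched pools
    IgM with IgD; switched pools IgG, IgA and IgE subclasses.
    """
    known: dict[str, float] = {}
    unknown = 0.0
    for r in rep.records:
        w = r.duplicate_count if weighting == "copies" else 1
        iso = r.c_call if r.c_call in UNSWITCHED | SWITCHED else "unknown"
        if iso == "unknown":
            unknown += w
        else:
            known[iso] = known.get(iso, 0.0) + w
    total_known = sum(known.values())
    fractions = {k: v / total_known for k, v in sorted(known.items())} if total_known else {}
    switched = sum(v for k, v in fractions.items() if k in SWITCHED)
    unswitched = sum(v for k, v in fractions.items() if k in UNSWITCHED)
    total = total_known + unknown
    return {
        "fractions": fractions,
        "switched": switched,
        "unswitched": unswitched,
        "unknown_fraction": unknown / total if total else 0.0,
    }


def downsample_unique(obj, n: int, seed: int):
    """Uniform sample without replacement of n unique sequences (or
    clones), deterministic under the seed.

    If n is at least the population size the input is returned unchanged
    (with a warning when strictly larger).
    """
    rng = np.random.default_rng(seed)
    if isinstance(obj, Repertoire):
        pop = obj.records
    else:
        pop = list(obj)
    if n >= len(pop):
        if n > len(pop):
            logger.warning("requested %d of %d: returning the full population", n, len(pop))
        return obj
    idx = rng.choice(len(pop), size=n, replace=False)
    idx.sort()
    picked = [pop[i] for i in idx]
    if isinstance(obj, Repertoire):
        return Repertoire(records=picked, donor_id=obj.donor_id,
                          compartment=obj.compartment, timepoint=obj.timepoint)
    return picked


def treemap_table(clones: list[CloneCluster], top: int = 2500) -> pd.DataFrame:
    """Table of the most abundant clones grouped by V gene and family,
    suitable as treemap input (clone_id, v_gene, v_family, frequency).

    A pure projection of the abundance table: frequencies are preserved,
    not renormalized over the selection.
    """
    ab = clone_abundance(clones).head(top)
    out = ab[["clone_id", "v_group", "frequency"]].copy()
    out = out.rename(columns={"v_group": "v_gene"})
    out["v_family"] = out["v_gene"].map(
        lambda g: "/".join(sorted({x.split("-")[0] for x in g.split("/")}))
    )
    return out[["clone_id", "v_gene", "v_family", "frequency"]]
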