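"""Clonal clustering of heavy-chain sequences by junction distance.

Clonally related B cells share the V gene, J gene and junction length of
their founding V(D)J recombination event and differ in the junction only
by somatic hypermutation.  Sequences are therefore partitioned by
(V gene set, J gene set, junction length) — ambiguous comma-separated
calls are treated as sets and partitions are unioned transitively when
both gene sets intersect — and single-linkage clustered on
length-normalized junction Hamming distance below a threshold.

The threshold is detected from the distribution of nearest-neighbor
distances: in a repertoire with clonal structure this distribution is
bimodal, with a low mode of within-clone distances and a high mode of
unrelated-sequence distances.  Instead of the local minimum between the
modes, the rule used here takes, after the first peak of the smoothed
histogram, the position of the first non-declining value; this remains
well defined on histograms whose valley never turns upward cleanly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .airr_io import Rearrangement, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceProfile",
    "CloneCluster",
    "gene_set",
    "nearest_neighbor_distances",
    "detect_threshold",
    "threshold_from_smoothed",
    "define_clones",
    "attach_germlines",
]

#: V region occupies IMGT-gapped positions 1..312; the junction block follows
V_REGION_END = 312


@dataclass
class DistanceProfile:
    """Nearest-neighbor distance vector with its histogram, smoothed
    histogram, detected peak and clustering threshold tau."""

    distances: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_width: float = 0.01
    counts: np.ndarray = field(default_factory=lambda: np.array([]))
    smoothed: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_index: int = -1
    threshold: float = float("nan")
    method: str = ""  # first_nondeclining | manual | fallback

    def as_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "peak_index": int(self.peak_index),
            "threshold": float(self.threshold),
            "method": self.method,
            "n_distances": int(len(self.distances)),
            "counts": [int(c) for c in self.counts],
            "smoothed": [float(s) for s in self.smoothed],
        }


@dataclass
class CloneCluster:
    """A clonotype: rearrangements sharing V gene, J gene and junction
    length, chained under the distance threshold."""

    clone_id: str
    sequence_ids: list[str]
    v_group: str
    j_group: str
    junction_length: int
    clone_copies: int
    clone_size: int
    members: list[Rearrangement] = field(default_factory=list, repr=False)


def gene_set(call: str, level: str = "gene") -> frozenset[str]:
    """Parse a possibly ambiguous comma-separated call into a set of
    identifiers at the requested level.

    level 'allele' keeps the call as-is; 'gene' strips the allele suffix
    ('IGHV4-34*01' -> 'IGHV4-34'); 'family' keeps only the family part
    ('IGHV4-34' -> 'IGHV4').
    """
    out = set()
    for part in call.split(","):
        part = part.strip()
        if not part:
            continue
        if level in ("gene", "family"):
            part = part.split("*")[0]
        if level == "family":
            part = part.split("-")[0].split("/")[0]
        out.add(part)
    return frozenset(out)


def _vjl_partitions(records: list[Rearrangement]) -> list[list[int]]:
    """Partition record indices by (V gene set, J gene set, junction
    length) with transitive union on gene-set intersection."""
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_len.setdefault(r.junction_length, []).append(i)

    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    vsets = [gene_set(r.v_call) for r in records]
    jsets = [gene_set(r.j_call) for r in records]

    for idxs in by_len.values():
        # index records of this length by single V gene for near-linear unions
        by_vgene: dict[str, int] = {}
        for i in idxs:
            for g in vsets[i]:
                if g in by_vgene:
                    j = by_vgene[g]
                    if jsets[i] & jsets[j]:
                        union(i, j)
                else:
                    by_vgene[g] = i
        # sharing a V gene alone is not enough: fall back to pairwise check
        # within candidate groups (groups are small in practice)
        for a, b in itertools.combinations(idxs, 2):
            if find(a) == find(b):
                continue
            if vsets[a] & vsets[b] and jsets[a] & jsets[b]:
                union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _junction_matrix(junctions: list[str]) -> np.ndarray:
    """Pairwise normalized Hamming distances among equal-length junctions."""
    arr = np.frombuffer("".join(junctions).encode(), dtype="S1").reshape(
        len(junctions), -1
    )
    L = arr.shape[1]
    neq = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return neq / L


def nearest_neighbor_distances(rep: Repertoire) -> DistanceProfile:
    """Length-normalized Hamming distance from each junction to its
    nearest neighbor within its (V, J, length) partition.

    Sequences alone in their partition contribute no distance.
    """
    records = list(rep.records)
    dists: list[float] = []
    for idxs in _vjl_partitions(records):
        if len(idxs) < 2:
            continue
        junctions = [records[i].junction for i in idxs]
        mat = _junction_matrix(junctions)
        np.fill_diagonal(mat, np.inf)
        dists.extend(mat.min(axis=1).tolist())
    if not dists:
        logger.warning("no partition holds two or more sequences: empty distance vector")
    return DistanceProfile(distances=np.asarray(dists, dtype=float))


def threshold_from_smoothed(smoothed: np.ndarray, bin_width: float) -> tuple[int, float, str]:
    """Apply the first-non-declining rule to a smoothed histogram.

    Returns (peak_index, threshold, method).  The first peak is the first
    bin, after skipping leading zero bins, that is at least as high as
    both neighbors (a dominant first nonzero bin counts as a peak).  The
    threshold is the midpoint of the first later bin whose value does not
    decline relative to its predecessor; the search stops at the last
    nonzero bin so an all-zero tail cannot qualify.  If no peak or no
    non-declining bin exists the method is 'fallback'.
    """
    s = np.asarray(smoothed, dtype=float)
    nz = np.nonzero(s)[0]
    if len(nz) == 0:
        return -1, float("nan"), "fallback"
    start, last = nz[0], nz[-1]

    peak = -1
    if start == 0 and len(s) > 1 and s[0] > s[1]:
        peak = 0  # histogram starts at a local maximum: that is the first peak
    else:
        for i in range(max(start, 1), len(s) - 1):
            if s[i] > 0 and s[i] >= s[i - 1] and s[i] >= s[i + 1]:
                peak = i
                break
    if peak == -1:
        return -1, float("nan"), "fallback"

    for j in range(peak + 1, last + 1):
        if s[j] >= s[j - 1]:
            tau = (j + 0.5) * bin_width
            return peak, tau, "first_nondeclining"
    return peak, float("nan"), "fallback"


def detect_threshold(
    profile: DistanceProfile,
    bin_width: float = 0.01,
    smooth_window: int = 5,
    min_distances: int = 20,
    fallback_threshold: float = 0.1,
) -> DistanceProfile:
    """Detect the clonal clustering threshold from nearest-neighbor
    distances.

    The distances are binned over [0, 1], the histogram smoothed with a
    centered moving average (window shrinks at the edges), and the
    first-non-declining rule applied after the first peak.  When the
    smoothed histogram declines monotonically to its end, the configured
    fallback threshold is used and a warning logged.

    Raises
    ------
    ValueError
        If fewer than ``min_distances`` distances are available.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    d = np.asarray(profile.distances, dtype=float)
    if len(d) < min_distances:
        raise ValueError(
            f"need at least {min_distances} nearest-neighbor distances, got {len(d)}"
        )
    nbins = math.ceil(1.0 / bin_width)
    edges = np.arange(nbins + 1) * bin_width
    edges[-1] = max(edges[-1], 1.0 + 1e-12)  # include distance exactly 1
    counts, _ = np.histogram(np.clip(d, 0.0, 1.0), bins=edges)

    half = smooth_window // 2
    smoothed = np.empty(nbins, dtype=float)
    for i in range(nbins):
        k = min(half, i, nbins - 1 - i)  # shrink the window at the edges
        smoothed[i] = counts[i - k : i + k + 1].mean()

    peak, tau, method = threshold_from_smoothed(smoothed, bin_width)
    if method == "fallback":
        tau = fallback_threshold
        logger.warning(
            "threshold detection fell back to default %.3f (no non-declining bin)",
            fallback_threshold,
        )
    return DistanceProfile(
        distances=d,
        bin_width=bin_width,
        counts=counts,
        smoothed=smoothed,
        peak_index=peak,
        threshold=tau,
        method=method,
    )


def define_clones(rep: Repertoire, tau: float) -> list[CloneCluster]:
    """Group sequences into clonotypes.

    Within each (V gene set, J gene set, junction length) partition,
    single-linkage clustering on length-normalized junction Hamming
    distance links any two sequences joined by a chain of pairwise
    distances <= tau.  Clone ids are deterministic: partition key plus an
    ordinal by descending clone copies (ties by smallest member
    sequence_id).
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    records = list(rep.records)
    raw: list[list[int]] = []
    for idxs in _vjl_partitions(records):
        if len(idxs) == 1:
            raw.append(idxs)
            continue
        junctions = [records[i].junction for i in idxs]
        mat = _junction_matrix(junctions)
        adj = mat <= tau + 1e-12
        # connected components = single linkage at cutoff tau
        n = len(idxs)
        seen = [False] * n
        for s0 in range(n):
            if seen[s0]:
                continue
            comp = []
            stack = [s0]
            seen[s0] = True
            while stack:
                x = stack.pop()
                comp.append(x)
                for y in np.nonzero(adj[x])[0]:
                    if not seen[y]:
                        seen[y] = True
                        stack.append(int(y))
            raw.append([idxs[x] for x in comp])

    clusters: list[CloneCluster] = []
    for idxs in raw:
        members = [records[i] for i in idxs]
        v_group = "/".join(sorted(set().union(*(gene_set(m.v_call) for m in members))))
        j_group = "/".join(sorted(set().union(*(gene_set(m.j_call) for m in members))))
        clusters.append(
            CloneCluster(
                clone_id="",
                sequence_ids=[m.sequence_id for m in members],
                v_group=v_group,
                j_group=j_group,
                junction_length=members[0].junction_length,
                clone_copies=sum(m.duplicate_count for m in members),
                clone_size=len(members),
                members=members,
            )
        )

    clusters.sort(key=lambda c: (-c.clone_copies, min(c.sequence_ids)))
    for rank, c in enumerate(clusters, start=1):
        c.clone_id = f"{c.v_group}_{c.j_group}_{c.junction_length}_{rank}"
        for m in c.members:
            m.clone_id = c.clone_id
    return clusters


def attach_germlines(rep: Repertoire, clones: list[CloneCluster]) -> Repertoire:
    """Attach a per-clone consensus germline to every clone member.

    Per gapped position, the majority germline base across members (ties
    broken alphabetically for determinism); the junction block — gapped
    positions V_REGION_END+1 .. V_REGION_END+junction_length — is masked
    to N, mirroring D-masked germline construction.  Members lacking any
    germline keep an empty germline and are flagged for exclusion from
    mutation analyses.
    """
    for clone in clones:
        germs = [m.germline_alignment for m in clone.members if m.germline_alignment]
        if not germs:
            logger.warning("clone %s has no germline information", clone.clone_id)
            continue
        L = max(len(g) for g in germs)
        germs = [g for g in germs if len(g) == L]
        consensus = []
        for pos in range(L):
            col = [g[pos] for g in germs]
            best = max(sorted(set(col)), key=col.count)
            consensus.append(best)
        jstart = V_REGION_END  # 0-based start of the junction block
        jend = min(jstart + clone.junction_length, L)
        for p in range(jstart, jend):
            consensus[p] = "N"
        cg = "".join(consensus)
        for m in clone.members:
            m.germline_alignment = cg
    return rep
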