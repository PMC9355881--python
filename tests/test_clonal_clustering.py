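"""Nearest-neighbor distances, the first-non-declining threshold rule,
clonotype definition and per-clone germline consensus."""

import numpy as np
import pytest

from bcrflow.airr_io import Repertoire
from bcrflow.clonal_clustering import (
    DistanceProfile,
    attach_germlines,
    define_clones,
    detect_threshold,
    gene_set,
    nearest_neighbor_distances,
    threshold_from_smoothed,
)


def test_gene_set_levels():
    assert gene_set("IGHV4-34*01,IGHV4-59*01") == {"IGHV4-34", "IGHV4-59"}
    assert gene_set("IGHV4-34*01", level="allele") == {"IGHV4-34*01"}
    assert gene_set("IGHV4-34*01", level="family") == {"IGHV4"}


class TestNearestNeighbor:
    def test_simple_pair(self, make_repertoire):
        # two junctions of length 12 differing at 3 positions
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTAAAAAATGG"},
                {"sid": "b", "junction": "TGTCCCAAATGG"},
            ]
        )
        prof = nearest_neighbor_distances(rep)
        assert np.allclose(sorted(prof.distances), [0.25, 0.25])

    def test_identical_junctions_distance_zero(self, make_repertoire):
        rep = make_repertoire(
            [{"sid": "a", "junction": "TGTTGG"}, {"sid": "b", "junction": "TGTTGG"}]
        )
        assert np.allclose(nearest_neighbor_distances(rep).distances, [0.0, 0.0])

    def test_singleton_partitions_contribute_nothing(self, make_repertoire):
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTTGG", "v": "IGHV1-2*01"},
                {"sid": "b", "junction": "TGTTGG", "v": "IGHV3-23*01"},
            ]
        )
        assert len(nearest_neighbor_distances(rep).distances) == 0

    def test_matches_all_pairs_oracle(self, make_rec):
        rng = np.random.default_rng(5)
        L = 12
        junctions = ["".join(rng.choice(list("ACGT"), L)) for _ in range(30)]
        rep = Repertoire(
            records=[make_rec(f"s{i}", junction=j) for i, j in enumerate(junctions)]
        )
        prof = nearest_neighbor_distances(rep)
        expected = []
        for i, a in enumerate(junctions):
            dmin = min(
                sum(x != y for x, y in zip(a, b)) / L
                for j, b in enumerate(junctions)
                if j != i
            )
            expected.append(dmin)
        assert np.allclose(sorted(prof.distances), sorted(expected))


class TestThresholdDetection:
    def test_hand_traced_histogram(self):
        smoothed = np.array([0, 2, 9, 6, 3, 1, 1, 5, 8, 4], dtype=float)
        peak, tau, method = threshold_from_smoothed(smoothed, 0.01)
        assert peak == 2
        assert method == "first_nondeclining"
        assert tau == pytest.approx(0.065, abs=1e-12)

    def test_strictly_declining_falls_back(self):
        # dense smoothly declining distances: no non-declining bin exists
        d = np.repeat(np.arange(10) * 0.01, np.arange(10)[::-1] * 10 + 5)
        prof = detect_threshold(DistanceProfile(distances=d), smooth_window=1)
        assert prof.method == "fallback"
        assert prof.threshold == pytest.approx(0.1)

    def test_too_few_distances_raises(self):
        with pytest.raises(ValueError, match="at least 20"):
            detect_threshold(DistanceProfile(distances=np.array([0.1, 0.2])))

    def test_bimodal_mixture_separates_modes(self):
        L, n = 45, 2000
        rng = np.random.default_rng(2024)
        within = rng.binomial(L, 0.02, n // 2) / L
        between = rng.binomial(L, 0.3, n // 2) / L
        prof = detect_threshold(
            DistanceProfile(distances=np.concatenate([within, between]))
        )
        assert prof.method == "first_nondeclining"
        assert 0.02 < prof.threshold < 0.3
        assert (between < prof.threshold).mean() < 0.01

    def test_tau_at_bin_midpoint(self):
        rng = np.random.default_rng(1)
        d = np.concatenate(
            [rng.binomial(45, 0.02, 500) / 45, rng.binomial(45, 0.3, 500) / 45]
        )
        prof = detect_threshold(DistanceProfile(distances=d), bin_width=0.01)
        # midpoint of a 0.01 bin: two decimals + 0.005
        assert prof.threshold * 100 % 1 == pytest.approx(0.5)


class TestDefineClones:
    def test_identical_junctions_one_clone(self, make_repertoire):
        rep = make_repertoire([{"sid": f"s{i}", "junction": "TGTTGG"} for i in range(4)])
        clones = define_clones(rep, 0.1)
        assert len(clones) == 1
        assert clones[0].clone_size == 4

    def test_single_linkage_chains(self, make_repertoire):
        # d(A,B)=0.1, d(B,C)=0.1, d(A,C)=0.2 at tau=0.1: one clone via B
        rep = make_repertoire(
            [
                {"sid": "A", "junction": "AAAAAAAAAA"},
                {"sid": "B", "junction": "AAAAAAAAAC"},
                {"sid": "C", "junction": "AAAAAAAACC"},
            ]
        )
        clones = define_clones(rep, 0.1)
        assert len(clones) == 1
        assert set(clones[0].sequence_ids) == {"A", "B", "C"}

    def test_disjoint_v_genes_never_cocluster(self, make_repertoire):
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTTGG", "v": "IGHV1-2*01"},
                {"sid": "b", "junction": "TGTTGG", "v": "IGHV3-23*01"},
            ]
        )
        assert len(define_clones(rep, 1.0)) == 2

    def test_ambiguous_calls_union_transitively(self, make_repertoire):
        # a:{V1},{b}:{V1,V2}, c:{V2} -> one partition through b
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTTGG", "v": "IGHV1-2*01"},
                {"sid": "b", "junction": "TGTTGG", "v": "IGHV1-2*01,IGHV3-23*01"},
                {"sid": "c", "junction": "TGTTGG", "v": "IGHV3-23*01"},
            ]
        )
        clones = define_clones(rep, 0.05)
        assert len(clones) == 1

    def test_monotone_in_tau(self, make_rec):
        rng = np.random.default_rng(9)
        recs = [
            make_rec(f"s{i}", junction="".join(rng.choice(list("ACGT"), 12)))
            for i in range(60)
        ]
        rep = Repertoire(records=recs)
        counts = [len(define_clones(rep, t)) for t in (0.05, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_clone_ids(self, make_rec):
        rng = np.random.default_rng(10)
        recs = [
            make_rec(f"s{i}", junction="".join(rng.choice(list("ACGT"), 9)), copies=i + 1)
            for i in range(20)
        ]
        ids1 = {m.sequence_id: m.clone_id for c in define_clones(Repertoire(records=recs), 0.2) for m in c.members}
        recs2 = [r.copy() for r in recs]
        ids2 = {m.sequence_id: m.clone_id for c in define_clones(Repertoire(records=recs2), 0.2) for m in c.members}
        assert ids1 == ids2


class TestAttachGermlines:
    def test_identical_germlines_unchanged_outside_junction(self, make_repertoire):
        germ = "A" * 312 + "NNNNNN" + "G" * 33
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTTGG", "alignment": "A" * 312 + "TGTTGG" + "G" * 33, "germline": germ},
                {"sid": "b", "junction": "TGTTGG", "alignment": "A" * 311 + "C" + "TGTTGG" + "G" * 33, "germline": germ},
            ]
        )
        clones = define_clones(rep, 0.1)
        attach_germlines(rep, clones)
        for r in rep.records:
            assert r.germline_alignment[:312] == "A" * 312
            assert r.germline_alignment[312:318] == "NNNNNN"

    def test_majority_vote_on_disagreement(self, make_repertoire):
        g1 = "A" * 312 + "NNNNNN" + "G" * 33
        g2 = "C" + "A" * 311 + "NNNNNN" + "G" * 33
        aln = "A" * 312 + "TGTTGG" + "G" * 33
        rep = make_repertoire(
            [
                {"sid": "a", "junction": "TGTTGG", "alignment": aln, "germline": g1},
                {"sid": "b", "junction": "TGTTGG", "alignment": aln, "germline": g1},
                {"sid": "c", "junction": "TGTTGG", "alignment": aln, "germline": g2},
            ]
        )
        clones = define_clones(rep, 0.1)
        attach_germlines(rep, clones)
        assert all(r.germline_alignment[0] == "A" for r in rep.records)

    def test_junction_region_masked(self, make_repertoire):
        g = "A" * 312 + "TGTTGG" + "G" * 33  # junction block unmasked on input
        rep = make_repertoire(
            [{"sid": "a", "junction": "TGTTGG", "alignment": g, "germline": g}]
        )
        clones = define_clones(rep, 0.1)
        attach_germlines(rep, clones)
        assert rep.records[0].germline_alignment[312:318] == "N" * 6
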