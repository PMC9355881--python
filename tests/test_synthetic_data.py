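"""Ground-truth guarantees of the repertoire generator: determinism,
satellite geometry, lineage structure and configuration handling."""

import numpy as np
import pytest

from bcrflow.airr_io import Repertoire
from bcrflow.error_correction import hamming
from bcrflow.shm_analysis import V_REGION_END, is_hotspot_context
from bcrflow.synthetic_data import (
    SimConfig,
    builtin_reference,
    generate_repertoires,
    inject_errors,
    simulate_lineage,
)


def flatten(reps):
    return [r for rep in reps.values() for r in rep.records]


class TestReference:
    def test_gene_lengths_and_names(self):
        ref = builtin_reference()
        assert all(len(v) == V_REGION_END for v in ref.v_genes.values())
        assert "IGHV4-34" in ref.v_genes
        assert set(ref.j_genes) == {f"IGHJ{i}" for i in range(1, 7)}

    def test_reference_is_stable(self):
        a, b = builtin_reference(), builtin_reference()
        assert a.v_genes == b.v_genes


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=11, n_lineages=20)
        reps1, truth1 = generate_repertoires(cfg)
        reps2, truth2 = generate_repertoires(SimConfig(seed=11, n_lineages=20))
        assert truth1.equals(truth2)
        r1, r2 = flatten(reps1), flatten(reps2)
        assert [(r.sequence_id, r.sequence_alignment, r.duplicate_count) for r in r1] == [
            (r.sequence_id, r.sequence_alignment, r.duplicate_count) for r in r2
        ]

    def test_different_seeds_differ(self):
        _, t1 = generate_repertoires(SimConfig(seed=1, n_lineages=20))
        _, t2 = generate_repertoires(SimConfig(seed=2, n_lineages=20))
        assert not t1.equals(t2)


class TestLineageStructure:
    def test_founder_is_unmutated_germline(self):
        cfg = SimConfig(seed=0, mu=0.0, junction_divergence=0.0)
        rng = np.random.default_rng(0)
        ref = builtin_reference()
        junction = "TGT" + "A" * 39 + "TGG"
        members = simulate_lineage(cfg, rng, "IGHV1-2", "IGHJ4", junction, size=1)
        assert members[0]["v_seq"] == ref.v_genes["IGHV1-2"]
        assert members[0]["junction"] == junction
        assert members[0]["mutation_positions"] == []
        assert members[0]["isotype"] in {"IGHM"} | set(
            ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE")
        )

    def test_members_unique_within_lineage(self):
        cfg = SimConfig(seed=3, mu=0.01)
        rng = np.random.default_rng(3)
        members = simulate_lineage(
            cfg, rng, "IGHV3-23", "IGHJ6", "TGT" + "C" * 42 + "TGG", size=30
        )
        keys = {m["v_seq"] + m["junction"] for m in members}
        assert len(keys) == len(members)

    def test_mutation_positions_match_sequence_diff(self):
        cfg = SimConfig(seed=7, mu=0.05)
        rng = np.random.default_rng(7)
        germ = builtin_reference().v_genes["IGHV1-69"]
        members = simulate_lineage(
            cfg, rng, "IGHV1-69", "IGHJ2", "TGT" + "G" * 30 + "TGG", size=10
        )
        for m in members:
            diffs = [i + 1 for i in range(len(germ)) if m["v_seq"][i] != germ[i]]
            assert diffs == m["mutation_positions"]

    def test_junction_divergence_bounded(self):
        cfg = SimConfig(seed=9, mu=0.02, junction_divergence=0.05)
        rng = np.random.default_rng(9)
        junction = "TGT" + "A" * 39 + "TGG"  # L = 45, max 1 mutation per member
        members = simulate_lineage(cfg, rng, "IGHV5-51", "IGHJ1", junction, size=20)
        L = len(junction)
        for a in members:
            for b in members:
                d = sum(x != y for x, y in zip(a["junction"], b["junction"])) / L
                assert d <= cfg.junction_divergence + 1e-12

    def test_hotspot_bias_shifts_mutations_to_hotspots(self):
        """With an extreme bias, single-step mutations should land on
        hotspot positions far more often than the hotspot density."""
        germ = builtin_reference().v_genes["IGHV3-30"]
        hot_positions = {
            i for i in range(len(germ)) if is_hotspot_context(germ, i)
        }
        density = len(hot_positions) / len(germ)
        assert 0 < density < 0.5  # sanity: hotspots are a minority
        cfg = SimConfig(seed=1, mu=0.01, hotspot_bias=50.0, junction_divergence=0.0)
        rng = np.random.default_rng(1)
        hits = total = 0
        for _ in range(60):
            members = simulate_lineage(
                cfg, rng, "IGHV3-30", "IGHJ3", "TGT" + "T" * 30 + "TGG", size=4
            )
            for m in members:
                for p in m["mutation_positions"]:
                    total += 1
                    hits += (p - 1) in hot_positions
        assert total > 50
        assert hits / total > 2 * density


class TestSatellites:
    def test_distance_exactly_one_and_low_copy(self, make_repertoire):
        rep = make_repertoire(
            [{"sid": f"t{i}", "alignment": "ACGT" * 80, "copies": 200}
             for i in range(1)]
        )
        rng = np.random.default_rng(2)
        sats, truth = inject_errors(rep.records, 1.0, 4, rng)
        assert len(sats) > 0
        for s in sats:
            assert hamming(s.sequence_alignment, rep.records[0].sequence_alignment) == 1
            assert 1 <= s.duplicate_count <= 4

    def test_zero_rate_yields_none(self, make_repertoire):
        rep = make_repertoire([{"sid": "t", "copies": 500}])
        sats, _ = inject_errors(rep.records, 0.0, 4, np.random.default_rng(0))
        assert sats == []

    def test_generated_satellites_flagged_in_truth(self):
        cfg = SimConfig(seed=6, n_lineages=30, error_rate=1.0)
        reps, truth = generate_repertoires(cfg)
        sats = truth[truth["is_error_satellite"]]
        assert len(sats) > 0
        by_id = {r.sequence_id: r for r in flatten(reps)}
        for _, row in sats.iterrows():
            rec = by_id[row["sequence_id"]]
            assert hamming(rec.sequence_alignment, row["true_sequence"]) == 1
            assert rec.duplicate_count < 5
        # true sequences all carry at least the copy floor
        true_ids = set(truth.loc[~truth["is_error_satellite"], "sequence_id"])
        assert all(by_id[i].duplicate_count >= 5 for i in true_ids)


class TestRepertoires:
    def test_every_record_has_truth_row(self):
        reps, truth = generate_repertoires(SimConfig(seed=4, n_lineages=25))
        ids = {r.sequence_id for r in flatten(reps)}
        assert ids == set(truth["sequence_id"])

    def test_alignments_unique(self):
        reps, _ = generate_repertoires(SimConfig(seed=4, n_lineages=50, error_rate=0.5))
        alns = [r.sequence_alignment for r in flatten(reps)]
        assert len(set(alns)) == len(alns)

    def test_vh434_floor(self):
        _, truth = generate_repertoires(
            SimConfig(seed=8, n_lineages=50, vh434_fraction=0.2)
        )
        lineage_v = truth.loc[~truth["is_error_satellite"]].groupby("lineage_id")[
            "v_call"
        ].first()
        assert (lineage_v == "IGHV4-34*01").sum() >= 10

    def test_lineage_members_share_vjl(self):
        reps, truth = generate_repertoires(SimConfig(seed=10, n_lineages=30))
        by_id = {r.sequence_id: r for r in flatten(reps)}
        for _, grp in truth.groupby("lineage_id"):
            recs = [by_id[i] for i in grp["sequence_id"]]
            assert len({r.v_call for r in recs}) == 1
            assert len({r.j_call for r in recs}) == 1
            assert len({r.junction_length for r in recs}) == 1

    def test_compartments_and_timepoints_partition_records(self):
        reps, _ = generate_repertoires(
            SimConfig(seed=12, n_lineages=30, timepoints=2)
        )
        for (comp, tp), rep in reps.items():
            assert all(r.compartment == comp and r.timepoint == tp for r in rep.records)

    def test_nonproductive_fraction(self):
        reps, truth = generate_repertoires(
            SimConfig(seed=13, n_lineages=200, nonproductive_fraction=0.5)
        )
        true_ids = set(truth.loc[~truth["is_error_satellite"], "sequence_id"])
        flags = [r.productive for r in flatten(reps) if r.sequence_id in true_ids]
        frac = sum(flags) / len(flags)
        assert 0.4 < frac < 0.6

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError, match="sharing_prob"):
            SimConfig(sharing_prob=1.5)
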