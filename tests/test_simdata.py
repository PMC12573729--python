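"""Generator ground-truth contracts: divergence control, read bookkeeping,
host-system scenarios and hit-table fixtures."""

import math

import numpy as np
import pandas as pd
import pytest

from wolbshift import divtime, lociscreen, simdata
from wolbshift.seqio import fasta_string


class TestEvolveStrains:
    def test_zero_distance_gives_identical_sequences(self):
        cfg = simdata.SimStrainConfig(
            seed=1, n_strains=3, target_distances=np.zeros((3, 3))
        )
        genomes, realized = simdata.evolve_strains(cfg)
        assert len({g.sequence for g in genomes}) == 1
        assert (realized.to_numpy() == 0).all()

    def test_realized_distance_tracks_target_with_multiple_hits(self):
        """Expected p-distance under uniform placement with replacement is
        slightly below the target: ~ d(1 - d/2) for small d."""
        target, L = 0.02, 20_000
        cfg = simdata.SimStrainConfig(
            seed=5, genome_length=L, n_strains=2,
            target_distances=np.array([[0, target], [target, 0]]),
        )
        _, realized = simdata.evolve_strains(cfg)
        p = realized.iloc[0, 1]
        expected = target * (1 - target / 2)
        se = math.sqrt(expected * (1 - expected) / L)
        assert abs(p - expected) < 3 * se

    def test_same_seed_gives_byte_identical_fasta(self):
        cfg = dict(seed=42, genome_length=5000, n_strains=3)
        out = []
        for _ in range(2):
            genomes, _ = simdata.evolve_strains(simdata.SimStrainConfig(**cfg))
            out.append(fasta_string([(g.id, g.sequence) for g in genomes]))
        assert out[0] == out[1]

    @pytest.mark.parametrize("bad_d", [0.71, -0.01])
    def test_out_of_range_distances_rejected(self, bad_d):
        with pytest.raises(ValueError):
            simdata.SimStrainConfig(
                seed=0, n_strains=2,
                target_distances=np.array([[0, bad_d], [bad_d, 0]]),
            )

    def test_realized_never_far_exceeds_target(self):
        """Multiple hits only pull realized distances below targets."""
        for seed in range(6):
            target, L = 0.05, 10_000
            cfg = simdata.SimStrainConfig(
                seed=seed, genome_length=L, n_strains=2,
                target_distances=np.array([[0, target], [target, 0]]),
            )
            _, realized = simdata.evolve_strains(cfg)
            se = math.sqrt(target * (1 - target) / L)
            assert realized.iloc[0, 1] <= target + 3 * se


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, strain_pair):
        genomes, _ = strain_pair
        reads = simdata.simulate_reads(
            genomes,
            simdata.SimReadConfig(
                mixture=[("strain_00", 1.0)], coverage=2, error_rate=0.0, seed=3
            ),
        )
        src = genomes[0].sequence
        for r in reads:
            assert src[r.position : r.position + len(r.sequence)] == r.sequence

    def test_read_count_follows_coverage_formula(self, strain_pair):
        genomes, _ = strain_pair
        reads = simdata.simulate_reads(
            genomes,
            simdata.SimReadConfig(
                mixture=[("strain_00", 1.0)], coverage=30, read_length=150, seed=4
            ),
        )
        assert len(reads) == round(30 * 20_000 / 150)  # 4000

    def test_balanced_mixture_counts(self, strain_pair):
        genomes, _ = strain_pair
        reads = simdata.simulate_reads(
            genomes,
            simdata.SimReadConfig(
                mixture=[("strain_00", 0.5), ("strain_01", 0.5)],
                coverage=30,
                seed=5,
            ),
        )
        counts = pd.Series([r.source_strain for r in reads]).value_counts()
        n = len(reads)
        se = math.sqrt(n * 0.25)
        assert abs(counts["strain_00"] - n / 2) < 3 * se
        # conservation: every read carries a truth label
        assert counts.sum() == n

    def test_unknown_mixture_strain_rejected(self, strain_pair):
        genomes, _ = strain_pair
        with pytest.raises(KeyError):
            simdata.simulate_reads(
                genomes,
                simdata.SimReadConfig(mixture=[("nope", 1.0)], seed=0),
            )

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            simdata.SimReadConfig(mixture=[("a", 1.0)], coverage=0)


class TestHostSystem:
    def test_all_uninfected_gives_empty_occurrence(self):
        cfg = simdata.HostSystemConfig(
            n_pairs=4, scenario_weights={"uninfected": 1.0}, seed=2
        )
        host = simdata.simulate_host_system(cfg)
        assert host.occurrence.to_numpy().sum() == 0
        assert all(len(s) == 0 for s in host.strain_sets.values())

    def test_scenario_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simdata.HostSystemConfig(scenario_weights={"uninfected": 0.5})

    def test_codivergence_pair_recovered_by_clock_range(self):
        """End-to-end: the symbiont split range computed from the simulated
        consensus pair contains the true host split in >= 90% of seeds."""
        from wolbshift.experiments import codivergence_recovery

        res = codivergence_recovery(seed=200, n_seeds=20)
        assert res["containment_rate"] >= 0.9

    def test_introgressive_pair_mito_matches_symbiont_clock(self):
        """Under introgression the mitogenome hitchhikes: the mito p-distance
        should match the distance implied by the symbiont split under the
        configured clocks."""
        cfg = simdata.HostSystemConfig(
            n_pairs=1,
            split_time_range=(2e6, 6e6),
            scenario_weights={"introgressive": 1.0},
            seed=31,
        )
        host = simdata.simulate_host_system(cfg)
        row = host.pair_table.iloc[0]
        assert row.mito_split_my < row.split_my
        d_mito = divtime.p_distance(
            host.mito_seqs[row.species_a], host.mito_seqs[row.species_b]
        )
        expected = (cfg.mito_rate / 100.0) * row.mito_split_my
        assert expected > 0
        se = math.sqrt(expected / cfg.mito_genome_length)
        assert abs(d_mito - expected) < max(4 * se, 0.15 * expected)

    def test_loss_pair_leaves_one_species_uninfected(self):
        cfg = simdata.HostSystemConfig(
            n_pairs=3, scenario_weights={"loss": 1.0}, seed=9
        )
        host = simdata.simulate_host_system(cfg)
        for row in host.pair_table.itertuples(index=False):
            assert len(host.strain_sets[row.species_a]) == 1
            assert len(host.strain_sets[row.species_b]) == 0
            assert not row.shares_strain


class TestHitTables:
    def test_single_operon_no_decoys_screens_clean(self):
        plan = simdata.HitTablePlan(genome_id="g1", n_operons=1)
        fx = simdata.simulate_hit_tables(plan, seed=1)
        call = lociscreen.screen_genome(
            "g1", fx.hits, fx.reciprocal, fx.features, fx.family_map
        )
        assert (call.n_cif_operons, call.n_orphan_cifA, call.n_orphan_cifB) == (1, 0, 0)

    def test_weak_evalue_decoy_removed_by_filter(self):
        plan = simdata.HitTablePlan(genome_id="g1", n_operons=0, n_wmk=1,
                                    decoys=("evalue",))
        fx = simdata.simulate_hit_tables(plan, seed=2)
        kept = lociscreen.filter_hits(fx.hits)
        decoy_ids = fx.truth.loc[fx.truth.kind == "decoy", "hit_id"]
        assert not kept["hit_id"].isin(decoy_ids).any()

    def test_wmk_copy_number_bookkeeping(self):
        plan = simdata.HitTablePlan(genome_id="g1", n_operons=0, n_wmk=6)
        fx = simdata.simulate_hit_tables(plan, seed=3)
        call = lociscreen.screen_genome(
            "g1", fx.hits, fx.reciprocal, fx.features, fx.family_map
        )
        assert call.n_wmk == 6
        assert lociscreen.tabulate([call]).iloc[0]["wmk"] == 6

    def test_truth_table_covers_every_hit(self):
        plan = simdata.HitTablePlan(
            genome_id="g1", n_operons=2, n_orphan_cifA=1, n_wmk=2,
            decoys=("evalue", "qcov", "reciprocal", "annotation"),
        )
        fx = simdata.simulate_hit_tables(plan, seed=4)
        assert set(fx.truth.hit_id) == set(fx.hits.hit_id)
        assert (fx.truth.loc[fx.truth.kind == "decoy", "decoy_kind"].notna()).all()
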