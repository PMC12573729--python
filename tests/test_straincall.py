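"""Competitive mapping, coverage statistics and the iterative strain caller."""

import numpy as np
import pytest

from wolbshift import simdata, straincall


def _reads_from(genomes, mixture, coverage=25, error_rate=0.0, seed=0):
    return simdata.simulate_reads(
        genomes,
        simdata.SimReadConfig(
            mixture=mixture, coverage=coverage, error_rate=error_rate, seed=seed
        ),
    )


class TestCompetitiveMap:
    def test_exact_substring_maps_with_zero_edits(self, strain_pair, random_genome):
        genomes, _ = strain_pair
        read = simdata.SimRead("r0", random_genome.sequence[500:650], "", 500)
        alns = straincall.competitive_map([read], [random_genome, genomes[0]])
        assert alns[0].mapped
        assert alns[0].ref_id == "random_bg"
        assert alns[0].ref_start == 500
        assert alns[0].edit_distance == 0

    def test_tie_broken_by_reference_input_order(self, strain_pair):
        genomes, _ = strain_pair
        # a read from a region identical in both references ties; find one
        a, b = genomes[0].sequence, genomes[1].sequence
        start = next(
            i for i in range(0, 19_000) if a[i : i + 150] == b[i : i + 150]
        )
        read = simdata.SimRead("r0", a[start : start + 150], "", start)
        alns = straincall.competitive_map([read], [genomes[1], genomes[0]])
        assert alns[0].ref_id == "strain_01"  # first in input order

    def test_most_reads_assigned_to_true_source(self):
        d = np.array([[0, 0.03], [0.03, 0]])
        genomes, _ = simdata.evolve_strains(
            simdata.SimStrainConfig(seed=21, genome_length=20_000, n_strains=2,
                                    target_distances=d)
        )
        reads = _reads_from(genomes, [("strain_00", 0.5), ("strain_01", 0.5)],
                            coverage=4, seed=22)[:500]
        alns = straincall.competitive_map(reads, genomes)
        correct = sum(
            a.ref_id == r.source_strain for a, r in zip(alns, reads)
        )
        assert correct / len(reads) >= 0.95

    def test_each_read_gets_at_most_one_alignment(self, strain_pair):
        genomes, _ = strain_pair
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=2, seed=1)
        alns = straincall.competitive_map(reads, genomes)
        assert len(alns) == len(reads)
        assert len({a.read_id for a in alns}) == len(reads)

    def test_empty_read_set_gives_empty_list(self, strain_pair):
        genomes, _ = strain_pair
        assert straincall.competitive_map([], genomes) == []


class TestPileupStats:
    def test_pure_sample_full_breadth_no_het(self, strain_pair):
        genomes, _ = strain_pair
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=30, seed=2)
        alns = straincall.competitive_map(reads, genomes[:1])
        pile = straincall.pileup(alns, reads, genomes[:1])
        st = straincall.coverage_stats(pile, "strain_00")
        assert st.breadth > 0.999
        assert st.het_per_kb == 0.0
        assert st.mean_depth == pytest.approx(30, rel=0.1)

    def test_mixture_on_single_ref_shows_divergence_as_het(self):
        d = np.array([[0, 0.02], [0.02, 0]])
        genomes, realized = simdata.evolve_strains(
            simdata.SimStrainConfig(seed=8, genome_length=20_000, n_strains=2,
                                    target_distances=d)
        )
        reads = _reads_from(genomes, [("strain_00", 0.5), ("strain_01", 0.5)],
                            coverage=30, seed=9)
        alns = straincall.competitive_map(reads, genomes[:1])
        pile = straincall.pileup(alns, reads, genomes[:1])
        st = straincall.coverage_stats(pile, "strain_00")
        expected = 1000.0 * realized.iloc[0, 1]  # divergent sites per kb
        assert abs(st.het_per_kb - expected) < 0.3 * expected

    def test_sequencing_error_alone_stays_below_het_threshold(self, strain_pair):
        """With two-read allele support, 0.5% error at 25x leaves the false
        het density well under the 10/kb co-infection threshold."""
        genomes, _ = strain_pair
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=25,
                            error_rate=0.005, seed=23)
        alns = straincall.competitive_map(reads, genomes[:1])
        pile = straincall.pileup(alns, reads, genomes[:1])
        st = straincall.coverage_stats(pile, "strain_00")
        assert st.het_per_kb < 10.0

    def test_zero_coverage_degenerate_stats(self, strain_pair):
        genomes, _ = strain_pair
        pile = straincall.pileup([], [], genomes[:1])
        st = straincall.coverage_stats(pile, "strain_00")
        assert st.breadth == 0.0
        assert st.het_per_kb == 0.0


class TestScreenAndIterate:
    def test_zero_reads_screen_uninfected(self, strain_pair):
        genomes, _ = strain_pair
        screen = straincall.screen_sample([], genomes)
        assert screen.preliminary_uninfected

    def test_true_reference_ranks_first_with_high_breadth(self, close_trio):
        genomes, _ = close_trio
        reads = _reads_from(genomes, [("strain_02", 1.0)], coverage=25,
                            error_rate=0.002, seed=3)
        screen = straincall.screen_sample(reads, genomes)
        assert screen.ranking[0] == "strain_02"
        assert screen.stats["strain_02"].breadth > 0.90

    def test_absent_strain_beyond_divergence_cap_gives_low_breadth(self):
        """Reads from a strain diverged beyond the per-read divergence cap
        (10% of read length) mostly fail to map, so the best panel genome
        stays below the infected-breadth threshold."""
        d = np.array([[0, 0.14], [0.14, 0]])
        genomes, _ = simdata.evolve_strains(
            simdata.SimStrainConfig(seed=13, genome_length=20_000, n_strains=2,
                                    target_distances=d)
        )
        reads = _reads_from(genomes, [("strain_01", 1.0)], coverage=10, seed=14)
        screen = straincall.screen_sample(reads, [genomes[0]])
        assert screen.stats["strain_00"].breadth < 0.90

    def test_absent_related_strain_shows_unresolved_het(self):
        """A strain related at ~5% to the only panel genome maps broadly but
        leaves an unresolvable heterozygosity excess: the decision chain
        flags the co-infection as unresolved rather than calling it clean."""
        d = np.array([[0, 0.05], [0.05, 0]])
        genomes, _ = simdata.evolve_strains(
            simdata.SimStrainConfig(seed=15, genome_length=20_000, n_strains=2,
                                    target_distances=d)
        )
        reads = _reads_from(
            genomes, [("strain_00", 0.5), ("strain_01", 0.5)], coverage=25, seed=16
        )
        call = straincall.iterate_strains(reads, [genomes[0]])
        assert "unresolved_coinfection" in call.flags

    def test_single_strain_sample_resolved_in_one_iteration(self, close_trio):
        genomes, _ = close_trio
        reads = _reads_from(genomes, [("strain_02", 1.0)], coverage=25,
                            error_rate=0.002, seed=4)
        call = straincall.detect(reads, genomes, sample_id="s")
        assert call.status == "infected"
        assert call.strain_ids == ["strain_02"]

    def test_dual_infection_recovered(self):
        d = np.array([[0, 0.03], [0.03, 0]])
        genomes, _ = simdata.evolve_strains(
            simdata.SimStrainConfig(seed=17, genome_length=20_000, n_strains=2,
                                    target_distances=d)
        )
        reads = _reads_from(genomes, [("strain_00", 0.5), ("strain_01", 0.5)],
                            coverage=25, error_rate=0.002, seed=18)
        call = straincall.detect(reads, genomes, sample_id="s")
        assert call.status == "infected"
        assert sorted(call.strain_ids) == ["strain_00", "strain_01"]

    def test_iteration_log_reconstructs_decisions(self, close_trio):
        genomes, _ = close_trio
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=25, seed=5)
        call = straincall.detect(reads, genomes, sample_id="s")
        assert call.iteration_log[0].get("screen_ranking")
        assert all("genomes" in e for e in call.iteration_log[1:])

    def test_default_thresholds(self):
        cfg = straincall.DetectionConfig()
        assert cfg.het_max_per_kb == 10.0
        assert cfg.breadth_infected == 0.90


class TestSamExport:
    def test_sam_roundtrip_preserves_placements(self, strain_pair, tmp_path):
        import pysam

        genomes, _ = strain_pair
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=1, seed=12)
        alns = straincall.competitive_map(reads, genomes)
        sam = tmp_path / "out.sam"
        straincall.write_sam(sam, alns, reads, genomes)
        seen = {}
        with pysam.AlignmentFile(str(sam)) as fh:
            for seg in fh:
                if not seg.is_unmapped:
                    seen[seg.query_name] = (seg.reference_name, seg.reference_start)
        for a in alns:
            if a.mapped:
                assert seen[a.read_id] == (a.ref_id, a.ref_start)


class TestConsensus:
    def test_reads_from_reference_reproduce_it(self, strain_pair):
        genomes, _ = strain_pair
        reads = _reads_from(genomes, [("strain_00", 1.0)], coverage=30, seed=6)
        alns = straincall.competitive_map(reads, genomes[:1])
        pile = straincall.pileup(alns, reads, genomes[:1])
        cons = straincall.call_consensus(pile, "strain_00")
        assert cons == genomes[0].sequence

    def test_cross_strain_reads_pull_consensus_toward_source(self, strain_pair):
        genomes, _ = strain_pair
        # reads from strain_01 mapped onto strain_00's reference
        reads = _reads_from(genomes, [("strain_01", 1.0)], coverage=30, seed=7)
        alns = straincall.competitive_map(reads, genomes[:1])
        pile = straincall.pileup(alns, reads, genomes[:1])
        cons = straincall.call_consensus(pile, "strain_00")
        ham_to_b = sum(c != b for c, b in zip(cons, genomes[1].sequence))
        ham_to_a = sum(c != a for c, a in zip(cons, genomes[0].sequence))
        assert ham_to_b < ham_to_a

    def test_no_coverage_falls_back_to_reference(self, strain_pair):
        genomes, _ = strain_pair
        pile = straincall.pileup([], [], genomes[:1])
        cons = straincall.call_consensus(pile, "strain_00")
        assert cons == genomes[0].sequence
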