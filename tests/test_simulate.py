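"""Synthetic-data generator: determinism, planted-structure contracts."""

import numpy as np
import pytest

from tilechip.genome import overlap_bp
from tilechip.simulate import (
    DEConfig,
    SimulationConfig,
    simulate_chip_tracks,
    simulate_expression,
    simulate_genome,
)

SMALL = dict(n_chroms=2, chrom_length_bp=100_000, n_orfs=50)


class TestSimulateGenome:
    def test_same_seed_identical_annotation(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert [f.__dict__ for f in a.features] == [f.__dict__ for f in b.features]

    def test_different_seeds_differ(self):
        a = simulate_genome(SimulationConfig(seed=1, **SMALL))
        b = simulate_genome(SimulationConfig(seed=2, **SMALL))
        assert [f.start for f in a.orfs] != [f.start for f in b.orfs]

    def test_orfs_pairwise_disjoint(self):
        ann = simulate_genome(SimulationConfig(seed=0))
        orfs = ann.orfs
        for i, a in enumerate(orfs):
            for b in orfs[i + 1 :]:
                assert overlap_bp(a, b) == 0

    def test_no_orfs_leaves_non_orf_features(self):
        ann = simulate_genome(SimulationConfig(seed=0, n_chroms=2, chrom_length_bp=50_000, n_orfs=0))
        assert ann.orfs == []
        assert len(ann.by_class("telomere")) == 4
        assert len(ann.by_class("centromere")) == 2

    def test_overfull_genome_is_error(self):
        with pytest.raises(ValueError, match="increase chrom_length_bp"):
            simulate_genome(SimulationConfig(seed=0, n_chroms=1, chrom_length_bp=20_000, n_orfs=50))

    def test_orf_metadata_within_bounds(self):
        ann = simulate_genome(SimulationConfig(seed=4, **SMALL))
        for g in ann.orfs:
            assert 0.0 < g.gc_fraction < 1.0
            assert g.expression_level > 0
            assert 600 <= g.length <= 8000


class TestSimulateChipTracks:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        ann = simulate_genome(cfg)
        a = simulate_chip_tracks(ann, cfg)
        b = simulate_chip_tracks(ann, cfg)
        for chrom in a.tracks:
            np.testing.assert_array_equal(a.tracks[chrom].values, b.tracks[chrom].values)
        assert a.planted == b.planted

    def test_instances_share_truth_but_not_noise(self):
        cfg = SimulationConfig(seed=5, **SMALL, expression_coupling=5.0)
        ann = simulate_genome(cfg)
        a = simulate_chip_tracks(ann, cfg, instance=0)
        b = simulate_chip_tracks(ann, cfg, instance=1)
        # strong coupling makes gene selection near-deterministic;
        # replicate noise must still differ between instances
        chrom = next(iter(a.tracks))
        assert not np.allclose(a.tracks[chrom].values, b.tracks[chrom].values)

    def test_zero_gradient_gives_flat_true_signal(self):
        cfg = SimulationConfig(
            seed=6, **SMALL, gradient_strength=0.0, noise_sd=0.0,
            amplitude_floor_fraction=0.5, n_chip_replicates=1,
        )
        ann = simulate_genome(cfg)
        chip = simulate_chip_tracks(ann, cfg)
        span = chip.planted[0]
        track = chip.tracks[span.chrom]
        lo = np.searchsorted(track.positions, span.start)
        hi = np.searchsorted(track.positions, span.end)
        inside = track.values[0, lo:hi]
        np.testing.assert_allclose(inside, inside[0])

    def test_minus_strand_gradient_rises_to_genomic_left(self):
        cfg = SimulationConfig(seed=8, **SMALL, noise_sd=0.0, n_chip_replicates=1,
                               amplitude_floor_fraction=0.5)
        ann = simulate_genome(cfg)
        chip = simulate_chip_tracks(ann, cfg)
        genes = {g.id: g for g in ann.orfs}
        minus = next(s for s in chip.planted if genes[s.feature_id].strand == "-")
        track = chip.tracks[minus.chrom]
        lo = np.searchsorted(track.positions, minus.start)
        hi = np.searchsorted(track.positions, minus.end)
        inside = track.values[0, lo:hi]
        assert inside[0] > inside[-1]  # 5' end of a minus gene is on the right

    def test_amplitude_monotone_in_expression(self):
        cfg = SimulationConfig(seed=9)
        ann = simulate_genome(cfg)
        chip = simulate_chip_tracks(ann, cfg)
        genes = {g.id: g for g in ann.orfs}
        pairs = sorted(
            (genes[s.feature_id].expression_level, s.amplitude) for s in chip.planted
        )
        third = len(pairs) // 3
        bottom = np.mean([a for _, a in pairs[:third]])
        top = np.mean([a for _, a in pairs[-third:]])
        assert top > bottom

    def test_mutant_spans_wider_and_more_numerous(self):
        cfg = SimulationConfig(seed=10, **SMALL)
        ann = simulate_genome(cfg)
        wt = simulate_chip_tracks(ann, cfg, factor="rrm3", condition="wild_type")
        mut = simulate_chip_tracks(ann, cfg, factor="rrm3", condition="mutant")
        assert len(mut.planted) > len(wt.planted)
        wt_len = np.mean([s.end - s.start for s in wt.planted])
        mut_len = np.mean([s.end - s.start for s in mut.planted])
        assert mut_len > wt_len

    def test_mutant_condition_only_affects_rrm3_like_factor(self):
        cfg = SimulationConfig(seed=10, **SMALL)
        ann = simulate_genome(cfg)
        a = simulate_chip_tracks(ann, cfg, factor="trex2", condition="wild_type")
        b = simulate_chip_tracks(ann, cfg, factor="trex2", condition="mutant")
        assert len(a.planted) == len(b.planted)

    def test_non_orf_signal_planted_when_enabled(self):
        cfg = SimulationConfig(seed=10, **SMALL, non_orf_signal=True)
        ann = simulate_genome(cfg)
        chip = simulate_chip_tracks(ann, cfg)
        gene_ids = {g.id for g in ann.orfs}
        assert any(s.feature_id not in gene_ids for s in chip.planted)


class TestSimulateExpression:
    def test_zero_de_fraction_all_unchanged(self):
        cfg = SimulationConfig(
            seed=1, **SMALL, de=DEConfig(fraction_up=0.0, fraction_down=0.0)
        )
        ann = simulate_genome(cfg)
        sim = simulate_expression(ann, cfg)
        assert set(sim.labels["status"]) == {"unchanged"}

    def test_planted_fold_reflected_in_means(self):
        cfg = SimulationConfig(seed=2, **SMALL, de=DEConfig(fold_range=(2.0, 2.0)))
        ann = simulate_genome(cfg)
        sim = simulate_expression(ann, cfg)
        down = sim.labels.query("status == 'down'").iloc[0]
        vals = sim.matrix.values.loc[down["gene_id"]]
        wt = vals[sim.matrix.strain_columns("wild_type")].mean()
        mut = vals[sim.matrix.strain_columns("mutant")].mean()
        assert mut / wt == pytest.approx(0.5, rel=0.25)  # within replicate noise

    def test_unbiased_generator_matches_genome_median(self):
        cfg = SimulationConfig(
            seed=3,
            n_orfs=800,
            chrom_length_bp=400_000,
            de=DEConfig(bias_length=0.0, bias_gc=0.0, bias_expression=0.0),
        )
        ann = simulate_genome(cfg)
        sim = simulate_expression(ann, cfg)
        de_genes = set(sim.labels.query("status != 'unchanged'")["gene_id"])
        lengths = {g.id: g.length for g in ann.orfs}
        genome_median = np.median(list(lengths.values()))
        de_median = np.median([lengths[g] for g in de_genes])
        # hypergeometric-level deviation only
        assert abs(np.log(de_median / genome_median)) < 0.15

    def test_second_mutant_shares_planted_truth(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        ann = simulate_genome(cfg)
        sim = simulate_expression(ann, cfg, n_mutants=2, shared_fraction=1.0)
        m1 = sim.labels.query("strain == 'mutant1' and status != 'unchanged'")
        m2 = sim.labels.query("strain == 'mutant2' and status != 'unchanged'")
        assert set(m1["gene_id"]) == set(m2["gene_id"])

    def test_deterministic(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        ann = simulate_genome(cfg)
        a = simulate_expression(ann, cfg)
        b = simulate_expression(ann, cfg)
        np.testing.assert_array_equal(a.matrix.values.to_numpy(), b.matrix.values.to_numpy())
        assert a.labels.equals(b.labels)
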