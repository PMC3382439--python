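"""Population dynamics: mutation operators, replacement, HGT, mixing."""

import numpy as np
import pytest
from scipy import stats

import evoguide as eg
from evoguide.cell_model import CellNetwork, RegulatoryEdge, Triplet, gate_cell
from evoguide.evolution import (
    HGTConfig,
    MutationConfig,
    Population,
    hgt_step,
    mix_populations,
    mutate,
    replace_on_division,
    run_epoch,
    sample_victim,
)


def only(**kw):
    """MutationConfig with every probability zero except the given ones."""
    base = dict(p_rate_perturbation=0.0, p_edge_addition=0.0,
                p_edge_deletion=0.0, p_triplet_duplication=0.0,
                p_triplet_deletion=0.0, weight_noise_scale=0.3)
    base.update(kw)
    return MutationConfig(**base)


def two_triplet_cell():
    t = Triplet(counts=(1, 2, 3), basal=(0.01, 0.2, 0.2),
                degradation=(0.02, 0.02, 0.02))
    edges = [RegulatoryEdge("S1", "G1", 2.0),
             RegulatoryEdge("P1", "G0", 1.5),
             RegulatoryEdge("P0", "M1", -1.0),
             RegulatoryEdge("P1", "M1", 0.5)]
    return CellNetwork(triplets=[t, t], edges=edges, energy=100.0)


class TestMutate:
    def test_zero_rates_preserve_genotype(self, rng, params):
        cell = two_triplet_cell()
        out = mutate(cell, MutationConfig.zero(), rng, params)
        assert out.to_dict() == cell.to_dict()

    def test_duplication_bookkeeping(self, rng, params):
        cell = two_triplet_cell()
        out = mutate(cell, only(p_triplet_duplication=1.0), rng, params)
        assert len(out.triplets) == len(cell.triplets) + 1
        # every edge incident to the copied triplet is duplicated with
        # endpoints remapped into the new block
        src_counts = {}
        for e in out.edges:
            src_counts[(e.source, e.target)] = src_counts.get(
                (e.source, e.target), 0) + 1
        # original edges all still present
        for e in cell.edges:
            assert (e.source, e.target) in src_counts
        # copied triplet index is 2; it must have incident edges mirroring
        # the original's wiring
        new_nodes = {"G2", "P2", "M2"}
        assert any(e.source in new_nodes or e.target in new_nodes
                   for e in out.edges)

    def test_deletion_never_removes_t0(self, rng, params):
        cell = CellNetwork(triplets=[Triplet()], edges=[], energy=10.0)
        out = mutate(cell, only(p_triplet_deletion=1.0), rng, params)
        assert len(out.triplets) == 1

    def test_deletion_remaps_edges(self, params):
        cell = two_triplet_cell()
        rng = np.random.default_rng(0)
        out = mutate(cell, only(p_triplet_deletion=1.0), rng, params)
        assert len(out.triplets) == 1
        # all surviving edges reference existing nodes only
        for e in out.edges:
            assert e.source in ("S1", "S2", "G0", "P0", "M0")
            assert e.target in ("G0", "P0", "M0")

    def test_edge_addition_respects_rules(self, params):
        cell = CellNetwork(triplets=[Triplet()], edges=[], energy=10.0)
        added = set()
        for seed in range(40):
            out = mutate(cell, only(p_edge_addition=1.0),
                         np.random.default_rng(seed), params)
            for e in out.edges:
                added.add((e.source, e.target))
        for s, t in added:
            assert not s.startswith("G")      # genes are not regulators
            assert t not in ("S1", "S2")      # sensors are never targets


class TestReplacement:
    def test_two_candidate_odds(self, params):
        # energies (1, 3): victim odds approach 3:1 for the poorer cell
        rng = np.random.default_rng(0)
        energies = np.array([1.0, 3.0, 1e9])  # parent is index 2
        picks = np.array([sample_victim(energies, 2, 1e-9, rng)
                          for _ in range(20_000)])
        ratio = np.mean(picks == 0) / np.mean(picks == 1)
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_equal_energies_uniform(self, params):
        rng = np.random.default_rng(1)
        energies = np.full(5, 2.0)
        picks = np.array([sample_victim(energies, 0, 0.01, rng)
                          for _ in range(8000)])
        freq = np.bincount(picks, minlength=5)[1:]
        chi2, p = stats.chisquare(freq)
        assert p > 0.01

    def test_parent_never_chosen(self, params):
        rng = np.random.default_rng(2)
        energies = np.array([0.0, 5.0, 5.0])
        picks = {sample_victim(energies, 0, 0.01, rng) for _ in range(200)}
        assert 0 not in picks

    def test_replace_on_division_bookkeeping(self, params, rng):
        cells = [gate_cell("AND", params) for _ in range(6)]
        for i, c in enumerate(cells):
            c.energy = 100.0 + i
        cells[0].energy = params.division_threshold + 10
        pop = Population.from_cells(cells, params)
        size_before = pop.size
        victim = replace_on_division(pop, 0, MutationConfig.zero(), rng)
        assert pop.size == size_before
        assert victim != 0
        half = (params.division_threshold + 10) / 2
        assert pop.energies[0] == pytest.approx(half)
        assert pop.energies[victim] == pytest.approx(half)
        assert pop.lineages[victim] == pop.lineages[0]

    def test_replace_requires_readiness(self, params, rng):
        pop = Population.from_cells([gate_cell("AND", params)] * 3, params)
        pop.energies[:] = params.division_threshold / 2
        with pytest.raises(ValueError):
            replace_on_division(pop, 0, MutationConfig.zero(), rng)


class TestHGT:
    def make_pop(self, params):
        donor = two_triplet_cell()
        # donor triplet 1 has edges: sensor->G1 (kept), P1->G0 (kept: T0 is
        # universal), P0->M1 (kept: T0 source), P1->M1 (internal, kept)
        recipient = CellNetwork(triplets=[Triplet()], edges=[], energy=50.0)
        return Population.from_cells([donor, recipient], params)

    def test_disabled_config_is_identity(self, params, rng):
        pop = self.make_pop(params)
        before = pop.genotype_fingerprint()
        assert hgt_step(pop, HGTConfig(enabled=False), rng) == 0
        assert pop.genotype_fingerprint() == before

    def test_transfer_bookkeeping(self, params):
        pop = self.make_pop(params)
        rng = np.random.default_rng(4)
        moved = 0
        for _ in range(50):
            moved += hgt_step(pop, HGTConfig(enabled=True, p_transfer=0.5), rng)
            if moved:
                break
        assert moved > 0
        cells = pop.to_cells()
        grown = [c for c in cells if len(c.triplets) > 2] + \
                [c for i, c in enumerate(cells) if i == 1 and len(c.triplets) > 1]
        assert grown, "some cell should have received a triplet"
        for c in cells:  # all edges reference existing nodes
            n = len(c.triplets)
            for e in c.edges:
                from evoguide.cell_model import node_index
                node_index(e.source, n)
                node_index(e.target, n)

    def test_cap_blocks_transfer(self, rng):
        from dataclasses import replace
        params1 = replace(eg.CellParams(), max_triplets=1)
        cells = [CellNetwork(triplets=[Triplet()], edges=[], energy=10.0)
                 for _ in range(4)]
        pop = Population.from_cells(cells, params1)
        assert hgt_step(pop, HGTConfig(enabled=True, p_transfer=1.0), rng) == 0


class TestStepPopulation:
    def test_clones_without_mutation_stay_identical(self, params, default_envs):
        cells = [gate_cell("AND", params) for _ in range(8)]
        pop = Population.from_cells(cells, params)
        tr = default_envs["AND"]
        for k in range(3):
            run_epoch(pop, tr, MutationConfig.zero(), seed=k)
        out = pop.to_cells()
        ref = {(len(out[0].triplets), len(out[0].edges))}
        for c in out:
            assert (len(c.triplets), len(c.edges)) in ref
            for e_a, e_b in zip(out[0].edges, c.edges):
                assert e_a.weight == e_b.weight

    def test_population_size_conserved(self, params, default_envs, rng):
        pop = Population.founders(16, rng, params)
        tr = default_envs["OR"]
        for k in range(3):
            run_epoch(pop, tr, MutationConfig(), seed=k)
        assert pop.size == 16

    def test_seeded_trajectory_reproducible(self, params, default_envs):
        tr = default_envs["AND"]

        def one():
            rng = np.random.default_rng(77)
            pop = Population.founders(12, rng, params)
            out = [run_epoch(pop, tr, MutationConfig(), seed=s)
                   for s in range(4)]
            return pop.genotype_fingerprint(), np.array(
                [np.nansum(f) for f in out])

        fp1, w1 = one()
        fp2, w2 = one()
        assert fp1 == fp2
        np.testing.assert_array_equal(w1, w2)

    def test_t0_survives_heavy_mutation(self, params, default_envs, rng):
        pop = Population.founders(12, rng, params)
        heavy = MutationConfig(0.9, 0.5, 0.5, 0.3, 0.5, 0.5)
        tr = default_envs["AND"]
        for k in range(4):
            run_epoch(pop, tr, heavy, seed=k)
        for c in pop.to_cells():
            assert len(c.triplets) >= 1

    def test_continuous_mutation_mode_acts_without_divisions(self, params,
                                                             default_envs):
        # cells that never divide still mutate when operators fire per step
        tr = default_envs["AND"]
        cells = [gate_cell("AND", params) for _ in range(6)]
        for mode, expect_change in ((True, False), (False, True)):
            pop = Population.from_cells(cells, params)
            pop.energies[:] = 0.0  # starved: no divisions possible
            mut = MutationConfig(1.0, 1.0, 1.0, 0.0, 0.0, 0.25,
                                 at_division=mode)
            before = pop.genotype_fingerprint()
            run_epoch(pop, tr, mut, seed=9)
            changed = pop.genotype_fingerprint() != before
            assert changed == expect_change

    def test_neutral_drift_fixation_is_symmetric(self, params):
        # identical genotypes, distinct lineages, constant nutrient:
        # fixation counts should be uniform across the 4 lineages
        n_lineages, reps = 4, 24
        ones = np.ones(400, np.int8)
        winners = []
        for r in range(reps):
            cells = [gate_cell("AND", params) for _ in range(n_lineages)]
            pop = Population.from_cells(cells, params)
            from evoguide.evolution import _run_trace
            for k in range(200):
                _run_trace(pop, ones, ones, ones, MutationConfig.zero(),
                           seed=r * 1000 + k)
                lin = set(pop.lineages.tolist())
                if len(lin) == 1:
                    winners.append(lin.pop())
                    break
        assert len(winners) >= reps // 2, "most replicates should fix"
        freq = np.bincount(winners, minlength=n_lineages)
        chi2, p = stats.chisquare(freq)
        assert p > 0.01


def test_snapshot_roundtrip(tmp_path, params, rng):
    import json

    pop = Population.founders(4, rng, params)
    pop.save_snapshot(tmp_path, fitness=[0.1, 0.2, 0.3, 0.4])
    manifest = (tmp_path / "manifest.tsv").read_text().splitlines()
    assert len(manifest) == 5
    with open(tmp_path / "cell_0000.json") as fh:
        from evoguide.cell_model import CellNetwork
        again = CellNetwork.from_dict(json.load(fh))
    assert again.to_dict() == pop.cell(0).to_dict()


class TestMix:
    def test_mix_counts_and_lineages(self, params, rng):
        a = Population.founders(10, rng, params)
        b = Population.founders(10, rng, params)
        a._p.lineage[:] = np.arange(10)
        b._p.lineage[:] = np.arange(100, 110)
        mixed = mix_populations(a, b, rng)
        assert mixed.size == 10
        from_a = np.sum(mixed.lineages < 100)
        assert from_a == 5
        assert set(mixed.lineages.tolist()) <= set(range(10)) | set(range(100, 110))

    def test_mix_of_identical_population(self, params, rng):
        a = Population.founders(6, rng, params)
        mixed = mix_populations(a, a, rng)
        assert set(mixed.lineages.tolist()) <= set(a.lineages.tolist())

    def test_size_mismatch_rejected(self, params, rng):
        a = Population.founders(6, rng, params)
        b = Population.founders(8, rng, params)
        with pytest.raises(ValueError):
            mix_populations(a, b, rng)
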