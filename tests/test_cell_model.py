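"""Single-cell network dynamics, energetics and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import evoguide as eg
from evoguide.cell_model import (
    CellNetwork,
    CellParams,
    RegulatoryEdge,
    Triplet,
    constitutive_cell,
    gate_cell,
    node_id,
    node_index,
    pack_cells,
    production_probability,
    random_cell,
    ready_to_divide,
    regulatory_input,
    simulate_cell,
    step_cell,
    unpack_cells,
)


def quiet_cell(energy=100.0):
    """A minimal cell with negligible rates (null dynamics)."""
    t0 = Triplet(counts=(5, 5, 0), basal=(1e-4, 1e-4, 1e-4),
                 degradation=(1e-4, 1e-4, 1e-4))
    return CellNetwork(triplets=[t0], edges=[], energy=energy)


class TestNodeIds:
    @pytest.mark.parametrize("idx,ident", [
        (0, "S1"), (1, "S2"), (2, "G0"), (3, "P0"), (4, "M0"), (5, "G1"),
    ])
    def test_roundtrip(self, idx, ident):
        assert node_id(idx) == ident
        assert node_index(ident) == idx

    def test_missing_triplet_rejected(self):
        with pytest.raises(ValueError):
            node_index("G3", n_triplets=2)

    def test_sensor_cannot_be_target(self):
        with pytest.raises(ValueError):
            CellNetwork(triplets=[Triplet()],
                        edges=[RegulatoryEdge("P0", "S1", 1.0)])


class TestProductionProbability:
    def test_zero_substrate_blocks_production(self, params):
        assert production_probability(5.0, 0.3, substrate_count=0,
                                      params=params) == 0.0

    def test_strong_activation_approaches_pmax(self, params):
        p = production_probability(50.0, 0.01, params=params)
        assert p == pytest.approx(params.p_max, rel=1e-6)

    def test_zero_regulation_gives_basal(self, params):
        assert production_probability(0.0, 0.2, params=params) == \
            pytest.approx(0.2)

    @settings(max_examples=30, deadline=None)
    @given(r1=st.floats(-20, 20), r2=st.floats(-20, 20),
           b=st.floats(0.001, 0.4))
    def test_monotone_in_regulation(self, r1, r2, b):
        lo, hi = sorted((r1, r2))
        assert production_probability(lo, b) <= production_probability(hi, b) + 1e-12


class TestRegulatoryInput:
    def test_no_edges_gives_zero(self, params):
        assert regulatory_input(quiet_cell(), "G0", params=params) == 0.0

    def test_saturated_activator_approaches_weight(self, params):
        t0 = Triplet(counts=(0, 1000, 0))
        cell = CellNetwork(triplets=[t0],
                           edges=[RegulatoryEdge("P0", "G0", 2.5)])
        assert regulatory_input(cell, "G0", params=params) == \
            pytest.approx(2.5, rel=0.02)

    def test_balanced_activator_inhibitor_cancel(self, params):
        t0 = Triplet(counts=(0, 40, 40))
        cell = CellNetwork(triplets=[t0], edges=[
            RegulatoryEdge("P0", "G0", 3.0), RegulatoryEdge("M0", "G0", -3.0)])
        assert regulatory_input(cell, "G0", params=params) == pytest.approx(0.0)

    def test_sensor_level_scales_input(self, params):
        cell = CellNetwork(triplets=[Triplet()],
                           edges=[RegulatoryEdge("S1", "G0", 1.0)])
        assert regulatory_input(cell, "G0", s1=0.0, params=params) == 0.0
        assert regulatory_input(cell, "G0", s1=1.0, params=params) > 0.5


class TestStepCell:
    def test_null_dynamics_only_maintenance(self, params, rng):
        cell = quiet_cell(energy=100.0)
        out = step_cell(cell, 0, 0, 0, rng, params)
        # counts essentially unchanged (rates 1e-4), energy down by upkeep
        assert out.energy <= 100.0 - params.maintenance * 3 + params.p_max
        assert abs(out.triplets[0].counts[0] - 5) <= 1

    def test_same_seed_reproducible(self, params):
        cell = gate_cell("AND", params)
        a = step_cell(cell, 1, 1, 1, np.random.default_rng(5), params)
        b = step_cell(cell, 1, 1, 1, np.random.default_rng(5), params)
        assert a.to_dict() == b.to_dict()

    def test_nutrient_with_expression_raises_energy(self, params):
        t0 = Triplet(counts=(10, 50, 0), basal=(1e-4, 1e-4, 1e-4),
                     degradation=(1e-4, 1e-4, 1e-4))
        cell = CellNetwork(triplets=[t0], edges=[], energy=500.0)
        fed = step_cell(cell, 0, 0, 1, np.random.default_rng(1), params)
        starved = step_cell(cell, 0, 0, 0, np.random.default_rng(1), params)
        assert fed.energy > starved.energy

    def test_counts_stay_bounded(self, params, rng):
        cell = constitutive_cell(params)
        cell, _ = simulate_cell(
            cell, np.ones(2000, np.int8), np.ones(2000, np.int8),
            np.ones(2000, np.int8), rng, params)
        for t in cell.triplets:
            assert all(0 <= c <= params.count_cap for c in t.counts)
        assert cell.energy >= 0

    def test_birth_death_mean_matches_master_equation(self, params, rng):
        # gene pinned at the cap => protein birth probability is constant
        # b_eff = basal * cap/(cap + K_s); per-molecule death rate d.
        # Stationary mean of the resulting M/M/inf-like chain is b_eff/d.
        b, d = 0.3, 0.03
        t0 = Triplet(counts=(60, 0, 0), basal=(0.5, b, 1e-4),
                     degradation=(1e-4, d, 1e-4))
        cell = CellNetwork(triplets=[t0], edges=[], energy=1e9)
        n = 10_000
        zeros = np.zeros(n, np.int8)
        cell, _, rp = simulate_cell(cell, zeros, zeros, zeros, rng, params,
                                    record_rp=True)
        b_eff = b * 60 / (params.substrate_k + 60)
        expected = b_eff / d
        burn = 500
        observed = rp[burn:].mean()
        # 3 standard errors with autocorrelation time ~1/d
        se = math.sqrt(expected) * math.sqrt(2 / (d * (n - burn)))
        assert abs(observed - expected) < 3 * se


class TestDivision:
    def test_zero_energy_not_ready(self, params):
        assert not ready_to_divide(quiet_cell(0.0), params)

    def test_threshold_inclusive(self, params):
        assert ready_to_divide(quiet_cell(params.division_threshold), params)

    def test_monotone_in_energy(self, params):
        for e in np.linspace(0, 2 * params.division_threshold, 20):
            if ready_to_divide(quiet_cell(e), params):
                assert ready_to_divide(quiet_cell(e + 1), params)


class TestSerialization:
    def test_json_roundtrip(self, rng, params):
        cell = random_cell(rng, params)
        again = CellNetwork.from_json(cell.to_json())
        assert again.to_dict() == cell.to_dict()

    def test_pack_unpack_roundtrip(self, rng, params):
        cells = [random_cell(rng, params) for _ in range(5)]
        again = unpack_cells(pack_cells(cells, params))
        for a, b in zip(cells, again):
            assert a.to_dict() == pytest.approx(b.to_dict()) or a.to_dict() == b.to_dict()

    def test_graphml_export(self, tmp_path, rng, params):
        import networkx as nx

        cell = gate_cell("XOR", params)
        path = tmp_path / "cell.graphml"
        cell.to_graphml(path)
        g = nx.read_graphml(path)
        assert "P0" in g and "S1" in g
        assert g.number_of_edges() == len(cell.edges)

    def test_graph_weights_preserved(self, params):
        cell = gate_cell("A", params)
        g = cell.to_graph()
        for e in cell.edges:
            assert g[e.source][e.target]["weight"] == pytest.approx(e.weight)


class TestDesignedCells:
    @pytest.mark.parametrize("gate", ["AND", "OR", "A", "B", "XOR"])
    def test_gate_cells_track_their_environment(self, default_envs, params,
                                                gate):
        tr = default_envs[gate]
        cell = gate_cell(gate, params)
        rng = np.random.default_rng(99)
        cell, _ = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng, params)
        _, w = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng, params)
        assert w > 0.5

    def test_constitutive_cell_uncorrelated(self, default_envs, params):
        tr = default_envs["AND"]
        rng = np.random.default_rng(3)
        cell = constitutive_cell(params)
        cell, _ = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng, params)
        _, w = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng, params)
        assert abs(w) < 0.35

    def test_gating_beats_constitutive_energetically(self, default_envs,
                                                     params):
        # the selective gradient: nutrient-timed expression accumulates
        # energy faster than constitutive expression (here: AND environment)
        tr = default_envs["AND"]
        rng = np.random.default_rng(11)

        def long_run_rate(cell):
            cell, _ = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng, params)
            e0 = cell.energy
            for _ in range(3):
                cell, _ = simulate_cell(cell, tr.s1, tr.s2, tr.nutrient, rng,
                                        params)
            return (cell.energy - e0) / 3

        assert long_run_rate(gate_cell("AND", params)) > \
            long_run_rate(constitutive_cell(params))
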