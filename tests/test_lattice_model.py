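"""Static model structure: target adjacency, pair energies, total energy."""

import numpy as np
import pytest

from slmassembly import (
    LatticeState,
    ModelParams,
    TargetSet,
    build_target_adjacency,
    compact_targets,
    distance_to_target,
    pair_interaction,
    total_energy,
)
from slmassembly.lattice_model import (
    InvalidLayoutError,
    InvalidStateError,
    board_adjacency,
)


def brute_force_adjacency(layout):
    """Independent oracle: double loop over particle pairs."""
    n = len(layout)
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j:
                dr = abs(layout[i][0] - layout[j][0])
                dc = abs(layout[i][1] - layout[j][1])
                adj[i, j] = int(dr + dc == 1)
    return adj


def brute_force_energy(state, targets, params):
    """Independent oracle: direct sum over all pairs with min-image PBC."""
    L, n = state.L, state.N
    E = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dr = abs(int(state.positions[i, 0]) - int(state.positions[j, 0]))
            dc = abs(int(state.positions[i, 1]) - int(state.positions[j, 1]))
            dr = min(dr, L - dr)
            dc = min(dc, L - dc)
            if dr + dc == 1:
                E += pair_interaction(i, j, int(state.states[i]),
                                      int(state.states[j]), targets, params)
    return E


class TestTargetAdjacency:
    def test_compact_square_has_40_bonds(self):
        layout = np.array([(r, c) for r in range(5) for c in range(5)])
        adj = build_target_adjacency(layout)
        assert adj.sum() // 2 == 40
        np.testing.assert_array_equal(adj, brute_force_adjacency(layout))

    def test_single_particle_zero_matrix(self):
        adj = build_target_adjacency(np.array([[3, 4]]))
        np.testing.assert_array_equal(adj, np.zeros((1, 1)))

    def test_two_adjacent_particles(self):
        adj = build_target_adjacency(np.array([[0, 0], [0, 1]]))
        assert adj[0, 1] == adj[1, 0] == 1
        assert adj[0, 0] == adj[1, 1] == 0

    def test_duplicate_cell_rejected(self):
        with pytest.raises(InvalidLayoutError):
            build_target_adjacency(np.array([[0, 0], [0, 0]]))

    def test_layout_roundtrip_through_state(self, table1_targets,
                                            table1_params):
        # adjacency of the assembled state reproduces I^m exactly
        for m in (1, 2):
            state = table1_targets.assembled_state(m, table1_params)
            B = board_adjacency(state)
            np.testing.assert_array_equal(B, table1_targets.adjacency[m - 1])

    def test_distinct_default_targets(self, table1_targets):
        assert not np.array_equal(table1_targets.adjacency[0],
                                  table1_targets.adjacency[1])
        assert table1_targets.n_bonds(1) == table1_targets.n_bonds(2) == 40

    def test_layout_file_roundtrip(self, tmp_path, table1_targets):
        path = tmp_path / "targets.tsv"
        table1_targets.save_layouts(path)
        loaded = TargetSet.load_layouts(path)
        np.testing.assert_array_equal(loaded.layouts, table1_targets.layouts)
        np.testing.assert_array_equal(loaded.adjacency,
                                      table1_targets.adjacency)


class TestPairInteraction:
    @pytest.mark.parametrize("s_i,s_j,expected", [
        (1, 1, -4.0),    # both match target 1: strong
        (1, 2, -2.5),    # half match: (J_s + J_w) / 2
        (2, 1, -2.5),
        (2, 2, -1.0),    # neighboring pair but neither state matches
    ])
    def test_neighboring_pair_energies(self, table1_targets, table1_params,
                                       s_i, s_j, expected):
        # particles 4 and 9 are neighbors in target 1 only (the snake
        # ordering of target 2 places 9 at the far end of row 1)
        assert table1_targets.adjacency[0, 4, 9] == 1
        assert table1_targets.adjacency[1, 4, 9] == 0
        e = pair_interaction(4, 9, s_i, s_j, table1_targets, table1_params)
        assert e == expected

    def test_non_neighboring_pair_is_weak(self, table1_targets,
                                          table1_params):
        # particles 0 and 12 are far apart in both stored targets
        assert table1_targets.adjacency[:, 0, 12].sum() == 0
        for s_i in (1, 2):
            for s_j in (1, 2):
                assert pair_interaction(0, 12, s_i, s_j, table1_targets,
                                        table1_params) == -1.0

    def test_symmetry(self, table1_targets, table1_params):
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(25, size=2, replace=False)
            s_i, s_j = rng.integers(1, 3, size=2)
            a = pair_interaction(int(i), int(j), int(s_i), int(s_j),
                                 table1_targets, table1_params)
            b = pair_interaction(int(j), int(i), int(s_j), int(s_i),
                                 table1_targets, table1_params)
            assert a == b

    def test_invalid_state_rejected(self, table1_targets, table1_params):
        with pytest.raises(InvalidStateError):
            pair_interaction(0, 1, 0, 1, table1_targets, table1_params)
        with pytest.raises(InvalidStateError):
            pair_interaction(0, 1, 1, 3, table1_targets, table1_params)

    def test_shared_bond_takes_most_attractive(self, table1_params):
        # two targets sharing the same bond between particles 0 and 1
        layout = np.array([[0, 0], [0, 1], [5, 5]])
        targets = TargetSet.from_layouts([layout, layout])
        # state matches target 2 only: J_s from target 2 beats J_w from 1
        e = pair_interaction(0, 1, 2, 2, targets, table1_params)
        assert e == table1_params.J_s


class TestTotalEnergy:
    def test_assembled_target_ground_state(self, table1_targets,
                                           table1_params):
        state = table1_targets.assembled_state(1, table1_params)
        assert total_energy(state, table1_targets, table1_params) == -160.0

    def test_no_adjacent_pairs_zero(self, table1_params, table1_targets):
        # particles spread on every third cell: no lattice contacts
        cells = [(r, c) for r in range(0, 15, 3) for c in range(0, 15, 3)]
        pos = np.array(cells)
        state = LatticeState.from_positions(
            pos, np.ones(25, dtype=np.int16), 15)
        assert total_energy(state, table1_targets, table1_params) == 0.0

    def test_random_configuration_matches_oracle(self, table1_targets,
                                                 table1_params):
        rng = np.random.default_rng(7)
        for _ in range(5):
            cells = rng.choice(225, size=25, replace=False)
            pos = np.column_stack([cells // 15, cells % 15])
            states = rng.integers(1, 3, size=25).astype(np.int16)
            state = LatticeState.from_positions(pos, states, 15)
            assert total_energy(state, table1_targets, table1_params) == (
                brute_force_energy(state, table1_targets, table1_params))

    def test_assembled_energy_is_strong_bond_sum(self, table1_targets,
                                                 table1_params):
        # d_m = 0 implies E = J_s * (number of target bonds)
        for m in (1, 2):
            state = table1_targets.assembled_state(m, table1_params)
            assert distance_to_target(state, m, table1_targets) == 0
            assert total_energy(state, table1_targets, table1_params) == (
                table1_params.J_s * table1_targets.n_bonds(m))


class TestDistanceToTarget:
    def test_assembled_distance_zero(self, table1_targets, table1_params):
        state = table1_targets.assembled_state(1, table1_params)
        assert distance_to_target(state, 1, table1_targets) == 0

    def test_dispersed_distance_is_bond_count(self, table1_targets,
                                              table1_params):
        cells = [(r, c) for r in range(0, 15, 3) for c in range(0, 15, 3)]
        state = LatticeState.from_positions(
            np.array(cells), np.ones(25, dtype=np.int16), 15)
        assert distance_to_target(state, 1, table1_targets) == 40

    def test_displaced_corner_particle_distance_two(self, table1_targets,
                                                    table1_params):
        # move the (0,0)-corner particle of the assembled square far away
        pos = table1_targets.layouts[0].copy()
        corner = int(np.flatnonzero((pos == [0, 0]).all(axis=1))[0])
        pos[corner] = (10, 10)
        state = LatticeState.from_positions(
            pos, np.ones(25, dtype=np.int16), 15)
        assert distance_to_target(state, 1, table1_targets) == 2

    def test_invalid_target_index(self, table1_targets, table1_params):
        state = table1_targets.assembled_state(1, table1_params)
        with pytest.raises(IndexError):
            distance_to_target(state, 3, table1_targets)


class TestModelParams:
    def test_defaults_match_reference_table(self):
        p = ModelParams()
        assert (p.N, p.L, p.M_T) == (25, 15, 2)
        assert (p.J_s, p.J_w) == (-4.0, -1.0)
        assert p.J_half == -2.5
        assert p.T_cap == 50_000_000

    def test_yaml_roundtrip(self, tmp_path):
        p = ModelParams(delta_mu=1.6, seed=42, T_cap=1000, record_every=10)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert ModelParams.from_yaml(path) == p

    @pytest.mark.parametrize("kwargs", [
        {"N": 0}, {"N": 226}, {"M_T": 0}, {"T_cap": 0},
        {"delta_mu": -0.1}, {"T_cap": 5, "record_every": 10},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
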