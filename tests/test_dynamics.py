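"""Stochastic update semantics: mortality, space-limited replication, run loop."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ktwsim import (
    DynamicsParams,
    HexLattice,
    RngStreams,
    SpeciesParams,
    count_abundances,
    load_config,
    run,
    step,
)


def constant_lattice(width, height, species_id):
    occ = np.full(width * height, species_id, dtype=np.int16)
    return HexLattice(width, height, occ)


def make_params(probs, mortality=0.0, n_steps=1):
    species = [SpeciesParams(i + 1, p) for i, p in enumerate(probs)]
    return DynamicsParams(species=species, mortality_prob=mortality,
                          n_steps=n_steps)


class TestStep:
    def test_frozen_dynamics_leaves_lattice_unchanged(self, small_lattice):
        params = make_params([0.0, 0.0, 0.0, 0.0], mortality=0.0)
        out = step(small_lattice, params, RngStreams.from_seed(0))
        assert np.array_equal(out.occ, small_lattice.occ)

    def test_forced_replication_doubles_single_cell(self):
        lattice = HexLattice.empty(5, 5)
        lattice.occ[12] = 1
        params = make_params([1.0])
        out = step(lattice, params, RngStreams.from_seed(0))
        ab = count_abundances(out, 1)
        assert ab.counts[0] == 2

    def test_full_lattice_cannot_grow(self):
        lattice = constant_lattice(6, 6, 1)
        params = make_params([1.0])
        out = step(lattice, params, RngStreams.from_seed(0))
        assert np.array_equal(out.occ, lattice.occ)

    def test_newborns_do_not_replicate_in_birth_step(self):
        # one cell with p = 1 can at most double per step: 1 -> 2 -> 4
        lattice = HexLattice.empty(8, 8)
        lattice.occ[0] = 1
        params = make_params([1.0])
        streams = RngStreams.from_seed(3)
        for expected in (2, 4):
            lattice = step(lattice, params, streams)
            assert lattice.n_occupied == expected

    def test_mortality_only_binomial_expectation(self):
        # 100 cells, d = 0.05: mean survivors over 10,000 one-step replicates
        # must sit within 3 standard errors of 100 * 0.95 = 95
        lattice = HexLattice.empty(10, 10)
        lattice.occ[:] = 1
        params = make_params([0.0], mortality=0.05)
        n_rep = 10_000
        survivors = np.empty(n_rep)
        for i in range(n_rep):
            out = step(lattice, params, RngStreams.from_seed(10_000 + i))
            survivors[i] = out.n_occupied
        se = np.sqrt(100 * 0.05 * 0.95 / n_rep)
        assert abs(survivors.mean() - 95.0) < 3 * se

    def test_multi_step_thinning_matches_decay_law(self):
        # with replication off, E[N_t] = N0 (1 - d)^t
        lattice = HexLattice.empty(20, 20)
        lattice.occ[:] = 1
        params = make_params([0.0], mortality=0.1)
        t, n_rep = 5, 400
        finals = np.empty(n_rep)
        for i in range(n_rep):
            lat, streams = lattice, RngStreams.from_seed(777 + i)
            for _ in range(t):
                lat = step(lat, params, streams)
            finals[i] = lat.n_occupied
        expected = 400 * 0.9**t
        # conservative bound: 4 sigma of a binomial(400, 0.9^5) mean
        sigma = np.sqrt(400 * 0.9**t * (1 - 0.9**t) / n_rep)
        assert abs(finals.mean() - expected) < 4 * sigma

    def test_step_is_deterministic_given_streams(self, small_lattice):
        params = make_params([0.3, 0.5, 0.7, 0.9], mortality=0.05)
        a = step(small_lattice, params, RngStreams.from_seed(123))
        b = step(small_lattice, params, RngStreams.from_seed(123))
        assert np.array_equal(a.occ, b.occ)

    def test_kernel_python_and_jit_paths_agree(self, small_lattice):
        from ktwsim._kernel import _replication_pass, replication_pass
        from ktwsim.hexlattice import neighbor_table
        nbr = neighbor_table(small_lattice)
        probs = np.array([0.3, 0.5, 0.7, 0.9])
        rng = np.random.default_rng(0)
        order = rng.permutation(np.flatnonzero(small_lattice.occ))
        u1, u2 = rng.random(order.size), rng.random(order.size)
        occ_a = small_lattice.occ.copy()
        occ_b = small_lattice.occ.copy()
        _replication_pass(occ_a, nbr, probs, order, u1, u2)
        replication_pass(occ_b, nbr, probs, order, u1, u2)
        assert np.array_equal(occ_a, occ_b)


class TestRun:
    def test_default_run_records_one_row_per_step(self, default_config):
        cfg = replace(default_config, n_steps=50, width=20, height=20)
        traj = run(cfg).trajectory
        assert len(traj) == 50
        assert traj["step"].tolist() == list(range(50))

    def test_zero_steps_rejected(self, default_config):
        with pytest.raises(ValueError):
            replace(default_config, n_steps=0)

    def test_identical_seed_reproduces_trajectory(self, default_config):
        cfg = replace(default_config, n_steps=40, width=15, height=15)
        a = run(cfg).trajectory
        b = run(cfg).trajectory
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, default_config):
        cfg = replace(default_config, n_steps=40, width=15, height=15)
        a = run(cfg).trajectory
        b = run(replace(cfg, seed=cfg.seed + 1)).trajectory
        assert not a.equals(b)

    def test_space_exclusion_throughout(self, default_config):
        cfg = replace(default_config, n_steps=80, width=12, height=12,
                      initial_occupancy=0.5)
        traj = run(cfg).trajectory
        assert (traj["total"] <= 144).all()
        count_cols = [f"count_{i}" for i in range(1, 5)]
        assert (traj[count_cols].sum(axis=1) == traj["total"]).all()

    def test_monotone_growth_without_death_or_surveillance(self, default_config):
        cfg = replace(default_config, n_steps=60, width=15, height=15,
                      mortality_prob=0.0,
                      schedule=type(default_config.schedule)(mode="off"))
        traj = run(cfg).trajectory
        for i in range(1, 5):
            assert (traj[f"count_{i}"].diff().dropna() >= 0).all()

    def test_fastest_species_wins_without_surveillance(self):
        # median final count over a small seed ensemble is maximal for the
        # species with the highest replication probability
        finals = []
        for seed in range(8):
            cfg = load_config(overrides={
                "surveillance.mode": "off",
                "dynamics.seed": seed,
                "dynamics.n_steps": 400,
                "lattice.width": 30, "lattice.height": 30,
            })
            traj = run(cfg).trajectory
            finals.append([traj[f"count_{i}"].iloc[-1] for i in range(1, 5)])
        medians = np.median(np.array(finals), axis=0)
        assert np.argmax(medians) == 3
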