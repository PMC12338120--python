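"""Harmonic lattice energy/forces, Langevin dynamics, and dataset protocol."""

import itertools

import numpy as np
import pytest

from gpcn.mt_simulator import (
    FEATURE_COEFFICIENTS,
    STRENGTH_GRID,
    STRENGTH_NAMES,
    InteractionParams,
    SimState,
    SimulationConfig,
    config_for_spec,
    desk_config,
    full_protocol,
    potential_energy,
    forces,
    run_simulation,
    generate_dataset,
    save_dataset,
    load_dataset,
    step_langevin,
)
from gpcn.tube_graphs import LatticeGeometry, TubeSpec, build_lattice_geometry


def toy_geometry(rng: np.random.Generator, n: int = 20) -> LatticeGeometry:
    """Random spring chain whose resting values equal its as-built geometry
    (every interaction gets its own type, so the start configuration has
    exactly zero energy)."""
    coords = rng.uniform(0, 10, size=(n, 3))
    bonds, angles = [], []
    for i in range(n - 1):
        bonds.append((i, i + 1, f"b{i}"))
    for j in range(1, n - 1):
        angles.append((j - 1, j, j + 1, f"a{j}"))
    lengths = {}
    for i, j, t in bonds:
        lengths[t] = float(np.linalg.norm(coords[i] - coords[j]))
    angs = {}
    for i, j, k, t in angles:
        u, v = coords[i] - coords[j], coords[k] - coords[j]
        angs[t] = float(np.degrees(
            np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        ))
    return LatticeGeometry(coords, bonds, angles, lengths, angs)


def toy_params(geom: LatticeGeometry) -> InteractionParams:
    """One strength per interaction type, deterministically varied."""
    strengths = {n: 1.0 for n in STRENGTH_NAMES}
    types = {t for *_, t in geom.bonds} | {t for *_, t in geom.angles}
    for idx, t in enumerate(sorted(types)):
        strengths[t] = 1.0 + (idx % 5)
    return InteractionParams(strengths)


def oracle_energy(geom: LatticeGeometry, pos: np.ndarray, params) -> float:
    """Term-by-term loop oracle for the harmonic lattice energy."""
    total = 0.0
    for i, j, t in geom.bonds:
        L = params.strengths.get(t, params.strengths.get("LatAssoc"))
        r = np.linalg.norm(pos[i] - pos[j])
        total += L * (r - geom.resting_lengths[t]) ** 2
    for i, j, k, t in geom.angles:
        L = params.strengths.get(t)
        u, v = pos[i] - pos[j], pos[k] - pos[j]
        phi = np.arccos(
            np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        )
        total += L * (phi - np.deg2rad(geom.resting_angles[t])) ** 2
    return total


class TestPotentialEnergy:
    def test_resting_geometry_has_zero_energy(self):
        geom = toy_geometry(np.random.default_rng(0))
        total, per_node = potential_energy(geom, geom.coordinates, toy_params(geom))
        assert total == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(per_node, 0.0)

    def test_single_stretched_bond(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        geom = LatticeGeometry(coords, [(0, 1, "b")], [], {"b": 1.5}, {})
        params = InteractionParams({**{n: 1.0 for n in STRENGTH_NAMES}, "b": 3.0})
        total, per_node = potential_energy(geom, coords, params)
        assert total == pytest.approx(3.0 * 0.5**2)
        assert np.allclose(per_node, total / 2)

    def test_per_node_sums_to_total_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        geom = toy_geometry(rng)
        params = toy_params(geom)
        pos = geom.coordinates + 0.3 * rng.standard_normal(geom.coordinates.shape)
        total, per_node = potential_energy(geom, pos, params)
        assert per_node.sum() == pytest.approx(total, rel=1e-12)
        assert total == pytest.approx(oracle_energy(geom, pos, params), rel=1e-10)


class TestForces:
    def test_zero_at_rest(self):
        geom = toy_geometry(np.random.default_rng(2))
        F = forces(geom, geom.coordinates, toy_params(geom))
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_stretched_bond_equal_opposite_axial(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        geom = LatticeGeometry(coords, [(0, 1, "b")], [], {"b": 1.5}, {})
        params = InteractionParams({**{n: 1.0 for n in STRENGTH_NAMES}, "b": 3.0})
        F = forces(geom, coords, params)
        assert F[0, 0] == pytest.approx(2 * 3.0 * 0.5)  # pulled toward node 1
        assert np.allclose(F[0], -F[1])
        assert np.allclose(F[:, 1:], 0.0)

    def test_matches_finite_differences_on_random_configurations(self):
        rng = np.random.default_rng(3)
        geom = toy_geometry(rng, n=12)
        params = toy_params(geom)
        eps = 1e-6
        for _ in range(100):
            pos = geom.coordinates + 0.2 * rng.standard_normal(geom.coordinates.shape)
            F = forces(geom, pos, params)
            i = int(rng.integers(geom.node_count))
            j = int(rng.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            fd = -(potential_energy(geom, pp, params)[0]
                   - potential_energy(geom, pm, params)[0]) / (2 * eps)
            scale = max(abs(fd), np.abs(F).max() * 1e-3, 1e-9)
            assert abs(F[i, j] - fd) / scale < 1e-5


class TestLangevin:
    def test_equilibrium_is_a_fixed_point(self):
        geom = toy_geometry(np.random.default_rng(4))
        config = SimulationConfig(timestep=0.01, ramp_steps=10, hold_steps=10,
                                  save_interval=10, max_force=0.0,
                                  temperature=0.0, damping=0.0)
        state = SimState(geom.coordinates.copy(), np.zeros_like(geom.coordinates))
        out = step_langevin(state, geom, toy_params(geom), config, np.random.default_rng(0))
        assert np.allclose(out.positions, state.positions)
        assert np.allclose(out.velocities, 0.0)

    def test_clamped_nodes_never_move(self):
        geom = build_lattice_geometry(TubeSpec(4, 13, 1))
        config = config_for_spec(
            geom.spec, timestep=0.005, ramp_steps=50, hold_steps=50,
            save_interval=100, max_force=2.0, temperature=1e-4, damping=0.5,
        )
        params = InteractionParams.uniform(10.0)
        state = SimState(geom.coordinates.copy(), np.zeros_like(geom.coordinates))
        rng = np.random.default_rng(1)
        for _ in range(20):
            state = step_langevin(state, geom, params, config, rng)
        clamped = list(config.clamped_nodes)
        assert np.array_equal(state.positions[clamped], geom.coordinates[clamped])
        assert np.any(state.positions[list(config.forced_nodes)]
                      != geom.coordinates[list(config.forced_nodes)])

    def test_undamped_two_body_oscillator_conserves_energy(self):
        """With no thermostat the scheme is velocity Verlet: the oscillator's
        total energy drifts only at integrator order."""
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        geom = LatticeGeometry(coords, [(0, 1, "b")], [], {"b": 1.0}, {})
        params = InteractionParams({**{n: 1.0 for n in STRENGTH_NAMES}, "b": 2.0})
        config = SimulationConfig(timestep=0.005, ramp_steps=10, hold_steps=10,
                                  save_interval=10, max_force=0.0,
                                  temperature=0.0, damping=0.0)
        state = SimState(coords.copy(), np.zeros_like(coords))
        rng = np.random.default_rng(0)

        def total_energy(s):
            pe = potential_energy(geom, s.positions, params)[0]
            ke = 0.5 * config.mass * np.sum(s.velocities**2)
            return pe + ke

        e0 = total_energy(state)
        for _ in range(2000):
            state = step_langevin(state, geom, params, config, rng)
        assert total_energy(state) == pytest.approx(e0, rel=1e-4)


class TestProtocol:
    def test_full_protocol_step_counts_give_12_frames(self):
        config = full_protocol()
        assert (config.ramp_steps, config.hold_steps, config.save_interval) == (
            128000, 256000, 32000,
        )
        assert config.frames_per_run == 12
        assert config.clamped_nodes == tuple(range(26))
        assert config.forced_nodes == tuple(range(598, 624))

    def test_full_grid_is_7_to_the_5(self):
        combos = list(itertools.product(*(STRENGTH_GRID for _ in STRENGTH_NAMES)))
        assert len(combos) == 7**5 == 16807

    def test_save_interval_must_divide_total(self):
        with pytest.raises(ValueError):
            SimulationConfig(ramp_steps=100, hold_steps=50, save_interval=40)

    def test_single_frame_run(self):
        geom = toy_geometry(np.random.default_rng(5))
        config = SimulationConfig(timestep=0.005, ramp_steps=20, hold_steps=20,
                                  save_interval=40, max_force=0.0,
                                  temperature=1e-5, damping=0.5, seed=3)
        frames = run_simulation(geom, toy_params(geom), config)
        assert len(frames) == 1
        f = frames[0]
        assert f.X.shape == (geom.node_count, 10)
        assert f.y.shape == (geom.node_count, 1)
        assert f.y.sum() == pytest.approx(f.total_energy, rel=1e-9)
        # the four coefficient columns are constant across nodes
        assert np.allclose(f.X[:, 6:], f.X[0, 6:])
        assert f.X[0, 6:].tolist() == [
            toy_params(geom).strengths[c] for c in FEATURE_COEFFICIENTS
        ]

    def test_equilibration_plateau_on_stiff_toy(self):
        geom = toy_geometry(np.random.default_rng(6), n=8)
        params = InteractionParams(
            {**{n: 1.0 for n in STRENGTH_NAMES},
             **{t: 30.0 for *_, t in geom.bonds},
             **{t: 20.0 for *_, t in geom.angles}}
        )
        config = SimulationConfig(timestep=0.002, ramp_steps=1200, hold_steps=1200,
                                  save_interval=200, max_force=0.0,
                                  temperature=0.0, damping=2.0, seed=0)
        # start displaced so there is something to relax
        geom = LatticeGeometry(
            geom.coordinates + 0.05 * np.random.default_rng(7).standard_normal(
                geom.coordinates.shape),
            geom.bonds, geom.angles, geom.resting_lengths, geom.resting_angles,
        )
        frames = run_simulation(geom, params, config)
        e = [f.total_energy for f in frames]
        # relative to the relaxation's starting energy: the equilibrium energy
        # of the unloaded chain is ~0, so e[-2] itself is a bad denominator
        assert abs(e[-1] - e[-2]) / max(e[0], 1e-12) < 0.01
        assert e[-1] < 0.01 * e[0]

    def test_dataset_bookkeeping(self):
        geom = build_lattice_geometry(TubeSpec(4, 13, 1))
        config = config_for_spec(
            geom.spec, timestep=0.005, ramp_steps=20, hold_steps=20,
            save_interval=20, max_force=0.1, temperature=1e-5, damping=0.5,
        )
        ds = generate_dataset(geom, config,
                              {n: [1.0, 2.0] if n == "LatAssoc" else [1.0]
                               for n in STRENGTH_NAMES})
        assert ds.n_frames == 2 * config.frames_per_run
        assert len(ds.manifest) == 2

    def test_dataset_h5_roundtrip(self, tmp_path, desk_data):
        path = tmp_path / "ds.h5"
        save_dataset(desk_data, path)
        back = load_dataset(path)
        assert np.array_equal(back.X, desk_data.X)
        assert np.array_equal(back.y, desk_data.y)
        assert back.manifest == desk_data.manifest


def test_stiffness_ordering_under_load(desk_data):
    """Tip deflection at full load is smaller when every spring is stiff."""
    from gpcn.mt_simulator import desk_geometry

    frames_per_run = 12
    # runs are in Cartesian-product order: first = all 3.0, last = all 57.0
    soft_final = desk_data.X[frames_per_run - 1]
    stiff_final = desk_data.X[-1]
    n_tip = 26  # last two rings
    y0 = desk_geometry().coordinates[-n_tip:, 1].mean()
    soft_deflection = abs(soft_final[-n_tip:, 1].mean() - y0)
    stiff_deflection = abs(stiff_final[-n_tip:, 1].mean() - y0)
    assert stiff_deflection < soft_deflection
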