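"""Coarse-grained harmonic spring-lattice simulator of a microtubule.

Each tubulin monomer is a point mass on the helical lattice; interactions are
harmonic bonds ``E = L (r - b0)^2`` and harmonic angles ``E = L (phi - phi0)^2``
(``phi`` in radians), with one strength parameter per interaction family
(LatAssoc, LongAssoc, LatAngle, LongAngle, QuadAngles).  No steric or dihedral
terms.  The tube is clamped at its first two rings and a downward (-y) load,
ramped linearly then held, is applied to its last two rings; Langevin dynamics
at small temperature (BAOAB velocity-Verlet splitting) relax the structure.

Every ``save_interval`` steps a frame is recorded: a per-node feature matrix
``X`` (position, velocity, four interaction coefficients) and the per-node
potential energy ``y``, where each interaction's energy is split equally among
its participants.  Sweeping the strength parameters over a value grid yields a
training dataset of (X, y) frames.

Units are reduced (lengths in nm, unit monomer mass, dimensionless force and
energy); the integrator timestep and load are configurable and chosen for
stability, and no physical-unit fidelity is claimed for the time axis.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tube_graphs import (
    LatticeGeometry,
    STRENGTH_OF_TYPE,
    TubeSpec,
    build_lattice_geometry,
)

__all__ = [
    "InteractionParams",
    "SimulationConfig",
    "FrameRecord",
    "Dataset",
    "STRENGTH_NAMES",
    "FEATURE_COEFFICIENTS",
    "potential_energy",
    "forces",
    "step_langevin",
    "run_simulation",
    "generate_dataset",
    "config_for_spec",
    "full_protocol",
    "desk_config",
    "desk_geometry",
    "desk_dataset",
    "save_dataset",
    "load_dataset",
]

STRENGTH_NAMES = ("LatAssoc", "LongAssoc", "LatAngle", "LongAngle", "QuadAngles")

#: strength parameters exposed as input features (4 of the 5; QuadAngles is
#: tied to LatAngle in the feature vector so X stays n x 10)
FEATURE_COEFFICIENTS = ("LatAssoc", "LongAssoc", "LatAngle", "LongAngle")

#: the full-protocol strength grid, swept as a Cartesian product over all
#: five parameters (7^5 combinations)
STRENGTH_GRID = (3.0, 9.0, 18.0, 30.0, 39.0, 48.0, 57.0)


@dataclass(frozen=True)
class InteractionParams:
    """Strength parameter of each interaction family."""

    strengths: dict[str, float]

    def __post_init__(self):
        missing = set(STRENGTH_NAMES) - set(self.strengths)
        if missing:
            raise ValueError(f"missing strength parameters: {sorted(missing)}")
        if any(v <= 0 for v in self.strengths.values()):
            raise ValueError("all strengths must be positive")

    @classmethod
    def uniform(cls, value: float) -> "InteractionParams":
        return cls({name: float(value) for name in STRENGTH_NAMES})

    def feature_vector(self) -> np.ndarray:
        return np.array([self.strengths[n] for n in FEATURE_COEFFICIENTS])


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol constants of one bending-load run.

    ``clamped_nodes`` / ``forced_nodes`` default to the first / last two rings
    of the tube spec when built through :func:`config_for_spec`.
    """

    timestep: float = 0.01
    ramp_steps: int = 128000
    hold_steps: int = 256000
    save_interval: int = 32000
    max_force: float = 5.0  # applied along -y to each forced node
    temperature: float = 1e-4
    damping: float = 0.5
    mass: float = 1.0
    seed: int = 0
    clamped_nodes: tuple[int, ...] = ()
    forced_nodes: tuple[int, ...] = ()

    def __post_init__(self):
        if (self.ramp_steps + self.hold_steps) % self.save_interval != 0:
            raise ValueError("save_interval must divide ramp_steps + hold_steps")
        if set(self.clamped_nodes) & set(self.forced_nodes):
            raise ValueError("clamped and forced node sets must be disjoint")

    @property
    def total_steps(self) -> int:
        return self.ramp_steps + self.hold_steps

    @property
    def frames_per_run(self) -> int:
        return self.total_steps // self.save_interval


def config_for_spec(spec: TubeSpec, **overrides) -> SimulationConfig:
    """Config whose boundary conditions clamp/load the first/last two rings."""
    k = spec.k_per_turn
    clamped = tuple(range(0, 2 * k))
    forced = tuple(range((spec.n_rings - 2) * k, spec.n_rings * k))
    return SimulationConfig(clamped_nodes=clamped, forced_nodes=forced, **overrides)


def full_protocol(spec: TubeSpec = TubeSpec(48, 13, 3)) -> SimulationConfig:
    """The full-scale protocol step counts: 128000-step ramp, 256000-step
    hold, one saved frame every 32000 steps (12 frames per run)."""
    return config_for_spec(
        spec, ramp_steps=128000, hold_steps=256000, save_interval=32000
    )


def desk_config(spec: TubeSpec, **overrides) -> SimulationConfig:
    """Desk-scale protocol: short ramp/hold, still 12 frames per run."""
    kw = dict(ramp_steps=1500, hold_steps=1500, save_interval=250)
    kw.update(overrides)
    return config_for_spec(spec, **kw)


def desk_geometry(n_rings: int = 12) -> LatticeGeometry:
    """Reduced 13-protofilament tube (default 12 rings, 156 monomers)."""
    return build_lattice_geometry(TubeSpec(n_rings, 13, 3))


@dataclass
class FrameRecord:
    """One saved frame: features X (n x 10), targets y (n x 1), metadata."""

    X: np.ndarray
    y: np.ndarray
    step: int
    run_id: str = ""
    forces: np.ndarray | None = None
    total_energy: float = 0.0


@dataclass
class Dataset:
    """Concatenated frames across runs: X (frames, n, 10), y (frames, n, 1)."""

    X: np.ndarray
    y: np.ndarray
    manifest: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# compiled interaction tables
# ---------------------------------------------------------------------------


class _CompiledGeometry:
    """Index arrays for vectorized energy/force evaluation."""

    def __init__(self, geom: LatticeGeometry):
        self.n = geom.node_count
        self.bond_idx = np.array([(i, j) for i, j, _ in geom.bonds], dtype=int).reshape(-1, 2)
        self.bond_types = [t for _, _, t in geom.bonds]
        self.bond_b0 = np.array([geom.resting_lengths[t] for t in self.bond_types])
        self.angle_idx = np.array(
            [(i, j, k) for i, j, k, _ in geom.angles], dtype=int
        ).reshape(-1, 3)
        self.angle_types = [t for *_, t in geom.angles]
        self.angle_phi0 = np.deg2rad(np.array([geom.resting_angles[t] for t in self.angle_types]))
        self.bond_strength_key = [STRENGTH_OF_TYPE.get(t, t) for t in self.bond_types]
        self.angle_strength_key = [STRENGTH_OF_TYPE.get(t, t) for t in self.angle_types]

    def strengths(self, params: InteractionParams) -> tuple[np.ndarray, np.ndarray]:
        bond_L = np.array([params.strengths[k] for k in self.bond_strength_key])
        angle_L = np.array([params.strengths[k] for k in self.angle_strength_key])
        return bond_L, angle_L


def _compiled(geom: LatticeGeometry) -> _CompiledGeometry:
    comp = getattr(geom, "_compiled_cache", None)
    if comp is None:
        comp = _CompiledGeometry(geom)
        geom._compiled_cache = comp
    return comp


def _angle_terms(positions: np.ndarray, comp: _CompiledGeometry):
    """Angle values and the unit-consistent geometry needed for their forces."""
    i, j, k = comp.angle_idx.T
    u = positions[i] - positions[j]
    v = positions[k] - positions[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise FloatingPointError("degenerate angle: zero-length arm")
    cosphi = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    phi = np.arccos(cosphi)
    return u, v, nu, nv, cosphi, phi


def potential_energy(
    geom: LatticeGeometry, positions: np.ndarray, params: InteractionParams
) -> tuple[float, np.ndarray]:
    """Total harmonic lattice energy and its per-node attribution.

    Bond energy ``L (r - b0)^2`` is split half/half between the endpoints;
    angle energy ``L (phi - phi0)^2`` one third to each participant, so the
    per-node vector sums exactly to the total.
    """
    comp = _compiled(geom)
    positions = np.asarray(positions, dtype=float).reshape(comp.n, 3)
    bond_L, angle_L = comp.strengths(params)
    per_node = np.zeros(comp.n)

    if len(comp.bond_idx):
        d = positions[comp.bond_idx[:, 0]] - positions[comp.bond_idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        e_bond = bond_L * (r - comp.bond_b0) ** 2
        np.add.at(per_node, comp.bond_idx[:, 0], 0.5 * e_bond)
        np.add.at(per_node, comp.bond_idx[:, 1], 0.5 * e_bond)
    if len(comp.angle_idx):
        *_, phi = _angle_terms(positions, comp)
        e_angle = angle_L * (phi - comp.angle_phi0) ** 2
        for col in range(3):
            np.add.at(per_node, comp.angle_idx[:, col], e_angle / 3.0)
    return float(per_node.sum()), per_node


def forces(
    geom: LatticeGeometry, positions: np.ndarray, params: InteractionParams
) -> np.ndarray:
    """Analytic forces ``-dE/dx`` of the harmonic lattice energy."""
    comp = _compiled(geom)
    positions = np.asarray(positions, dtype=float).reshape(comp.n, 3)
    bond_L, angle_L = comp.strengths(params)
    F = np.zeros_like(positions)

    if len(comp.bond_idx):
        i, j = comp.bond_idx.T
        d = positions[i] - positions[j]
        r = np.linalg.norm(d, axis=1)
        # dE/dr = 2 L (r - b0); force along the bond axis
        fmag = -2.0 * bond_L * (r - comp.bond_b0)
        fvec = (fmag / r)[:, None] * d
        np.add.at(F, i, fvec)
        np.add.at(F, j, -fvec)
    if len(comp.angle_idx):
        i, j, k = comp.angle_idx.T
        u, v, nu, nv, cosphi, phi = _angle_terms(positions, comp)
        sinphi = np.sqrt(np.maximum(1.0 - cosphi**2, 1e-14))
        dEdphi = 2.0 * angle_L * (phi - comp.angle_phi0)
        # dphi/du = -(1/sin) (v/(|u||v|) - cos u/|u|^2), same with u<->v for dphi/dv
        inv = -1.0 / sinphi
        dphi_du = inv[:, None] * (v / (nu * nv)[:, None] - (cosphi / nu**2)[:, None] * u)
        dphi_dv = inv[:, None] * (u / (nu * nv)[:, None] - (cosphi / nv**2)[:, None] * v)
        np.add.at(F, i, -dEdphi[:, None] * dphi_du)
        np.add.at(F, k, -dEdphi[:, None] * dphi_dv)
        np.add.at(F, j, dEdphi[:, None] * (dphi_du + dphi_dv))
    return F


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    positions: np.ndarray
    velocities: np.ndarray
    step: int = 0


def _external_force(config: SimulationConfig, step: int, n: int) -> np.ndarray:
    """-y load on the forced nodes, ramped linearly then held at max_force."""
    F = np.zeros((n, 3))
    if config.forced_nodes:
        ramp = 1.0 if config.ramp_steps == 0 else min(step / config.ramp_steps, 1.0)
        F[list(config.forced_nodes), 1] = -config.max_force * ramp
    return F


def step_langevin(
    state: SimState,
    geom: LatticeGeometry,
    params: InteractionParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimState:
    """One BAOAB Langevin velocity-Verlet step.

    With zero damping and temperature this reduces to plain velocity Verlet;
    clamped nodes are pinned (zero velocity, fixed position) throughout.
    """
    dt, m = config.timestep, config.mass
    x = state.positions.copy()
    v = state.velocities.copy()
    clamped = list(config.clamped_nodes)

    def total_force(x, step):
        return forces(geom, x, params) + _external_force(config, step, x.shape[0])

    F = total_force(x, state.step)
    v += 0.5 * dt * F / m                      # B
    x += 0.5 * dt * v                          # A
    if config.damping > 0:                     # O (Ornstein-Uhlenbeck kick)
        c1 = np.exp(-config.damping * dt)
        c2 = np.sqrt(config.temperature / m * max(1.0 - c1**2, 0.0))
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x += 0.5 * dt * v                          # A
    if clamped:
        x[clamped] = state.positions[clamped]
        v[clamped] = 0.0
    F = total_force(x, state.step + 1)
    v += 0.5 * dt * F / m                      # B
    if clamped:
        v[clamped] = 0.0
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise FloatingPointError(
            f"non-finite state at step {state.step + 1}; reduce timestep or load"
        )
    return SimState(positions=x, velocities=v, step=state.step + 1)


def run_simulation(
    geom: LatticeGeometry,
    params: InteractionParams,
    config: SimulationConfig,
    run_id: str = "",
) -> list[FrameRecord]:
    """Ramp-then-hold bending run; returns one FrameRecord per save interval."""
    rng = np.random.default_rng(config.seed)
    state = SimState(
        positions=geom.coordinates.copy(),
        velocities=np.zeros_like(geom.coordinates),
    )
    coeffs = np.tile(params.feature_vector(), (geom.node_count, 1))
    frames: list[FrameRecord] = []
    for _ in range(config.total_steps):
        state = step_langevin(state, geom, params, config, rng)
        if state.step % config.save_interval == 0:
            total, per_node = potential_energy(geom, state.positions, params)
            X = np.hstack([state.positions, state.velocities, coeffs])
            frames.append(
                FrameRecord(
                    X=X,
                    y=per_node[:, None],
                    step=state.step,
                    run_id=run_id,
                    forces=forces(geom, state.positions, params)
                    + _external_force(config, state.step, geom.node_count),
                    total_energy=total,
                )
            )
    return frames


def generate_dataset(
    geom: LatticeGeometry,
    config: SimulationConfig,
    grid: dict[str, list[float]] | None = None,
) -> Dataset:
    """Sweep the strength-parameter grid; one run per Cartesian combination.

    ``grid`` maps each of the five strength names to its value list (the full
    protocol uses seven values per parameter, 7^5 runs; desk-scale presets use
    two or three).  Failed runs are logged in the manifest and skipped.
    """
    if grid is None:
        grid = {name: list(STRENGTH_GRID) for name in STRENGTH_NAMES}
    names = list(STRENGTH_NAMES)
    X_parts, y_parts, manifest = [], [], []
    for combo in itertools.product(*(grid[n] for n in names)):
        params = InteractionParams(dict(zip(names, combo)))
        run_id = "run_" + "_".join(f"{v:g}" for v in combo)
        entry = {"run_id": run_id, **dict(zip(names, map(float, combo)))}
        try:
            frames = run_simulation(geom, params, config, run_id=run_id)
        except FloatingPointError as exc:
            entry.update(status="failed", error=str(exc))
            manifest.append(entry)
            continue
        entry.update(status="ok", n_frames=len(frames))
        manifest.append(entry)
        X_parts.extend(f.X for f in frames)
        y_parts.extend(f.y for f in frames)
    if not X_parts:
        raise RuntimeError("every simulation run failed")
    return Dataset(X=np.stack(X_parts), y=np.stack(y_parts), manifest=manifest)


def desk_dataset(
    n_rings: int = 12,
    values: tuple[float, ...] = (3.0, 57.0),
    seed: int = 0,
    **config_overrides,
) -> Dataset:
    """Desk-scale dataset: reduced tube, 2-3 values per strength parameter."""
    geom = desk_geometry(n_rings)
    config = desk_config(geom.spec, seed=seed, **config_overrides)
    grid = {name: list(values) for name in STRENGTH_NAMES}
    return generate_dataset(geom, config, grid)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=dataset.X)
        fh.create_dataset("y", data=dataset.y)
        fh.attrs["manifest"] = json.dumps(dataset.manifest)


def load_dataset(path: str | Path) -> Dataset:
    import h5py

    with h5py.File(path, "r") as fh:
        return Dataset(
            X=fh["X"][...],
            y=fh["y"][...],
            manifest=json.loads(fh.attrs.get("manifest", "[]")),
        )
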