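"""Langevin NVT dynamics with the built-in BAOAB integrator.

The integrator is the symmetric splitting B-A-O-A-B (half kick, half
drift, Ornstein-Uhlenbeck velocity refresh, half drift, half kick),
which samples the canonical ensemble accurately even at the long time
steps coarse-grained potentials allow.  Default protocol: friction
0.01 1/ps, 298 K, 10 fs equilibration and 20 fs production time steps.
Trajectories are fully reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .energy import NEIGHBOR_SKIN, OverlappingBeadsError, SystemState

__all__ = ["RunConfig", "Trajectory", "run_langevin", "minimize_then_equilibrate",
           "minimize", "SimulationBlowupError"]


class SimulationBlowupError(RuntimeError):
    """Raised when the dynamics produce non-finite coordinates or energies."""

    def __init__(self, step: int):
        super().__init__(f"numerical blow-up at step {step}")
        self.step = step


@dataclass
class RunConfig:
    temperature: float = 298.0  # K
    friction: float = 0.01  # 1/ps
    dt_equil: float = 10.0  # fs
    dt_prod: float = 20.0  # fs
    n_equil_steps: int = 5000
    n_prod_steps: int = 100_000
    seed: int = 0
    report_interval: int = 1000
    trajectory_path: str | None = None

    def __post_init__(self):
        if self.friction < 0 or (self.friction == 0 and self.temperature > 0):
            raise ValueError("friction must be positive (zero allowed only "
                             "for zero-temperature energy-conservation runs)")
        if self.dt_prod <= 0 or self.dt_equil <= 0:
            raise ValueError("time steps must be positive")


@dataclass
class Trajectory:
    """In-memory trajectory: frames plus scalar time series."""

    frames: list[np.ndarray] = field(default_factory=list)
    steps: list[int] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    potential: list[float] = field(default_factory=list)
    kinetic: list[float] = field(default_factory=list)
    box: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        return np.array(self.frames)

    def scalars(self):
        import pandas as pd
        return pd.DataFrame({"step": self.steps, "temperature": self.temperature,
                             "potential": self.potential, "kinetic": self.kinetic})


def _instant_temperature(vel: np.ndarray, mass: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(mass[:, None] * vel * vel))
    ndof = 3 * vel.shape[0]
    return 2.0 * ke / (ndof * KB), ke


def run_langevin(state: SystemState, run: RunConfig,
                 dt_fs: float | None = None,
                 velocities: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> tuple[Trajectory, SystemState]:
    """Integrate Langevin dynamics for ``run.n_prod_steps`` steps.

    Returns the recorded trajectory and the final state.  ``dt_fs``
    overrides the production time step (used internally for the
    equilibration stage).  Velocities default to a Maxwell-Boltzmann
    draw at the run temperature.
    """
    model = state.model()
    mass = model.mass
    n = state.topology.n_beads
    dt = (dt_fs if dt_fs is not None else run.dt_prod) * 1e-3  # fs -> ps
    gamma = run.friction
    kT = KB * run.temperature
    if rng is None:
        rng = np.random.default_rng(run.seed)

    x = state.coordinates.copy()
    if velocities is None:
        if run.temperature > 0:
            v = rng.normal(size=(n, 3)) * np.sqrt(kT / mass)[:, None]
        else:
            v = np.zeros((n, 3))
    else:
        v = velocities.copy()

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sqrt_kT_m = np.sqrt(kT / mass)[:, None] if run.temperature > 0 else 0.0

    pairs = model.build_pair_list(x, state.box)
    x_ref = x.copy()
    try:
        breakdown, f = model.evaluate(x, state.box, pairs=pairs)
    except OverlappingBeadsError as err:
        raise SimulationBlowupError(0) from err

    traj = Trajectory(box=state.box.copy(), seed=run.seed)

    def record(step):
        t_inst, ke = _instant_temperature(v, mass)
        e_pot = breakdown.total
        if not (np.isfinite(e_pot) and np.all(np.isfinite(x))):
            raise SimulationBlowupError(step)
        traj.frames.append(x.copy())
        traj.steps.append(step)
        traj.temperature.append(t_inst)
        traj.potential.append(e_pot)
        traj.kinetic.append(ke)

    half = 0.5 * dt
    inv_m = (1.0 / mass)[:, None]
    for step in range(1, run.n_prod_steps + 1):
        v += half * f * inv_m
        x += half * v
        if run.temperature > 0:
            v = c1 * v + c2 * sqrt_kT_m * rng.normal(size=(n, 3))
        else:
            v = c1 * v
        x += half * v
        # neighbor list refresh when any bead moved more than half the skin
        disp2 = np.max(np.sum((x - x_ref) ** 2, axis=1))
        if not np.isfinite(disp2):
            raise SimulationBlowupError(step)
        if disp2 > (0.5 * NEIGHBOR_SKIN) ** 2:
            pairs = model.build_pair_list(x, state.box)
            x_ref = x.copy()
        try:
            breakdown, f = model.evaluate(x, state.box, pairs=pairs)
        except OverlappingBeadsError as err:
            raise SimulationBlowupError(step) from err
        v += half * f * inv_m
        if step % run.report_interval == 0 or step == run.n_prod_steps:
            record(step)

    final = SystemState(coordinates=x, box=state.box.copy(),
                        topology=state.topology, params=state.params)
    final.velocities = v
    if run.trajectory_path:
        from .io import write_dcd
        write_dcd(run.trajectory_path, traj)
    return traj, final


def minimize(state: SystemState, max_iter: int = 500,
             force_tol: float = 10.0) -> SystemState:
    """Steepest-descent energy minimization with adaptive step size."""
    model = state.model()
    x = state.coordinates.copy()
    breakdown, f = model.evaluate(x, state.box)
    e = breakdown.total
    step = 0.01  # nm per unit normalized force
    for _ in range(max_iter):
        fmax = np.max(np.abs(f))
        if fmax < force_tol:
            break
        trial = x + step * f / max(fmax, 1e-12)
        try:
            b_t, f_t = model.evaluate(trial, state.box)
            ok = np.isfinite(b_t.total)
        except Exception:
            ok = False
        if ok and b_t.total < e:
            x, f, e = trial, f_t, b_t.total
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return SystemState(coordinates=x, box=state.box.copy(),
                       topology=state.topology, params=state.params)


def minimize_then_equilibrate(state: SystemState, run: RunConfig) -> SystemState:
    """Prepare a configuration for production dynamics.

    Steepest-descent minimization removes bead overlaps, followed by
    ``run.n_equil_steps`` of Langevin dynamics at the equilibration
    time step.  Raises if overlaps persist (any nonbonded pair closer
    than 0.2 sigma_ij).
    """
    relaxed = minimize(state)
    if run.n_equil_steps > 0:
        equil = RunConfig(**{**run.__dict__, "n_prod_steps": run.n_equil_steps,
                             "report_interval": max(1, run.n_equil_steps),
                             "trajectory_path": None})
        _, relaxed = run_langevin(relaxed, equil, dt_fs=run.dt_equil)
    model = relaxed.model()
    pairs = model.build_pair_list(relaxed.coordinates, relaxed.box)
    if len(pairs):
        d = relaxed.coordinates[pairs[:, 0]] - relaxed.coordinates[pairs[:, 1]]
        d -= relaxed.box * np.round(d / relaxed.box)
        r = np.linalg.norm(d, axis=1)
        sij = 0.5 * (model.sigma[pairs[:, 0]] + model.sigma[pairs[:, 1]])
        if np.any(r < 0.2 * sij):
            raise RuntimeError("persistent bead overlap after minimization")
    return relaxed
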