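"""Reference integrators and sampling protocols.

* Langevin dynamics with the BAOAB splitting ("Langevin middle"
  discretization: half kick, half drift, full Ornstein-Uhlenbeck friction
  step, half drift, half kick). With friction -> 0 the scheme reduces
  exactly to velocity Verlet, which is how the NVE limit is exercised.
* A single-chain Nose-Hoover thermostat; the "collision frequency" nu of
  the protocol maps to the thermostat relaxation time tau = 1/nu through
  the chain mass Q = g kB T tau^2.
* Energy minimization (steepest descent with backtracking, monotone by
  construction).
* NPT compression with a Monte Carlo barostat: isotropic log-volume moves
  scaling molecule centers of mass, Metropolis acceptance on
  dU + P dV - N kB T ln(V'/V) with N the molecule count.
* Temperature replica exchange with alternating even/odd neighbor pairs,
  Metropolis acceptance min(1, exp[(beta_i - beta_j)(E_i - E_j)]) on
  potential energies, and velocity rescaling by sqrt(T_new/T_old) on
  accepted swaps.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .units import KB
from .energetics import (Box, SystemState, CompiledSystem, ENERGY_ABORT,
                         make_force_callable, compute_energy_forces)
from .trajectory import TrajectoryHandle

#: 1 bar in kJ/mol/nm^3.
BAR_TO_KJ_MOL_NM3 = 0.0602214076

ForceFn = Callable[[np.ndarray], tuple[float, np.ndarray]]


class SimulationDiverged(RuntimeError):
    pass


@dataclass
class ThermostatSpec:
    kind: str = "langevin_middle"  # langevin_middle | nose_hoover
    temperature: float = 300.0     # K
    friction_or_collision: float = 1.0  # ps^-1
    timestep: float = 0.01         # ps
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("langevin_middle", "nose_hoover"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.timestep <= 0 or self.temperature <= 0:
            raise ValueError("timestep and temperature must be positive")


@dataclass
class BarostatSpec:
    pressure: float = 1.0            # bar
    move_interval: int = 25          # steps between volume moves
    max_log_volume_step: float = 0.02
    attempted: int = 0
    accepted: int = 0

    @property
    def acceptance(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0


@dataclass
class RemdSpec:
    ladder: tuple[float, ...]
    exchange_interval: int = 1000
    seed: int = 0
    attempted: np.ndarray = field(default=None)  # per neighbor pair
    accepted: np.ndarray = field(default=None)
    exchange_log: list = field(default_factory=list)
    replica_at_temp: list = field(default_factory=list)

    def __post_init__(self):
        ladder = tuple(float(t) for t in self.ladder)
        if len(ladder) < 2:
            raise ValueError("REMD ladder needs at least 2 temperatures")
        if any(b < a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("REMD ladder must be non-decreasing")
        self.ladder = ladder
        n = len(ladder) - 1
        if self.attempted is None:
            self.attempted = np.zeros(n, dtype=int)
        if self.accepted is None:
            self.accepted = np.zeros(n, dtype=int)

    @property
    def acceptance_ratios(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempted > 0,
                            self.accepted / np.maximum(self.attempted, 1), np.nan)


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * velocities ** 2))


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """2 KE / (3 N kB)."""
    n = len(masses)
    return 2.0 * kinetic_energy(velocities, masses) / (3.0 * n * KB)


def draw_maxwell_boltzmann(masses: np.ndarray, temperature: float,
                           rng: np.random.Generator) -> np.ndarray:
    sd = np.sqrt(KB * temperature / masses)[:, None]
    return rng.normal(size=(len(masses), 3)) * sd


# ---------------------------------------------------------------------------
# integrator cores
# ---------------------------------------------------------------------------

class _Baoab:
    """BAOAB Langevin stepper; gamma = 0 reduces to velocity Verlet."""

    def __init__(self, masses, dt, gamma, rng):
        self.m = masses[:, None]
        self.dt = dt
        self.gamma = gamma
        self.rng = rng
        self.c1 = np.exp(-gamma * dt) if gamma > 0 else 1.0
        self.c2 = np.sqrt(1.0 - self.c1 ** 2)

    def step(self, x, v, force, force_fn: ForceFn, kT: float):
        dt, m = self.dt, self.m
        v = v + 0.5 * dt * force / m
        x = x + 0.5 * dt * v
        if self.gamma > 0:
            sd = np.sqrt(kT / m)
            v = self.c1 * v + self.c2 * sd * self.rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v
        e, force = force_fn(x)
        v = v + 0.5 * dt * force / m
        return x, v, force, e


class _NoseHoover:
    """Single-chain Nose-Hoover thermostat around velocity Verlet."""

    def __init__(self, masses, dt, collision_freq, rng=None):
        self.m = masses[:, None]
        self.dt = dt
        self.tau = 1.0 / collision_freq
        self.g = 3 * len(masses)
        self.xi = 0.0  # thermostat velocity

    def _thermo_half(self, v, kT):
        Q = self.g * kT * self.tau ** 2
        dt4 = 0.25 * self.dt
        ke2 = float(np.sum(self.m * v ** 2))
        self.xi += dt4 * (ke2 - self.g * kT) / Q
        v = v * np.exp(-self.xi * 0.5 * self.dt)
        ke2 = float(np.sum(self.m * v ** 2))
        self.xi += dt4 * (ke2 - self.g * kT) / Q
        return v

    def step(self, x, v, force, force_fn: ForceFn, kT: float):
        dt, m = self.dt, self.m
        v = self._thermo_half(v, kT)
        v = v + 0.5 * dt * force / m
        x = x + dt * v
        e, force = force_fn(x)
        v = v + 0.5 * dt * force / m
        v = self._thermo_half(v, kT)
        return x, v, force, e


def _make_stepper(kind: str, masses, dt, coupling, rng):
    if kind == "langevin_middle":
        return _Baoab(masses, dt, coupling, rng)
    return _NoseHoover(masses, dt, coupling)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def run_md(topology, assignment, state: SystemState,
           thermostat: ThermostatSpec, n_steps: int,
           temperature_schedule: Optional[np.ndarray] = None,
           traj_stride: int = 10_000, energy_stride: int = 1_000,
           force_fn: Optional[ForceFn] = None,
           observer: Optional[Callable] = None,
           ) -> tuple[SystemState, TrajectoryHandle]:
    """Constant-volume MD with the chosen thermostat.

    ``temperature_schedule`` (length ``n_steps``) overrides the thermostat
    target per step, which is how annealing protocols are expressed.
    ``observer(step, positions, velocities, energy)`` is invoked every
    ``energy_stride`` steps. Deterministic for a fixed ``thermostat.seed``.
    """
    masses = topology.masses if hasattr(topology, "masses") else None
    if force_fn is None:
        force_fn = make_force_callable(topology, assignment, state.box)
    if temperature_schedule is not None:
        temperature_schedule = np.asarray(temperature_schedule, dtype=float)
        if len(temperature_schedule) != n_steps:
            raise ValueError("temperature schedule length must equal n_steps")
    rng = np.random.default_rng(thermostat.seed)
    stepper = _make_stepper(thermostat.kind, masses, thermostat.timestep,
                            thermostat.friction_or_collision, rng)
    traj = TrajectoryHandle.new(provenance=assignment.provenance,
                                seed=thermostat.seed,
                                extra={"thermostat": thermostat.kind,
                                       "timestep_ps": thermostat.timestep})
    x = state.positions.copy()
    v = state.velocities.copy()
    e, force = force_fn(x)
    t = state.time
    for step in range(n_steps):
        T = (temperature_schedule[step] if temperature_schedule is not None
             else thermostat.temperature)
        x, v, force, e = stepper.step(x, v, force, force_fn, KB * T)
        t += thermostat.timestep
        if energy_stride and (step + 1) % energy_stride == 0:
            if not np.isfinite(e) or abs(e) > ENERGY_ABORT:
                raise SimulationDiverged(
                    f"potential energy {e:.3e} kJ/mol at step {step + 1}")
            if observer is not None:
                observer(step + 1, x, v, e)
        if traj_stride and (step + 1) % traj_stride == 0:
            traj.append(x, state.box, t)
    return SystemState(x, v, state.box, t), traj


def minimize(topology, assignment, state: SystemState,
             tolerance: float = 10.0, max_iter: int = 10_000,
             force_fn: Optional[ForceFn] = None) -> SystemState:
    """Steepest descent with backtracking; energy never increases.

    Terminates when the largest force component falls below ``tolerance``
    (kJ/mol/nm) or after ``max_iter`` accepted steps.
    """
    if force_fn is None:
        force_fn = make_force_callable(topology, assignment, state.box)
    x = state.positions.copy()
    e, f = force_fn(x)
    if not np.isfinite(e):
        raise SimulationDiverged("non-finite energy at minimization start")
    alpha = 1e-4
    for _ in range(max_iter):
        fmax = np.abs(f).max()
        if fmax < tolerance:
            break
        while True:
            x_new = x + alpha * f / max(fmax, 1.0)
            e_new, f_new = force_fn(x_new)
            if np.isfinite(e_new) and e_new <= e:
                x, e, f = x_new, e_new, f_new
                alpha = min(alpha * 1.5, 0.5)
                break
            alpha *= 0.5
            if alpha < 1e-14:
                return SystemState(x, state.velocities.copy(), state.box,
                                   state.time)
    return SystemState(x, state.velocities.copy(), state.box, state.time)


def npt_compress(topology, assignment, state: SystemState,
                 barostat: BarostatSpec, thermostat: ThermostatSpec,
                 n_steps: int, seed: Optional[int] = None) -> SystemState:
    """NPT with a Monte Carlo barostat (isotropic, cubic boxes).

    Every ``move_interval`` MD steps a log-volume move is attempted:
    molecule centers of mass are scaled, intramolecular geometry is kept
    rigid, and the move is accepted with probability
    min(1, exp(-beta [dU + P dV - N kB T ln(V'/V)])) where N counts
    molecules. Moves that produce divergent overlaps are rejected.
    """
    from .energetics import OverlapError
    if len(set(state.box.lengths)) != 1:
        raise ValueError("npt_compress requires a cubic box")
    rng = np.random.default_rng(thermostat.seed + 7919 if seed is None else seed)
    cs = CompiledSystem(topology, assignment)
    n_mol = cs.topology.n_molecules
    mol_of = cs.topology.molecule_of_bead
    P = barostat.pressure * BAR_TO_KJ_MOL_NM3
    kT = KB * thermostat.temperature
    box = state.box
    x, v, t = state.positions.copy(), state.velocities.copy(), state.time

    def potential(pos, b):
        st = SystemState(pos, np.zeros_like(pos), b)
        bd, _ = compute_energy_forces(None, None, st, method="brute", compiled=cs)
        return bd.total

    steps_done = 0
    while steps_done < n_steps:
        chunk = min(barostat.move_interval, n_steps - steps_done)
        seg = SystemState(x, v, box, t)
        fn = make_force_callable(topology, assignment, box)
        seg, _ = run_md(cs.topology, assignment, seg, thermostat, chunk,
                        traj_stride=0, force_fn=fn)
        x, v, t = seg.positions, seg.velocities, seg.time
        steps_done += chunk
        if steps_done >= n_steps:
            break
        # volume move
        barostat.attempted += 1
        V = box.volume
        lnV_new = np.log(V) + rng.uniform(-1, 1) * barostat.max_log_volume_step
        V_new = np.exp(lnV_new)
        s = (V_new / V) ** (1.0 / 3.0)
        box_new = Box.cubic(box.lengths[0] * s)
        x_new = x.copy()
        for _, mi, (lo, hi) in cs.topology.iter_copies():
            com = np.average(x[lo:hi], axis=0, weights=cs.masses[lo:hi])
            x_new[lo:hi] = x[lo:hi] + (s - 1.0) * com
        try:
            u_old = potential(x, box)
            u_new = potential(x_new, box_new)
        except OverlapError:
            continue
        dU = u_new - u_old
        arg = -(dU + P * (V_new - V) - n_mol * kT * np.log(V_new / V)) / kT
        if np.log(rng.uniform()) < arg:
            barostat.accepted += 1
            x, box = x_new, box_new
    return SystemState(x, v, box, t)


def run_remd(topology, assignment, states: Sequence[SystemState],
             remd: RemdSpec, thermostat_kind: str = "langevin_middle",
             n_steps: int = 10_000, timestep: float = 0.01,
             friction: float = 1.0, traj_stride: int = 0,
             force_fn: Optional[ForceFn] = None,
             ) -> tuple[list[TrajectoryHandle], RemdSpec]:
    """Temperature replica exchange.

    One state per ladder temperature; exchanges between neighboring
    temperature slots are attempted every ``exchange_interval`` steps,
    alternating even (0-1, 2-3, ...) and odd (1-2, 3-4, ...) pairs.
    """
    ladder = remd.ladder
    if len(states) != len(ladder):
        raise ValueError("need one initial state per ladder temperature")
    if force_fn is None:
        force_fn = make_force_callable(topology, assignment, states[0].box)
    masses = topology.masses
    rng = np.random.default_rng(remd.seed)
    reps = [s.copy() for s in states]
    replica_id = list(range(len(ladder)))  # which walker sits at each temp slot
    tag = assignment.provenance if assignment is not None else "custom-force"
    trajs = [TrajectoryHandle.new(provenance=tag, seed=remd.seed,
                                  extra={"temperature_K": T})
             for T in ladder]
    steppers = [
        _make_stepper(thermostat_kind, masses, timestep, friction,
                      np.random.default_rng(remd.seed + 1000 + k))
        for k in range(len(ladder))]
    energies = np.zeros(len(ladder))
    forces = []
    for k, s in enumerate(reps):
        e, f = force_fn(s.positions)
        energies[k] = e
        forces.append(f)

    n_rounds = n_steps // remd.exchange_interval
    attempt_parity = 0
    step_count = 0
    for rnd in range(n_rounds):
        for k, s in enumerate(reps):
            x, v, frc = s.positions, s.velocities, forces[k]
            kT = KB * ladder[k]
            e = energies[k]
            for _ in range(remd.exchange_interval):
                x, v, frc, e = steppers[k].step(x, v, frc, force_fn, kT)
            reps[k] = SystemState(x, v, s.box, s.time
                                  + remd.exchange_interval * timestep)
            energies[k] = e
            forces[k] = frc
            if traj_stride:
                trajs[k].append(x, s.box, reps[k].time)
        step_count += remd.exchange_interval
        # exchange attempts, alternating parity
        for i in range(attempt_parity, len(ladder) - 1, 2):
            j = i + 1
            beta_i = 1.0 / (KB * ladder[i])
            beta_j = 1.0 / (KB * ladder[j])
            delta = (beta_i - beta_j) * (energies[i] - energies[j])
            accept = delta >= 0 or rng.uniform() < np.exp(delta)
            remd.attempted[i] += 1
            if accept:
                remd.accepted[i] += 1
                reps[i], reps[j] = reps[j], reps[i]
                energies[i], energies[j] = energies[j], energies[i]
                forces[i], forces[j] = forces[j], forces[i]
                reps[i].velocities *= np.sqrt(ladder[i] / ladder[j])
                reps[j].velocities *= np.sqrt(ladder[j] / ladder[i])
                replica_id[i], replica_id[j] = replica_id[j], replica_id[i]
            remd.exchange_log.append(
                {"step": step_count, "pair": (i, j), "delta": float(delta),
                 "accepted": bool(accept)})
        remd.replica_at_temp.append(tuple(replica_id))
        attempt_parity = 1 - attempt_parity
    return trajs, remd


def export_exchange_log(remd: RemdSpec, path) -> None:
    """Columnar text log of every exchange attempt."""
    import pandas as pd
    pd.DataFrame(remd.exchange_log).to_csv(path, sep="\t", index=False)
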