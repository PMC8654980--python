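"""Langevin dynamics over the Cα-bead topology with switched restraints.

The integrator is BAOAB Langevin; with friction set to zero it reduces to
velocity Verlet, which the energy-conservation tests exploit. The cross-link
restraint schedule re-draws ``n_active`` restraint indices (uniformly,
without replacement) every ``tau_xl`` picoseconds from a stream derived from
the run seed, so a run is fully reproducible from (topology, params, config,
seed).

Internal units: Å, ps, Da; energies converted from kcal/mol via
``KCAL_TO_INTERNAL`` (1 kcal/mol = 418.4 Da·Å²/ps²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .forcefield import (CGTopology, ForceFieldParams, RestraintSpec,
                         KBOLTZ, KCAL_TO_INTERNAL, total_energy_forces)

__all__ = [
    "SimulationConfig",
    "Ensemble",
    "RestraintSchedule",
    "frame_schedule",
    "restraint_schedule",
    "initialize_flexible",
    "run",
]


class DivergenceError(RuntimeError):
    """Integration produced a non-finite state."""


@dataclass
class SimulationConfig:
    """Engine settings; time quantities in ps, temperature in K, mass in Da."""

    timestep: float = 0.01
    temperature: float = 300.0
    friction: float = 1.0          # ps⁻¹; 0 gives the velocity-Verlet limit
    mass: float = 110.0            # Da per bead
    total_time: float = 1000.0
    save_interval: float = 100.0
    seed: int = 0
    restraints: list[RestraintSpec] = field(default_factory=list)
    frozen_core: bool = False      # hold rigid beads fixed at reference

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        steps = self.save_interval / self.timestep
        if self.save_interval <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ValueError("save_interval must be a positive multiple of timestep")


@dataclass
class Ensemble:
    """Ordered conformations with optional normalized per-frame weights."""

    frames: np.ndarray             # (F, N, 3) Å
    times: np.ndarray              # (F,) ps
    weights: np.ndarray | None = None
    energies: np.ndarray | None = None      # per-frame potential, kcal/mol
    temperatures: np.ndarray | None = None  # per-frame kinetic T, K

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or len(self.frames) != len(self.times):
            raise ValueError("frames must be (F, N, 3) matching times")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def effective_weights(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        return np.full(self.n_frames, 1.0 / self.n_frames)


@dataclass
class RestraintSchedule:
    """Contiguous epochs of active restraint indices (1-based ids)."""

    epoch_starts: np.ndarray       # (E,) ps
    active: np.ndarray             # (E, n_active) int ids in [1, n_xl]
    tau: float

    def active_at(self, t: float) -> np.ndarray:
        e = min(int(t // self.tau), len(self.epoch_starts) - 1)
        return self.active[e]


def frame_schedule(total_time: float, save_interval: float) -> np.ndarray:
    """Save times save_interval, 2·save_interval, … ≤ total_time."""
    n = int(np.floor(total_time / save_interval + 1e-9))
    if n == 0:
        warnings.warn("save_interval exceeds total_time: empty frame schedule")
    return save_interval * np.arange(1, n + 1)


def restraint_schedule(n_xl: int, n_active: int, tau_xl: float,
                       total_time: float, seed: int) -> RestraintSchedule:
    """Random restraint epochs: ceil(total_time/tau_xl) draws of n_active
    distinct ids, uniform over [1, n_xl], from a seeded Philox stream."""
    if n_xl < n_active:
        raise ValueError(f"only {n_xl} restraints but n_active={n_active}; "
                         "lower n_active")
    n_epochs = int(np.ceil(total_time / tau_xl - 1e-9))
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    active = np.stack([rng.choice(n_xl, size=n_active, replace=False) + 1
                       for _ in range(n_epochs)])
    starts = tau_xl * np.arange(n_epochs)
    return RestraintSchedule(epoch_starts=starts, active=active, tau=tau_xl)


# ---------------------------------------------------------------------------
# initial coordinates for flexible regions


def _flexible_runs(topology: CGTopology) -> list[list[int]]:
    runs, current = [], []
    for idx in range(topology.n_beads):
        if topology.flexible[idx]:
            if current and (topology.keys[idx][0] != topology.keys[current[-1]][0]
                            or topology.keys[idx][1] != topology.keys[current[-1]][1] + 1):
                runs.append(current)
                current = []
            current.append(idx)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def initialize_flexible(topology: CGTopology, seed: int,
                        params: ForceFieldParams | None = None,
                        max_retries: int = 200,
                        relax_steps: int = 500) -> np.ndarray:
    """Place flexible beads and return full starting coordinates.

    Singly-anchored runs (free termini) grow as self-avoiding random walks
    of step b_0 from their rigid anchor; doubly-anchored runs are laid along
    the anchor-anchor line with small jitter. No bead pair is allowed closer
    than σ_R/2 during growth. The full system is then relaxed by
    ``relax_steps`` steps of backtracking steepest descent.
    """
    params = params or ForceFieldParams()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, 7])))
    coords = topology.reference.copy()
    min_sep = params.sigma_rep / 2.0
    placed = list(np.flatnonzero(~topology.flexible))

    def clash(p: np.ndarray) -> bool:
        if not placed:
            return False
        pts = coords[placed]
        return bool(np.any(np.linalg.norm(pts - p, axis=1) < min_sep))

    for run_ in _flexible_runs(topology):
        first, last = run_[0], run_[-1]
        left = first - 1 if first > 0 and not topology.flexible[first - 1] \
            and topology.keys[first - 1][0] == topology.keys[first][0] else None
        right = last + 1 if last + 1 < topology.n_beads \
            and not topology.flexible[last + 1] \
            and topology.keys[last + 1][0] == topology.keys[last][0] else None

        if left is not None and right is not None:
            a, b = coords[left], coords[right]
            ts = np.linspace(0, 1, len(run_) + 2)[1:-1]
            for idx, t in zip(run_, ts):
                coords[idx] = a + t * (b - a) + rng.normal(0, 0.5, 3)
                placed.append(idx)
            continue

        order = run_ if left is not None else list(reversed(run_))
        anchor = left if left is not None else right
        prev = coords[anchor] if anchor is not None else np.zeros(3)
        if anchor is None and placed:
            # fully flexible chain: start offset from the occupied region
            prev = coords[placed].mean(axis=0) + np.array(
                [np.ptp(coords[placed][:, 0]) + 10.0, 0.0, 0.0])
        for idx in order:
            for attempt in range(max_retries):
                step = rng.normal(size=3)
                step *= params.b_0 / np.linalg.norm(step)
                candidate = prev + step
                if not clash(candidate):
                    break
            else:
                raise RuntimeError(f"failed to place flexible bead {idx} after "
                                   f"{max_retries} retries")
            coords[idx] = candidate
            placed.append(idx)
            prev = candidate

    # short steepest-descent relaxation of the newly-placed flexible beads;
    # rigid beads stay at their reference coordinates
    e, f = total_energy_forces(topology, coords, (), params)
    step = 1e-3
    movable = topology.flexible if topology.flexible.any() else \
        np.ones(topology.n_beads, dtype=bool)
    for _ in range(relax_steps):
        trial = coords.copy()
        trial[movable] = coords[movable] + step * f[movable]
        try:
            e2, f2 = total_energy_forces(topology, trial, (), params)
        except FloatingPointError:
            step *= 0.5
            continue
        if e2 < e:
            coords, e, f = trial, e2, f2
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-9:
                break
    return coords


# ---------------------------------------------------------------------------
# dynamics


def run(topology: CGTopology, params: ForceFieldParams,
        config: SimulationConfig, initial: np.ndarray | None = None,
        schedule: RestraintSchedule | None = None,
        record_restraints: bool = False):
    """BAOAB Langevin trajectory; returns an :class:`Ensemble`.

    ``schedule`` (if given) switches which of ``config.restraints`` are
    active each epoch; ids in the schedule are 1-based indices into that
    list. When ``record_restraints`` is true, returns ``(ensemble, table)``
    where the table holds per-frame active ids and restraint distances.
    """
    n = topology.n_beads
    seed_seq = np.random.SeedSequence([int(config.seed), 11])
    rng = np.random.Generator(np.random.Philox(seed_seq))

    coords = (initial.copy() if initial is not None
              else initialize_flexible(topology, config.seed, params))
    if coords.shape != (n, 3):
        raise ValueError("initial coordinates have wrong shape")

    dt = config.timestep
    m = config.mass
    kt_int = KBOLTZ * config.temperature * KCAL_TO_INTERNAL  # Da Å²/ps²
    vel = rng.normal(0.0, np.sqrt(kt_int / m), size=(n, 3))
    frozen = (~topology.flexible) if config.frozen_core else np.zeros(n, bool)
    vel[frozen] = 0.0

    if config.friction > 0:
        c1 = np.exp(-config.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kt_int / m)
    else:
        c1, c2 = 1.0, 0.0

    save_times = frame_schedule(config.total_time, config.save_interval)
    n_steps = int(round(config.total_time / dt))
    save_every = int(round(config.save_interval / dt))

    restraints = list(config.restraints)

    def active_set(t: float) -> list[RestraintSpec]:
        if schedule is None:
            return restraints
        ids = schedule.active_at(t)
        return [restraints[i - 1] for i in ids]

    current = active_set(0.0)
    epoch_every = (max(1, int(round(schedule.tau / dt)))
                   if schedule is not None else None)

    energy, forces = total_energy_forces(topology, coords, current, params)
    acc = forces * (KCAL_TO_INTERNAL / m)

    frames, energies, temps, rows = [], [], [], []
    for step in range(1, n_steps + 1):
        vel[~frozen] += 0.5 * dt * acc[~frozen]
        coords[~frozen] += 0.5 * dt * vel[~frozen]
        if c2 > 0:
            vel[~frozen] = (c1 * vel[~frozen]
                            + c2 * rng.normal(size=vel[~frozen].shape))
        coords[~frozen] += 0.5 * dt * vel[~frozen]

        t = step * dt
        if epoch_every is not None and step % epoch_every == 0:
            current = active_set(t)
        try:
            energy, forces = total_energy_forces(topology, coords, current, params)
        except FloatingPointError as exc:
            raise DivergenceError(
                f"non-finite state at step {step} (t={t:.3f} ps); max |F| was "
                f"{np.abs(forces).max():.3g} kcal/mol/Å — try a smaller timestep"
            ) from exc
        if not np.isfinite(energy):
            raise DivergenceError(
                f"non-finite energy at step {step} (t={t:.3f} ps); max |F| = "
                f"{np.abs(forces).max():.3g} kcal/mol/Å — try a smaller timestep")
        acc = forces * (KCAL_TO_INTERNAL / m)
        vel[~frozen] += 0.5 * dt * acc[~frozen]

        if step % save_every == 0 and len(frames) < len(save_times):
            frames.append(coords.copy())
            energies.append(energy)
            temps.append(kinetic_temperature(vel[~frozen], m))
            if record_restraints:
                dists = {s.index: float(np.linalg.norm(coords[s.i] - coords[s.j]))
                         for s in restraints}
                rows.append({"time_ps": t, "potential_kcal_mol": energy,
                             "active": [s.index for s in current],
                             "distances": dists})

    ens = Ensemble(frames=np.array(frames).reshape(len(frames), n, 3),
                   times=save_times[:len(frames)],
                   energies=np.asarray(energies),
                   temperatures=np.asarray(temps))
    if record_restraints:
        return ens, rows
    return ens


def kinetic_temperature(vel: np.ndarray, mass: float) -> float:
    """Instantaneous kinetic temperature (K) from velocities in Å/ps."""
    ke_int = 0.5 * mass * float(np.sum(vel * vel))      # Da Å²/ps²
    ndof = 3 * len(vel)
    return 2.0 * ke_int / (ndof * KBOLTZ * KCAL_TO_INTERNAL)


def run_nve(topology: CGTopology, params: ForceFieldParams,
            config: SimulationConfig, initial: np.ndarray,
            n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-Verlet (friction ignored) run returning per-step total and
    kinetic energies in kcal/mol — used for conservation checks."""
    n = topology.n_beads
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(
        [int(config.seed), 11])))
    coords = initial.copy()
    m = config.mass
    kt_int = KBOLTZ * config.temperature * KCAL_TO_INTERNAL
    vel = rng.normal(0.0, np.sqrt(kt_int / m), size=(n, 3))
    dt = config.timestep
    energy, forces = total_energy_forces(topology, coords, (), params)
    acc = forces * (KCAL_TO_INTERNAL / m)
    totals, kinetics = np.empty(n_steps), np.empty(n_steps)
    for s in range(n_steps):
        vel += 0.5 * dt * acc
        coords += dt * vel
        energy, forces = total_energy_forces(topology, coords, (), params)
        acc = forces * (KCAL_TO_INTERNAL / m)
        vel += 0.5 * dt * acc
        ke = 0.5 * m * float(np.sum(vel * vel)) / KCAL_TO_INTERNAL
        totals[s] = energy + ke
        kinetics[s] = ke
    return totals, kinetics
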