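"""Rigid-body NVT/NVE molecular dynamics of patchy particles.

Positions evolve under velocity-Verlet; orientations under an isotropic
rigid-body scheme (the rotational inertia is that of a uniform sphere, so
the angular velocity is simply L / I in the lab frame and the free drift is
an exact rotation).  NVT sampling uses either a BAOAB-style Langevin
thermostat acting on both translational and rotational momenta, or a
Berendsen velocity-rescale thermostat.  Forces come from a neighbor list
(periodic k-d tree with a Verlet skin, rebuilt on a displacement trigger).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import MixtureSpec
from .potential import ForceField, PotentialParams
from .rigid import quat_multiply, quat_normalize, random_unit_quaternions, rotvec_to_quat
from .units import INERTIA, MASS

__all__ = [
    "State",
    "Thermostat",
    "Schedule",
    "Trajectory",
    "IntegrationError",
    "compute_forces",
    "step",
    "run",
    "thermalize",
    "kinetic_temperatures",
]


class IntegrationError(RuntimeError):
    """Raised when coordinates become non-finite during integration."""


@dataclass
class State:
    """Instantaneous configuration of N rigid patchy particles in a periodic box."""

    box: np.ndarray                  # (3,) edge lengths in sigma
    positions: np.ndarray            # (N, 3), wrapped into [0, L)
    orientations: np.ndarray         # (N, 4) unit quaternions
    velocities: np.ndarray           # (N, 3)
    ang_momenta: np.ndarray          # (N, 3) lab frame
    species_index: np.ndarray        # (N,) ints into species_names
    species_names: tuple[str, ...]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        for name in ("orientations", "velocities", "ang_momenta", "species_index"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != N = {n}")
            setattr(self, name, arr)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> None:
        self.positions %= self.box

    def copy(self) -> "State":
        return State(
            box=self.box.copy(),
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            velocities=self.velocities.copy(),
            ang_momenta=self.ang_momenta.copy(),
            species_index=self.species_index.copy(),
            species_names=self.species_names,
            time=self.time,
        )

    def species_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.species_index == k))
            for k, name in enumerate(self.species_names)
        }


@dataclass(frozen=True)
class Thermostat:
    """NVT coupling: 'langevin' (stochastic, default) or 'velocity_rescale' (Berendsen)."""

    kind: str = "langevin"
    target: float = 0.1            # T* = kB T / epsilon
    coupling: float = 0.1          # coupling time in t*

    def __post_init__(self) -> None:
        if self.kind not in ("langevin", "velocity_rescale"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.target <= 0:
            raise ValueError("target temperature must be positive")


@dataclass(frozen=True)
class Schedule:
    """Run schedule: timestep, length, snapshot stride and RNG seed.

    ``scalar_stride`` records the per-frame scalars (energies, pressure
    tensor) more densely than full configuration snapshots; it defaults to
    the snapshot stride.
    """

    dt: float = 0.001
    n_steps: int = 1000
    snapshot_stride: int = 100
    seed: int = 0
    thermostat: Optional[Thermostat] = None
    scalar_stride: Optional[int] = None


class Trajectory:
    """Time-ordered state snapshots plus per-frame scalar observables."""

    def __init__(self, species_names: Sequence[str], box: np.ndarray, metadata: dict | None = None):
        self.species_names = tuple(species_names)
        self.box = np.asarray(box, dtype=float)
        self.frames: list[State] = []
        self._scalars: list[dict] = []
        self.metadata = dict(metadata or {})

    def append(self, state: State, scalars: dict | None = None) -> None:
        if self.frames and state.time <= self.frames[-1].time:
            raise ValueError("frame times must be strictly increasing")
        self.frames.append(state.copy())
        if scalars is not None:
            self.record_scalars(state.time, scalars)

    def record_scalars(self, time: float, scalars: dict) -> None:
        """Record a scalar row (may be denser in time than the frames)."""
        row = {"time": time}
        row.update(scalars)
        self._scalars.append(row)

    @property
    def scalars(self) -> pd.DataFrame:
        return pd.DataFrame(self._scalars)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> State:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - box * np.round(disp / box)


def neighbor_pairs(positions: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Unordered index pairs within cutoff under periodic boundaries."""
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(positions % box, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.astype(np.intp)


class NeighborList:
    """Verlet list: pairs within cutoff + skin, rebuilt on displacement trigger."""

    def __init__(self, cutoff: float, skin: float = 0.3):
        self.cutoff = cutoff
        self.skin = skin
        self.pairs = np.empty((0, 2), dtype=np.intp)
        self._ref: np.ndarray | None = None

    def build(self, positions: np.ndarray, box: np.ndarray) -> np.ndarray:
        self.pairs = neighbor_pairs(positions, box, self.cutoff + self.skin)
        self._ref = (positions % box).copy()
        return self.pairs

    def needs_rebuild(self, positions: np.ndarray, box: np.ndarray) -> bool:
        from ._kernels import HAVE_NUMBA, max_displacement_sq

        if self._ref is None or len(positions) != len(self._ref):
            return True
        if HAVE_NUMBA:
            d2 = max_displacement_sq(positions, self._ref, box)
        else:
            disp = minimum_image(positions % box - self._ref, box)
            d2 = np.max(np.einsum("ij,ij->i", disp, disp), initial=0.0)
        return bool(d2 > (0.5 * self.skin) ** 2)


def _resolve_forcefield(mixture) -> ForceField:
    if isinstance(mixture, ForceField):
        return mixture
    if isinstance(mixture, MixtureSpec):
        return ForceField(mixture)
    raise TypeError("expected a MixtureSpec or ForceField")


def compute_forces(state: State, mixture, pairs: np.ndarray | None = None,
                   backend: str = "auto"):
    """Total forces, torques, potential energy and virial tensor.

    The virial accumulates r_ij (x) f_ij per pair with the minimum-image
    convention; the instantaneous pressure tensor is
    (sum_i m v_i (x) v_i + virial) / V.  ``backend`` selects the compiled
    kernel ("numba", default when available) or the numpy reference path.
    """
    from .potential import _system_compute

    ff = _resolve_forcefield(mixture)
    if pairs is None:
        pairs = neighbor_pairs(state.positions, state.box, ff.params.cutoff)
    forces, torques, energy, virial, _ = _system_compute(
        ff, state.positions, state.orientations, state.species_index,
        state.box, pairs, backend=backend,
    )
    return forces, torques, energy, virial


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def kinetic_temperatures(state: State) -> tuple[float, float]:
    """Translational and rotational kinetic temperatures (3N dof each)."""
    n = state.n_particles
    if n == 0:
        return 0.0, 0.0
    t_trans = MASS * np.sum(state.velocities ** 2) / (3.0 * n)
    t_rot = np.sum(state.ang_momenta ** 2) / INERTIA / (3.0 * n)
    return float(t_trans), float(t_rot)


def thermalize(state: State, temperature: float, rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann momenta at T* and remove center-of-mass drift."""
    n = state.n_particles
    state.velocities = rng.normal(0.0, np.sqrt(temperature / MASS), size=(n, 3))
    state.velocities -= state.velocities.mean(axis=0)
    state.ang_momenta = rng.normal(0.0, np.sqrt(temperature * INERTIA), size=(n, 3))


def _rotate(state: State, dt: float) -> None:
    from ._kernels import HAVE_NUMBA, rotate_quats_inplace

    if HAVE_NUMBA:
        rotate_quats_inplace(state.orientations, state.ang_momenta, 1.0 / INERTIA, dt)
        return
    omega = state.ang_momenta / INERTIA
    dq = rotvec_to_quat(omega * dt)
    state.orientations = quat_normalize(quat_multiply(dq, state.orientations))


def _o_step(state: State, thermo: Thermostat, dt: float, rng: np.random.Generator) -> None:
    c1 = np.exp(-dt / thermo.coupling)
    n = state.n_particles
    state.velocities = c1 * state.velocities + np.sqrt(
        (1.0 - c1 ** 2) * thermo.target / MASS
    ) * rng.standard_normal((n, 3))
    state.ang_momenta = c1 * state.ang_momenta + np.sqrt(
        (1.0 - c1 ** 2) * thermo.target * INERTIA
    ) * rng.standard_normal((n, 3))


def _rescale_step(state: State, thermo: Thermostat, dt: float) -> None:
    t_tr, t_rot = kinetic_temperatures(state)
    for current, attr in ((t_tr, "velocities"), (t_rot, "ang_momenta")):
        if current <= 0:
            continue
        lam = np.sqrt(1.0 + (dt / thermo.coupling) * (thermo.target / current - 1.0))
        setattr(state, attr, getattr(state, attr) * lam)


def step(
    state: State,
    mixture,
    dt: float,
    thermostat: Thermostat | None = None,
    rng: np.random.Generator | None = None,
) -> State:
    """Advance one timestep (velocity-Verlet / BAOAB); returns a new State.

    Intended for small-scale and testing use: forces are recomputed from
    scratch at both ends of the step.  ``run`` amortizes force evaluations
    and the neighbor list over a whole schedule.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if thermostat is not None and thermostat.kind == "langevin" and rng is None:
        raise ValueError("langevin thermostat requires an rng")
    ff = _resolve_forcefield(mixture)
    s = state.copy()
    forces, torques, _, _ = compute_forces(s, ff)
    _step_inplace(s, ff, dt, forces, torques, thermostat, rng, NeighborList(ff.params.cutoff))
    return s


def _step_inplace(state, ff, dt, forces, torques, thermostat, rng, nlist):
    """One BAOAB step in place; returns updated (forces, torques, U, virial)."""
    half = 0.5 * dt
    state.velocities += half * forces / MASS
    state.ang_momenta += half * torques
    state.positions += half * state.velocities
    _rotate(state, half)
    if thermostat is not None and thermostat.kind == "langevin":
        _o_step(state, thermostat, dt, rng)
    state.positions += half * state.velocities
    _rotate(state, half)
    state.wrap()
    if not np.all(np.isfinite(state.positions)):
        raise IntegrationError(f"non-finite coordinates at t* = {state.time}")
    if nlist.needs_rebuild(state.positions, state.box):
        nlist.build(state.positions, state.box)
    out = compute_forces(state, ff, pairs=nlist.pairs)
    forces, torques = out[0], out[1]
    state.velocities += half * forces / MASS
    state.ang_momenta += half * torques
    if thermostat is not None and thermostat.kind == "velocity_rescale":
        _rescale_step(state, thermostat, dt)
    state.time += dt
    return out


def _scalar_row(state: State, potential_energy: float, virial: np.ndarray) -> dict:
    t_tr, t_rot = kinetic_temperatures(state)
    v = state.volume
    kin = MASS * np.einsum("ni,nj->ij", state.velocities, state.velocities)
    p = (kin + virial) / v
    return {
        "potential_energy": potential_energy,
        "kinetic_T_trans": t_tr,
        "kinetic_T_rot": t_rot,
        "Pxx": p[0, 0],
        "Pyy": p[1, 1],
        "Pzz": p[2, 2],
    }


def run(initial: State, mixture, schedule: Schedule) -> Trajectory:
    """Integrate a schedule; deterministic for a given seed.

    Snapshots (state + energies + pressure tensor) are recorded every
    ``snapshot_stride`` steps, including the initial state.
    """
    ff = _resolve_forcefield(mixture)
    rng = np.random.default_rng(schedule.seed)
    state = initial.copy()
    state.wrap()
    traj = Trajectory(
        state.species_names,
        state.box,
        metadata={
            "seed": schedule.seed,
            "dt": schedule.dt,
            "n_steps": schedule.n_steps,
            "snapshot_stride": schedule.snapshot_stride,
            "thermostat": None if schedule.thermostat is None else vars(schedule.thermostat),
            "mixture": ff.mixture.name,
        },
    )
    scalar_stride = schedule.scalar_stride or schedule.snapshot_stride
    nlist = NeighborList(ff.params.cutoff)
    nlist.build(state.positions, state.box)
    forces, torques, pot, virial = compute_forces(state, ff, pairs=nlist.pairs)
    traj.append(state)
    traj.record_scalars(state.time, _scalar_row(state, pot, virial))
    for k in range(schedule.n_steps):
        forces, torques, pot, virial = _step_inplace(
            state, ff, schedule.dt, forces, torques, schedule.thermostat, rng, nlist
        )
        if (k + 1) % scalar_stride == 0:
            traj.record_scalars(state.time, _scalar_row(state, pot, virial))
        if (k + 1) % schedule.snapshot_stride == 0:
            traj.append(state)
    return traj
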