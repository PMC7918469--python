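"""Synthetic trajectories with known ground truth for analysis validation.

Four generators: a uniform ideal gas (known density), a two-phase slab
sampled from a double-tanh density profile (known coexisting densities and
interface width), a concentric layered droplet (known per-species shell
assignments), and a scripted exchange trajectory with an exact number of
condensate/dilute movers per interval.  Each returns the trajectory plus
the ground-truth parameters (and scripted membership labels where
relevant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import State, Trajectory
from .rigid import random_unit_quaternions
from .structure import MembershipLabels

__all__ = ["FixtureResult", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("ideal_gas", "tanh_slab", "layered_droplet", "exchange_script")


@dataclass
class FixtureResult:
    trajectory: Trajectory
    ground_truth: dict
    labels: list[MembershipLabels] | None = None


def _make_state(positions, box, species_index, names, time, rng) -> State:
    n = len(positions)
    return State(
        box=np.asarray(box, dtype=float),
        positions=np.asarray(positions, dtype=float),
        orientations=random_unit_quaternions(n, rng),
        velocities=np.zeros((n, 3)),
        ang_momenta=np.zeros((n, 3)),
        species_index=np.asarray(species_index, dtype=np.intp),
        species_names=tuple(names),
        time=time,
    )


def _ideal_gas(params: dict, rng: np.random.Generator) -> FixtureResult:
    n = int(params.get("n", 1000))
    box = np.asarray(params.get("box", (10.0, 10.0, 10.0)), dtype=float)
    n_frames = int(params.get("n_frames", 20))
    traj = Trajectory(("A",), box)
    for f in range(n_frames):
        traj.append(_make_state(rng.random((n, 3)) * box, box, np.zeros(n), ("A",), float(f), rng))
    rho = n / float(np.prod(box))
    return FixtureResult(traj, {"density": rho, "n": n})


def _tanh_slab(params: dict, rng: np.random.Generator) -> FixtureResult:
    rho_l = float(params.get("rho_l", 0.6))
    rho_v = float(params.get("rho_v", 0.05))
    width = float(params.get("width", 1.5))
    box = np.asarray(params.get("box", (8.0, 8.0, 32.0)), dtype=float)
    slab_fraction = float(params.get("slab_fraction", 1.0 / 3.0))
    n_frames = int(params.get("n_frames", 10))
    lz = box[2]
    z1 = 0.5 * lz * (1.0 - slab_fraction)
    z2 = 0.5 * lz * (1.0 + slab_fraction)
    zg = np.linspace(0.0, lz, 4096)
    rho_z = rho_v + 0.5 * (rho_l - rho_v) * (np.tanh((zg - z1) / width) - np.tanh((zg - z2) / width))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (rho_z[1:] + rho_z[:-1]) * np.diff(zg))])
    n = int(round(cdf[-1] * box[0] * box[1]))
    cdf /= cdf[-1]
    traj = Trajectory(("A",), box)
    for f in range(n_frames):
        z = np.interp(rng.random(n), cdf, zg)
        xy = rng.random((n, 2)) * box[:2]
        pos = np.column_stack([xy, z])
        traj.append(_make_state(pos, box, np.zeros(n), ("A",), float(f), rng))
    return FixtureResult(
        traj,
        {"rho_l": rho_l, "rho_v": rho_v, "width": width, "n": n,
         "interfaces": (z1, z2)},
    )


def _layered_droplet(params: dict, rng: np.random.Generator) -> FixtureResult:
    n_core = int(params.get("n_core", 400))
    n_shell = int(params.get("n_shell", 400))
    r_core = float(params.get("r_core", 5.0))
    r_shell = float(params.get("r_shell", 7.0))
    box = np.asarray(params.get("box", (20.0, 20.0, 20.0)), dtype=float)
    n_frames = int(params.get("n_frames", 5))
    if r_shell <= r_core or 2 * r_shell >= box.min():
        raise ValueError("need r_core < r_shell < min(box)/2")
    center = box / 2.0

    def sample_radii(n, r_lo, r_hi):
        u = rng.random(n)
        return (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)

    traj = Trajectory(("core", "shell"), box)
    labels = []
    n = n_core + n_shell
    sidx = np.concatenate([np.zeros(n_core), np.ones(n_shell)])
    for f in range(n_frames):
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.concatenate(
            [sample_radii(n_core, 0.0, r_core), sample_radii(n_shell, r_core, r_shell)]
        )
        pos = center + dirs * radii[:, None]
        traj.append(_make_state(pos, box, sidx, ("core", "shell"), float(f), rng))
        labels.append(MembershipLabels(np.zeros(n, dtype=int), (n,)))
    return FixtureResult(
        traj,
        {"r_core": r_core, "r_shell": r_shell, "n_core": n_core, "n_shell": n_shell},
        labels=labels,
    )


def _exchange_script(params: dict, rng: np.random.Generator) -> FixtureResult:
    k = int(params.get("k", 4))
    n_intervals = int(params.get("n_intervals", 10))
    n = int(params.get("n", 64))
    box = np.asarray(params.get("box", (10.0, 10.0, 40.0)), dtype=float)
    hop = float(params.get("hop", 1.2))  # per-frame displacement > 1 sigma
    if 2 * k > n:
        raise ValueError("need n >= 2k particles")
    pos0 = rng.random((n, 3)) * box
    phase = np.zeros(n, dtype=bool)
    phase[: n // 2] = True  # half start inside the condensate
    traj = Trajectory(("A",), box)
    labels = []

    def snapshot(f):
        pos = (pos0 + np.array([hop, 0.0, 0.0]) * f) % box
        traj.append(_make_state(pos, box, np.zeros(n), ("A",), float(f), rng))
        lab = np.where(phase, 0, -1)
        labels.append(MembershipLabels(lab, (int(phase.sum()),)))

    snapshot(0)
    movers = np.arange(n)
    ptr = 0
    for f in range(1, n_intervals + 1):
        for _ in range(k):
            phase[movers[ptr % n]] = ~phase[movers[ptr % n]]
            ptr += 1
        snapshot(f)
    return FixtureResult(
        traj,
        {"k": k, "n_intervals": n_intervals, "area": 2.0 * box[0] * box[1],
         "expected_rate": k / (2.0 * box[0] * box[1])},
        labels=labels,
    )


_DISPATCH = {
    "ideal_gas": _ideal_gas,
    "tanh_slab": _tanh_slab,
    "layered_droplet": _layered_droplet,
    "exchange_script": _exchange_script,
}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> FixtureResult:
    """Generate a synthetic trajectory of the given kind with known ground truth."""
    if kind not in _DISPATCH:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return _DISPATCH[kind](dict(params or {}), np.random.default_rng(seed))
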