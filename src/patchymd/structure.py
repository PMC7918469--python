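"""Condensate membership, layering profiles, exchange kinetics, order parameters.

Phase membership is defined through the bonded network: particle pairs
whose total patch-patch attraction is below an energy cutoff are bonded,
and connected components of at least ``min_size`` particles are
condensates (indexed by decreasing size); everything else is the dilute
phase.  On top of the labels this module measures center-of-mass layering
profiles, the exchange-rate order parameter between condensate and dilute
phase, the molar-fraction time series inside the largest condensate during
nucleation, and the two mixture order parameters (scaffold-client valency
difference and binding-affinity variance) that organize the presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .coexistence import DensityProfile
from .engine import State, Trajectory, minimum_image, neighbor_pairs
from .model import MixtureSpec
from .potential import ForceField

__all__ = [
    "MembershipLabels",
    "ExchangeRateResult",
    "MixtureOrderParams",
    "WeightedProfile",
    "TrajectoryTooShortError",
    "identify_condensates",
    "label_trajectory",
    "com_layering_profile",
    "weighted_family_profile",
    "exchange_rate",
    "molar_fraction_timeseries",
    "mixture_order_parameters",
]

BOND_ENERGY_CUTOFF = -0.1  # epsilon; pair counts as bonded below this
MIN_CONDENSATE_SIZE = 10


class TrajectoryTooShortError(RuntimeError):
    """No pair of independent frames could be extracted."""


@dataclass
class MembershipLabels:
    """Per-particle phase labels: 0..K-1 for condensates (by decreasing size), -1 dilute."""

    labels: np.ndarray
    sizes: tuple[int, ...]

    @property
    def n_condensates(self) -> int:
        return len(self.sizes)

    @property
    def in_condensate(self) -> np.ndarray:
        return self.labels >= 0

    def members(self, k: int = 0) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


@dataclass(frozen=True)
class ExchangeRateResult:
    """Per-species boundary-crossing rates per sigma^2 per independent interval."""

    rates: dict[str, float]
    independence_stride: float       # mean retained-frame spacing in t*
    interfacial_area: float          # 2 Lx Ly for slab geometry
    n_intervals: int


@dataclass(frozen=True)
class MixtureOrderParams:
    """Scaffold-client valency difference and binding-affinity variance."""

    delta_valency: float
    affinity_variance: float
    scaffolds: tuple[str, ...]
    clients: tuple[str, ...]


@dataclass
class WeightedProfile:
    """Family-weighted density rho_w*: total family density / number of types."""

    bin_centers: np.ndarray
    scaffold: np.ndarray
    client: np.ndarray
    n_scaffold_types: int
    n_client_types: int


# ---------------------------------------------------------------------------
# Membership
# ---------------------------------------------------------------------------

def _bond_pairs(state: State, ff: ForceField, energy_cutoff: float) -> np.ndarray:
    from .potential import _system_compute

    pairs = neighbor_pairs(state.positions, state.box, ff.params.cutoff)
    if len(pairs) == 0:
        return pairs
    _, _, _, _, bonds = _system_compute(
        ff, state.positions, state.orientations, state.species_index,
        state.box, pairs, want_bonds=True,
    )
    return pairs[bonds < energy_cutoff * ff.params.epsilon]


def identify_condensates(
    state: State,
    mixture,
    energy_cutoff: float = BOND_ENERGY_CUTOFF,
    min_size: int = MIN_CONDENSATE_SIZE,
) -> MembershipLabels:
    """Partition particles into condensates and dilute phase via the bonded network."""
    ff = mixture if isinstance(mixture, ForceField) else ForceField(mixture)
    n = state.n_particles
    pairs = _bond_pairs(state, ff, energy_cutoff)
    if len(pairs) == 0:
        return MembershipLabels(np.full(n, -1, dtype=int), ())
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp)
    big = np.flatnonzero(sizes >= min_size)
    order = big[np.argsort(sizes[big])[::-1]]
    labels = np.full(n, -1, dtype=int)
    for rank, c in enumerate(order):
        labels[comp == c] = rank
    return MembershipLabels(labels, tuple(int(sizes[c]) for c in order))


def label_trajectory(traj: Trajectory, mixture, **kwargs) -> list[MembershipLabels]:
    ff = mixture if isinstance(mixture, ForceField) else ForceField(mixture)
    return [identify_condensates(fr, ff, **kwargs) for fr in traj]


# ---------------------------------------------------------------------------
# Layering profiles around the largest condensate
# ---------------------------------------------------------------------------

def _periodic_com(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Periodic-aware centroid via the circular mean in each dimension."""
    theta = 2.0 * np.pi * positions / box
    return box / (2.0 * np.pi) * np.arctan2(
        np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0)
    )


def com_layering_profile(
    trajectory: Trajectory,
    labels: Sequence[MembershipLabels],
    bins: int = 40,
    r_max: float | None = None,
    geometry: str = "slab",
) -> DensityProfile:
    """Per-species rho*(d) versus distance from the largest condensate's COM.

    The COM is recomputed per frame with the periodic-aware centroid of the
    largest condensate's members.  With ``geometry="slab"`` (the direct-
    coexistence default) the distance is taken along the long (z) axis of
    the box, perpendicular to the interfaces, and both sides are folded
    together; with ``geometry="droplet"`` spherical shells around the full
    3D centroid are used (appropriate for a compact droplet, with bins
    reaching the inscribed sphere).  Frames without a condensate are
    skipped; if none has one, signals "no droplet".
    """
    if geometry not in ("slab", "droplet"):
        raise ValueError("geometry must be 'slab' or 'droplet'")
    box = trajectory.box
    if r_max is not None:
        rmax = r_max
    elif geometry == "slab":
        rmax = float(box[2]) / 2.0
    else:
        rmax = float(box.min()) / 2.0
    edges = np.linspace(0.0, rmax, bins + 1)
    if geometry == "slab":
        bin_vol = 2.0 * box[0] * box[1] * np.diff(edges)
    else:
        bin_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    names = trajectory.species_names
    hists = {nm: np.zeros(bins) for nm in names}
    used = 0
    for fr, lab in zip(trajectory, labels):
        if lab.n_condensates == 0:
            continue
        com = _periodic_com(fr.positions[lab.members(0)], box)
        if geometry == "slab":
            dz = fr.positions[:, 2] - com[2]
            d = np.abs(dz - box[2] * np.round(dz / box[2]))
        else:
            d = np.linalg.norm(minimum_image(fr.positions - com, box), axis=1)
        for k, nm in enumerate(names):
            hists[nm] += np.histogram(d[fr.species_index == k], bins=edges)[0]
        used += 1
    if used == 0:
        raise ValueError("no droplet: no frame contains a condensate")
    densities = {nm: h / (bin_vol * used) for nm, h in hists.items()}
    densities["total"] = sum(densities[nm] for nm in names)
    return DensityProfile(
        axis="r_from_COM",
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_width=float(edges[1] - edges[0]),
        densities=densities,
        n_frames=used,
        box=box.copy(),
    )


def weighted_family_profile(
    profile: DensityProfile, scaffolds: Sequence[str]
) -> WeightedProfile:
    """Scaffold/client weighted densities rho_w* (family total / number of types)."""
    scaffolds = tuple(scaffolds)
    clients = tuple(nm for nm in profile.densities if nm not in scaffolds and nm != "total")
    if not scaffolds or not clients:
        raise ValueError("need at least one scaffold and one client species")
    sc = sum(profile.densities[nm] for nm in scaffolds) / len(scaffolds)
    cl = sum(profile.densities[nm] for nm in clients) / len(clients)
    return WeightedProfile(profile.bin_centers, sc, cl, len(scaffolds), len(clients))


# ---------------------------------------------------------------------------
# Exchange kinetics
# ---------------------------------------------------------------------------

def _independent_frames(
    trajectory: Trajectory, labels: Sequence[MembershipLabels], msd_threshold: float
) -> list[int]:
    """Greedy decimation: keep a frame once condensate residents of the last
    retained frame have moved one molecular diameter on average."""
    box = trajectory.box
    retained = [0]
    for k in range(1, len(trajectory)):
        ref = retained[-1]
        residents = np.flatnonzero(labels[ref].in_condensate)
        if len(residents) == 0:
            retained.append(k)  # no condensate yet: every frame is fresh
            continue
        disp = minimum_image(
            trajectory[k].positions[residents] - trajectory[ref].positions[residents], box
        )
        if np.mean(np.einsum("ij,ij->i", disp, disp)) >= msd_threshold:
            retained.append(k)
    return retained


def exchange_rate(
    trajectory: Trajectory,
    labels: Sequence[MembershipLabels],
    msd_threshold: float = 1.0,
    hysteresis: bool = True,
    mode: str = "movers",
) -> ExchangeRateResult:
    """Per-species condensate/dilute exchange rate per unit interfacial area.

    Frames are decimated to an independence stride (condensate residents
    must diffuse at least one molecular diameter between retained frames);
    between consecutive retained frames every particle whose phase label
    flipped counts as one exchange event (in- and out-movers alike).  With
    ``hysteresis`` a flip must persist at the following retained frame to
    count, suppressing single-frame flicker.  The rate divides the mean
    events per interval by the slab's interfacial area 2 Lx Ly.

    ``mode="net"`` counts the absolute change in condensate occupancy
    |Delta N| per interval instead of individual movers (a lower bound:
    simultaneous in- and out-movers cancel).
    """
    if mode not in ("movers", "net"):
        raise ValueError("mode must be 'movers' or 'net'")
    if len(trajectory) < 2:
        raise TrajectoryTooShortError("need at least two frames")
    retained = _independent_frames(trajectory, labels, msd_threshold)
    if len(retained) < 2:
        raise TrajectoryTooShortError(
            "trajectory too short to reach an independent configuration"
        )
    box = trajectory.box
    area = 2.0 * box[0] * box[1]
    names = trajectory.species_names
    phase = np.stack([labels[k].in_condensate for k in retained])  # (F, N)
    sidx = trajectory[0].species_index
    counts = {nm: [] for nm in names}
    for f in range(len(retained) - 1):
        moved = phase[f + 1] != phase[f]
        if hysteresis and f + 2 < len(retained):
            moved &= phase[f + 2] == phase[f + 1]
        for k, nm in enumerate(names):
            sel = moved & (sidx == k)
            if mode == "net":
                entered = int(np.sum(sel & phase[f + 1]))
                left = int(np.sum(sel & ~phase[f + 1]))
                counts[nm].append(abs(entered - left))
            else:
                counts[nm].append(int(np.sum(sel)))
    times = trajectory.times[retained]
    return ExchangeRateResult(
        rates={nm: float(np.mean(c)) / area for nm, c in counts.items()},
        independence_stride=float(np.mean(np.diff(times))),
        interfacial_area=area,
        n_intervals=len(retained) - 1,
    )


def molar_fraction_timeseries(
    trajectory: Trajectory, labels: Sequence[MembershipLabels]
) -> pd.DataFrame:
    """Molar fraction of each species inside the largest condensate per frame.

    Frames without a condensate carry NaN fractions; where a condensate
    exists the fractions sum to one.
    """
    names = trajectory.species_names
    rows = []
    for fr, lab in zip(trajectory, labels):
        row = {"time": fr.time}
        if lab.n_condensates == 0:
            row.update({nm: np.nan for nm in names})
            row["condensate_size"] = 0
        else:
            members = lab.members(0)
            total = len(members)
            sidx = fr.species_index[members]
            for k, nm in enumerate(names):
                row[nm] = float(np.sum(sidx == k)) / total
            row["condensate_size"] = total
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixture order parameters
# ---------------------------------------------------------------------------

def mixture_order_parameters(
    mixture: MixtureSpec, scaffolds: Sequence[str] | None = None
) -> MixtureOrderParams:
    """Scaffold-client valency difference and pairwise binding-affinity variance.

    Scaffolds default to the 4-valency species in the mixture; for presets
    forming two separate condensates pass each scaffold separately.  The
    valency difference is the (mean) scaffold valency minus the mean
    valency of clients bound to a scaffold with non-zero affinity.  The
    affinity score of an unordered species pair (homotypic pairs included)
    is the mean of the two valencies when the pair attracts, zero
    otherwise; its population variance over all pairs is the second order
    parameter.
    """
    species = mixture.species
    val = {sp.name: sp.effective_valency for sp in species}
    if scaffolds is None:
        scaffolds = tuple(sp.name for sp in species if sp.effective_valency >= 4.0)
    else:
        scaffolds = tuple(scaffolds)
    if not scaffolds:
        raise ValueError("no scaffold species in mixture")
    clients = tuple(
        sp.name
        for sp in species
        if sp.name not in scaffolds
        and any(mixture.species_pair_enabled(sp.name, sc) for sc in scaffolds)
    )
    if clients:
        delta = float(np.mean([val[s] for s in scaffolds]) - np.mean([val[c] for c in clients]))
    else:
        delta = float(np.mean([val[s] for s in scaffolds]))
    scores = []
    for i, a in enumerate(species):
        for b in species[i:]:
            if mixture.species_pair_enabled(a.name, b.name):
                scores.append(0.5 * (val[a.name] + val[b.name]))
            else:
                scores.append(0.0)
    return MixtureOrderParams(
        delta_valency=delta,
        affinity_variance=float(np.var(scores)),
        scaffolds=scaffolds,
        clients=clients,
    )
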