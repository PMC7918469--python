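"""Direct-coexistence workflow: slab setup, density profiles, coexistence fits.

A dense slab of the mixture is placed in the middle of an elongated
periodic box and relaxed in the NVT ensemble; once the dense and dilute
phases reach their equilibrium densities, per-species density profiles
along the long axis give the coexisting densities via a two-interface
hyperbolic-tangent fit.  Repeating at several temperatures and combining
the universal Ising scaling of the density gap (beta = 0.325) with the law
of rectilinear diameters locates the critical point (Tc*, rho_c*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .engine import State, Trajectory, minimum_image, thermalize
from .model import MixtureSpec
from .rigid import random_unit_quaternions

__all__ = [
    "DensityProfile",
    "CoexistencePoint",
    "CriticalPointFit",
    "PhaseDiagram",
    "PackingError",
    "SinglePhaseError",
    "init_direct_coexistence",
    "init_homogeneous",
    "slab_density_profile",
    "fit_coexistence_densities",
    "estimate_critical_point",
    "ISING_BETA",
]

ISING_BETA = 0.325  # 3D Ising order-parameter exponent, held fixed in fits


class PackingError(RuntimeError):
    """Requested density could not be reached by random insertion."""


class SinglePhaseError(RuntimeError):
    """The density profile shows no two-phase (slab) structure."""


@dataclass
class DensityProfile:
    """Per-species reduced density versus a spatial coordinate.

    ``axis`` is ``"z"`` for slab profiles (bins span the full box length,
    so the integral over the box recovers the particle counts exactly) or
    ``"r_from_COM"`` for radial droplet profiles (bins reach the inscribed
    sphere).  ``densities`` maps species name -> rho*(coordinate) and also
    holds a ``"total"`` entry.  ``block_densities`` optionally carries the
    same profiles per trajectory block for uncertainty estimates.
    """

    axis: str
    bin_centers: np.ndarray
    bin_width: float
    densities: dict[str, np.ndarray]
    n_frames: int
    box: np.ndarray
    block_densities: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def total(self) -> np.ndarray:
        return self.densities["total"]


@dataclass(frozen=True)
class CoexistencePoint:
    """Coexisting vapor/liquid densities at one reduced temperature."""

    temperature: float
    rho_vapor: float
    rho_liquid: float
    rho_vapor_err: float = float("nan")
    rho_liquid_err: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.rho_liquid >= self.rho_vapor >= 0.0):
            raise ValueError("require rho_liquid >= rho_vapor >= 0")


@dataclass(frozen=True)
class CriticalPointFit:
    """Critical point from Ising scaling + rectilinear diameters."""

    tc: float
    rho_c: float
    tc_err: float
    rho_c_err: float
    amplitude: float
    slope: float


@dataclass(frozen=True)
class PhaseDiagram:
    points: tuple[CoexistencePoint, ...]
    critical: CriticalPointFit

    def __post_init__(self) -> None:
        tmax = max(p.temperature for p in self.points if p.rho_liquid > p.rho_vapor)
        if self.critical.tc < tmax:
            raise ValueError("fitted Tc* below a two-phase temperature")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _random_insert(
    n: int,
    box: np.ndarray,
    z_range: tuple[float, float],
    min_dist: float,
    rng: np.random.Generator,
    max_attempts: int = 5000,
) -> np.ndarray:
    """Sequential random insertion with a minimum-distance rejection rule."""
    placed = np.empty((n, 3))
    d2 = min_dist * min_dist
    for i in range(n):
        for _ in range(max_attempts):
            cand = rng.random(3) * box
            cand[2] = rng.uniform(*z_range)
            if i:
                disp = minimum_image(placed[:i] - cand, box)
                if np.min(np.einsum("ij,ij->i", disp, disp)) < d2:
                    continue
            placed[i] = cand
            break
        else:
            raise PackingError(
                f"could not place particle {i + 1}/{n} at the requested density"
            )
    return placed


def _species_array(mixture: MixtureSpec, rng: np.random.Generator) -> np.ndarray:
    idx = np.repeat(np.arange(len(mixture.species)), mixture.counts)
    rng.shuffle(idx)
    return idx


def init_direct_coexistence(
    mixture: MixtureSpec,
    slab_density: float,
    aspect: tuple[float, float, float] = (1.0, 1.0, 4.0),
    slab_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    temperature: float | None = None,
    min_dist: float = 0.95,
    box: np.ndarray | None = None,
) -> State:
    """Dense slab of randomly oriented, non-overlapping particles, vacuum elsewhere.

    The box is sized so the slab (centered in z, spanning ``slab_fraction``
    of Lz) holds all particles at ``slab_density``; with ``box`` given the
    slab thickness follows from the requested density instead.
    """
    names = tuple(sp.name for sp in mixture.species)
    rng = np.random.default_rng(seed)
    if slab_density == 0.0:
        b = np.asarray(box if box is not None else (10.0, 10.0, 40.0), dtype=float)
        empty = np.empty((0, 3))
        return State(b, empty, np.empty((0, 4)), empty.copy(), empty.copy(),
                     np.empty(0, dtype=np.intp), names)
    if slab_density < 0:
        raise ValueError("slab density must be non-negative")
    n = mixture.n_particles
    if box is None:
        ax, ay, az = aspect
        if not (az > ax == ay):
            raise ValueError("need an elongated box: aspect (a, a, c) with c > a")
        # Lx^3 * (az/ax) * slab_fraction * rho = N
        lx = (n / (slab_density * slab_fraction * (az / ax))) ** (1.0 / 3.0)
        b = np.array([lx, lx, lx * az / ax])
        h = slab_fraction * b[2]
    else:
        b = np.asarray(box, dtype=float)
        h = n / (slab_density * b[0] * b[1])
        if h > b[2]:
            raise PackingError("slab thicker than the box at the requested density")
    z0 = 0.5 * (b[2] - h)
    positions = _random_insert(n, b, (z0, z0 + h), min_dist, rng)
    state = State(
        box=b,
        positions=positions,
        orientations=random_unit_quaternions(n, rng),
        velocities=np.zeros((n, 3)),
        ang_momenta=np.zeros((n, 3)),
        species_index=_species_array(mixture, rng),
        species_names=names,
    )
    if temperature is not None:
        thermalize(state, temperature, rng)
    return state


def init_homogeneous(
    mixture: MixtureSpec,
    density: float,
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    temperature: float | None = None,
    min_dist: float = 0.95,
) -> State:
    """Uniform fluid of the mixture at overall density rho* (nucleation starts)."""
    if density <= 0:
        raise ValueError("density must be positive")
    n = mixture.n_particles
    ax, ay, az = aspect
    lx = (n / (density * (ay / ax) * (az / ax))) ** (1.0 / 3.0)
    b = np.array([lx, lx * ay / ax, lx * az / ax])
    rng = np.random.default_rng(seed)
    positions = _random_insert(n, b, (0.0, b[2]), min_dist, rng)
    state = State(
        box=b,
        positions=positions,
        orientations=random_unit_quaternions(n, rng),
        velocities=np.zeros((n, 3)),
        ang_momenta=np.zeros((n, 3)),
        species_index=_species_array(mixture, rng),
        species_names=tuple(sp.name for sp in mixture.species),
    )
    if temperature is not None:
        thermalize(state, temperature, rng)
    return state


# ---------------------------------------------------------------------------
# Slab density profiles
# ---------------------------------------------------------------------------

def _recenter_z(z: np.ndarray, lz: float) -> np.ndarray:
    """Shift z so the periodic (circular-mean) center of mass sits at Lz/2."""
    theta = 2.0 * np.pi * z / lz
    com = lz / (2.0 * np.pi) * np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return (z - com + 0.5 * lz) % lz


def slab_density_profile(
    trajectory: Trajectory,
    bins: int = 100,
    equilibration_fraction: float = 0.5,
    n_blocks: int = 5,
    recenter: bool = True,
) -> DensityProfile:
    """Per-species rho*(z), recentered on the slab center of mass per frame.

    The first ``equilibration_fraction`` of frames is discarded; the rest
    is split into ``n_blocks`` contiguous blocks whose individual profiles
    feed the uncertainty estimates of downstream fits.  Recentering removes
    slab drift; disable it for configurations without a slab (a uniform
    fluid has no meaningful center, and recentering on density noise would
    imprint spurious structure).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    start = int(np.floor(equilibration_fraction * len(trajectory)))
    frames = trajectory.frames[start:]
    if not frames:
        raise ValueError("no frames left after equilibration discard")
    box = trajectory.box
    lz = box[2]
    edges = np.linspace(0.0, lz, bins + 1)
    dz = edges[1] - edges[0]
    names = trajectory.species_names
    slab_vol = box[0] * box[1] * dz

    def accumulate(subset: Sequence[State]) -> dict[str, np.ndarray]:
        hists = {nm: np.zeros(bins) for nm in names}
        for fr in subset:
            z = fr.positions[:, 2] % lz
            if recenter:
                z = _recenter_z(z, lz)
            for k, nm in enumerate(names):
                hists[nm] += np.histogram(z[fr.species_index == k], bins=edges)[0]
        out = {nm: h / (slab_vol * len(subset)) for nm, h in hists.items()}
        out["total"] = sum(out[nm] for nm in names)
        return out

    densities = accumulate(frames)
    blocks = []
    if len(frames) >= n_blocks >= 2:
        for chunk in np.array_split(np.arange(len(frames)), n_blocks):
            blocks.append(accumulate([frames[i] for i in chunk]))
    return DensityProfile(
        axis="z",
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_width=dz,
        densities=densities,
        n_frames=len(frames),
        box=box.copy(),
        block_densities=blocks,
    )


# ---------------------------------------------------------------------------
# Coexistence-density extraction
# ---------------------------------------------------------------------------

def _double_tanh(z, rho_v, rho_l, z1, z2, w):
    return rho_v + 0.5 * (rho_l - rho_v) * (np.tanh((z - z1) / w) - np.tanh((z - z2) / w))


def _fit_profile(z: np.ndarray, rho: np.ndarray, lz: float):
    lo, hi = np.percentile(rho, [10, 90])
    if hi <= 0 or (hi - lo) < 0.25 * (hi + lo):
        raise SinglePhaseError("profile has no two-phase structure")
    # initial interface guesses: where the profile crosses the midpoint
    mid = 0.5 * (hi + lo)
    above = rho > mid
    p0 = [max(lo, 1e-6), hi, 0.5 * lz - 0.25 * lz * above.mean() * 2.0,
          0.5 * lz + 0.25 * lz * above.mean() * 2.0, 1.5]
    rho_cap = 1.5 * float(rho.max())
    p0[1] = min(p0[1], rho_cap)
    popt, _ = curve_fit(
        _double_tanh, z, rho, p0=p0,
        bounds=([0.0, 0.0, 0.0, 0.0, 0.05], [rho_cap, rho_cap, lz, lz, lz / 4.0]),
        maxfev=20000,
    )
    rho_v, rho_l = float(popt[0]), float(popt[1])
    if rho_l < rho_v:
        rho_v, rho_l = rho_l, rho_v
    return rho_v, rho_l


def fit_coexistence_densities(
    profile: DensityProfile, temperature: float = float("nan")
) -> CoexistencePoint:
    """Vapor/liquid densities from a two-interface tanh fit of the total profile.

    Uncertainties come from refitting the per-block profiles when the
    profile carries them (standard error over blocks).  A profile without
    two plateaus raises :class:`SinglePhaseError`.
    """
    z = profile.bin_centers
    lz = profile.box[2]
    rho_v, rho_l = _fit_profile(z, profile.total, lz)
    err_v = err_l = float("nan")
    if len(profile.block_densities) >= 2:
        vs, ls = [], []
        for blk in profile.block_densities:
            try:
                bv, bl = _fit_profile(z, blk["total"], lz)
            except (SinglePhaseError, RuntimeError):
                continue
            vs.append(bv)
            ls.append(bl)
        if len(vs) >= 2:
            err_v = float(np.std(vs, ddof=1) / np.sqrt(len(vs)))
            err_l = float(np.std(ls, ddof=1) / np.sqrt(len(ls)))
    return CoexistencePoint(temperature, rho_v, rho_l, err_v, err_l)


# ---------------------------------------------------------------------------
# Critical point
# ---------------------------------------------------------------------------

def estimate_critical_point(
    points: Sequence[CoexistencePoint], beta: float = ISING_BETA
) -> CriticalPointFit:
    """Joint fit of the density gap and the rectilinear diameter.

    rho_l - rho_v = A (1 - T/Tc)^beta  and  (rho_l + rho_v)/2 =
    rho_c + s (Tc - T), solved by least squares for (Tc, rho_c, A, s) with
    beta held at the 3D Ising value.  Requires at least three coexistence
    points spanning a temperature range.  Points carrying block-averaging
    uncertainties are weighted inversely (noisy near-critical points count
    less).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 coexistence points")
    t = np.array([p.temperature for p in points])
    gap = np.array([p.rho_liquid - p.rho_vapor for p in points])
    dia = np.array([0.5 * (p.rho_liquid + p.rho_vapor) for p in points])
    err = np.array(
        [np.hypot(p.rho_liquid_err, p.rho_vapor_err) for p in points]
    )
    if np.all(np.isfinite(err)) and np.all(err > 0):
        w = 1.0 / np.clip(err, 0.2 * np.median(err), None)
        w /= w.mean()
    else:
        w = np.ones_like(t)

    closed = gap <= 0.0
    if np.any(closed):
        # a point with rho_l = rho_v sits at the critical temperature
        tc = float(t[closed].min())
        s, rc = np.polyfit(tc - t, dia, 1)
        return CriticalPointFit(tc, float(rc), 0.0, float("nan"), float("nan"), float(s))

    tmax = t.max()
    gap_scale = max(gap.max(), 1e-12)

    def residuals(p):
        tc, rc, a, s = p
        red = np.clip(1.0 - t / tc, 0.0, None)
        return np.concatenate([w * (gap - a * red ** beta) / gap_scale,
                               w * (dia - (rc + s * (tc - t))) / gap_scale])

    t_span = max(tmax - t.min(), 1e-3)
    p0 = [tmax + 0.5 * t_span, dia.mean(), gap.max() / max(t_span / tmax, 1e-3) ** beta, 0.5]
    sol = least_squares(residuals, p0, bounds=([tmax * (1 + 1e-9), 0.0, 0.0, -np.inf],
                                               [np.inf, np.inf, np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError("critical-point fit did not converge")
    tc, rc, a, s = sol.x
    # approximate covariance from the Jacobian
    dof = max(len(sol.fun) - 4, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2.0 * sol.cost / dof
        tc_err, rc_err = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        tc_err = rc_err = float("nan")
    return CriticalPointFit(float(tc), float(rc), tc_err, rc_err, float(a), float(s))
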