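"""Pair interaction between two patchy particles: energy, force and torques.

The potential is the sum of

* a continuous pseudo-hard-sphere core: a cut-and-shifted steep Mie
  (50, 49) repulsion that vanishes with zero slope at r = (50/49) sigma,
  so particles behave as hard spheres of diameter sigma at the simulated
  temperatures, and
* for every patch pair (a on particle i, b on particle j) an attractive
  well  U_ab = -eps * d_ab * phi(r) * Omega(c_a) * Omega(c_b)  where
  d_ab in [0, 1] is the affinity-matrix depth, phi is a compact cos^2
  radial bump of half-width ``well_halfwidth`` centered at
  ``well_position`` (its maximum is exactly 1), and Omega is a smooth
  Gaussian modulation in (1 - cos theta) with a configurable angular
  half-width at half maximum.  c_a is the cosine between patch a and the
  center-to-center direction.

With the default geometry a perfectly aligned full-strength bond has energy
exactly -eps, and the angular width is narrow enough that a patch can
engage at most one partner (excluded volume forbids two partners inside one
patch cone).  Forces and torques are analytic derivatives of the energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .rigid import rotate_vectors

if TYPE_CHECKING:  # pragma: no cover
    from .model import InteractionMatrix, MixtureSpec, SpeciesSpec

__all__ = ["PotentialParams", "ForceField", "OverlapError", "pair_interaction"]


class OverlapError(RuntimeError):
    """Raised when two centers come closer than the minimum-separation guard."""


# angular modulation is treated as zero beyond this many Gaussian widths
# (Omega < e^-18 ~ 1.5e-8), keeping both evaluation backends bit-identical
ANGULAR_PRUNE = 6.0


@dataclass(frozen=True)
class PotentialParams:
    """Tunable parameters of the pair potential, in reduced units.

    epsilon : full well depth (the unit of energy).
    sigma : particle diameter (the unit of length).
    core_epsilon : energy scale of the pseudo-hard-sphere repulsion.
    well_position : center of the radial attraction bump; must exceed the
        core cutoff (50/49) sigma so the bound-state minimum is exactly
        -depth * epsilon.
    well_halfwidth : radial half-width of the bump; the attraction is zero
        beyond well_position + well_halfwidth (~0.12 sigma past contact by
        default).
    angular_hwhm : angular half-width at half maximum of the patch
        modulation, radians.  0.3 rad keeps bonding single-valent.
    min_separation : overlap guard; configurations with any pair closer
        than this are rejected as invalid.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    core_epsilon: float = 1.0
    well_position: float = 1.03
    well_halfwidth: float = 0.09
    angular_hwhm: float = 0.3
    min_separation: float = 0.7

    # Mie (50, 49) exponents of the pseudo-hard-sphere core
    _LR: int = field(default=50, repr=False)
    _LA: int = field(default=49, repr=False)

    @property
    def core_cutoff(self) -> float:
        return (self._LR / self._LA) * self.sigma

    @property
    def core_prefactor(self) -> float:
        return self._LR * (self._LR / self._LA) ** self._LA

    @property
    def cutoff(self) -> float:
        """Interaction range: beyond this the pair energy is identically 0."""
        return max(self.core_cutoff, self.well_position + self.well_halfwidth)

    @property
    def angular_scale(self) -> float:
        """Gaussian scale a such that Omega = 1/2 at theta = angular_hwhm."""
        return (1.0 - np.cos(self.angular_hwhm)) / np.sqrt(2.0 * np.log(2.0))

    def __post_init__(self) -> None:
        if self.well_position <= self.core_cutoff:
            raise ValueError("well_position must lie beyond the core cutoff")
        if self.well_halfwidth <= 0 or self.angular_hwhm <= 0:
            raise ValueError("well_halfwidth and angular_hwhm must be positive")


class ForceField:
    """A mixture compiled into dense per-species tables for fast evaluation.

    Species are padded to ``max_patches`` slots; padding slots carry class
    index 0, whose row/column in the depth matrix is identically zero.
    """

    def __init__(self, mixture: "MixtureSpec", params: PotentialParams | None = None):
        from .model import MixtureSpec  # noqa: F401  (runtime import to avoid cycle)

        self.mixture = mixture
        self.params = params or PotentialParams()
        species = mixture.species
        self.species_names = tuple(sp.name for sp in species)
        labels = sorted({c.label for sp in species for c in sp.patch_classes})
        self._class_index = {lab: k + 1 for k, lab in enumerate(labels)}  # 0 = padding
        n_class = len(labels) + 1
        D = np.zeros((n_class, n_class))
        for a in labels:
            for b in labels:
                if (a, b) in mixture.matrix:
                    D[self._class_index[a], self._class_index[b]] = mixture.matrix.depth(a, b)
        self.depth_table = D
        self.max_patches = max(sp.n_patches for sp in species)
        self.n_patches_per_species = np.array([sp.n_patches for sp in species], dtype=np.intp)
        S = len(species)
        self.body_patches = np.zeros((S, self.max_patches, 3))
        self.patch_class = np.zeros((S, self.max_patches), dtype=np.intp)
        for s, sp in enumerate(species):
            self.body_patches[s, : sp.n_patches] = sp.directions
            self.patch_class[s, : sp.n_patches] = [
                self._class_index[c.label] for c in sp.patch_classes
            ]

    def species_id(self, name: str) -> int:
        return self.species_names.index(name)

    # -- core potential -----------------------------------------------------

    def _core(self, r: np.ndarray):
        p = self.params
        u = np.zeros_like(r)
        du = np.zeros_like(r)
        inside = r < p.core_cutoff
        if np.any(inside):
            x = p.sigma / r[inside]
            xla = x ** p._LA
            xlr = xla * x ** (p._LR - p._LA)
            c = p.core_prefactor * p.core_epsilon
            u[inside] = c * (xlr - xla) + p.core_epsilon
            du[inside] = -c * (p._LR * xlr - p._LA * xla) / r[inside]
        return u, du

    def _radial_bump(self, r: np.ndarray):
        p = self.params
        phi = np.zeros_like(r)
        dphi = np.zeros_like(r)
        inside = np.abs(r - p.well_position) < p.well_halfwidth
        if np.any(inside):
            x = 0.5 * np.pi * (r[inside] - p.well_position) / p.well_halfwidth
            phi[inside] = np.cos(x) ** 2
            dphi[inside] = -0.5 * np.pi / p.well_halfwidth * np.sin(2.0 * x)
        return phi, dphi

    def _angular(self, c: np.ndarray):
        # the Gaussian tail is truncated once Omega < e^-18 (misaligned patches)
        a = self.params.angular_scale
        dev = 1.0 - c
        om = np.where(dev < ANGULAR_PRUNE * a, np.exp(-(dev ** 2) / (2.0 * a * a)), 0.0)
        dom = om * dev / (a * a)
        return om, dom

    # -- pair evaluation ----------------------------------------------------

    def evaluate_pairs(
        self,
        rvec: np.ndarray,
        quat_i: np.ndarray,
        quat_j: np.ndarray,
        species_i: np.ndarray,
        species_j: np.ndarray,
        patch_energy: bool = False,
    ):
        """Energy/forces/torques for M pair geometries.

        rvec points from particle i to particle j (minimum image already
        applied).  Returns ``(energy, grad_j, torque_i, torque_j)`` per
        pair, where grad_j is the gradient of the pair energy with respect
        to the position of j (force on j = -grad_j, force on i = +grad_j).
        With ``patch_energy=True`` also returns the (M, P, P) per-patch-pair
        attraction energies (used for bond detection).
        """
        p = self.params
        rvec = np.atleast_2d(np.asarray(rvec, dtype=float))
        r = np.linalg.norm(rvec, axis=1)
        if np.any(r < p.min_separation):
            raise OverlapError(
                f"center-center distance below {p.min_separation} sigma: invalid configuration"
            )
        rhat = rvec / r[:, None]

        ucore, ducore = self._core(r)
        energy = ucore.copy()
        dUdr = ducore.copy()

        ni = rotate_vectors(quat_i[:, None, :], self.body_patches[species_i])
        nj = rotate_vectors(quat_j[:, None, :], self.body_patches[species_j])
        ca = np.einsum("mpk,mk->mp", ni, rhat)          # patch a on i toward j
        cb = -np.einsum("mpk,mk->mp", nj, rhat)         # patch b on j toward i

        phi, dphi = self._radial_bump(r)
        oa, doa = self._angular(ca)
        ob, dob = self._angular(cb)
        depth = self.depth_table[self.patch_class[species_i][:, :, None],
                                 self.patch_class[species_j][:, None, :]]

        # u_ab = -eps * depth * phi * oa * ob
        pref = -p.epsilon * depth * phi[:, None, None]
        e_ab = pref * oa[:, :, None] * ob[:, None, :]
        energy += e_ab.sum(axis=(1, 2))

        # radial part of the gradient
        dUdr += (-p.epsilon * depth * dphi[:, None, None]
                 * oa[:, :, None] * ob[:, None, :]).sum(axis=(1, 2))

        # angular parts: dU/dc_a and dU/dc_b, contracted over the partner patch
        dU_dca = (pref * doa[:, :, None] * ob[:, None, :]).sum(axis=2)   # (M, P)
        dU_dcb = (pref * oa[:, :, None] * dob[:, None, :]).sum(axis=1)   # (M, P)

        # grad wrt r_j:  dU/dr * rhat + sum_a dU/dc_a * (n_a - c_a rhat)/r
        #                            + sum_b dU/dc_b * (-n_b - c_b rhat)/r
        grad = dUdr[:, None] * rhat
        grad += (dU_dca[:, :, None] * (ni - ca[:, :, None] * rhat[:, None, :])).sum(axis=1) / r[:, None]
        grad += (dU_dcb[:, :, None] * (-nj - cb[:, :, None] * rhat[:, None, :])).sum(axis=1) / r[:, None]

        # torques: tau_i = -sum_a dU/dc_a (n_a x rhat); tau_j = +sum_b dU/dc_b (n_b x rhat)
        tau_i = -(dU_dca[:, :, None] * np.cross(ni, rhat[:, None, :])).sum(axis=1)
        tau_j = (dU_dcb[:, :, None] * np.cross(nj, rhat[:, None, :])).sum(axis=1)

        if patch_energy:
            return energy, grad, tau_i, tau_j, e_ab
        return energy, grad, tau_i, tau_j


def _minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    return disp - box * np.round(disp / box)


def _system_compute(
    ff: "ForceField",
    positions: np.ndarray,
    orientations: np.ndarray,
    species_index: np.ndarray,
    box: np.ndarray,
    pairs: np.ndarray,
    want_bonds: bool = False,
    backend: str = "auto",
):
    """Aggregate pair interactions over a pair list (numba or numpy backend).

    Returns ``(forces, torques, energy, virial, bond_energies)`` where
    ``bond_energies`` aligns with ``pairs`` and holds each pair's total
    patch attraction (zeros unless ``want_bonds``).
    """
    from ._kernels import HAVE_NUMBA, pair_forces_kernel, rotate_labdirs

    n = len(positions)
    p = ff.params
    if len(pairs) == 0:
        return (np.zeros((n, 3)), np.zeros((n, 3)), 0.0, np.zeros((3, 3)), np.zeros(0))
    if backend == "numba" or (backend == "auto" and HAVE_NUMBA):
        labdirs = rotate_labdirs(orientations, ff.body_patches, species_index.astype(np.int64))
        forces, torques, energy, virial, bonds, overlap = pair_forces_kernel(
            positions,
            box.astype(float),
            pairs[:, 0].astype(np.int64),
            pairs[:, 1].astype(np.int64),
            labdirs,
            ff.patch_class[species_index].astype(np.int64),
            ff.n_patches_per_species[species_index].astype(np.int64),
            ff.depth_table,
            p.epsilon,
            p.core_epsilon,
            p.core_prefactor,
            p.core_cutoff,
            p.sigma,
            p.well_position,
            p.well_halfwidth,
            p.angular_scale,
            ANGULAR_PRUNE,
            p.cutoff,
            p.min_separation,
            want_bonds,
        )
        if overlap >= 0:
            raise OverlapError(
                f"center-center distance below {p.min_separation} sigma: invalid configuration"
            )
        return forces, torques, float(energy), virial, bonds
    # numpy reference path
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    dvec = _minimum_image(positions[j_idx] - positions[i_idx], box)
    r2 = np.einsum("ij,ij->i", dvec, dvec)
    keep = r2 < p.cutoff ** 2
    bonds_full = np.zeros(len(pairs))
    forces = np.zeros((n, 3))
    torques = np.zeros((n, 3))
    if not np.any(keep):
        return forces, torques, 0.0, np.zeros((3, 3)), bonds_full
    i_k, j_k, dvec_k = i_idx[keep], j_idx[keep], dvec[keep]
    e, grad, tau_i, tau_j, e_ab = ff.evaluate_pairs(
        dvec_k,
        orientations[i_k],
        orientations[j_k],
        species_index[i_k],
        species_index[j_k],
        patch_energy=True,
    )
    for k in range(3):
        forces[:, k] = np.bincount(i_k, grad[:, k], minlength=n) - np.bincount(
            j_k, grad[:, k], minlength=n
        )
        torques[:, k] = np.bincount(i_k, tau_i[:, k], minlength=n) + np.bincount(
            j_k, tau_j[:, k], minlength=n
        )
    virial = -np.einsum("mi,mj->ij", dvec_k, grad)
    if want_bonds:
        bonds_full[keep] = e_ab.sum(axis=(1, 2))
    return forces, torques, float(e.sum()), virial, bonds_full


def pair_interaction(
    r_ij: np.ndarray,
    q_i: np.ndarray,
    q_j: np.ndarray,
    species_i: "SpeciesSpec",
    species_j: "SpeciesSpec",
    matrix: "InteractionMatrix",
    params: PotentialParams | None = None,
):
    """Energy, force on i and torques for a single pair.

    ``r_ij`` is the displacement from particle i to particle j in sigma;
    orientations are unit quaternions.  Force on j is the negative of the
    returned force on i (Newton's third law).
    """
    from .model import MixtureSpec

    if species_i.name == species_j.name:
        comp = ((species_i, 1),)
        si = sj = 0
    else:
        comp = ((species_i, 1), (species_j, 1))
        si, sj = 0, 1
    ff = ForceField(MixtureSpec("pair", comp, matrix), params)
    e, grad, tau_i, tau_j = ff.evaluate_pairs(
        np.asarray(r_ij, dtype=float)[None, :],
        np.asarray(q_i, dtype=float)[None, :],
        np.asarray(q_j, dtype=float)[None, :],
        np.array([si]),
        np.array([sj]),
    )
    return float(e[0]), grad[0], tau_i[0], tau_j[0]
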