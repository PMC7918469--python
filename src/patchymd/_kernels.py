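"""Numba-compiled force loop; numerically identical to the numpy reference.

The kernel walks a precomputed neighbor-pair list, applies the minimum
image, and accumulates forces, torques, potential energy, the virial
tensor and (optionally) per-pair patch-attraction energies for bond
detection.  `patchymd.potential.ForceField.evaluate_pairs` is the readable
reference implementation; the two are cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def rotate_labdirs(quats, body_patches, species_index):
    """Lab-frame patch directions (N, P, 3) from unit quaternions."""
    n = quats.shape[0]
    p = body_patches.shape[1]
    out = np.empty((n, p, 3))
    for i in range(n):
        w, x, y, z = quats[i, 0], quats[i, 1], quats[i, 2], quats[i, 3]
        r00 = 1.0 - 2.0 * (y * y + z * z)
        r01 = 2.0 * (x * y - w * z)
        r02 = 2.0 * (x * z + w * y)
        r10 = 2.0 * (x * y + w * z)
        r11 = 1.0 - 2.0 * (x * x + z * z)
        r12 = 2.0 * (y * z - w * x)
        r20 = 2.0 * (x * z - w * y)
        r21 = 2.0 * (y * z + w * x)
        r22 = 1.0 - 2.0 * (x * x + y * y)
        s = species_index[i]
        for k in range(p):
            bx = body_patches[s, k, 0]
            by = body_patches[s, k, 1]
            bz = body_patches[s, k, 2]
            out[i, k, 0] = r00 * bx + r01 * by + r02 * bz
            out[i, k, 1] = r10 * bx + r11 * by + r12 * bz
            out[i, k, 2] = r20 * bx + r21 * by + r22 * bz
    return out


@njit(cache=True)
def rotate_quats_inplace(quats, ang_momenta, inv_inertia, dt):
    """Free rigid-body drift for isotropic inertia: rotate each quaternion
    by omega * dt and renormalize."""
    n = quats.shape[0]
    for i in range(n):
        px = ang_momenta[i, 0] * inv_inertia * dt
        py = ang_momenta[i, 1] * inv_inertia * dt
        pz = ang_momenta[i, 2] * inv_inertia * dt
        angle = math.sqrt(px * px + py * py + pz * pz)
        half = 0.5 * angle
        if angle < 1e-8:
            f = 0.5 - angle * angle / 48.0
        else:
            f = math.sin(half) / angle
        aw = math.cos(half)
        ax = f * px
        ay = f * py
        az = f * pz
        bw, bx, by, bz = quats[i, 0], quats[i, 1], quats[i, 2], quats[i, 3]
        w = aw * bw - ax * bx - ay * by - az * bz
        x = aw * bx + ax * bw + ay * bz - az * by
        y = aw * by - ax * bz + ay * bw + az * bx
        z = aw * bz + ax * by - ay * bx + az * bw
        norm = math.sqrt(w * w + x * x + y * y + z * z)
        quats[i, 0] = w / norm
        quats[i, 1] = x / norm
        quats[i, 2] = y / norm
        quats[i, 3] = z / norm


@njit(cache=True)
def max_displacement_sq(positions, ref, box):
    out = 0.0
    for i in range(positions.shape[0]):
        d2 = 0.0
        for k in range(3):
            d = positions[i, k] - ref[i, k]
            d -= box[k] * math.floor(d / box[k] + 0.5)
            d2 += d * d
        if d2 > out:
            out = d2
    return out


@njit(cache=True)
def pair_forces_kernel(
    positions,
    box,
    i_idx,
    j_idx,
    labdirs,      # (N, P, 3) lab-frame patch directions
    clsidx,       # (N, P) patch-class indices (0 = padding)
    npatch,       # (N,) patches per particle
    depth,        # (C, C) well-depth table
    eps,
    core_eps,
    core_pref,
    core_cut,
    sigma,
    well_pos,
    well_hw,
    ang_scale,
    ang_prune,
    cutoff,
    min_sep,
    want_bonds,
):
    n = positions.shape[0]
    m = i_idx.shape[0]
    forces = np.zeros((n, 3))
    torques = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    bonds = np.zeros(m if want_bonds else 0)
    energy = 0.0
    overlap = -1
    cut2 = cutoff * cutoff
    a2 = ang_scale * ang_scale
    prune = ang_prune * ang_scale
    for p in range(m):
        i = i_idx[p]
        j = j_idx[p]
        dx = positions[j, 0] - positions[i, 0]
        dy = positions[j, 1] - positions[i, 1]
        dz = positions[j, 2] - positions[i, 2]
        dx -= box[0] * math.floor(dx / box[0] + 0.5)
        dy -= box[1] * math.floor(dy / box[1] + 0.5)
        dz -= box[2] * math.floor(dz / box[2] + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut2:
            continue
        r = math.sqrt(r2)
        if r < min_sep:
            overlap = p
            break
        hx = dx / r
        hy = dy / r
        hz = dz / r
        # pseudo-hard-sphere core
        dudr = 0.0
        if r < core_cut:
            x = sigma / r
            xla = x ** 49
            xlr = xla * x
            c = core_pref * core_eps
            energy += c * (xlr - xla) + core_eps
            dudr += -c * (50.0 * xlr - 49.0 * xla) / r
        # patch attraction
        dr = r - well_pos
        if dr < well_hw and dr > -well_hw:
            arg = 0.5 * math.pi * dr / well_hw
            cosv = math.cos(arg)
            phi = cosv * cosv
            dphi = -0.5 * math.pi / well_hw * math.sin(2.0 * arg)
            e_pair = 0.0
            for ap in range(npatch[i]):
                nax = labdirs[i, ap, 0]
                nay = labdirs[i, ap, 1]
                naz = labdirs[i, ap, 2]
                ca = nax * hx + nay * hy + naz * hz
                deva = 1.0 - ca
                if deva >= prune:
                    continue
                oa = math.exp(-deva * deva / (2.0 * a2))
                doa = oa * deva / a2
                for bp in range(npatch[j]):
                    d = depth[clsidx[i, ap], clsidx[j, bp]]
                    if d == 0.0:
                        continue
                    nbx = labdirs[j, bp, 0]
                    nby = labdirs[j, bp, 1]
                    nbz = labdirs[j, bp, 2]
                    cb = -(nbx * hx + nby * hy + nbz * hz)
                    devb = 1.0 - cb
                    if devb >= prune:
                        continue
                    ob = math.exp(-devb * devb / (2.0 * a2))
                    dob = ob * devb / a2
                    pref = -eps * d
                    e_ab = pref * phi * oa * ob
                    e_pair += e_ab
                    dudr += pref * dphi * oa * ob
                    du_dca = pref * phi * doa * ob
                    du_dcb = pref * phi * oa * dob
                    # grad wrt r_j, angular contributions
                    ga = du_dca / r
                    gb = du_dcb / r
                    gx = ga * (nax - ca * hx) + gb * (-nbx - cb * hx)
                    gy = ga * (nay - ca * hy) + gb * (-nby - cb * hy)
                    gz = ga * (naz - ca * hz) + gb * (-nbz - cb * hz)
                    forces[i, 0] += gx
                    forces[i, 1] += gy
                    forces[i, 2] += gz
                    forces[j, 0] -= gx
                    forces[j, 1] -= gy
                    forces[j, 2] -= gz
                    virial[0, 0] -= dx * gx
                    virial[0, 1] -= dx * gy
                    virial[0, 2] -= dx * gz
                    virial[1, 0] -= dy * gx
                    virial[1, 1] -= dy * gy
                    virial[1, 2] -= dy * gz
                    virial[2, 0] -= dz * gx
                    virial[2, 1] -= dz * gy
                    virial[2, 2] -= dz * gz
                    # torques: tau_i = -dU/dca (n_a x rhat); tau_j = +dU/dcb (n_b x rhat)
                    torques[i, 0] += -du_dca * (nay * hz - naz * hy)
                    torques[i, 1] += -du_dca * (naz * hx - nax * hz)
                    torques[i, 2] += -du_dca * (nax * hy - nay * hx)
                    torques[j, 0] += du_dcb * (nby * hz - nbz * hy)
                    torques[j, 1] += du_dcb * (nbz * hx - nbx * hz)
                    torques[j, 2] += du_dcb * (nbx * hy - nby * hx)
            energy += e_pair
            if want_bonds:
                bonds[p] = e_pair
        # radial force part (core + patch radial derivative)
        if dudr != 0.0:
            gx = dudr * hx
            gy = dudr * hy
            gz = dudr * hz
            forces[i, 0] += gx
            forces[i, 1] += gy
            forces[i, 2] += gz
            forces[j, 0] -= gx
            forces[j, 1] -= gy
            forces[j, 2] -= gz
            virial[0, 0] -= dx * gx
            virial[0, 1] -= dx * gy
            virial[0, 2] -= dx * gz
            virial[1, 0] -= dy * gx
            virial[1, 1] -= dy * gy
            virial[1, 2] -= dy * gz
            virial[2, 0] -= dz * gx
            virial[2, 1] -= dz * gy
            virial[2, 2] -= dz * gz
    return forces, torques, energy, virial, bonds, overlap
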