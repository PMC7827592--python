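"""Numba kernels: bonded/nonbonded energies and forces, Ewald sums, MD block.

Unit conventions inside the kernels: lengths in nm, energies in k_BT,
charges in e, forces in k_BT/nm.  The Langevin integrator uses a reduced
particle mass m = 1 and k_BT = 1, so the time unit is nm * sqrt(m/k_BT);
the caller converts the protocol time step (given in tau = sigma*sqrt(m/eps))
into this unit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi
SQRT_PI = math.sqrt(math.pi)


@njit(cache=True)
def _min_image(d: float, L: float) -> float:
    return d - L * round(d / L)


@njit(cache=True)
def bond_energy_forces(pos, bonds, b0, kh, L, forces, do_forces):
    """Harmonic bond energy U = (kh/2)(r - b)^2 summed over the bond list."""
    e = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b0[m]
        e += 0.5 * kh * dr * dr
        if do_forces and r > 0.0:
            fmag = -kh * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return e


@njit(cache=True)
def _wca_pair(r2, eps, sigma, rcut):
    """WCA energy and -dU/dr / r for one pair (0 beyond rcut)."""
    if r2 >= rcut * rcut:
        return 0.0, 0.0
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    e = 4.0 * eps * (s12 - s6) + eps
    fr = 24.0 * eps * (2.0 * s12 - s6) / r2  # (1/r) dU/dr with sign for repulsion
    return e, fr


@njit(cache=True)
def pair_energy_forces(
    pos, q, n, L, lB, alpha, rc_coul, eps, sigma, rcut_wca, forces, do_forces
):
    """Minimum-image pair sum: WCA + Ewald real-space Coulomb.

    Returns (E_wca, E_real).  ``eps <= 0`` disables WCA, ``lB <= 0``
    disables electrostatics.
    """
    e_wca = 0.0
    e_real = 0.0
    do_wca = eps > 0.0
    do_coul = lB > 0.0
    rc2 = rc_coul * rc_coul
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        qi = q[i]
        for j in range(i + 1, n):
            dx = _min_image(xi - pos[j, 0], L)
            dy = _min_image(yi - pos[j, 1], L)
            dz = _min_image(zi - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            fr = 0.0
            if do_wca:
                ew, fw = _wca_pair(r2, eps, sigma, rcut_wca)
                e_wca += ew
                fr += fw
            if do_coul and r2 < rc2:
                qq = qi * q[j]
                if qq != 0.0:
                    r = math.sqrt(r2)
                    ar = alpha * r
                    erfc_ar = math.erfc(ar)
                    e_real += lB * qq * erfc_ar / r
                    if do_forces:
                        fr += (
                            lB
                            * qq
                            * (
                                erfc_ar / r
                                + 2.0 * alpha / SQRT_PI * math.exp(-ar * ar)
                            )
                            / r2
                        )
            if do_forces and fr != 0.0:
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
    return e_wca, e_real


@njit(cache=True, inline="always")
def _fill_phase_tables(pos, j, L, nmax, tre, tim):
    """Per-axis tables exp(i 2 pi n x_a / L) for n = 0..nmax (recursion)."""
    for a in range(3):
        ph = TWO_PI * pos[j, a] / L
        c1 = math.cos(ph)
        s1 = math.sin(ph)
        tre[a, 0] = 1.0
        tim[a, 0] = 0.0
        cr = 1.0
        ci = 0.0
        for nn in range(1, nmax + 1):
            nr = cr * c1 - ci * s1
            ci = cr * s1 + ci * c1
            cr = nr
            tre[a, nn] = cr
            tim[a, nn] = ci


@njit(cache=True, inline="always")
def _phase_product(kint, m, tre, tim):
    """exp(i k.r_j) from the per-axis tables; kz >= 0 by construction."""
    nx = kint[m, 0]
    ny = kint[m, 1]
    nz = kint[m, 2]
    ax = nx if nx >= 0 else -nx
    ar = tre[0, ax]
    ai = tim[0, ax] if nx >= 0 else -tim[0, ax]
    ay = ny if ny >= 0 else -ny
    br = tre[1, ay]
    bi = tim[1, ay] if ny >= 0 else -tim[1, ay]
    cr = ar * br - ai * bi
    ci = ar * bi + ai * br
    dr = tre[2, nz]
    di = tim[2, nz]
    return cr * dr - ci * di, cr * di + ci * dr


@njit(cache=True)
def structure_factor(pos, q, n, kint, nmax, L, out_re, out_im):
    """S(k) = sum_j q_j exp(i k.r_j) for each integer triple row of ``kint``."""
    nk = kint.shape[0]
    for m in range(nk):
        out_re[m] = 0.0
        out_im[m] = 0.0
    tre = np.empty((3, nmax + 1))
    tim = np.empty((3, nmax + 1))
    for j in range(n):
        qj = q[j]
        if qj == 0.0:
            continue
        _fill_phase_tables(pos, j, L, nmax, tre, tim)
        for m in range(nk):
            pr, pi = _phase_product(kint, m, tre, tim)
            out_re[m] += qj * pr
            out_im[m] += qj * pi


@njit(cache=True)
def kspace_energy(s_re, s_im, coef, prefactor):
    """Reciprocal-space Ewald energy from a cached structure factor.

    ``prefactor`` = 4*pi*lB/V (the half-space factor 2 is included).
    """
    e = 0.0
    for m in range(s_re.shape[0]):
        e += coef[m] * (s_re[m] * s_re[m] + s_im[m] * s_im[m])
    return prefactor * e


@njit(cache=True)
def kspace_forces(pos, q, n, kvecs, kint, nmax, L, coef, prefactor, s_re, s_im, forces):
    """Accumulate reciprocal-space forces; returns the reciprocal energy."""
    nk = kvecs.shape[0]
    e = 0.0
    for m in range(nk):
        e += coef[m] * (s_re[m] * s_re[m] + s_im[m] * s_im[m])
    tre = np.empty((3, nmax + 1))
    tim = np.empty((3, nmax + 1))
    for j in range(n):
        qj = q[j]
        if qj == 0.0:
            continue
        _fill_phase_tables(pos, j, L, nmax, tre, tim)
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for m in range(nk):
            pr, pi = _phase_product(kint, m, tre, tim)
            # Im(S* exp(i k.r_j)) = S_re * pi - S_im * pr
            w = coef[m] * (s_re[m] * pi - s_im[m] * pr)
            fx += w * kvecs[m, 0]
            fy += w * kvecs[m, 1]
            fz += w * kvecs[m, 2]
        forces[j, 0] += 2.0 * prefactor * qj * fx
        forces[j, 1] += 2.0 * prefactor * qj * fy
        forces[j, 2] += 2.0 * prefactor * qj * fz
    return prefactor * e


@njit(cache=True)
def kspace_delta(kvecs, coef, prefactor, s_re, s_im, dpos, dq, ds_re, ds_im):
    """Reciprocal-space energy change for a few point-charge changes.

    ``dpos``/``dq`` list the positions and charge increments (a site toggle
    is dq at the bead position; an insertion/deletion is +/-q at the ion
    position).  Writes the structure-factor increment into ``ds_re/ds_im``
    so the caller can commit it on acceptance.
    """
    nk = kvecs.shape[0]
    nm = dq.shape[0]
    de = 0.0
    for m in range(nk):
        dsr = 0.0
        dsi = 0.0
        kx = kvecs[m, 0]
        ky = kvecs[m, 1]
        kz = kvecs[m, 2]
        for t in range(nm):
            ph = kx * dpos[t, 0] + ky * dpos[t, 1] + kz * dpos[t, 2]
            dsr += dq[t] * math.cos(ph)
            dsi += dq[t] * math.sin(ph)
        de += coef[m] * (
            2.0 * (s_re[m] * dsr + s_im[m] * dsi) + dsr * dsr + dsi * dsi
        )
        ds_re[m] = dsr
        ds_im[m] = dsi
    return prefactor * de


@njit(cache=True)
def delta_real_charge(pos, q, n, L, lB, alpha, rc_coul, idx, dq):
    """Real-space Ewald energy change from changing q[idx] by dq."""
    e = 0.0
    rc2 = rc_coul * rc_coul
    xi = pos[idx, 0]
    yi = pos[idx, 1]
    zi = pos[idx, 2]
    for j in range(n):
        if j == idx:
            continue
        qj = q[j]
        if qj == 0.0:
            continue
        dx = _min_image(xi - pos[j, 0], L)
        dy = _min_image(yi - pos[j, 1], L)
        dz = _min_image(zi - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            r = math.sqrt(r2)
            e += lB * dq * qj * math.erfc(alpha * r) / r
    return e


@njit(cache=True)
def particle_interaction_energy(
    pos, q, n, L, lB, alpha, rc_coul, eps, sigma, rcut_wca, rp, qp, skip
):
    """Interaction energy of a test particle at ``rp`` (charge qp) with all
    active particles except index ``skip`` (pass -1 to include everyone).

    Used for insertion (positive sign) and deletion (caller negates).
    """
    e = 0.0
    rc2 = rc_coul * rc_coul
    do_wca = eps > 0.0
    do_coul = lB > 0.0 and qp != 0.0
    for j in range(n):
        if j == skip:
            continue
        dx = _min_image(rp[0] - pos[j, 0], L)
        dy = _min_image(rp[1] - pos[j, 1], L)
        dz = _min_image(rp[2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-20:
            return 1e30  # exact overlap: certain rejection
        if do_wca:
            ew, _ = _wca_pair(r2, eps, sigma, rcut_wca)
            e += ew
        if do_coul and r2 < rc2 and q[j] != 0.0:
            r = math.sqrt(r2)
            e += lB * qp * q[j] * math.erfc(alpha * r) / r
    return e


@njit(cache=True)
def kspace_sf_forces(
    pos, q, n, kvecs, kint, nmax, L, coef, prefactor, s_re, s_im, forces,
    phase_re, phase_im,
):
    """Structure factor and reciprocal-space forces in one pass.

    The per-(particle, k) phase factors computed while accumulating S(k)
    are kept in ``phase_re/phase_im`` (shape (n, n_k) scratch) and reused
    for the force pass.  Returns the reciprocal energy.
    """
    nk = kint.shape[0]
    for m in range(nk):
        s_re[m] = 0.0
        s_im[m] = 0.0
    tre = np.empty((3, nmax + 1))
    tim = np.empty((3, nmax + 1))
    for j in range(n):
        qj = q[j]
        if qj == 0.0:
            continue
        _fill_phase_tables(pos, j, L, nmax, tre, tim)
        for m in range(nk):
            pr, pi = _phase_product(kint, m, tre, tim)
            phase_re[j, m] = pr
            phase_im[j, m] = pi
            s_re[m] += qj * pr
            s_im[m] += qj * pi
    e = 0.0
    for m in range(nk):
        e += coef[m] * (s_re[m] * s_re[m] + s_im[m] * s_im[m])
    for j in range(n):
        qj = q[j]
        if qj == 0.0:
            continue
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for m in range(nk):
            w = coef[m] * (s_re[m] * phase_im[j, m] - s_im[m] * phase_re[j, m])
            fx += w * kvecs[m, 0]
            fy += w * kvecs[m, 1]
            fz += w * kvecs[m, 2]
        forces[j, 0] += 2.0 * prefactor * qj * fx
        forces[j, 1] += 2.0 * prefactor * qj * fy
        forces[j, 2] += 2.0 * prefactor * qj * fz
    return prefactor * e


@njit(cache=True)
def compute_forces(
    pos, q, n, bonds, b0, kh, L, lB, alpha, rc_coul,
    eps, sigma, rcut_wca, kvecs, kint, nmax, coef, prefactor, s_re, s_im, forces,
    phase_re, phase_im,
):
    """Total conservative forces; returns total potential energy in k_BT."""
    for j in range(n):
        forces[j, 0] = 0.0
        forces[j, 1] = 0.0
        forces[j, 2] = 0.0
    e = bond_energy_forces(pos, bonds, b0, kh, L, forces, True)
    e_wca, e_real = pair_energy_forces(
        pos, q, n, L, lB, alpha, rc_coul, eps, sigma, rcut_wca, forces, True
    )
    e += e_wca + e_real
    if lB > 0.0:
        e += kspace_sf_forces(
            pos, q, n, kvecs, kint, nmax, L, coef, prefactor, s_re, s_im,
            forces, phase_re, phase_im,
        )
        sq = 0.0
        for j in range(n):
            sq += q[j] * q[j]
        e -= lB * alpha / SQRT_PI * sq
    return e


@njit(cache=True)
def md_block(
    pos, vel, img, q, n, bonds, b0, kh, L, lB, alpha, rc_coul,
    eps, sigma, rcut_wca, kvecs, kint, nmax, coef, prefactor, s_re, s_im,
    dt, gamma, n_steps, noise, forces, phase_re, phase_im,
):
    """Velocity-Verlet Langevin dynamics for ``n_steps`` steps.

    The friction and the pre-drawn Gaussian kicks (``noise``, scaled to
    sqrt(2*gamma*kBT*m/dt) by the caller) enter the force on both half
    steps; with gamma = 0 and zero noise this reduces to plain velocity
    Verlet.  Positions are wrapped into [0, L) with image counters in
    ``img``.  Returns 0 on success, 1 if a displacement exceeded L/2
    (unstable configuration).
    """
    e = compute_forces(
        pos, q, n, bonds, b0, kh, L, lB, alpha, rc_coul,
        eps, sigma, rcut_wca, kvecs, kint, nmax, coef, prefactor, s_re, s_im,
        forces, phase_re, phase_im,
    )
    half = L / 2.0
    for step in range(n_steps):
        for j in range(n):
            for a in range(3):
                f = forces[j, a] - gamma * vel[j, a] + noise[step, j, a]
                vel[j, a] += 0.5 * dt * f
                dx = dt * vel[j, a]
                if abs(dx) > half:
                    return 1
                x = pos[j, a] + dx
                # wrap into [0, L)
                shift = int(math.floor(x / L))
                pos[j, a] = x - shift * L
                img[j, a] += shift
        e = compute_forces(
            pos, q, n, bonds, b0, kh, L, lB, alpha, rc_coul,
            eps, sigma, rcut_wca, kvecs, kint, nmax, coef, prefactor, s_re, s_im,
            forces, phase_re, phase_im,
        )
        for j in range(n):
            for a in range(3):
                f = forces[j, a] - gamma * vel[j, a] + noise[step, j, a]
                vel[j, a] += 0.5 * dt * f
    return 0
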