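"""Numba-accelerated Metropolis kernel for the Cα Gō / quasi-chemical model.

The kernel recomputes the full potential per proposal (topologies here are
small, and the branch-free loops vectorize well), applies crankshaft /
single-bead moves, and carries the ratchet-and-pawl bias on the sharp
native-contact fraction Q.  The pure-NumPy :class:`PotentialEnergyModel`
remains the reference implementation; tests pin the kernel against it.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _energy(x, bond_r0, bond_k,
            ang_t0, angle_k,
            dih_p0, k1, k3,
            nat_i, nat_j, nat_r0, eps_nat,
            nn_i, nn_j, nn_e, lam, sigma_rep, eps_rep, r_on, nn_cut):
    n = x.shape[0]
    e = 0.0
    for b in range(n - 1):
        dx = x[b + 1, 0] - x[b, 0]
        dy = x[b + 1, 1] - x[b, 1]
        dz = x[b + 1, 2] - x[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += bond_k * (r - bond_r0[b]) ** 2
    for b in range(n - 2):
        ux, uy, uz = x[b, 0] - x[b + 1, 0], x[b, 1] - x[b + 1, 1], x[b, 2] - x[b + 1, 2]
        vx, vy, vz = x[b + 2, 0] - x[b + 1, 0], x[b + 2, 1] - x[b + 1, 1], x[b + 2, 2] - x[b + 1, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        t = math.acos(c)
        e += angle_k * (t - ang_t0[b]) ** 2
    for b in range(n - 3):
        b1x, b1y, b1z = x[b + 1, 0] - x[b, 0], x[b + 1, 1] - x[b, 1], x[b + 1, 2] - x[b, 2]
        b2x, b2y, b2z = x[b + 2, 0] - x[b + 1, 0], x[b + 2, 1] - x[b + 1, 1], x[b + 2, 2] - x[b + 1, 2]
        b3x, b3y, b3z = x[b + 3, 0] - x[b + 2, 0], x[b + 3, 1] - x[b + 2, 1], x[b + 3, 2] - x[b + 2, 2]
        n1x, n1y, n1z = b1y * b2z - b1z * b2y, b1z * b2x - b1x * b2z, b1x * b2y - b1y * b2x
        n2x, n2y, n2z = b2y * b3z - b2z * b3y, b2z * b3x - b2x * b3z, b2x * b3y - b2y * b3x
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx, my, mz = n1y * n2z - n1z * n2y, n1z * n2x - n1x * n2z, n1x * n2y - n1y * n2x
        y = (mx * b2x + my * b2y + mz * b2z) / nb2
        cph = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(y, cph)
        dp = phi - dih_p0[b]
        e += k1 * (1.0 - math.cos(dp)) + k3 * (1.0 - math.cos(3.0 * dp))
    for p in range(nat_i.shape[0]):
        i, j = nat_i[p], nat_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        q = nat_r0[p] / r
        q2 = q * q
        q10 = q2 * q2 * q2 * q2 * q2
        e += eps_nat * (5.0 * q10 * q2 - 6.0 * q10)
    for p in range(nn_i.shape[0]):
        i, j = nn_i[p], nn_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        s = sigma_rep / r
        s2 = s * s
        e += eps_rep * (s2 * s2 * s2) ** 2
        if lam != 0.0 and r < nn_cut:
            if r <= r_on:
                sw = 1.0
            else:
                sw = 0.5 * (1.0 + math.cos(math.pi * (r - r_on) / (nn_cut - r_on)))
            e += lam * nn_e[p] * sw
    return e


@njit(cache=True)
def _q_sharp(x, nat_i, nat_j, nat_r0, tol):
    m = nat_i.shape[0]
    if m == 0:
        return 0.0
    cnt = 0
    for p in range(m):
        i, j = nat_i[p], nat_j[p]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= tol * nat_r0[p]:
            cnt += 1
    return cnt / m


@njit(cache=True)
def mc_run(x0, n_sweeps, stride, kBT, seed,
           crank_max, disp_max, mix, seg_lo, seg_hi,
           bond_r0, bond_k, ang_t0, angle_k, dih_p0, k1, k3,
           nat_i, nat_j, nat_r0, eps_nat,
           nn_i, nn_j, nn_e, lam, sigma_rep, eps_rep, r_on, nn_cut,
           k_ratchet, tol, q_record0, q_stop):
    """Sweep-based Metropolis run with optional ratchet bias.

    Returns (frames, energies, qs, q_records, n_accepted, n_frames_used).
    Frames are saved every ``stride`` sweeps plus the initial state.
    """
    np.random.seed(seed)
    n = x0.shape[0]
    x = x0.copy()
    n_save = n_sweeps // stride + 1
    frames = np.empty((n_save, n, 3))
    energies = np.empty(n_save)
    qs = np.empty(n_save)
    qrecs = np.empty(n_save)

    e = _energy(x, bond_r0, bond_k, ang_t0, angle_k, dih_p0, k1, k3,
                nat_i, nat_j, nat_r0, eps_nat,
                nn_i, nn_j, nn_e, lam, sigma_rep, eps_rep, r_on, nn_cut)
    q = _q_sharp(x, nat_i, nat_j, nat_r0, tol)
    q_rec = max(q_record0, q)
    frames[0] = x
    energies[0] = e
    qs[0] = q
    qrecs[0] = q_rec
    nsaved = 1
    nacc = 0

    xt = np.empty((n, 3))
    for sweep in range(1, n_sweeps + 1):
        for _ in range(n):
            for b in range(n):
                xt[b, 0] = x[b, 0]
                xt[b, 1] = x[b, 1]
                xt[b, 2] = x[b, 2]
            if np.random.random() < mix and n >= 4:
                hi = seg_hi
                if hi > n - 2:
                    hi = n - 2
                seg = np.random.randint(seg_lo, hi + 1)
                i0 = np.random.randint(0, n - seg - 1)
                j0 = i0 + seg + 1
                ax = x[j0, 0] - x[i0, 0]
                ay = x[j0, 1] - x[i0, 1]
                az = x[j0, 2] - x[i0, 2]
                an = math.sqrt(ax * ax + ay * ay + az * az)
                if an < 1e-9:
                    ax, ay, az = 1.0, 0.0, 0.0
                    an = 1.0
                ax, ay, az = ax / an, ay / an, az / an
                ang = (2.0 * np.random.random() - 1.0) * crank_max
                ca, sa = math.cos(ang), math.sin(ang)
                for b in range(i0 + 1, j0):
                    px = x[b, 0] - x[i0, 0]
                    py = x[b, 1] - x[i0, 1]
                    pz = x[b, 2] - x[i0, 2]
                    dot = px * ax + py * ay + pz * az
                    cx = ay * pz - az * py
                    cy = az * px - ax * pz
                    cz = ax * py - ay * px
                    xt[b, 0] = x[i0, 0] + px * ca + cx * sa + ax * dot * (1 - ca)
                    xt[b, 1] = x[i0, 1] + py * ca + cy * sa + ay * dot * (1 - ca)
                    xt[b, 2] = x[i0, 2] + pz * ca + cz * sa + az * dot * (1 - ca)
            else:
                b = np.random.randint(0, n)
                xt[b, 0] = x[b, 0] + (2.0 * np.random.random() - 1.0) * disp_max
                xt[b, 1] = x[b, 1] + (2.0 * np.random.random() - 1.0) * disp_max
                xt[b, 2] = x[b, 2] + (2.0 * np.random.random() - 1.0) * disp_max

            et = _energy(xt, bond_r0, bond_k, ang_t0, angle_k, dih_p0, k1, k3,
                         nat_i, nat_j, nat_r0, eps_nat,
                         nn_i, nn_j, nn_e, lam, sigma_rep, eps_rep,
                         r_on, nn_cut)
            de = et - e
            if k_ratchet > 0.0:
                qt = _q_sharp(xt, nat_i, nat_j, nat_r0, tol)
                eb_old = 0.0
                if q < q_rec:
                    eb_old = 0.5 * k_ratchet * (q_rec - q) ** 2
                eb_new = 0.0
                if qt < q_rec:
                    eb_new = 0.5 * k_ratchet * (q_rec - qt) ** 2
                de += eb_new - eb_old

            acc = False
            u = np.random.random()
            if de <= 0.0:
                acc = True
            elif kBT > 0.0 and u < math.exp(-de / kBT):
                acc = True
            if acc:
                for b in range(n):
                    x[b, 0] = xt[b, 0]
                    x[b, 1] = xt[b, 1]
                    x[b, 2] = xt[b, 2]
                e = et
                if k_ratchet > 0.0:
                    q = qt
                    if q > q_rec:
                        q_rec = q
                nacc += 1
        if sweep % stride == 0:
            if k_ratchet <= 0.0:
                q = _q_sharp(x, nat_i, nat_j, nat_r0, tol)
                if q > q_rec:
                    q_rec = q
            frames[nsaved] = x
            energies[nsaved] = e
            qs[nsaved] = q
            qrecs[nsaved] = q_rec
            nsaved += 1
            if q_stop <= 1.0 and q >= q_stop:
                break
    return frames, energies, qs, qrecs, nacc, nsaved


def kernel_args(model, moveset, tol=1.2):
    """Pack a PotentialEnergyModel + MoveSet into mc_run's argument tuple."""
    go = model.go
    if model.qc is not None and model.qc.lambda_nn > 0:
        lam = model.qc.lambda_nn
        nn_e = np.ascontiguousarray(model.nn_e, dtype=float)
        r_on = model.qc.nn_cutoff - model.qc.switching_width
        nn_cut = model.qc.nn_cutoff
    else:
        lam = 0.0
        nn_e = np.zeros(len(model.nonnative_pairs))
        r_on, nn_cut = 6.0, 7.5
    return dict(
        crank_max=moveset.crankshaft_max_angle,
        disp_max=moveset.displacement_max,
        mix=moveset.mix,
        seg_lo=moveset.segment_range[0],
        seg_hi=moveset.segment_range[1],
        bond_r0=np.ascontiguousarray(model.bond_r0),
        bond_k=go.bond_k,
        ang_t0=np.ascontiguousarray(model.angle_t0),
        angle_k=go.angle_k,
        dih_p0=np.ascontiguousarray(model.dihedral_p0),
        k1=go.dihedral_k1, k3=go.dihedral_k3,
        nat_i=np.ascontiguousarray(model.native_pairs[:, 0]),
        nat_j=np.ascontiguousarray(model.native_pairs[:, 1]),
        nat_r0=np.ascontiguousarray(model.native_r0),
        eps_nat=go.epsilon_native,
        nn_i=np.ascontiguousarray(model.nonnative_pairs[:, 0]),
        nn_j=np.ascontiguousarray(model.nonnative_pairs[:, 1]),
        nn_e=nn_e, lam=lam,
        sigma_rep=go.sigma_rep, eps_rep=go.epsilon_rep,
        r_on=r_on, nn_cut=nn_cut,
        tol=tol,
    )
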