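"""Numba kernels for the annealing builder.

The builder works on a coordinate array in *kinematic order* (per residue
N, CA, C, CB, O): with that layout the atoms moved by a phi rotation of
residue r are exactly the suffix starting at C(r), and for psi the suffix
starting at O(r), so every torsion move is one in-place rotation of a
contiguous block and the whole Metropolis trajectory plus the greedy
quench can run inside one compiled kernel.

Random numbers come from numba's internal Mersenne Twister seeded per
trajectory, so builds are deterministic per (seed, round, model).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _rotate_suffix(coords, p0x, p0y, p0z, ax, ay, az, angle, start):
    """Right-handed rotation of coords[start:] about the unit axis
    (ax, ay, az) anchored at p0, by ``angle`` radians."""
    c = np.cos(angle)
    s = np.sin(angle)
    t = 1.0 - c
    r00 = c + ax * ax * t
    r01 = ax * ay * t - az * s
    r02 = ax * az * t + ay * s
    r10 = ax * ay * t + az * s
    r11 = c + ay * ay * t
    r12 = ay * az * t - ax * s
    r20 = ax * az * t - ay * s
    r21 = ay * az * t + ax * s
    r22 = c + az * az * t
    for i in range(start, coords.shape[0]):
        x = coords[i, 0] - p0x
        y = coords[i, 1] - p0y
        z = coords[i, 2] - p0z
        coords[i, 0] = p0x + r00 * x + r01 * y + r02 * z
        coords[i, 1] = p0y + r10 * x + r11 * y + r12 * z
        coords[i, 2] = p0z + r20 * x + r21 * y + r22 * z


@njit(cache=False)
def _apply_phi(coords, i_n, i_ca, i_c, r, angle):
    nx, ny, nz = coords[i_n[r], 0], coords[i_n[r], 1], coords[i_n[r], 2]
    ax = coords[i_ca[r], 0] - nx
    ay = coords[i_ca[r], 1] - ny
    az = coords[i_ca[r], 2] - nz
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    _rotate_suffix(coords, nx, ny, nz, ax / norm, ay / norm, az / norm,
                   angle, i_c[r])


@njit(cache=False)
def _apply_psi(coords, i_ca, i_c, i_o, r, angle):
    px, py, pz = coords[i_ca[r], 0], coords[i_ca[r], 1], coords[i_ca[r], 2]
    ax = coords[i_c[r], 0] - px
    ay = coords[i_c[r], 1] - py
    az = coords[i_c[r], 2] - pz
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    _rotate_suffix(coords, px, py, pz, ax / norm, ay / norm, az / norm,
                   angle, i_o[r])


@njit(cache=False)
def _dihedral_rad(coords, i0, i1, i2, i3):
    b0x = coords[i1, 0] - coords[i0, 0]
    b0y = coords[i1, 1] - coords[i0, 1]
    b0z = coords[i1, 2] - coords[i0, 2]
    b1x = coords[i2, 0] - coords[i1, 0]
    b1y = coords[i2, 1] - coords[i1, 1]
    b1z = coords[i2, 2] - coords[i1, 2]
    b2x = coords[i3, 0] - coords[i2, 0]
    b2y = coords[i3, 1] - coords[i2, 1]
    b2z = coords[i3, 2] - coords[i2, 2]
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    m1x = (n1y * b1z - n1z * b1y) / nb
    m1y = (n1z * b1x - n1x * b1z) / nb
    m1z = (n1x * b1y - n1y * b1x) / nb
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    return np.arctan2(-y, x)


@njit(cache=False)
def _energy(coords, ci, cj, targets, weights, k_act, vi, vj, rsum, rsum2):
    u = 0.0
    for k in range(k_act):
        dx = coords[ci[k], 0] - coords[cj[k], 0]
        dy = coords[ci[k], 1] - coords[cj[k], 1]
        dz = coords[ci[k], 2] - coords[cj[k], 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = d - targets[k]
        u += weights[k] * dev * dev
    for k in range(vi.shape[0]):
        dx = coords[vi[k], 0] - coords[vj[k], 0]
        dy = coords[vi[k], 1] - coords[vj[k], 1]
        dz = coords[vi[k], 2] - coords[vj[k], 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < rsum2[k]:
            ov = rsum[k] - np.sqrt(d2)
            u += ov * ov
    return u


@njit(cache=False)
def _torsion_gradient(coords, ci, cj, targets, weights, k_act,
                      vi, vj, rsum, rsum2,
                      i_n, i_ca, i_c, i_o, grad):
    """Analytic dU/dtheta (radians) for all 2*n_res torsions.

    Uses the crossing-restraint identity: only pairs split by a torsion's
    moving suffix contribute, accumulated with difference arrays over the
    kinematic atom axis (force and torque), then one prefix sweep.
    """
    n_atoms = coords.shape[0]
    n_res = i_n.shape[0]
    fdiff = np.zeros((n_atoms + 1, 3))
    tdiff = np.zeros((n_atoms + 1, 3))

    for k in range(k_act):
        a = ci[k]
        b = cj[k]
        if a > b:
            a, b = b, a
        dx = coords[b, 0] - coords[a, 0]
        dy = coords[b, 1] - coords[a, 1]
        dz = coords[b, 2] - coords[a, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-9:
            continue
        coef = 2.0 * weights[k] * (d - targets[k]) / d
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        # force acts on b (the moving endpoint for boundaries in (a, b])
        fdiff[a + 1, 0] += fx
        fdiff[a + 1, 1] += fy
        fdiff[a + 1, 2] += fz
        fdiff[b + 1, 0] -= fx
        fdiff[b + 1, 1] -= fy
        fdiff[b + 1, 2] -= fz
        tx = coords[b, 1] * fz - coords[b, 2] * fy
        ty = coords[b, 2] * fx - coords[b, 0] * fz
        tz = coords[b, 0] * fy - coords[b, 1] * fx
        tdiff[a + 1, 0] += tx
        tdiff[a + 1, 1] += ty
        tdiff[a + 1, 2] += tz
        tdiff[b + 1, 0] -= tx
        tdiff[b + 1, 1] -= ty
        tdiff[b + 1, 2] -= tz

    for k in range(vi.shape[0]):
        a = vi[k]
        b = vj[k]
        if a > b:
            a, b = b, a
        dx = coords[b, 0] - coords[a, 0]
        dy = coords[b, 1] - coords[a, 1]
        dz = coords[b, 2] - coords[a, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rsum2[k]:
            continue
        d = np.sqrt(d2)
        if d < 1e-9:
            continue
        coef = -2.0 * (rsum[k] - d) / d
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        fdiff[a + 1, 0] += fx
        fdiff[a + 1, 1] += fy
        fdiff[a + 1, 2] += fz
        fdiff[b + 1, 0] -= fx
        fdiff[b + 1, 1] -= fy
        fdiff[b + 1, 2] -= fz
        tx = coords[b, 1] * fz - coords[b, 2] * fy
        ty = coords[b, 2] * fx - coords[b, 0] * fz
        tz = coords[b, 0] * fy - coords[b, 1] * fx
        tdiff[a + 1, 0] += tx
        tdiff[a + 1, 1] += ty
        tdiff[a + 1, 2] += tz
        tdiff[b + 1, 0] -= tx
        tdiff[b + 1, 1] -= ty
        tdiff[b + 1, 2] -= tz

    # prefix sums: S_F(t), S_T(t) = sums over restraints crossing boundary t
    for i in range(1, n_atoms + 1):
        for c in range(3):
            fdiff[i, c] += fdiff[i - 1, c]
            tdiff[i, c] += tdiff[i - 1, c]

    for r in range(n_res):
        # phi(r): boundary at C(r), pivot N(r), axis N->CA
        if r > 0:
            px, py, pz = coords[i_n[r], 0], coords[i_n[r], 1], coords[i_n[r], 2]
            ax = coords[i_ca[r], 0] - px
            ay = coords[i_ca[r], 1] - py
            az = coords[i_ca[r], 2] - pz
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            t = i_c[r]
            sfx, sfy, sfz = fdiff[t, 0], fdiff[t, 1], fdiff[t, 2]
            stx, sty, stz = tdiff[t, 0], tdiff[t, 1], tdiff[t, 2]
            # u . (S_T - p x S_F)
            cx = stx - (py * sfz - pz * sfy)
            cy = sty - (pz * sfx - px * sfz)
            cz = stz - (px * sfy - py * sfx)
            grad[r] = (ax * cx + ay * cy + az * cz) / norm
        else:
            grad[r] = 0.0
        # psi(r): boundary at O(r), pivot CA(r), axis CA->C
        if r < n_res - 1:
            px, py, pz = coords[i_ca[r], 0], coords[i_ca[r], 1], coords[i_ca[r], 2]
            ax = coords[i_c[r], 0] - px
            ay = coords[i_c[r], 1] - py
            az = coords[i_c[r], 2] - pz
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            t = i_o[r]
            sfx, sfy, sfz = fdiff[t, 0], fdiff[t, 1], fdiff[t, 2]
            stx, sty, stz = tdiff[t, 0], tdiff[t, 1], tdiff[t, 2]
            cx = stx - (py * sfz - pz * sfy)
            cy = sty - (pz * sfx - px * sfz)
            cz = stz - (px * sfy - py * sfx)
            grad[n_res + r] = (ax * cx + ay * cy + az * cz) / norm
        else:
            grad[n_res + r] = 0.0


@njit(cache=False)
def _apply_delta(coords, i_n, i_ca, i_c, i_o, delta):
    """Add delta (radians; [phi_0..phi_n-1, psi_0..psi_n-1]) to all
    torsions, from the C-terminus inward so each rotation moves the
    smallest suffix."""
    n_res = i_n.shape[0]
    for r in range(n_res - 1, -1, -1):
        if r < n_res - 1 and delta[n_res + r] != 0.0:
            _apply_psi(coords, i_ca, i_c, i_o, r, delta[n_res + r])
        if r > 0 and delta[r] != 0.0:
            _apply_phi(coords, i_n, i_ca, i_c, r, delta[r])


@njit(cache=False)
def _gradient_quench(coords, ci, cj, targets, weights, k_act,
                     vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o,
                     max_iter, lr0):
    """Torsion-space FIRE minimization (inertial relaxation).

    Plain steepest descent stalls in the narrow, anisotropic valleys of
    the restraint landscape; FIRE's adaptive inertia descends orders of
    magnitude further at the same cost per iteration.
    """
    n_res = i_n.shape[0]
    nt = 2 * n_res
    grad = np.zeros(nt)
    vel = np.zeros(nt)
    dt = lr0 * 100.0
    dt_max = dt * 20.0
    alpha = 0.1
    n_pos = 0
    u = _energy(coords, ci, cj, targets, weights, k_act, vi, vj, rsum, rsum2)
    best_u = u
    best = coords.copy()
    for _ in range(max_iter):
        _torsion_gradient(coords, ci, cj, targets, weights, k_act,
                          vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o, grad)
        gnorm = 0.0
        vnorm = 0.0
        power = 0.0
        for t in range(nt):
            power -= grad[t] * vel[t]
            gnorm += grad[t] * grad[t]
            vnorm += vel[t] * vel[t]
        gnorm = np.sqrt(gnorm)
        vnorm = np.sqrt(vnorm)
        if gnorm < 1e-10:
            break
        if power > 0.0:
            n_pos += 1
            for t in range(nt):
                vel[t] = (1.0 - alpha) * vel[t] - alpha * vnorm * grad[t] / gnorm
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            for t in range(nt):
                vel[t] = 0.0
        delta = np.zeros(nt)
        for t in range(nt):
            vel[t] -= dt * grad[t]
            d = dt * vel[t]
            if d > 0.1:
                d = 0.1
            if d < -0.1:
                d = -0.1
            delta[t] = d
        _apply_delta(coords, i_n, i_ca, i_c, i_o, delta)
        u = _energy(coords, ci, cj, targets, weights, k_act, vi, vj, rsum, rsum2)
        if u < best_u:
            best_u = u
            best = coords.copy()
    coords[:, :] = best
    return best_u


@njit(cache=False)
def anneal_trajectory(start_coords, ci, cj, targets, weights,
                      vi, vj, rsum, rsum2,
                      i_n, i_ca, i_c, i_o,
                      temps, active, res_class, prior_cum,
                      local_move_prob, local_sigma_rad,
                      quench_iter, seed):
    """One build trajectory: quench-accelerated Metropolis annealing.

    Each step proposes a torsion change for one residue (a prior-drawn
    replacement or a small local tweak), relaxes the proposal with a
    short analytic-gradient quench at the currently active restraint
    level, and Metropolis-accepts on the quenched energy (basin-hopping
    Monte Carlo).  The variable-target schedule in ``active`` ramps the
    restraint set from short to full sequence separation; a deep quench
    of the best-visited full-restraint state finishes the trajectory.
    Returns (coords, u_initial, u_final).
    """
    np.random.seed(seed)
    n_res = i_n.shape[0]
    n_bins = 36
    coords = start_coords.copy()
    n_con = ci.shape[0]
    u0 = _energy(coords, ci, cj, targets, weights, n_con, vi, vj, rsum, rsum2)
    # melt: replace every residue's torsions with prior draws (Metropolis
    # at infinite temperature) so trajectories explore distinct basins
    for r in range(n_res):
        row = prior_cum[res_class[r]]
        flat = np.searchsorted(row, np.random.random())
        if flat >= row.shape[0]:
            flat = row.shape[0] - 1
        bi = flat // n_bins
        bj = flat % n_bins
        phi_t = (-180.0 + 10.0 * (bi + np.random.random())) * np.pi / 180.0
        psi_t = (-180.0 + 10.0 * (bj + np.random.random())) * np.pi / 180.0
        if r > 0:
            cur = _dihedral_rad(coords, i_c[r - 1], i_n[r], i_ca[r], i_c[r])
            _apply_phi(coords, i_n, i_ca, i_c, r, phi_t - cur)
        if r < n_res - 1:
            cur = _dihedral_rad(coords, i_n[r], i_ca[r], i_c[r], i_n[r + 1])
            _apply_psi(coords, i_ca, i_c, i_o, r, psi_t - cur)
    k_act = active[0]
    u = _gradient_quench(coords, ci, cj, targets, weights, k_act,
                         vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o, 30, 1e-4)
    best_u = 1e300
    best = coords.copy()
    steps = temps.shape[0]
    t_start = temps[0]
    for s in range(steps):
        if active[s] != k_act:
            k_act = active[s]
            u = _gradient_quench(coords, ci, cj, targets, weights, k_act,
                                 vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o,
                                 30, 1e-4)
        r = int(np.random.random() * n_res)
        if r >= n_res:
            r = n_res - 1
        trial = coords.copy()
        if np.random.random() < local_move_prob:
            sigma = local_sigma_rad * np.sqrt(temps[s] / t_start)
            if sigma < 0.035:
                sigma = 0.035
            if r > 0:
                _apply_phi(trial, i_n, i_ca, i_c, r,
                           np.random.normal() * sigma)
            if r < n_res - 1:
                _apply_psi(trial, i_ca, i_c, i_o, r,
                           np.random.normal() * sigma)
        else:
            row = prior_cum[res_class[r]]
            flat = np.searchsorted(row, np.random.random())
            if flat >= row.shape[0]:
                flat = row.shape[0] - 1
            bi = flat // n_bins
            bj = flat % n_bins
            phi_t = (-180.0 + 10.0 * (bi + np.random.random())) * np.pi / 180.0
            psi_t = (-180.0 + 10.0 * (bj + np.random.random())) * np.pi / 180.0
            if r > 0:
                cur = _dihedral_rad(trial, i_c[r - 1], i_n[r], i_ca[r], i_c[r])
                _apply_phi(trial, i_n, i_ca, i_c, r, phi_t - cur)
            if r < n_res - 1:
                cur = _dihedral_rad(trial, i_n[r], i_ca[r], i_c[r], i_n[r + 1])
                _apply_psi(trial, i_ca, i_c, i_o, r, psi_t - cur)
        u_new = _gradient_quench(trial, ci, cj, targets, weights, k_act,
                                 vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o,
                                 25, 1e-4)
        accept = u_new <= u
        if not accept:
            if np.random.random() < np.exp(-(u_new - u) / temps[s]):
                accept = True
        if accept:
            coords = trial
            u = u_new
            if k_act == n_con and u < best_u:
                best_u = u
                best = coords.copy()
    # deep-quench both the best-visited and the final state, keep lower
    u_end = _gradient_quench(coords, ci, cj, targets, weights, n_con,
                             vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o,
                             quench_iter, 1e-4)
    if best_u < 1e300:
        u_best = _gradient_quench(best, ci, cj, targets, weights, n_con,
                                  vi, vj, rsum, rsum2, i_n, i_ca, i_c, i_o,
                                  quench_iter, 1e-4)
        if u_best < u_end:
            return best, u0, u_best
    return coords, u0, u_end
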