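"""Numba kernels: force evaluation, cell-list pair building, BAOAB stepping.

Everything here works in the internal um/ng/us unit system and on flat
numpy arrays prepared by :mod:`silkbundle.dynamics`.  Bead mobility codes:
0 = free, 1 = fixed (velocity zero), 2 = pulled (prescribed +x velocity),
3 = dead (defect; participates in nothing).

The integrator is BAOAB at zero temperature (velocity Verlet with an
exponential friction sub-step), which stays stable for any ``gamma*dt``
and reduces to plain velocity Verlet when the damping is zero.
"""

import math

import numpy as np
from numba import njit

FREE, FIXED, PULLED, DEAD = 0, 1, 2, 3


@njit(cache=True)
def build_pairs(pos, fibril, mobility, rc):
    """Inter-fibril bead pairs closer than ``rc`` (cell-linked list, two passes)."""
    n = pos.shape[0]
    rc2 = rc * rc
    # bounding box over live beads
    xmin = ymin = zmin = 1e30
    xmax = ymax = zmax = -1e30
    for i in range(n):
        if mobility[i] == DEAD:
            continue
        if pos[i, 0] < xmin: xmin = pos[i, 0]
        if pos[i, 0] > xmax: xmax = pos[i, 0]
        if pos[i, 1] < ymin: ymin = pos[i, 1]
        if pos[i, 1] > ymax: ymax = pos[i, 1]
        if pos[i, 2] < zmin: zmin = pos[i, 2]
        if pos[i, 2] > zmax: zmax = pos[i, 2]
    ncx = max(1, int((xmax - xmin) / rc) + 1)
    ncy = max(1, int((ymax - ymin) / rc) + 1)
    ncz = max(1, int((zmax - zmin) / rc) + 1)
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        if mobility[i] == DEAD:
            continue
        ix = int((pos[i, 0] - xmin) / rc)
        iy = int((pos[i, 1] - ymin) / rc)
        iz = int((pos[i, 2] - zmin) / rc)
        if ix >= ncx: ix = ncx - 1
        if iy >= ncy: iy = ncy - 1
        if iz >= ncz: iz = ncz - 1
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i

    # pass 1: count
    total = 0
    for i in range(n):
        if mobility[i] == DEAD:
            continue
        for dx in range(-1, 2):
            ix = cx[i] + dx
            if ix < 0 or ix >= ncx:
                continue
            for dy in range(-1, 2):
                iy = cy[i] + dy
                if iy < 0 or iy >= ncy:
                    continue
                for dz in range(-1, 2):
                    iz = cz[i] + dz
                    if iz < 0 or iz >= ncz:
                        continue
                    j = head[(ix * ncy + iy) * ncz + iz]
                    while j >= 0:
                        if j > i and fibril[j] != fibril[i]:
                            ddx = pos[i, 0] - pos[j, 0]
                            ddy = pos[i, 1] - pos[j, 1]
                            ddz = pos[i, 2] - pos[j, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < rc2:
                                total += 1
                        j = nxt[j]
    # pass 2: fill
    pairs = np.empty((total, 2), dtype=np.int64)
    count = 0
    for i in range(n):
        if mobility[i] == DEAD:
            continue
        for dx in range(-1, 2):
            ix = cx[i] + dx
            if ix < 0 or ix >= ncx:
                continue
            for dy in range(-1, 2):
                iy = cy[i] + dy
                if iy < 0 or iy >= ncy:
                    continue
                for dz in range(-1, 2):
                    iz = cz[i] + dz
                    if iz < 0 or iz >= ncz:
                        continue
                    j = head[(ix * ncy + iy) * ncz + iz]
                    while j >= 0:
                        if j > i and fibril[j] != fibril[i]:
                            ddx = pos[i, 0] - pos[j, 0]
                            ddy = pos[i, 1] - pos[j, 1]
                            ddz = pos[i, 2] - pos[j, 2]
                            if ddx * ddx + ddy * ddy + ddz * ddz < rc2:
                                pairs[count, 0] = i
                                pairs[count, 1] = j
                                count += 1
                        j = nxt[j]
    return pairs


@njit(cache=True)
def build_contact_pairs(pos, fibril_beads, offsets, fibril_pairs, rc):
    """Mutual-nearest contact pairs between candidate fibril pairs.

    ``fibril_beads``/``offsets`` give, per fibril, its live bead ids sorted
    by axial position; ``fibril_pairs`` are the transversely adjacent
    fibril index pairs (0-based) worth checking.  For each fibril pair the
    facing partner of every bead is found by a monotone two-pointer walk
    on the axial coordinate; a pair is emitted when the two beads are each
    other's nearest and closer than ``rc``.
    """
    rc2 = rc * rc
    nmax = 0
    for q in range(fibril_pairs.shape[0]):
        f = fibril_pairs[q, 0]
        nmax += offsets[f + 1] - offsets[f]
    pairs = np.empty((nmax, 2), dtype=np.int64)
    count = 0
    for q in range(fibril_pairs.shape[0]):
        f = fibril_pairs[q, 0]
        g = fibril_pairs[q, 1]
        fs, fe = offsets[f], offsets[f + 1]
        gs, ge = offsets[g], offsets[g + 1]
        if fe == fs or ge == gs:
            continue
        j = gs
        for ii in range(fs, fe):
            i = fibril_beads[ii]
            xi = pos[i, 0]
            # advance j while the next bead of g is closer in x
            while j + 1 < ge and \
                    abs(pos[fibril_beads[j + 1], 0] - xi) <= \
                    abs(pos[fibril_beads[j], 0] - xi):
                j += 1
            jj = fibril_beads[j]
            # mutual check: is i the nearest bead of f to jj?
            xj = pos[jj, 0]
            best = ii
            if ii > fs and abs(pos[fibril_beads[ii - 1], 0] - xj) < \
                    abs(pos[fibril_beads[best], 0] - xj):
                best = ii - 1
            if ii + 1 < fe and abs(pos[fibril_beads[ii + 1], 0] - xj) < \
                    abs(pos[fibril_beads[best], 0] - xj):
                best = ii + 1
            if best != ii:
                continue
            dx = pos[i, 0] - pos[jj, 0]
            dy = pos[i, 1] - pos[jj, 1]
            dz = pos[i, 2] - pos[jj, 2]
            if dx * dx + dy * dy + dz * dz < rc2:
                pairs[count, 0] = i
                pairs[count, 1] = jj
                count += 1
    return pairs[:count]


@njit(cache=True)
def compute_forces(pos, frc, bonds, bond_alive, angles, angle_bonds,
                   pairs, D, alpha, r0, rupt_r, kb, eps, sigma, rc,
                   strain_now, break_bond, break_x, break_strain, n_broken,
                   jun_rest, jun_alive, jun_k, jun_uc,
                   mobility, anchor0, anchor_k, chain_L):
    """Zero ``frc`` and accumulate bond, angle and inter-fibril forces.

    When ``anchor_k > 0`` the boundary beads are tethered elastically:
    fixed beads to their construction position, pulled beads to an anchor
    advanced by ``strain_now * chain_L`` along +x.  (With ``anchor_k == 0``
    the integrator holds them rigidly instead.)

    Bonds stretched beyond ``rupt_r`` are irreversibly killed and logged
    (bond id, axial midpoint, applied strain).  Returns the updated broken
    count.

    Inter-fibril coupling: when ``jun_rest`` is non-empty the pairs are
    sacrificial elastic junctions — harmonic in the displacement from the
    construction offset vector, with stiffness ``jun_k`` (the LJ well
    curvature 57.15 eps/sigma^2) and irreversible detachment beyond
    ``jun_uc`` (where the stored energy equals the well depth eps).
    Otherwise the pairs interact through the truncated 12-6 potential.
    """
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0

    if anchor_k > 0.0:
        disp = strain_now * chain_L
        for i in range(n):
            if mobility[i] == FIXED:
                frc[i, 0] += anchor_k * (anchor0[i, 0] - pos[i, 0])
                frc[i, 1] += anchor_k * (anchor0[i, 1] - pos[i, 1])
                frc[i, 2] += anchor_k * (anchor0[i, 2] - pos[i, 2])
            elif mobility[i] == PULLED:
                frc[i, 0] += anchor_k * (anchor0[i, 0] + disp - pos[i, 0])
                frc[i, 1] += anchor_k * (anchor0[i, 1] - pos[i, 1])
                frc[i, 2] += anchor_k * (anchor0[i, 2] - pos[i, 2])

    # Morse bonds + rupture
    for b in range(bonds.shape[0]):
        if not bond_alive[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > rupt_r:
            bond_alive[b] = False
            break_bond[n_broken] = b
            break_x[n_broken] = 0.5 * (pos[i, 0] + pos[j, 0])
            break_strain[n_broken] = strain_now
            n_broken += 1
            continue
        e = math.exp(-alpha * (r - r0))
        fmag = 2.0 * D * alpha * (1.0 - e) * e / r   # tension/r
        frc[i, 0] += fmag * dx
        frc[i, 1] += fmag * dy
        frc[i, 2] += fmag * dz
        frc[j, 0] -= fmag * dx
        frc[j, 1] -= fmag * dy
        frc[j, 2] -= fmag * dz

    # angular springs (need both member bonds alive)
    for a in range(angles.shape[0]):
        if not (bond_alive[angle_bonds[a, 0]] and bond_alive[angle_bonds[a, 1]]):
            continue
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = math.sqrt(ux * ux + uy * uy + uz * uz)
        lv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        nux, nuy, nuz = ux / lu, uy / lu, uz / lu
        nvx, nvy, nvz = vx / lv, vy / lv, vz / lv
        c = nux * nvx + nuy * nvy + nuz * nvz
        if c > 1.0: c = 1.0
        if c < -1.0: c = -1.0
        s2 = 1.0 - c * c
        theta = math.acos(c)
        # F = coef * d(cos theta)/dr with coef = 2 kb (theta - pi)/sin(theta);
        # (theta - pi)/sin(theta) -> -1 smoothly as theta -> pi
        if s2 > 1e-12:
            coef = 2.0 * kb * (theta - math.pi) / math.sqrt(s2)
        else:
            coef = -2.0 * kb
        dix = (nvx - c * nux) / lu
        diy = (nvy - c * nuy) / lu
        diz = (nvz - c * nuz) / lu
        dkx = (nux - c * nvx) / lv
        dky = (nuy - c * nvy) / lv
        dkz = (nuz - c * nvz) / lv
        frc[i, 0] += coef * dix
        frc[i, 1] += coef * diy
        frc[i, 2] += coef * diz
        frc[k, 0] += coef * dkx
        frc[k, 1] += coef * dky
        frc[k, 2] += coef * dkz
        frc[j, 0] -= coef * (dix + dkx)
        frc[j, 1] -= coef * (diy + dky)
        frc[j, 2] -= coef * (diz + dkz)

    if jun_rest.shape[0] > 0:
        # sacrificial elastic junctions
        for p in range(pairs.shape[0]):
            if not jun_alive[p]:
                continue
            i = pairs[p, 0]
            j = pairs[p, 1]
            ux = pos[i, 0] - pos[j, 0] - jun_rest[p, 0]
            uy = pos[i, 1] - pos[j, 1] - jun_rest[p, 1]
            uz = pos[i, 2] - pos[j, 2] - jun_rest[p, 2]
            u2 = ux * ux + uy * uy + uz * uz
            if u2 > jun_uc * jun_uc:
                jun_alive[p] = False
                continue
            frc[i, 0] -= jun_k * ux
            frc[i, 1] -= jun_k * uy
            frc[i, 2] -= jun_k * uz
            frc[j, 0] += jun_k * ux
            frc[j, 1] += jun_k * uy
            frc[j, 2] += jun_k * uz
    else:
        # inter-fibril Lennard-Jones (truncated at rc; forces need no shift)
        rc2 = rc * rc
        s2ref = sigma * sigma
        for p in range(pairs.shape[0]):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2 or r2 < 1e-12:
                continue
            sr2 = s2ref / r2
            sr6 = sr2 * sr2 * sr2
            fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2   # (dE/dr)/(-r)
            frc[i, 0] += fr * dx
            frc[i, 1] += fr * dy
            frc[i, 2] += fr * dz
            frc[j, 0] -= fr * dx
            frc[j, 1] -= fr * dy
            frc[j, 2] -= fr * dz

    return n_broken


@njit(cache=True)
def junction_energy(pos, pairs, jun_rest, jun_alive, jun_k):
    """Elastic energy stored in live junctions (pJ)."""
    e = 0.0
    for p in range(pairs.shape[0]):
        if not jun_alive[p]:
            continue
        i = pairs[p, 0]
        j = pairs[p, 1]
        ux = pos[i, 0] - pos[j, 0] - jun_rest[p, 0]
        uy = pos[i, 1] - pos[j, 1] - jun_rest[p, 1]
        uz = pos[i, 2] - pos[j, 2] - jun_rest[p, 2]
        e += 0.5 * jun_k * (ux * ux + uy * uy + uz * uz)
    return e


@njit(cache=True)
def potential_energy(pos, bonds, bond_alive, angles, angle_bonds, pairs,
                     D, alpha, r0, kb, eps, sigma, rc):
    """Bond + angle + pairwise-LJ potential energy (pJ; LJ shifted at rc)."""
    e_tot = 0.0
    for b in range(bonds.shape[0]):
        if not bond_alive[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = 1.0 - math.exp(-alpha * (r - r0))
        e_tot += D * x * x
    for a in range(angles.shape[0]):
        if not (bond_alive[angle_bonds[a, 0]] and bond_alive[angle_bonds[a, 1]]):
            continue
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = math.sqrt(ux * ux + uy * uy + uz * uz)
        lv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if c > 1.0: c = 1.0
        if c < -1.0: c = -1.0
        d = math.acos(c) - math.pi
        e_tot += kb * d * d
    rc2 = rc * rc
    src6 = (sigma / rc) ** 6
    eshift = 4.0 * eps * (src6 * src6 - src6)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        sr6 = (sigma * sigma / r2) ** 3
        e_tot += 4.0 * eps * (sr6 * sr6 - sr6) - eshift
    return e_tot


@njit(cache=True)
def kinetic_energy(vel, mobility, m_eff):
    ke = 0.0
    for i in range(vel.shape[0]):
        if mobility[i] == DEAD:
            continue
        ke += 0.5 * m_eff * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    return ke


@njit(cache=True)
def run_chunk(pos, vel, frc, mobility, bonds, bond_alive, angles, angle_bonds,
              pairs, D, alpha, r0, rupt_r, kb, eps, sigma, rc,
              m_eff, gamma, dt, v_pull, strain_rate, step_offset, n_steps,
              break_bond, break_x, break_strain, n_broken,
              jun_rest, jun_alive, jun_k, jun_uc,
              anchor0, anchor_k, chain_L):
    """Advance ``n_steps`` BAOAB steps; entering invariant: ``frc`` is current.

    Returns the updated broken-bond count.  With soft anchors
    (``anchor_k > 0``) boundary beads are ordinary dynamic beads tethered
    by the anchor springs; otherwise pulled beads translate rigidly at
    ``v_pull`` and fixed beads do not move.  The drag acts on every
    integrated bead.
    """
    n = pos.shape[0]
    half = 0.5 * dt
    damp = math.exp(-gamma * dt)
    inv_m = 1.0 / m_eff
    soft = anchor_k > 0.0
    for s in range(n_steps):
        for i in range(n):
            mob = mobility[i]
            if mob == FREE or (soft and mob != DEAD):
                vel[i, 0] += half * frc[i, 0] * inv_m
                vel[i, 1] += half * frc[i, 1] * inv_m
                vel[i, 2] += half * frc[i, 2] * inv_m
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
                vel[i, 0] *= damp
                vel[i, 1] *= damp
                vel[i, 2] *= damp
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
            elif mob == PULLED:
                pos[i, 0] += dt * v_pull
        strain_now = (step_offset + s + 1) * dt * strain_rate
        n_broken = compute_forces(pos, frc, bonds, bond_alive, angles,
                                  angle_bonds, pairs, D, alpha, r0, rupt_r,
                                  kb, eps, sigma, rc, strain_now,
                                  break_bond, break_x, break_strain, n_broken,
                                  jun_rest, jun_alive, jun_k, jun_uc,
                                  mobility, anchor0, anchor_k, chain_L)
        for i in range(n):
            if mobility[i] == FREE or (soft and mobility[i] != DEAD):
                vel[i, 0] += half * frc[i, 0] * inv_m
                vel[i, 1] += half * frc[i, 1] * inv_m
                vel[i, 2] += half * frc[i, 2] * inv_m
    return n_broken
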