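"""Compiled (numba) kernels for force evaluation and Langevin propagation.

The kernels duplicate the algebra of :mod:`patchybind.potentials` in a form
that loops over all pairs; the unit tests assert agreement between the two
routes.  Pair parameters arrive as dense species-by-species matrices
prepared by the integrator:

``kind``      0 = WCA/steric repulsion, 1 = angular LJ, 2 = none
``sig2``      pair diameter squared
``rcut2``     cutoff squared
``rep_shift`` 4 eps (sigma/r_cut)^12  (angular LJ repulsive-branch shift)
``att_shift`` 4 eps (sigma/r_cut)^6   (attractive-branch shift)
``axis``      for angular pairs: 1 if the row species carries the binding
              axis (is the receptor), 2 if the column species does

The pair interaction is evaluated inline in both the all-pairs and the
cell-list loop (the bodies are intentionally duplicated: a shared helper
costs a per-pair call that dominates the step time).

Boundary conditions: periodic in x and y (minimum image), reflective walls
in z at the membrane (z = sigma/2) and the ceiling (z = lz - sigma/2) for
bulk particles; membrane particles are pinned to z = 0 with zero
z-velocity.

Error codes from the force kernels: 0 = ok, 1 = a pair closer than
1e-6 sigma (bad configuration).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_REPULSIVE = 0
KIND_ANGULAR = 1
KIND_NONE = 2

_WLC_XC = 0.99  # clamp fraction of the contour length


@njit(cache=True, fastmath=True)
def _bond_accumulate(pos, bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, forces):
    """WLC linker tensions.  Returns (energy, n_overstretch)."""
    energy = 0.0
    n_over = 0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= lx * round(dx / lx)
        dy -= ly * round(dy / ly)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        l0 = bond_l0[b]
        klp = bond_klp[b]  # kBT / lp
        x = r / l0
        if x >= _WLC_XC:
            if x >= 1.0:
                n_over += 1
            f = bond_fmax[b]
            ec = klp * l0 * (
                0.25 / (1.0 - _WLC_XC) - 0.25 - 0.25 * _WLC_XC + 0.5 * _WLC_XC**2
            )
            energy += ec + f * (r - _WLC_XC * l0)
        else:
            f = klp * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
            energy += klp * l0 * (0.25 / (1.0 - x) - 0.25 - 0.25 * x + 0.5 * x * x)
        if r > 1.0e-12:
            fx = -f * dx / r  # tension pulls the ends together
            fy = -f * dy / r
            fz = -f * dz / r
            forces[j, 0] += fx
            forces[j, 1] += fy
            forces[j, 2] += fz
            forces[i, 0] -= fx
            forces[i, 1] -= fy
            forces[i, 2] -= fz
    return energy, n_over


# NOTE: the pair-evaluation body below is textually duplicated between
# forces_allpairs and forces_celllist; keep the two in sync.


@njit(cache=True, fastmath=True)
def forces_allpairs(
    pos, spidx, kind, eps, sig2, rcut2, rep_shift, att_shift, ngeom, thcut, axis,
    bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, forces,
):
    """O(N^2) force evaluation.

    Returns (potential_energy, error_code, n_overstretch).
    """
    n = pos.shape[0]
    forces[:] = 0.0
    energy = 0.0
    err = 0
    for i in range(n):
        si = spidx[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            sj = spidx[j]
            k = kind[si, sj]
            if k == KIND_NONE:
                continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            dx -= lx * round(dx / lx)
            dy -= ly * round(dy / ly)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rcut2[si, sj]:
                continue
            s2 = sig2[si, sj]
            if r2 < 1.0e-12 * s2:
                err = 1
                continue
            e = eps[si, sj]
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            if k == KIND_REPULSIVE:
                energy += 4.0 * e * (sr12 - sr6) + e
                fmag = 24.0 * e * (2.0 * sr12 - sr6) / r2
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                forces[j, 0] += fx
                forces[j, 1] += fy
                forces[j, 2] += fz
                forces[i, 0] -= fx
                forces[i, 1] -= fy
                forces[i, 2] -= fz
            else:
                if axis[si, sj] == 1:
                    ux = dx
                    uy = dy
                    uz = dz
                    lig = j
                    rec = i
                else:
                    ux = -dx
                    uy = -dy
                    uz = -dz
                    lig = i
                    rec = j
                r = math.sqrt(r2)
                v_rep = 4.0 * e * sr12 - rep_shift[si, sj]
                v_att = -4.0 * e * sr6 + att_shift[si, sj]
                dvrep = -48.0 * e * sr12 / r
                dvatt = 24.0 * e * sr6 / r
                cos_t = uz / r
                if cos_t > 1.0:
                    cos_t = 1.0
                elif cos_t < -1.0:
                    cos_t = -1.0
                theta = math.acos(cos_t)
                tc = thcut[si, sj]
                ng = ngeom[si, sj]
                if theta >= tc:
                    g = 0.0
                    dg = 0.0
                elif ng == 0.0:
                    g = 1.0
                    dg = 0.0
                else:
                    a = 0.5 * math.pi / tc
                    c = math.cos(a * theta)
                    g = c ** (2.0 * ng)
                    dg = -2.0 * ng * a * math.sin(a * theta) * c ** (2.0 * ng - 1.0)
                energy += v_rep + g * v_att
                fr = -(dvrep + g * dvatt) / r
                flx = fr * ux
                fly = fr * uy
                flz = fr * uz
                if dg != 0.0:
                    sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
                    if sin_t > 1.0e-12:
                        pref = v_att * dg / (r * sin_t)
                        flx += pref * (-cos_t * ux / r)
                        fly += pref * (-cos_t * uy / r)
                        flz += pref * (1.0 - cos_t * uz / r)
                forces[lig, 0] += flx
                forces[lig, 1] += fly
                forces[lig, 2] += flz
                forces[rec, 0] -= flx
                forces[rec, 1] -= fly
                forces[rec, 2] -= flz
    eb, n_over = _bond_accumulate(
        pos, bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, forces
    )
    return energy + eb, err, n_over


@njit(cache=True, fastmath=True)
def forces_celllist(
    pos, spidx, kind, eps, sig2, rcut2, rep_shift, att_shift, ngeom, thcut, axis,
    bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, lz, rmax, forces,
):
    """Cell-list force evaluation; identical contract to :func:`forces_allpairs`.

    Cells are periodic in x, y and bounded in z.  Requires at least three
    cells along x and y (the caller falls back to all-pairs otherwise).
    """
    n = pos.shape[0]
    forces[:] = 0.0
    ncx = max(int(lx / rmax), 1)
    ncy = max(int(ly / rmax), 1)
    ncz = max(int(lz / rmax), 1)
    cx = lx / ncx
    cy = ly / ncy
    cz = lz / ncz
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / cx) % ncx
        iy = int(pos[i, 1] / cy) % ncy
        iz = int(pos[i, 2] / cz)
        if iz < 0:
            iz = 0
        elif iz >= ncz:
            iz = ncz - 1
        c = (iz * ncy + iy) * ncx + ix
        nxt[i] = head[c]
        head[c] = i
    energy = 0.0
    err = 0
    for iz in range(ncz):
        for iy in range(ncy):
            for ix in range(ncx):
                c = (iz * ncy + iy) * ncx + ix
                i = head[c]
                while i >= 0:
                    si = spidx[i]
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    zi = pos[i, 2]
                    for dzc in range(-1, 2):
                        jz = iz + dzc
                        if jz < 0 or jz >= ncz:
                            continue
                        for dyc in range(-1, 2):
                            jy = (iy + dyc) % ncy
                            for dxc in range(-1, 2):
                                jx = (ix + dxc) % ncx
                                c2 = (jz * ncy + jy) * ncx + jx
                                j = head[c2]
                                while j >= 0:
                                    if j <= i:
                                        j = nxt[j]
                                        continue
                                    sj = spidx[j]
                                    k = kind[si, sj]
                                    if k == KIND_NONE:
                                        j = nxt[j]
                                        continue
                                    dx = pos[j, 0] - xi
                                    dy = pos[j, 1] - yi
                                    dz = pos[j, 2] - zi
                                    dx -= lx * round(dx / lx)
                                    dy -= ly * round(dy / ly)
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 >= rcut2[si, sj]:
                                        j = nxt[j]
                                        continue
                                    s2 = sig2[si, sj]
                                    if r2 < 1.0e-12 * s2:
                                        err = 1
                                        j = nxt[j]
                                        continue
                                    e = eps[si, sj]
                                    sr2 = s2 / r2
                                    sr6 = sr2 * sr2 * sr2
                                    sr12 = sr6 * sr6
                                    if k == KIND_REPULSIVE:
                                        energy += 4.0 * e * (sr12 - sr6) + e
                                        fmag = 24.0 * e * (2.0 * sr12 - sr6) / r2
                                        fx = fmag * dx
                                        fy = fmag * dy
                                        fz = fmag * dz
                                        forces[j, 0] += fx
                                        forces[j, 1] += fy
                                        forces[j, 2] += fz
                                        forces[i, 0] -= fx
                                        forces[i, 1] -= fy
                                        forces[i, 2] -= fz
                                    else:
                                        if axis[si, sj] == 1:
                                            ux = dx
                                            uy = dy
                                            uz = dz
                                            lig = j
                                            rec = i
                                        else:
                                            ux = -dx
                                            uy = -dy
                                            uz = -dz
                                            lig = i
                                            rec = j
                                        r = math.sqrt(r2)
                                        v_rep = 4.0 * e * sr12 - rep_shift[si, sj]
                                        v_att = -4.0 * e * sr6 + att_shift[si, sj]
                                        dvrep = -48.0 * e * sr12 / r
                                        dvatt = 24.0 * e * sr6 / r
                                        cos_t = uz / r
                                        if cos_t > 1.0:
                                            cos_t = 1.0
                                        elif cos_t < -1.0:
                                            cos_t = -1.0
                                        theta = math.acos(cos_t)
                                        tc = thcut[si, sj]
                                        ng = ngeom[si, sj]
                                        if theta >= tc:
                                            g = 0.0
                                            dg = 0.0
                                        elif ng == 0.0:
                                            g = 1.0
                                            dg = 0.0
                                        else:
                                            a = 0.5 * math.pi / tc
                                            c_ = math.cos(a * theta)
                                            g = c_ ** (2.0 * ng)
                                            dg = (
                                                -2.0 * ng * a * math.sin(a * theta)
                                                * c_ ** (2.0 * ng - 1.0)
                                            )
                                        energy += v_rep + g * v_att
                                        fr = -(dvrep + g * dvatt) / r
                                        flx = fr * ux
                                        fly = fr * uy
                                        flz = fr * uz
                                        if dg != 0.0:
                                            sin_t = math.sqrt(
                                                max(1.0 - cos_t * cos_t, 0.0)
                                            )
                                            if sin_t > 1.0e-12:
                                                pref = v_att * dg / (r * sin_t)
                                                flx += pref * (-cos_t * ux / r)
                                                fly += pref * (-cos_t * uy / r)
                                                flz += pref * (1.0 - cos_t * uz / r)
                                        forces[lig, 0] += flx
                                        forces[lig, 1] += fly
                                        forces[lig, 2] += flz
                                        forces[rec, 0] -= flx
                                        forces[rec, 1] -= fly
                                        forces[rec, 2] -= flz
                                    j = nxt[j]
                    i = nxt[i]
    eb, n_over = _bond_accumulate(
        pos, bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, forces
    )
    return energy + eb, err, n_over


@njit(cache=True)
def baoab_chunk(
    pos, vel, spidx,
    mass_s, gamma_s, mobile_s, membrane_s, sigma_s,
    kind, eps, sig2, rcut2, rep_shift, att_shift, ngeom, thcut, axis,
    bond_i, bond_j, bond_l0, bond_klp, bond_fmax,
    lx, ly, lz, kT, dt, noise, forces, use_cells, rmax,
):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps in place.

    ``forces`` must hold the forces of the entry configuration and holds
    those of the exit configuration on return.  ``noise`` is a
    (n_steps, N, 3) array of standard normal deviates (z-components are
    ignored for membrane species).  Frozen species (``mobile == 0``) never
    move.

    Returns (potential_energy, error_code, n_overstretch_events).
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    epot = 0.0
    err = 0
    n_over_total = 0
    half = 0.5 * dt
    for step in range(nsteps):
        for i in range(n):
            s = spidx[i]
            if mobile_s[s] == 0:
                continue
            inv_m = 1.0 / mass_s[s]
            # B
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            if membrane_s[s] == 0:
                vel[i, 2] += half * forces[i, 2] * inv_m
            # A
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            if membrane_s[s] == 0:
                pos[i, 2] += half * vel[i, 2]
            # O
            g = gamma_s[s]
            c1 = math.exp(-g * dt)
            c2 = math.sqrt(kT * inv_m * (1.0 - c1 * c1))
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
            if membrane_s[s] == 0:
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
            # A
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            if membrane_s[s] == 0:
                pos[i, 2] += half * vel[i, 2]
            # boundaries: wrap x, y; reflect z for bulk species
            pos[i, 0] -= lx * math.floor(pos[i, 0] / lx)
            pos[i, 1] -= ly * math.floor(pos[i, 1] / ly)
            if membrane_s[s] == 0:
                zlo = 0.5 * sigma_s[s]
                zhi = lz - 0.5 * sigma_s[s]
                if pos[i, 2] < zlo:
                    pos[i, 2] = 2.0 * zlo - pos[i, 2]
                    vel[i, 2] = -vel[i, 2]
                if pos[i, 2] > zhi:
                    pos[i, 2] = 2.0 * zhi - pos[i, 2]
                    vel[i, 2] = -vel[i, 2]
            else:
                pos[i, 2] = 0.0
                vel[i, 2] = 0.0
        if use_cells:
            epot, err_f, n_over = forces_celllist(
                pos, spidx, kind, eps, sig2, rcut2, rep_shift, att_shift,
                ngeom, thcut, axis,
                bond_i, bond_j, bond_l0, bond_klp, bond_fmax,
                lx, ly, lz, rmax, forces,
            )
        else:
            epot, err_f, n_over = forces_allpairs(
                pos, spidx, kind, eps, sig2, rcut2, rep_shift, att_shift,
                ngeom, thcut, axis,
                bond_i, bond_j, bond_l0, bond_klp, bond_fmax, lx, ly, forces,
            )
        if err_f != 0:
            err = err_f
        n_over_total += n_over
        for i in range(n):
            s = spidx[i]
            if mobile_s[s] == 0:
                continue
            inv_m = 1.0 / mass_s[s]
            # B
            vel[i, 0] += half * forces[i, 0] * inv_m
            vel[i, 1] += half * forces[i, 1] * inv_m
            if membrane_s[s] == 0:
                vel[i, 2] += half * forces[i, 2] * inv_m
    return epot, err, n_over_total


@njit(cache=True)
def pair_energy_matrix(
    pos_l, pos_r, eps, sigma, rcut, ngeom, thcut, lx, ly, out
):
    """Angular-LJ energies between every ligand (rows) and receptor (cols).

    Used by bound-pair detection; the receptor binding axis is +z.
    """
    nl = pos_l.shape[0]
    nr = pos_r.shape[0]
    src6 = (sigma / rcut) ** 6
    for a in range(nl):
        for b in range(nr):
            ux = pos_l[a, 0] - pos_r[b, 0]
            uy = pos_l[a, 1] - pos_r[b, 1]
            uz = pos_l[a, 2] - pos_r[b, 2]
            ux -= lx * round(ux / lx)
            uy -= ly * round(uy / ly)
            r2 = ux * ux + uy * uy + uz * uz
            if r2 >= rcut * rcut or r2 <= 0.0:
                out[a, b] = 0.0
                continue
            r = math.sqrt(r2)
            sr6 = (sigma / r) ** 6
            v_rep = 4.0 * eps * (sr6 * sr6 - src6 * src6)
            v_att = -4.0 * eps * (sr6 - src6)
            cos_t = uz / r
            if cos_t > 1.0:
                cos_t = 1.0
            elif cos_t < -1.0:
                cos_t = -1.0
            theta = math.acos(cos_t)
            if theta >= thcut:
                g = 0.0
            elif ngeom == 0.0:
                g = 1.0
            else:
                g = math.cos(0.5 * math.pi * theta / thcut) ** (2.0 * ngeom)
            out[a, b] = v_rep + g * v_att
    return out
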