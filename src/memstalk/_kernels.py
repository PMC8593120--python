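"""Numba force kernels for the coarse-grained engine.

Pair interactions follow a Cooke-style solvent-free lipid model:
WCA repulsion between all beads with per-pair effective diameters, a
smoothly truncated cos^2 attraction between tail beads, FENE bonds along
each lipid chain and harmonic 1-3 "straightening" springs.  Periodic
minimum-image convention in all three dimensions.

Nonbonded interactions run off a Verlet pair list built with a cell grid;
the integrator rebuilds the list when any bead has moved more than half
the skin.  All kernels accumulate forces in-place and return the potential
energy.  A FENE bond stretched to its maximum extension returns +inf
energy, which the integrator treats as a blow-up signal.
"""

import numpy as np
from numba import njit

_SIX_ROOT_TWO = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=True, inline="always")
def _wrap(d, box, half):
    while d > half:
        d -= box
    while d < -half:
        d += box
    return d


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, ptype, rlist_tt, rlist_other, pairs_tt, pairs_other,
                counts):
    """Split Verlet lists: tail-tail pairs (attractive range) vs the rest.

    Tail-tail pairs are kept out to ``rlist_tt``; all other pairs only need
    the WCA range ``rlist_other``.  Writes counts into ``counts`` (-1 on
    buffer overflow, caller grows and retries).  Uses a cell grid with a
    one- or two-shell stencil depending on how many cells fit; falls back
    to an all-pairs sweep in very small boxes.
    """
    n = pos.shape[0]
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    r2tt = rlist_tt * rlist_tt
    r2ot = rlist_other * rlist_other
    cap_tt = pairs_tt.shape[0]
    cap_ot = pairs_other.shape[0]
    n_tt = 0
    n_ot = 0
    # choose stencil: shell=1 needs cell >= rlist_tt and >=3 cells/dim;
    # shell=2 needs cell >= rlist_tt/2 and >=5 cells/dim
    shell = 0
    ncx = ncy = ncz = 1
    for s in (1, 2):
        cx = int(box[0] * s / rlist_tt)
        cy = int(box[1] * s / rlist_tt)
        cz = int(box[2] * s / rlist_tt)
        if cx >= 2 * s + 1 and cy >= 2 * s + 1 and cz >= 2 * s + 1:
            shell = s
            ncx, ncy, ncz = cx, cy, cz
            break
    if shell == 0 and box[2] <= 2.0 * rlist_tt:
        # degenerate box: plain all-pairs sweep
        for i in range(n):
            ti = ptype[i]
            for j in range(i + 1, n):
                dx = _wrap(pos[i, 0] - pos[j, 0], box[0], hx)
                dy = _wrap(pos[i, 1] - pos[j, 1], box[1], hy)
                dz = _wrap(pos[i, 2] - pos[j, 2], box[2], hz)
                r2 = dx * dx + dy * dy + dz * dz
                if ti == 1 and ptype[j] == 1:
                    if r2 < r2tt:
                        if n_tt >= cap_tt:
                            counts[0] = -1
                            return
                        pairs_tt[n_tt, 0] = i
                        pairs_tt[n_tt, 1] = j
                        n_tt += 1
                elif r2 < r2ot:
                    if n_ot >= cap_ot:
                        counts[1] = -1
                        return
                    pairs_other[n_ot, 0] = i
                    pairs_other[n_ot, 1] = j
                    n_ot += 1
        counts[0] = n_tt
        counts[1] = n_ot
        return
    if shell == 0:
        # small box: z-sorted sweep — only candidate pairs within rlist_tt
        # along z (circularly) are distance-checked
        order = np.argsort(pos[:, 2])
        zs = pos[order, 2]
        for a in range(n):
            i = order[a]
            ti = ptype[i]
            zi = zs[a]
            b = a + 1
            steps = 0
            while steps < n - 1:
                bb = b if b < n else b - n
                dzc = zs[bb] - zi
                gap = dzc if dzc >= 0 else dzc + box[2]
                # upward circular gap grows monotonically along the sweep;
                # each unordered pair is seen once (requires Lz > 2 rlist)
                if gap > rlist_tt:
                    break
                j = order[bb]
                dx = _wrap(pos[i, 0] - pos[j, 0], box[0], hx)
                dy = _wrap(pos[i, 1] - pos[j, 1], box[1], hy)
                dz = _wrap(pos[i, 2] - pos[j, 2], box[2], hz)
                r2 = dx * dx + dy * dy + dz * dz
                if ti == 1 and ptype[j] == 1:
                    if r2 < r2tt:
                        if n_tt >= cap_tt:
                            counts[0] = -1
                            return
                        pairs_tt[n_tt, 0] = i
                        pairs_tt[n_tt, 1] = j
                        n_tt += 1
                elif r2 < r2ot:
                    if n_ot >= cap_ot:
                        counts[1] = -1
                        return
                    pairs_other[n_ot, 0] = i
                    pairs_other[n_ot, 1] = j
                    n_ot += 1
                b += 1
                steps += 1
        counts[0] = n_tt
        counts[1] = n_ot
        return
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int64)
    nxt = np.empty(n, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] / box[0] - np.floor(pos[i, 0] / box[0])) * ncx) % ncx
        cy = int((pos[i, 1] / box[1] - np.floor(pos[i, 1] / box[1])) * ncy) % ncy
        cz = int((pos[i, 2] / box[2] - np.floor(pos[i, 2] / box[2])) * ncz) % ncz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    # half stencil: all offsets lexicographically positive, plus self cell
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for ox in range(0, shell + 1):
                    for oy in range(-shell if ox > 0 else 0, shell + 1):
                        for oz in range(-shell if (ox > 0 or oy > 0) else 0,
                                        shell + 1):
                            jx = (cx + ox) % ncx
                            jy = (cy + oy) % ncy
                            jz = (cz + oz) % ncz
                            c2 = (jx * ncy + jy) * ncz + jz
                            same = c2 == c
                            i = head[c]
                            while i >= 0:
                                j = nxt[i] if same else head[c2]
                                while j >= 0:
                                    dx = _wrap(pos[i, 0] - pos[j, 0], box[0], hx)
                                    dy = _wrap(pos[i, 1] - pos[j, 1], box[1], hy)
                                    dz = _wrap(pos[i, 2] - pos[j, 2], box[2], hz)
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if ptype[i] == 1 and ptype[j] == 1:
                                        if r2 < r2tt:
                                            if n_tt >= cap_tt:
                                                counts[0] = -1
                                                return
                                            pairs_tt[n_tt, 0] = i
                                            pairs_tt[n_tt, 1] = j
                                            n_tt += 1
                                    elif r2 < r2ot:
                                        if n_ot >= cap_ot:
                                            counts[1] = -1
                                            return
                                        pairs_other[n_ot, 0] = i
                                        pairs_other[n_ot, 1] = j
                                        n_ot += 1
                                    j = nxt[j]
                                i = nxt[i]
    counts[0] = n_tt
    counts[1] = n_ot
    return


@njit(cache=True, fastmath=True, inline="always")
def _wrap1(d, box, half):
    if d > half:
        d -= box
    elif d < -half:
        d += box
    return d


@njit(cache=True, fastmath=True)
def nonbonded_pairs(pos, box, ptype, b_tab, eps, sigma, wc,
                    pairs_tt, n_tt, pairs_other, n_ot, forces):
    """WCA for all listed pairs plus cos^2 attraction for tail-tail pairs."""
    energy = 0.0
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    rc = _SIX_ROOT_TWO * sigma
    rc2 = rc * rc
    rcw = rc + wc
    rcw2 = rcw * rcw
    pref = np.pi / (2.0 * wc)
    s2 = sigma * sigma
    for k in range(n_tt):
        i = pairs_tt[k, 0]
        j = pairs_tt[k, 1]
        dx = _wrap1(pos[i, 0] - pos[j, 0], box[0], hx)
        dy = _wrap1(pos[i, 1] - pos[j, 1], box[1], hy)
        dz = _wrap1(pos[i, 2] - pos[j, 2], box[2], hz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcw2:
            continue
        if r2 < rc2:
            # WCA (shifted by +eps) plus the -eps attraction plateau
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * eps * (sr6 * sr6 - sr6)
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        else:
            r = np.sqrt(r2)
            c2 = np.cos(2.0 * pref * (r - rc))    # cos(2 theta)
            energy += -0.5 * eps * (1.0 + c2)
            # sin(2 theta) >= 0 on [0, pi], so the sqrt branch is safe
            sin2t = np.sqrt(max(0.0, 1.0 - c2 * c2))
            fmag = -eps * sin2t * pref / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    for k in range(n_ot):
        i = pairs_other[k, 0]
        j = pairs_other[k, 1]
        b = b_tab[ptype[i], ptype[j]]
        dx = _wrap1(pos[i, 0] - pos[j, 0], box[0], hx)
        dy = _wrap1(pos[i, 1] - pos[j, 1], box[1], hy)
        dz = _wrap1(pos[i, 2] - pos[j, 2], box[2], hz)
        r2 = dx * dx + dy * dy + dz * dz
        rc_wca2 = _SIX_ROOT_TWO * _SIX_ROOT_TWO * b * b
        if r2 < rc_wca2:
            sr2 = (b * b) / r2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * eps * (sr6 * sr6 - sr6) + eps
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return energy


@njit(cache=True, fastmath=True)
def chain_coordinate(pos, box, sel, center_x, center_y, z_bottom, z_top,
                     radius, n_slices, n0, zeta, eps_r, cap_h,
                     n_s, delta_s, grad, need_gradient):
    """Fused chain-coordinate evaluation: n_s, delta_s and the gradient.

    Same mathematics as the reference numpy path: half-cosine edge ramps
    (each bead touches at most two slices since zeta < d/2), half-cosine
    radial switch, monotone cubic occupancy cap.  ``grad`` is (N, 3) and
    zeroed here; returns xi.
    """
    d = (z_top - z_bottom) / n_slices
    length = z_top - z_bottom
    z_mid = 0.5 * (z_bottom + z_top)
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    nsel = sel.shape[0]
    n_s[:] = 0.0
    if need_gradient:
        grad[:, :] = 0.0
    # per-bead scratch: slice indices and (w_ax, dw_ax) for <= 2 slices
    s_idx = np.full((nsel, 2), -1, np.int64)
    w_ax = np.zeros((nsel, 2))
    dw_ax = np.zeros((nsel, 2))
    w_rad = np.zeros(nsel)
    dw_rad = np.zeros(nsel)
    ux = np.zeros(nsel)
    uy = np.zeros(nsel)
    for a in range(nsel):
        i = sel[a]
        dx = _wrap1(pos[i, 0] - center_x, box[0], hx)
        dy = _wrap1(pos[i, 1] - center_y, box[1], hy)
        rho = np.sqrt(dx * dx + dy * dy)
        if rho >= radius + eps_r:
            continue
        dzz = _wrap1(pos[i, 2] - z_mid, box[2], hz)
        z_rel = dzz + 0.5 * length
        if z_rel <= -zeta or z_rel >= length + zeta:
            continue
        if rho <= radius - eps_r:
            wr = 1.0
            dwr = 0.0
        else:
            t = (rho - (radius - eps_r)) / (2.0 * eps_r)
            wr = 0.5 * (1.0 + np.cos(np.pi * t))
            dwr = -0.5 * np.pi * np.sin(np.pi * t) / (2.0 * eps_r)
        w_rad[a] = wr
        dw_rad[a] = dwr
        if rho > 1e-12:
            ux[a] = dx / rho
            uy[a] = dy / rho
        s_lo = int(np.floor((z_rel - zeta) / d))
        s_hi = int(np.floor((z_rel + zeta) / d))
        k = 0
        for s in range(max(0, s_lo), min(n_slices - 1, s_hi) + 1):
            # edge ramps at e_s = s d and e_{s+1}
            e0 = s * d
            e1 = e0 + d
            t0 = (z_rel - (e0 - zeta)) / (2.0 * zeta)
            t1 = (z_rel - (e1 - zeta)) / (2.0 * zeta)
            if t0 <= 0.0:
                r0, dr0 = 0.0, 0.0
            elif t0 >= 1.0:
                r0, dr0 = 1.0, 0.0
            else:
                r0 = 0.5 * (1.0 - np.cos(np.pi * t0))
                dr0 = 0.5 * np.pi * np.sin(np.pi * t0) / (2.0 * zeta)
            if t1 <= 0.0:
                r1, dr1 = 0.0, 0.0
            elif t1 >= 1.0:
                r1, dr1 = 1.0, 0.0
            else:
                r1 = 0.5 * (1.0 - np.cos(np.pi * t1))
                dr1 = 0.5 * np.pi * np.sin(np.pi * t1) / (2.0 * zeta)
            w = r0 - r1
            if w != 0.0 or dr0 != dr1:
                s_idx[a, k] = s
                w_ax[a, k] = w
                dw_ax[a, k] = dr0 - dr1
                n_s[s] += w * wr
                k += 1
                if k == 2:
                    break
    # occupancy cap per slice
    x0c = 1.0 - cap_h
    x1c = 1.0 + cap_h
    dxc = 2.0 * cap_h
    dpsi = np.zeros(n_slices)
    for s in range(n_slices):
        x = n_s[s] / n0
        if x <= x0c:
            delta_s[s] = x
            dpsi[s] = 1.0
        elif x >= x1c:
            delta_s[s] = 1.0
            dpsi[s] = 0.0
        else:
            t = (x - x0c) / dxc
            h00 = 2 * t**3 - 3 * t**2 + 1
            h10 = t**3 - 2 * t**2 + t
            h01 = -2 * t**3 + 3 * t**2
            delta_s[s] = h00 * x0c + h10 * dxc + h01
            dpsi[s] = ((6 * t**2 - 6 * t) * x0c
                       + (3 * t**2 - 4 * t + 1) * dxc
                       + (6 * t - 6 * t**2)) / dxc
    xi = 0.0
    for s in range(n_slices):
        xi += delta_s[s]
    xi /= n_slices
    if need_gradient:
        pref = 1.0 / (n0 * n_slices)
        for a in range(nsel):
            if w_rad[a] == 0.0 and dw_rad[a] == 0.0:
                continue
            i = sel[a]
            gz = 0.0
            grho = 0.0
            for k in range(2):
                s = s_idx[a, k]
                if s < 0:
                    continue
                c = dpsi[s] * pref
                gz += c * dw_ax[a, k] * w_rad[a]
                grho += c * w_ax[a, k] * dw_rad[a]
            grad[i, 0] = grho * ux[a]
            grad[i, 1] = grho * uy[a]
            grad[i, 2] = gz
    return xi


@njit(cache=True)
def brownian_quartic(n_steps, dt, kt_mob_dt, noise_amp, h, a, c,
                     kappa, xi0, x_init, noise, stride):
    """Overdamped Euler–Maruyama on U = h[(x/a)^2-1]^2 + c x (+ harmonic bias).

    ``kt_mob_dt`` is mobility*dt; ``noise`` is pre-drawn standard normals.
    Records every ``stride`` steps; returns the recorded positions.
    """
    n_out = n_steps // stride
    out = np.empty(n_out)
    x = x_init
    k = 0
    for step in range(n_steps):
        f = -(4.0 * h * x * ((x / a) ** 2 - 1.0) / (a * a) + c)
        if kappa > 0.0:
            f += -kappa * (x - xi0)
        x += kt_mob_dt * f + noise_amp * noise[step]
        if (step + 1) % stride == 0:
            out[k] = x
            k += 1
    return out


@njit(cache=True, fastmath=True)
def bonded_forces(pos, box, bonds, fene_k, fene_rinf, bends, bend_k, bend_r0,
                  forces):
    """FENE bonds plus harmonic 1-3 straightening springs."""
    energy = 0.0
    hx, hy, hz = 0.5 * box[0], 0.5 * box[1], 0.5 * box[2]
    rinf2 = fene_rinf * fene_rinf
    for k in range(bonds.shape[0]):
        i, j = bonds[k, 0], bonds[k, 1]
        dx = _wrap(pos[i, 0] - pos[j, 0], box[0], hx)
        dy = _wrap(pos[i, 1] - pos[j, 1], box[1], hy)
        dz = _wrap(pos[i, 2] - pos[j, 2], box[2], hz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rinf2:
            return np.inf  # bond beyond maximum extension: blow-up signal
        energy += -0.5 * fene_k * rinf2 * np.log(1.0 - r2 / rinf2)
        fmag = -fene_k / (1.0 - r2 / rinf2)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    for k in range(bends.shape[0]):
        i, j = bends[k, 0], bends[k, 1]
        dx = _wrap(pos[i, 0] - pos[j, 0], box[0], hx)
        dy = _wrap(pos[i, 1] - pos[j, 1], box[1], hy)
        dz = _wrap(pos[i, 2] - pos[j, 2], box[2], hz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            energy += 0.5 * bend_k * (r - bend_r0) ** 2
            fmag = -bend_k * (r - bend_r0) / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return energy
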