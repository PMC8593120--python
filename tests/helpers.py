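"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the WHAM
reference solves the histogram maximum-likelihood problem directly with a
quasi-Newton optimizer instead of the package's self-consistent fixed-point
iteration, and the brute-force chain-coordinate evaluator recomputes every
weight with straightforward scalar code.
"""

import numpy as np
from scipy.optimize import minimize

KB = 0.0083145


def wham_ml_reference(series_list, xi0s, kappas, temperature, edges):
    """Histogram-WHAM by direct maximum likelihood.

    Maximizes  sum_w N_w f_w - sum_b C_b ln sum_w N_w exp(f_w - u_wb)
    over the window free energies f (in kT), then reads off
    G_b = -kT ln( C_b / sum_w N_w exp(f_w - u_wb) ).
    Returns (bin centers, G) with G NaN on empty bins.
    """
    kt = KB * temperature
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.array([np.histogram(s, bins=edges)[0] for s in series_list],
                     dtype=float)
    counts = hists.sum(axis=0)
    n_w = hists.sum(axis=1)
    u = np.array([0.5 * k * (centers - x0) ** 2
                  for x0, k in zip(xi0s, kappas)]) / kt

    def neglog(f_tail):
        f = np.concatenate([[0.0], f_tail])
        a = np.log(n_w)[:, None] + f[:, None] - u       # (W, B)
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        val = (counts * log_den).sum() - (n_w * f).sum()
        # gradient wrt f_tail
        wgt = np.exp(a - log_den[None, :])              # (W, B)
        grad = (counts[None, :] * wgt).sum(axis=1) - n_w
        return val, grad[1:]

    res = minimize(neglog, np.zeros(len(xi0s) - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    f = np.concatenate([[0.0], res.x])
    a = np.log(n_w)[:, None] + f[:, None] - u
    amax = a.max(axis=0)
    log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -kt * (np.log(counts) - log_den)
    g = np.where(counts > 0, g, np.nan)
    g -= np.nanmin(g)
    return centers, g


def xi_brute_force(positions, box, tail_mask, center, z_bottom, z_top,
                   radius, n_slices, n0, zeta, eps_r, cap_h):
    """Scalar re-implementation of the chain coordinate (value only)."""
    d = (z_top - z_bottom) / n_slices
    z_mid = 0.5 * (z_bottom + z_top)
    n_s = np.zeros(n_slices)
    for i in np.flatnonzero(tail_mask):
        dx = positions[i, 0] - center[0]
        dx -= box[0] * round(dx / box[0])
        dy = positions[i, 1] - center[1]
        dy -= box[1] * round(dy / box[1])
        dz = positions[i, 2] - z_mid
        dz -= box[2] * round(dz / box[2])
        rho = np.hypot(dx, dy)
        if rho >= radius + eps_r:
            continue
        if rho <= radius - eps_r:
            w_rad = 1.0
        else:
            t = (rho - (radius - eps_r)) / (2 * eps_r)
            w_rad = 0.5 * (1 + np.cos(np.pi * t))
        z_rel = dz + 0.5 * (z_top - z_bottom)
        for s in range(n_slices):
            lo_e, hi_e = s * d, (s + 1) * d

            def ramp(edge):
                t = (z_rel - (edge - zeta)) / (2 * zeta)
                if t <= 0:
                    return 0.0
                if t >= 1:
                    return 1.0
                return 0.5 * (1 - np.cos(np.pi * t))

            w_ax = ramp(lo_e) - ramp(hi_e)
            n_s[s] += w_ax * w_rad
    deltas = np.empty(n_slices)
    for s in range(n_slices):
        x = n_s[s] / n0
        if x <= 1 - cap_h:
            deltas[s] = x
        elif x >= 1 + cap_h:
            deltas[s] = 1.0
        else:
            t = (x - (1 - cap_h)) / (2 * cap_h)
            h00 = 2 * t**3 - 3 * t**2 + 1
            h10 = t**3 - 2 * t**2 + t
            h01 = -2 * t**3 + 3 * t**2
            deltas[s] = h00 * (1 - cap_h) + h10 * 2 * cap_h + h01
    return deltas.mean(), n_s, deltas
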