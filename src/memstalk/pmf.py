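"""WHAM reconstruction of the free-energy profile along the chain coordinate.

Umbrella windows are merged by the weighted histogram analysis method: the
unbiased bin probabilities and the window free energies are iterated to
self-consistency,

    P(b) = sum_w H_w(b) / sum_w N_w exp[(F_w - U_w(xi_b)) / kT]
    F_w  = -kT ln sum_b P(b) exp[-U_w(xi_b) / kT]

with U_w the harmonic window bias.  Errors come from a whole-window
bootstrap: windows are resampled with replacement, WHAM is re-run per
replicate, and the per-bin standard deviation over aligned replicates is
reported as 1 SE.  Resampling whole windows (rather than samples within a
window) respects within-window autocorrelation.

``stalk_metrics`` reduces a profile to the free energy of the stalk
relative to the flat state and, when present, the nucleation barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import KB


@dataclass
class WindowSample:
    """One umbrella window's restraint parameters and coordinate series."""

    xi0: float
    kappa: float
    series: np.ndarray            # equilibrated xi(t) samples
    temperature: float = 310.0
    times: Optional[np.ndarray] = None
    full_series: Optional[np.ndarray] = None
    n_equil: int = 0              # samples flagged as equilibration
    seed: Optional[int] = None
    equilibrated_near_target: bool = True

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 1:
            raise ValueError("series must be 1-D")


@dataclass
class PMFProfile:
    """G(xi) with bootstrap SE; G = 0 at the flat-state minimum."""

    bins: np.ndarray              # bin centers, strictly increasing
    free_energy: np.ndarray       # kJ/mol
    se: np.ndarray                # kJ/mol, >= 0 (NaN where G undefined)
    temperature: float
    reference: str = "flat_min"
    n_iterations: int = 0
    residual: float = 0.0
    window_free_energies: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(np.diff(self.bins) <= 0):
            raise ValueError("bins must be strictly increasing")


@dataclass
class StalkMetrics:
    """Free energy of the stalk and of its nucleation barrier (if any)."""

    dg_stalk: float
    dg_barrier: Optional[float]
    xi_flat_min: float
    xi_stalk: float
    metastable: bool
    dg_stalk_se: Optional[float] = None
    dg_barrier_se: Optional[float] = None


class WhamError(RuntimeError):
    pass


def _histograms(windows: Sequence[WindowSample], edges: np.ndarray):
    hists = np.empty((len(windows), len(edges) - 1))
    for w, win in enumerate(windows):
        hists[w], _ = np.histogram(win.series, bins=edges)
    return hists


def _check_overlap(windows, hists):
    """Adjacent windows (by xi0) must share at least one populated bin."""
    order = np.argsort([w.xi0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            raise WhamError(
                "no histogram overlap between windows at xi0="
                f"{windows[a].xi0:.3f} and xi0={windows[b].xi0:.3f}")


def wham(windows: Sequence[WindowSample], bin_width: float = 0.008,
         n_bins: Optional[int] = None, tol: float = 1e-8,
         max_iter: int = 100_000,
         f_init: Optional[np.ndarray] = None,
         min_samples: int = 100) -> PMFProfile:
    """Self-consistent WHAM over harmonic umbrella windows.

    ``tol`` is the convergence threshold on the window free energies in
    units of kT.  Non-overlapping adjacent windows raise, naming the gap;
    so does non-convergence, reporting the residual.  Windows thinner
    than ``min_samples`` retained samples are rejected (set the floor to
    0 to disable).
    """
    if not windows:
        raise ValueError("no windows")
    for w in windows:
        if len(w.series) < min_samples:
            raise WhamError(
                f"window at xi0={w.xi0:.3f} retains only {len(w.series)} "
                f"samples (< floor {min_samples})")
    temps = {round(w.temperature, 6) for w in windows}
    if len(temps) > 1:
        raise WhamError("windows must share a common temperature")
    kt = KB * windows[0].temperature
    lo = min(w.series.min() for w in windows)
    hi = max(w.series.max() for w in windows)
    if n_bins is None:
        n_bins = max(2, int(np.ceil((hi - lo) / bin_width)))
    pad = 1e-9 * (hi - lo + 1.0)
    edges = np.linspace(lo, hi + pad, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = _histograms(windows, edges)
    _check_overlap(windows, hists)

    n_w = np.array([len(w.series) for w in windows], dtype=float)
    bias_u = np.array([0.5 * w.kappa * (centers - w.xi0) ** 2
                       for w in windows]) / kt      # (W, B), units of kT
    counts = hists.sum(axis=0)                      # (B,)
    f = (np.zeros(len(windows)) if f_init is None
         else np.asarray(f_init, dtype=float).copy())    # F_w / kT
    log_nw = np.log(n_w)
    for it in range(1, max_iter + 1):
        # log denominator per bin, stabilized
        a = log_nw[:, None] + f[:, None] - bias_u    # (W, B)
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_p = np.where(counts > 0, np.log(counts) - log_den, -np.inf)
        b = log_p[None, :] - bias_u                  # (W, B)
        bmax = b.max(axis=1)
        f_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        resid = np.abs(f_new - f).max()
        f = f_new
        if resid < tol:
            break
    else:
        raise WhamError(f"WHAM did not converge in {max_iter} iterations; "
                        f"residual {resid:.2e} kT > tol {tol:.2e} kT")
    with np.errstate(invalid="ignore"):
        g = np.where(np.isfinite(log_p), -kt * log_p, np.nan)
    g -= np.nanmin(g)
    return PMFProfile(bins=centers, free_energy=g,
                      se=np.zeros_like(g), temperature=windows[0].temperature,
                      n_iterations=it, residual=float(resid),
                      window_free_energies=f * kt)


def bootstrap_pmf(windows: Sequence[WindowSample], n_boot: int = 50,
                  seed: int = 0, bin_width: float = 0.008,
                  flat_window: Optional[tuple] = None,
                  stalk_window: Optional[tuple] = None,
                  tol: float = 1e-7, max_iter: int = 100_000):
    """Whole-window bootstrap SE for the profile (and stalk metrics).

    Returns ``(profile, metrics_se)`` where ``profile`` is the full-data
    WHAM result with its ``se`` field filled, and ``metrics_se`` is a dict
    with SEs of ``dg_stalk`` / ``dg_barrier`` (only when the window ranges
    are given, else None).  Each replicate is aligned at the reference bin
    (the full-profile minimum) before the spread is taken.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if n_boot < 20:
        warnings.warn("fewer than 20 bootstrap replicates; SEs will be noisy")
    base = wham(windows, bin_width=bin_width, tol=tol, max_iter=max_iter)
    # align replicates at the best-sampled bin: the minimum bin can sit in
    # a barely-visited tail whose own noise would contaminate every SE
    width = base.bins[1] - base.bins[0]
    edges = np.r_[base.bins - 0.5 * width, base.bins[-1] + 0.5 * width]
    tot = np.zeros(len(base.bins))
    for w in windows:
        h, _ = np.histogram(w.series, bins=edges)
        tot += h
    ref_bin = int(np.argmax(tot))
    kt_f = base.window_free_energies / (KB * base.temperature)
    rng = np.random.default_rng(seed)
    n_bins = len(base.bins)
    reps = np.full((n_boot, n_bins), np.nan)
    metric_reps = {"dg_stalk": [], "dg_barrier": []}
    r = 0
    attempts = 0
    while r < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, len(windows), len(windows))
        sub = [windows[i] for i in idx]
        try:
            prof = wham(sub, n_bins=None, bin_width=bin_width, tol=tol,
                        max_iter=max_iter, f_init=kt_f[idx])
        except WhamError:
            continue  # resample lacking overlap; draw again
        g = np.interp(base.bins, prof.bins, prof.free_energy,
                      left=np.nan, right=np.nan)
        if not np.isfinite(g[ref_bin]):
            continue
        g = g - g[ref_bin]
        reps[r] = g
        if flat_window is not None and stalk_window is not None:
            try:
                m = stalk_metrics(
                    PMFProfile(base.bins, g, np.zeros_like(g),
                               base.temperature), flat_window, stalk_window)
                metric_reps["dg_stalk"].append(m.dg_stalk)
                if m.dg_barrier is not None:
                    metric_reps["dg_barrier"].append(m.dg_barrier)
            except ValueError:
                pass
        r += 1
    if r < n_boot:
        warnings.warn(f"only {r}/{n_boot} bootstrap replicates had "
                      "sufficient window overlap")
        reps = reps[:r]
    valid = np.isfinite(reps).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.nanstd(reps, axis=0, ddof=1)
    se = np.where(valid >= max(2, r // 2), se, np.nan)
    base.se = se
    metrics_se = None
    if flat_window is not None and stalk_window is not None:
        metrics_se = {
            "dg_stalk": (float(np.std(metric_reps["dg_stalk"], ddof=1))
                         if len(metric_reps["dg_stalk"]) > 1 else np.nan),
            "dg_barrier": (float(np.std(metric_reps["dg_barrier"], ddof=1))
                           if len(metric_reps["dg_barrier"]) > 1 else np.nan),
        }
    return base, metrics_se


def stalk_metrics(profile: PMFProfile, flat_window: tuple,
                  stalk_window: tuple) -> StalkMetrics:
    """Reduce a profile to (dg_stalk, dg_barrier, metastability).

    ``dg_stalk`` is the free energy at the stalk-side local minimum (or at
    the largest sampled coordinate when the profile rises monotonically)
    relative to the flat-side minimum.  The barrier is the maximum between
    the two minima and is reported only when it exceeds both endpoints by
    more than 1 SE; a barrier on the closure side marks the stalk
    metastable.
    """
    bins, g, se = profile.bins, profile.free_energy, profile.se
    finite = np.isfinite(g)

    def window_mask(w):
        m = (bins >= w[0]) & (bins <= w[1]) & finite
        if not m.any():
            raise ValueError(f"window {w} outside the sampled profile")
        return m

    m_flat = window_mask(flat_window)
    m_stalk = window_mask(stalk_window)
    i_flat = np.flatnonzero(m_flat)[np.nanargmin(g[m_flat])]
    # local minimum inside the stalk window, if one exists; else the
    # highest sampled coordinate
    idx_stalk = np.flatnonzero(m_stalk)
    g_stalk_win = g[idx_stalk]
    # a stalk minimum exists only if the window argmin sits strictly inside
    # the window; an argmin pinned to the lower window edge means the
    # profile still rises there, and the stalk value is read at the highest
    # sampled coordinate instead
    j = int(np.nanargmin(g_stalk_win))
    has_local_min = len(idx_stalk) >= 3 and 0 < j < len(idx_stalk) - 1
    i_stalk = idx_stalk[j] if has_local_min else np.flatnonzero(finite)[-1]
    dg_stalk = float(g[i_stalk] - g[i_flat])

    lo, hi = sorted((i_flat, i_stalk))
    between = np.arange(lo, hi + 1)
    between = between[np.isfinite(g[between])]
    dg_barrier = None
    metastable = False
    if len(between) > 2:
        i_top = between[np.nanargmax(g[between])]
        g_top = g[i_top]
        se_top = se[i_top] if np.isfinite(se[i_top]) else 0.0
        if (g_top - g[i_stalk] > se_top) and (g_top - g[i_flat] > se_top):
            dg_barrier = float(g_top - g[i_flat])
            metastable = g_top - g[i_stalk] > se_top
    if dg_barrier is not None:
        dg_barrier = max(dg_barrier, max(0.0, dg_stalk))
    return StalkMetrics(dg_stalk=dg_stalk, dg_barrier=dg_barrier,
                        xi_flat_min=float(bins[i_flat]),
                        xi_stalk=float(bins[i_stalk]),
                        metastable=metastable)
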