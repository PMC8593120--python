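"""Transition counting and rate/free-energy consistency checks.

Unbiased trajectories of the chain coordinate are reduced to two-state
statistics with committor-style core logic: the trace must fully enter the
flat core (xi below ``xi_flat_core``) or the stalk core (xi above
``xi_stalk_core``) before a transition is registered, so excursions that
linger in the barrier region never count.  The time between commitments is
assigned to the last-committed state.

Rates follow as k = (number of departures) / (residence time of the
departed state), with Poisson standard errors k/sqrt(n).  Detailed balance
links the two rates to a free-energy difference,
dG = -kT ln(k_forward / k_backward), and transition-state theory inverts a
rate and a barrier into an attempt frequency nu = k exp(+dG_barrier/kT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import KB


@dataclass
class CoreDefinition:
    """State cores: flat below ``xi_flat_core``, stalk above ``xi_stalk_core``."""

    xi_flat_core: float = 0.4
    xi_stalk_core: float = 0.8

    def __post_init__(self):
        if not 0 <= self.xi_flat_core < self.xi_stalk_core <= 1:
            raise ValueError("need 0 <= xi_flat_core < xi_stalk_core <= 1")


@dataclass
class TransitionStats:
    n_open: int                    # flat -> stalk transitions
    n_close: int                   # stalk -> flat transitions
    residence_flat: float          # total time assigned to the flat state
    residence_stalk: float
    k_stalk: Optional[float] = None      # 1 / time unit of the input
    k_closure: Optional[float] = None
    k_stalk_se: Optional[float] = None
    k_closure_se: Optional[float] = None
    dg_rates: Optional[float] = None     # kJ/mol


def detect_transitions(traces: Sequence[tuple], cores: CoreDefinition
                       ) -> TransitionStats:
    """Count core-to-core transitions over one or more (t, xi) traces.

    Each trace is an independent continuous trajectory; counts and
    residence times are pooled.  A trace that never commits to either core
    raises.
    """
    n_open = n_close = 0
    res = {0: 0.0, 1: 0.0}  # 0 flat, 1 stalk
    committed_any = False
    for t, xi in traces:
        t = np.asarray(t, dtype=float)
        xi = np.asarray(xi, dtype=float)
        if t.shape != xi.shape or t.ndim != 1:
            raise ValueError("each trace must be a pair of 1-D arrays")
        state = np.where(xi <= cores.xi_flat_core, 0,
                         np.where(xi >= cores.xi_stalk_core, 1, -1))
        inside = np.flatnonzero(state >= 0)
        if inside.size == 0:
            raise ValueError("trace never enters either core")
        committed_any = True
        cur = state[inside[0]]
        t_commit = t[inside[0]]
        # time before first commitment is assigned to the first-committed
        # state, so a whole trace is accounted for
        t_last = t[0]
        for i in inside[1:]:
            s = state[i]
            if s != cur:
                res[cur] += t[i] - t_last
                if cur == 0:
                    n_open += 1
                else:
                    n_close += 1
                cur = s
                t_last = t[i]
        res[cur] += t[-1] - t_last
    if not committed_any:
        raise ValueError("no trace committed to a core")
    stats = TransitionStats(n_open=n_open, n_close=n_close,
                            residence_flat=res[0], residence_stalk=res[1])
    return stats


def rates_from_stats(stats: TransitionStats,
                     temperature: Optional[float] = None) -> TransitionStats:
    """Fill in rates, Poisson SEs and (when both rates exist) dG.

    A state with zero observed departures gets rate 0 and a one-sided
    Poisson upper bound (1/residence) stored in its SE slot.
    """
    if stats.residence_flat <= 0 and stats.n_open > 0:
        raise ValueError("transitions out of a state with zero residence")
    if stats.residence_stalk <= 0 and stats.n_close > 0:
        raise ValueError("transitions out of a state with zero residence")

    def one(n, tau):
        if tau <= 0:
            return 0.0, np.inf
        k = n / tau
        return k, (k / np.sqrt(n) if n > 0 else 1.0 / tau)

    stats.k_stalk, stats.k_stalk_se = one(stats.n_open, stats.residence_flat)
    stats.k_closure, stats.k_closure_se = one(stats.n_close,
                                              stats.residence_stalk)
    if temperature is not None and stats.k_stalk > 0 and stats.k_closure > 0:
        stats.dg_rates = dg_from_rates(stats.k_stalk, stats.k_closure,
                                       temperature)
    return stats


def dg_from_rates(k_forward: float, k_backward: float,
                  temperature: float) -> float:
    """Free energy of the product state from detailed balance, kJ/mol.

    With ``k_forward`` the formation rate and ``k_backward`` the closure
    rate, returns dG(stalk) - dG(flat) = -kT ln(k_forward / k_backward).
    """
    if k_forward <= 0 or k_backward <= 0:
        raise ValueError("both rates must be positive")
    return -KB * temperature * np.log(k_forward / k_backward)


def attempt_frequency(k: float, dg_barrier: float, temperature: float) -> float:
    """TST prefactor nu from k = nu exp(-dG_barrier / kT)."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return k * np.exp(dg_barrier / (KB * temperature))


def rate_from_attempt(nu: float, dg_barrier: float, temperature: float) -> float:
    """Inverse of :func:`attempt_frequency`: k = nu exp(-dG_barrier / kT)."""
    return nu * np.exp(-dg_barrier / (KB * temperature))


def telegraph_process(k01: float, k10: float, t_total: float, dt: float,
                      seed: int = 0):
    """Two-state Markov jump process sampled on a uniform grid.

    Returns (t, state) with state in {0, 1}; an exact-rate oracle for the
    transition counter.
    """
    rng = np.random.default_rng(seed)
    n = int(t_total / dt)
    t = np.arange(n) * dt
    state = np.empty(n, dtype=np.int64)
    s = 0
    p01 = 1.0 - np.exp(-k01 * dt)
    p10 = 1.0 - np.exp(-k10 * dt)
    u = rng.random(n)
    for i in range(n):
        state[i] = s
        if s == 0 and u[i] < p01:
            s = 1
        elif s == 1 and u[i] < p10:
            s = 0
    return t, state
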