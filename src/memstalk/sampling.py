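"""Pulling and umbrella-window orchestration along the chain coordinate.

The production protocol mirrors standard umbrella sampling practice: a
constant-velocity pull drags the system across the coordinate range, window
start points are picked from the pulling trajectory as the frames closest
to each window target, and every window is then simulated independently
under a stiff harmonic restraint.  The first part of each window (default
20 %) is flagged as equilibration and excluded from the retained series,
but never deleted.  Forward- and backward-initialized campaigns provide the
standard hysteresis check: their PMFs must agree within error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .bias import PullSchedule, UmbrellaBias
from .chain_coordinate import (ChainCoordParams, Configuration, CylinderSpec,
                               compute_xi)
from .engine import IntegratorParams, System, Trajectory, langevin_run
from .pmf import WindowSample


@dataclass
class WindowPlan:
    """Umbrella window layout: anchors, stiffness, run length, seeds."""

    xi0: np.ndarray                     # strictly increasing anchors
    kappa: float = 5000.0               # kJ/mol per unit xi^2
    steps_per_window: int = 4000
    equil_fraction: float = 0.2
    seeds: Optional[Sequence[int]] = None

    def __post_init__(self):
        self.xi0 = np.asarray(self.xi0, dtype=float)
        if np.any(np.diff(self.xi0) <= 0):
            raise ValueError("window anchors must be strictly increasing")
        if not 0 <= self.equil_fraction < 1:
            raise ValueError("equil_fraction must be in [0, 1)")
        if self.seeds is None:
            self.seeds = list(range(len(self.xi0)))
        if len(self.seeds) != len(self.xi0):
            raise ValueError("need one seed per window")

    @classmethod
    def default(cls, n_windows: int = 19, xi_range=(0.2, 1.0), **kw):
        """The standard layout: 19 equidistant windows over [0.2, 1.0]."""
        return cls(xi0=np.linspace(*xi_range, n_windows), **kw)


def run_pull(system: System, sched: PullSchedule, cylinder: CylinderSpec,
             coord_params: ChainCoordParams, integ: IntegratorParams,
             kappa: float = 5000.0, stride: int = 50, xi_stride: int = 5,
             lag_warn: float = 0.15, extra_steps_frac: float = 0.1,
             end_warn: float = 0.1) -> Trajectory:
    """Constant-velocity pull along the coordinate.

    Runs slightly past the schedule traversal time so the end state can
    settle at ``xi_end``.  Warns (with the maximum lag) if the coordinate
    trails the moving anchor by more than ``lag_warn``.
    """
    n_steps = int(np.ceil(sched.duration / integ.dt * (1 + extra_steps_frac)))
    traj = langevin_run(system, integ, n_steps,
                        bias=UmbrellaBias(sched.xi_start, kappa),
                        schedule=sched, cylinder=cylinder,
                        coord_params=coord_params, stride=stride,
                        xi_stride=xi_stride)
    lag = np.max(np.abs(traj.xi0 - traj.xi))
    if lag > lag_warn:
        warnings.warn(f"coordinate lagged the pull schedule by up to "
                      f"{lag:.3f} (threshold {lag_warn})")
    end_err = abs(traj.xi[-1] - sched.xi_end)
    if end_err > end_warn:
        warnings.warn(f"pull ended {end_err:.3f} away from xi_end")
    return traj


def seed_windows(pull_traj: Trajectory, plan: WindowPlan,
                 template: Configuration, max_dist: float = 0.1):
    """Starting configurations: the pulled frame nearest each anchor.

    The pulling trajectory must bracket every anchor to within
    ``max_dist`` in xi; otherwise the offending window is named.
    Returns (configs, frame_xi, frame_centers).
    """
    if pull_traj.xi is None:
        raise ValueError("pulling trajectory carries no xi series")
    # xi at the recorded frames: nearest xi record per frame time
    frame_xi = np.interp(pull_traj.times, pull_traj.xi_times, pull_traj.xi)
    configs, xis, centers = [], [], []
    for xi0 in plan.xi0:
        i = int(np.argmin(np.abs(frame_xi - xi0)))
        if abs(frame_xi[i] - xi0) > max_dist:
            raise ValueError(
                f"no pulled frame within {max_dist} of window xi0={xi0:.3f} "
                f"(closest: {frame_xi[i]:.3f})")
        configs.append(pull_traj.frame_config(i, template))
        xis.append(float(frame_xi[i]))
        j = int(np.argmin(np.abs(pull_traj.xi_times - pull_traj.times[i])))
        centers.append(pull_traj.centers[j] if pull_traj.centers is not None
                       else None)
    return configs, np.array(xis), centers


def run_umbrella(starts: Sequence[Configuration], plan: WindowPlan,
                 system: System, cylinder: CylinderSpec,
                 coord_params: ChainCoordParams, integ: IntegratorParams,
                 centers: Optional[Sequence] = None,
                 xi_stride: int = 5, stride: int = 10**9,
                 target_tolerance_sigmas: float = 2.0,
                 sequential: Optional[str] = None):
    """Umbrella windows; returns a list of WindowSample.

    Each window gets its own seed and fresh Maxwell velocities.  The first
    ``equil_fraction`` of each series is flagged (kept in ``full_series``,
    excluded from ``series``).  Windows whose retained mean sits further
    than ``target_tolerance_sigmas`` standard deviations from the anchor
    are flagged as unequilibrated in the sample's metadata.

    With ``sequential="ascending"`` (or ``"descending"``) windows run in
    coordinate order and each one starts from the previous window's final
    state instead of its pulled frame; only the first window uses its
    supplied start.  Relaxation then accumulates along the chain, which
    suppresses the memory of the pulling direction far better than
    independent pulled seeds for the same total cost.
    """
    if len(starts) != len(plan.xi0):
        raise ValueError("need exactly one start per window")
    if sequential not in (None, "ascending", "descending"):
        raise ValueError("sequential must be None/'ascending'/'descending'")
    order = range(len(plan.xi0))
    if sequential == "descending":
        order = range(len(plan.xi0) - 1, -1, -1)
    chain_state = None   # (config, center) handed down the chain
    samples_by_w = {}
    for w in order:
        start, xi0 = starts[w], plan.xi0[w]
        if sequential is not None and chain_state is not None:
            start = chain_state[0]
        wsys = replace(system, config=start.copy())
        cyl = cylinder
        if sequential is not None and chain_state is not None:
            cyl = replace(cylinder, center_xy=np.asarray(chain_state[1]))
        elif centers is not None and centers[w] is not None:
            cyl = replace(cylinder, center_xy=np.asarray(centers[w]))
        wi = IntegratorParams(dt=integ.dt, gamma=integ.gamma,
                              temperature=integ.temperature,
                              seed=int(plan.seeds[w]))
        traj = langevin_run(wsys, wi, plan.steps_per_window,
                            bias=UmbrellaBias(float(xi0), plan.kappa),
                            cylinder=cyl, coord_params=coord_params,
                            stride=stride, xi_stride=xi_stride)
        n_equil = int(np.ceil(plan.equil_fraction * len(traj.xi)))
        series = traj.xi[n_equil:]
        ok = True
        if series.std() > 0:
            ok = abs(series.mean() - xi0) <= (target_tolerance_sigmas
                                              * series.std())
        if not ok:
            warnings.warn(f"window {w} (xi0={xi0:.3f}) retained mean "
                          f"{series.mean():.3f} is far from its anchor")
        samples_by_w[w] = WindowSample(
            xi0=float(xi0), kappa=plan.kappa, series=series,
            temperature=integ.temperature, times=traj.xi_times[n_equil:],
            full_series=traj.xi, n_equil=n_equil, seed=int(plan.seeds[w]),
            equilibrated_near_target=ok)
        if sequential is not None:
            end_cyl = traj.final_cylinder
            chain_state = (wsys.config.copy(),
                           (end_cyl.center_xy if end_cyl is not None
                            else cyl.center_xy))
    return [samples_by_w[w] for w in range(len(plan.xi0))]
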