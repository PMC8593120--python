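"""High-level pipeline: build → calibrate → pull → umbrella → WHAM → metrics.

Thin glue over the library modules, shared by the command-line interface,
the examples and the validation scripts.  Every stage takes its parameters
from a :class:`~memstalk.config.RunConfig` and a single integer seed from
which all per-stage seeds are derived deterministically.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .bias import PullSchedule
from .chain_coordinate import (ChainCoordParams, CylinderSpec,
                               calibrate_cylinder, compute_xi)
from .config import RunConfig
from .engine import (IntegratorParams, System, SystemBuildSpec,
                     build_double_bilayer, langevin_run, relax)
from .pmf import bootstrap_pmf, stalk_metrics, wham
from .sampling import WindowPlan, run_pull, run_umbrella, seed_windows


def _subseed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0]
               % (2**31 - 1))


def integrator(rc: RunConfig, seed: int) -> IntegratorParams:
    return IntegratorParams(dt=rc.engine.dt, gamma=rc.engine.gamma,
                            temperature=rc.engine.temperature, seed=seed)


def prepare_system(rc: RunConfig, seed: int,
                   separation: Optional[float] = None):
    """Build, relax and equilibrate the double bilayer; calibrate the
    cylinder on the flat state.  Returns (system, cylinder, coord params)."""
    spec = SystemBuildSpec(
        lipids_per_leaflet=rc.build.lipids_per_leaflet,
        tail_beads=rc.build.tail_beads,
        area_per_lipid=rc.build.area_per_lipid,
        separation=(separation if separation is not None
                    else rc.build.separation),
        n_solvent=rc.build.n_solvent)
    system = build_double_bilayer(spec, seed=_subseed(seed, 0))
    system.ff.com_halfwidth = rc.build.com_halfwidth
    system.ff.com_k = rc.build.com_k
    relax(system, 150)
    if rc.build.equilibration_steps:
        langevin_run(system, integrator(rc, _subseed(seed, 1)),
                     rc.build.equilibration_steps)
    params = ChainCoordParams(
        n0=rc.coordinate.n0, zeta=rc.coordinate.zeta,
        eps_r=rc.coordinate.eps_r, cap_h=rc.coordinate.cap_h,
        center_mode=rc.coordinate.center_mode)
    t_half = system.head_half_thickness
    zb = system.com_targets[0] + t_half
    zt = system.com_targets[1] - t_half
    template = CylinderSpec(system.config.box[:2] / 2, zb, zt,
                            rc.coordinate.radius,
                            max(2, int((zt - zb)
                                       / rc.coordinate.slice_thickness)))
    cyl = calibrate_cylinder(system.config, rc.coordinate.target_flat_xi,
                             template, params,
                             slice_thickness=rc.coordinate.slice_thickness)
    return system, cyl, params


def clone_system(system: System) -> System:
    """Independent copy sharing topology but not mutable state."""
    new = replace(system, config=system.config.copy())
    if hasattr(new, "_mem_cache"):
        del new._mem_cache
    return new


def pull_across(system: System, cyl, params, rc: RunConfig, seed: int,
                backward: bool = False, overshoot: float = 0.1):
    """Constant-velocity pull across the sampling range (either direction).

    The anchor overshoots the window range at the far end so that slow,
    activated relaxation (stalk closure in particular) still delivers
    frames near the extreme windows.
    """
    lo, hi = rc.sampling.xi_range
    back_rate = (rc.sampling.pull_rate_backward
                 if rc.sampling.pull_rate_backward is not None
                 else 0.4 * rc.sampling.pull_rate)
    # the backward anchor starts where the forward overshoot left it, so
    # the restraint force is continuous across the turn-around
    sched = (PullSchedule(hi + overshoot, max(0.0, lo - overshoot),
                          back_rate, "backward")
             if backward else
             PullSchedule(lo, hi + overshoot, rc.sampling.pull_rate,
                          "forward"))
    return run_pull(system, sched, cyl, params, integrator(rc, seed),
                    kappa=rc.sampling.pull_kappa,
                    end_warn=0.1 + overshoot, stride=25)


def umbrella_campaign(rc: RunConfig, seed: int, backward: bool = False,
                      system=None, cyl=None, params=None):
    """Full umbrella campaign; returns (windows, system, cyl, params).

    A backward campaign first pulls the system into the stalk state, then
    seeds its windows from a reverse pull, probing hysteresis.
    """
    if system is None:
        system, cyl, params = prepare_system(rc, seed)
    if backward:
        pull_across(system, cyl, params, rc, _subseed(seed, 2))
        pull = pull_across(system, cyl, params, rc, _subseed(seed, 3),
                           backward=True)
    else:
        pull = pull_across(system, cyl, params, rc, _subseed(seed, 2))
    plan = WindowPlan(
        xi0=np.linspace(*rc.sampling.xi_range, rc.sampling.n_windows),
        kappa=rc.sampling.kappa,
        steps_per_window=rc.sampling.steps_per_window,
        equil_fraction=rc.sampling.equil_fraction,
        seeds=[_subseed(seed, 100 + w) for w in range(rc.sampling.n_windows)])
    starts, _, centers = seed_windows(pull, plan, system.config)
    sequential = None
    if rc.sampling.sequential:
        sequential = "descending" if backward else "ascending"
    windows = run_umbrella(starts, plan, system, cyl, params,
                           integrator(rc, seed), centers=centers,
                           sequential=sequential)
    return windows, system, cyl, params


def profile_with_errors(windows, rc: RunConfig, seed: int):
    """WHAM + whole-window bootstrap + stalk metrics with SEs."""
    prof, mse = bootstrap_pmf(
        windows, n_boot=rc.wham.n_boot, seed=_subseed(seed, 7),
        bin_width=rc.wham.bin_width,
        flat_window=rc.wham.flat_window, stalk_window=rc.wham.stalk_window)
    metrics = stalk_metrics(prof, rc.wham.flat_window, rc.wham.stalk_window)
    if mse:
        metrics.dg_stalk_se = mse.get("dg_stalk")
        metrics.dg_barrier_se = mse.get("dg_barrier")
    return prof, metrics
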