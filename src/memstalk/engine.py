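"""Minimal solvent-free coarse-grained membrane engine.

A Cooke-style three-to-four-bead lipid model (one head bead plus ``m`` tail
beads) integrated with BAOAB Langevin dynamics provides a desk-scale double
bilayer on which the chain coordinate, umbrella sampling, WHAM and kinetics
machinery can be exercised end to end.  The model is a deliberately small
stand-in: WCA repulsion with slightly reduced head diameters, a smoothly
truncated cos^2 tail-tail attraction that drives self-assembly, FENE bonds
and harmonic 1-3 straightening springs.  Two stacked bilayers are kept at a
controlled separation by weak flat-bottom restraints on each membrane's
center-of-mass height.

Units: nm, ps, kJ/mol, K, atomic mass units; k_B = 0.0083145 kJ/mol/K.

The module also provides a tilted 1-D double well with exact quadrature
free energies, used as an analytically solvable landscape for the PMF and
kinetics machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad

from . import _kernels
from .bias import PullSchedule, UmbrellaBias, bias_energy_force, schedule_value
from .chain_coordinate import (BeadClass, ChainCoordParams, Configuration,
                               CylinderSpec, compute_xi, update_center)

KB = 0.0083145  # kJ/mol/K


class EngineError(RuntimeError):
    """Integration failure; carries the last finite frame when available."""

    def __init__(self, msg, last_good: Optional[Configuration] = None):
        super().__init__(msg)
        self.last_good = last_good


@dataclass
class ForceFieldParams:
    """Cooke-model parameters.  ``b_head`` shrinks head-involved diameters
    so heads pack slightly looser than tails, which stabilizes the bilayer."""

    epsilon: float = 2.5          # kJ/mol
    sigma: float = 0.45           # nm
    w_c: float = 0.585            # attraction range, nm (1.3 sigma)
    fene_k: float = None          # kJ/mol/nm^2, default 30 eps/sigma^2
    fene_rinf: float = None       # nm, default 1.5 sigma
    bend_k: float = None          # kJ/mol/nm^2, default 10 eps/sigma^2
    bend_r0: float = None         # nm, default 4 sigma
    b_head_factor: float = 0.95
    com_k: float = 1000.0         # membrane COM-z restraint, kJ/mol/nm^2
    com_halfwidth: float = 0.2    # flat-bottom half width, nm

    def __post_init__(self):
        s, e = self.sigma, self.epsilon
        if s <= 0 or e <= 0 or self.w_c <= 0:
            raise ValueError("epsilon, sigma, w_c must be positive")
        if self.fene_k is None:
            self.fene_k = 30.0 * e / s**2
        if self.fene_rinf is None:
            self.fene_rinf = 1.5 * s
        if self.bend_k is None:
            self.bend_k = 10.0 * e / s**2
        if self.bend_r0 is None:
            self.bend_r0 = 4.0 * s

    @property
    def b_table(self) -> np.ndarray:
        """Per-pair effective WCA diameters for (head, tail, solvent)."""
        s, f = self.sigma, self.b_head_factor
        b = np.full((3, 3), f * s)
        b[1, 1] = s
        return b

    @property
    def r_cut_tt(self) -> float:
        """Tail-tail cutoff: WCA plus the attraction range."""
        return 2 ** (1 / 6) * self.sigma + self.w_c

    @property
    def r_cut_other(self) -> float:
        """Cutoff for pairs involving a head or solvent bead (WCA only)."""
        b = self.b_table.copy()
        b[1, 1] = 0.0
        return 2 ** (1 / 6) * b.max()

    @property
    def r_cut(self) -> float:
        return max(self.r_cut_other, self.r_cut_tt)


@dataclass
class IntegratorParams:
    dt: float = 0.02              # ps
    gamma: float = 1.0            # friction, 1/ps
    temperature: float = 310.0    # K
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")


@dataclass
class SystemBuildSpec:
    """Geometry of the stacked double-bilayer test system."""

    lipids_per_leaflet: int = 64
    tail_beads: int = 3
    area_per_lipid: float = 0.26      # nm^2, Cooke fluid-phase packing
    separation: float = 1.2           # proximal head-plane gap, nm
    n_solvent: int = 0
    distal_gap: float = 2.0           # distal spacing across the z boundary
    bead_mass: float = 72.0           # u
    bond_length: float = None         # nm, default 0.96 sigma

    def __post_init__(self):
        if self.tail_beads < 2:
            raise ValueError("need at least 2 tail beads per lipid")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


@dataclass
class System:
    """Configuration plus topology and restraint bookkeeping."""

    config: Configuration
    ff: ForceFieldParams
    bonds: np.ndarray                     # (nb, 2) FENE pairs
    bends: np.ndarray                     # (na, 2) 1-3 spring pairs
    pair_type: np.ndarray                 # (N,) 0 head / 1 tail / 2 solvent
    com_targets: dict = field(default_factory=dict)   # membrane id -> z
    tether_k: Optional[np.ndarray] = None             # per-bead k, kJ/mol/nm^2
    tether_ref: Optional[np.ndarray] = None
    head_half_thickness: float = 0.0      # membrane midplane -> head plane

    @property
    def n_beads(self) -> int:
        return self.config.n_beads


def build_double_bilayer(spec: SystemBuildSpec, seed: int = 0
                         ) -> System:
    """Two parallel bilayers on a jittered lattice, deterministic per seed.

    Proximal leaflets face each other across a solvent-capable gap of width
    ``spec.separation`` (head plane to head plane).  Distal leaflets face
    each other across the periodic z boundary at ``spec.distal_gap``.
    """
    ff = ForceFieldParams()
    l0 = spec.bond_length if spec.bond_length else 0.96 * ff.sigma
    m = spec.tail_beads
    n = spec.lipids_per_leaflet
    # nearly square fully-filled lattice
    nx = next(d for d in range(int(np.sqrt(n)), 0, -1) if n % d == 0)
    ny = n // nx
    a = np.sqrt(spec.area_per_lipid)
    lx, ly = nx * a, ny * a
    t_half = (m + 0.5) * l0          # midplane -> head plane
    lz = 4 * t_half + spec.separation + spec.distal_gap
    if 2 * t_half >= lz:
        raise ValueError("membranes do not fit in the box")
    z_mid_a = 0.5 * spec.distal_gap + t_half
    z_mid_b = z_mid_a + 2 * t_half + spec.separation

    rng = np.random.default_rng(seed)
    beads_per_lipid = 1 + m
    n_lipid_beads = 4 * n * beads_per_lipid
    pos = np.empty((n_lipid_beads + spec.n_solvent, 3))
    membrane = np.full(len(pos), -1, dtype=np.int64)
    classes = np.empty(len(pos), dtype=np.int64)
    species = np.empty(len(pos), dtype="U4")
    bonds, bends = [], []

    k = 0
    for mem, z_mid in ((0, z_mid_a), (1, z_mid_b)):
        for leaflet in (-1, +1):     # -1: heads at lower z
            shift = 0.25 * a if leaflet > 0 else 0.0  # stagger leaflets
            for i in range(nx):
                for j in range(ny):
                    x = (i + 0.5) * a + shift
                    y = (j + 0.5) * a + shift
                    z_head = z_mid + leaflet * t_half
                    first = k
                    for b in range(beads_per_lipid):
                        jit = rng.uniform(-0.02, 0.02, 3)
                        z = z_head - leaflet * b * l0
                        pos[k] = ((x + jit[0]) % lx, (y + jit[1]) % ly,
                                  (z + 0.5 * jit[2]) % lz)
                        classes[k] = (int(BeadClass.HEADGROUP) if b == 0
                                      else int(BeadClass.APOLAR_TAIL))
                        species[k] = "LIP"
                        membrane[k] = mem
                        if b > 0:
                            bonds.append((k - 1, k))
                        if b > 1:
                            bends.append((k - 2, k))
                        k += 1
                    assert k - first == beads_per_lipid
    # solvent in the proximal gap, jittered grid to avoid hard overlaps
    if spec.n_solvent:
        gap_lo = z_mid_a + t_half + 0.25
        gap_hi = z_mid_b - t_half - 0.25
        height = gap_hi - gap_lo
        if height <= 0:
            raise ValueError("separation too small for solvent beads")
        ns = spec.n_solvent
        # number of z layers limited by the available height; fill each
        # layer with a near-square xy grid
        gz = max(1, int(round(height / ff.sigma)))
        per_layer = int(np.ceil(ns / gz))
        gx = max(1, int(np.ceil(np.sqrt(per_layer * lx / ly))))
        gy = max(1, int(np.ceil(per_layer / gx)))
        if min(lx / gx, ly / gy) < 0.85 * ff.sigma:
            raise ValueError(
                f"{ns} solvent beads do not fit in the proximal gap")
        sites = [((i + 0.5 + 0.25 * (q % 2)) * lx / gx,
                  (j + 0.5 + 0.25 * (q % 2)) * ly / gy,
                  gap_lo + (q + 0.5) * height / gz)
                 for q in range(gz) for i in range(gx) for j in range(gy)]
        for s in range(ns):
            x, y, z = sites[s]
            jit = rng.uniform(-0.03, 0.03, 3)
            pos[n_lipid_beads + s] = ((x + jit[0]) % lx, (y + jit[1]) % ly,
                                      np.clip(z + jit[2], gap_lo, gap_hi))
            classes[n_lipid_beads + s] = int(BeadClass.SOLVENT)
            species[n_lipid_beads + s] = "SOL"

    config = Configuration(pos, np.array([lx, ly, lz]), classes, species,
                           membrane=membrane,
                           masses=np.full(len(pos), spec.bead_mass))
    pair_type = np.where(classes == int(BeadClass.HEADGROUP), 0,
                         np.where(classes == int(BeadClass.APOLAR_TAIL), 1, 2)
                         ).astype(np.int64)
    sys = System(config=config, ff=ff,
                 bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
                 bends=np.array(bends, dtype=np.int64).reshape(-1, 2),
                 pair_type=pair_type,
                 com_targets={0: z_mid_a, 1: z_mid_b},
                 head_half_thickness=t_half)
    _check_no_overlap(sys)
    return sys


def _check_no_overlap(system: System, factor: float = 0.5):
    """Reject built geometries with beads deep inside the repulsive core."""
    try:
        e, _ = energy_forces(system)
    except EngineError as exc:
        raise ValueError(f"built geometry overlaps: {exc}") from exc
    cfg = system.config
    pl = PairList(system, skin=0.0)
    pl.update(cfg.positions, cfg.box, force=True)
    r_min = np.inf
    for pairs, n in ((pl.pairs_tt, pl.counts[0]),
                     (pl.pairs_other, pl.counts[1])):
        if n == 0:
            continue
        i, j = pairs[:n, 0], pairs[:n, 1]
        d = cfg.positions[i] - cfg.positions[j]
        d -= cfg.box * np.round(d / cfg.box)
        r_min = min(r_min, float(np.sqrt((d * d).sum(axis=1).min())))
    if r_min < factor * system.ff.sigma:
        raise ValueError(
            f"built geometry overlaps: minimum pair distance {r_min:.3f} nm "
            f"< {factor} sigma")


class PairList:
    """Split Verlet neighbor lists with a skin, rebuilt on half-skin drift."""

    def __init__(self, system: System, skin: float = 0.25):
        self.skin = skin
        self.rlist_tt = system.ff.r_cut_tt + skin
        self.rlist_other = system.ff.r_cut_other + skin
        self.ptype = system.pair_type
        n = system.n_beads
        self.pairs_tt = np.empty((max(1024, n * 30), 2), np.int64)
        self.pairs_other = np.empty((max(1024, n * 30), 2), np.int64)
        self.counts = np.zeros(2, np.int64)
        self.ref = None

    def update(self, pos: np.ndarray, box: np.ndarray, force: bool = False):
        if not force and self.ref is not None:
            disp = pos - self.ref
            disp -= box * np.round(disp / box)
            if (disp * disp).sum(axis=1).max() < (0.5 * self.skin) ** 2:
                return
        while True:
            self.counts[:] = 0
            _kernels.build_pairs(pos, box, self.ptype, self.rlist_tt,
                                 self.rlist_other, self.pairs_tt,
                                 self.pairs_other, self.counts)
            if self.counts[0] < 0:
                self.pairs_tt = np.empty((2 * self.pairs_tt.shape[0], 2),
                                         np.int64)
            elif self.counts[1] < 0:
                self.pairs_other = np.empty((2 * self.pairs_other.shape[0], 2),
                                            np.int64)
            else:
                break
        self.ref = pos.copy()


def energy_forces(system: System, config: Optional[Configuration] = None,
                  pair_list: Optional[PairList] = None):
    """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm)."""
    cfg = config if config is not None else system.config
    pos = np.ascontiguousarray(cfg.positions)
    box = cfg.box
    ff = system.ff
    forces = np.zeros_like(pos)
    if pair_list is None:
        pair_list = PairList(system, skin=0.0)
        pair_list.update(pos, box, force=True)
    e = _kernels.nonbonded_pairs(pos, box, system.pair_type, ff.b_table,
                                 ff.epsilon, ff.sigma, ff.w_c,
                                 pair_list.pairs_tt, pair_list.counts[0],
                                 pair_list.pairs_other, pair_list.counts[1],
                                 forces)
    e += _kernels.bonded_forces(pos, box, system.bonds, ff.fene_k,
                                ff.fene_rinf, system.bends, ff.bend_k,
                                ff.bend_r0, forces)
    if not np.isfinite(e):
        raise EngineError("FENE bond beyond maximum extension")
    e += _restraint_forces(system, cfg, forces)
    return e, forces


def _membrane_cache(system: System, cfg: Configuration):
    cache = getattr(system, "_mem_cache", None)
    if cache is None:
        masses = (cfg.masses if cfg.masses is not None
                  else np.ones(cfg.n_beads))
        cache = {}
        for mem, z0 in system.com_targets.items():
            idx = np.flatnonzero(cfg.membrane == mem)
            if idx.size:
                m = masses[idx]
                cache[mem] = (idx, m, m.sum(), m / m.sum())
        system._mem_cache = cache
    return cache


def _restraint_forces(system: System, cfg: Configuration, forces: np.ndarray):
    """Membrane COM flat-bottom restraints and optional per-bead tethers."""
    e = 0.0
    ff = system.ff
    if system.com_targets and cfg.membrane is not None:
        for mem, z0 in system.com_targets.items():
            entry = _membrane_cache(system, cfg).get(mem)
            if entry is None:
                continue
            idx, msel, mtot, mfrac = entry
            # minimum-image COM relative to the restraint target
            dz = cfg.positions[idx, 2] - z0
            dz -= cfg.box[2] * np.round(dz / cfg.box[2])
            com_dev = float(msel @ dz) / mtot
            excess = abs(com_dev) - ff.com_halfwidth
            if excess > 0:
                s = 1.0 if com_dev > 0 else -1.0
                e += 0.5 * ff.com_k * excess**2
                forces[idx, 2] += (-ff.com_k * excess * s) * mfrac
    if system.tether_k is not None:
        d = cfg.positions - system.tether_ref
        d -= cfg.box * np.round(d / cfg.box)
        e += float(np.sum(0.5 * system.tether_k[:, None] * d * d))
        forces -= system.tether_k[:, None] * d
    return e


@dataclass
class Trajectory:
    """Strided frames plus the biased-coordinate timeseries."""

    times: np.ndarray
    frames: list                      # list of (N, 3) position arrays
    box: np.ndarray
    xi_times: np.ndarray = None
    xi: np.ndarray = None             # xi at each recorded step
    xi0: np.ndarray = None            # bias anchor at each recorded step
    centers: np.ndarray = None        # cylinder center per xi record

    def frame_config(self, i: int, template: Configuration) -> Configuration:
        cfg = template.copy()
        cfg.positions = self.frames[i].copy()
        cfg.time = float(self.times[i])
        return cfg

    def save(self, path):
        """Chunked binary dump (npz): times, stacked frames, box, and the
        biased-coordinate records when present."""
        arrays = {"times": self.times, "frames": np.stack(self.frames),
                  "box": self.box}
        for name in ("xi_times", "xi", "xi0", "centers"):
            v = getattr(self, name)
            if v is not None:
                arrays[name] = v
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            traj = cls(times=z["times"], frames=list(z["frames"]),
                       box=z["box"])
            for name in ("xi_times", "xi", "xi0", "centers"):
                if name in z:
                    setattr(traj, name, z[name])
        return traj


def relax(system: System, n_steps: int = 200, max_disp: float = 0.01):
    """Capped steepest-descent relaxation to remove builder overlaps."""
    cfg = system.config
    for _ in range(n_steps):
        _, f = energy_forces(system, cfg)
        fmax = np.abs(f).max()
        if fmax < 1e-3:
            break
        step = min(max_disp / fmax, 1e-4)
        cfg.positions = np.mod(cfg.positions + step * f, cfg.box)
    return system


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    return 2.0 * ke / (3.0 * len(masses) * KB)


def langevin_run(system: System, integ: IntegratorParams, n_steps: int,
                 bias: Optional[UmbrellaBias] = None,
                 schedule: Optional[PullSchedule] = None,
                 cylinder: Optional[CylinderSpec] = None,
                 coord_params: Optional[ChainCoordParams] = None,
                 stride: int = 200, xi_stride: int = 10,
                 center_update_every: int = 10,
                 velocities: Optional[np.ndarray] = None) -> Trajectory:
    """BAOAB Langevin dynamics with an optional chain-coordinate restraint.

    With a bias attached, the coordinate (and its gradient) is evaluated
    every step; a dynamic cylinder center is refreshed every
    ``center_update_every`` steps from the then-current weights, lagging the
    gradient as the coordinate definition prescribes.  Records positions
    every ``stride`` steps and (t, xi, xi0) every ``xi_stride`` steps.
    """
    cfg = system.config
    masses = (cfg.masses if cfg.masses is not None
              else np.full(cfg.n_beads, 72.0))
    rng = np.random.default_rng(integ.seed)
    kt = KB * integ.temperature
    dt = integ.dt
    c1 = np.exp(-integ.gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(kt / masses)[:, None]

    v = (velocities.copy() if velocities is not None
         else rng.normal(0.0, 1.0, (cfg.n_beads, 3)) * sig_v)
    x = cfg.positions.copy()
    biased = bias is not None or schedule is not None
    if biased and (cylinder is None or coord_params is None):
        raise ValueError("biased runs need a cylinder and coordinate params")
    cyl = cylinder
    plist = PairList(system)
    sel_cache = None
    if biased:
        from .chain_coordinate import select_apolar_beads
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            sel_cache = select_apolar_beads(cfg, coord_params.selection_rule)

    def total_force(x_now, t_now):
        nonlocal cyl
        cfg.positions = x_now
        cfg.time = t_now
        plist.update(x_now, cfg.box)
        e, f = energy_forces(system, cfg, pair_list=plist)
        xi_val = None
        xi0_now = None
        if biased:
            res = compute_xi(cfg, cyl, coord_params, selection=sel_cache)
            xi_val = res.xi
            if schedule is not None:
                # schedules run on time since the start of this run
                xi0_now = schedule_value(schedule, t_now - t0)
                b = UmbrellaBias(xi0_now, bias.kappa if bias else 1000.0)
            else:
                b = bias
                xi0_now = b.xi0
            eb, fb = bias_energy_force(res, b)
            f += fb
        return f, xi_val, xi0_now

    times, frames = [], []
    xi_t, xi_v, xi_a, centers = [], [], [], []
    t0 = cfg.time
    f, xi_val, xi0_now = total_force(x, t0)

    def record(step, xi_val, xi0_now):
        t = t0 + step * dt
        if step % stride == 0:
            times.append(t)
            frames.append(x.copy())
        if biased and step % xi_stride == 0:
            xi_t.append(t)
            xi_v.append(xi_val)
            xi_a.append(xi0_now)
            centers.append(cyl.center_xy.copy())

    record(0, xi_val, xi0_now)
    last_good = x.copy()
    kin_sum = 0.0
    kin_n = 0
    kin_skip = n_steps // 5    # discard the first 20 % for the T average
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / masses[:, None]
        x += 0.5 * dt * v
        if integ.gamma > 0:
            v = c1 * v + c2 * sig_v * rng.normal(0.0, 1.0, v.shape)
        x += 0.5 * dt * v
        x %= cfg.box
        if (biased and coord_params.center_mode == "dynamic"
                and step % center_update_every == 0):
            cfg.positions = x
            from dataclasses import replace as _replace
            cyl = _replace(cyl, center_xy=update_center(cfg, cyl, coord_params))
        try:
            f, xi_val, xi0_now = total_force(x, t0 + step * dt)
        except EngineError:
            cfg.positions = last_good
            raise EngineError(
                f"integration blew up at step {step}",
                last_good=cfg.copy())
        if not np.all(np.isfinite(x)):
            cfg.positions = last_good
            raise EngineError(f"non-finite coordinates at step {step}",
                              last_good=cfg.copy())
        v += 0.5 * dt * f / masses[:, None]
        last_good = x.copy()
        if step > kin_skip:
            kin_sum += float(np.sum(masses[:, None] * v * v))
            kin_n += 1
        record(step, xi_val, xi0_now)

    cfg.positions = x
    cfg.time = t0 + n_steps * dt
    traj = Trajectory(times=np.array(times), frames=frames, box=cfg.box.copy())
    if biased:
        traj.xi_times = np.array(xi_t)
        traj.xi = np.array(xi_v)
        traj.xi0 = np.array(xi_a)
        traj.centers = np.array(centers)
    traj.final_velocities = v
    traj.final_cylinder = cyl
    traj.mean_kinetic_temperature = (
        kin_sum / (3.0 * cfg.n_beads * KB * kin_n) if kin_n else np.nan)
    return traj


# ---------------------------------------------------------------------------
# 1-D tilted double well: exact landscape for PMF and kinetics oracles

@dataclass
class DoubleWell1D:
    """U(x) = h [(x/a)^2 - 1]^2 + c x, with quadrature thermodynamics.

    ``h`` sets the barrier scale (kJ/mol), ``a`` the well positions and
    ``c`` tilts the landscape; c = 0 is symmetric by construction.
    """

    h: float
    a: float = 1.0
    c: float = 0.0

    def __post_init__(self):
        if self.h <= 0 or self.a <= 0:
            raise ValueError("h and a must be positive")

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        return self.h * ((x / self.a) ** 2 - 1.0) ** 2 + self.c * x

    def force(self, x):
        x = np.asarray(x, dtype=float)
        return -(4.0 * self.h * x * ((x / self.a) ** 2 - 1.0) / self.a**2
                 + self.c)

    def barrier_top(self) -> float:
        """Stationary point between the wells (root of U' nearest 0)."""
        roots = np.roots([4 * self.h / self.a**4, 0.0,
                          -4 * self.h / self.a**2, self.c])
        real = roots[np.abs(roots.imag) < 1e-9].real
        return float(real[np.argmin(np.abs(real))])

    def dg_quadrature(self, temperature: float) -> float:
        """G(right well) - G(left well) by numerical quadrature, kJ/mol."""
        kt = KB * temperature
        xb = self.barrier_top()
        lim = 3.0 * self.a + 10.0 * np.sqrt(kt / self.h) * self.a
        zl = quad(lambda x: np.exp(-self.potential(x) / kt), -lim, xb)[0]
        zr = quad(lambda x: np.exp(-self.potential(x) / kt), xb, lim)[0]
        return -kt * np.log(zr / zl)

    def sample_brownian(self, n_steps: int, dt: float, temperature: float,
                        gamma: float = 1.0, mass: float = 1.0, seed: int = 0,
                        x0: Optional[float] = None,
                        bias: Optional[UmbrellaBias] = None,
                        stride: int = 1):
        """Overdamped Langevin sampling, optionally under a harmonic bias
        acting directly on x.  Returns (times, positions)."""
        rng = np.random.default_rng(seed)
        kt = KB * temperature
        mob = 1.0 / (gamma * mass)
        noise_amp = np.sqrt(2.0 * kt * mob * dt)
        x = float(x0) if x0 is not None else -self.a
        kappa = bias.kappa if bias is not None else 0.0
        xi0 = bias.xi0 if bias is not None else 0.0
        noise = rng.standard_normal(n_steps)
        out_x = _kernels.brownian_quartic(
            n_steps, dt, mob * dt, noise_amp, self.h, self.a, self.c,
            kappa, xi0, x, noise, stride)
        out_t = dt * stride * (1.0 + np.arange(len(out_x)))
        return out_t, out_x
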