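"""Chain coordinate for membrane-spanning hydrophobic connectivity.

The chain coordinate ``xi`` measures the degree of hydrophobic connectivity
between two apposed membranes.  A cylinder spanning the head-group/solvent
region between the membranes is decomposed into ``N_s`` thin slices, and
``xi`` is the fraction of slices occupied by apolar lipid-tail beads.  A flat
membrane pair leaves most slices empty (``xi`` around 0.2 after calibration),
while a fully formed stalk fills the whole cylinder (``xi`` near 1).

All weight functions are C1-smooth so the coordinate can be biased with
well-behaved forces:

* axial slice weights are trapezoids with half-cosine ramps of half-width
  ``zeta`` at each slice boundary, forming a partition of unity across
  adjacent slices;
* the radial weight is a half-cosine switch of width ``2 * eps_r`` around
  the cylinder radius;
* per-slice occupancies saturate through a cap ``Psi`` that is linear below
  ``1 - cap_h``, equal to one above ``1 + cap_h``, and bridged by a monotone
  cubic Hermite polynomial in between.

Units are nm throughout; ``xi`` is dimensionless and confined to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Callable, Optional, Sequence

import numpy as np


class BeadClass(IntEnum):
    """Chemical classification of a coarse-grained bead."""

    APOLAR_TAIL = 0
    HEADGROUP = 1
    SOLVENT = 2
    OTHER = 3


_CLASS_NAMES = {c.name.lower(): c for c in BeadClass}


def bead_class_from_name(name: str) -> BeadClass:
    try:
        return _CLASS_NAMES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown bead class {name!r}; valid: {sorted(_CLASS_NAMES)}")


@dataclass
class Configuration:
    """One snapshot: positions, orthorhombic box and per-bead labels.

    Parameters
    ----------
    positions : (N, 3) float array, nm
    box : (3,) float array, nm — orthorhombic box lengths
    bead_class : (N,) int array of :class:`BeadClass` codes
    species : (N,) array of short species labels (e.g. residue names)
    time : float, ps
    membrane : optional (N,) int array assigning each bead to a membrane
        (used by membrane-relative cylinder anchoring and by the engine)
    masses : optional (N,) float array, u
    """

    positions: np.ndarray
    box: np.ndarray
    bead_class: np.ndarray
    species: np.ndarray
    time: float = 0.0
    membrane: Optional[np.ndarray] = None
    masses: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.bead_class = np.asarray(self.bead_class, dtype=np.int64)
        self.species = np.asarray(self.species)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        n = len(self.positions)
        if len(self.bead_class) != n or len(self.species) != n:
            raise ValueError("label arrays must match the number of beads")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.box.copy(), self.bead_class.copy(),
            self.species.copy(), self.time,
            None if self.membrane is None else self.membrane.copy(),
            None if self.masses is None else self.masses.copy(),
        )


@dataclass
class CylinderSpec:
    """Geometry of the slice-decomposed cylinder defining the coordinate.

    ``z_bottom``/``z_top`` are absolute when ``z_anchor == "absolute"``;
    with ``z_anchor == "membrane_relative"`` they are offsets added to the
    instantaneous mean z of the lower/upper membrane's tail slab.
    """

    center_xy: np.ndarray
    z_bottom: float
    z_top: float
    radius: float
    n_slices: int
    z_anchor: str = "absolute"

    def __post_init__(self):
        self.center_xy = np.asarray(self.center_xy, dtype=np.float64)
        if self.center_xy.shape != (2,):
            raise ValueError("center_xy must be a 2-vector")
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_slices < 2:
            raise ValueError("need at least 2 slices")
        if self.z_anchor not in ("absolute", "membrane_relative"):
            raise ValueError("z_anchor must be 'absolute' or 'membrane_relative'")

    @property
    def length(self) -> float:
        return self.z_top - self.z_bottom

    @property
    def slice_thickness(self) -> float:
        return self.length / self.n_slices


# A selection rule is either a callable predicate over (bead_class, species)
# arrays returning a boolean mask, or a SelectionRule value object.
@dataclass(frozen=True)
class SelectionRule:
    """Declarative bead selection: class membership and optional species set."""

    classes: tuple = (BeadClass.APOLAR_TAIL,)
    species: Optional[tuple] = None

    def mask(self, config: Configuration) -> np.ndarray:
        m = np.isin(config.bead_class, [int(c) for c in self.classes])
        if self.species is not None:
            m &= np.isin(config.species, list(self.species))
        return m


@dataclass
class ChainCoordParams:
    """Tunables of the chain coordinate.

    ``n0`` is the bead count that saturates one slice; ``zeta`` the axial
    ramp half-width; ``eps_r`` the radial switch half-width; ``cap_h`` the
    relative half-width of the smooth occupancy cap.
    """

    n0: float = 2.0
    zeta: float = 0.025
    eps_r: float = 0.05
    cap_h: float = 0.25
    center_mode: str = "fixed"
    selection_rule: SelectionRule | Callable = field(default_factory=SelectionRule)

    def __post_init__(self):
        if self.n0 <= 0 or self.zeta <= 0 or self.eps_r <= 0:
            raise ValueError("n0, zeta and eps_r must be positive")
        if not 0 < self.cap_h < 1:
            raise ValueError("cap_h must lie in (0, 1)")
        if self.center_mode not in ("fixed", "dynamic"):
            raise ValueError("center_mode must be 'fixed' or 'dynamic'")


@dataclass
class CoordinateResult:
    """Value, per-slice occupancies, and per-bead gradient of the coordinate."""

    xi: float
    raw_counts: np.ndarray      # n_s, soft bead count per slice
    occupancies: np.ndarray     # delta_s = Psi(n_s / n0), each in [0, 1]
    gradient: np.ndarray        # (N, 3) d(xi)/d(r_i), 1/nm; zero off-cylinder
    center_used: np.ndarray     # (2,) xy center actually used, nm
    z_range_used: tuple = (0.0, 0.0)


# ---------------------------------------------------------------------------
# smooth ingredient functions (value + derivative)

def _edge_ramp(z: np.ndarray, edges: np.ndarray, zeta: float):
    """Half-cosine ramp across each edge: 0 below e-zeta, 1 above e+zeta.

    Returns (R, dR/dz) with shape (n_beads, n_edges).
    """
    t = (z[:, None] - (edges[None, :] - zeta)) / (2.0 * zeta)
    inside = (t > 0.0) & (t < 1.0)
    tc = np.clip(t, 0.0, 1.0)
    r = 0.5 * (1.0 - np.cos(np.pi * tc))
    dr = np.where(inside, 0.5 * np.pi * np.sin(np.pi * tc) / (2.0 * zeta), 0.0)
    return r, dr


def radial_switch(rho: np.ndarray, radius: float, eps_r: float):
    """C1 switch: 1 for rho <= R - eps_r, 0 for rho >= R + eps_r."""
    t = (rho - (radius - eps_r)) / (2.0 * eps_r)
    inside = (t > 0.0) & (t < 1.0)
    tc = np.clip(t, 0.0, 1.0)
    w = np.where(t <= 0.0, 1.0, np.where(t >= 1.0, 0.0, 0.5 * (1.0 + np.cos(np.pi * tc))))
    dw = np.where(inside, -0.5 * np.pi * np.sin(np.pi * tc) / (2.0 * eps_r), 0.0)
    return w, dw


def occupancy_cap(x: np.ndarray, cap_h: float):
    """Saturation Psi: identity below 1-h, one above 1+h, monotone C1 bridge.

    The bridge is the cubic Hermite interpolant matching value and slope at
    both ends; its monotonicity follows from the Fritsch–Carlson condition.
    Returns (Psi(x), Psi'(x)).
    """
    x = np.asarray(x, dtype=np.float64)
    h = cap_h
    x0, x1 = 1.0 - h, 1.0 + h
    t = (x - x0) / (x1 - x0)
    tc = np.clip(t, 0.0, 1.0)
    h00 = 2 * tc**3 - 3 * tc**2 + 1
    h10 = tc**3 - 2 * tc**2 + tc
    h01 = -2 * tc**3 + 3 * tc**2
    dh00 = 6 * tc**2 - 6 * tc
    dh10 = 3 * tc**2 - 4 * tc + 1
    dh01 = -dh00
    dx = x1 - x0
    bridge = h00 * x0 + h10 * dx * 1.0 + h01 * 1.0
    dbridge = (dh00 * x0 + dh10 * dx * 1.0 + dh01 * 1.0) / dx
    val = np.where(x <= x0, x, np.where(x >= x1, 1.0, bridge))
    der = np.where(x <= x0, 1.0, np.where(x >= x1, 0.0, dbridge))
    return val, der


def _min_image(delta: np.ndarray, length) -> np.ndarray:
    return delta - length * np.round(delta / length)


# ---------------------------------------------------------------------------
# operations

def select_apolar_beads(config: Configuration,
                        rule: SelectionRule | Callable | None = None) -> np.ndarray:
    """Indices of beads matching the selection rule, in stable order.

    An empty selection is legal (the coordinate is then identically zero)
    and only triggers a warning.
    """
    if rule is None:
        rule = SelectionRule()
    mask = rule.mask(config) if isinstance(rule, SelectionRule) else rule(config)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("selection matched no beads; xi will be 0", stacklevel=2)
    return idx


def resolve_cylinder(config: Configuration, cyl: CylinderSpec,
                     params: ChainCoordParams) -> CylinderSpec:
    """Resolve membrane-relative z anchoring against the current frame."""
    if cyl.z_anchor == "absolute":
        return cyl
    if config.membrane is None:
        raise ValueError("membrane_relative anchoring needs membrane labels")
    tails = config.bead_class == int(BeadClass.APOLAR_TAIL)
    mems = np.unique(config.membrane[config.membrane >= 0])
    if len(mems) != 2:
        raise ValueError("membrane_relative anchoring needs exactly 2 membranes")
    z_means = sorted(config.positions[tails & (config.membrane == m), 2].mean()
                     for m in mems)
    return replace(cyl, z_bottom=z_means[0] + cyl.z_bottom,
                   z_top=z_means[1] + cyl.z_top, z_anchor="absolute")


def _relative_coords(config: Configuration, cyl: CylinderSpec, idx: np.ndarray):
    """Axial coordinate from z_bottom and radial distance, minimum-image."""
    pos = config.positions[idx]
    box = config.box
    dxy = _min_image(pos[:, :2] - cyl.center_xy[None, :], box[None, :2])
    rho = np.hypot(dxy[:, 0], dxy[:, 1])
    z_mid = 0.5 * (cyl.z_bottom + cyl.z_top)
    dz = _min_image(pos[:, 2] - z_mid, box[2])
    z_rel = dz + 0.5 * cyl.length  # measured from z_bottom
    return dxy, rho, z_rel


def slice_occupancies(config: Configuration, cyl: CylinderSpec,
                      params: ChainCoordParams):
    """Soft per-slice counts ``n_s`` and capped occupancies ``delta_s``."""
    res = compute_xi(config, cyl, params, _need_gradient=False)
    return res.raw_counts, res.occupancies


def compute_xi(config: Configuration, cyl: CylinderSpec, params: ChainCoordParams,
               _need_gradient: bool = True,
               selection: Optional[np.ndarray] = None) -> CoordinateResult:
    """Evaluate the chain coordinate and its analytic per-bead gradient.

    The gradient flows through the occupancy cap, the axial ramps and the
    radial switch, but never through the cylinder center: a dynamic center
    is a lagged parameter updated between force evaluations.  ``selection``
    lets a caller reuse a precomputed bead index set (the labels never
    change during a run).
    """
    from . import _kernels
    cyl = resolve_cylinder(config, cyl, params)
    d = cyl.slice_thickness
    if params.zeta >= d / 2:
        raise ValueError(
            f"zeta={params.zeta} must be < half the slice thickness {d / 2}: "
            "overlapping ramps would break the partition of unity")
    if params.eps_r >= cyl.radius:
        raise ValueError("eps_r must be smaller than the cylinder radius")
    if selection is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selection = select_apolar_beads(config, params.selection_rule)
    idx = np.ascontiguousarray(selection, dtype=np.int64)
    n_s = np.empty(cyl.n_slices)
    delta_s = np.empty(cyl.n_slices)
    grad = np.zeros_like(config.positions)
    xi = _kernels.chain_coordinate(
        config.positions, config.box, idx,
        float(cyl.center_xy[0]), float(cyl.center_xy[1]),
        float(cyl.z_bottom), float(cyl.z_top), float(cyl.radius),
        int(cyl.n_slices), float(params.n0), float(params.zeta),
        float(params.eps_r), float(params.cap_h),
        n_s, delta_s, grad, _need_gradient)
    return CoordinateResult(xi=float(xi), raw_counts=n_s,
                            occupancies=delta_s, gradient=grad,
                            center_used=cyl.center_xy.copy(),
                            z_range_used=(cyl.z_bottom, cyl.z_top))


def update_center(config: Configuration, cyl: CylinderSpec,
                  params: ChainCoordParams, min_weight: float = 1e-3) -> np.ndarray:
    """One fixed-point relocation of the cylinder axis.

    The new center is the weight-averaged xy position of the selected beads
    under the *current* axial and radial weights, with displacements taken
    minimum-image relative to the old center.  If almost no weight falls
    inside the cylinder the center is left unchanged.
    """
    cyl = resolve_cylinder(config, cyl, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idx = select_apolar_beads(config, params.selection_rule)
    if idx.size == 0:
        return cyl.center_xy.copy()
    dxy, rho, z_rel = _relative_coords(config, cyl, idx)
    edges = cyl.slice_thickness * np.arange(cyl.n_slices + 1)
    ramp, _ = _edge_ramp(z_rel, edges, params.zeta)
    w_ax_tot = ramp[:, 0] - ramp[:, -1]
    w_rad, _ = radial_switch(rho, cyl.radius, params.eps_r)
    w = w_ax_tot * w_rad
    total = w.sum()
    if total < min_weight:
        return cyl.center_xy.copy()
    shift = (w[:, None] * dxy).sum(axis=0) / total
    new = cyl.center_xy + shift
    return np.mod(new, config.box[:2])


def converge_center(config: Configuration, cyl: CylinderSpec,
                    params: ChainCoordParams, max_iter: int = 50,
                    tol: float = 1e-10) -> CylinderSpec:
    """Iterate :func:`update_center` to its fixed point."""
    for _ in range(max_iter):
        new = update_center(config, cyl, params)
        step = np.abs(_min_image(new - cyl.center_xy, config.box[:2])).max()
        cyl = replace(cyl, center_xy=new)
        if step < tol:
            break
    return cyl


def calibrate_cylinder(flat_config: Configuration, target_xi: float,
                       cyl_template: CylinderSpec, params: ChainCoordParams,
                       slice_thickness: float = 0.1, tol: float = 0.02,
                       max_extension: Optional[float] = None) -> CylinderSpec:
    """Extend the cylinder symmetrically into the hydrophobic cores.

    The template cylinder is assumed to span the inter-membrane head-group/
    solvent gap of an unperturbed flat state, where it contains no tail
    beads.  Both ends are extended by the same amount until the flat-state
    coordinate reaches ``target_xi`` within ``tol`` — the usual convention
    makes a flat membrane read about 0.2, i.e. 20 % of the slices lie inside
    the tail slabs.  ``n_slices`` is recomputed to keep the slice thickness
    close to ``slice_thickness``.
    """

    def spec_for(ext: float) -> CylinderSpec:
        zb, zt = cyl_template.z_bottom - ext, cyl_template.z_top + ext
        n = max(2, int(round((zt - zb) / slice_thickness)))
        return replace(cyl_template, z_bottom=zb, z_top=zt, n_slices=n)

    def xi_at(ext: float) -> float:
        return compute_xi(flat_config, spec_for(ext), params,
                          _need_gradient=False).xi

    box_z = flat_config.box[2]
    if max_extension is None:
        max_extension = 0.5 * (0.95 * box_z - cyl_template.length)
    if max_extension < 0:
        raise ValueError("cylinder template does not fit in the box")

    lo, f_lo = 0.0, xi_at(0.0)
    if abs(f_lo - target_xi) <= tol:
        return spec_for(0.0)
    if f_lo > target_xi:
        raise ValueError(
            f"target xi {target_xi} below the flat-state value {f_lo:.3f} "
            "of the unextended template; shrink the template instead")
    # coarse scan for a bracket, then bisection
    n_scan = max(8, int(np.ceil(max_extension / (slice_thickness / 2))))
    hi = None
    for ext in np.linspace(0.0, max_extension, n_scan + 1)[1:]:
        f = xi_at(ext)
        if f >= target_xi:
            hi, f_hi = ext, f
            break
        lo, f_lo = ext, f
    if hi is None:
        raise ValueError(
            f"target xi {target_xi} unreachable within the box: achievable "
            f"range is [{xi_at(0.0):.3f}, {f_lo:.3f}] "
            f"for extensions up to {max_extension:.2f} nm")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = xi_at(mid)
        if abs(f - target_xi) <= tol:
            return spec_for(mid)
        if f < target_xi:
            lo = mid
        else:
            hi = mid
    return spec_for(0.5 * (lo + hi))
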