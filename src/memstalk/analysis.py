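"""Stalk-ensemble analyses: density maps, enrichment, slope fits,
hydration metrics and composition summaries.

Density maps are accumulated in cylindrical (r, z) coordinates around the
stalk axis, averaging over frames and dividing by exact annular bin
volumes pi (r_out^2 - r_in^2) dz, which stays finite for on-axis beads.
Enrichment compares the mean density inside a stalk region with a
reference region in the flat membrane, rho_stalk / rho_mem - 1: positive
values mean the species accumulates in the stalk.  Composition scans
(stalk free energy versus mole fraction of an admixed lipid) are reduced
to a sensitivity slope by (optionally SE-weighted) linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chain_coordinate import Configuration, BeadClass


@dataclass
class DensityMap2D:
    """Cylindrically averaged mass density per species, u/nm^3."""

    r_edges: np.ndarray
    z_edges: np.ndarray
    densities: dict               # species name -> (nr, nz) array
    n_frames: int

    @property
    def total(self) -> np.ndarray:
        return sum(self.densities.values())

    @property
    def bin_volumes(self) -> np.ndarray:
        r2 = self.r_edges ** 2
        ann = np.pi * np.diff(r2)                    # (nr,)
        dz = np.diff(self.z_edges)                   # (nz,)
        return ann[:, None] * dz[None, :]


@dataclass
class RegionBox:
    """Stalk and reference sampling regions in (r, z), nm.

    Defaults place the stalk box on the axis around the inter-membrane
    midplane and the reference box in the same z band but far from the
    axis, inside the flat membrane."""

    stalk_r: tuple = (0.0, 1.0)
    stalk_z: tuple = (-1.5, 1.5)
    ref_r: tuple = (3.0, 4.0)
    ref_z: tuple = (-1.5, 1.5)

    def __post_init__(self):
        if self.stalk_r[1] > self.ref_r[0] and self.stalk_z[1] > self.ref_z[0] \
                and self.stalk_z[0] < self.ref_z[1] and self.stalk_r[0] < self.ref_r[1]:
            raise ValueError("stalk and reference regions must be disjoint")


@dataclass
class CompositionScan:
    """(mole fraction, dG_stalk, SE) points from a mixture series."""

    x_lipid: np.ndarray
    dg_stalk: np.ndarray
    se: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x_lipid = np.asarray(self.x_lipid, dtype=float)
        self.dg_stalk = np.asarray(self.dg_stalk, dtype=float)
        if np.any((self.x_lipid < 0) | (self.x_lipid > 1)):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.x_lipid) <= 0):
            raise ValueError("mole fractions must be strictly increasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)


@dataclass
class LipidSpec:
    """Species template: headgroup class and per-bead tail saturation."""

    name: str
    headgroup: str
    tails: Sequence[Sequence[bool]]   # per tail, per bead: True = saturated
    is_sterol: bool = False

    def __post_init__(self):
        if not self.is_sterol and len(self.tails) < 1:
            raise ValueError("non-sterol lipids need at least one tail")


def density_map(frames: Sequence[Configuration],
                r_edges: np.ndarray, z_edges: np.ndarray,
                centers: Optional[Sequence[np.ndarray]] = None,
                z_origin: Optional[float] = None,
                species_of: Optional[callable] = None) -> DensityMap2D:
    """Time-averaged cylindrical mass density around the stalk axis.

    ``centers`` gives the per-frame lateral stalk center (defaults to the
    box center); ``z_origin`` the z reference (defaults to the box middle,
    i.e. the inter-membrane midplane of the standard double bilayer).
    ``species_of`` maps a Configuration to a per-bead species label array
    (defaults to the configuration's own species labels).
    """
    import warnings as _warnings
    r_edges = np.asarray(r_edges, dtype=float)
    z_edges = np.asarray(z_edges, dtype=float)
    maps: dict = {}
    if len(frames) == 0:
        raise ValueError("no frames")
    for fi, cfg in enumerate(frames):
        center = (np.asarray(centers[fi]) if centers is not None
                  else cfg.box[:2] / 2)
        z0 = z_origin if z_origin is not None else cfg.box[2] / 2
        labels = (species_of(cfg) if species_of is not None
                  else np.asarray(cfg.species))
        dxy = cfg.positions[:, :2] - center[None, :]
        dxy -= cfg.box[None, :2] * np.round(dxy / cfg.box[None, :2])
        r = np.hypot(dxy[:, 0], dxy[:, 1])
        dz = cfg.positions[:, 2] - z0
        dz -= cfg.box[2] * np.round(dz / cfg.box[2])
        masses = (cfg.masses if cfg.masses is not None
                  else np.ones(cfg.n_beads))
        for name in np.unique(labels):
            sel = labels == name
            h, _, _ = np.histogram2d(r[sel], dz[sel],
                                     bins=(r_edges, z_edges),
                                     weights=masses[sel])
            maps[name] = maps.get(name, 0.0) + h
    vols = (np.pi * np.diff(r_edges ** 2)[:, None] * np.diff(z_edges)[None, :])
    out = {name: h / (vols * len(frames)) for name, h in maps.items()}
    if all(h.sum() == 0 for h in out.values()):
        _warnings.warn("selection contributed no mass; map is empty")
    return DensityMap2D(r_edges=r_edges, z_edges=z_edges, densities=out,
                        n_frames=len(frames))


def _region_mean_density(dmap: DensityMap2D, density: np.ndarray,
                         r_range: tuple, z_range: tuple) -> float:
    """Volume-weighted mean density over bins whose centers fall in the box."""
    rc = 0.5 * (dmap.r_edges[:-1] + dmap.r_edges[1:])
    zc = 0.5 * (dmap.z_edges[:-1] + dmap.z_edges[1:])
    mr = (rc >= r_range[0]) & (rc <= r_range[1])
    mz = (zc >= z_range[0]) & (zc <= z_range[1])
    if not (mr.any() and mz.any()):
        raise ValueError("region contains no bins")
    v = dmap.bin_volumes[np.ix_(mr, mz)]
    d = density[np.ix_(mr, mz)]
    return float((d * v).sum() / v.sum())


def enrichment(dmap: DensityMap2D, regions: RegionBox,
               species: Optional[str] = None) -> float:
    """rho_stalk / rho_mem - 1 for one species (or the total density)."""
    density = dmap.densities[species] if species is not None else dmap.total
    rho_stalk = _region_mean_density(dmap, density, regions.stalk_r,
                                     regions.stalk_z)
    rho_mem = _region_mean_density(dmap, density, regions.ref_r,
                                   regions.ref_z)
    if rho_mem <= 0:
        raise ValueError("reference region has zero density")
    return rho_stalk / rho_mem - 1.0


def _linfit(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None):
    """Weighted least-squares line fit; returns (slope, intercept, slope SE).

    With weights (1/SE^2) the slope variance is read from (X^T W X)^-1;
    unweighted fits scale it by the residual variance (n-2 dof).  Handles
    n = 2 exactly (zero SE).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 points")
    if w is None:
        W = np.ones(n)
        scale_by_residuals = True
    else:
        W = np.asarray(w, dtype=float)
        scale_by_residuals = False
    sw = W.sum()
    xbar = (W * x).sum() / sw
    ybar = (W * y).sum() / sw
    sxx = (W * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("degenerate abscissa")
    slope = (W * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    if n == 2:
        return slope, intercept, 0.0
    if scale_by_residuals:
        resid = y - (intercept + slope * x)
        s2 = (W * resid ** 2).sum() / (n - 2)
        var_slope = s2 / sxx
    else:
        var_slope = 1.0 / sxx
    return slope, intercept, float(np.sqrt(var_slope))


def fit_dg_slope(scan: CompositionScan, weighting: str = "none"):
    """Sensitivity of dG_stalk to the admixed lipid's mole fraction.

    Returns (slope, slope SE) in kJ/mol per unit mole fraction.  With
    ``weighting="se"`` each point is weighted by 1/SE^2 and the slope SE
    comes from the known-variance formula; unweighted fits use the
    residual-variance estimate.
    """
    if len(scan.x_lipid) < 3:
        raise ValueError("need at least 3 composition points")
    if weighting not in ("none", "se"):
        raise ValueError("weighting must be 'none' or 'se'")
    w = None
    if weighting == "se":
        if scan.se is None:
            raise ValueError("SE weighting requested but scan carries no SEs")
        w = 1.0 / scan.se ** 2
    slope, _, se = _linfit(scan.x_lipid, scan.dg_stalk, w)
    return float(slope), float(se)


def hydration_metrics(config: Configuration,
                      solvent_class: BeadClass = BeadClass.SOLVENT):
    """Waters per proximal lipid and per membrane area.

    The proximal compartment is the z slab between the two facing
    leaflets' head-group planes (the mean head z of the upper leaflet of
    the lower membrane and the lower leaflet of the upper membrane).
    Returns (solvent beads per proximal lipid, solvent beads per nm^2).
    """
    if config.membrane is None:
        raise ValueError("configuration carries no membrane labels")
    heads = config.bead_class == int(BeadClass.HEADGROUP)
    if not heads.any():
        raise ValueError("no lipids in configuration")
    mems = np.unique(config.membrane[config.membrane >= 0])
    if len(mems) != 2:
        raise ValueError("need exactly two membranes")
    z = config.positions[:, 2]
    mids = {m: z[(config.membrane == m) & heads].mean() for m in mems}
    lower = min(mems, key=lambda m: mids[m])
    upper = max(mems, key=lambda m: mids[m])
    # proximal head planes: heads of each membrane on the gap side
    lo_heads = heads & (config.membrane == lower) & (z > mids[lower])
    hi_heads = heads & (config.membrane == upper) & (z < mids[upper])
    if not (lo_heads.any() and hi_heads.any()):
        raise ValueError("could not identify proximal leaflets")
    z_lo = z[lo_heads].mean()
    z_hi = z[hi_heads].mean()
    solvent = config.bead_class == int(solvent_class)
    n_w = int(np.count_nonzero(solvent & (z > z_lo) & (z < z_hi)))
    n_lipids = int(np.count_nonzero(lo_heads) + np.count_nonzero(hi_heads))
    area = config.box[0] * config.box[1]
    return hydration_from_counts(n_w, n_lipids, area)


def hydration_from_counts(n_waters: int, n_proximal_lipids: int,
                          area: float):
    """(waters per lipid, waters per nm^2) from raw counts."""
    if n_proximal_lipids <= 0:
        raise ValueError("no proximal lipids")
    if area <= 0:
        raise ValueError("area must be positive")
    return n_waters / n_proximal_lipids, n_waters / area


def composition_summary(lipids: Sequence[tuple],
                        include_sterols_in_tails: bool = False) -> dict:
    """Mole-fraction-weighted composition statistics.

    ``lipids`` is a sequence of (LipidSpec, mole fraction).  Returns a dict
    with headgroup-class mole fractions, saturated/unsaturated tail-bead
    fractions and the mean tail length in beads (averaged per tail).
    Sterols are excluded from the tail statistics by default (flagged in
    the report).
    """
    if not lipids:
        raise ValueError("empty composition table")
    fracs = np.array([f for _, f in lipids], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"mole fractions sum to {fracs.sum()}, not 1")
    head_fracs: dict = {}
    for spec, f in lipids:
        head_fracs[spec.headgroup] = head_fracs.get(spec.headgroup, 0.0) + f
    sat_w = unsat_w = 0.0
    len_w = tails_w = 0.0
    for spec, f in lipids:
        if spec.is_sterol and not include_sterols_in_tails:
            continue
        for tail in spec.tails:
            for bead_saturated in tail:
                if bead_saturated:
                    sat_w += f
                else:
                    unsat_w += f
            len_w += f * len(tail)
            tails_w += f
    if tails_w == 0:
        raise ValueError("no tail-bearing species: tail statistics undefined")
    tot = sat_w + unsat_w
    return {
        "headgroup_fractions": head_fracs,
        "saturated_bead_fraction": sat_w / tot,
        "unsaturated_bead_fraction": unsat_w / tot,
        "mean_tail_length_beads": len_w / tails_w,
        "sterols_in_tail_stats": include_sterols_in_tails,
    }
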