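"""Harmonic umbrella and constant-velocity pulling restraints along xi.

The restraint energy is ``E = kappa/2 * (xi - xi0)**2`` and the force on
bead *i* follows from the chain rule through the coordinate gradient,
``F_i = -kappa * (xi - xi0) * d(xi)/d(r_i)``.  A pull schedule moves the
anchor ``xi0`` linearly in time between two values and clamps at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_coordinate import CoordinateResult


@dataclass
class UmbrellaBias:
    """Harmonic restraint ``kappa/2 (xi - xi0)^2`` in kJ/mol."""

    xi0: float
    kappa: float  # kJ/mol per unit xi^2

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class PullSchedule:
    """Linear anchor motion from xi_start to xi_end at |rate| per ps."""

    xi_start: float
    xi_end: float
    rate: float  # xi per ps, > 0
    direction: str = "forward"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @property
    def duration(self) -> float:
        """Time to traverse the schedule, ps."""
        return abs(self.xi_end - self.xi_start) / self.rate


def schedule_value(sched: PullSchedule, t: float) -> float:
    """Anchor position xi0(t): linear in t, clamped at xi_end."""
    if t < 0:
        raise ValueError("t must be non-negative")
    span = sched.xi_end - sched.xi_start
    if span == 0:
        return sched.xi_start
    frac = min(1.0, t * sched.rate / abs(span))
    return sched.xi_start + frac * span


def bias_energy_force(coord: CoordinateResult, bias: UmbrellaBias):
    """Bias energy (kJ/mol) and per-bead forces (kJ/mol/nm).

    Beads with zero coordinate gradient receive exactly zero force.
    """
    if coord.gradient is None:
        raise ValueError("coordinate result carries no gradient")
    dxi = coord.xi - bias.xi0
    energy = 0.5 * bias.kappa * dxi * dxi
    forces = (-bias.kappa * dxi) * coord.gradient
    return energy, forces
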