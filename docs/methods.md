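# Methods

## The chain coordinate

The package's central object is a smooth order parameter for hydrophobic
connectivity between two apposed membranes.  A cylinder of radius
`R_cyl` spans the head-group/solvent gap; it is divided into `N_s` axial
slices of thickness `d = (z_top - z_bottom) / N_s`.  Each selected bead
(by default every apolar tail bead) contributes to slice `s` a weight
`w_ax,s(z) * w_rad(rho)` built from C1 switching functions, giving a soft
per-slice count `n_s`.  The slice occupancy saturates through a cap,
`delta_s = Psi(n_s / N_0)`, and the coordinate is the mean occupancy

    xi = (1/N_s) * sum_s Psi(n_s / N_0),

so `xi = 0` for an empty cylinder and `xi = 1` once every slice holds at
least `N_0` beads.  After calibration (below) a flat membrane pair reads
`xi ≈ 0.2` — the cylinder ends sit inside the two hydrophobic cores — and
a fully formed stalk reads `xi ≈ 1`.

Functional forms (all C1, so the biasing force is continuous):

* axial: half-cosine ramps of half-width `zeta` at every slice boundary;
  the per-slice weights are differences of edge ramps, hence an exact
  partition of unity across adjacent slices and a trapezoid profile at
  the cylinder ends;
* radial: half-cosine switch from 1 at `rho <= R_cyl - eps_r` to 0 at
  `rho >= R_cyl + eps_r`;
* cap: identity below `1 - cap_h`, constant 1 above `1 + cap_h`, and the
  monotone cubic Hermite bridge in between (Fritsch–Carlson condition
  holds, so `Psi` never overshoots and `xi` stays in [0, 1] and is
  monotone under addition of beads).

The analytic gradient flows through all three factors by the chain rule.
Distances are minimum-image in all three dimensions relative to the
cylinder reference point.  With `center_mode="dynamic"` the cylinder axis
is re-estimated between force evaluations as the weight-averaged lateral
position of contributing beads; the gradient deliberately does not flow
through the center (standard lag approximation for defect-tracking
coordinates — it keeps forces smooth at the cost of a formally
first-order-in-lag error that vanishes for a converged center).

Defaults: `d ≈ 0.1 nm` (so `N_s` follows from the cylinder length),
`zeta = 0.025 nm`, `R_cyl = 1.2 nm` (of order one lipid–lipid spacing:
the coordinate localizes the protrusion laterally but does not dictate
the stalk's shape or radius), `eps_r = 0.05 nm`, `N_0 = 2`,
`cap_h = 0.25`.  These widths were fixed once from smoothness
considerations (ramps well separated: `zeta < d/2`, `eps_r << R_cyl`) and
are exposed as parameters.

**Calibration.**  `calibrate_cylinder` starts from a template spanning
only the inter-membrane gap (where a flat state has `xi = 0`) and extends
both ends symmetrically into the hydrophobic cores until the flat-state
value reaches the target (default 0.2) within ±0.02, re-choosing `N_s`
to keep the slice thickness near the configured `d`.  An unreachable
target raises with the achievable range.  Cylinder z-anchoring is
absolute by default; a membrane-relative mode anchors the ends to the
instantaneous mean tail-slab height of each membrane plus the offsets
captured at calibration, for robustness against drift.

## Biasing

The umbrella restraint is `E = kappa/2 (xi - xi0)^2` with per-bead force
`-kappa (xi - xi0) * grad_i xi`.  Pulling moves `xi0` linearly in time
(clamped at the end value).  The default `kappa = 5000 kJ/mol` makes the
restrained fluctuation `sigma_xi = sqrt(kT/kappa) ≈ 0.023`, about half
the spacing of 19 windows over [0.2, 1.0] — chosen for histogram overlap
in WHAM, not re-tuned afterwards.

## The engine

A deliberately minimal solvent-free coarse-grained membrane model
(Cooke-type): each lipid is one head bead plus `m >= 2` tail beads (three
by default).  Pair interactions are WCA repulsion with per-pair diameters
(head-involved pairs use `0.95 sigma`, giving heads slightly smaller
effective size), a smoothly truncated `-eps cos^2` attraction between
tail beads of range `w_c = 1.3 sigma` (this attraction drives
self-assembly and bilayer cohesion), FENE bonds (`k = 30 eps/sigma^2`,
`r_inf = 1.5 sigma`) and harmonic 1-3 straightening springs
(`k = 10 eps/sigma^2`, rest length `4 sigma`).  Units are nm, ps,
kJ/mol, K with `k_B = 0.0083145 kJ/mol/K`; defaults
`sigma = 0.45 nm`, `eps = 2.5 kJ/mol`, `T = 310 K` put the reduced
temperature `kT/eps ≈ 1.03` inside the model's fluid-bilayer regime at
this attraction range.  T is configurable; 310 K is the package-wide
default for a physiological setting.

Two stacked bilayers are built on a jittered lattice at
0.26 nm²/lipid, with the proximal head planes a configurable separation
apart; weak flat-bottom restraints on each membrane's center-of-mass
height (half-width 0.2 nm, k = 1000 kJ/mol/nm²) maintain the separation
— without them the bias could simply translate the membranes together.
Optional solvent beads (WCA-only) populate the proximal gap so hydration
metrics are meaningful.

Dynamics are BAOAB Langevin with `dt = 0.02 ps`; the time-averaged
kinetic temperature at these settings sits within 2 % of the target.
The friction default is `gamma = 1/ps`; production umbrella campaigns
use `gamma = 0.3/ps`, which thermostats equally well but lets the
solvent-free membrane relax its slow collective modes about three times
faster (friction is a thermostat coupling here, not a physical
observable — small gamma is the usual choice for implicit-solvent
sampling).  With `gamma = 0` the scheme reduces to
velocity Verlet, which the energy-drift test exploits.  Nonbonded forces
run off split Verlet pair lists (tail–tail with the attraction range,
everything else with the WCA range) rebuilt when any bead moves half the
0.25 nm skin; the builder falls back to a two-shell cell stencil or an
all-pairs sweep in small boxes.  A FENE bond at its maximum extension or
non-finite coordinates abort the run with the last finite frame attached.

The engine is a stand-in that makes every downstream stage testable at
desk scale; no fidelity to any particular lipid force field is claimed.
Absolute free energies from it are properties of this toy model only —
trends and estimator properties are what transfer.

A tilted quartic double well `U(x) = h[(x/a)^2 - 1]^2 + c x` with
overdamped Brownian dynamics (Euler–Maruyama; `dt` small enough that
`mobility * U'' * dt << 1`, since the discretization bias in sampled
variances is first order in that product) provides an exactly solvable
landscape: well free energies come from numerical quadrature of the
Boltzmann weight split at the barrier top.

## Umbrella protocol

Forward campaigns pull from the flat state across the coordinate range at
0.005/ps and seed each window with the pulled frame nearest its anchor
(error if none lies within 0.1).  Backward campaigns first form a stalk,
then pull down at 0.4× the forward rate — closure is activated and lags
the anchor, so the reverse pull must be slower — with the anchor starting
exactly where the forward overshoot ended so the restraint force is
continuous at the turn-around.  Pull anchors overshoot the window range
by 0.1 at the far end, which keeps frames available near the extreme
windows despite restraint lag.  By default windows run independently
with per-window seeds and fresh Maxwell velocities; the first 20 % (45 %
in the hysteresis experiments) of each series is flagged as
equilibration and excluded from the retained samples but never deleted.

`run_umbrella` also offers *sequential* initialization: windows run in
coordinate order and each starts from the previous window's relaxed end
state (ascending for forward campaigns, descending for backward ones).
Relaxation then accumulates along the chain at no extra cost, which
suppresses memory of the pulling direction far better than independent
pulled seeds; the production campaigns use it.

Two details matter for reversibility checks.  First, forward and
backward campaigns must share one prepared, calibrated system: cylinder
calibration carries a small per-build tolerance, and two independently
calibrated cylinders are two slightly different observables whose stalk
free energies can differ by tens of kJ/mol on a steep profile.
Second, the membrane center-of-mass restraints are tightened (half-width
0.05 nm, k = 2000) in these experiments so the inter-membrane separation
— otherwise a slowly drifting collective mode — is pinned to the same
value on both branches.

## WHAM, errors, metrics

Histogram WHAM with bin width 0.008 in xi, convergence when every window
free energy moves less than 1e-8 kT (1e5 iteration cap), log-space
stabilized.  Adjacent windows without a shared populated bin raise an
error naming the gap.  Errors come from a whole-window bootstrap:
windows are resampled with replacement, WHAM re-runs warm-started from
the full-data window free energies, and each replicate is aligned at the
best-sampled bin before the per-bin standard deviation is taken.  Whole
windows (not samples) are resampled because within-window autocorrelation
would make a per-sample bootstrap anti-conservative; alignment uses the
best-sampled bin rather than the minimum bin because the minimum can sit
in a barely-visited tail whose own noise would contaminate every SE.
Replicates that lose overlap are redrawn (bounded, with a warning).

`stalk_metrics` reports `dG_stalk` as the free energy at the stalk-side
local minimum — or at the highest sampled coordinate when the profile
still rises there (argmin pinned to the window edge) — relative to the
flat-side minimum, and a nucleation barrier only when the maximum between
the two minima exceeds both by more than 1 SE.  The profile is plotted
and stored with G = 0 at the flat-state minimum.

## Kinetics

Transition counting is committor-style: default cores at xi < 0.4 (flat)
and xi > 0.8 (stalk) — generous buffers around the flat (~0.2) and stalk
(~1) values — and a transition registers only on full entry into the
opposite core, so barrier-region chatter never counts.  Time between
commitments belongs to the last-committed state; rates are
departures/residence with Poisson SE `k/sqrt(n)`; detailed balance gives
`dG = -kT ln(k_f/k_b)` and the TST inversion `nu = k exp(+dG_barrier/kT)`
recovers attempt frequencies.

## Analyses

Density maps are cylindrical (r, z) histograms around the per-frame stalk
axis, normalized by exact annular volumes `pi (r_out^2 - r_in^2) dz`
(finite on the axis).  Enrichment is `rho_stalk/rho_mem - 1` over two
disjoint region boxes; defaults put the stalk box at `r < 1 nm`,
`|z - midplane| < 1.5 nm` and the reference at `r in [3, 4] nm` in the
same z band (region bounds are configurable; on small toy boxes tighter
regions are used).  Composition-scan slopes are (optionally SE-weighted)
least squares with the standard variance estimate; the weighted variant
treats the supplied SEs as known variances.  Composition summaries weight
per-bead saturation flags and per-tail lengths by mole fraction; sterols
are excluded from tail statistics by default (configurable), and the
report records the convention.

## The separation / hydration scan

The free energy of the toy stalk is essentially independent of the
inter-membrane separation when the gap is empty: without a medium to
displace, a longer hydrophobic bridge costs almost nothing extra.  The
physically meaningful scan therefore fills the proximal gap with solvent
beads at a fixed number density (count proportional to the gap volume,
8 beads/nm³ of usable gap), so that a larger separation also means more
interleaflet solvent — the same coupling real apposed membranes have,
where equilibrium separation grows with hydration.  With the hydrated
gap, `dG_stalk` rises steeply and monotonically with separation.

## Problem sizes in the validation suite

The automated suite exercises the full pipeline at deliberately small
scale, chosen as the smallest systems that still show the physics:
256-lipid membranes (64 per leaflet) for the reversibility check with
19 sequential windows of 9 000 steps (restraint 3 500 kJ/mol, 45 %
equilibration discard, 30 bootstrap replicates), and 144-lipid hydrated
membranes with 21 sequential windows of 2 200 steps for the separation
scan.  The double-well oracles use 15 windows of 2.4·10^6 Brownian
steps.

## Known limitations

* The toy engine's stalk free energies are far larger than those of
  chemically realistic coarse-grained membranes at comparable hydration;
  only estimator properties and qualitative trends (e.g. dG_stalk grows
  with inter-membrane separation) are meaningful.
* The generator's membranes are single-species; composition scans are
  analyzed from synthetic inputs rather than simulated mixtures.
* Hysteresis at fast pulling is real in this landscape: the stalk closes
  through a metastable partial-protrusion intermediate (visible as a
  shoulder near xi ≈ 0.34), and forward/backward agreement requires the
  slower backward pull, sequential window initialization, the shared
  calibrated system, pinned membrane heights and the low-friction
  thermostat described above.  Forward-seeded windows near the stalk
  relax toward their equilibrium means over several hundred ps; window
  lengths shorter than that bias the forward branch high.
* No pore (water-filled defect) variant of the coordinate is provided,
  and the dynamic center never carries a gradient.
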