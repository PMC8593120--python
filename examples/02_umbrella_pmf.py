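"""Full stalk PMF on the toy membrane: pull, umbrella, WHAM, bootstrap.

Runs the whole production pipeline at desk scale (a few minutes on one
core): constant-velocity pulling drags two apposed bilayers into a stalk,
umbrella windows sample the coordinate range, WHAM reconstructs the free
energy profile, and a whole-window bootstrap attaches error bars.
"""

import numpy as np

from memstalk.config import RunConfig
from memstalk import pipeline

rc = RunConfig()
rc.build.lipids_per_leaflet = 36          # 144 lipids total
rc.build.equilibration_steps = 1500
rc.sampling.n_windows = 13
rc.sampling.steps_per_window = 2000
rc.sampling.kappa = 4000.0
rc.wham.n_boot = 25

windows, system, cylinder, params = pipeline.umbrella_campaign(rc, seed=1)
profile, metrics = pipeline.profile_with_errors(windows, rc, seed=1)

print("xi        G [kJ/mol]   1 SE")
step = max(1, len(profile.bins) // 14)
for i in range(0, len(profile.bins), step):
    g, s = profile.free_energy[i], profile.se[i]
    if np.isfinite(g):
        print(f"{profile.bins[i]:5.2f} {g:12.1f} {s:6.1f}")
print(f"\nflat minimum at xi = {metrics.xi_flat_min:.2f}; "
      f"stalk read at xi = {metrics.xi_stalk:.2f}")
print(f"dG_stalk = {metrics.dg_stalk:.1f} +/- {metrics.dg_stalk_se:.1f} "
      "kJ/mol")
if metrics.dg_barrier is not None:
    print(f"nucleation barrier = {metrics.dg_barrier:.1f} kJ/mol "
          f"(stalk metastable: {metrics.metastable})")
else:
    print("no nucleation barrier resolved: the profile rises monotonically,"
          " so the stalk is unstable at this separation")
print("a large positive dG_stalk means this toy membrane pair strongly "
      "resists stalk formation at the default separation")
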