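"""Umbrella sampling + WHAM against an exactly solvable landscape.

Brownian dynamics on a quartic double well is biased with 15 harmonic
umbrella windows; WHAM merges the biased histograms back into the free
energy profile, which can be compared bin by bin with the analytic
potential.  The printed RMS deviation (in units of kT) is the end-to-end
accuracy of the sampling + reconstruction machinery.
"""

import numpy as np

import memstalk as ms
from memstalk.engine import KB, DoubleWell1D
from memstalk.pmf import WindowSample

T = 310.0
KT = KB * T
dw = DoubleWell1D(h=6 * KT, a=1.0)

windows = []
for i, x0 in enumerate(np.linspace(-1.3, 1.3, 15)):
    _, x = dw.sample_brownian(2_400_000, dt=5e-4, temperature=T,
                              seed=100 + i, x0=x0,
                              bias=ms.UmbrellaBias(x0, 60.0), stride=120)
    windows.append(WindowSample(x0, 60.0, x[len(x) // 10:], T))

profile = ms.wham(windows, bin_width=0.02)
g_ref = dw.potential(profile.bins)
g_ref -= g_ref.min()
mask = np.isfinite(profile.free_energy) & (g_ref < 8 * KT)
resid = profile.free_energy[mask] - g_ref[mask]
rms = np.sqrt(np.mean((resid - resid.mean()) ** 2))

print(f"WHAM converged in {profile.n_iterations} iterations "
      f"(residual {profile.residual:.1e} kT)")
fin = np.isfinite(profile.free_energy)
g_top = np.interp(0.0, profile.bins[fin], profile.free_energy[fin] - resid.mean())
print(f"barrier at x = 0: analytic {6.0:.2f} kT, "
      f"reconstructed {g_top / KT:.2f} kT")
print(f"RMS deviation from the analytic potential over G < 8 kT: "
      f"{rms / KT:.3f} kT")
print("values well below 0.3 kT mean the estimator reproduces a known "
      "free energy surface to a fraction of the thermal energy")
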