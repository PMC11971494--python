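"""Simulate eddy-current-driven high-order field dynamics.

A rectangular gradient step excites a single-exponential eddy mode; the
simulated k time-course is compared with the analytic convolution integral
k(t) = -gamma A dG tau (1 - exp(-t/tau)).
"""

import numpy as np

from fieldcomp import (GAMMA_PROTON, EddyGradientScene, EddyMode,
                       GradientWaveform, simulate_k_true)

dt, tau, A, dg = 1e-5, 2e-3, 1.5, 0.02
g = np.zeros((3, 800))
g[0, 100:] = dg                                 # 20 mT/m step on x
wf = GradientWaveform(g, dt, smax=1e6)          # ideal step (no slew limit)

scene = EddyGradientScene(wf, modes=(EddyMode(6, 0, A, tau),), noise_sd=0.0)
k = simulate_k_true(scene, max_order=2)

t = np.arange(700) * dt
analytic = -GAMMA_PROTON * A * dg * tau * (1 - np.exp(-t / tau))
rel = np.max(np.abs(k.k[6, 100:] - analytic)) / np.max(np.abs(analytic))
print(f"eddy mode on basis (2,0), tau = {tau * 1e3:.0f} ms, step {dg * 1e3:.0f} mT/m")
print(f"k(t) at 3 time points [rad/m^2]: {k.k[6, [150, 400, 780]]}")
print(f"max relative deviation from closed form: {rel:.2e}")
print("The simulator evaluates the LTI convolution exactly for")
print("piecewise-constant gradients, so the step response is analytic.")
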