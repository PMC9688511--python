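"""Simulate one NAD(P)H-like decay curve and recover its parameters.

A single cell's cytoplasm at the baseline metabolic state — free NAD(P)H
(0.38 ns) at 77% amplitude, protein-bound (2.7 ns) at 23% — observed for
one frame at 1e5 detected photons, then fitted with the biexponential
Poisson-MLE model.
"""

import numpy as np

from flimcell import (
    AcquisitionConfig,
    DecaySpec,
    fit_biexp,
    make_irf,
    simulate_decay_histogram,
)

cfg = AcquisitionConfig(seed=1)  # 80 MHz sync -> 12.5 ns window, 256 bins
irf = make_irf(cfg)
truth = DecaySpec(lifetimes=(0.38, 2.7), amplitudes=(0.77, 0.23), label="nadh")

curve = simulate_decay_histogram(truth, cfg, photons=1e5, rng=np.random.default_rng(1))
fit = fit_biexp(curve, irf)

print(f"simulated photons : {curve.total_photons:.0f}")
print(f"tau1 (free)       : {fit.tau1:.3f} ns   (truth 0.380)")
print(f"tau2 (bound)      : {fit.tau2:.3f} ns   (truth 2.700)")
print(f"a1 (free fraction): {fit.a1:.1f} %     (truth 77.0)")
print(f"tau_m             : {fit.tau_m:.3f} ns  (truth 0.914)")
print(f"reduced chi2      : {fit.chi2_reduced:.2f}  (0.8-1.2 = well specified)")
# tau_m tracks the metabolic state: more free NAD(P)H (higher a1) means a
# shorter mean lifetime, i.e. a shift toward glycolysis.
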