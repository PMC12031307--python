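"""Fit the equivalent circuit to one noisy synthetic spectrum.

Simulates a plausible fruit, perturbs the spectrum with realistic
measurement noise (0.5% on |Z|, 0.5 deg on phase), fits the 7-parameter
circuit and prints true vs. estimated parameters with the chi-square.
"""

import numpy as np

from bisfruit import (
    EC_PARAMETER_NAMES,
    ECParameters,
    FitConfig,
    FrequencyGrid,
    fit_spectrum,
    from_polar,
    simulate_spectrum,
)

grid = FrequencyGrid.default()
true = ECParameters.from_array([500.0, 2e-6, 0.85, 2.0e4, 6.0e3, 8e-7, 0.80])
clean = simulate_spectrum(true, grid)

rng = np.random.default_rng(0)
mag = clean.magnitude * (1 + rng.normal(0, 0.005, len(grid)))
phase = clean.phase_deg + rng.normal(0, 0.5, len(grid))
noisy = clean.with_values(from_polar(mag, phase))

result = fit_spectrum(noisy, FitConfig(seed=0))

print(f"chi-square: {result.chi_square:.3e}  (quality gate 3e-4)")
print(f"converged:  {result.converged}, winning start #{result.start_index}")
print(f"{'parameter':>10} {'true':>12} {'fitted':>12} {'rel err':>9}")
for name, t, f in zip(EC_PARAMETER_NAMES, true.as_array(), result.params.as_array()):
    print(f"{name:>10} {t:12.4g} {f:12.4g} {abs(f / t - 1):9.2%}")
print(
    "\nA chi-square well below the gate means the fitted curve is\n"
    "indistinguishable from the measurement at the noise level.  The\n"
    "tissue parameters (r_ex, r_i) recover within a few percent; the\n"
    "electrode block contributes only ~4% of |Z| here, so its parameters\n"
    "are weakly constrained once noise is present."
)
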