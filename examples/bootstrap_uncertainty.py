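"""Parameter uncertainty for a single transition via residual bootstrap.

A single noisy recovery (sigma = 2 mL/kg/min, a realistic breath-noise level) is
fitted, then the fit's residuals are resampled 1000 times to give per-parameter SDs,
coefficients of variation and 95% percentile confidence intervals — the route to
uncertainty when a swimmer performs each transition only once.
"""

import warnings

from vo2kinetics import GeneratorConfig, fit, generate_uniform, preset_spec, residual_bootstrap

warnings.filterwarnings("ignore", message="series span")

spec, truth = preset_spec("off", "severe")
u = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=2.0, seed=42))

base = fit(u, spec, seed=0)
bs = residual_bootstrap(u, base, n_samples=1000, seed=1)

print(f"model {spec.name}, n={base.n}, SER={base.ser:.2f} mL/kg/min")
print(f"{'parameter':<10}{'truth':>8}{'estimate':>10}{'SD':>8}{'CV%':>8}{'95% CI':>20}")
for name in spec.free_params:
    lo, hi = bs.ci[name]
    print(f"{name:<10}{truth.get(name):>8.1f}{base.estimates.get(name):>10.2f}"
          f"{bs.sd[name]:>8.2f}{bs.cv[name]:>8.1f}{f'({lo:.1f}, {hi:.1f})':>20}")
print("\n(the CI for tau should cover the generating value 37 s; CVs of a few percent")
print(" for amplitudes and ~5-15% for tau match what single-transition data supports)")
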