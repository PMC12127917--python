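"""Validation protocol in miniature: noise-free recovery data fitted exactly.

Generates a severe-intensity recovery curve from known parameters with zero noise,
fits all four off-transient models and prints the selection table.  A standard error
of regression (SER) of ~0 with estimates equal to the inputs shows the fitting engine
reproduces known truths exactly; the parsimony rule picks the generating
mono-exponential form even though the bi-exponential forms fit equally well.
"""

import warnings

from vo2kinetics import GeneratorConfig, generate_uniform, preset_spec, select_best

warnings.filterwarnings("ignore", message="series span")

spec, truth = preset_spec("off", "severe")
print(f"truth ({spec.name}): {truth.to_dict()}")

u = generate_uniform(GeneratorConfig(spec=spec, truth=truth, noise_sd=0.0, seed=1))
report = select_best(u, "off", seed=1)

print(f"\n{'model':<22}{'p':>3}{'SER':>12}{'RSS':>12}  competed selected")
for row in report.table():
    print(f"{row['model']:<22}{row['p']:>3}{row['ser']:>12.2e}{row['rss']:>12.2e}"
          f"  {str(row['competed']):<9}{row['selected']}")
print("\nestimates of the selected model:", report.best.estimates.to_dict())
print("(SER ~ 1e-14 means the fit is exact to machine precision; every parameter")
print(" matches its generating value, the validation claim for noise-free data)")
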