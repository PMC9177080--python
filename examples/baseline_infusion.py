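"""Baseline CED infusion of a 20 nm drug: concentration history and budget.

0.5 ml/h for 6 h (3 ml total) through a 1.5 mm catheter whose tip sits
3 mm above the center of a 6 mm tumor; 100 nm tumor vessel-wall pores and
tumor interstitial conductivity 2e-13 m2/(Pa s).  Prints the
tumor-average relative concentration over 24 h and where the infused drug
mass ended up.
"""

from cedsim import ScenarioConfig, run_scenario

HOUR = 3600.0

res = run_scenario(ScenarioConfig(drug_diameter=20e-9))

print("tumor-average relative concentration:")
for h in (1, 3, 6, 9, 12, 24):
    marker = "  <- end of infusion (maximum)" if h == 6 else ""
    print(f"  t = {h:2d} h: {res.avg.at_time(h * HOUR):6.3f}{marker}")

b = res.budget
infused = b["infused"]
print(f"\ndrug-mass budget after 24 h (fractions of the {infused * 1e6:.2f} ml-equivalents infused):")
for label, key in [
    ("still in tissue", "tissue_mass"),
    ("lost to tumor/healthy vessels", "vascular_loss"),
    ("lost to healthy lymphatics", "lymphatic_loss"),
    ("advected out of the domain", "boundary_outflow"),
]:
    print(f"  {label:30s} {100 * b[key] / infused:6.2f}%")
print(f"  budget closure residual        {b['closure_residual_relative']:.2e} (discrete audit)")

print("\nThe average peaks when the pump stops; with the default leaky-vessel")
print("filtration the infusate is reabsorbed close to the tip, so the drug")
print("accumulates locally instead of sweeping the whole tumor.")
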