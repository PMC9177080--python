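"""Catheter misplacement: tip 1 mm outside the tumor boundary.

When the tip misses the tumor, outward pressure gradients at the
tumor/healthy interface drive the infusate away from the lesion and most
drug accumulates in healthy tissue.  Tumor coverage is quantified as the
percentage of tumor volume whose relative concentration exceeds 0.2.
"""

from cedsim import ScenarioConfig, run_scenario, volume_fraction_above

HOUR = 3600.0

for drug_nm, t_h in ((1.0, 6.0), (60.0, 12.0)):
    cfg = ScenarioConfig(drug_diameter=drug_nm * 1e-9, catheter_placement="outside_1mm")
    res = run_scenario(cfg)
    pct = 100.0 * volume_fraction_above(res.series, res.mesh, 0.2, t_h * HOUR)
    print(
        f"{drug_nm:4.0f} nm drug, t = {t_h:4.1f} h: "
        f"{pct:5.2f}% of tumor volume above C = 0.2 "
        f"(tumor average {res.avg.at_time(t_h * HOUR):.3f})"
    )

print("\nSmall molecules are cleared by the vasculature before reaching the")
print("tumor; nanoparticles persist, so the 60 nm agent covers more tumor")
print("volume than the 1 nm one despite the misplaced tip.")
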