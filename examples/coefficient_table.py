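"""Hindered-transport coefficients across the drug-size / pore-size grid.

Every drug- and pore-size-dependent input of the simulator derives from
lambda = drug radius / pore radius: the diffusive hindrance H, the
reflection coefficient sigma_f, the Stokes-Einstein free diffusivity
D_free and its interstitial value D_i, the vessel-wall hydraulic
conductivity L_p, and the transvascular drug permeability P.
"""

from cedsim import transport_coefficients

print(f"{'drug':>6} {'pore':>6} {'lambda':>8} {'H':>8} {'sigma_f':>8} {'D_i [m2/s]':>11} {'P [m/s]':>10}")
for drug_nm in (1.0, 20.0, 60.0):
    for pore_nm in (50.0, 100.0, 150.0):
        c = transport_coefficients(drug_nm * 1e-9, pore_nm * 1e-9)
        print(
            f"{drug_nm:4.0f}nm {pore_nm:4.0f}nm {c.lam:8.3f} {c.H:8.4f} "
            f"{c.sigma_f:8.4f} {c.D_tissue:11.2e} {c.P:10.2e}"
        )

c1 = transport_coefficients(1e-9, 100e-9)
c20 = transport_coefficients(20e-9, 100e-9)
print(f"\npermeability reduction, 20 nm vs 1 nm drug in 100 nm pores: "
      f"{100 * (1 - c20.P / c1.P):.1f}%")
print("A 60 nm drug in 50 nm pores (lambda > 1) is fully excluded: P = 0, sigma_f = 1.")
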