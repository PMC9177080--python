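# cedsim — convection-enhanced drug delivery in brain tumors

`cedsim` is a finite-element simulator of convection-enhanced delivery
(CED): direct infusion of a therapeutic agent through a catheter into the
interstitial space of a brain tumor, bypassing the blood-brain barrier.
It is written for researchers in tissue biotransport and computational
drug delivery who want a transparent, scriptable model of how drug size,
vessel-wall pore size, tissue hydraulic conductivity and catheter
placement shape the spatio-temporal drug distribution.

## Model

Brain tissue is a rigid porous medium containing a 6 mm spherical tumor
and a 1.5 mm cylindrical catheter cavity. The interstitial fluid obeys a
quasi-steady Darcy/Brinkman balance with Starling transvascular exchange:

    div(u) = Q_m,                u = -k grad(p_i),
    Q_m = L_p S_v (p_v - p_i) - L_pl S_vl (p_i - p_l),

where `p_i` is the interstitial fluid pressure (IFP), `k` the tissue
hydraulic conductivity, `L_p S_v` the vascular filtration coefficient and
the lymphatic term is zero inside the tumor (dysfunctional lymphatics).
The relative drug concentration `C_i` follows transient
convection-diffusion with transvascular exchange, degradation and
lymphatic drainage:

    dC_i/dt + div(C_i u - D_i grad C_i) = Q - k_d C_i - k_l C_i,
    Q = (C_v - C_i) P S_v + (1 - sigma_f)(p_v - p_i) L_p S_v C_v,

with `C_v = 0` during CED, so vessels act as a diffusive drug sink.
All size-dependent coefficients come from hindered transport theory for a
rigid sphere (radius `r_s`) in liquid-filled cylindrical wall pores
(radius `r_0`), as functions of `lambda = r_s / r_0`:

    L_p = gamma r_0^2 / (8 mu L_vw),     P = gamma H(lambda) D / L_vw,
    D = K_b T / (6 pi mu r_s)            (Stokes-Einstein),
    sigma_f = 1 - W(lambda),             D_i = D / tortuosity^2,

with Bungay-Brenner hindrance factors `H`, `W` by default (a Renkin-style
centerline correlation is selectable). `lambda >= 1` means total
exclusion: `P = 0`, `sigma_f = 1`.

## Worked example

```python
from cedsim import ScenarioConfig, run_scenario, transport_coefficients

c = transport_coefficients(20e-9, 100e-9)   # 20 nm drug, 100 nm pores
print(f"lambda={c.lam:.2f} H={c.H:.3f} sigma_f={c.sigma_f:.3f} P={c.P:.2e} m/s")

res = run_scenario(ScenarioConfig(drug_diameter=20e-9))  # baseline scenario
for h in (3, 6, 12, 24):
    print(f"t={h:2d} h: tumor-average C = {res.avg.at_time(h*3600):.3f}")
```

prints

```
lambda=0.20 H=0.381 sigma_f=0.153 P=1.73e-09 m/s
t= 3 h: tumor-average C = 1.074
t= 6 h: tumor-average C = 1.727
t=12 h: tumor-average C = 0.701
t=24 h: tumor-average C = 0.131
```

A 20 nm agent is ~98% less vessel-permeable than a 1 nm one for 100 nm
pores, so it is retained after the 6 h infusion instead of clearing into
the blood. The tumor average peaks when the pump stops. Averages can
exceed 1 here because, with the default leaky-vessel filtration, the
infusate is reabsorbed by tumor vessels near the tip while the drug is
not (the vascular sink is diffusive only), concentrating the agent
locally — see `docs/methods.md` for the parameter regimes and their
consequences. The mass budget of every run is audited
(`res.budget["closure_residual_relative"]`, typically ~1e-15).

The `examples/` directory holds short narrative scripts, one per
capability (coefficient tables, the leaky-sphere IFP verification against
a closed-form oracle, the baseline infusion, catheter misplacement,
heterogeneity profiles). A thin CLI mirrors the library:

```sh
cedsim coefficients                 # drug x pore coefficient table
cedsim mesh --out out/              # synthetic domain + region report
cedsim flow --infusion-on --out out/
cedsim run --config scenario.yaml --out out/
cedsim sweep --out out/             # full 3 x 3 x 3 study grid + misplacement
```

Configuration files are YAML in human units (nm, mm, ml/h, h); unknown
keys are rejected. Outputs are VTU field snapshots, CSV time
series/profiles and a JSON run manifest.

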