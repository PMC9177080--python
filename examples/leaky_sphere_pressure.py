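"""Interstitial fluid pressure of a leaky tumor sphere: FE vs closed form.

A tumor with uniformly leaky vessels and no functional lymphatics builds
up interstitial fluid pressure toward the vascular pressure p_v in its
core and sheds it across a thin rim — the classical elevated-IFP picture
of solid tumors.  The finite-element solver is verified here against the
closed-form radial profile p(r) = p_v [1 - (R/r) sinh(ar/R)/sinh(a)].
"""

import numpy as np

from cedsim import GeometryConfig, RegionProperties, analytic_radial_ifp, build_domain, solve_flow

k, R, p_v, alpha = 2e-13, 6e-3, 3330.0, 2.0
LpSv = k * (alpha / R) ** 2
props = {
    "tumor": RegionProperties(k=k, epsilon_p=0.3, Lp_Sv=LpSv, p_v=p_v, S_v=2e4),
    # essentially unresisting, non-leaky surroundings: the oracle's
    # zero-pressure condition at the tumor edge
    "healthy": RegionProperties(k=k * 1e3, epsilon_p=0.2, Lp_Sv=0.0, p_v=0.0, S_v=7e3),
}

mesh = build_domain(GeometryConfig(catheter_tip_offset=20e-3))  # cavity parked away
ff = solve_flow(mesh, props, infusion_on=False)

r = np.hypot(mesh.points[:, 0], mesh.points[:, 1])
inside = r < 0.999 * R
exact = analytic_radial_ifp(r[inside], R, k, LpSv, p_v)
err = np.linalg.norm(ff.p[inside] - exact) / np.linalg.norm(exact)

print(f"leaky sphere, alpha = R sqrt(LpSv/k) = {alpha}")
print(f"{'r/R':>5} {'p_FE [Pa]':>10} {'p_exact [Pa]':>12}")
for x in (0.0, 0.25, 0.5, 0.75, 0.95):
    i = np.argmin(np.abs(r - x * R))
    print(f"{x:5.2f} {ff.p[i]:10.1f} {analytic_radial_ifp(r[i], R, k, LpSv, p_v):12.1f}")
print(f"\nrelative L2 error inside the tumor: {100 * err:.2f}%  (converges ~O(h^1.5))")
print("The pressure plateaus toward p_v in the core and falls to ~0 at the rim,")
print("so interstitial flow is confined to the tumor margin.")
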