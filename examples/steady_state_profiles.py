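"""Predicted kinesin-1 distributions for the four transport models.

Builds the closed-form steady state of each model in a 30 µm process at the
measured kinetics (v = 0.78 µm/s, D = 4.08 µm²/s, k_on = 1.22 s⁻¹,
k_off = 0.67 s⁻¹), cross-checks it against the PDE solver, and prints the
tip/middle density contrast. Linear profiles (Diligent Worker, Hybrid 1)
have a mild contrast; exponential ones (Loose Bucket Brigade, Hybrid 2) pile
motors up at the tip — the feature that discriminates the models in
volume-corrected immunostain line scans.
"""

import numpy as np

import kinesim as ks

p = ks.PAPER_PARAMS
geom = ks.Geometry1D(30.0)

print(f"kinetics: v={p.v} µm/s  D={p.D} µm²/s  k_on={p.k_on}/s  k_off={p.k_off}/s")
print(f"LBB decay length  λ = {ks.decay_length(p):.3f} µm")
print(f"H2  decay length  ℓ = {ks.decay_length(p, ks.HYBRID2):.3f} µm\n")

for var in (ks.DILIGENT_WORKER, ks.LOOSE_BUCKET_BRIGADE, ks.HYBRID1, ks.HYBRID2):
    ss = ks.steady_state(var, p, geom, J=1.0)
    f = ks.steady_state_numeric(var, p, geom, ks.SolverConfig(dx=0.01), J=1.0)
    exact = ss.c_tot(f.x)
    rel_l2 = np.linalg.norm(f.c_tot - exact) / np.linalg.norm(exact)
    contrast = ss.c_tot(np.array(29.0)) / ss.c_tot(np.array(15.0))
    print(
        f"{var.name:22s} family={ss.profile_family:12s} "
        f"tip/middle density = {contrast:8.1f}   PDE vs closed form: {100*rel_l2:.2f}%"
    )

print(
    "\nThe tip/middle contrast of the exponential models is what an"
    "\nexponentially increasing KHC/EGFP ratio profile reports; the PDE"
    "\ncolumn confirms the closed forms against an independent solver."
)
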