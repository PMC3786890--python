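"""FRAP diffusion-coefficient estimation and the fit-window bias.

Generates a noisy synthetic strip-bleach recovery (35 µm strip, true
D = 4.08 µm²/s, 90 s at 3 s frames, σ = 0.02), fits it over the first 15 s,
then shows on a transport-contaminated curve why a short early window
matters: slow directed transport masquerades as extra diffusion and inflates
long-window estimates.
"""

import kinesim as ks
from kinesim.frap import FRAPConfig
from kinesim.synth import NoiseModel, gen_frap_series

cfg = FRAPConfig(w=35.0, b=0.0, fit_window=15.0)
curve, _, meta = gen_frap_series(cfg, 4.08, NoiseModel(sigma=0.02), seed=11)
fit = ks.fit_diffusion(curve, cfg)
print(f"true D = {meta['D_star_um2_s']} µm²/s")
print(f"fitted D (15 s window) = {fit.D:.3f} µm²/s, error of fit = {fit.error_of_fit:.4f}")

contaminated, _, _ = gen_frap_series(
    FRAPConfig(w=35.0), 4.08, NoiseModel(sigma=0.0), seed=1,
    transport_amplitude=0.15, transport_tau=60.0,
)
for window in (15.0, 30.0, None):
    f = ks.fit_diffusion(contaminated, FRAPConfig(w=35.0, fit_window=window))
    label = f"{window:.0f} s" if window else "full 90 s"
    print(f"with slow transport component, {label:9s} window: D̂ = {f.D:.2f} µm²/s")

print(
    "\nThe error of fit is the mean |data − model| over the window; on the"
    "\ncontaminated curve the estimate grows with window length, so the early"
    "\nwindow is the faithful one for the diffusing pool."
)
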