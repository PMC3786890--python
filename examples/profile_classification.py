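"""From a two-channel line scan to the microtubule binding rate.

Generates a synthetic KHC/EGFP line profile under the Loose Bucket Brigade
(volume taper and growth-cone bulge included, SNR 10), takes the
point-by-point ratio to cancel volume, classifies the increasing portion as
exponential vs linear by corrected AIC, and inverts the fitted decay length
to the motor–microtubule binding rate k_on.
"""

import kinesim as ks
from kinesim.synth import VolumeProfile, gen_line_profile

p = ks.PAPER_PARAMS
geom = ks.Geometry1D(30.0)

profile, meta = gen_line_profile(
    ks.LOOSE_BUCKET_BRIGADE, p, geom, VolumeProfile(), seed=5, snr=10
)
print(f"ground truth: family={meta['profile_family']}, λ = {meta['lambda_um']:.3f} µm, "
      f"k_on = {meta['params']['k_on']} s⁻¹")

rp = ks.ratio_profile(profile)
fit = ks.fit_profile(rp)
print(f"fitted: family={fit.family} (ΔAICc = {fit.delta_aicc:.1f}"
      + (", ambiguous)" if fit.ambiguous else ")"))
print(f"fitted decay length λ̂ = {fit.lam:.3f} ± {fit.lam_se:.3f} µm")

k_on, se = ks.binding_rate_from_profile(fit, v=p.v, D=p.D, k_off=p.k_off)
print(f"inferred k_on = {k_on:.3f} ± {se:.3f} s⁻¹  (via k_on = D/λ² + D·k_off/(v·λ))")

lin, _ = gen_line_profile(ks.DILIGENT_WORKER, p, geom, VolumeProfile(), seed=5, snr=10)
fit_lin = ks.fit_profile(ks.ratio_profile(lin))
print(f"\nsame pipeline on a Diligent-Worker profile: family={fit_lin.family}")
print(
    "\nAn exponential ratio profile is the signature of motors that detach,"
    "\ndiffuse and reattach along the process; its decay length plus the"
    "\nindependently measured v, D, k_off pins down the binding rate."
)
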