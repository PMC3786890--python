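# kinesim

Models and analysis tools for the transport and diffusive recycling of
kinesin-1 motors in quasi-1D neuronal processes (neurites and axons).

After a kinesin-1 motor has hauled its cargo to the microtubule plus ends at
the process tip, how does it get back for another round? `kinesim`
implements the quantitative machinery to answer that question from light
microscopy data: four two-state transport models with closed-form steady
states and cycle times, a reaction–advection–diffusion solver, a stochastic
single-motor simulator with an in silico photoactivation assay, strip-bleach
FRAP fitting for the free-motor diffusion coefficient, and a line-profile
analysis that classifies motor distributions and extracts the
motor–microtubule binding rate.

## The models

All models share one description: a cargo-**bound** motor moves tipward at
speed *v*; a **free** (autoinhibited) motor diffuses with coefficient *D*;
exchange happens at rates *k*<sub>off</sub> (bound → free) and
*k*<sub>on</sub> (free → bound). The four variants differ only in when a
motor may detach and rebind:

| model | detaches in transit | rebinds | total steady-state density |
|---|---|---|---|
| Diligent Worker | no | never | linear in *x* |
| Loose Bucket Brigade | yes | anywhere | exponential, length λ |
| Hybrid 1 | yes | never | saturating/linear |
| Hybrid 2 | no | on the way back | exponential, length √(D/k<sub>on</sub>) |

At steady state the closed system carries zero net axial flux,
*v·c*<sub>b</sub> = *D·∂c*<sub>f</sub>/∂x, which for the Loose Bucket
Brigade gives exponential modes e^(x/λ) with 1/λ = *y* the positive root of

    D·v·y² + D·k_off·y − k_on·v = 0.

Inverted, a measured decay length yields the binding rate:

    k_on = D/λ² + D·k_off/(v·λ).

Cycle times: the Diligent Worker needs T = L/v + L²/(2D) per round trip
(quadratic in process length — ~10 min at 65 µm); the Loose Bucket Brigade
needs T = 1/k_off + 1/k_on per hand-off cycle, independent of length.

Default kinetics are the measured values for kinesin-1 in differentiated
CAD-cell neurites: v = 0.78 µm/s, D = 4.08 µm²/s, k_off = 0.67 s⁻¹, and the
inferred k_on = 1.22 s⁻¹ (`kinesim.PAPER_PARAMS`).

## Worked example

```sh
python examples/profile_classification.py
```

```
ground truth: family=exponential, λ = 3.762 µm, k_on = 1.22 s⁻¹
fitted: family=exponential (ΔAICc = 186.6)
fitted decay length λ̂ = 3.886 ± 0.157 µm
inferred k_on = 1.172 ± 0.058 s⁻¹  (via k_on = D/λ² + D·k_off/(v·λ))

same pipeline on a Diligent-Worker profile: family=linear
```

A synthetic two-channel line scan (motor channel = volume × total motor
density; EGFP channel = volume) is generated under the Loose Bucket Brigade
at SNR 10, the point-by-point ratio cancels the volume, the increasing
portion is fitted by both a linear and an exponential model (corrected-AIC
selection), and the fitted decay length is inverted to the binding rate —
recovering the ground truth within its quoted uncertainty, while a profile
generated under the Diligent Worker is correctly classified linear.

The other scripts in `examples/` each run one capability end to end:
`steady_state_profiles.py` (closed forms vs the PDE solver),
`cycle_times.py` (analytic vs Monte-Carlo recycling times),
`frap_fit.py` (diffusion fitting and the fit-window bias),
`photoactivation.py` (single vs repeated tip activation, ~2 min).

A thin CLI exposes the same operations, e.g.:

```sh
kinesim cycle-time --model diligent_worker --L 65      # → 601.1 s (10 min)
kinesim synth frap --seed 1 --out frap.csv
kinesim frap-fit frap.csv --w 35 --fit-window 15
```

## Layout

- `src/kinesim/params.py` — kinetic parameters, model variants, geometry
- `src/kinesim/steady.py` — closed-form steady states, decay lengths, cycle times
- `src/kinesim/pde.py` — finite-volume reaction–advection–diffusion solver
- `src/kinesim/montecarlo.py` — stochastic motors, photoactivation assay
- `src/kinesim/frap.py` — strip-bleach recovery model and diffusion fitting
- `src/kinesim/profiles.py` — ratio profiles, model selection, k_on inference
- `src/kinesim/synth.py` — synthetic data generators with recorded ground truth
- `src/kinesim/io.py`, `cli.py` — delimited-text I/O and the CLI
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
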