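# Methods

## The two-field transport model

A neuronal process is a 1D segment 0 ≤ x ≤ L (µm), x = 0 at the soma/base,
x = L at the tip. Motor state is reduced to two (optionally three) pools:

- **bound** — attached to cargo on the microtubule, advecting tipward at
  constant speed v (µm/s); microtubules are treated as uniformly polarized
  plus-end-out, so bound motion is purely anterograde;
- **free** — autoinhibited and soluble, diffusing with coefficient D
  (µm²/s), able to rebind at rate k_on (s⁻¹);
- **inert** — diffusing like the free pool but excluded from rebinding
  (used by variants that forbid reattachment for some or all released
  motors).

Exchange is local and position-independent: bound → diffusing at k_off
(s⁻¹), free → bound at k_on. The four named variants are pure policy
choices on this skeleton (who detaches, who rebinds); they share every
parameter. Motor number is conserved — no synthesis or degradation — which
matches the observation that the motor pool is stable on the experimental
timescale.

Default kinetics (`PAPER_PARAMS`): v = 0.78 µm/s, D = 4.08 µm²/s,
k_off = 0.67 s⁻¹, k_on = 1.22 s⁻¹. Units are fixed to µm/s/s⁻¹ everywhere;
nothing converts units.

### Boundary conditions

The soma is modelled as a reservoir: diffusing motors reaching x = 0 are
absorbed (the cell body is large compared with the process) and bound motors
are injected at flux J (motors/s), representing cargo loading at the base.
In closed-recycling mode the absorbed flux is re-injected, so the total
motor number is constant; the steady-state *shape* is identical to any
fixed-J solution. The tip reflects diffusing motors, and arriving bound flux
v·c_b(L) converts instantaneously to the diffusing pool (motors disengage at
the plus end). A fully reflecting soma is also available (used by the
stochastic photoactivation assay, where the labelled pool must be closed).

### Steady states and the dispersion relation

At stationarity the net axial flux v·c_b − D·∂c_f/∂x is constant, and zero
for the recycling system. Exponential modes e^(y·x) of the zero-flux
two-field system obey

    D·v·y² + D·k_off·y − k_on·v = 0,

whose positive root gives the tipward decay length λ = 1/y⁺ of the Loose
Bucket Brigade; the negative root y⁻ supplies a subdominant mode that
satisfies the absorbing-soma condition c_f(0) = 0. The closed forms
implemented in `steady.py` are the exact solutions of these boundary-value
problems:

- Diligent Worker: c_b = J/v uniform; diffusing pool J·x/D (linear).
- Loose Bucket Brigade: c_f = A(e^(y⁺x) − e^(y⁻x)), c_b = (D/v)·A·(y⁺e^(y⁺x)
  − y⁻e^(y⁻x)), A = J/(D(y⁺ − y⁻)).
- Hybrid 2: c_b = (J/v)·cosh(x/ℓ), c_f = (Jℓ/D)·sinh(x/ℓ), ℓ = √(D/k_on).
- Hybrid 1 (default, no rebinding at all): c_b = (J/v)e^(−x/ℓ_b) with
  ℓ_b = v/k_off, inert pool (J·ℓ_b/D)(1 − e^(−x/ℓ_b)) — a saturating total.
  The alternative reading (rebinding allowed in transit, only tip-arrived
  motors inert) yields an LBB-like active pair plus a linearly increasing
  inert pool; its three mode amplitudes are solved from the boundary
  conditions.

Two structural consequences worth knowing:

- **Soma boundary layer.** The subdominant e^(y⁻x) mode makes the exact
  exponential-family totals dip within ~1/|y⁻| (≈0.9 µm at default
  kinetics) of the absorbing soma before growing; "log-linear" and
  "non-decreasing" statements hold outside this layer, and the tests assert
  them there.
- **Bound fraction.** The stationary local bound fraction is
  D·y⁺/(D·y⁺ + v) = k_on/(k_on + k_off + v·y⁺) ≈ 0.582 at default kinetics
  — *below* the boundary-free two-state value k_on/(k_on + k_off) ≈ 0.645,
  because tip conversion adds an extra bound→free channel (total balance:
  k_on·N_f = k_off·N_b + v·c_b(L)). The PDE and the stochastic simulator
  both reproduce 0.582.

### Cycle times

- Diligent Worker: T = L/v + L²/(2D); the second term is the mean
  first-passage time of diffusion from a reflecting tip to an absorbing
  base. At L = 65 µm, T ≈ 601 s ≈ 10 min; at L = 10 µm the diffusive return
  (12.3 s) is comparable to the run itself (12.8 s), so diffusion does not
  limit recycling in short processes.
- Loose Bucket Brigade: T = 1/k_off + 1/k_on ≈ 2.31 s — one bound episode
  plus one diffusive episode, independent of L.
- The hybrids have no canonical single-motor cycle (a motor may never
  return, or may rebind mid-return); `cycle_time` raises for them.

The Monte-Carlo cycle estimator measures the Loose-Bucket-Brigade cycle as
one renewal of the detach/reattach clock, with plus-end *stalling*
semantics: a bound motor reaching x = L stops translocating but keeps its
k_off clock, so bound episodes are exactly exponential and the estimate is
length-independent, matching the closed form. Everywhere else (ensemble
stepping, density profiles, photoactivation) tip arrival converts the motor
instantaneously, matching the PDE; the stalled residence (~1/k_off ≈ 1.5 s)
is a tip boundary layer the continuum model idealizes away.

## Numerics

### PDE solver (`pde.py`)

Finite-volume, cell-centered, uniform grid. Bound advection uses first-order
upwind differencing — monotone, so densities stay non-negative; its O(dx)
accuracy is verified by a grid-refinement test (observed order ≥ 1).
Diffusion is central-difference; the absorbing soma is a Dirichlet-0 ghost
at the wall, the reflecting tip a zero-flux face. Tip conversion deposits
the advective flux leaving the last bound cell into the last cell of the
target pool (mass-conserving).

The semi-discrete system is assembled once as a sparse operator
dc/dt = M·c + s. Two time steppers (forward Euler; and forward Euler on
advection/reactions with backward-Euler diffusion, limited only by the
advective CFL) share that operator, and the default steady-state method
solves M·c = −s directly — the exact fixed point of either stepper. Direct
solve matters because tip-concentrated steady states hold motors for times
growing like e^(L/λ); marching to 1e-6/s relative change takes ~10⁵
simulated seconds for the Loose Bucket Brigade at L = 30 µm and far longer
for Hybrid 2. Marching remains available (and is tested for
initial-condition independence on a short process).

Default dx = 0.01 µm resolves every length scale in the problem (smallest:
1/|y⁻| ≈ 0.9 µm) and puts all four variants within 0.4% relative L2 of the
closed forms at L = 30 µm.

### Stochastic simulator (`montecarlo.py`)

Independent motors; Euler–Maruyama for the free pool (Gaussian increments of
SD √(2·D·dt), reflection by coordinate folding) and per-step exponential
switching probabilities 1 − e^(−k·dt). dt must keep switching probabilities
below 0.1; defaults (0.005–0.05 s depending on the assay) keep the
discretization bias of episode durations (≈ k·dt/2 relative) well below
Monte-Carlo error, which the cycle-time tests check against the closed
forms. Same seed + same configuration reproduces trajectories bit-exactly.

### FRAP model (`frap.py`)

The bleached strip (width w, post-bleach fraction b) recovering by pure
diffusion on an effectively infinite process has window-averaged
fluorescence F(t) = 1 − (1−b)·A(t) with

    A(t) = erf(α) − (1 − e^(−α²))/(α·√π),   α = w/(2√(D·t)),

the triangular self-correlation of the strip smoothed by the heat kernel
(variance 2Dt). The infinite-domain form is appropriate because bleaching is
done mid-neurite, far from the ends, and is validated against a
Crank–Nicolson finite-difference oracle to < 1e-3 over the fitting window; a
finite reflecting-domain cosine-series solution is provided for cases where
the strip is a sizeable fraction of the process (recovery then plateaus at
1 − (1−b)·w/L).

Fitting is nonlinear least squares over D (optionally also b), initialized
from the half-recovery heuristic D₀ = w²/(4·t_half), bounded to
(1e-4, 1e3) µm²/s, restricted to a chosen time window; the reported
goodness-of-fit is the mean absolute residual over that window. Because
directed transport contributes extra late recovery, long windows inflate D̂
— restricting to the first ~15 s suppresses that bias, and the generators
include a slow-transport contaminant a·(1 − e^(−t/τ)) to demonstrate the
ordering D̂(long) > D̂(short) > D*. The strip width is a required explicit
input (published descriptions of the same protocol quote different sizes),
and normalization follows the convention pre-bleach mean = 1.

### Profile analysis (`profiles.py`)

The motor channel of a two-channel line scan is volume × total motor
density; the volume channel is volume alone; their point-by-point ratio
cancels volume exactly. Points with volume signal below a floor are masked,
never interpolated. The fitted segment — the "increasing portion" — runs
from the profile's minimum (searched on a 5-point running mean within the
distal half by default; the search window is configurable because no
standard definition exists) to the tip, and must keep ≥ 8 points.

Both families are fitted: y = a + b·s (2 parameters) and y = a + A·e^(s/λ)
(3 parameters; log-space slope initialization, then full nonlinear
refinement). Selection is by corrected AIC; |ΔAICc| < 2 is flagged
ambiguous. λ's standard error comes from the fit covariance and propagates
to k_on = D/λ² + D·k_off/(v·λ) by the first-order delta method. At SNR 10
on 150-point profiles this pipeline classifies ≥ 95% of
exponential-vs-linear profiles correctly and recovers k_on with median
error < 10% across k_on ∈ [0.3, 2.4] s⁻¹.

## Synthetic data (`synth.py`)

Generators emulate the three experimental inputs: FRAP recovery curves
(90 s at 3 s frames by default, optional multiplicative acquisition
bleaching with a matched reference curve), two-channel line profiles (model
steady state modulated by a volume profile with a mild linear taper and a
growth-cone tip bulge), and photoactivation time courses (tip window
labelled once or every 4 min ×10, soma-window labelled count imaged every
minute for 40 min). Every generator returns complete ground-truth metadata
(model, parameters, noise, seed) and the I/O layer writes it as a JSON
sidecar.

Conventions chosen here (no measured values exist): additive Gaussian noise
on normalized intensities — σ = 0.02 for FRAP, per-channel σ = mean/SNR with
SNR 10 for profiles (a Poisson-scaled mode exists because real confocal
noise is intensity-dependent; negative noisy intensities are clipped at
zero); process length L = 30 µm, typical of differentiated CAD-cell
neurites; photoactivation window = distal 10% of the process and soma window
= proximal 20%.

What the generators do *not* emulate: imaging point-spread functions,
motor–motor exclusion or cargo jams, mixed microtubule polarity (dendrites),
branched geometry, and any retrograde motor activity. Passing the recovery
studies therefore demonstrates that the estimators are consistent and
correctly calibrated for data generated by the models' own assumptions —
not that those assumptions hold in any particular cell.

## Known limitations

- First-order upwind advection converges slowly (O(dx)); accuracy is bought
  with grid resolution, which the direct steady solver makes cheap.
- The caption-reading Hybrid 1 yields a total density that *decreases*
  toward saturation whenever D > v²/k_off (true at the default kinetics), so
  it does not reproduce a distal motor build-up; the reattaching reading
  does. Both are implemented; neither is asserted as canonical.
- The photoactivation assay is run in a closed process, so the tip window
  contains a large share of all motors and the single-vs-repeated contrast
  is milder than in a real cell whose soma holds most of the motor pool;
  the qualitative ordering (repeated > single > none = 0) is the robust
  output.
- The exponential-profile fit assumes a single decay length; profiles from
  mixed or spatially varying kinetics will classify as exponential with an
  effective λ rather than flag model misfit.
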