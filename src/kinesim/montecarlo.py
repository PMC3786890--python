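"""Stochastic single-motor simulation and the in silico photoactivation assay.

Motors are independent agents on ``0 <= x <= L``. A bound motor advances
deterministically at ``v`` and (variant permitting) detaches with per-step
probability ``1 - exp(-k_off·dt)``; a diffusing motor takes Euler–Maruyama
Brownian increments of SD ``sqrt(2·D·dt)``, reflects at the boundaries by
coordinate folding, and — if its pool may rebind — attaches with probability
``1 - exp(-k_on·dt)``. A bound motor crossing the tip is released into the
variant's tip pool (free or inert) with its ``post_tip`` flag set.

Soma handling: ``recycle`` mode absorbs diffusing motors at x <= 0 and
re-loads them onto cargo at the base (bound, x = 0), the agent-level
counterpart of the PDE's reservoir boundary; ``reflect`` mode folds them back
(fully closed process).

Photoactivation is a pure label: activated motors are flagged, never moved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import Geometry1D, ModelVariant, MotorParams

__all__ = [
    "BOUND",
    "FREE",
    "INERT",
    "MotorEnsemble",
    "ActivationProtocol",
    "init_ensemble",
    "step",
    "run",
    "empirical_profile",
    "ProfileHistogram",
    "mean_cycle_time_mc",
    "photoactivation_experiment",
    "sample_free_periods",
    "free_excursions",
]

BOUND, FREE, INERT = 0, 1, 2

_MAX_SWITCH_PROB = 0.1


def _check_dt(params: MotorParams, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k = max(params.k_on, params.k_off)
    if k > 0 and 1.0 - math.exp(-k * dt) >= _MAX_SWITCH_PROB:
        raise ValueError(
            f"dt={dt} too large: switching probability "
            f"{1.0 - math.exp(-k * dt):.3f} >= {_MAX_SWITCH_PROB} for rate {k} s⁻¹"
        )


@dataclass
class MotorEnsemble:
    """State of an independent-motor ensemble at one instant."""

    x: np.ndarray
    state: np.ndarray  # BOUND / FREE / INERT per motor
    post_tip: np.ndarray  # has been released at the tip at least once
    activated: np.ndarray  # photoactivation label
    seed: int
    rng: np.random.Generator = field(repr=False, default=None)
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    @property
    def n(self) -> int:
        return len(self.x)


def init_ensemble(
    n: int,
    geom: Geometry1D,
    seed: int,
    *,
    start: str = "uniform_bound",
) -> MotorEnsemble:
    """Fresh ensemble: positions uniform on [0, L], all in one state."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, geom.L, size=n)
    state_map = {"uniform_bound": BOUND, "uniform_free": FREE}
    try:
        s0 = state_map[start]
    except KeyError:
        raise ValueError(f"unknown start {start!r}") from None
    return MotorEnsemble(
        x=x,
        state=np.full(n, s0, dtype=np.int8),
        post_tip=np.zeros(n, dtype=bool),
        activated=np.zeros(n, dtype=bool),
        seed=seed,
        rng=rng,
    )


def _reflect_top(x: np.ndarray, L: float) -> None:
    over = x > L
    while np.any(over):
        x[over] = 2.0 * L - x[over]
        over = x > L
        under = x < 0.0
        x[under] = -x[under]
        over |= x > L


def step(
    ens: MotorEnsemble,
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    dt: float,
    *,
    soma_mode: str = "recycle",
) -> MotorEnsemble:
    """Advance the ensemble by one time step ``dt`` (in place)."""
    _check_dt(params, dt)
    if soma_mode not in ("recycle", "reflect"):
        raise ValueError(f"unknown soma_mode {soma_mode!r}")
    L = geom.L
    rng = ens.rng
    x, state = ens.x, ens.state

    # bound motors: advect, release at the tip, stochastic detachment
    bound = state == BOUND
    x[bound] += params.v * dt

    at_tip = bound & (x >= L)
    if np.any(at_tip):
        x[at_tip] = L
        state[at_tip] = FREE if variant.tip_target == "free" else INERT
        ens.post_tip[at_tip] = True

    still_bound = bound & ~at_tip
    if variant.detach_in_transit and params.k_off > 0 and np.any(still_bound):
        p_off = 1.0 - math.exp(-params.k_off * dt)
        detach = still_bound & (rng.random(ens.n) < p_off)
        state[detach] = FREE if variant.detach_target == "free" else INERT

    # diffusing motors: Brownian increment + boundary handling
    diffusing = state != BOUND
    n_diff = int(np.count_nonzero(diffusing))
    if n_diff and params.D > 0:
        x[diffusing] += rng.normal(0.0, math.sqrt(2.0 * params.D * dt), size=n_diff)
        hit_soma = diffusing & (x <= 0.0)
        if soma_mode == "recycle":
            if np.any(hit_soma):
                x[hit_soma] = 0.0
                state[hit_soma] = BOUND  # re-loaded onto cargo at the base
                ens.post_tip[hit_soma] = False
        else:
            x[hit_soma] = -x[hit_soma]
        _reflect_top(x, L)

    # attachment: only the free (rebinding-capable) pool
    free = state == FREE
    if params.k_on > 0 and np.any(free):
        p_on = 1.0 - math.exp(-params.k_on * dt)
        attach = free & (rng.random(ens.n) < p_on)
        state[attach] = BOUND

    ens.t += dt
    return ens


def run(
    ens: MotorEnsemble,
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    t: float,
    dt: float,
    *,
    soma_mode: str = "recycle",
) -> MotorEnsemble:
    """Advance the ensemble by simulated time ``t``."""
    for _ in range(math.ceil(t / dt)):
        step(ens, variant, params, geom, dt, soma_mode=soma_mode)
    return ens


@dataclass
class ProfileHistogram:
    """Binned motor counts along the process with multinomial uncertainty."""

    counts: np.ndarray
    edges: np.ndarray
    se: np.ndarray
    low_count: np.ndarray  # bins with < 5 motors: treat CIs as unreliable

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def empirical_profile(
    positions: np.ndarray,
    geom: Geometry1D,
    n_bins: int,
    *,
    state: Optional[np.ndarray] = None,
    keep: Optional[int] = None,
) -> ProfileHistogram:
    """Histogram of motor positions (optionally one state only)."""
    pos = np.asarray(positions, dtype=float)
    if state is not None and keep is not None:
        pos = pos[np.asarray(state) == keep]
    counts, edges = np.histogram(pos, bins=n_bins, range=(0.0, geom.L))
    n = counts.sum()
    p = counts / n if n else counts.astype(float)
    se = np.sqrt(n * p * (1.0 - p)) if n else np.zeros_like(p)
    return ProfileHistogram(counts, edges, se, counts < 5)


# ---------------------------------------------------------------------------
# cycle times
# ---------------------------------------------------------------------------

def mean_cycle_time_mc(
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    n_cycles: int,
    seed: int,
    *,
    dt: float = 0.01,
    max_steps: int = 10_000_000,
) -> tuple[float, float]:
    """Monte-Carlo mean transport-and-recycle cycle time with its SE.

    Diligent Worker: one full trip — ballistic run from the base to the tip,
    then reflected Brownian return to the absorbing soma.

    Loose Bucket Brigade: one renewal of the detach/reattach clock — a bound
    episode followed by a diffusive episode. A bound motor reaching the plus
    end stalls there (stops translocating) but keeps its k_off detachment
    clock, so bound episodes are exponential wherever the motor is and the
    cycle time is length-independent.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    L = geom.L

    if variant.name == "diligent_worker":
        if params.v <= 0 or params.D <= 0:
            raise ValueError("need v > 0 and D > 0")
        t_run = L / params.v
        times = np.full(n_cycles, float(t_run))
        x = np.full(n_cycles, float(L))
        alive = np.ones(n_cycles, dtype=bool)
        sigma = math.sqrt(2.0 * params.D * dt)
        steps = 0
        while np.any(alive):
            idx = np.flatnonzero(alive)
            x[idx] += rng.normal(0.0, sigma, size=len(idx))
            over = idx[x[idx] > L]
            x[over] = 2.0 * L - x[over]
            times[idx] += dt
            done = idx[x[idx] <= 0.0]
            alive[done] = False
            steps += 1
            if steps > max_steps:
                raise RuntimeError("cycle simulation exceeded step budget")
        return float(times.mean()), float(times.std(ddof=1) / math.sqrt(n_cycles))

    if variant.name != "loose_bucket_brigade":
        raise ValueError(f"Monte-Carlo cycle time defined for diligent_worker "
                         f"and loose_bucket_brigade, not {variant.name!r}")

    if params.k_on <= 0 or params.k_off <= 0:
        raise ValueError("need k_on > 0 and k_off > 0")
    _check_dt(params, dt)
    p_off = 1.0 - math.exp(-params.k_off * dt)
    p_on = 1.0 - math.exp(-params.k_on * dt)
    x = rng.uniform(0.0, L, size=n_cycles)
    bound = np.ones(n_cycles, dtype=bool)
    done = np.zeros(n_cycles, dtype=bool)
    times = np.zeros(n_cycles)
    sigma = math.sqrt(2.0 * params.D * dt)
    steps = 0
    while not np.all(done):
        active = ~done
        was_bound = bound.copy()
        # bound phase: advance (stalling at the plus end), detach at k_off
        b = active & was_bound
        if np.any(b):
            x[b] = np.minimum(x[b] + params.v * dt, L)
            detach = b & (rng.random(n_cycles) < p_off)
            bound[detach] = False
        # free phase: diffuse (reflect both ends), reattach at k_on
        f = active & ~was_bound
        if np.any(f):
            idx = np.flatnonzero(f)
            x[idx] += rng.normal(0.0, sigma, size=len(idx))
            x[idx] = np.abs(x[idx])
            over = idx[x[idx] > L]
            x[over] = 2.0 * L - x[over]
            attach = f & (rng.random(n_cycles) < p_on)
            done[attach] = True
        times[active] += dt
        steps += 1
        if steps > max_steps:
            raise RuntimeError("cycle simulation exceeded step budget")
    return float(times.mean()), float(times.std(ddof=1) / math.sqrt(n_cycles))


# ---------------------------------------------------------------------------
# photoactivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationProtocol:
    """Photoactivation / imaging schedule.

    ``activation_window`` and ``soma_window`` are (lo, hi) intervals in µm;
    ``None`` defaults to the distal 10% and proximal 20% of the process —
    conventions of this package, documented in the methods note, since the
    source experiments do not state window sizes.
    """

    mode: str  # {"none", "single", "repeated"}
    n_activations: int = 10
    activation_interval: float = 240.0  # s between repeated activations
    imaging_interval: float = 60.0  # s between soma-signal samples
    total_time: float = 2400.0  # s of imaging after the first activation
    activation_window: Optional[tuple[float, float]] = None
    soma_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "single", "repeated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "repeated" and self.n_activations < 2:
            raise ValueError("repeated mode needs >= 2 activations")
        for f in ("activation_interval", "imaging_interval", "total_time"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")

    def resolve_windows(self, geom: Geometry1D) -> tuple[tuple[float, float], tuple[float, float]]:
        act = self.activation_window or (0.9 * geom.L, geom.L)
        soma = self.soma_window or (0.0, 0.2 * geom.L)
        for name, (lo, hi) in (("activation_window", act), ("soma_window", soma)):
            if not (0.0 <= lo < hi <= geom.L):
                raise ValueError(f"{name} {lo, hi} is empty or outside [0, {geom.L}]")
        return act, soma

    def activation_times(self) -> np.ndarray:
        if self.mode == "none":
            return np.array([])
        if self.mode == "single":
            return np.array([0.0])
        times = np.arange(self.n_activations) * self.activation_interval
        return times[times < self.total_time]


def photoactivation_experiment(
    protocol: ActivationProtocol,
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    n_motors: int,
    seed: int,
    *,
    dt: float = 0.02,
    burn_in: float = 400.0,
    soma_mode: str = "reflect",
) -> pd.DataFrame:
    """Label motors in a tip window and watch the labelled count at the soma.

    The ensemble is pre-equilibrated for ``burn_in`` s before t = 0. Returns a
    DataFrame with columns ``t_s`` (imaging times) and ``soma_count``
    (activated motors inside the soma window).
    """
    act_win, soma_win = protocol.resolve_windows(geom)
    ens = init_ensemble(n_motors, geom, seed)
    run(ens, variant, params, geom, burn_in, dt, soma_mode=soma_mode)
    ens.t = 0.0

    act_times = list(protocol.activation_times())
    image_times = np.arange(0.0, protocol.total_time + 0.5 * protocol.imaging_interval,
                            protocol.imaging_interval)
    records = []
    next_act = 0

    def maybe_activate():
        nonlocal next_act
        while next_act < len(act_times) and ens.t >= act_times[next_act] - 0.5 * dt:
            in_win = (ens.x >= act_win[0]) & (ens.x <= act_win[1])
            ens.activated |= in_win
            next_act += 1

    def soma_count() -> int:
        in_soma = (ens.x >= soma_win[0]) & (ens.x <= soma_win[1])
        return int(np.count_nonzero(ens.activated & in_soma))

    maybe_activate()
    records.append((0.0, soma_count()))
    for t_img in image_times[1:]:
        while ens.t < t_img - 0.5 * dt:
            maybe_activate()
            step(ens, variant, params, geom, dt, soma_mode=soma_mode)
        records.append((float(t_img), soma_count()))
    return pd.DataFrame(records, columns=["t_s", "soma_count"])


# ---------------------------------------------------------------------------
# diagnostics used by the model-validation studies
# ---------------------------------------------------------------------------

def sample_free_periods(
    params: MotorParams,
    geom: Geometry1D,
    n: int,
    seed: int,
    *,
    dt: float = 0.01,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Durations of n diffusive periods (detachment to reattachment).

    Positions diffuse and reflect at both ends; the attachment clock runs at
    k_on everywhere, so the durations should be Exp(k_on).
    """
    _check_dt(params, dt)
    if params.k_on <= 0:
        raise ValueError("k_on must be > 0")
    rng = np.random.default_rng(seed)
    p_on = 1.0 - math.exp(-params.k_on * dt)
    x = rng.uniform(0.0, geom.L, size=n)
    times = np.zeros(n)
    active = np.ones(n, dtype=bool)
    sigma = math.sqrt(2.0 * params.D * dt)
    steps = 0
    while np.any(active):
        idx = np.flatnonzero(active)
        x[idx] += rng.normal(0.0, sigma, size=len(idx))
        x[idx] = np.abs(x[idx])
        over = idx[x[idx] > geom.L]
        x[over] = 2.0 * geom.L - x[over]
        times[idx] += dt
        attach = active & (rng.random(n) < p_on)
        active &= ~attach
        steps += 1
        if steps > max_steps:
            raise RuntimeError("free-period sampling exceeded step budget")
    return times


def free_excursions(
    params: MotorParams,
    geom: Geometry1D,
    x0: float,
    n: int,
    seed: int,
    *,
    dt: float = 0.01,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Whether each of n free excursions from ``x0`` reaches the soma.

    An excursion starts at ``x0``, diffuses (reflecting tip), and ends either
    by reattachment (rate k_on) or by hitting x = 0. Returns a boolean array:
    True where the soma was reached first.
    """
    _check_dt(params, dt)
    rng = np.random.default_rng(seed)
    p_on = 1.0 - math.exp(-params.k_on * dt)
    x = np.full(n, float(x0))
    reached = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    sigma = math.sqrt(2.0 * params.D * dt)
    steps = 0
    while np.any(active):
        idx = np.flatnonzero(active)
        x[idx] += rng.normal(0.0, sigma, size=len(idx))
        over = idx[x[idx] > geom.L]
        x[over] = 2.0 * geom.L - x[over]
        hit = active & (x <= 0.0)
        reached[hit] = True
        active &= ~hit
        attach = active & (rng.random(n) < p_on)
        active &= ~attach
        steps += 1
        if steps > max_steps:
            raise RuntimeError("excursion sampling exceeded step budget")
    return reached
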