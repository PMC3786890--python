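"""Closed-form steady states, decay lengths and cycle times.

The transport models share one two-field description on ``0 <= x <= L``:
cargo-bound motors advect tipward at speed ``v`` and free (autoinhibited)
motors diffuse with coefficient ``D``; local exchange happens at rates
``k_off`` (bound -> diffusing) and ``k_on`` (diffusing -> bound) according to
the variant's policy flags. Boundary conditions: the soma (x = 0) is a
reservoir — absorbing for diffusing motors, re-injecting bound motors at flux
``J`` — and the tip (x = L) reflects diffusing motors while converting the
arriving bound flux ``v·c_b(L)`` into the diffusing pool.

At steady state the net axial flux ``v·c_b - D·∂c_f/∂x`` is constant, and
zero for the closed recycling system. For the Loose Bucket Brigade the
zero-flux exponential modes ``exp(y·x)`` obey the dispersion relation

    D·v·y² + D·k_off·y - k_on·v = 0,

whose unique positive root gives the tipward decay length λ = 1/y of the
exponentially increasing total motor density. Inverting it for ``k_on`` given
a measured λ,

    k_on = D/λ² + D·k_off/(v·λ),

is how the microtubule binding rate is extracted from a fitted profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .params import Geometry1D, ModelVariant, MotorParams, LOOSE_BUCKET_BRIGADE

__all__ = [
    "SteadyState",
    "dispersion_roots",
    "decay_length",
    "infer_binding_rate",
    "steady_state",
    "cycle_time",
]


def dispersion_roots(params: MotorParams) -> tuple[float, float]:
    """Roots (y_plus > 0 > y_minus) of D·v·y² + D·k_off·y − k_on·v = 0.

    Requires v, D, k_on > 0 (k_off may be zero).
    """
    v, D, k_on, k_off = params.v, params.D, params.k_on, params.k_off
    if v <= 0 or D <= 0:
        raise ValueError("dispersion relation requires v > 0 and D > 0")
    if k_on <= 0:
        raise ValueError("k_on must be > 0 for exponential accumulation")
    a, b, c = D * v, D * k_off, -k_on * v
    disc = math.sqrt(b * b - 4.0 * a * c)
    y_plus = (-b + disc) / (2.0 * a)
    y_minus = (-b - disc) / (2.0 * a)
    return y_plus, y_minus


def decay_length(params: MotorParams, variant: ModelVariant = LOOSE_BUCKET_BRIGADE) -> float:
    """Steady-state exponential decay length λ (µm) of the total density.

    Loose Bucket Brigade: λ = 1/y with y the positive dispersion root.
    Hybrid 2: λ = sqrt(D/k_on) (free motors are consumed by reattachment on
    that length scale while returning from the tip).

    ``k_on = 0`` means no exponential accumulation; returns ``math.inf``.
    """
    if params.v <= 0 or params.D <= 0:
        raise ValueError("decay_length requires v > 0 and D > 0")
    if params.k_on == 0:
        return math.inf
    if variant.name == "hybrid2":
        return math.sqrt(params.D / params.k_on)
    if variant.name in ("diligent_worker", "hybrid1"):
        raise ValueError(f"{variant.name} has no exponential decay length")
    y_plus, _ = dispersion_roots(params)
    return 1.0 / y_plus


def infer_binding_rate(lam: float, *, v: float, D: float, k_off: float) -> float:
    """Microtubule binding rate k_on (s⁻¹) from a measured decay length λ.

    Exact inverse of :func:`decay_length` for the Loose Bucket Brigade:
    k_on = D/λ² + D·k_off/(v·λ).
    """
    if not (lam > 0):
        raise ValueError(f"decay length must be > 0, got {lam!r}")
    if v <= 0 or D <= 0 or k_off < 0:
        raise ValueError("require v > 0, D > 0, k_off >= 0")
    if math.isinf(lam):
        return 0.0
    return D / lam**2 + D * k_off / (v * lam)


@dataclass
class SteadyState:
    """Closed-form steady state of one model variant.

    ``c_bound``/``c_free``/``c_inert`` are vectorized callables of position
    (µm) returning linear densities (motors/µm, scale set by the loading flux
    ``J``); ``c_tot`` is their sum. ``bound_fraction`` is the mass-weighted
    fraction of motors in the bound state over [0, L].
    """

    profile_family: str  # {"exponential", "linear", "flat"}
    decay_length: Optional[float]
    bound_fraction: float
    J: float
    geom: Geometry1D
    c_bound: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    c_free: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    c_inert: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def c_tot(self, x):
        x = np.asarray(x, dtype=float)
        return self.c_bound(x) + self.c_free(x) + self.c_inert(x)


def _const(value: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda x: np.full_like(np.asarray(x, dtype=float), value)


_ZERO = _const(0.0)


def _mass_fraction(ss_cb, ss_tot, L: float) -> float:
    x = np.linspace(0.0, L, 2001)
    tot = np.trapezoid(ss_tot(x), x)
    if tot <= 0:
        return 0.0
    return float(np.trapezoid(ss_cb(x), x) / tot)


def steady_state(
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    J: float = 1.0,
) -> SteadyState:
    """Closed-form steady state for a variant under soma-reservoir loading.

    Degenerate inputs (v = 0 or J = 0) give a flat profile: with no loading
    or no transport the closed system relaxes to a uniform diffusing pool
    (unit total mass by convention).
    """
    if J < 0:
        raise ValueError("loading flux J must be >= 0")
    v, D, k_on, k_off = params.v, params.D, params.k_on, params.k_off
    L = geom.L

    if J == 0 or v == 0:
        uniform = _const(1.0 / L)
        return SteadyState("flat", None, 0.0, J, geom, _ZERO, uniform, _ZERO)
    if D <= 0:
        raise ValueError("steady state with transport requires D > 0")

    name = variant.name
    eff_k_off = k_off if variant.detach_in_transit else 0.0
    rebinds = variant.reattach_after_tip or (
        variant.detach_in_transit and variant.reattach_in_transit
    )

    # --- non-rebinding family: Diligent Worker / caption-reading Hybrid 1 ---
    if not rebinds:
        if eff_k_off == 0.0:  # Diligent Worker
            cb = _const(J / v)
            ci = lambda x: (J / D) * np.asarray(x, dtype=float)
        else:  # detach in transit, never rebind
            ell = v / eff_k_off
            cb = lambda x: (J / v) * np.exp(-np.asarray(x, dtype=float) / ell)
            ci = lambda x: (J * ell / D) * (1.0 - np.exp(-np.asarray(x, dtype=float) / ell))
        ss = SteadyState("linear", None, 0.0, J, geom, cb, _ZERO, ci)
        ss.bound_fraction = _mass_fraction(ss.c_bound, ss.c_tot, L)
        return ss

    # --- Hybrid 2: no detachment in transit, rebinding on the way back ---
    if not variant.detach_in_transit:
        if k_on == 0.0:  # reduces to the Diligent Worker
            cb = _const(J / v)
            cf = lambda x: (J / D) * np.asarray(x, dtype=float)
            ss = SteadyState("linear", None, 0.0, J, geom, cb, cf, _ZERO)
        else:
            ell = math.sqrt(D / k_on)
            cb = lambda x: (J / v) * np.cosh(np.asarray(x, dtype=float) / ell)
            cf = lambda x: (J * ell / D) * np.sinh(np.asarray(x, dtype=float) / ell)
            ss = SteadyState("exponential", ell, 0.0, J, geom, cb, cf, _ZERO)
        ss.bound_fraction = _mass_fraction(ss.c_bound, ss.c_tot, L)
        return ss

    # --- detachment + rebinding in transit: LBB or main-text Hybrid 1 ---
    if k_on == 0.0:
        # free motors never rebind: same closed form as the non-rebinding family
        ell = v / k_off if k_off > 0 else math.inf
        if math.isinf(ell):
            cb = _const(J / v)
            cf = lambda x: (J / D) * np.asarray(x, dtype=float)
        else:
            cb = lambda x: (J / v) * np.exp(-np.asarray(x, dtype=float) / ell)
            cf = lambda x: (J * ell / D) * (1.0 - np.exp(-np.asarray(x, dtype=float) / ell))
        ss = SteadyState("linear", None, 0.0, J, geom, cb, cf, _ZERO)
        ss.bound_fraction = _mass_fraction(ss.c_bound, ss.c_tot, L)
        return ss

    y_p, y_m = dispersion_roots(params)

    if variant.reattach_after_tip:
        # Loose Bucket Brigade: zero-flux mode pair with c_free(0) = 0,
        # v·c_bound(0) = J.
        A = J / (D * (y_p - y_m))
        cf = lambda x: A * (
            np.exp(y_p * np.asarray(x, dtype=float)) - np.exp(y_m * np.asarray(x, dtype=float))
        )
        cb = lambda x: (D / v) * A * (
            y_p * np.exp(y_p * np.asarray(x, dtype=float))
            - y_m * np.exp(y_m * np.asarray(x, dtype=float))
        )
        ss = SteadyState("exponential", 1.0 / y_p, 0.0, J, geom, cb, cf, _ZERO)
        ss.bound_fraction = _mass_fraction(ss.c_bound, ss.c_tot, L)
        return ss

    # Main-text Hybrid 1: active pair behaves like the LBB but tip arrivals
    # leave the active system (inert pool, linear retrograde profile).
    # c_free = (k_off/k_on)·G + A e^{y+x} + B e^{y−x}
    # c_bound = G + (D/v)(A y+ e^{y+x} + B y− e^{y−x})
    # BCs: c_free(0)=0, c_bound(0)=J/v, c_free'(L)=0.
    M = np.array(
        [
            [k_off / k_on, 1.0, 1.0],
            [1.0, (D / v) * y_p, (D / v) * y_m],
            [0.0, y_p * math.exp(y_p * L), y_m * math.exp(y_m * L)],
        ]
    )
    rhs = np.array([0.0, J / v, 0.0])
    G, A, B = np.linalg.solve(M, rhs)

    def cf(x):
        x = np.asarray(x, dtype=float)
        return (k_off / k_on) * G + A * np.exp(y_p * x) + B * np.exp(y_m * x)

    def cb(x):
        x = np.asarray(x, dtype=float)
        return G + (D / v) * (A * y_p * np.exp(y_p * x) + B * y_m * np.exp(y_m * x))

    R = v * float(cb(np.array(L)))  # inert creation rate at the tip
    ci = lambda x: (R / D) * np.asarray(x, dtype=float)
    ss = SteadyState("linear", None, 0.0, J, geom, cb, cf, ci)
    ss.bound_fraction = _mass_fraction(ss.c_bound, ss.c_tot, L)
    return ss


def cycle_time(variant: ModelVariant, params: MotorParams, geom: Geometry1D) -> float:
    """Mean duration of one transport-and-recycle cycle, s.

    Diligent Worker: the full out-and-back trip — ballistic run L/v plus the
    mean first-passage time L²/(2D) of diffusion from the (reflecting) tip to
    the (absorbing) soma. Grows quadratically with process length.

    Loose Bucket Brigade: one bound episode plus one diffusive episode,
    1/k_off + 1/k_on — independent of process length, which is why diffusion
    never limits recycling in this mode.
    """
    L = geom.L
    if variant.name == "diligent_worker":
        if params.v <= 0 or params.D <= 0:
            raise ValueError("Diligent Worker cycle time requires v > 0 and D > 0")
        return L / params.v + L * L / (2.0 * params.D)
    if variant.name == "loose_bucket_brigade":
        if params.k_off <= 0 or params.k_on <= 0:
            raise ValueError("Loose Bucket Brigade cycle time requires k_on, k_off > 0")
        return 1.0 / params.k_off + 1.0 / params.k_on
    raise ValueError(f"cycle time is defined for diligent_worker and loose_bucket_brigade, not {variant.name!r}")
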