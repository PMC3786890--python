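"""Finite-volume solver for the two-field reaction–advection–diffusion system.

Bound motors advect tipward (first-order upwind, monotone); diffusing pools
(free = can rebind, inert = cannot) use central-difference diffusion. The tip
converts the outgoing bound flux into the diffusing pool of the variant's
choice (mass-conserving discrete source in the last cell); the soma is either
a reservoir (diffusing pools absorbed through a Dirichlet-0 wall, bound
motors injected at flux ``J``) or fully reflecting.

The semi-discrete system is assembled once as a sparse operator
``dc/dt = M·c + s`` on the stacked state ``c = (c_bound, c_free, c_inert)``.
Time stepping is forward Euler on the whole operator (``explicit``) or
forward Euler on advection/reactions with backward Euler diffusion
(``semi_implicit``; the advective CFL alone then limits the step, and the
split scheme's fixed point is exactly ``M·c + s = 0``). Steady states are
obtained either by direct sparse solve of ``M·c = -s`` (fast, and identical
to the time-stepper's fixed point) or by marching until the field stops
changing: tip-concentrated steady states hold motors for times that grow
exponentially with L/λ, so direct solve is the default.

This solver is the numerical oracle for the closed forms in
:mod:`kinesim.steady` and the backend for synthetic steady-state profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import Geometry1D, ModelVariant, MotorParams

__all__ = [
    "ConcentrationField",
    "SolverConfig",
    "uniform_field",
    "evolve",
    "steady_state_numeric",
]


@dataclass
class ConcentrationField:
    """Bound/free/inert motor densities on a uniform cell-centered grid."""

    x: np.ndarray  # cell centers, µm
    c_bound: np.ndarray  # motors/µm
    c_free: np.ndarray
    c_inert: np.ndarray
    t: float = 0.0
    injected: float = 0.0  # cumulative motors injected at the soma
    absorbed: float = 0.0  # cumulative motors absorbed at the soma

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("c_bound", "c_free", "c_inert"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have the same length as x")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
            setattr(self, name, arr)
        if n >= 2:
            dxs = np.diff(self.x)
            if not np.allclose(dxs, dxs[0]):
                raise ValueError("grid must be uniform")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def c_tot(self) -> np.ndarray:
        return self.c_bound + self.c_free + self.c_inert

    def total_mass(self) -> float:
        return float(self.c_tot.sum() * self.dx)

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(
            self.x.copy(), self.c_bound.copy(), self.c_free.copy(), self.c_inert.copy(),
            self.t, self.injected, self.absorbed,
        )


@dataclass(frozen=True)
class SolverConfig:
    """Grid and time-step configuration.

    ``dt=None`` picks 0.9× the stability limit of the chosen scheme.
    ``steady_tolerance`` is the maximum relative field change per simulated
    second below which a marched solution counts as stationary.
    """

    dx: float = 0.01
    dt: Optional[float] = None
    scheme: str = "semi_implicit"  # or "explicit"
    steady_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.scheme not in ("explicit", "semi_implicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def resolve_dt(self, params: MotorParams) -> float:
        """Stable step: advective CFL always; diffusive limit if explicit."""
        limits = [math.inf]
        if params.v > 0:
            limits.append(self.dx / params.v)
        if self.scheme == "explicit" and params.D > 0:
            limits.append(self.dx * self.dx / (2.0 * params.D))
        rates = params.k_on + params.k_off
        if rates > 0:
            limits.append(0.5 / rates)
        stable = 0.9 * min(limits)
        if self.dt is None:
            if not math.isfinite(stable):
                raise ValueError("cannot pick dt automatically: no transport or kinetics")
            return stable
        if self.dt > stable:
            raise ValueError(
                f"dt={self.dt} violates the stability limit {stable:.3g} s "
                f"for scheme={self.scheme!r}, dx={self.dx}"
            )
        return self.dt


def uniform_field(
    geom: Geometry1D, config: SolverConfig, *, bound=0.0, free=0.0, inert=0.0
) -> ConcentrationField:
    """A spatially uniform field on the grid implied by ``geom`` and ``config``."""
    n = max(2, int(round(geom.L / config.dx)))
    dx = geom.L / n
    x = (np.arange(n) + 0.5) * dx
    return ConcentrationField(
        x, np.full(n, float(bound)), np.full(n, float(free)), np.full(n, float(inert))
    )


class _System:
    """Sparse semi-discrete operator dc/dt = M c + s for one configuration."""

    def __init__(self, n, dx, variant, params, soma_mode, J):
        if soma_mode not in ("reservoir", "reflecting"):
            raise ValueError(f"unknown soma_mode {soma_mode!r}")
        if J < 0:
            raise ValueError("J must be >= 0")
        self.n, self.dx = n, dx
        self.variant, self.params = variant, params
        self.soma_mode, self.J = soma_mode, J
        v, D = params.v, params.D
        k_on = params.k_on
        k_off = params.k_off if variant.detach_in_transit else 0.0
        absorbing = soma_mode == "reservoir"

        # advection of the bound pool, upwind: d cb_i/dt = -v(cb_i - cb_{i-1})/dx
        adv = sp.diags([np.full(n, -v / dx), np.full(n - 1, v / dx)], [0, -1], format="lil")

        # diffusion with reflecting tip; soma reflecting or Dirichlet-0 wall
        lap = sp.diags(
            [np.full(n, -2.0), np.full(n - 1, 1.0), np.full(n - 1, 1.0)], [0, 1, -1], format="lil"
        )
        lap[n - 1, n - 1] = -1.0
        lap[0, 0] = -3.0 if absorbing else -1.0
        diff = (D / dx**2) * lap.tocsr()

        zero = sp.csr_matrix((n, n))
        Ab = adv.tocsr()

        # tip conversion: bound flux v·cb[-1] deposited in the last cell of the
        # target pool
        tip = sp.lil_matrix((n, n))
        tip[n - 1, n - 1] = v / dx
        tip = tip.tocsr()
        tip_free = tip if variant.tip_target == "free" else zero
        tip_inert = tip if variant.tip_target == "inert" else zero

        # local exchange
        I = sp.identity(n, format="csr")
        det_free = k_off * I if variant.detach_target == "free" else zero
        det_inert = k_off * I if variant.detach_target == "inert" else zero

        M_adv = sp.bmat(
            [
                [Ab - k_off * I, k_on * I, zero],
                [det_free + tip_free, -k_on * I, zero],
                [det_inert + tip_inert, zero, zero],
            ],
            format="csr",
        )
        M_diff = sp.bmat([[zero, zero, zero], [zero, diff, zero], [zero, zero, diff]], format="csr")
        self.M_adv, self.M_diff = M_adv, M_diff
        self.M = (M_adv + M_diff).tocsc()

        self.s = np.zeros(3 * n)
        if absorbing and J > 0:
            self.s[0] = J / dx  # bound injection at the base

        # absorbed soma flux functional (per unit time): 2D/dx ·(cf[0] + ci[0])
        self.absorb_vec = np.zeros(3 * n)
        if absorbing:
            self.absorb_vec[n] = 2.0 * D / dx
            self.absorb_vec[2 * n] = 2.0 * D / dx

        self._diff_solver = None

    def diffusion_solver(self, dt):
        if self._diff_solver is None:
            A = (sp.identity(3 * self.n, format="csc") - dt * self.M_diff.tocsc())
            self._diff_solver = spla.factorized(A)
        return self._diff_solver


def _pack(f: ConcentrationField) -> np.ndarray:
    return np.concatenate([f.c_bound, f.c_free, f.c_inert])


def _unpack(f: ConcentrationField, c: np.ndarray) -> None:
    n = len(f.x)
    f.c_bound, f.c_free, f.c_inert = c[:n].copy(), c[n : 2 * n].copy(), c[2 * n :].copy()


def evolve(
    field: ConcentrationField,
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    config: SolverConfig,
    t_end: float,
    *,
    soma_mode: str = "reservoir",
    J: float = 0.0,
    recycle: bool = False,
) -> ConcentrationField:
    """Advance the field to (at least) ``t_end``; returns a new field.

    ``recycle=True`` re-injects the soma-absorbed diffusive flux as bound
    flux at x = 0, keeping the total motor number constant (a cell with
    fixed kinesin content); otherwise ``J`` is a fixed loading flux.
    """
    out = field.copy()
    n, dx = len(out.x), out.dx
    sys_ = _System(n, dx, variant, params, soma_mode, J)
    dt = config.resolve_dt(params)
    n_steps = max(0, math.ceil((t_end - out.t) / dt))
    c = _pack(out)
    explicit = config.scheme == "explicit"
    solver = None if explicit else sys_.diffusion_solver(dt)
    inj_cell = np.zeros_like(c)
    inj_cell[0] = 1.0 / dx
    recycle_flux = 0.0
    for _ in range(n_steps):
        s = sys_.s.copy()
        if recycle:
            s = recycle_flux * inj_cell
        if explicit:
            c_new = c + dt * (sys_.M @ c + s)
        else:
            c_star = c + dt * (sys_.M_adv @ c + s)
            c_new = solver(c_star)
        absorbed_rate = float(sys_.absorb_vec @ c_new)
        out.absorbed += absorbed_rate * dt
        out.injected += float(s.sum() * dx) * dt
        recycle_flux = absorbed_rate
        c = c_new
        out.t += dt
    _unpack(out, c)
    return out


def steady_state_numeric(
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    config: SolverConfig,
    *,
    J: float = 1.0,
    soma_mode: str = "reservoir",
    method: str = "direct",
    init: Optional[ConcentrationField] = None,
    mass: Optional[float] = None,
    max_time: float = 2e4,
    check_interval: float = 5.0,
) -> ConcentrationField:
    """Stationary field for one variant.

    ``method="direct"`` solves the discrete steady system ``M·c = -s`` (the
    exact fixed point of the time stepper) — use this by default; the
    residence time of tip-concentrated profiles makes marching prohibitively
    slow. ``method="march"`` advances from ``init`` (or an empty field) until
    the maximum relative change per simulated second drops below
    ``config.steady_tolerance``, raising ``RuntimeError`` with diagnostics on
    non-convergence.

    ``mass`` rescales the result to a prescribed total motor number (the
    steady-state *shape* under reservoir recycling is that of any fixed
    J > 0, so this covers the closed recycling system).
    """
    n = max(2, int(round(geom.L / config.dx)))
    dx = geom.L / n
    x = (np.arange(n) + 0.5) * dx

    if method == "direct":
        if J <= 0:
            raise ValueError("direct steady solve needs J > 0")
        sys_ = _System(n, dx, variant, params, soma_mode, J)
        if soma_mode == "reflecting":
            raise ValueError("reflecting soma has no unique loaded steady state; use method='march'")
        c = spla.spsolve(sys_.M, -sys_.s)
        c = np.maximum(c, 0.0)
        f = ConcentrationField(x, c[:n], c[n : 2 * n], c[2 * n :])
        f.t = math.inf
    elif method == "march":
        f = init.copy() if init is not None else ConcentrationField(
            x, np.zeros(n), np.zeros(n), np.zeros(n)
        )
        if J == 0 and f.total_mass() == 0:
            raise ValueError("need J > 0 or a nonzero initial field")
        t_start = f.t
        prev = f.c_tot.copy()
        prev_t = f.t
        rate = math.inf
        while f.t - t_start < max_time:
            f = evolve(f, variant, params, geom, config, f.t + check_interval,
                       soma_mode=soma_mode, J=J)
            scale = max(float(np.max(f.c_tot)), 1e-300)
            rate = float(np.max(np.abs(f.c_tot - prev))) / scale / (f.t - prev_t)
            if rate < config.steady_tolerance:
                break
            prev = f.c_tot.copy()
            prev_t = f.t
        if rate >= config.steady_tolerance:
            raise RuntimeError(
                f"no steady state within {max_time} s simulated (last relative change "
                f"rate {rate:.3e}/s, tolerance {config.steady_tolerance:.1e}/s)"
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    if mass is not None:
        m = f.total_mass()
        if m <= 0:
            raise RuntimeError("steady state has zero mass; cannot rescale")
        for name in ("c_bound", "c_free", "c_inert"):
            setattr(f, name, getattr(f, name) * (mass / m))
    return f
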