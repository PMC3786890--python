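"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator returns (data, metadata) where the metadata dictionary
records the complete ground truth — model, parameters, noise and seed — so a
round trip (generate, write, read, refit) can check parameter recovery.

Default conventions (documented in the methods note): additive Gaussian
noise on normalized intensities (σ = 0.02 for FRAP curves, SNR 10 for line
profiles); process length L = 30 µm; volume profile with a mild linear taper
and a growth-cone bulge at the tip. A Poisson-scaled noise mode exists
because real confocal noise is intensity-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .frap import FRAPConfig, RecoveryCurve, recovery_curve
from .montecarlo import ActivationProtocol, photoactivation_experiment
from .params import Geometry1D, ModelVariant, MotorParams
from .profiles import LineProfile
from .steady import steady_state

__all__ = [
    "NoiseModel",
    "VolumeProfile",
    "gen_frap_series",
    "gen_line_profile",
    "gen_photoactivation_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to a clean signal.

    ``gaussian_additive``: y + N(0, σ²).
    ``poisson_scaled``: scale · Poisson(y/scale) — variance proportional to
    the signal, emulating shot noise; ``sigma`` is the scale parameter.
    """

    kind: str = "gaussian_additive"
    sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_additive", "poisson_scaled", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "none" or self.sigma == 0:
            return y.copy()
        if self.kind == "gaussian_additive":
            return y + rng.normal(0.0, self.sigma, size=y.shape)
        return self.sigma * rng.poisson(np.maximum(y, 0.0) / self.sigma).astype(float)


@dataclass(frozen=True)
class VolumeProfile:
    """Relative cross-section along the process: linear taper + tip bulge.

    v(s) = 1 − taper·s/L + bulge_height·exp(−(s−L)²/(2·(bulge_width·L)²)),
    which stays positive for taper < 1. The bulge emulates a growth cone.
    """

    taper: float = 0.3
    bulge_height: float = 0.5
    bulge_width: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must be in [0, 1)")
        if self.bulge_height < 0 or self.bulge_width <= 0:
            raise ValueError("bulge_height >= 0 and bulge_width > 0 required")

    def __call__(self, s: np.ndarray, L: float) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (
            1.0
            - self.taper * s / L
            + self.bulge_height * np.exp(-((s - L) ** 2) / (2.0 * (self.bulge_width * L) ** 2))
        )


def gen_frap_series(
    config: FRAPConfig,
    D_star: float,
    noise: NoiseModel,
    seed: int,
    *,
    duration: float = 90.0,
    acquisition_decay: float = 0.0,
    transport_amplitude: float = 0.0,
    transport_tau: float = 60.0,
) -> tuple[RecoveryCurve, Optional[RecoveryCurve], dict]:
    """Synthetic FRAP recovery sampled at the frame interval.

    Optional contaminations: ``acquisition_decay`` β applies a multiplicative
    exp(−β·t) imaging bleach to both the target curve and a returned
    reference curve (for exercising photobleach correction; reference is
    None when β = 0); ``transport_amplitude`` a adds a slow directed-
    transport recovery component a·(1 − exp(−t/τ)).

    Returns (curve, reference, metadata).
    """
    if D_star <= 0:
        raise ValueError("D_star must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * config.frame_interval, config.frame_interval)
    clean = recovery_curve(config, D_star, t)
    if transport_amplitude:
        clean = clean + transport_amplitude * (1.0 - np.exp(-t / transport_tau))
    reference = None
    if acquisition_decay:
        decay = np.exp(-acquisition_decay * t)
        clean = clean * decay
        reference = RecoveryCurve(t.copy(), noise.apply(decay, rng))
    F = noise.apply(clean, rng)
    curve = RecoveryCurve(t, F)
    meta = {
        "generator": "gen_frap_series",
        "D_star_um2_s": D_star,
        "bleach_width_um": config.w,
        "bleach_depth": config.b,
        "frame_interval_s": config.frame_interval,
        "duration_s": duration,
        "domain": config.domain,
        "acquisition_decay_per_s": acquisition_decay,
        "transport_amplitude": transport_amplitude,
        "transport_tau_s": transport_tau,
        "noise": asdict(noise),
        "seed": seed,
    }
    return curve, reference, meta


def gen_line_profile(
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    volume: VolumeProfile,
    seed: int,
    *,
    snr: float = 10.0,
    noise_kind: str = "gaussian_additive",
    n_points: int = 150,
    khc_gain: float = 1.0,
    egfp_gain: float = 1.0,
) -> tuple[LineProfile, dict]:
    """Two-channel line scan from a model steady state.

    khc(s) = volume(s)·c_tot(s)·gain + noise; egfp(s) = volume(s)·gain' +
    noise. Channel noise σ = mean(channel)/snr (snr = inf for noiseless).
    Negative noisy intensities are clipped at zero (photon counts cannot be
    negative). The metadata records the ground-truth decay length when the
    steady state is exponential.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, geom.L, n_points)
    ss = steady_state(variant, params, geom)
    c_tot = ss.c_tot(s)
    c_tot = c_tot / c_tot.mean()  # arbitrary units; keep scale O(1)
    vol = volume(s, geom.L)
    khc_clean = khc_gain * vol * c_tot
    egfp_clean = egfp_gain * vol
    channels = []
    for clean in (khc_clean, egfp_clean):
        if math.isinf(snr):
            channels.append(clean.copy())
        else:
            sigma = float(np.mean(clean)) / snr
            nm = NoiseModel(noise_kind, sigma)
            channels.append(np.clip(nm.apply(clean, rng), 0.0, None))
    profile = LineProfile(s, channels[0], channels[1])
    meta = {
        "generator": "gen_line_profile",
        "variant": variant.name,
        "params": asdict(params),
        "L_um": geom.L,
        "profile_family": ss.profile_family,
        "lambda_um": ss.decay_length,
        "snr": snr,
        "noise_kind": noise_kind,
        "n_points": n_points,
        "volume": asdict(volume),
        "seed": seed,
    }
    return profile, meta


def gen_photoactivation_series(
    protocol: ActivationProtocol,
    variant: ModelVariant,
    params: MotorParams,
    geom: Geometry1D,
    n_motors: int,
    seed: int,
    *,
    sigma: float = 0.0,
    dt: float = 0.02,
    burn_in: float = 400.0,
) -> tuple[pd.DataFrame, dict]:
    """Soma-signal time course of an in silico photoactivation experiment.

    Wraps the stochastic simulator and adds additive Gaussian measurement
    noise of SD ``sigma`` (in motor-count units) on the recorded signal.
    Returns a DataFrame with columns ``t_s``, ``soma_count`` (clean) and
    ``signal`` (noisy), plus metadata.
    """
    seq = np.random.SeedSequence(seed)
    mc_seed, noise_seed = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2))
    df = photoactivation_experiment(
        protocol, variant, params, geom, n_motors, mc_seed, dt=dt, burn_in=burn_in
    )
    rng = np.random.default_rng(noise_seed)
    noise = NoiseModel("gaussian_additive", sigma)
    df = df.copy()
    df["signal"] = noise.apply(df["soma_count"].to_numpy(dtype=float), rng)
    meta = {
        "generator": "gen_photoactivation_series",
        "variant": variant.name,
        "params": asdict(params),
        "L_um": geom.L,
        "protocol": {
            "mode": protocol.mode,
            "n_activations": protocol.n_activations,
            "activation_interval_s": protocol.activation_interval,
            "imaging_interval_s": protocol.imaging_interval,
            "total_time_s": protocol.total_time,
        },
        "n_motors": n_motors,
        "sigma": sigma,
        "dt_s": dt,
        "burn_in_s": burn_in,
        "seed": seed,
    }
    return df, meta
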