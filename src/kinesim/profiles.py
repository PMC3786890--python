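"""Volume-corrected motor line profiles, model fits and binding-rate inference.

A two-channel line scan along a process carries the motor channel (KHC
immunostain, proportional to local volume × total motor density) and a
volume channel (soluble EGFP, proportional to volume alone). Their
point-by-point ratio cancels the volume and reports the total motor density
shape, which the transport models predict to be either linear (Diligent
Worker / Hybrid 1) or exponentially increasing tipward (Loose Bucket
Brigade / Hybrid 2). The fitted exponential decay length λ, together with
independently measured v, D and k_off, inverts to the microtubule binding
rate k_on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .steady import infer_binding_rate

__all__ = [
    "LineProfile",
    "RatioProfile",
    "ProfileFit",
    "ratio_profile",
    "increasing_portion",
    "fit_profile",
    "binding_rate_from_profile",
]


@dataclass
class LineProfile:
    """Two-channel intensities along the arclength of a process."""

    s: np.ndarray  # µm from the base, strictly increasing
    khc: np.ndarray  # motor channel, arbitrary units, >= 0
    egfp: np.ndarray  # volume channel, arbitrary units, >= 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.khc = np.asarray(self.khc, dtype=float)
        self.egfp = np.asarray(self.egfp, dtype=float)
        if not (self.s.shape == self.khc.shape == self.egfp.shape) or self.s.ndim != 1:
            raise ValueError("s, khc, egfp must be 1D arrays of equal length")
        if len(self.s) and np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if np.any(self.khc < 0) or np.any(self.egfp < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class RatioProfile:
    """KHC/EGFP ratio with low-volume points masked out."""

    s: np.ndarray
    ratio: np.ndarray
    n_masked: int


@dataclass
class ProfileFit:
    """Result of fitting both profile families and selecting one.

    ``family`` is the selected model ("exponential" or "linear"); ``delta_aicc``
    is AICc(linear) − AICc(exponential), so positive favours the exponential.
    |delta_aicc| < 2 is reported as ambiguous. ``params`` holds (offset,
    amplitude, lam) for the exponential family or (intercept, slope) for the
    linear one; ``lam_se`` is the 1σ uncertainty of λ from the fit covariance.
    """

    family: str
    params: tuple
    residual: float  # mean |data - model| of the selected family
    delta_aicc: float
    ambiguous: bool
    lam: Optional[float] = None
    lam_se: Optional[float] = None
    exp_converged: bool = True
    residual_linear: Optional[float] = None
    residual_exponential: Optional[float] = None


def ratio_profile(profile: LineProfile, floor: float = 1e-6) -> RatioProfile:
    """Point-by-point khc/egfp ratio; points with egfp < floor are masked."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    keep = profile.egfp >= floor
    n_masked = int(np.count_nonzero(~keep))
    if not np.any(keep):
        raise ValueError("all points masked: volume channel below the floor everywhere")
    return RatioProfile(profile.s[keep], profile.khc[keep] / profile.egfp[keep], n_masked)


def increasing_portion(
    rp: RatioProfile,
    *,
    search_fraction: float = 0.5,
    min_points: int = 8,
    smooth: int = 5,
) -> RatioProfile:
    """Trim to the increasing (tipward) portion of the ratio profile.

    The fitted segment runs from the profile's minimum to the tip; by default
    the minimum is searched within the distal half (``search_fraction=0.5``)
    of the scan, on a ``smooth``-point running mean to avoid locking onto a
    noise dip. If fewer than ``min_points`` would survive, the segment falls
    back to the start of the search region. ``search_fraction=1.0`` searches
    (and may keep) the whole profile.
    """
    n = len(rp.s)
    if n < min_points:
        raise ValueError(f"need >= {min_points} unmasked points, got {n}")
    start_search = int(math.floor((1.0 - search_fraction) * n))
    start_search = min(start_search, n - min_points)
    y = rp.ratio
    if smooth > 1 and n >= smooth:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(rp.ratio, kernel, mode="same")
    seg = slice(start_search, n)
    i_min = start_search + int(np.argmin(y[seg]))
    if n - i_min < min_points:
        i_min = start_search
    return RatioProfile(rp.s[i_min:], rp.ratio[i_min:], rp.n_masked)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    out = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        out += 2 * k * (k + 1) / (n - k - 1)
    return out


def _exp_model(s, offset, amplitude, lam):
    return offset + amplitude * np.exp(np.clip(s / lam, -700, 700))


def fit_profile(
    rp: RatioProfile,
    *,
    restrict_increasing: bool = True,
    search_fraction: float = 0.5,
) -> ProfileFit:
    """Fit linear and exponential models and select by corrected AIC.

    The linear family is y = a + b·s (2 parameters); the exponential family
    is y = a + A·exp(s/λ) (3 parameters). Selection is by lower AICc; a
    difference below 2 is flagged ambiguous. If the exponential fit fails to
    converge the result is linear-only with ``exp_converged=False``.
    """
    if restrict_increasing:
        rp = increasing_portion(rp, search_fraction=search_fraction)
    s, y = rp.s, rp.ratio
    n = len(s)
    if n < 8:
        raise ValueError(f"need >= 8 points to fit, got {n}")

    # linear family
    coeffs, res_lin, *_ = np.polyfit(s, y, 1, full=True)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    model_lin = intercept + slope * s
    rss_lin = float(np.sum((y - model_lin) ** 2))
    aicc_lin = _aicc(rss_lin, n, 2)
    mae_lin = float(np.mean(np.abs(y - model_lin)))

    # exponential family: log-space initialization, then nonlinear refinement
    span = s[-1] - s[0]
    exp_ok = True
    lam_hat = lam_se = None
    try:
        y_min = float(np.min(y))
        shifted = y - y_min + 1e-3 * max(np.ptp(y), 1e-12)
        slope_log = np.polyfit(s, np.log(shifted), 1)[0]
        lam0 = 1.0 / slope_log if slope_log > 0 else span
        lam0 = float(np.clip(lam0, span / 50.0, span * 50.0))
        amp0 = max((y[-1] - y[0]) / max(math.exp(s[-1] / lam0) - math.exp(s[0] / lam0), 1e-12), 1e-12)
        p0 = [y_min, amp0, lam0]
        popt, pcov = curve_fit(
            _exp_model, s, y, p0=p0,
            bounds=([-np.inf, 1e-300, span / 1e4], [np.inf, np.inf, span * 1e4]),
            maxfev=20000,
        )
        model_exp = _exp_model(s, *popt)
        rss_exp = float(np.sum((y - model_exp) ** 2))
        aicc_exp = _aicc(rss_exp, n, 3)
        mae_exp = float(np.mean(np.abs(y - model_exp)))
        lam_hat = float(popt[2])
        lam_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else None
    except (RuntimeError, ValueError):
        exp_ok = False

    if not exp_ok:
        return ProfileFit(
            family="linear", params=(intercept, slope), residual=mae_lin,
            delta_aicc=float("nan"), ambiguous=False, exp_converged=False,
            residual_linear=mae_lin, residual_exponential=None,
        )

    delta = aicc_lin - aicc_exp  # > 0 favours the exponential
    ambiguous = abs(delta) < 2.0
    if delta > 0:
        return ProfileFit(
            family="exponential", params=(float(popt[0]), float(popt[1]), lam_hat),
            residual=mae_exp, delta_aicc=delta, ambiguous=ambiguous,
            lam=lam_hat, lam_se=lam_se,
            residual_linear=mae_lin, residual_exponential=mae_exp,
        )
    return ProfileFit(
        family="linear", params=(intercept, slope), residual=mae_lin,
        delta_aicc=delta, ambiguous=ambiguous,
        lam=lam_hat, lam_se=lam_se,
        residual_linear=mae_lin, residual_exponential=mae_exp,
    )


def binding_rate_from_profile(
    fit: ProfileFit,
    *,
    v: float,
    D: float,
    k_off: float,
) -> tuple[float, Optional[float]]:
    """k_on (s⁻¹) from a fitted exponential decay length, with its SE.

    Delegates to the dispersion-relation inversion
    k_on = D/λ² + D·k_off/(v·λ) and propagates the λ uncertainty to k_on by
    the first-order delta method. Raises if the profile was not classified
    exponential.
    """
    if fit.family != "exponential":
        raise ValueError("profile not exponential; binding rate undefined")
    lam = fit.lam
    k_on = infer_binding_rate(lam, v=v, D=D, k_off=k_off)
    se = None
    if fit.lam_se is not None:
        dk_dlam = -2.0 * D / lam**3 - D * k_off / (v * lam**2)
        se = abs(dk_dlam) * fit.lam_se
    return k_on, se
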