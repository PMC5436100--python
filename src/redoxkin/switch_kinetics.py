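"""The minimal redox-switch model: master equation, dynamic range, response time.

A redox switch cycles between a reduced form (oxidized by H₂O₂ with
second-order constant ``k_ox``) and an oxidized form (re-reduced
enzymatically with pseudo-first-order constant ``k_switchoff``).  With a
sustained local H₂O₂ concentration H, the reduced molar fraction ``rd``
obeys the linear ODE

    d(rd)/dt = −k_ox·H·rd + k_switchoff·(1 − rd)

whose solution relaxes exponentially with rate λ = k_ox·H + k_switchoff:

    rd(t) = rd_ss + (rd0 − rd_ss)·exp(−λ·t),   rd_ss = k_switchoff / λ

The steady-state oxidized fraction is a hyperbolic function of H,

    ox_ss = k_ox·H / (k_ox·H + k_switchoff)

so the H₂O₂ concentration window a switch can sense is set by the *ratio*
k_switchoff/k_ox, while its response half-time ln(2)/λ is set by the *sum*
of the two rates.  Two switches with the same ratio sense the same H₂O₂
range, but the one with the faster turnover responds faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import RateConstants, ThresholdPolicy

__all__ = [
    "SwitchParams",
    "SwitchTimeCourse",
    "DynamicRange",
    "rate_sum",
    "ox_steady_state",
    "h2o2_for_ox",
    "dynamic_range",
    "solve_time_course",
    "integrate_time_course",
    "response_time",
    "response_time_at_ox",
    "time_to_half_reduced",
    "sweep_dose_response",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SwitchParams:
    """A redox switch exposed to a sustained local H₂O₂ concentration.

    ``rd0`` is the reduced molar fraction at time zero (1.0 = fully
    reduced).  ``target_tot_uM`` is an optional total switch concentration
    used only to convert fractions back to absolute amounts; the fractional
    model itself is independent of it.
    """

    rc: RateConstants
    h2o2: float  # M, sustained
    rd0: float = 1.0
    target_tot_uM: float | None = None

    def __post_init__(self) -> None:
        if self.h2o2 < 0:
            raise ValueError("h2o2 must be >= 0")
        if not (0.0 <= self.rd0 <= 1.0):
            raise ValueError("rd0 must lie in [0, 1]")
        if self.target_tot_uM is not None and not self.target_tot_uM > 0:
            raise ValueError("target_tot_uM must be > 0 when given")


@dataclass
class SwitchTimeCourse:
    """Trajectory of reduced/oxidized molar fractions of a switch."""

    times: np.ndarray  # s, strictly increasing
    rd: np.ndarray
    ox: np.ndarray
    params: SwitchParams
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rd = np.asarray(self.rd, dtype=float)
        self.ox = np.asarray(self.ox, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "rd_fraction": self.rd, "ox_fraction": self.ox}
        )


@dataclass(frozen=True)
class DynamicRange:
    """Input H₂O₂ window over which a switch transmits information.

    ``h_low`` elicits the policy's low oxidation threshold (default 10%)
    and ``h_high`` the high threshold (default 90%).  For any switch the
    span ``h_high/h_low`` equals the odds-ratio factor
    (ox_high/(1−ox_high))·((1−ox_low)/ox_low) — 81 for the 10–90% policy —
    because the dose–response curve is a fixed hyperbola shifted along the
    concentration axis by k_switchoff/k_ox.
    """

    h_low: float  # M
    h_high: float  # M
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)

    @property
    def span(self) -> float:
        return self.h_high / self.h_low


def rate_sum(rc: RateConstants, h2o2: float) -> float:
    """Relaxation rate λ = k_ox·[H₂O₂] + k_switchoff, s⁻¹."""
    return rc.k_ox * h2o2 + rc.k_switchoff


def ox_steady_state(rc: RateConstants, h2o2) -> float | np.ndarray:
    """Steady-state oxidized fraction at a sustained H₂O₂ concentration.

    Accepts a scalar or array of concentrations (M); lies in [0, 1) and is
    zero iff the concentration is zero.
    """
    h = np.asarray(h2o2, dtype=float)
    if np.any(h < 0):
        raise ValueError("h2o2 must be >= 0")
    out = rc.k_ox * h / (rc.k_ox * h + rc.k_switchoff)
    return float(out) if np.isscalar(h2o2) else out


def h2o2_for_ox(rc: RateConstants, ox: float) -> float:
    """H₂O₂ concentration (M) sustaining a given steady-state oxidation.

    Exact inverse of :func:`ox_steady_state`:
    H = (ox/(1−ox))·(k_switchoff/k_ox).  Only defined on the open interval
    0 < ox < 1; a fully oxidized switch is reached only asymptotically.
    """
    if not (0.0 < ox < 1.0):
        raise ValueError(
            f"oxidized fraction must lie strictly in (0, 1), got {ox}; "
            "the steady-state dose-response saturates at 1"
        )
    return (ox / (1.0 - ox)) * (rc.k_switchoff / rc.k_ox)


def dynamic_range(
    rc: RateConstants, policy: ThresholdPolicy | None = None
) -> DynamicRange:
    """Input dynamic range of a switch under an oxidation-threshold policy."""
    policy = policy or ThresholdPolicy()
    return DynamicRange(
        h_low=h2o2_for_ox(rc, policy.ox_low),
        h_high=h2o2_for_ox(rc, policy.ox_high),
        policy=policy,
    )


def solve_time_course(params: SwitchParams, times) -> SwitchTimeCourse:
    """Closed-form time course of the switch's reduced/oxidized fractions.

    Evaluates the exponential relaxation solution of the master equation on
    the given time grid (s).
    """
    t = np.asarray(times, dtype=float)
    lam = rate_sum(params.rc, params.h2o2)
    rd_ss = params.rc.k_switchoff / lam
    rd = rd_ss + (params.rd0 - rd_ss) * np.exp(-lam * t)
    return SwitchTimeCourse(times=t, rd=rd, ox=1.0 - rd, params=params)


def integrate_time_course(
    params: SwitchParams,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SwitchTimeCourse:
    """Numerically integrate the switch ODE (independent of the closed form).

    Uses an implicit Radau solver so that very fast relaxation rates (λ up
    to ~10⁵ s⁻¹) remain stable on long windows.  Serves as a cross-check of
    :func:`solve_time_course`; the two agree to the integration tolerance.
    """
    t = np.asarray(times, dtype=float)
    kf = params.rc.k_ox * params.h2o2
    kb = params.rc.k_switchoff

    def rhs(_t, y):
        return [-kf * y[0] + kb * (1.0 - y[0])]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]) if len(t) > 1 else (0.0, t[0] if t[0] > 0 else 1.0),
        [params.rd0],
        method="Radau",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    rd = sol.y[0]
    return SwitchTimeCourse(times=t, rd=rd, ox=1.0 - rd, params=params)


def response_time(rc: RateConstants, h2o2: float) -> float:
    """Response half-time of a switch to a sustained H₂O₂ concentration, s.

    The half-time of the exponential relaxation toward the new oxidation
    steady state, ln(2)/(k_ox·[H₂O₂] + k_switchoff).  It depends on the
    *sum* of the oxidation and reduction rates: at H₂O₂ = 0 it reduces to
    ln(2)/k_switchoff, and it shortens as H₂O₂ rises.
    """
    if h2o2 < 0:
        raise ValueError("h2o2 must be >= 0")
    return LN2 / rate_sum(rc, h2o2)


def response_time_at_ox(rc: RateConstants, ox_ss: float) -> float:
    """Response half-time expressed through the steady-state oxidation, s.

    Algebraically identical to
    ``response_time(rc, h2o2_for_ox(rc, ox_ss))`` but written as
    ln(2)·(1 − ox_ss)/k_switchoff, which hides both k_ox and the H₂O₂
    concentration: switches held at the same steady-state oxidation respond
    on a time scale set purely by their reduction rate.
    """
    if not (0.0 < ox_ss < 1.0):
        raise ValueError(f"ox_ss must lie strictly in (0, 1), got {ox_ss}")
    return LN2 * (1.0 - ox_ss) / rc.k_switchoff


def time_to_half_reduced(params: SwitchParams) -> float:
    """Time at which the reduced fraction falls to half its initial value, s.

    The literal reading of "time needed to oxidize half of the initially
    present target".  Defined only when the steady state lies below the
    half-way point (rd_ss < rd0/2, i.e. ox_ss > 1 − rd0/2); otherwise half
    the initial pool is never oxidized and a ``ValueError`` is raised.  For
    most purposes :func:`response_time` — the relaxation half-time, which
    is finite for every input — is the appropriate quantity.
    """
    lam = rate_sum(params.rc, params.h2o2)
    rd_ss = params.rc.k_switchoff / lam
    target = params.rd0 / 2.0
    if rd_ss >= target:
        raise ValueError(
            f"steady-state reduced fraction {rd_ss:.4g} never falls below "
            f"rd0/2 = {target:.4g}; half the initial pool is never oxidized"
        )
    return math.log((params.rd0 - rd_ss) / (target - rd_ss)) / lam


def sweep_dose_response(
    rc: RateConstants,
    h_grid,
    policy: ThresholdPolicy | None = None,
) -> pd.DataFrame:
    """Dose–response sweep: steady-state oxidation and half-time per dose.

    Returns one row per H₂O₂ concentration with columns ``h2o2_M``,
    ``ox_ss``, ``t_half_s`` and two flags marking the signal-transmitting
    zones: ``in_dynamic_range`` (oxidation within [ox_low, ox_high]) and
    ``fast_enough`` (half-time ≤ t_max_signal).
    """
    policy = policy or ThresholdPolicy()
    h = np.asarray(h_grid, dtype=float)
    if h.ndim != 1 or len(h) == 0:
        raise ValueError("h_grid must be a non-empty 1-D sequence")
    if np.any(h <= 0) or np.any(np.diff(h) <= 0):
        raise ValueError("h_grid must be positive and strictly increasing")
    ox = ox_steady_state(rc, h)
    t_half = LN2 / (rc.k_ox * h + rc.k_switchoff)
    return pd.DataFrame(
        {
            "h2o2_M": h,
            "ox_ss": ox,
            "t_half_s": t_half,
            "in_dynamic_range": (ox >= policy.ox_low) & (ox <= policy.ox_high),
            "fast_enough": t_half <= policy.t_max_signal,
        }
    )
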