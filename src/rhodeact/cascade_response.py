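"""Downstream stage: effector activation and the photocurrent response.

An R* path drives activated effector (transducin-PDE complex) E* through

    dE*/dt = nu_{s(t)} - k_E * E*,

with s(t) the occupied state (nu = 0 after arrestin capture).  Between jumps
the drive is constant, so E*(t) is piecewise exponential and is evaluated in
closed form.

The photocurrent stage is a deliberately well-mixed surrogate of the
spatio-temporal (diffusional) transduction models used for absolute current
predictions: cGMP is hydrolyzed at rate beta_dark + beta_e*E*, synthesized by
a Ca2+-inhibited cyclase, and gates the circulating current through a Hill
nonlinearity; Ca2+ enters in proportion to the current and is cleared first
order.  The surrogate preserves the orderings and inequality structure of the
full model (amplitude/time-to-peak/area orderings across genotypes,
current-level variability suppression) but not its absolute amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .markov_analytic import ProbabilityEvolution, mean_activity
from .scheme import DeactivationScheme
from .stochastic_sim import Trajectory

__all__ = [
    "CascadeParams",
    "DEFAULT_CASCADE",
    "EffectorTimecourse",
    "CurrentResponse",
    "total_integrated_activity",
    "effector_from_path",
    "effector_at_time",
    "mean_effector",
    "effector_functionals",
    "current_response",
    "current_response_ensemble",
    "apply_geometry",
]


@dataclass(frozen=True)
class CascadeParams:
    """Constants of the well-mixed transduction surrogate.

    Concentrations are in uM, rates in 1/s; the rod-outer-segment volume is
    relative to the wild-type geometry (1.0), and the effector-to-hydrolysis
    coupling scales with its inverse (fixed number of PDE targets in a
    smaller cytosol).
    """

    k_E: float = 3.5          # effector deactivation rate, 1/s
    cg_dark: float = 6.0      # dark cGMP concentration, uM
    beta_dark: float = 4.1    # basal cGMP hydrolysis rate, 1/s
    beta_e: float = 0.0364    # extra hydrolysis rate per E* unit, 1/s
    ca_dark: float = 0.25     # dark Ca2+ concentration, uM
    ca_min: float = 0.023     # Ca2+ floor (exchanger limit), uM
    K_ca: float = 0.135       # cyclase half-inhibition Ca2+, uM
    m_cyc: float = 1.5        # cyclase Hill coefficient
    n_ch: float = 2.0         # CNG-channel cooperativity exponent
    gamma_ca: float = 25.0    # Ca2+ clearance rate, 1/s
    ros_length: float = 23.6  # outer-segment length, um
    ros_volume: float = 1.0   # cytosolic volume relative to WT
    n_channels: float = 1.0   # channel count relative to WT (fixed density knob)

    def __post_init__(self) -> None:
        vals = [self.k_E, self.cg_dark, self.beta_dark, self.beta_e,
                self.ca_dark, self.ca_min, self.K_ca, self.m_cyc, self.n_ch,
                self.gamma_ca, self.ros_length, self.ros_volume,
                self.n_channels]
        if any(v <= 0 for v in vals):
            raise ValueError("all cascade parameters must be positive")

    @property
    def alpha_max(self) -> float:
        """Maximal cyclase rate, fixed by the dark steady state."""
        return self.beta_dark * self.cg_dark * (
            1.0 + (self.ca_dark / self.K_ca) ** self.m_cyc)

    @property
    def beta_e_eff(self) -> float:
        """Per-E* hydrolysis coupling at the current geometry."""
        return self.beta_e / self.ros_volume


DEFAULT_CASCADE = CascadeParams()


@dataclass(frozen=True, eq=False)
class EffectorTimecourse:
    """E*(t) on a reporting grid, with the decay rate that produced it."""

    time_grid: np.ndarray
    e_star: np.ndarray
    k_E: float
    source: str = "single path"


@dataclass(frozen=True, eq=False)
class CurrentResponse:
    """Relative current suppression dJ/J(t) and its scalar functionals."""

    time_grid: np.ndarray
    dj: np.ndarray           # dJ/J(t), dimensionless in [0, 1]
    cum_charge: np.ndarray   # integral of dJ/J up to t, s
    peak: float              # max suppression
    t_peak: float            # time of the peak, s
    area: float              # SPR area: cum_charge at the horizon, s


# ---------------------------------------------------------------------------
# effector stage (linear, closed form)


def total_integrated_activity(traj: Trajectory,
                              scheme: DeactivationScheme) -> float:
    """T_tot = sum over visited states of nu_k * (time spent in k).

    Sojourns are already truncated at the horizon, so censored paths
    contribute their activity up to the horizon.  Independent of k_E.
    """
    return float(np.sum(scheme.nu[traj.states - 1] * traj.sojourns))


def _segments(traj: Trajectory, scheme: DeactivationScheme):
    """(t_start, duration, nu) per constant-drive segment, incl. post-shutoff."""
    starts = np.concatenate([[0.0], np.cumsum(traj.sojourns)[:-1]])
    segs = [(float(t0), float(dt), float(scheme.nu[s - 1]))
            for t0, dt, s in zip(starts, traj.sojourns, traj.states)]
    if not traj.censored:
        segs.append((float(traj.shutoff_time), math.inf, 0.0))
    else:
        # censored: final state persists beyond the horizon
        t0, dt, nu = segs[-1]
        segs[-1] = (t0, math.inf, nu)
    return segs


def effector_at_time(traj: Trajectory, scheme: DeactivationScheme,
                     k_E: float, t: float) -> float:
    """Exact E*(t) for a single time, by the piecewise-exponential recursion."""
    e = 0.0
    for t0, dt, nu in _segments(traj, scheme):
        target = nu / k_E
        if t <= t0 + dt or math.isinf(dt):
            return target + (e - target) * math.exp(-k_E * (t - t0))
        e = target + (e - target) * math.exp(-k_E * dt)
    return e


def effector_from_path(traj: Trajectory, scheme: DeactivationScheme,
                       k_E: float, time_grid: np.ndarray) -> EffectorTimecourse:
    """Evaluate the piecewise-exponential E*(t) on a reporting grid.

    The grid must cover the trajectory horizon.
    """
    t = np.asarray(time_grid, dtype=float)
    if t[-1] < traj.horizon - 1e-12:
        raise ValueError(
            f"time grid ends at {t[-1]} s but the trajectory horizon is "
            f"{traj.horizon} s")
    e = np.empty_like(t)
    e_entry = 0.0
    for t0, dt, nu in _segments(traj, scheme):
        target = nu / k_E
        if math.isinf(dt):
            sel = t >= t0
        else:
            sel = (t >= t0) & (t < t0 + dt)
        e[sel] = target + (e_entry - target) * np.exp(-k_E * (t[sel] - t0))
        if not math.isinf(dt):
            e_entry = target + (e_entry - target) * math.exp(-k_E * dt)
    e[t < 0] = 0.0
    return EffectorTimecourse(time_grid=t, e_star=e, k_E=k_E)


def mean_effector(prob: ProbabilityEvolution, k_E: float) -> EffectorTimecourse:
    """Deterministic companion: dE/dt = sum_k nu_k P_k(t) - k_E E.

    By linearity this equals the ensemble mean of ``effector_from_path`` over
    fully random (Case 3) paths.  Integrated exactly for a drive that is
    linearly interpolated between grid points.
    """
    t = prob.time_grid
    drive = mean_activity(prob)
    e = np.zeros_like(t)
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        a, b = drive[i - 1], (drive[i] - drive[i - 1]) / dt
        decay = math.exp(-k_E * dt)
        w = (1.0 - decay) / k_E
        e[i] = e[i - 1] * decay + a * w + b * (dt / k_E - w / k_E)
    return EffectorTimecourse(time_grid=t, e_star=e, k_E=k_E,
                              source="ensemble mean")


def effector_functionals(tc: EffectorTimecourse, t_bar: float,
                         traj: Trajectory | None = None,
                         scheme: DeactivationScheme | None = None) -> dict:
    """Scalar functionals of an effector timecourse.

    Returns ``E_tbar`` (point evaluation at t_bar), ``cum_integral`` (the
    running integral of E* on the grid, unit-seconds) and ``T_tot`` (total
    integrated activity, k_E-independent: computed from the path when one is
    supplied, else as k_E * integral of E* plus the activity still bound in
    E* at the horizon).
    """
    t, e = tc.time_grid, tc.e_star
    if not tc.time_grid[0] <= t_bar <= tc.time_grid[-1]:
        raise ValueError("t_bar outside the reporting grid")
    cum = np.concatenate([[0.0],
                          np.cumsum(0.5 * (e[1:] + e[:-1]) * np.diff(t))])
    e_tbar = float(np.interp(t_bar, t, e))
    if traj is not None and scheme is not None:
        t_tot = total_integrated_activity(traj, scheme)
    else:
        t_tot = tc.k_E * float(cum[-1]) + float(e[-1])
    return {"E_tbar": e_tbar, "cum_integral": cum, "T_tot": t_tot}


# ---------------------------------------------------------------------------
# photocurrent stage (well-mixed surrogate)


def _integrate_cascade(time_grid: np.ndarray, e_star: np.ndarray,
                       params: CascadeParams, max_dt: float = 2.5e-4):
    """Fixed-step RK4 of the cGMP/Ca2+ system, vectorized across trials.

    ``e_star`` has shape (n_trials, n_times); E* is interpolated linearly
    inside the sub-steps.  Returns dJ/J with the same shape.
    """
    t = np.asarray(time_grid, dtype=float)
    E = np.atleast_2d(np.asarray(e_star, dtype=float))
    p = params
    alpha_max = p.alpha_max
    be = p.beta_e_eff
    ca_drive = p.ca_dark - p.ca_min

    def deriv(cg, ca, e):
        j = (cg / p.cg_dark) ** p.n_ch
        dcg = alpha_max / (1.0 + (ca / p.K_ca) ** p.m_cyc) \
            - (p.beta_dark + be * e) * cg
        dca = p.gamma_ca * (ca_drive * j - (ca - p.ca_min))
        return dcg, dca

    cg = np.full(E.shape[0], p.cg_dark)
    ca = np.full(E.shape[0], p.ca_dark)
    dj = np.zeros_like(E)
    for i in range(1, t.size):
        dt_full = t[i] - t[i - 1]
        n_sub = max(1, int(math.ceil(dt_full / max_dt)))
        h = dt_full / n_sub
        e0, e1 = E[:, i - 1], E[:, i]
        for s in range(n_sub):
            frac0 = s / n_sub
            ea = e0 + (e1 - e0) * frac0
            em = e0 + (e1 - e0) * (frac0 + 0.5 / n_sub)
            eb = e0 + (e1 - e0) * (frac0 + 1.0 / n_sub)
            k1c, k1a = deriv(cg, ca, ea)
            k2c, k2a = deriv(cg + 0.5 * h * k1c, ca + 0.5 * h * k1a, em)
            k3c, k3a = deriv(cg + 0.5 * h * k2c, ca + 0.5 * h * k2a, em)
            k4c, k4a = deriv(cg + h * k3c, ca + h * k3a, eb)
            cg = cg + h / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
            ca = ca + h / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
        if not (np.all(np.isfinite(cg)) and np.all(np.isfinite(ca))):
            raise RuntimeError(
                f"cascade integration diverged at t={t[i]:.4f} s with "
                f"params {params}")
        dj[:, i] = 1.0 - (np.clip(cg, 0.0, None) / p.cg_dark) ** p.n_ch
    return dj


def _response_from_dj(time_grid: np.ndarray, dj: np.ndarray) -> CurrentResponse:
    t = np.asarray(time_grid, dtype=float)
    cum = np.concatenate([[0.0],
                          np.cumsum(0.5 * (dj[1:] + dj[:-1]) * np.diff(t))])
    i_peak = int(np.argmax(dj))
    return CurrentResponse(time_grid=t, dj=dj, cum_charge=cum,
                           peak=float(dj[i_peak]), t_peak=float(t[i_peak]),
                           area=float(cum[-1]))


def current_response(tc: EffectorTimecourse,
                     params: CascadeParams = DEFAULT_CASCADE) -> CurrentResponse:
    """Photocurrent response dJ/J(t) driven by one effector timecourse."""
    dj = _integrate_cascade(tc.time_grid, tc.e_star, params)[0]
    return _response_from_dj(tc.time_grid, dj)


def current_response_ensemble(time_grid: np.ndarray, e_star: np.ndarray,
                              params: CascadeParams = DEFAULT_CASCADE):
    """dJ/J for a stack of effector timecourses, shape (n_trials, n_times)."""
    return _integrate_cascade(time_grid, e_star, params)


def apply_geometry(params: CascadeParams,
                   length_fraction: float) -> CascadeParams:
    """Shorten the outer segment, keeping the channel count fixed.

    Volume scales linearly with length; the effector-to-hydrolysis coupling
    scales with inverse volume (same PDE drive in a smaller cytosol), so a
    shorter segment gives a larger response per photoisomerization.
    """
    if length_fraction <= 0:
        raise ValueError("length_fraction must be positive")
    return replace(params,
                   ros_length=params.ros_length * length_fraction,
                   ros_volume=params.ros_volume * length_fraction)
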