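"""Stochastic path sampling of R* deactivation under three randomness regimes.

Case 1 fixes the number of shutoff steps at the integer closest to its mean N
and draws random exponential sojourns; Case 2 fixes every sojourn at its mean
and draws the random step count M; Case 3 (the biologically realistic regime)
draws both.  Genotypes that can never shut off (0P-2P, arrestin knockout)
traverse all their available states and are censored at the horizon in every
case.

Ensembles use counter-based per-trial substreams derived from (seed, trial
index), so results are bit-reproducible and independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov_analytic import (StepDistribution, mean_steps, step_distribution,
                              DEFICIT_TOL)
from .scheme import DeactivationScheme, mean_sojourn_times

__all__ = [
    "Trajectory",
    "round_half_away",
    "sample_path",
    "sample_ensemble",
    "empirical_step_distribution",
]


@dataclass(frozen=True, eq=False)
class Trajectory:
    """One sampled R* path.

    ``states`` are the visited active states (1-based, consecutive from 1) and
    ``sojourns`` the time actually spent in each, truncated at the horizon.
    ``censored`` is True when no arrestin-binding event occurred before the
    horizon, in which case ``shutoff_time``/``shutoff_step`` are None.
    """

    states: np.ndarray
    sojourns: np.ndarray
    censored: bool
    shutoff_time: float | None
    shutoff_step: int | None
    case: int
    horizon: float

    def __post_init__(self) -> None:
        if self.states.size != self.sojourns.size:
            raise ValueError("states and sojourns must have equal length")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (4.5 -> 5)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -round_half_away(-x)


def _truncate(states: list[int], sojourns: list[float], horizon: float,
              shutoff_step: int | None, case: int) -> Trajectory:
    """Clip a fully sampled path at the horizon and package it."""
    out_states: list[int] = []
    out_soj: list[float] = []
    t = 0.0
    censored = True
    shutoff_time = None
    for i, (s, dt) in enumerate(zip(states, sojourns)):
        if t + dt >= horizon or not math.isfinite(dt):
            out_states.append(s)
            out_soj.append(horizon - t)
            break
        out_states.append(s)
        out_soj.append(dt)
        t += dt
        if shutoff_step is not None and i + 1 == shutoff_step:
            censored = False
            shutoff_time = t
    return Trajectory(states=np.asarray(out_states, dtype=int),
                      sojourns=np.asarray(out_soj, dtype=float),
                      censored=censored, shutoff_time=shutoff_time,
                      shutoff_step=None if censored else shutoff_step,
                      case=case, horizon=horizon)


def sample_path(scheme: DeactivationScheme, case: int, horizon: float,
                rng: np.random.Generator) -> Trajectory:
    """Sample one deactivation path under the given randomness regime."""
    if case not in (1, 2, 3):
        raise ValueError(f"case must be 1, 2 or 3, got {case!r}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    tau = mean_sojourn_times(scheme)
    dist = step_distribution(scheme)
    no_shutoff = dist.deficit > DEFICIT_TOL

    if case == 3:
        states: list[int] = []
        sojourns: list[float] = []
        t = 0.0
        k = 1
        while True:
            states.append(k)
            if math.isinf(tau[k - 1]):
                sojourns.append(math.inf)
                return _truncate(states, sojourns, horizon, None, case)
            dt = rng.exponential(tau[k - 1])
            sojourns.append(dt)
            t += dt
            if t >= horizon:
                return _truncate(states, sojourns, horizon, None, case)
            if rng.random() < scheme.p[k - 1]:
                return _truncate(states, sojourns, horizon, len(states), case)
            k += 1

    if no_shutoff:
        # interpretive reading for 0P-2P / arrestin KO: the walker traverses
        # all available states (random or fixed sojourns) with no binding
        m_star = None
        n_visit = scheme.n_active
    elif case == 1:
        m_star = round_half_away(mean_steps(scheme))
        n_visit = m_star
    else:  # case 2, shutoff certain
        m_star = int(rng.choice(dist.support, p=dist.pmf / dist.pmf.sum()))
        n_visit = m_star

    states = list(range(1, n_visit + 1))
    if case == 1:
        sojourns = [rng.exponential(tau[k - 1]) if math.isfinite(tau[k - 1])
                    else math.inf for k in states]
    else:
        sojourns = [tau[k - 1] for k in states]
    return _truncate(states, sojourns, horizon, m_star, case)


def sample_ensemble(scheme: DeactivationScheme, case: int, horizon: float,
                    n_trials: int, seed: int) -> list[Trajectory]:
    """Sample independent trajectories with per-trial substreams.

    Trial i uses ``SeedSequence(seed, spawn_key=(i,))``, so identical inputs
    give a bit-identical ensemble regardless of execution order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    out = []
    for i in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(i,)))
        out.append(sample_path(scheme, case, horizon, rng))
    return out


def empirical_step_distribution(ensemble: list[Trajectory]) -> StepDistribution:
    """Relative frequencies of shutoff step counts over an ensemble.

    Censored trajectories count toward the deficit.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    max_states = max(t.states[-1] for t in ensemble)
    counts = np.zeros(int(max_states))
    n_censored = 0
    for t in ensemble:
        if t.censored:
            n_censored += 1
        else:
            counts[t.shutoff_step - 1] += 1
    n = len(ensemble)
    return StepDistribution(support=np.arange(1, counts.size + 1),
                            pmf=counts / n, deficit=n_censored / n)
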