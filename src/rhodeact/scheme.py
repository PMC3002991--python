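"""Deactivation schemes: the rate sequences defining the R* shutoff chain.

Activated rhodopsin (R*) is deactivated by sequential phosphorylation by
rhodopsin kinase followed by arrestin capture.  The process is a continuous-time
Markov chain on states 1..n+1 (state k carries k-1 phosphates) plus one
absorbing arrestin-bound state n+2.  A scheme bundles the three per-state rate
sequences that fully determine the chain:

* phosphorylation rates  lam_k = omega * (n - k + 1), lam_{n+1} = 0
  (proportional to the number of still-available serine/threonine sites);
* arrestin-binding rates mu_k = 0 below the phosphorylation threshold
  (fewer than 3 attached phosphates do not support stable arrestin binding),
  mu_k = mu_max at and above it;
* catalytic activities   nu_k = nu1 * exp(-k_nu * (k - 1)), the rate at which
  R* in state k activates its effector (transducin/PDE), decaying
  exponentially with each added phosphate.

All rates are per second, times are seconds; reporting helpers convert to ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "DynamicsPreset",
    "DeactivationScheme",
    "SLOW",
    "FAST",
    "PRESETS",
    "ARRESTIN_PHOSPHATE_THRESHOLD",
    "build_scheme",
    "mean_sojourn_times",
    "save_scheme",
    "load_scheme",
]

#: attached phosphates required before arrestin binds with quenching affinity
ARRESTIN_PHOSPHATE_THRESHOLD = 3


@dataclass(frozen=True)
class DynamicsPreset:
    """A named (omega, mu_max, nu1, k_nu) quadruple with its target R* lifetime.

    The slow preset corresponds to an effective WT R* lifetime of 75 ms, the
    fast preset to 41 ms; both use the same activity decay constant k_nu = 0.5.
    """

    name: str
    omega: float          # base per-site phosphorylation rate, 1/s
    mu_max: float         # saturated arrestin-binding rate, 1/s
    nu1: float            # catalytic activity of unphosphorylated R*, units/s
    k_nu: float           # activity decay constant per phosphate, dimensionless
    tau_R_target: float   # effective WT lifetime the preset was calibrated to, s


SLOW = DynamicsPreset("slow", omega=10.5, mu_max=60.0, nu1=330.0, k_nu=0.5,
                      tau_R_target=0.075)
FAST = DynamicsPreset("fast", omega=19.0, mu_max=120.0, nu1=500.0, k_nu=0.5,
                      tau_R_target=0.041)
PRESETS: dict[str, DynamicsPreset] = {"slow": SLOW, "fast": FAST}


@dataclass(frozen=True, eq=False)
class DeactivationScheme:
    """Rate sequences of the deactivation chain for one genotype/preset.

    ``lam``, ``mu`` and ``nu`` have length ``n_sites + 1`` (one entry per
    active state); the absorbing arrestin-bound state carries no rates.
    """

    n_sites: int
    omega: float
    mu_max: float
    nu1: float
    k_nu: float
    lam: np.ndarray
    mu: np.ndarray
    nu: np.ndarray
    arrestin_ko: bool = False
    label: str = ""

    @property
    def n_active(self) -> int:
        """Number of active states (1 unphosphorylated + n_sites levels)."""
        return self.n_sites + 1

    @property
    def inactive_state(self) -> int:
        """1-based label of the absorbing arrestin-bound state."""
        return self.n_sites + 2

    @property
    def total_rates(self) -> np.ndarray:
        """Exit rate lam_k + mu_k of every active state."""
        return self.lam + self.mu

    @property
    def q(self) -> np.ndarray:
        """Per-state probability of phosphorylation (vs. arrestin binding).

        States with zero total exit rate never leave; q is 0 there so that
        downstream visit probabilities terminate correctly.
        """
        tot = self.total_rates
        return np.divide(self.lam, tot, out=np.zeros_like(tot), where=tot > 0)

    @property
    def p(self) -> np.ndarray:
        """Per-state probability that the exit is arrestin binding."""
        tot = self.total_rates
        return np.divide(self.mu, tot, out=np.zeros_like(tot), where=tot > 0)

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "nu"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.n_sites + 1,):
                raise ValueError(
                    f"{name} must have length n_sites+1={self.n_sites + 1}, "
                    f"got {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} entries must be finite and >= 0")
        if np.any(self.nu <= 0):
            raise ValueError("catalytic activities must be strictly positive")


def build_scheme(n_sites: int,
                 preset: DynamicsPreset | str = SLOW,
                 arrestin_ko: bool = False,
                 mu_threshold: int = ARRESTIN_PHOSPHATE_THRESHOLD,
                 label: str | None = None) -> DeactivationScheme:
    """Construct the deactivation scheme for a genotype under a preset.

    Parameters
    ----------
    n_sites
        Number of available phosphorylation sites, 0-6.  Mutants with m of
        the six sites removed are modelled by truncating the chain
        (sites are exchangeable; only their count matters).
    preset
        Dynamics preset or its name ("slow" / "fast").
    arrestin_ko
        If True, all arrestin-binding rates are zero (arrestin knockout);
        the phosphorylation sequence is unchanged.
    mu_threshold
        Number of attached phosphates below which arrestin cannot bind
        stably.  Default 3; exposed for sensitivity exploration only.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if not 0 <= n_sites <= 6:
        raise ValueError(f"n_sites must be in 0..6, got {n_sites}")
    if min(preset.omega, preset.mu_max, preset.nu1) <= 0 or preset.k_nu < 0:
        raise ValueError("preset rates must be positive")
    if mu_threshold < 0:
        raise ValueError("mu_threshold must be >= 0")

    k = np.arange(1, n_sites + 2)  # 1-based active-state labels
    lam = preset.omega * (n_sites - k + 1).astype(float)
    lam[-1] = 0.0  # fully phosphorylated state cannot phosphorylate further
    if arrestin_ko:
        mu = np.zeros(n_sites + 1)
    else:
        # state k carries k-1 phosphates; binding needs >= mu_threshold of them
        mu = np.where(k - 1 >= mu_threshold, preset.mu_max, 0.0)
    nu = preset.nu1 * np.exp(-preset.k_nu * (k - 1))

    if label is None:
        label = "arrKO" if arrestin_ko else f"{n_sites}P"
    return DeactivationScheme(
        n_sites=n_sites, omega=preset.omega, mu_max=preset.mu_max,
        nu1=preset.nu1, k_nu=preset.k_nu, lam=lam, mu=mu, nu=nu,
        arrestin_ko=arrestin_ko, label=label)


def mean_sojourn_times(scheme: DeactivationScheme) -> np.ndarray:
    """Mean residence time 1/(lam_k + mu_k) of each active state, seconds.

    States with zero exit rate (e.g. the single state of a 0P scheme, or the
    terminal state of an arrestin knockout) get ``math.inf``: downstream code
    must branch on infinity explicitly rather than receive a large float.
    """
    tot = scheme.total_rates
    tau = np.full(scheme.n_active, math.inf)
    np.divide(1.0, tot, out=tau, where=tot > 0)
    return tau


# ---------------------------------------------------------------------------
# scheme files (plain YAML key-value configuration)

def save_scheme(scheme: DeactivationScheme, path) -> None:
    """Write a scheme's defining parameters as a YAML configuration file."""
    positive = np.nonzero(scheme.mu > 0)[0]
    # phosphate threshold is recoverable from the first state with mu > 0
    threshold = (int(positive[0]) if positive.size
                 else ARRESTIN_PHOSPHATE_THRESHOLD)
    doc = {
        "label": scheme.label,
        "n_sites": int(scheme.n_sites),
        "omega": float(scheme.omega),
        "mu_max": float(scheme.mu_max),
        "nu1": float(scheme.nu1),
        "k_nu": float(scheme.k_nu),
        "arrestin_ko": bool(scheme.arrestin_ko),
        "mu_threshold": threshold,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scheme(path) -> DeactivationScheme:
    """Rebuild a scheme from a YAML configuration written by save_scheme."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    preset = DynamicsPreset(
        name=doc.get("preset", "custom"), omega=doc["omega"],
        mu_max=doc["mu_max"], nu1=doc["nu1"], k_nu=doc["k_nu"],
        tau_R_target=float(doc.get("tau_R_target", float("nan"))))
    return build_scheme(doc["n_sites"], preset,
                        arrestin_ko=doc.get("arrestin_ko", False),
                        mu_threshold=doc.get("mu_threshold",
                                             ARRESTIN_PHOSPHATE_THRESHOLD),
                        label=doc.get("label"))
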