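"""Mean-field predictions of the collisional model.

Closed forms used both as oracles for the simulator and as references for
the data statistics:

* stationary profile without duplication: Poisson(lambda), lambda fixed by
  the (conserved) initial mean;
* stationary variance with duplication: Var(V) = lambda (1 + p_d/(p_h (1 - p_h)));
* grazing-collision limit (p_d, p_h -> 0 at fixed ratio): negative binomial
  with mean lambda and variance lambda (p_d + p_h)/p_h;
* exponential relaxation of all moments with time constant 1/(p_h (1 - p_h))
  sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnalyticProfile",
    "poisson_profile",
    "grazing_limit_profile",
    "stationary_variance",
    "relaxation_time_sweeps",
    "variance_relaxation_time_sweeps",
    "expected_variance_trajectory",
    "fit_relaxation_time",
]


@dataclass(frozen=True)
class AnalyticProfile:
    """A truncated analytic abundance profile over v = 0..v_max."""

    lam: float
    v_max: int
    pmf: np.ndarray
    family: str  # {"poisson", "negative_binomial"}

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.v_max + 1)

    def mean(self) -> float:
        return float(np.sum(self.support * self.pmf))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum((self.support - m) ** 2 * self.pmf))


def poisson_profile(lam: float, v_max: int = 450) -> AnalyticProfile:
    """Poisson(lambda) pmf over 0..v_max, evaluated stably in log space."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if v_max < 0:
        raise ValueError("v_max must be non-negative")
    v = np.arange(v_max + 1)
    pmf = np.exp(sps.poisson.logpmf(v, lam))
    return AnalyticProfile(lam=float(lam), v_max=int(v_max), pmf=pmf, family="poisson")


def grazing_limit_profile(
    lam: float, p_h: float, p_d: float, v_max: int = 450
) -> AnalyticProfile:
    """Stationary profile in the grazing-collision limit.

    Negative binomial parameterized by moment matching to mean lambda and
    variance lambda (p_d + p_h)/p_h: size r = lambda p_h/p_d, success
    probability q = p_h/(p_d + p_h).  For p_d = 0 this degenerates to the
    Poisson profile.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if p_h <= 0:
        raise ValueError("p_h must be positive")
    if p_d < 0:
        raise ValueError("p_d must be non-negative")
    if p_d == 0:
        prof = poisson_profile(lam, v_max)
        return AnalyticProfile(
            lam=prof.lam, v_max=prof.v_max, pmf=prof.pmf, family="negative_binomial"
        )
    r = lam * p_h / p_d
    q = p_h / (p_d + p_h)
    v = np.arange(v_max + 1)
    pmf = np.exp(sps.nbinom.logpmf(v, r, q))
    return AnalyticProfile(
        lam=float(lam), v_max=int(v_max), pmf=pmf, family="negative_binomial"
    )


def stationary_variance(lam: float, p_h: float, p_d: float) -> float:
    """Mean-field stationary variance lambda (1 + p_d/(p_h (1 - p_h)))."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < p_h < 1:
        raise ValueError("formula is singular at p_h in {0, 1}")
    if p_d < 0:
        raise ValueError("p_d must be non-negative")
    return lam * (1.0 + p_d / (p_h * (1.0 - p_h)))


def relaxation_time_sweeps(p_h: float) -> float:
    """Mean-field reference relaxation constant 1/(p_h (1 - p_h)) in sweeps.

    Depends only on p_h, even when p_d > 0.  See
    ``variance_relaxation_time_sweeps`` for the exact sweep-based constant
    the simulated ensemble variance follows.
    """
    if not 0 < p_h < 1:
        raise ValueError("p_h must lie strictly between 0 and 1")
    return 1.0 / (p_h * (1.0 - p_h))


def variance_relaxation_time_sweeps(p_h: float) -> float:
    """Exact relaxation time of the ensemble variance, in sweeps.

    Both collision partners update, so each genome takes part in two
    collisions per sweep of N collisions, and the centred second moment
    contracts by (1 - p_h)^2 + p_h^2 = 1 - 2 p_h (1 - p_h) per
    participation.  The ensemble variance therefore approaches its
    stationary value at rate 4 p_h (1 - p_h) per sweep — independent of
    p_d, which only sets the stationary level — i.e. a factor 4 faster
    than the per-participation first-moment reference constant
    ``relaxation_time_sweeps``.
    """
    if not 0 < p_h < 1:
        raise ValueError("p_h must lie strictly between 0 and 1")
    return 0.25 / (p_h * (1.0 - p_h))


def expected_variance_trajectory(
    t: np.ndarray | float, var0: float, var_inf: float, p_h: float
) -> np.ndarray | float:
    """Exponential approach of the ensemble variance to its stationary value."""
    t = np.asarray(t, dtype=float)
    out = var_inf + (var0 - var_inf) * np.exp(-t * p_h * (1.0 - p_h))
    return out if out.ndim else float(out)


def fit_relaxation_time(
    times: np.ndarray,
    variances: np.ndarray,
    var_inf: float,
    rel_floor: float = 0.05,
) -> float:
    """Recover the relaxation time from a variance trajectory.

    Least-squares line through log|Var(t) - Var(inf)| vs t, restricted to
    points whose residual exceeds ``rel_floor`` of the initial residual (the
    tail is dominated by finite-ensemble noise).  Returns -1/slope in sweeps.
    """
    t = np.asarray(times, dtype=float)
    r = np.abs(np.asarray(variances, dtype=float) - var_inf)
    if r[0] <= 0:
        raise ValueError("trajectory starts at the stationary variance")
    keep = r > rel_floor * r[0]
    if keep.sum() < 3:
        raise ValueError("too few informative points for an exponential fit")
    slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
    if slope >= 0:
        raise ValueError("variance trajectory is not relaxing")
    return -1.0 / slope
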