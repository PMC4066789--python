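"""Collisional model of gene-family copy-number dynamics across species.

A fixed ensemble of ``N`` species genomes evolves the copy number ``V_i`` of a
single gene family through pairwise "collisions".  In one collision two
genomes are picked (uniformly at random, or with probability proportional to
a pair-weight kernel, e.g. derived from phylogenetic distances) and

* each partner gains copies from the other by per-copy Bernoulli trials of
  probability ``p_h`` (inter-species horizontal transfer),
* each of its own copies is, exclusively, lost with probability ``p_l`` or
  duplicated with probability ``p_d`` (intra-species expansion).

Stationarity of the total copy number requires ``p_h + p_d = p_l`` (and
``p_d + p_l <= 1`` for the per-copy outcomes to be probabilities).  Time is
measured in sweeps of ``N`` collisions.  Families are independent, so one
state describes one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = [
    "ModelParams",
    "AbundanceState",
    "CollisionKernel",
    "Trajectory",
    "validate_params",
    "initialize_state",
    "collide_pair",
    "run_simulation",
    "abundance_histogram",
    "exponential_kernel",
    "stationary_sweeps",
]

_RATE_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Validated collision-model rates and ensemble size.

    p_h : per-copy probability of horizontal gain from the collision partner
    p_d : per-copy probability of duplication
    p_l : per-copy probability of loss (= p_h + p_d at stationarity)
    N   : number of species genomes (>= 2)
    """

    p_h: float
    p_d: float
    p_l: float
    N: int


@dataclass
class AbundanceState:
    """Copy numbers of one family across N species; ``t`` in sweeps."""

    V: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.int64)
        if self.V.ndim != 1:
            raise ValueError("V must be one-dimensional")
        if (self.V < 0).any():
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class CollisionKernel:
    """Symmetric non-negative pair weights W_ij (zero diagonal) biasing
    which genome pairs collide."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("kernel must be a square matrix")
        if not np.allclose(W, W.T):
            raise ValueError("kernel must be symmetric")
        if (W < 0).any():
            raise ValueError("kernel weights must be non-negative")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        if not (W > 0).any():
            raise ValueError("kernel needs at least one positive off-diagonal weight")
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class Trajectory:
    """Recorded ensemble moments of V over a run plus the final state."""

    times: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    skewnesses: np.ndarray
    final_state: AbundanceState
    params: ModelParams | None = field(default=None, repr=False)


def validate_params(p_h: float, p_d: float, p_l: float | None, N: int) -> ModelParams:
    """Validate collision rates; if ``p_l`` is omitted it is set to p_h + p_d.

    Rejects parameterizations that are non-stationary (p_h + p_d != p_l) or
    whose per-copy outcomes are not probabilities (p_d + p_l > 1).
    """
    if p_l is None:
        p_l = p_h + p_d
    for name, p in (("p_h", p_h), ("p_d", p_d), ("p_l", p_l)):
        if not np.isfinite(p) or p < 0 or p > 1:
            raise ValueError(f"{name}={p} is not a probability")
    if abs((p_h + p_d) - p_l) > _RATE_TOL:
        raise ValueError(
            f"non-stationary rates: p_h + p_d = {p_h + p_d} != p_l = {p_l}"
        )
    if p_d + p_l > 1 + _RATE_TOL:
        raise ValueError(f"p_d + p_l = {p_d + p_l} exceeds 1")
    N = int(N)
    if N < 2:
        raise ValueError("need at least two species")
    return ModelParams(float(p_h), float(p_d), float(p_l), N)


def initialize_state(N: int, init) -> AbundanceState:
    """All-species initial condition: scalar broadcast or length-N vector."""
    N = int(N)
    if np.isscalar(init):
        if init < 0:
            raise ValueError("initial abundance must be non-negative")
        V = np.full(N, int(init), dtype=np.int64)
    else:
        V = np.asarray(init, dtype=np.int64)
        if V.shape != (N,):
            raise ValueError(f"initial vector has length {V.size}, expected {N}")
        if (V < 0).any():
            raise ValueError("initial abundances must be non-negative")
        V = V.copy()
    return AbundanceState(V=V, t=0.0)


def collide_pair(
    state: AbundanceState,
    i: int,
    j: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> AbundanceState:
    """One collision between genomes i and j (reference numpy implementation).

    Gains are Binomial(V_partner, p_h); each own copy is, exclusively, lost /
    duplicated / kept with probabilities (p_l, p_d, 1 - p_l - p_d).  All draws
    use pre-collision abundances and both partners update simultaneously.
    """
    if i == j:
        raise ValueError("a genome cannot collide with itself")
    V = state.V.copy()
    vi, vj = int(V[i]), int(V[j])
    probs = (params.p_l, params.p_d, 1.0 - params.p_l - params.p_d)
    gain_i = rng.binomial(vj, params.p_h)
    gain_j = rng.binomial(vi, params.p_h)
    loss_i, dup_i, _ = rng.multinomial(vi, probs)
    loss_j, dup_j, _ = rng.multinomial(vj, probs)
    V[i] = vi + gain_i + dup_i - loss_i
    V[j] = vj + gain_j + dup_j - loss_j
    return AbundanceState(V=V, t=state.t)


def _kernel_arrays(kernel: CollisionKernel):
    iu, ju = np.triu_indices(kernel.n, k=1)
    w = kernel.W[iu, ju]
    keep = w > 0
    return np.cumsum(w[keep]), iu[keep].astype(np.int64), ju[keep].astype(np.int64)


def run_simulation(
    params: ModelParams,
    state: AbundanceState,
    n_sweeps: int,
    record_interval: int = 1,
    seed: int = 0,
    kernel: CollisionKernel | None = None,
) -> Trajectory:
    """Run ``n_sweeps`` sweeps (N collisions each) from ``state``.

    Records ensemble mean/variance/skewness at t=0 and every
    ``record_interval`` sweeps.  Identical seeds give identical trajectories.
    """
    n_sweeps = int(n_sweeps)
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    record_interval = int(record_interval)
    if record_interval < 1:
        raise ValueError("record_interval must be >= 1")
    if state.V.size != params.N:
        raise ValueError("state size does not match params.N")
    if kernel is not None:
        if kernel.n != params.N:
            raise ValueError(
                f"kernel dimension {kernel.n} does not match N={params.N}"
            )
        cum_w, pair_i, pair_j = _kernel_arrays(kernel)
        use_kernel = True
    else:
        cum_w = np.ones(1)
        pair_i = np.zeros(1, dtype=np.int64)
        pair_j = np.ones(1, dtype=np.int64)
        use_kernel = False
    V = state.V.copy()
    times, means, variances, skews, V = _kernel.run_collisions(
        V,
        params.p_h,
        params.p_d,
        params.p_l,
        n_sweeps,
        record_interval,
        int(seed),
        use_kernel,
        cum_w,
        pair_i,
        pair_j,
    )
    final = AbundanceState(V=V, t=state.t + n_sweeps)
    return Trajectory(
        times=times,
        means=means,
        variances=variances,
        skewnesses=skews,
        final_state=final,
        params=params,
    )


def abundance_histogram(state: AbundanceState) -> np.ndarray:
    """Empirical probability vector over v = 0..max(V); sums to 1."""
    counts = np.bincount(state.V)
    return counts / counts.sum()


def exponential_kernel(distances: np.ndarray, d0: float) -> CollisionKernel:
    """Distance-biased kernel W_ij = exp(-d_ij / d0): collisions become less
    probable with increasing (phylogenetic) distance."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    D = np.asarray(distances, dtype=float)
    return CollisionKernel(W=np.exp(-D / d0))


def stationary_sweeps(p_h: float, factor: float = 10.0) -> float:
    """Default burn-in before calling a run stationary: ``factor`` relaxation
    times, i.e. factor / (p_h (1 - p_h)) sweeps."""
    if not 0 < p_h < 1:
        raise ValueError("p_h must lie strictly between 0 and 1")
    return factor / (p_h * (1.0 - p_h))
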