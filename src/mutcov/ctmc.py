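"""Continuous-time Markov chain rate estimation for movement states.

Worm locomotion is summarized as a three-state process (still ``S``,
forward ``F``, backward ``B``) observed at a fixed frame rate.  The
instantaneous dynamics are governed by a 3x3 generator matrix ``Q``
whose off-diagonal entries ``q_ij >= 0`` are the transition rates
(per second) between distinct states and whose diagonal entries are
constrained so that every row sums to zero:

    q_ii = -sum_{j != i} q_ij

Only the six off-diagonal rates are free parameters; self-transitions
are not modelled.  Because the chain is observed only at frame times,
the likelihood of the data depends on ``Q`` through the interval
transition-probability matrix ``P(dt) = expm(Q * dt)``.  The sufficient
statistic is the 3x3 table of consecutive-frame transition counts, and
the six log-rates are estimated by maximizing

    ll(Q) = sum_ij n_ij * ln P_ij(dt)

in unconstrained log-rate space.  An optional random-walk Metropolis
sampler over the log-rates is provided for posterior-mean estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

#: Canonical state order used for all 3x3 matrices.
STATES: tuple[str, ...] = ("S", "F", "B")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: Off-diagonal (row, col) index pairs in trait order.
OFF_DIAGONAL: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1),
)

#: Trait labels matching OFF_DIAGONAL: source state then destination state.
TRAITS: tuple[str, ...] = ("SF", "SB", "FS", "FB", "BS", "BF")

#: Lower floor (per second) for rates that the data cannot identify.
RATE_FLOOR: float = 1e-8

_ROW_SUM_TOL = 1e-12


class RateMatrixError(ValueError):
    """Raised when a generator matrix violates the CTMC structure."""


@dataclass(frozen=True)
class RateMatrix:
    """A valid 3x3 CTMC generator over the states (S, F, B).

    Off-diagonal entries are transition rates in s^-1; each diagonal
    entry is minus the sum of its row's off-diagonals.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (3, 3):
            raise RateMatrixError(f"Q must be 3x3, got {q.shape}")
        off = q[~np.eye(3, dtype=bool)]
        if np.any(off < 0):
            raise RateMatrixError("off-diagonal rates must be non-negative")
        if np.any(np.abs(q.sum(axis=1)) > _ROW_SUM_TOL * max(1.0, np.abs(q).max())):
            raise RateMatrixError("rows of Q must sum to zero")
        object.__setattr__(self, "q", q)

    @classmethod
    def from_rates(cls, rates: Sequence[float]) -> "RateMatrix":
        """Build a generator from the six off-diagonal rates in TRAITS order."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (6,):
            raise RateMatrixError("expected six off-diagonal rates")
        q = np.zeros((3, 3))
        for (i, j), r in zip(OFF_DIAGONAL, rates):
            q[i, j] = r
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(q)

    @property
    def rates(self) -> np.ndarray:
        """The six off-diagonal rates in TRAITS order."""
        return np.array([self.q[i, j] for i, j in OFF_DIAGONAL])

    def stationary_distribution(self) -> np.ndarray:
        """Solve pi @ Q = 0 with pi >= 0, sum(pi) = 1 (requires ergodic Q)."""
        _, _, vt = np.linalg.svd(self.q.T)
        pi = np.abs(vt[-1])
        return pi / pi.sum()


@dataclass(frozen=True)
class StateSequence:
    """Movement states of one tracked object sampled at a fixed interval."""

    states: np.ndarray
    dt: float
    object_id: str = "0"

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype="U1")
        if states.size < 2:
            raise ValueError("a state sequence needs at least two observations")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        unknown = set(states.tolist()) - set(STATES)
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class TransitionCounts:
    """Consecutive-frame transition counts pooled over sequences."""

    n: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.shape != (3, 3) or np.any(n < 0):
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "n", n.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.n.sum())


def count_transitions(sequences: Iterable[StateSequence]) -> TransitionCounts:
    """Pool consecutive-frame transition counts across sequences.

    All sequences must share the same observation interval ``dt``.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences supplied")
    dt = sequences[0].dt
    n = np.zeros((3, 3), dtype=np.int64)
    for seq in sequences:
        if seq.dt != dt:
            raise ValueError(f"mixed dt: {seq.dt} != {dt}")
        idx = np.array([STATE_INDEX[s] for s in seq.states])
        np.add.at(n, (idx[:-1], idx[1:]), 1)
    return TransitionCounts(n=n, dt=dt)


def transition_probability(Q: RateMatrix, dt: float) -> np.ndarray:
    """Interval transition probabilities P(dt) = expm(Q * dt)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    P = expm(Q.q * dt)
    # expm of a generator is stochastic up to round-off; clip tiny negatives.
    P = np.clip(P, 0.0, None)
    return P


def log_likelihood(Q: RateMatrix, counts: TransitionCounts) -> float:
    """Discrete-observation log-likelihood sum_ij n_ij * ln P_ij(dt)."""
    P = transition_probability(Q, counts.dt)
    n = counts.n
    mask = n > 0
    if np.any(P[mask] <= 0):
        return -np.inf
    return float(np.sum(n[mask] * np.log(P[mask])))


def naive_rates(counts: TransitionCounts) -> np.ndarray:
    """First-order rate estimates q_ij = n_ij / (n_i * dt), floored.

    Exact only in the small-dt limit; used as the MLE initializer.
    """
    row_tot = counts.n.sum(axis=1)
    rates = np.empty(6)
    for k, (i, j) in enumerate(OFF_DIAGONAL):
        if row_tot[i] > 0:
            rates[k] = counts.n[i, j] / (row_tot[i] * counts.dt)
        else:
            rates[k] = RATE_FLOOR
    return np.maximum(rates, RATE_FLOOR)


@dataclass
class RateFit:
    """MLE of the six transition rates with fit diagnostics."""

    Q: RateMatrix
    log_lik: float
    converged: bool
    #: per-rate flags in TRAITS order: True where the rate is unidentifiable
    #: (source state never observed) or pinned at the lower floor.
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=bool))
    n_transitions: int = 0

    @property
    def log_rates(self) -> np.ndarray:
        return np.log(self.Q.rates)


_LOG_FLOOR = np.log(RATE_FLOOR)
_LOG_CEIL = np.log(1e3)


def fit_rates(counts: TransitionCounts, init: Optional[RateMatrix] = None) -> RateFit:
    """Maximum-likelihood fit of the six off-diagonal rates.

    Optimization runs in unconstrained log-rate space (which keeps every
    q_ij positive); the diagonal is reconstructed from the row-sum
    constraint.  Rates leaving a state that is never observed as a
    source are unidentifiable: they are pinned at RATE_FLOOR and
    flagged, never silently dropped.
    """
    if counts.total < 1:
        raise ValueError("need at least one observed transition")
    row_tot = counts.n.sum(axis=1)
    unidentifiable = np.array([row_tot[i] == 0 for i, _ in OFF_DIAGONAL])

    x0 = np.log(init.rates if init is not None else naive_rates(counts))
    x0 = np.clip(x0, _LOG_FLOOR, _LOG_CEIL)
    lo = np.full(6, _LOG_FLOOR)
    hi = np.full(6, _LOG_CEIL)
    hi[unidentifiable] = _LOG_FLOOR  # pin: lb == ub
    x0[unidentifiable] = _LOG_FLOOR

    def neg_ll(x: np.ndarray) -> float:
        Q = RateMatrix.from_rates(np.exp(x))
        return -log_likelihood(Q, counts)

    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
    rates = np.exp(res.x)
    at_floor = res.x <= _LOG_FLOOR + 1e-9
    fit = RateFit(
        Q=RateMatrix.from_rates(rates),
        log_lik=-float(res.fun),
        converged=bool(res.success),
        flagged=unidentifiable | at_floor,
        n_transitions=counts.total,
    )
    return fit


def sample_rates_posterior(
    counts: TransitionCounts,
    n_iter: int = 5000,
    rng: Optional[np.random.Generator] = None,
    proposal_sd: float = 0.05,
    prior_sd: float = 10.0,
    init: Optional[RateMatrix] = None,
) -> tuple[np.ndarray, float]:
    """Random-walk Metropolis over log-rates with independent normal priors.

    Returns (samples of the six log-rates, acceptance rate).  With the
    data volumes of a typical movie the posterior mean is numerically
    indistinguishable from the MLE; the sampler exists for parity checks.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.log((init or fit_rates(counts).Q).rates)

    def log_post(z: np.ndarray) -> float:
        ll = log_likelihood(RateMatrix.from_rates(np.exp(z)), counts)
        return ll - 0.5 * float(np.sum((z / prior_sd) ** 2))

    lp = log_post(x)
    samples = np.empty((n_iter, 6))
    accepted = 0
    for t in range(n_iter):
        prop = x + proposal_sd * rng.standard_normal(6)
        lp_prop = log_post(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        samples[t] = x
    return samples, accepted / n_iter


def summarize_plate_rates(
    sequences: Iterable[StateSequence],
) -> tuple[np.ndarray, RateFit]:
    """Per-plate natural-log transition rates in (SF, SB, FS, FB, BS, BF) order.

    Pools all sequences of the plate into transition counts, fits the
    rates by maximum likelihood and returns their natural logs together
    with the fit diagnostics (unidentifiability flags propagate).
    """
    counts = count_transitions(sequences)
    fit = fit_rates(counts)
    return fit.log_rates, fit
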