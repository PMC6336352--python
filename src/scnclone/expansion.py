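"""Fetal bone-marrow expansion with irreversible CSF3R mutation.

A time-continuous Markov branching process: the pooled HSC+CMP population is
initiated by a small number ``N0`` of ELANE-mutant ("wild-type" for our
purposes) cells, each dividing after an exponential interdivision time with
rate ``lam``.  At each wild-type division one daughter acquires the CSF3R
truncation with probability ``mu``; mutants breed true and, during the
expansion phase, are selectively neutral.

Expected counts (wild-type W and mutant i)::

    W(t) = N0 exp[(1 - mu) lam t]
    i(t) = N0 {exp(lam t) - exp[(1 - mu) lam t]}

Eliminating time, the expected mutant count when the population has grown to
size N is ``N - N0^mu N^(1-mu)``, which for small mu and moderate N0 is
``~ mu N ln N`` — the form inverted to back-calculate the mutation rate from
a required mutant count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpansionModel",
    "ExpansionSummary",
    "MutantExpectation",
    "expected_counts",
    "expected_mutants_at_size",
    "mutation_rate_for_target",
    "time_to_size",
    "simulate_expansion_exact",
    "simulate_expansion_exact_many",
    "simulate_expansion_fast",
    "simulate_expansion_fast_many",
]


@dataclass(frozen=True)
class ExpansionModel:
    """Branching-process parameters of the fetal expansion phase."""

    n0: int = 1
    lam: float = 0.25  # divisions per day (mean interdivision time 1/lam)
    mu: float = 1e-8
    neutral: bool = True  # mutants share lam during expansion

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must lie in [0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not self.neutral:
            raise ValueError(
                "mutants are neutral during the expansion phase; selection "
                "enters only in the postnatal takeover model"
            )


@dataclass(frozen=True)
class ExpansionSummary:
    """Expected counts at time t (days since the start of the expansion)."""

    t: float
    n_wildtype: float
    i_expected: float

    @property
    def n_total(self) -> float:
        return self.n_wildtype + self.i_expected


class MutantExpectation(float):
    """Approximate expectation ``mu N ln N`` carrying the exact form too."""

    exact: float

    def __new__(cls, approx: float, exact: float):
        obj = super().__new__(cls, approx)
        obj.exact = exact
        return obj


def expected_counts(model: ExpansionModel, t: float) -> ExpansionSummary:
    """Expected wild-type and mutant counts after ``t`` days of expansion."""
    if t < 0:
        raise ValueError("t must be >= 0")
    n0, lam, mu = model.n0, model.lam, model.mu
    wt = n0 * math.exp((1.0 - mu) * lam * t)
    total = n0 * math.exp(lam * t)
    return ExpansionSummary(t=t, n_wildtype=wt, i_expected=total - wt)


def expected_mutants_at_size(
    N_final: float, mu: float, N0: float = 1.0
) -> MutantExpectation:
    """Expected mutant count when the population has expanded to ``N_final``.

    Returns the approximation ``mu N ln N`` (valid for small mu, moderate
    N0), as a float whose ``.exact`` attribute holds the exact branching
    form ``N - N0^mu N^(1-mu)``.
    """
    if N_final <= N0 or N0 < 1:
        raise ValueError("need N_final > N0 >= 1")
    exact = N_final - N0**mu * N_final ** (1.0 - mu)
    approx = mu * N_final * math.log(N_final)
    return MutantExpectation(approx, exact)


def mutation_rate_for_target(i_target: float, N_final: float) -> float:
    """Mutation rate per division producing ``i_target`` expected mutants.

    Inverts the approximation ``i = mu N ln N``.
    """
    if i_target <= 0:
        raise ValueError("i_target must be positive")
    if N_final <= math.e:
        raise ValueError("N_final must exceed e for the log to be positive")
    return i_target / (N_final * math.log(N_final))


def time_to_size(model: ExpansionModel, N_final: float) -> float:
    """Days for the expected wild-type count to reach ``N_final``."""
    if N_final < model.n0:
        raise ValueError("N_final must be >= n0")
    return math.log(N_final / model.n0) / ((1.0 - model.mu) * model.lam)


def simulate_expansion_exact_many(
    model: ExpansionModel, N_stop: int, reps: int, rng_seed: int
) -> np.ndarray:
    """Mutant counts at population size ``N_stop``, one per replicate.

    Simulates the embedded jump chain of the branching process: with no
    death, the population grows by one cell per division and the dividing
    cell is uniform among living cells (a Yule process), so only the
    sequence of divisions matters, not the exponential clock.  Each
    wild-type division produces one mutant daughter with probability mu.
    """
    if N_stop > 10**6:
        raise ValueError("per-division simulation intended for N_stop <= 1e6")
    if N_stop < model.n0:
        raise ValueError("N_stop must be >= n0")
    rng = np.random.default_rng(rng_seed)
    mu = model.mu
    m = np.zeros(reps, dtype=np.int64)
    for k in range(model.n0, N_stop):  # population size before the division
        dividing_mutant = rng.random(reps) * k < m
        mutated = ~dividing_mutant & (rng.random(reps) < mu)
        m += dividing_mutant + mutated
    return m


def simulate_expansion_exact(
    model: ExpansionModel, N_stop: int, rng_seed: int
) -> int:
    """Single-replicate convenience wrapper around the exact simulator."""
    return int(simulate_expansion_exact_many(model, N_stop, 1, rng_seed)[0])


def simulate_expansion_fast_many(
    model: ExpansionModel, N_stop: float, reps: int, rng_seed: int
) -> np.ndarray:
    """Large-N sampler of the mutant count at population size ``N_stop``.

    Mutation events are thinned over the division sequence: the division
    taking the population from size k to k+1 founds a mutant clone with
    probability ``mu`` (wild-type depletion is negligible for small mu), so
    the event count is Poisson(mu (N_stop - n0)) with founding sizes k
    uniform on [n0, N_stop).  A clone founded as 1 cell among k+1 grows
    under neutral uniform attachment (Polya urn), so its final size is
    ``1 + X`` with ``X | p ~ Binomial(N_stop - k - 1, p)``, ``p ~ Beta(1, k)``
    — the beta-binomial clone-size law tested against the exact simulator.
    """
    rng = np.random.default_rng(rng_seed)
    n0 = model.n0
    N_stop = int(N_stop)
    if N_stop <= n0:
        raise ValueError("N_stop must exceed n0")
    counts = np.zeros(reps, dtype=np.int64)
    if model.mu == 0:
        return counts
    n_events = rng.poisson(model.mu * (N_stop - n0), size=reps)
    for r in range(reps):
        ne = n_events[r]
        if ne == 0:
            continue
        k = rng.integers(n0, N_stop, size=ne)  # size before the mutating division
        p = rng.beta(1.0, k.astype(float))
        extra = rng.binomial(N_stop - k - 1, p)
        counts[r] = ne + extra.sum()
    return counts


def simulate_expansion_fast(
    model: ExpansionModel, N_stop: float, rng_seed: int
) -> int:
    return int(simulate_expansion_fast_many(model, N_stop, 1, rng_seed)[0])
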