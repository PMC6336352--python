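"""Constant-size Moran process with directional selection.

The proof-of-principle model of postnatal clonal takeover: a population of
``N`` granulocyte precursor cells in which ``i`` carry the CSF3R-truncation
mutation.  At each step one cell dies (uniformly) and is replaced by the
offspring of a cell drawn with odds ``r = 1 + s`` in favour of the mutant.

Closed forms used here::

    P[fixation]        = (1 - (1-s)^i) / (1 - (1-s)^N)
    E[T_fix | fix]     = (2 ln N - ln i) / s       (cell-division units)

The module also provides an exact absorbing-chain oracle (dense/banded
linear solve, feasible for N <= 5000) and a stochastic simulator, both used
to validate the closed forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .constants import (
    BIRTH_POOL_3KG,
    DIVISIONS_PER_YEAR,
    FIXATION_PROBABILITY_TARGET,
    N_ADULT,
    TABLE1_S_VALUES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MoranModel",
    "FixationSummary",
    "fixation_probability",
    "required_initial_mutants",
    "conditional_fixation_time",
    "exact_fixation_oracle",
    "simulate_moran",
    "simulate_moran_many",
    "divisions_to_years",
    "proof_of_principle_table",
]


@dataclass(frozen=True)
class MoranModel:
    """Parameters of the constant-size Moran model.

    N may be as large as the adult HSC+CMP pool (~1.5e10); the analytic
    routes below remain numerically stable there.  ``i`` may be a
    non-integer when used analytically (e.g. the unrounded required count).
    """

    N: float
    s: float
    i: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not -1 < self.s:
            raise ValueError("selection coefficient must satisfy s > -1")
        if not 0 <= self.i <= self.N:
            raise ValueError("initial mutant count must lie in [0, N]")

    @property
    def r(self) -> float:
        """Relative fitness of the mutant, r = 1 + s."""
        return 1.0 + self.s


@dataclass(frozen=True)
class FixationSummary:
    p_fix: float
    t_fix_divisions: float
    t_fix_years: float
    divisions_per_year: float


def fixation_probability(N: float, s: float, i: float) -> float:
    """Probability that ``i`` mutants with selection ``s`` fix in a pool of ``N``.

    Evaluates ``(1-(1-s)^i) / (1-(1-s)^N)`` via ``expm1``/``log1p`` so that
    the huge-N regime (where ``(1-s)^N`` underflows for s > 0, or overflows
    for s < 0) is handled without loss of precision.

    For ``s == 0`` the neutral limit ``i / N`` is returned with a log note
    rather than raising, so parameter sweeps may cross zero.
    """
    if not 0 <= i <= N:
        raise ValueError("i must lie in [0, N]")
    if i == 0:
        return 0.0
    if i == N:
        return 1.0
    if s == 0:
        logger.info("s = 0: returning the neutral fixation probability i/N")
        return i / N
    L = math.log1p(-s)  # log(1 - s)
    a, b = i * L, N * L
    if b > 700.0:  # s < 0 with N huge: (1-s)^N overflows; work in log space
        return math.exp(a - b) * (-math.expm1(-a))
    return math.expm1(a) / math.expm1(b)


def required_initial_mutants(
    N: float, s: float, p_target: float = FIXATION_PROBABILITY_TARGET
) -> tuple[float, int]:
    """Initial mutant count whose fixation probability equals ``p_target``.

    Inverts the fixation-probability formula:
    ``i = log_{1-s}(1 - p [1 - (1-s)^N])``.  Returns the unrounded solution
    and its nearest integer (half away from zero, matching the convention
    used to print the proof-of-principle table).
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must lie in (0, 1)")
    if not 0 < s < 1:
        raise ValueError("the log base 1-s requires s in (0, 1)")
    L = math.log1p(-s)
    one_minus_pow = -math.expm1(N * L)  # 1 - (1-s)^N, -> 1 for large N
    i_real = math.log1p(-p_target * one_minus_pow) / L
    i_rounded = int(math.floor(i_real + 0.5))
    return i_real, i_rounded


def conditional_fixation_time(
    N: float,
    s: float,
    i: float,
    divisions_per_year: float = DIVISIONS_PER_YEAR,
) -> FixationSummary:
    """Expected time to fixation given fixation, ``(2 ln N - ln i)/s``.

    The asymptotic (large N, small i, s > 0) conditional absorption time of
    the Moran chain, in cell-division units; converted to years at
    ``divisions_per_year`` (default 365/4, one division per 4 days).
    """
    if not 0 < i < N:
        raise ValueError("need 0 < i < N (otherwise already absorbed)")
    if s <= 0:
        raise ValueError("the asymptotic conditional time requires s > 0")
    t_div = (2.0 * math.log(N) - math.log(i)) / s
    return FixationSummary(
        p_fix=fixation_probability(N, s, i),
        t_fix_divisions=t_div,
        t_fix_years=t_div / divisions_per_year,
        divisions_per_year=divisions_per_year,
    )


def divisions_to_years(
    divisions: float, divisions_per_year: float = DIVISIONS_PER_YEAR
) -> float:
    if divisions < 0:
        raise ValueError("divisions must be >= 0")
    return divisions / divisions_per_year


def _step_probabilities(N: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-step up/down probabilities of the birth-death chain, states 0..N."""
    k = np.arange(N + 1, dtype=float)
    denom = (r * k + (N - k)) * N
    up = r * k * (N - k) / denom
    down = k * (N - k) / denom
    return up, down


def exact_fixation_oracle(N: int, s: float, i: int) -> tuple[float, float]:
    """Fixation probability and conditional absorption time by linear solve.

    Builds the (N+1)-state absorbing birth-death chain and solves the
    standard linear systems: harmonicity for the fixation probability and
    the Doob h-transformed one-step equations for the expected number of
    Moran steps to fixation, conditional on fixation.  Independent of the
    closed forms above (which replace ``(1+s)^{-i}`` by ``(1-s)^i``).

    Returns ``(p_fix, conditional_mean_steps)``; one Moran step is one
    death-replacement event, so ``steps / N`` is time in cell-division
    (generation) units.
    """
    if N > 5000:
        raise ValueError("N too large for the dense oracle; use the analytic route")
    if not 0 <= i <= N:
        raise ValueError("i must lie in [0, N]")
    r = 1.0 + s
    up, down = _step_probabilities(N, r)

    # Fixation probability: (up+down) pi_k - up pi_{k+1} - down pi_{k-1} = 0,
    # pi_0 = 0, pi_N = 1; tridiagonal solve over interior states 1..N-1.
    n_int = N - 1
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -up[1 : N - 1]          # superdiagonal
    ab[1, :] = up[1:N] + down[1:N]      # diagonal
    ab[2, :-1] = -down[2:N]             # subdiagonal
    rhs = np.zeros(n_int)
    rhs[-1] = up[N - 1]                 # pi_N = 1 boundary
    pi = np.empty(N + 1)
    pi[0], pi[N] = 0.0, 1.0
    pi[1:N] = solve_banded((1, 1), ab, rhs)

    if i == 0:
        return 0.0, math.nan
    if i == N:
        return 1.0, 0.0

    # Conditional time: transform to the chain conditioned on fixation,
    # up~_k = up_k pi_{k+1}/pi_k, down~_k = down_k pi_{k-1}/pi_k (zero at
    # k=1 since pi_0 = 0); holding steps are counted, so
    # (up~+down~) tau_k - up~ tau_{k+1} - down~ tau_{k-1} = 1, tau_N = 0.
    upc = up[1:N] * pi[2 : N + 1] / pi[1:N]
    downc = down[1:N] * pi[0 : N - 1] / pi[1:N]
    ab_t = np.zeros((3, n_int))
    ab_t[0, 1:] = -upc[:-1]
    ab_t[1, :] = upc + downc
    ab_t[2, :-1] = -downc[1:]
    rhs_t = np.ones(n_int)  # tau_N = 0 boundary adds nothing
    tau = solve_banded((1, 1), ab_t, rhs_t)
    return float(pi[i]), float(tau[i - 1])


class MoranRealization(NamedTuple):
    fixed: bool
    absorbed: bool
    steps: int


def simulate_moran(
    N: int, s: float, i: int, rng_seed: int, max_steps: int = 10**9
) -> MoranRealization:
    """Simulate one Moran trajectory until absorption (or ``max_steps``).

    Exploits the structure of the chain: given that the composition changes,
    the move is up with probability r/(1+r) independently of the state, and
    the number of holding steps at state k is geometric with success
    probability ``up_k + down_k``.  Exactly equivalent in law to stepping
    the chain one death-replacement at a time, but much faster.
    """
    if N > 10**5:
        raise ValueError("direct simulation is intended for N <= 1e5")
    rng = np.random.default_rng(rng_seed)
    r = 1.0 + s
    p_up_given_change = r / (1.0 + r)
    k = i
    steps = 0
    while 0 < k < N:
        denom = (r * k + (N - k)) * N
        p_change = (r + 1.0) * k * (N - k) / denom
        steps += rng.geometric(p_change)
        if steps > max_steps:
            return MoranRealization(fixed=False, absorbed=False, steps=max_steps)
        k += 1 if rng.random() < p_up_given_change else -1
    return MoranRealization(fixed=(k == N), absorbed=True, steps=steps)


def simulate_moran_many(
    N: int, s: float, i: int, reps: int, rng_seed: int
) -> np.ndarray:
    """Vectorised fixation outcomes of ``reps`` independent trajectories.

    Returns a boolean array (True = fixation).  Holding steps are not
    tracked; only the embedded jump chain (a biased simple random walk with
    up-probability r/(1+r)) is simulated.
    """
    rng = np.random.default_rng(rng_seed)
    r = 1.0 + s
    p_up = r / (1.0 + r)
    state = np.full(reps, i, dtype=np.int64)
    active = (state > 0) & (state < N)
    while active.any():
        moves = np.where(rng.random(active.sum()) < p_up, 1, -1)
        state[active] += moves
        active = (state > 0) & (state < N)
    return state == N


def proof_of_principle_table(
    s_values: Sequence[float] = TABLE1_S_VALUES,
    N: float = N_ADULT,
    p_target: float = FIXATION_PROBABILITY_TARGET,
    birth_pool: float = BIRTH_POOL_3KG,
    divisions_per_year: float = DIVISIONS_PER_YEAR,
    use_unrounded_i: bool = True,
):
    """Regenerate the proof-of-principle summary table.

    For each selection coefficient: the initial mutant count required for
    fixation probability ``p_target`` (unrounded and rounded), the fetal
    mutation rate that yields that count by the end of the expansion to
    ``birth_pool`` cells, and the expected age at fixation in years.

    ``use_unrounded_i`` feeds the unrounded count into the time formula and
    the mutation-rate inversion (the convention that best matches the
    published values); set False to use the rounded count throughout.
    """
    import pandas as pd

    from .expansion import mutation_rate_for_target

    rows = []
    for s in s_values:
        i_real, i_rounded = required_initial_mutants(N, s, p_target)
        i_used = i_real if use_unrounded_i else float(i_rounded)
        summary = conditional_fixation_time(N, s, i_used, divisions_per_year)
        mu = mutation_rate_for_target(i_used, birth_pool)
        rows.append(
            {
                "s": s,
                "i_real": i_real,
                "i_rounded": i_rounded,
                "mu": mu,
                "E_years": summary.t_fix_years,
            }
        )
    return pd.DataFrame(rows)
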