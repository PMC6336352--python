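"""Clonal takeover of CSF3R-truncation mutants in a growing CMP pool.

A Moran-type process with time-varying population size N(t) (the CMP
compartment of the hematopoiesis model), recurrent wild-type -> mutant
mutation at probability ``mu`` per division, and a selection coefficient
that switches from 0 to ``s_gcsf`` when chronic G-CSF therapy starts
(default: age six months).  Mutant influx from the HSC compartment is
disregarded.

Per-cell simulation at N ~ 1e10 is infeasible, so a hybrid engine is used:

* **Stochastic phase** (mutant count M below ``exact_threshold``):
  tau-leaping of the continuous-time Moran rates.  With turnover rate b
  (one death-replacement per cell per interdivision time) the transition
  rates are ``up = b (1+s) M (N-M) / ((1+s)M + N-M) + g M`` and
  ``down = b M (N-M) / ((1+s)M + N-M)`` where ``g = d ln N/dt``, so neutral
  lineages are critical at constant N and track N(t) otherwise.  New
  mutants arrive as a Poisson stream at rate ``mu x (wild-type divisions
  per day)``.  Before birth the pool expands without turnover (pure
  growth, matching the fetal branching model): divisions occur at rate g.

* **Deterministic phase** (M at or above the threshold): once thousands of
  mutant cells exist, drift is negligible and the mutant fraction f obeys
  ``df/dt = s(t) b f (1-f) + mu b (1-f)`` on top of N(t).

Replacement ("fixation" at this resolution) is the first age with
f >= ``replacement_fraction`` (default 0.99; the last few wild-type cells
of a 1e10 pool take a biologically irrelevant extra time to disappear).
With recurrent mutation, fixation is certain — only its timing is random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import B_CMP, DAYS_PER_YEAR, GCSF_START_DAYS

__all__ = [
    "HybridSimConfig",
    "ReplacementSimResult",
    "simulate_replacement",
    "simulate_replacement_many",
    "sweep_nomogram",
    "selection_for_age",
    "mutants_at_age",
]


@dataclass(frozen=True)
class HybridSimConfig:
    """Parameters of the hybrid takeover simulation."""

    mu: float = 2.5e-9
    s_gcsf: float = 0.014
    t_gcsf: float = GCSF_START_DAYS      # days
    b: float = B_CMP                     # CMP turnover (divisions/cell/day)
    exact_threshold: float = 1e4         # switch M to deterministic phase
    replacement_fraction: float = 0.99
    seed: int = 0
    t_max_years: float = 40.0
    dt: float = 1.0                      # tau-leap / ODE step, days

    def __post_init__(self) -> None:
        if not 0 < self.replacement_fraction <= 1:
            raise ValueError("replacement_fraction must lie in (0, 1]")
        if self.exact_threshold < 1:
            raise ValueError("exact_threshold must be >= 1")
        if self.mu < 0 or self.s_gcsf < -1:
            raise ValueError("invalid mu or s_gcsf")


@dataclass
class ReplacementSimResult:
    """Outcome of one replicate set of the takeover simulation."""

    age_at_replacement: np.ndarray   # years; NaN where censored at t_max
    censored: np.ndarray             # bool per replicate
    checkpoint_ages: np.ndarray      # years
    mutant_counts: np.ndarray        # (reps, n_checkpoints)
    mutant_count_age1: np.ndarray    # count at age 1 yr per replicate
    engine_switch_age: np.ndarray    # years; NaN if never left phase A
    config: HybridSimConfig = field(repr=False, default=None)


def _rk4_logistic(f, s, b, mu, dt):
    """One RK4 step of df/dt = s b f(1-f) + mu b (1-f) (vectorised)."""

    def rhs(x):
        return s * b * x * (1.0 - x) + mu * b * (1.0 - x)

    k1 = rhs(f)
    k2 = rhs(f + 0.5 * dt * k1)
    k3 = rhs(f + 0.5 * dt * k2)
    k4 = rhs(f + dt * k3)
    return f + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_replacement_many(
    config: HybridSimConfig,
    trajectory,
    reps: int = 1,
    checkpoint_ages_years: np.ndarray | None = None,
    initial_mutants: int = 0,
    t_start: float | None = None,
) -> ReplacementSimResult:
    """Run ``reps`` independent replicates of the hybrid takeover model.

    ``trajectory`` must provide ``cmp_count(t)`` and ``cmp_growth_rate(t)``
    for ages in days (see :mod:`scnclone.hematopoiesis`).  ``t_start``
    defaults to the trajectory's first age (the fetal marrow onset) for
    compartment trajectories and 0 for constant ones.  ``initial_mutants``
    seeds M at t_start (0: all mutants arise by recurrent mutation).
    """
    rng = np.random.default_rng(config.seed)
    if t_start is None:
        t_start = float(getattr(trajectory, "ages", np.array([0.0]))[0])
    t_end = config.t_max_years * DAYS_PER_YEAR
    dt = config.dt
    tgrid = np.arange(t_start, t_end + dt, dt)
    N = np.maximum(np.asarray(trajectory.cmp_count(tgrid), dtype=float), 1.0)
    g = np.asarray(trajectory.cmp_growth_rate(tgrid), dtype=float)

    if checkpoint_ages_years is None:
        checkpoint_ages_years = np.arange(0.0, config.t_max_years + 1e-9, 1.0)
    checkpoint_ages_years = np.asarray(checkpoint_ages_years, dtype=float)
    n_cp = len(checkpoint_ages_years)
    cp_days = checkpoint_ages_years * DAYS_PER_YEAR
    next_cp = np.searchsorted(cp_days, t_start)

    M = np.full(reps, float(initial_mutants))
    f = np.zeros(reps)
    in_det = np.zeros(reps, dtype=bool)
    done = np.zeros(reps, dtype=bool)
    t_replace = np.full(reps, np.nan)
    t_switch = np.full(reps, np.nan)
    counts = np.zeros((reps, n_cp))
    count_age1 = np.full(reps, np.nan)

    for k in range(len(tgrid) - 1):
        t = tgrid[k]
        Nk, gk = N[k], g[k]
        s_t = config.s_gcsf if t >= config.t_gcsf else 0.0
        turnover = config.b if t >= 0.0 else 0.0
        growth = max(gk, 0.0)

        # --- stochastic phase ---------------------------------------------
        sto = ~done & ~in_det
        if sto.any():
            m = M[sto]
            wt = np.maximum(Nk - m, 0.0)
            denom = (1.0 + s_t) * m + wt
            with np.errstate(invalid="ignore"):
                moran = np.where(denom > 0, turnover * m * wt / denom, 0.0)
            up = (1.0 + s_t) * moran + growth * m
            down = moran
            influx = config.mu * (turnover + growth) * wt
            dm = (
                rng.poisson(up * dt)
                - rng.poisson(down * dt)
                + rng.poisson(influx * dt)
            )
            m = np.clip(m + dm, 0.0, Nk)
            M[sto] = m
            # replacement can be reached inside the stochastic phase when
            # the threshold exceeds replacement_fraction * N (small pools)
            reached = sto.copy()
            reached[sto] = m >= config.replacement_fraction * Nk
            if reached.any():
                done[reached] = True
                t_replace[reached] = (t + dt) / DAYS_PER_YEAR
            # promote to the deterministic phase
            promote = sto & ~done
            promote[promote] = M[promote] >= config.exact_threshold
            if promote.any():
                f[promote] = M[promote] / Nk
                in_det[promote] = True
                t_switch[promote] = np.where(
                    np.isnan(t_switch[promote]), t / DAYS_PER_YEAR, t_switch[promote]
                )

        # --- deterministic phase ------------------------------------------
        det = ~done & in_det
        if det.any():
            f[det] = np.clip(
                _rk4_logistic(f[det], s_t, turnover, config.mu, dt), 0.0, 1.0
            )
            M[det] = f[det] * N[k + 1]
            reached = det.copy()
            reached[det] = f[det] >= config.replacement_fraction
            if reached.any():
                done[reached] = True
                t_replace[reached] = (t + dt) / DAYS_PER_YEAR

        # --- checkpoints ---------------------------------------------------
        t_next = tgrid[k + 1]
        while next_cp < n_cp and cp_days[next_cp] <= t_next:
            counts[:, next_cp] = np.where(done, N[k + 1], np.where(in_det, f * N[k + 1], M))
            next_cp += 1

        # all replicates resolved (fixed, or extinct with no further influx)
        if next_cp >= n_cp and (done | ((M == 0) & ~in_det & (config.mu == 0))).all():
            break

    # count at age 1 yr from the checkpoint grid if present, else NaN
    idx1 = np.where(np.isclose(checkpoint_ages_years, 1.0))[0]
    if idx1.size:
        count_age1 = counts[:, idx1[0]]

    return ReplacementSimResult(
        age_at_replacement=t_replace,
        censored=np.isnan(t_replace),
        checkpoint_ages=checkpoint_ages_years,
        mutant_counts=counts,
        mutant_count_age1=count_age1,
        engine_switch_age=t_switch,
        config=config,
    )


def simulate_replacement(
    config: HybridSimConfig, trajectory, **kwargs
) -> ReplacementSimResult:
    """Single-replicate convenience wrapper."""
    return simulate_replacement_many(config, trajectory, reps=1, **kwargs)


def sweep_nomogram(
    mu_grid,
    s_grid,
    trajectory,
    reps: int = 20,
    seed: int = 0,
    **config_kwargs,
):
    """Mean age at replacement (years) over a (mu, s) grid.

    Returns a DataFrame with mutation rates as rows and selection
    coefficients as columns; censored replicates enter as NaN and are
    excluded from the mean.  Paired seeds (one per grid cell derived from
    ``seed``) keep columns comparable.
    """
    import pandas as pd

    mu_grid = np.asarray(mu_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    out = np.full((len(mu_grid), len(s_grid)), np.nan)
    for i, mu in enumerate(mu_grid):
        for j, s in enumerate(s_grid):
            cfg = HybridSimConfig(mu=mu, s_gcsf=s, seed=seed + i, **config_kwargs)
            res = simulate_replacement_many(cfg, trajectory, reps=reps)
            ages = res.age_at_replacement
            if np.isfinite(ages).any():
                out[i, j] = np.nanmean(ages)
    return pd.DataFrame(out, index=mu_grid, columns=s_grid)


def selection_for_age(
    mu: float,
    target_age_yr: float,
    trajectory,
    reps: int = 20,
    tol: float = 0.02,
    s_bracket: tuple[float, float] = (1e-3, 0.5),
    seed: int = 0,
    t_max_years: float = 60.0,
    **config_kwargs,
) -> float:
    """Selection coefficient whose mean replacement age equals the target.

    Monotone bisection on the mean replacement age as a function of s,
    using common random numbers (the same seed at every s) so the curve is
    smooth.  ``tol`` is the relative tolerance on s.  Raises if the target
    age is unreachable inside ``s_bracket``.
    """
    if target_age_yr <= GCSF_START_DAYS / DAYS_PER_YEAR:
        raise ValueError("target age precedes the start of selection")

    def mean_age(s):
        cfg = HybridSimConfig(
            mu=mu, s_gcsf=s, seed=seed, t_max_years=t_max_years, **config_kwargs
        )
        res = simulate_replacement_many(cfg, trajectory, reps=reps)
        ages = res.age_at_replacement
        if np.isnan(ages).all():
            return np.inf
        return float(np.nanmean(np.where(np.isnan(ages), t_max_years, ages)))

    lo, hi = s_bracket
    a_hi = mean_age(hi)  # strongest selection -> earliest age
    if a_hi > target_age_yr:
        raise ValueError(
            f"target age {target_age_yr} yr unreachable: even s={hi} gives "
            f"mean age {a_hi:.1f} yr"
        )
    a_lo = mean_age(lo)
    if a_lo < target_age_yr:
        raise ValueError(
            f"target age {target_age_yr} yr unreachable: even s={lo} gives "
            f"mean age {a_lo:.1f} yr"
        )
    while hi / lo > 1.0 + tol:
        mid = math.sqrt(lo * hi)
        if mean_age(mid) > target_age_yr:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def mutants_at_age(
    mu: float,
    age_yr: float,
    trajectory,
    reps: int = 50,
    seed: int = 0,
    **config_kwargs,
) -> dict:
    """Replicate summary of the mutant count at a given age with s = 0.

    Intended for the pre-selection regime (the count before / shortly after
    G-CSF starts); returns mean, median and quartiles over replicates.
    """
    cfg = HybridSimConfig(
        mu=mu,
        s_gcsf=0.0,
        seed=seed,
        t_max_years=max(age_yr, 1.0) + 1.0,
        **config_kwargs,
    )
    res = simulate_replacement_many(
        cfg,
        trajectory,
        reps=reps,
        checkpoint_ages_years=np.array([age_yr]),
    )
    counts = res.mutant_counts[:, 0]
    return {
        "mu": mu,
        "age_yr": age_yr,
        "reps": reps,
        "mean": float(counts.mean()),
        "median": float(np.median(counts)),
        "q25": float(np.quantile(counts, 0.25)),
        "q75": float(np.quantile(counts, 0.75)),
    }
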