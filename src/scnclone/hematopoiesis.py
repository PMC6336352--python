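"""Age-dependent deterministic model of the granulocyte arm of hematopoiesis.

Two proliferating compartments — pluripotent HSC (P) and committed myeloid
progenitors/CMP (C) — feed the peripheral granulocyte pool.  Expectation
equations of the self-renewal/differentiation scheme::

    dP/dt = (2 c(t) - 1) a(t) P
    dC/dt = 2 (1 - c(t)) a(t) m P + (2 d(t) - 1) b C
    betaG(t) = 2 (1 - d(t)) b C(t)          (granulocyte output per day)

with a(t) = 1/Tp(t) the HSC proliferation rate (interdivision time Tp
increases strongly with age), b the CMP proliferation rate (1/4 d^-1),
c(t), d(t) the self-renewal probabilities, and m the fraction of committed
flux entering the granulocyte lineage (1/4).

The model is calibrated so the pooled P+C count tracks 1.98e8 cells per kg
of body weight over life: the free coefficients c(t) and d(t) are solved
pointwise from the target trajectories, then the ODEs are re-integrated as
a round-trip check.  Before birth (ages -90..0 d) the pool ramps
geometrically from a small founding count, consistent with the fetal
branching-expansion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .constants import (
    ADULT_WEIGHT_KG,
    BIRTH_WEIGHT_KG,
    B_CMP,
    CELLS_PER_KG,
    DAYS_PER_YEAR,
    FETAL_ONSET_DAYS,
)

__all__ = [
    "BodyGrowthCurve",
    "CompartmentSchedule",
    "CompartmentTrajectory",
    "ConstantTrajectory",
    "body_weight",
    "default_age_grid",
    "hsc_interdivision_time",
    "calibrate_schedule",
    "integrate_compartments",
    "build_reference_trajectory",
]

# Typical body weights (kg) at reference ages; monotone PCHIP through these
# anchors (0 d, 3.4 kg) and (18 yr, ~adult) gives a smooth growth curve.
_WEIGHT_KNOTS_YEARS = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 14.0, 18.0, 25.0])
_WEIGHT_KNOTS_KG = np.array([3.4, 7.5, 10.0, 12.5, 18.0, 32.0, 50.0, 68.0, 75.0])


@dataclass(frozen=True)
class BodyGrowthCurve:
    """Monotone body-weight-for-age curve, birth to adulthood.

    Defaults interpolate typical pediatric weights between the stated birth
    and adult anchors; the knots are rescaled if the anchors are changed.
    Negative ages return ``birth_weight`` (the fetal cell pool is handled
    separately by a geometric ramp, not by body weight).
    """

    birth_weight: float = BIRTH_WEIGHT_KG
    adult_weight: float = ADULT_WEIGHT_KG
    _interp: Callable = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        scale = np.interp(
            _WEIGHT_KNOTS_KG,
            [_WEIGHT_KNOTS_KG[0], _WEIGHT_KNOTS_KG[-1]],
            [self.birth_weight, self.adult_weight],
        )
        interp = PchipInterpolator(_WEIGHT_KNOTS_YEARS * DAYS_PER_YEAR, scale)
        object.__setattr__(self, "_interp", interp)

    def __call__(self, age_days):
        age = np.asarray(age_days, dtype=float)
        clipped = np.clip(age, 0.0, _WEIGHT_KNOTS_YEARS[-1] * DAYS_PER_YEAR)
        w = self._interp(clipped)
        return w if w.ndim else float(w)

    def derivative(self, age_days):
        """dW/dt in kg/day (zero outside the growth window)."""
        age = np.asarray(age_days, dtype=float)
        t_max = _WEIGHT_KNOTS_YEARS[-1] * DAYS_PER_YEAR
        inside = (age >= 0.0) & (age <= t_max)
        dw = np.where(inside, self._interp.derivative()(np.clip(age, 0.0, t_max)), 0.0)
        return dw if dw.ndim else float(dw)


def body_weight(age_days, curve: BodyGrowthCurve | None = None):
    """Body weight (kg) at the given age in days."""
    return (curve or BodyGrowthCurve())(age_days)


def hsc_interdivision_time(
    age_days,
    tp_birth: float = 2.5,
    tp_adult: float = 280.0,
    maturation_years: float = 18.0,
):
    """Default HSC interdivision-time profile Tp(t), days.

    Log-linear slowing from a few days around birth to hundreds of days in
    adults (telomere-attrition-based estimates), constant thereafter.
    """
    age = np.asarray(age_days, dtype=float)
    frac = np.clip(age / (maturation_years * DAYS_PER_YEAR), 0.0, 1.0)
    tp = tp_birth * (tp_adult / tp_birth) ** frac
    return tp if tp.ndim else float(tp)


@dataclass
class CompartmentSchedule:
    """Time-varying rates of the two-compartment model.

    ``a``, ``c``, ``d`` are callables of age (days); ``b`` is the CMP
    proliferation rate (constant by default; pass a callable to vary it)
    and ``m`` the granulocyte-lineage fraction of the committed flux.
    """

    a: Callable
    c: Callable
    d: Callable
    b: float | Callable = B_CMP
    m: float = 0.25

    def b_at(self, t):
        return self.b(t) if callable(self.b) else self.b


@dataclass
class CompartmentTrajectory:
    """Age-indexed compartment counts and granulocyte output rate."""

    ages: np.ndarray          # days; starts at the fetal marrow onset (-90)
    P: np.ndarray             # HSC count
    C: np.ndarray             # CMP count
    G_out: np.ndarray         # granulocyte production rate per day
    weight: np.ndarray        # body weight, kg (birth weight before age 0)
    schedule: CompartmentSchedule | None = None

    def cmp_count(self, t):
        """CMP count at arbitrary ages (log-linear interpolation)."""
        return np.exp(np.interp(t, self.ages, np.log(self.C)))

    def cmp_growth_rate(self, t):
        """d ln C / dt at arbitrary ages (per day)."""
        logc = np.log(self.C)
        grad = np.gradient(logc, self.ages)
        return np.interp(t, self.ages, grad)

    @property
    def pool(self) -> np.ndarray:
        return self.P + self.C


@dataclass(frozen=True)
class ConstantTrajectory:
    """Constant-size stand-in trajectory (testing and small-N checks)."""

    N: float
    t_start: float = 0.0

    def cmp_count(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.N)

    def cmp_growth_rate(self, t):
        return np.zeros_like(np.asarray(t, dtype=float))


def default_age_grid(t_max_years: float = 60.0) -> np.ndarray:
    """Age grid (days): daily through age 2, coarsening geometrically after."""
    fetal = np.arange(FETAL_ONSET_DAYS, 0.0, 1.0)
    infancy = np.arange(0.0, 2.0 * DAYS_PER_YEAR, 1.0)
    later = np.geomspace(2.0 * DAYS_PER_YEAR, t_max_years * DAYS_PER_YEAR, 400)
    return np.unique(np.concatenate([fetal, infancy, later]))


def calibrate_schedule(
    curve: BodyGrowthCurve | None = None,
    hsc_fraction: float = 1e-3,
    hsc_slowing_profile: Callable = hsc_interdivision_time,
    b: float = B_CMP,
    m: float = 0.25,
    ages: np.ndarray | None = None,
    pool_density: float = CELLS_PER_KG,
    fetal_start_pool: float = 10.0,
) -> tuple[CompartmentSchedule, CompartmentTrajectory]:
    """Solve pointwise for c(t), d(t) so that P+C tracks the body-weight pool.

    Targets: ``P = hsc_fraction * pool(t)``, ``C = (1-hsc_fraction) * pool(t)``
    with ``pool(t) = pool_density * weight(t)`` after birth and a geometric
    ramp from ``fetal_start_pool`` over the prenatal window.  Given the HSC
    slowing profile ``Tp(t)`` (so ``a = 1/Tp``; the prenatal division rate
    comes from the ramp itself), the P equation yields
    ``c = (1 + (dlnP/dt)/a)/2`` and the C equation yields ``d``.  Values are
    clipped to [0, 1]; a sustained clip raises an error since the target
    would then be untrackable.

    Returns the schedule and the target trajectory (for round-trip checks).
    """
    curve = curve or BodyGrowthCurve()
    if ages is None:
        ages = default_age_grid()
    ages = np.asarray(ages, dtype=float)

    t_fetal0 = min(ages[0], 0.0)
    birth_pool = pool_density * curve(0.0)
    lam_f = (
        np.log(birth_pool / fetal_start_pool) / (0.0 - t_fetal0)
        if t_fetal0 < 0
        else 0.0
    )

    def pool_fn(t):
        t = np.asarray(t, dtype=float)
        post = pool_density * np.asarray(curve(np.maximum(t, 0.0)))
        fetal = birth_pool * np.exp(lam_f * np.minimum(t, 0.0))
        return np.where(t < 0, fetal, post)

    def dlnpool_fn(t):
        t = np.asarray(t, dtype=float)
        w = np.asarray(curve(np.maximum(t, 0.0)))
        post = np.asarray(curve.derivative(np.maximum(t, 0.0))) / w
        return np.where(t < 0, lam_f, post)

    def a_fn(t):
        t = np.asarray(t, dtype=float)
        post = 1.0 / np.asarray(hsc_slowing_profile(np.maximum(t, 0.0)))
        return np.where(t < 0, lam_f, post)

    def c_fn(t):
        return np.clip(0.5 * (1.0 + dlnpool_fn(t) / a_fn(t)), 0.0, 1.0)

    def d_fn(t):
        pool = pool_fn(t)
        P = hsc_fraction * pool
        C = (1.0 - hsc_fraction) * pool
        dC = (1.0 - hsc_fraction) * pool * dlnpool_fn(t)
        influx = 2.0 * (1.0 - c_fn(t)) * a_fn(t) * m * P
        return np.clip(0.5 * (1.0 + (dC - influx) / (b * C)), 0.0, 1.0)

    pool = pool_fn(ages)
    P_target = hsc_fraction * pool
    C_target = (1.0 - hsc_fraction) * pool

    # feasibility: the clip must not bind over a sustained window
    c_raw = 0.5 * (1.0 + dlnpool_fn(ages) / a_fn(ages))
    dC = C_target * dlnpool_fn(ages)
    influx = 2.0 * (1.0 - np.clip(c_raw, 0, 1)) * a_fn(ages) * m * P_target
    d_raw = 0.5 * (1.0 + (dC - influx) / (b * C_target))
    for name, raw in (("c", c_raw), ("d", d_raw)):
        bad = (raw < -1e-9) | (raw > 1 + 1e-9)
        if bad.mean() > 0.05:
            raise ValueError(
                f"self-renewal probability {name} leaves [0,1] over a "
                f"sustained age window (first at {ages[bad][0]:.0f} d); "
                "the requested pool trajectory is not trackable"
            )
    c = np.clip(c_raw, 0.0, 1.0)
    d = np.clip(d_raw, 0.0, 1.0)

    schedule = CompartmentSchedule(a=a_fn, c=c_fn, d=d_fn, b=b, m=m)
    target = CompartmentTrajectory(
        ages=ages,
        P=P_target,
        C=C_target,
        G_out=2.0 * (1.0 - d) * b * C_target,
        weight=np.asarray(curve(np.maximum(ages, 0.0))),
        schedule=schedule,
    )
    return schedule, target


def integrate_compartments(
    schedule: CompartmentSchedule,
    ages: np.ndarray,
    P0: float,
    C0: float,
    rtol: float = 1e-8,
) -> CompartmentTrajectory:
    """Integrate the compartment ODEs over ``ages`` from (P0, C0).

    Raises if the schedule drives either compartment negative, reporting
    the first offending age.
    """
    ages = np.asarray(ages, dtype=float)

    def rhs(t, y):
        P, C = y
        a, c, d = schedule.a(t), schedule.c(t), schedule.d(t)
        b = schedule.b_at(t)
        dP = (2.0 * c - 1.0) * a * P
        dC = 2.0 * (1.0 - c) * a * schedule.m * P + (2.0 * d - 1.0) * b * C
        return [dP, dC]

    sol = solve_ivp(
        rhs,
        (ages[0], ages[-1]),
        [P0, C0],
        t_eval=ages,
        rtol=rtol,
        atol=1e-12 * max(P0 + C0, 1.0),
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"compartment integration failed: {sol.message}")
    P, C = sol.y
    for name, arr in (("P", P), ("C", C)):
        neg = arr <= 0
        if neg.any():
            raise ValueError(
                f"{name} becomes non-positive at age {ages[neg][0]:.1f} d"
            )
    d = schedule.d(ages)
    b = schedule.b_at(ages) if callable(schedule.b) else schedule.b
    weight = np.maximum(
        BodyGrowthCurve()(np.maximum(ages, 0.0)), 0.0
    )
    return CompartmentTrajectory(
        ages=ages,
        P=P,
        C=C,
        G_out=2.0 * (1.0 - d) * b * C,
        weight=weight,
        schedule=schedule,
    )


def build_reference_trajectory(
    t_max_years: float = 60.0, **calibrate_kwargs
) -> CompartmentTrajectory:
    """Calibrate the default schedule and return the integrated trajectory."""
    ages = default_age_grid(t_max_years)
    schedule, target = calibrate_schedule(ages=ages, **calibrate_kwargs)
    return integrate_compartments(schedule, ages, target.P[0], target.C[0])
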