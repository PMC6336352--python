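"""Experimental estimation of the selection coefficient of CSF3R mutants.

Two readouts of Ba/F3 cells expressing the wild-type (Type I) or truncated
(D715) receptor under G-CSF underpin the estimate:

* **Cell-cycle (G1/G0) fractions.**  With constant interdivision time ``T``,
  constant G1/G0 residence time ``T1`` and division efficiency ``alpha``
  (probability a daughter re-enters the cycle), growth is asymptotically
  exponential at rate ``lambda = ln(2 alpha)/T`` and the G1/G0 fraction is
  ``phi = (1 - e^{-lambda T1}) / (1 - e^{-lambda T})``.  Inverting for
  ``psi = T1/T``, attributing the whole interdivision-time difference
  between the two lines to G1 shortening ``Delta`` gives
  ``Delta = T (psi - psi*) / (1 - psi*)``, hence the mutant growth rate
  ``lambda* = ln(2 alpha*)/(T - Delta)`` and the Moran selection
  coefficient ``s = lambda*/lambda - 1``.

* **Dose-response (MTT) curves.**  Absorbance-vs-dose data for both lines
  are fitted jointly by Hill-type sigmoids sharing a baseline ``y0``::

      y = y0 + a (ln x - c)^n / ((ln x - c)^n + b^n)

  The crossing dose of the two fitted curves separates the regime where the
  mutant proliferates faster (above) from neutral/disadvantageous (below);
  one-sided rank tests on the raw points, split at that threshold, assess
  the difference nonparametrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CellCycleObservation",
    "SelectionEstimate",
    "HillCurve",
    "DoseResponseData",
    "growth_rate",
    "g1_fraction",
    "psi_from_phi",
    "delta_from_psi",
    "estimate_selection",
    "fit_hill",
    "crossing_concentration",
    "split_rank_test",
]


@dataclass(frozen=True)
class CellCycleObservation:
    """A paired cell-cycle measurement of reference and mutant lines.

    Either the G1/G0 fractions (``phi``, ``phi_star``) or the residence
    ratios (``psi``, ``psi_star``) may be supplied for each line; ratios
    take precedence when both are given.
    """

    phi: float | None = None
    phi_star: float | None = None
    psi: float | None = None
    psi_star: float | None = None
    T: float = 4.0
    alpha: float = 1.0
    alpha_star: float = 1.0

    def __post_init__(self) -> None:
        for name, val in (("phi", self.phi), ("phi_star", self.phi_star)):
            if val is not None and not 0 < val < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")
        for name, a in (("alpha", self.alpha), ("alpha_star", self.alpha_star)):
            if not 0.5 < a <= 1:
                raise ValueError(f"{name} must satisfy 2*{name} > 1 (growth)")
        if self.phi is None and self.psi is None:
            raise ValueError("reference line needs phi or psi")
        if self.phi_star is None and self.psi_star is None:
            raise ValueError("mutant line needs phi_star or psi_star")


@dataclass(frozen=True)
class SelectionEstimate:
    psi: float
    psi_star: float
    Delta: float
    lam: float
    lam_star: float
    s: float


def growth_rate(T: float, alpha: float) -> float:
    """Asymptotic exponential growth rate ``ln(2 alpha)/T`` per day."""
    if 2.0 * alpha <= 1.0:
        raise ValueError("2*alpha must exceed 1 for a growing population")
    if T <= 0:
        raise ValueError("T must be positive")
    return math.log(2.0 * alpha) / T


def g1_fraction(lam: float, T1: float, T: float) -> float:
    """Asymptotic G1/G0 fraction ``(1 - e^{-lam T1}) / (1 - e^{-lam T})``."""
    if not 0 < T1 <= T:
        raise ValueError("need 0 < T1 <= T")
    return math.expm1(-lam * T1) / math.expm1(-lam * T)


def psi_from_phi(phi: float, alpha: float) -> float:
    """Residence ratio ``psi = T1/T`` from the G1/G0 fraction.

    Exact algebraic inverse of :func:`g1_fraction` with
    ``lam = ln(2 alpha)/T``: ``psi = -ln[1 - phi (1 - (2 alpha)^-1)] / ln(2 alpha)``.
    """
    if 2.0 * alpha <= 1.0:
        raise ValueError("2*alpha must exceed 1")
    arg = 1.0 - phi * (1.0 - 1.0 / (2.0 * alpha))
    if arg <= 0:
        raise ValueError("phi too large for this alpha: log argument <= 0")
    return -math.log(arg) / math.log(2.0 * alpha)


def delta_from_psi(psi: float, psi_star: float, T: float) -> float:
    """G1-shortening ``Delta = T (psi - psi*) / (1 - psi*)`` in days."""
    if psi_star >= 1:
        raise ValueError("psi_star must be < 1")
    return T * (psi - psi_star) / (1.0 - psi_star)


def estimate_selection(obs: CellCycleObservation) -> SelectionEstimate:
    """Chain phi -> psi -> Delta -> lambda -> s for a paired observation."""
    psi = obs.psi if obs.psi is not None else psi_from_phi(obs.phi, obs.alpha)
    psi_star = (
        obs.psi_star
        if obs.psi_star is not None
        else psi_from_phi(obs.phi_star, obs.alpha_star)
    )
    delta = delta_from_psi(psi, psi_star, obs.T)
    if delta >= obs.T:
        raise ValueError("Delta >= T: mutant interdivision time would vanish")
    lam = growth_rate(obs.T, obs.alpha)
    lam_star = growth_rate(obs.T - delta, obs.alpha_star)
    return SelectionEstimate(
        psi=psi,
        psi_star=psi_star,
        Delta=delta,
        lam=lam,
        lam_star=lam_star,
        s=lam_star / lam - 1.0,
    )


# --------------------------------------------------------------------------
# Hill-type dose-response fitting


@dataclass(frozen=True)
class HillCurve:
    """Hill-type sigmoid on the log-dose axis (doses in ng/ml)."""

    y0: float
    a: float
    b: float
    c: float
    n: float

    def __call__(self, x):
        lx = np.log(np.asarray(x, dtype=float)) - self.c
        if np.any(lx <= 0):
            raise ValueError("curve not evaluable: ln(x) <= c")
        t = lx**self.n
        y = self.y0 + self.a * t / (t + self.b**self.n)
        return y if y.ndim else float(y)


@dataclass(frozen=True)
class DoseResponseData:
    """Replicate absorbance readings per dose for one cell line."""

    doses: np.ndarray        # (k,) ng/ml, positive
    absorbance: np.ndarray   # (k, r) replicate readings
    label: str = ""

    def __post_init__(self) -> None:
        doses = np.atleast_1d(np.asarray(self.doses, dtype=float))
        absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if np.any(doses <= 0):
            raise ValueError("doses must be positive (log scale)")
        if len(np.unique(doses)) < 3:
            raise ValueError("need at least 3 distinct doses")
        if absorbance.shape[0] != doses.shape[0]:
            raise ValueError("absorbance must have one row per dose")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "absorbance", absorbance)

    def long(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (dose, value) pairs."""
        r = self.absorbance.shape[1]
        return np.repeat(self.doses, r), self.absorbance.ravel()


def _hill_values(lx, a, b, c, n):
    t = (lx - c) ** n
    return a * t / (t + b**n)


def fit_hill(
    data_ref: DoseResponseData,
    data_mut: DoseResponseData,
    n_max: float = 50.0,
) -> tuple[HillCurve, HillCurve, float]:
    """Joint least-squares Hill fit with a baseline shared across lines.

    One optimisation over (y0, a, b, c, n, a*, b*, c*, n*): the baseline
    absorbance y0 is common to both curves, amplitude/shape parameters are
    per line.  Multi-started from a grid of log-dose offsets and Hill
    exponents; the best residual sum of squares wins.  The exponent is
    bounded in (0, ``n_max``].

    Returns ``(curve_ref, curve_mut, rss)``.
    """
    if len(data_ref.doses) < 5 or len(data_mut.doses) < 5:
        raise ValueError("need >= 5 doses per group")
    xr, yr = data_ref.long()
    xm, ym = data_mut.long()
    lxr, lxm = np.log(xr), np.log(xm)
    lx_min = min(lxr.min(), lxm.min())

    def residuals(p):
        y0 = p[0]
        ar, br, cr, nr = p[1:5]
        am, bm, cm, nm = p[5:9]
        return np.concatenate(
            [
                y0 + _hill_values(lxr, ar, br, cr, nr) - yr,
                y0 + _hill_values(lxm, am, bm, cm, nm) - ym,
            ]
        )

    y_all = np.concatenate([yr, ym])
    y0_guess = float(y_all.min())
    amp_r = max(float(yr.max() - yr.min()), 1e-6)
    amp_m = max(float(ym.max() - ym.min()), 1e-6)
    # half-rise dose guess: dose whose mean is closest to mid-amplitude
    mid_r = np.log(xr[np.argmin(np.abs(yr - (yr.min() + amp_r / 2)))])
    mid_m = np.log(xm[np.argmin(np.abs(ym - (ym.min() + amp_m / 2)))])

    lo = [-np.inf, 0.0, 1e-3, -200.0, 1e-3, 0.0, 1e-3, -200.0, 1e-3]
    hi = [np.inf, 10.0, 1e3, lx_min - 0.5, n_max, 10.0, 1e3, lx_min - 0.5, n_max]

    best = None
    for offset in (2.0, 8.0, 16.0, 25.0):
        for n0 in (3.0, 10.0, 25.0):
            c0 = lx_min - offset
            p0 = [
                y0_guess,
                amp_r,
                mid_r - c0,
                c0,
                n0,
                amp_m,
                mid_m - c0,
                c0,
                n0,
            ]
            try:
                sol = optimize.least_squares(
                    residuals, p0, bounds=(lo, hi), max_nfev=5000
                )
            except ValueError:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")
    rss, p = best
    curve_ref = HillCurve(p[0], *p[1:5])
    curve_mut = HillCurve(p[0], *p[5:9])
    return curve_ref, curve_mut, rss


def crossing_concentration(
    curve1: HillCurve, curve2: HillCurve, bracket: tuple[float, float] = (0.01, 10.0)
) -> float:
    """Dose at which two fitted curves cross, by root bracketing."""
    f = lambda x: curve1(x) - curve2(x)
    lo, hi = bracket
    if f(lo) * f(hi) >= 0:  # includes identical curves (difference == 0)
        raise ValueError(
            f"curves do not cross inside the bracket ({lo}, {hi}) ng/ml"
        )
    return float(optimize.brentq(f, lo, hi))


def split_rank_test(
    data_ref: DoseResponseData,
    data_mut: DoseResponseData,
    threshold: float = 0.1,
) -> tuple[float, float]:
    """One-sided rank tests of mutant vs reference, split at a dose threshold.

    Above ``threshold`` the alternative is mutant > reference (``p_high``);
    at or below it, reference > mutant (``p_low``).  Exact enumeration is
    used for untied strata with at most 10 points per group, otherwise the
    midrank normal approximation without continuity correction (so
    identical samples give exactly 0.5).
    """
    out = []
    for side, alternative in (("high", "greater"), ("low", "less")):
        pick = (lambda d: d > threshold) if side == "high" else (lambda d: d <= threshold)
        vals = []
        for data in (data_ref, data_mut):
            x, y = data.long()
            sel = pick(x)
            if sel.sum() < 3:
                raise ValueError(
                    f"stratum '{side}' (doses {'>' if side == 'high' else '<='} "
                    f"{threshold} ng/ml) has fewer than 3 points in group "
                    f"'{data.label or 'unnamed'}'"
                )
            vals.append(y[sel])
        ref, mut = vals
        pooled = np.concatenate([mut, ref])
        if np.all(pooled == pooled[0]):
            out.append(0.5)  # fully degenerate stratum: no evidence either way
            continue
        ties = len(np.unique(pooled)) < len(pooled)
        method = (
            "exact" if not ties and max(len(ref), len(mut)) <= 10 else "asymptotic"
        )
        res = stats.mannwhitneyu(
            mut, ref, alternative=alternative, method=method, use_continuity=False
        )
        out.append(float(res.pvalue))
    return out[0], out[1]
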