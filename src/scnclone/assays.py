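"""Synthetic generators emulating the wet-lab assay readouts.

Two small generators stand in for the experimental data streams the
selection-inference module consumes:

* an MTT-style dose-response generator (triplicate absorbance readings on a
  log-spaced G-CSF dose grid, Hill-curve means plus Gaussian read noise),
  whose default curve coefficients are the published fits for the Type I
  and D715 receptor lines; and

* a flow-cytometry-style G1/G0 time series (percentage of cells in G1/G0
  sampled over hours after release from a starvation block, with an initial
  transient decaying to line-specific asymptotes and binomial counting
  noise from a finite number of gated cells).

Both are seed-reproducible and form closed loops with the estimators: data
generated at the defaults can be fitted back to the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import (
    CellCycleObservation,
    DoseResponseData,
    HillCurve,
    SelectionEstimate,
    estimate_selection,
)

__all__ = [
    "AssayGeneratorConfig",
    "G1SeriesConfig",
    "REFERENCE_HILL",
    "MUTANT_HILL",
    "generate_dose_response",
    "generate_g1_series",
    "selection_from_g1_series",
]

#: Published joint-fit coefficients (shared baseline) used as generator truth.
REFERENCE_HILL = HillCurve(y0=0.349, a=0.449, b=20.802, c=-23.309, n=11.149)
MUTANT_HILL = HillCurve(y0=0.349, a=0.479, b=21.075, c=-23.278, n=28.255)


@dataclass(frozen=True)
class AssayGeneratorConfig:
    """Dose-response generator settings (doses ng/ml, absorbance a.u.)."""

    hill_ref: HillCurve = REFERENCE_HILL
    hill_mut: HillCurve = MUTANT_HILL
    noise_sd: float = 0.02
    doses: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-3, 1e3, 13)
    )
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class G1SeriesConfig:
    """G1/G0 time-series generator settings (percentages, times in hours).

    Defaults emulate the 100 ng/ml G-CSF condition: asymptotic G1/G0
    percentages separated by 6.05 points (use 4.28 for the 50 ng/ml
    condition); the series starts near the starvation-arrest level and
    relaxes over ``transient_h`` hours.
    """

    phi_ref: float = 70.0
    phi_mut: float = 63.95
    start_level: float = 85.0
    transient_h: float = 1.0
    times_h: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 10.5, 0.5)
    )
    cells_per_sample: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("phi_ref", self.phi_ref), ("phi_mut", self.phi_mut)):
            if not 0 < v < 100:
                raise ValueError(f"{name} must be a percentage in (0, 100)")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")


def generate_dose_response(
    config: AssayGeneratorConfig,
) -> tuple[DoseResponseData, DoseResponseData]:
    """Triplicate absorbance tables for the reference and mutant lines."""
    rng = np.random.default_rng(config.seed)
    out = []
    for curve, label in ((config.hill_ref, "reference"), (config.hill_mut, "mutant")):
        mean = np.asarray(curve(config.doses))
        values = mean[:, None] + config.noise_sd * rng.standard_normal(
            (len(config.doses), config.replicates)
        )
        out.append(DoseResponseData(config.doses, values, label=label))
    return out[0], out[1]


def generate_g1_series(config: G1SeriesConfig) -> pd.DataFrame:
    """Long-form table (time_h, group, g1_percent) of the G1/G0 series.

    The mean relaxes exponentially from ``start_level`` to the group
    asymptote with time constant ``transient_h / 3`` (so the transient is
    essentially over after ``transient_h``); each sample draws the gated
    cell count binomially, so fluctuations shrink as cells_per_sample grows.
    """
    rng = np.random.default_rng(config.seed)
    tau = config.transient_h / 3.0
    rows = []
    for target, group in ((config.phi_ref, "reference"), (config.phi_mut, "mutant")):
        mean = target + (config.start_level - target) * np.exp(
            -config.times_h / tau
        )
        counts = rng.binomial(config.cells_per_sample, mean / 100.0)
        for t, k in zip(config.times_h, counts):
            rows.append(
                {
                    "time_h": t,
                    "group": group,
                    "g1_percent": 100.0 * k / config.cells_per_sample,
                }
            )
    return pd.DataFrame(rows)


def selection_from_g1_series(
    series: pd.DataFrame,
    T: float = 4.0,
    alpha: float = 1.0,
    alpha_star: float = 1.0,
    transient_h: float = 1.0,
) -> SelectionEstimate:
    """Estimate s from a generated (or measured) G1/G0 series.

    Post-transient samples (time > ``transient_h``) are averaged per group
    to give the phi pair fed into the cell-cycle inference chain.
    """
    post = series[series["time_h"] > transient_h]
    means = post.groupby("group")["g1_percent"].mean()
    obs = CellCycleObservation(
        phi=means["reference"] / 100.0,
        phi_star=means["mutant"] / 100.0,
        T=T,
        alpha=alpha,
        alpha_star=alpha_star,
    )
    return estimate_selection(obs)
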