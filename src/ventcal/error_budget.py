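"""Propagation of sensor errors through the O2-uptake equation.

VO2 = (R * FIO2 - FEO2) * VE with VE held fixed.  Independent relative
errors sigma_R (ratio measurement) and sigma_O2 (expired O2 reading)
propagate first-order in quadrature:

    rel_err(VO2) = sqrt((sigma_R * R * FIO2)^2 + (sigma_O2 * FEO2)^2)
                   / (R * FIO2 - FEO2)

The denominator is the O2 extraction; because extraction is a small
difference of near-unity operands at high FIO2, fractional errors of a few
tenths of a percent in the operands blow up to several percent of VO2.  A
seeded Monte Carlo of the same two perturbations cross-checks the analytic
delta-method result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .metabolism import vo2 as _vo2

__all__ = [
    "ErrorModel",
    "MonteCarloSummary",
    "analytic_vo2_relative_error",
    "monte_carlo_vo2_error",
    "error_vs_fio2_profile",
    "DEFAULT_SEED",
]

#: Default RNG seed recorded in output metadata.
DEFAULT_SEED = 20210617


@dataclass(frozen=True)
class ErrorModel:
    """Independent multiplicative (1-sigma relative) sensor errors.

    ``sigma_r_rel`` applies to the ratio measurement R, ``sigma_o2_rel`` to
    O2 readings; "+/- x%" specifications are interpreted as 1-sigma.
    """

    sigma_r_rel: float = 0.003
    sigma_o2_rel: float = 0.002
    n_draws: int = 100_000
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.sigma_r_rel < 0 or self.sigma_o2_rel < 0:
            raise DomainError("sigmas must be non-negative")
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")


@dataclass(frozen=True)
class MonteCarloSummary:
    """Relative-scale summary of Monte-Carlo VO2 perturbations."""

    mean_rel: float
    sd_rel: float
    ci95_half_width_rel: float
    n_draws: int
    seed: int
    low_n_warning: bool = False


def analytic_vo2_relative_error(
    r: float, fio2: float, feo2: float, model: ErrorModel
) -> float:
    """First-order relative error of VO2 under independent R and FEO2 errors.

    Zero iff both sigmas are zero.  The inspired fraction is treated as a
    set value; its sensor error is not separately propagated (the expired
    reading dominates the O2 term at matched relative error).
    """
    extraction = r * fio2 - feo2
    if extraction <= 0:
        raise DomainError(f"degenerate extraction r*fio2 - feo2 = {extraction:.6f}")
    return (
        sqrt((model.sigma_r_rel * r * fio2) ** 2 + (model.sigma_o2_rel * feo2) ** 2)
        / extraction
    )


def monte_carlo_vo2_error(
    r: float, fio2: float, feo2: float, ve: float, model: ErrorModel
) -> MonteCarloSummary:
    """Monte-Carlo cross-check of :func:`analytic_vo2_relative_error`.

    Draws independent multiplicative Gaussian perturbations of R and of the
    expired O2 reading, recomputes VO2, and summarizes the relative
    deviations from the unperturbed value.  Deterministic for a given seed.
    """
    vo2_true = _vo2(r, fio2, feo2, ve)
    rng = np.random.default_rng(model.seed)
    r_draws = r * (1.0 + model.sigma_r_rel * rng.standard_normal(model.n_draws))
    feo2_draws = feo2 * (1.0 + model.sigma_o2_rel * rng.standard_normal(model.n_draws))
    vo2_draws = (r_draws * fio2 - feo2_draws) * ve
    rel = vo2_draws / vo2_true - 1.0
    lo, hi = np.quantile(rel, [0.025, 0.975])
    return MonteCarloSummary(
        mean_rel=float(rel.mean()),
        sd_rel=float(rel.std(ddof=1)) if model.n_draws > 1 else 0.0,
        ci95_half_width_rel=float(hi - lo) / 2.0,
        n_draws=model.n_draws,
        seed=model.seed,
        low_n_warning=model.n_draws < 100,
    )


def error_vs_fio2_profile(
    model: ErrorModel,
    fio2_grid: Sequence[float],
    extraction: float,
    r: float = 1.0,
    with_monte_carlo: bool = False,
    ve: float = 180.0,
) -> pd.DataFrame:
    """Relative VO2 error over a grid of inspired O2 fractions.

    The O2 extraction (r*fio2 - feo2) is held fixed, so feo2 tracks fio2
    along the grid; the resulting error is monotone non-decreasing in fio2.
    Returns columns ``fio2, extraction, analytic_rel_err[, mc_rel_err],
    n_draws, seed``.
    """
    if extraction <= 0:
        raise DomainError("extraction must be positive")
    rows = []
    for fio2 in fio2_grid:
        feo2 = r * fio2 - extraction
        if feo2 < 0:
            raise DomainError(
                f"fio2 {fio2} below extraction {extraction}: grid must lie in (extraction, 1]"
            )
        row = {
            "fio2": fio2,
            "extraction": extraction,
            "analytic_rel_err": analytic_vo2_relative_error(r, fio2, feo2, model),
        }
        if with_monte_carlo:
            row["mc_rel_err"] = monte_carlo_vo2_error(r, fio2, feo2, ve, model).sd_rel
        row["n_draws"] = model.n_draws
        row["seed"] = model.seed
        rows.append(row)
    return pd.DataFrame(rows)
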