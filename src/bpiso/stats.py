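"""Study-level statistics: condition regressions, correlation matrices,
Bartlett's variance test, experiment summaries, and the water-H mass
balance.

These operations sit on top of the reduced per-treatment results: does a
manipulated condition (temperature, pH, doubling time, ...) shift the
lipid/water fractionation; how do growth, cyclization, and fractionation
covary; is the spread of ε values in one group of organisms narrower than
another; and what fraction of lipid H is sourced from growth water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import IsotopeValue, TreatmentResult
from .exceptions import FittingError, MassBalanceError

__all__ = [
    "RegressionSummary",
    "MassBalanceResult",
    "condition_regression",
    "correlation_matrix",
    "bartlett_homogeneity",
    "water_h_fraction",
    "summarize_experiment",
    "ExperimentSummary",
]


@dataclass
class RegressionSummary:
    """OLS slope of ε (or any response) on a condition level."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of range: {self.r_squared}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")
        self.significant = self.p_value < 0.05


def condition_regression(
    x: Sequence[float], y: Sequence[float], labels: Optional[Sequence[str]] = None
) -> RegressionSummary:
    """Ordinary least squares of a response on a condition level.

    Two-sided t test on the slope; significance flagged at α = 0.05.
    ``labels`` (treatment names) are accepted for error messages only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise FittingError(f"need >= 3 points for a condition regression, got {x.size}")
    if np.ptp(x) == 0:
        raise FittingError("condition level is constant; regression undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if not np.isfinite(p):  # perfectly collinear data
        p = 0.0
    return RegressionSummary(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        p_value=min(max(p, 0.0), 1.0),
        n=int(x.size),
    )


#: significance star thresholds used in correlation reports
STAR_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for thresh, mark in STAR_THRESHOLDS:
        if p < thresh:
            return mark
    return ""


def correlation_matrix(variables: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p values and stars.

    Returns a tidy frame (var_a, var_b, r, p, stars, n). Pairs need at
    least 3 complete rows; a zero-variance column yields NaN r/p for its
    pairs (reported as undefined, not an error).
    """
    df = pd.DataFrame(variables)
    names = list(df.columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            pair = df[[a, b]].dropna() if a != b else df[[a]].dropna()
            n = len(pair)
            if a == b:
                va = np.asarray(pair[a], dtype=float)
                r, p = (1.0, 0.0) if np.ptp(va) > 0 else (float("nan"), float("nan"))
            elif n < 3 or np.ptp(pair[a]) == 0 or np.ptp(pair[b]) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = sps.pearsonr(pair[a], pair[b])
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "r": float(r),
                    "p": float(p),
                    "stars": _stars(p) if np.isfinite(p) else "",
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def bartlett_homogeneity(*groups: Sequence[float]) -> tuple[float, float]:
    """Bartlett's K² test for homogeneity of variances across groups.

    Returns (K², p) where K² has k−1 degrees of freedom under the null of
    equal variances. Each group needs n >= 2 and non-zero variance.
    """
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance; K² undefined")
    stat, p = sps.bartlett(*arrays)
    return float(stat), float(p)


@dataclass
class MassBalanceResult:
    """Two-endmember water/substrate apportionment of lipid hydrogen."""

    f_water: float
    f_water_sigma: float
    substrate_delta: float
    assumptions: dict

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.f_water <= 1.0 + 1e-9):
            raise ValueError(
                f"water H fraction {self.f_water:.4f} outside [0, 1]; "
                "check the endmember assumptions"
            )


def water_h_fraction(
    delta_lipid: IsotopeValue,
    delta_water: IsotopeValue,
    delta_substrate: IsotopeValue,
    eps_water_path: float,
    eps_substrate_path: float,
    lower_bound_mode: bool = False,
) -> MassBalanceResult:
    """Fraction of lipid H sourced from growth water, by linear mixing.

    δ_L = f_w·(δ_W + ε_w) + (1 − f_w)·(δ_S + ε_s), solved for f_w. The
    path fractionations ε_w and ε_s must be supplied explicitly — they
    are model assumptions, not measurements. ``lower_bound_mode`` sets
    ε_s = 0, the "at least this much water H" reading: any real
    (negative) substrate-path fractionation would push f_w higher.
    σ is first-order in the three isotope inputs.
    """
    eps_s = 0.0 if lower_bound_mode else eps_substrate_path
    end_w = delta_water.value + eps_water_path
    end_s = delta_substrate.value + eps_s
    denom = end_w - end_s
    if abs(denom) < 1e-9:
        raise MassBalanceError(
            "water and substrate endmembers coincide; f_water unidentifiable"
        )
    f = (delta_lipid.value - end_s) / denom
    # ∂f/∂δ_L = 1/Δ ; ∂f/∂δ_W = −f/Δ ; ∂f/∂δ_S = (f − 1)/Δ
    sigma = (
        math.sqrt(
            delta_lipid.sigma**2
            + (f * delta_water.sigma) ** 2
            + ((1.0 - f) * delta_substrate.sigma) ** 2
        )
        / abs(denom)
    )
    return MassBalanceResult(
        f_water=float(np.clip(f, 0.0, 1.0)),
        f_water_sigma=sigma,
        substrate_delta=delta_substrate.value,
        assumptions={
            "eps_water_path": eps_water_path,
            "eps_substrate_path": eps_s,
            "lower_bound_mode": lower_bound_mode,
        },
    )


@dataclass
class ExperimentSummary:
    """Ranges and pooled statistics over the treatments of one experiment."""

    experiment: str
    n_treatments: int
    epsilon_range: float  # ‰, max − min of weighted ε
    epsilon_mean: float
    epsilon_sd: float
    ri_range: tuple[float, float]
    d2h_range: tuple[float, float]
    mean_ring_difference: float  # ‰/ring, mean of treatment ring slopes


def summarize_experiment(
    results: Sequence[TreatmentResult], experiment: str = ""
) -> ExperimentSummary:
    """Summary statistics over a set of treatment results.

    Ranges are over treatment-level abundance-weighted values; the pooled
    mean/SD treat treatments as equal units; the mean ring difference
    averages each treatment's ε-on-ring slope. Order invariant.
    """
    if not results:
        raise ValueError("summarize_experiment needs at least one treatment")
    eps = np.array([r.weighted_epsilon.value for r in results])
    d2h = np.array([r.weighted_d2H.value for r in results])
    ri = np.array([r.ring_index for r in results])
    slopes = np.array(
        [
            r.mean_ring_difference.value
            for r in results
            if r.mean_ring_difference is not None
        ]
    )
    return ExperimentSummary(
        experiment=experiment or results[0].experiment,
        n_treatments=len(results),
        epsilon_range=float(eps.max() - eps.min()),
        epsilon_mean=float(eps.mean()),
        epsilon_sd=float(eps.std(ddof=1)) if len(eps) > 1 else 0.0,
        ri_range=(float(ri.min()), float(ri.max())),
        d2h_range=(float(d2h.min()), float(d2h.max())),
        mean_ring_difference=float(slopes.mean()) if slopes.size else float("nan"),
    )
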